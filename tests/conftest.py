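import numpy as np
import pandas as pd
import pytest

from mlpacall import assay


@pytest.fixture(scope="session")
def probes():
    return {p.probe_id: p for p in assay.fcgr3b_probes()}


@pytest.fixture(scope="session")
def wt_allele():
    return assay.synthetic_promoter_reference()


@pytest.fixture(scope="session")
def mut_allele():
    return assay.mutant_allele()


def make_peak_table(heights: dict[str, dict[str, float]], batch: str = "batch0") -> pd.DataFrame:
    """heights: sample_id -> probe_id -> peak_height."""
    rows = [
        {"sample_id": s, "probe_id": p, "peak_height": h, "batch": batch}
        for s, probes in heights.items()
        for p, h in probes.items()
    ]
    return pd.DataFrame(rows)
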