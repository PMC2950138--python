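"""End-to-end convenience wrappers: peaks -> ratios -> calls -> genotypes."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import assay
from .caller import ClusterModel, call_samples, fit_ratio_clusters
from .genotype import derive_genotypes
from .normalize import QC_PASS, normalize_peaks


def call_cohort(
    peaks: pd.DataFrame,
    control_probes: Sequence[str] = assay.CONTROL_GENES,
    probe_ids: Sequence[str] | None = None,
    max_cn: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, ClusterModel], dict[str, pd.DataFrame]]:
    """Normalize a peak table and call integer CN for the requested probes.

    Returns ``(ratios, models, calls)`` where ``models`` and ``calls`` are
    keyed by probe id.  Only QC-passing samples enter the mixture fit;
    failed samples stay in the call tables with NA calls.
    """
    ratios = normalize_peaks(peaks, control_probes)
    if probe_ids is None:
        probe_ids = sorted(set(ratios["probe_id"]))
    models: dict[str, ClusterModel] = {}
    calls: dict[str, pd.DataFrame] = {}
    for pid in probe_ids:
        sub = ratios[ratios["probe_id"] == pid]
        passing = sub[sub["qc_flag"] == QC_PASS]
        model = fit_ratio_clusters(
            passing["normalized_ratio"].to_numpy(float),
            probe_id=pid,
            max_cn=max_cn,
            seed=seed,
        )
        models[pid] = model
        calls[pid] = call_samples(model, sub)
    return ratios, models, calls


def genotype_cohort(
    calls_wt_probe: pd.DataFrame, calls_total_probe: pd.DataFrame
) -> pd.DataFrame:
    """Pair per-probe call tables by sample and derive indel genotypes."""
    pairs = calls_wt_probe[["sample_id", "cn"]].rename(columns={"cn": "cn_wt_probe"}).merge(
        calls_total_probe[["sample_id", "cn"]].rename(columns={"cn": "cn_total_probe"}),
        on="sample_id",
        how="inner",
    )
    return derive_genotypes(pairs)


def mlpa_to_genotypes(
    peaks: pd.DataFrame,
    control_probes: Sequence[str] = assay.CONTROL_GENES,
    wt_probe: str = assay.PROBE_WT_ONLY,
    total_probe: str = assay.PROBE_TOTAL,
    max_cn: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, ClusterModel], dict[str, pd.DataFrame], pd.DataFrame]:
    """Full MLPA pipeline: normalize, call both informative probes, genotype."""
    ratios, models, calls = call_cohort(
        peaks, control_probes, probe_ids=[wt_probe, total_probe], max_cn=max_cn, seed=seed
    )
    genotypes = genotype_cohort(calls[wt_probe], calls[total_probe])
    return ratios, models, calls, genotypes
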