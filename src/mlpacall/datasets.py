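"""Published count tables from the originating FCGR3B case-control study.

The study typed 518 Dutch rheumatoid-arthritis (RA) cases and 304 healthy
Dutch controls by MLPA.  Two count tables were printed and are bundled here
as analysis inputs: per-probe copy-number class counts (one row block per
MLPA probe) and the indel-genotype / allele counts obtained by combining the
total-CN probe with the WT-only probe.  Counts reflect per-probe
missingness: the typed totals differ between probes and fall short of the
enrolled cohort.
"""

from __future__ import annotations

import pandas as pd

N_CASES_ENROLLED = 518
N_CONTROLS_ENROLLED = 304

RA = "RA"
CONTROL = "control"


def probe1_cn_counts() -> pd.DataFrame:
    """Copy-number class counts for the WT-only probe (FCGR3B#1), 0..3 copies."""
    return pd.DataFrame(
        {"0": [54, 43], "1": [175, 113], "2": [179, 98], "3": [10, 1]},
        index=pd.Index([RA, CONTROL], name="status"),
    )


def probe2_cn_counts() -> pd.DataFrame:
    """Copy-number class counts for the total-CN probe (FCGR3B#2)."""
    return pd.DataFrame(
        {"low": [25, 17], "two": [344, 213], "high": [49, 24]},
        index=pd.Index([RA, CONTROL], name="status"),
    )


def probe3_cn_counts() -> pd.DataFrame:
    """Counts for the uninformative probe (FCGR3B#3); almost no CNV signal."""
    return pd.DataFrame(
        {"low": [3, 0], "two": [416, 252], "high": [0, 3]},
        index=pd.Index([RA, CONTROL], name="status"),
    )


def indel_genotype_counts() -> pd.DataFrame:
    """Genotype-class counts (WT>MT / WT=MT / WT<MT) per group."""
    return pd.DataFrame(
        {"WT>MT": [197, 102], "WT=MT": [150, 97], "WT<MT": [63, 51]},
        index=pd.Index([RA, CONTROL], name="status"),
    )


def indel_allele_counts() -> pd.DataFrame:
    """Per-allele counts: every gene copy counted once as MT or WT."""
    return pd.DataFrame(
        {"MT": [306, 207], "WT": [546, 302]},
        index=pd.Index([RA, CONTROL], name="status"),
    )


#: control copy-number class probabilities implied by the total-CN probe
#: (17/254 low, 213/254 two copies, 24/254 high), rounded as reported
CONTROL_CN_CLASS_FREQ = {"low": 0.067, "two": 0.839, "high": 0.094}

#: control mutant-allele frequency implied by the allele counts (207/509)
CONTROL_MT_ALLELE_FREQ = 0.407
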