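"""Case-control association statistics for CNV classes, genotypes and alleles.

Contingency tables are plain pandas DataFrames: rows are phenotype groups
(cases first by convention), columns are copy-number classes, genotype
classes or alleles, cells are nonnegative integer counts.  Odds ratios come
with Woolf (log-normal) confidence intervals and a Haldane-Anscombe
correction for zero cells; chi-square tests are Pearson (no Yates
correction) and Cochran-Mantel-Haenszel for (optionally stratified) 2x2
tables.  No multiple-testing correction is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

METHOD_PEARSON = "pearson"
METHOD_MH = "mantel_haenszel"
METHOD_WOOLF = "woolf_ci"
TAG_HALDANE = "haldane_corrected"


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    statistic: float
    df: int
    p_value: float
    method: str

    def __post_init__(self):
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if (
            np.isfinite(self.odds_ratio)
            and np.isfinite(self.ci_low)
            and not (self.ci_low <= self.odds_ratio <= self.ci_high)
        ):
            raise ValueError("odds ratio outside its confidence interval")


def _as_counts(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise ValueError("counts must be finite and nonnegative")
    return arr


def collapse_to_2x2(
    table: pd.DataFrame, exposed: Sequence[str]
) -> pd.DataFrame:
    """Sum the ``exposed`` columns against the rest, per row.

    Returns a 2-column frame ``[exposed, rest]`` with the input's row index.
    """
    exposed = list(exposed)
    missing = [c for c in exposed if c not in table.columns]
    if missing:
        raise ValueError(f"exposed labels not in table: {missing}")
    rest = [c for c in table.columns if c not in exposed]
    if not rest:
        raise ValueError("exposed columns cover the whole table (degenerate)")
    out = pd.DataFrame(
        {
            "exposed": table[exposed].sum(axis=1),
            "rest": table[rest].sum(axis=1),
        },
        index=table.index,
    )
    return out


def odds_ratio(
    table: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    zero_cell_correction: bool = True,
) -> AssociationResult:
    """Odds ratio of a 2x2 table with a Woolf confidence interval.

    OR = (a*d)/(b*c) for table [[a, b], [c, d]]; CI = exp(ln OR +/- z*sqrt(
    1/a + 1/b + 1/c + 1/d)).  A zero cell triggers the Haldane-Anscombe
    correction (0.5 added to every cell) and tags the method; an all-zero
    row or column is undefined and raises.
    """
    arr = _as_counts(table)
    if arr.shape != (2, 2):
        raise ValueError("odds ratio requires a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row or column: odds ratio undefined")
    method = METHOD_WOOLF
    if (arr == 0).any():
        if not zero_cell_correction:
            raise ValueError("zero cell present and correction disabled")
        arr = arr + 0.5
        method = f"{METHOD_WOOLF}+{TAG_HALDANE}"
    a, b, c, d = arr.ravel()
    or_ = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    return AssociationResult(
        odds_ratio=float(or_),
        ci_low=float(lo),
        ci_high=float(hi),
        statistic=np.nan,
        df=1,
        p_value=np.nan,
        method=method,
    )


def pearson_chi2(table: pd.DataFrame | np.ndarray) -> AssociationResult:
    """Pearson chi-square test of independence, df = (r-1)(c-1), no Yates.

    The odds ratio (with Woolf CI) is attached for 2x2 inputs, NaN otherwise.
    """
    arr = _as_counts(table)
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=False)
    if (expected == 0).any():
        raise ValueError("zero expected count: chi-square undefined")
    if arr.shape == (2, 2):
        orr = odds_ratio(arr)
        or_, lo, hi = orr.odds_ratio, orr.ci_low, orr.ci_high
    else:
        or_ = lo = hi = np.nan
    return AssociationResult(
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        statistic=float(chi2),
        df=int(df),
        p_value=float(p),
        method=METHOD_PEARSON,
    )


def mantel_haenszel(
    strata: Sequence[pd.DataFrame | np.ndarray],
) -> AssociationResult:
    """Cochran-Mantel-Haenszel test and common OR over stratified 2x2 tables.

    Continuity-uncorrected; with a single stratum the statistic equals
    (N-1)/N times the Pearson chi-square.  The CI is the MH log-OR interval.
    """
    arrays = [_as_counts(t) for t in strata]
    if not arrays:
        raise ValueError("need at least one stratum")
    for arr in arrays:
        if arr.shape != (2, 2):
            raise ValueError("every stratum must be 2x2")
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise ValueError("degenerate stratum (zero margin)")
    st = sm.stats.StratifiedTable([a for a in arrays])
    res = st.test_null_odds(correction=False)
    or_ = float(st.oddsratio_pooled)
    lo, hi = st.oddsratio_pooled_confint()
    return AssociationResult(
        odds_ratio=or_,
        ci_low=float(lo),
        ci_high=float(hi),
        statistic=float(res.statistic),
        df=1,
        p_value=float(res.pvalue),
        method=METHOD_MH,
    )


def allelic_test(table: pd.DataFrame | np.ndarray) -> AssociationResult:
    """Association test on a per-allele 2x2 count table (each copy counted once).

    Combines the Woolf-CI odds ratio with the Pearson chi-square p-value.
    """
    arr = _as_counts(table)
    if arr.shape != (2, 2):
        raise ValueError("allelic test requires a 2x2 allele-count table")
    orr = odds_ratio(arr)
    chi = pearson_chi2(arr)
    return AssociationResult(
        odds_ratio=orr.odds_ratio,
        ci_low=orr.ci_low,
        ci_high=orr.ci_high,
        statistic=chi.statistic,
        df=chi.df,
        p_value=chi.p_value,
        method=f"{METHOD_PEARSON}+{orr.method}",
    )


def genotypic_test(table: pd.DataFrame | np.ndarray) -> AssociationResult:
    """Chi-square test over the three genotype classes (2 df for 2 groups)."""
    return pearson_chi2(table)
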