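"""Relative copy-number quantification from qPCR Ct values (delta-delta Ct).

Each sample is assayed in replicate for the target locus and a reference
gene known not to vary in copy number.  With perfect doubling per cycle, the
target-minus-reference Ct difference dCt maps to a relative quantity
Q = 2^(-dCt); copy numbers are obtained by anchoring the cohort mean at two
copies: CN_i = 2 * Q_i / mean(Q).  No efficiency correction is applied.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

DEFAULT_SD_THRESHOLD = 0.5  # cycles; replicate scatter above this flags QC


def aggregate_ct(
    replicates: Sequence[float], sd_threshold: float = DEFAULT_SD_THRESHOLD
) -> tuple[float, bool]:
    """Arithmetic mean of replicate Ct values plus a scatter QC verdict.

    Returns ``(mean_ct, qc_ok)``; ``qc_ok`` is False when the replicate
    standard deviation (ddof=1) exceeds ``sd_threshold`` cycles.  Fewer than
    two finite replicates is an error (the sample should be excluded).
    """
    x = np.asarray(replicates, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need >=2 finite Ct replicates")
    if ((x <= 0) | (x >= 45)).any():
        raise ValueError("Ct values must lie in (0, 45) cycles")
    return float(x.mean()), bool(x.std(ddof=1) <= sd_threshold)


def ddct_copy_number(
    delta_ct: Sequence[float] | pd.Series, anchor: float = 2.0
) -> pd.DataFrame:
    """Map per-sample dCt values to copy-number estimates, cohort mean = anchor.

    Q = 2^(-dCt); CN = anchor * Q / mean(Q).  The anchoring makes the result
    invariant to any constant shift of dCt (e.g. a different reference gene
    baseline) and forces mean(CN) == anchor exactly.
    """
    d = np.asarray(delta_ct, dtype=float)
    if d.size == 0 or not np.isfinite(d).all():
        raise ValueError("delta_ct must be non-empty and finite")
    q = np.exp2(-d)
    cn = anchor * q / q.mean()
    return pd.DataFrame({"delta_ct": d, "q": q, "cn_estimate": cn})


def qpcr_copy_numbers(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    anchor: float = 2.0,
    calibrator: str | None = None,
) -> pd.DataFrame:
    """Full qPCR pipeline on a long-format Ct table.

    Parameters
    ----------
    ct
        Long table ``sample_id, assay, ct`` (one row per replicate).
    target, reference
        Assay labels for the quantified locus and the no-CNV reference gene.
    calibrator
        Optional sample id; when given, CN is expressed as
        ``anchor * 2^-(dCt_i - dCt_calibrator)`` (textbook delta-delta Ct)
        instead of cohort-mean anchoring.

    Returns
    -------
    DataFrame ``sample_id, delta_ct, q, cn_estimate, qc_flag`` sorted by
    sample.  QC-flagged samples keep their estimate but are marked.
    """
    for col in ("sample_id", "assay", "ct"):
        if col not in ct.columns:
            raise ValueError(f"Ct table lacks column {col!r}")
    rows = []
    for sid, grp in ct.groupby("sample_id", sort=True):
        means = {}
        flags = {}
        for role in (target, reference):
            reps = grp.loc[grp["assay"] == role, "ct"].to_numpy(float)
            reps = reps[np.isfinite(reps)]
            if reps.size < 2:
                means[role] = None
                continue
            means[role], flags[role] = aggregate_ct(reps, sd_threshold)
        if means.get(target) is None or means.get(reference) is None:
            import warnings

            warnings.warn(f"sample {sid}: <2 replicates for an assay; excluded")
            continue
        rows.append(
            {
                "sample_id": sid,
                "delta_ct": means[target] - means[reference],
                "qc_flag": "pass" if (flags[target] and flags[reference]) else "high_replicate_sd",
            }
        )
    if not rows:
        raise ValueError("no sample passed replicate requirements")
    out = pd.DataFrame(rows)
    d = out["delta_ct"].to_numpy(float)
    q = np.exp2(-d)
    if calibrator is not None:
        sel = out["sample_id"] == calibrator
        if not sel.any():
            raise ValueError(f"calibrator sample {calibrator!r} not found")
        cn = anchor * q / q[sel.to_numpy()][0]
    else:
        cn = anchor * q / q.mean()
    out["q"] = q
    out["cn_estimate"] = cn
    return out[["sample_id", "delta_ct", "q", "cn_estimate", "qc_flag"]]


def correlate_platforms(
    qpcr_cn: Sequence[float], mlpa_cn: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between qPCR and MLPA copy numbers."""
    x = np.asarray(qpcr_cn, dtype=float)
    y = np.asarray(mlpa_cn, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of >=3 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = pearsonr(x, y)
    return float(r), float(p)
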