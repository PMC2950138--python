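"""Raw MLPA peak heights -> normalized dosage ratios.

An MLPA reaction reports one fluorescence peak per probe.  Copy number is
encoded in peak height relative to probes targeting reference genes that do
not vary in copy number.  The dosage ratio of a target probe is its peak
height divided by the sum of the control-probe peaks of the same sample;
ratios are then rescaled per probe and per assay batch so that the cohort
median sits at 2.0, i.e. the median individual is assumed diploid.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

QC_PASS = "pass"
QC_FAILED_CONTROL_SUM = "failed_control_sum"
QC_FAILED_PROBE_MEDIAN = "failed_probe_median"

#: columns expected in a long-format peak table
PEAK_COLUMNS = ("sample_id", "probe_id", "peak_height")


class ProbeConfigError(ValueError):
    """A control-probe identifier does not exist in the peak table."""


def _check_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak table lacks required columns: {missing}")
    peaks = peaks.copy()
    if "batch" not in peaks.columns:
        peaks["batch"] = "batch0"  # whole table treated as one assay
    if (peaks["peak_height"].dropna() < 0).any():
        raise ValueError("peak heights must be nonnegative")
    dup = peaks.duplicated(subset=["sample_id", "probe_id"])
    if dup.any():
        raise ValueError("duplicate (sample_id, probe_id) rows in peak table")
    return peaks


def compute_ratios(
    peaks: pd.DataFrame,
    control_probes: Sequence[str],
    include_controls: bool = False,
) -> pd.DataFrame:
    """Divide each target peak by the sample's summed control peaks.

    Parameters
    ----------
    peaks
        Long table with columns ``sample_id, probe_id, peak_height`` and an
        optional ``batch`` column (absent -> one batch).  An explicit height
        of 0 is a biological zero (candidate homozygous deletion), not
        missing data; genuinely absent peaks are simply absent rows (or NaN).
    control_probes
        Identifiers of the reference-gene probes (>=1).  All must appear in
        the table.
    include_controls
        Also emit ratios for the control probes themselves (each control
        divided by the full control sum); useful for QC plots.

    Returns
    -------
    DataFrame with columns ``sample_id, probe_id, batch, raw_ratio, qc_flag``.
    Samples whose control sum is not finite and positive are flagged
    ``failed_control_sum`` with NaN ratios; they are retained so that
    downstream accounting stays auditable.
    """
    peaks = _check_peaks(peaks)
    control_probes = list(control_probes)
    if not control_probes:
        raise ProbeConfigError("at least one control probe is required")
    known = set(peaks["probe_id"])
    unknown = [p for p in control_probes if p not in known]
    if unknown:
        raise ProbeConfigError(f"unknown control probe id(s): {unknown}")

    ctrl = peaks[peaks["probe_id"].isin(control_probes)]
    # every sample must report every control probe; NaN poisons the sum
    ctrl_counts = ctrl.groupby("sample_id")["peak_height"].agg(["sum", "count"])
    n_ctrl = len(control_probes)

    out = peaks if include_controls else peaks[~peaks["probe_id"].isin(control_probes)]
    out = out[["sample_id", "probe_id", "batch", "peak_height"]].copy()
    csum = ctrl_counts["sum"].reindex(out["sample_id"]).to_numpy(float)
    ccount = ctrl_counts["count"].reindex(out["sample_id"]).to_numpy(float)
    ok = np.isfinite(csum) & (csum > 0) & (ccount == n_ctrl)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["peak_height"].to_numpy(float) / csum
    out["raw_ratio"] = np.where(ok, ratio, np.nan)
    out["qc_flag"] = np.where(ok, QC_PASS, QC_FAILED_CONTROL_SUM)
    return out.drop(columns="peak_height").reset_index(drop=True)


def normalize_batch(
    ratios: pd.DataFrame,
    target_level: float = 2.0,
    value_col: str = "raw_ratio",
) -> pd.DataFrame:
    """Anchor the per-probe, per-batch median ratio at ``target_level``.

    For every (probe, batch) cell the passing samples' median raw ratio m is
    computed and each ratio is multiplied by ``target_level / m``.  A cell
    whose median is not positive (e.g. a probe that failed in one batch) is
    flagged ``failed_probe_median`` and left NaN.

    The operation is idempotent: normalizing an already-normalized column
    reproduces it exactly (median of the normalized values is the target).
    """
    if value_col not in ratios.columns:
        raise ValueError(f"missing ratio column {value_col!r}")
    out = ratios.copy()
    if "qc_flag" not in out.columns:
        out["qc_flag"] = QC_PASS
    passing = out["qc_flag"] == QC_PASS
    med = (
        out[passing]
        .groupby(["batch", "probe_id"])[value_col]
        .median()
        .rename("probe_batch_median")
    )
    if not len(med):
        raise ValueError("no passing samples to normalize")
    key = pd.MultiIndex.from_frame(out[["batch", "probe_id"]])
    m = med.reindex(key).to_numpy(float)
    bad = ~(np.isfinite(m) & (m > 0))
    factor = np.where(bad, np.nan, target_level / m)
    out["normalized_ratio"] = out[value_col].to_numpy(float) * factor
    out.loc[bad & passing.to_numpy(), "qc_flag"] = QC_FAILED_PROBE_MEDIAN
    out["normalization_factor"] = factor
    return out


def normalize_peaks(
    peaks: pd.DataFrame,
    control_probes: Sequence[str],
    target_level: float = 2.0,
    include_controls: bool = False,
) -> pd.DataFrame:
    """Convenience wrapper: :func:`compute_ratios` then :func:`normalize_batch`."""
    return normalize_batch(
        compute_ratios(peaks, control_probes, include_controls=include_controls),
        target_level=target_level,
    )
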