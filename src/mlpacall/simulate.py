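"""Synthetic case-control cohorts with CNV + indel structure and assay noise.

The generator emulates the study design the analysis assumes: a Dutch-style
case-control cohort (518 RA cases / 304 controls by default), a control
copy-number distribution matching the total-CN probe (low 6.7% / two copies
83.9% / high 9.4%, the high class split 3:4:5 copies as 8% / 1% / 0.4% of
the cohort), each gene copy independently carrying the -256A>TG indel with
frequency 40.7%, multiplicative lognormal MLPA peak noise, and Gaussian Ct
replicate noise.  Case copy-number distributions are parameterized through
per-class odds ratios against the control distribution (odds-rescale, then
renormalize), so null and alternative simulations share one code path.
Everything is deterministic under the single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import assay
from .ligation import expected_probe_signal

BEHAVIOR_ALL = "counts_all"
BEHAVIOR_WT_ONLY = "counts_wt_only"
BEHAVIOR_NO_CNV = "no_cnv"

DEFAULT_CONTROL_CN_PROBS = {1: 0.067, 2: 0.839, 3: 0.08, 4: 0.01, 5: 0.004}


@dataclass(frozen=True)
class SimulationParams:
    n_cases: int = 518
    n_controls: int = 304
    control_cn_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_CN_PROBS)
    )
    #: per-CN-class case:control odds ratios; classes absent -> 1.0 (null)
    cn_class_odds_ratios: dict[int, float] = field(default_factory=dict)
    mt_allele_freq: float = 0.407
    #: lognormal sigma of the multiplicative MLPA ratio noise
    mlpa_sigma: float = 0.07
    #: summed control-peak fluorescence scale (arbitrary units)
    control_height_scale: float = 3000.0
    #: per-sample DNA-amount factor (lognormal sigma); cancels in ratios
    sample_scale_sigma: float = 0.1
    #: half-normal sd of near-zero peaks from zero-signal probes, as a
    #: fraction of one copy-unit of ratio; None -> 0.3 * mlpa_sigma
    floor_sigma: float | None = None
    ct_target_baseline: float = 26.0
    ct_reference_baseline: float = 24.0
    ct_sd: float = 0.15
    n_ct_replicates: int = 3
    probe_behavior: dict[str, str] = field(
        default_factory=lambda: dict(assay.DEFAULT_PROBE_BEHAVIOR)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        probs = np.array(list(self.control_cn_probs.values()), dtype=float)
        if (probs < 0).any() or (probs > 1).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("CN class probabilities must be in [0,1] and sum to 1")
        if not (0 <= self.mt_allele_freq <= 1):
            raise ValueError("mt_allele_freq must be in [0,1]")
        if self.mlpa_sigma < 0 or self.ct_sd < 0:
            raise ValueError("noise scales must be nonnegative")

    @property
    def effective_floor_sigma(self) -> float:
        return 0.3 * self.mlpa_sigma if self.floor_sigma is None else self.floor_sigma


def case_cn_probs(params: SimulationParams) -> dict[int, float]:
    """Case CN-class distribution: per-class odds rescaled, then renormalized."""
    out = {}
    for cls, p in params.control_cn_probs.items():
        orr = params.cn_class_odds_ratios.get(cls, 1.0)
        if orr < 0:
            raise ValueError(f"odds ratio for class {cls} must be nonnegative")
        if p >= 1.0:
            if orr != 1.0:
                raise ValueError(f"class {cls} probability 1.0 cannot be odds-rescaled")
            out[cls] = 1.0
            continue
        odds = orr * p / (1 - p)
        out[cls] = odds / (1 + odds)
    total = sum(out.values())
    if total <= 0:
        raise ValueError("odds rescaling drove all class probabilities to zero")
    return {cls: v / total for cls, v in out.items()}


def _probe_allele_signals(params: SimulationParams) -> dict[str, tuple[int, int]]:
    """(signal on a WT copy, signal on an MT copy) per probe, via ligation."""
    ref = assay.synthetic_promoter_reference()
    mut = assay.mutant_allele()
    out = {}
    for probe in assay.fcgr3b_probes():
        if probe.probe_id in params.probe_behavior:
            out[probe.probe_id] = (
                expected_probe_signal([ref], probe),
                expected_probe_signal([mut], probe),
            )
    for pid in params.probe_behavior:
        if pid not in out:  # probes without bundled sequences: behavior only
            out[pid] = (1, 1)
    return out


def simulate_cohort(params: SimulationParams) -> pd.DataFrame:
    """Draw per-individual gene-copy configurations and true probe signals.

    Returns one row per individual: ``sample_id, status, cn_total,
    wt_copies, mt_copies, copies`` (tuple of "WT"/"MT" tags) and one
    ``signal_<probe>`` column per probe in the behavior map, holding the
    ligation-model signal of the copy configuration (before any
    phenomenological no-CNV override, which is applied at render time).
    """
    rng = np.random.default_rng(params.seed)
    ctrl_classes = np.array(list(params.control_cn_probs.keys()))
    ctrl_p = np.array(list(params.control_cn_probs.values()))
    case_map = case_cn_probs(params)
    case_p = np.array([case_map[c] for c in ctrl_classes])

    signals = _probe_allele_signals(params)
    rows = []
    for status, n, p in (
        ("RA", params.n_cases, case_p),
        ("control", params.n_controls, ctrl_p),
    ):
        cns = rng.choice(ctrl_classes, size=n, p=p)
        for i, cn in enumerate(cns):
            is_mt = rng.random(int(cn)) < params.mt_allele_freq
            copies = tuple("MT" if m else "WT" for m in is_mt)
            wt = int((~is_mt).sum())
            mt = int(is_mt.sum())
            row = {
                "sample_id": f"{status}_{i:05d}",
                "status": status,
                "cn_total": int(cn),
                "wt_copies": wt,
                "mt_copies": mt,
                "copies": copies,
            }
            for pid, (s_wt, s_mt) in signals.items():
                row[f"signal_{pid}"] = wt * s_wt + mt * s_mt
            rows.append(row)
    return pd.DataFrame(rows)


def _expected_ratio(truth: pd.DataFrame, pid: str, behavior: str) -> np.ndarray:
    if behavior == BEHAVIOR_NO_CNV:
        return np.full(len(truth), 2.0)
    return truth[f"signal_{pid}"].to_numpy(float)


def render_mlpa(truth: pd.DataFrame, params: SimulationParams) -> pd.DataFrame:
    """Generate a raw peak-height table from true signals.

    Control-probe heights are drawn around ``control_height_scale / 3`` each
    with the same lognormal noise; a target probe's height is its expected
    ratio times the sample's realized control sum times median-1 lognormal
    noise, so the median ratio of the modal class is exact.  Zero-signal
    probes emit half-normal near-zero peaks that vanish when sigma = 0.
    A per-sample DNA-amount factor multiplies every peak and cancels in the
    ratios.
    """
    rng = np.random.default_rng(params.seed + 1)
    sig = params.mlpa_sigma
    floor = params.effective_floor_sigma
    n = len(truth)
    scale = np.exp(rng.normal(0.0, params.sample_scale_sigma, size=n))
    rows = []
    ctrl_each = params.control_height_scale / len(assay.CONTROL_GENES)
    ctrl_heights = {
        g: ctrl_each * np.exp(rng.normal(0.0, sig, size=n)) for g in assay.CONTROL_GENES
    }
    ctrl_sum = np.sum(list(ctrl_heights.values()), axis=0)
    for g, h in ctrl_heights.items():
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": truth["sample_id"],
                    "probe_id": g,
                    "peak_height": h * scale,
                }
            )
        )
    for pid, behavior in params.probe_behavior.items():
        expected = _expected_ratio(truth, pid, behavior)
        noise = np.exp(rng.normal(0.0, sig, size=n))
        height = expected * ctrl_sum * noise
        zero = expected == 0
        if zero.any():
            height[zero] = np.abs(rng.normal(0.0, floor, size=int(zero.sum()))) * ctrl_sum[zero]
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": truth["sample_id"],
                    "probe_id": pid,
                    "peak_height": height * scale,
                }
            )
        )
    peaks = pd.concat(rows, ignore_index=True)
    peaks["batch"] = "batch0"
    return peaks


def render_qpcr(
    truth: pd.DataFrame,
    params: SimulationParams,
    sample_ids: pd.Series | list | None = None,
    target_assay: str = "FCGR3B",
    reference_assay: str = "FOXP2",
) -> pd.DataFrame:
    """Generate a long-format triplicate Ct table from true total copy numbers.

    Target mean Ct is ``baseline - log2(max(copies, 0.5) / 2)`` (a
    zero-copy sample amplifies late rather than never, floored at half a
    copy); the reference gene sits at its baseline.  Replicates get i.i.d.
    Gaussian noise.
    """
    rng = np.random.default_rng(params.seed + 2)
    sub = truth if sample_ids is None else truth[truth["sample_id"].isin(sample_ids)]
    rows = []
    for r in sub.itertuples():
        t_mean = params.ct_target_baseline - np.log2(max(r.cn_total, 0.5) / 2.0)
        for rep in range(params.n_ct_replicates):
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "assay": target_assay,
                    "replicate": rep + 1,
                    "ct": t_mean + rng.normal(0.0, params.ct_sd),
                }
            )
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "assay": reference_assay,
                    "replicate": rep + 1,
                    "ct": params.ct_reference_baseline + rng.normal(0.0, params.ct_sd),
                }
            )
    return pd.DataFrame(rows)


def select_verification_panel(truth: pd.DataFrame, n: int = 24) -> pd.DataFrame:
    """Pick up to ``n`` individuals spanning the observed copy-number classes.

    Emulates how a platform-comparison panel is assembled: samples showing
    *different* copy numbers are chosen deliberately, round-robin across the
    CN classes present (rarest first), never at random.
    """
    by_class = [
        grp["sample_id"].tolist()
        for _, grp in sorted(
            truth.groupby("cn_total"), key=lambda kv: (len(kv[1]), kv[0])
        )
    ]
    chosen: list[str] = []
    i = 0
    while len(chosen) < n and any(by_class):
        bucket = by_class[i % len(by_class)]
        if bucket:
            chosen.append(bucket.pop(0))
        else:
            by_class.pop(i % len(by_class))
            continue
        i += 1
    return truth[truth["sample_id"].isin(chosen)]


def truth_metrics(
    truth: pd.DataFrame, calls: pd.DataFrame, probe_id: str
) -> dict:
    """Confusion matrix and per-class accuracy of CN calls against truth.

    ``calls`` needs ``sample_id`` and ``cn``.  The truth column is the
    probe's ligation signal (what a perfect assay would count).
    """
    merged = truth[["sample_id", f"signal_{probe_id}"]].merge(
        calls[["sample_id", "cn"]], on="sample_id", how="inner", validate="1:1"
    )
    if len(merged) != len(calls):
        raise ValueError("sample ids in calls do not match the truth table")
    t = merged[f"signal_{probe_id}"].to_numpy(int)
    c = merged["cn"].to_numpy(float)
    ok = np.isfinite(c)
    confusion = pd.crosstab(
        pd.Series(t[ok], name="true"), pd.Series(c[ok].astype(int), name="called")
    )
    acc = float((t[ok] == c[ok]).mean()) if ok.any() else np.nan
    per_class = {
        int(cls): float((c[ok][t[ok] == cls] == cls).mean())
        for cls in np.unique(t[ok])
    }
    return {"confusion": confusion, "accuracy": acc, "per_class_accuracy": per_class}


def mt_frequency_error(truth: pd.DataFrame, genotypes: pd.DataFrame) -> float:
    """|MT allele frequency from valid genotype calls - realized truth frequency|."""
    valid = genotypes[genotypes["valid"]]
    est = valid["mt_copies"].sum() / (valid["mt_copies"].sum() + valid["wt_copies"].sum())
    realized = truth["mt_copies"].sum() / (
        truth["mt_copies"].sum() + truth["wt_copies"].sum()
    )
    return float(abs(est - realized))
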