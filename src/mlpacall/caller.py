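"""Integer copy-number calling from 1-D normalized dosage ratios.

Normalized MLPA ratios for a copy-number-variable probe form clusters on an
(approximately) integer lattice: one cluster per copy-number class, spaced
by the per-copy unit u.  This module formalizes cluster assignment that is
often done by eye: a 1-D Gaussian mixture is fitted for a range of component
counts, the Bayesian information criterion selects the number of clusters,
and the components are mapped onto integer copy numbers.

Labeling rule
-------------
The median-to-2 normalization makes the modal cluster diploid *for a probe
that counts all copies*, so the primary unit candidate anchors the
highest-weight component at CN 2 (u = modal mean / 2).  A probe whose signal
counts only a subset of copies (e.g. a ligation probe silenced by an
allele-specific indel) violates that assumption: the modal individual may
carry one countable copy and the modal anchor then labels the clusters
0, 2, 4, ... with a half-sized unit.  Candidate units — modal mean / 2, the
median spacing between adjacent component means, modal mean — are therefore
scored by their weighted lattice misfit, after rejecting any that label the
modal component far from the diploid anchor or give all substantial
components a common label factor (the half-unit signature); smallest misfit
wins, with unpopulated interior classes tolerated as tie-breaks.
Components whose labels collide are merged moment-matched; a component
below 0.3 u is labeled CN 0.

Copy-number classes too rare to earn a mixture component (a handful of 4-5
copy individuals in a cohort) would otherwise be absorbed by the nearest
fitted cluster, so the fitted components are extended with low-weight
lattice components at unfitted integer positions; assignment remains
maximum-posterior over the extended set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

ZERO_COPY_FRACTION = 0.3  # ratio below this fraction of u -> CN 0
BIC_TIE_WINDOW = 2.0  # BIC differences below this favor the smaller K
LATTICE_RESIDUAL_TOL = 0.05  # weighted mean-square lattice misfit (copy units)
DEFAULT_POSTERIOR_THRESHOLD = 0.9


@dataclass(frozen=True)
class Component:
    mean: float
    var: float
    weight: float
    cn: int


@dataclass
class ClusterModel:
    """Fitted per-probe mixture with integer copy-number labels."""

    probe_id: str
    components: tuple[Component, ...]  # sorted by mean, strictly increasing
    unit: float  # estimated ratio per gene copy
    no_cnv: bool
    bic_table: dict[int, float]
    n_samples: int
    seed: int
    #: low-weight lattice positions above the fitted range, used only for
    #: assignment of rare extreme ratios
    extrapolated: tuple[Component, ...] = ()

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def assignment_components(self) -> tuple[Component, ...]:
        return self.components + self.extrapolated

    def to_dict(self) -> dict:
        def comp(c: Component) -> dict:
            return {"mean": c.mean, "var": c.var, "weight": c.weight, "cn": c.cn}

        return {
            "probe_id": self.probe_id,
            "k": self.k,
            "unit": self.unit,
            "no_cnv": self.no_cnv,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "components": [comp(c) for c in self.components],
            "extrapolated": [comp(c) for c in self.extrapolated],
            "bic_table": {int(k): float(v) for k, v in self.bic_table.items()},
        }


@dataclass(frozen=True)
class CopyNumberCall:
    sample_id: str
    probe_id: str
    ratio: float
    cn: int
    posterior: float
    low_confidence: bool


def _labels_for_unit(means: np.ndarray, unit: float) -> np.ndarray:
    labels = np.rint(means / unit).astype(int)
    labels[means < ZERO_COPY_FRACTION * unit] = 0
    return np.maximum(labels, 0)


def _contiguous(labels: Sequence[int]) -> bool:
    uniq = sorted(set(int(x) for x in labels))
    return all(b - a == 1 for a, b in zip(uniq, uniq[1:]))


def _merge_by_label(
    means: np.ndarray, variances: np.ndarray, weights: np.ndarray, labels: np.ndarray
) -> list[Component]:
    comps = []
    for lab in sorted(set(labels.tolist())):
        sel = labels == lab
        w = weights[sel].sum()
        m = float(np.average(means[sel], weights=weights[sel]))
        # moment-matched pooled variance: within + between
        v = float(
            np.average(variances[sel] + means[sel] ** 2, weights=weights[sel]) - m**2
        )
        comps.append(Component(mean=m, var=max(v, 1e-12), weight=float(w), cn=int(lab)))
    return comps


def _label_components(
    means: np.ndarray, variances: np.ndarray, weights: np.ndarray
) -> tuple[list[Component], float]:
    order = np.argsort(means)
    means, variances, weights = means[order], variances[order], weights[order]
    # modal anchor among components with positive mean (a zero-copy atom can
    # never be the diploid reference even if it is the heaviest cluster)
    positive = means > 0
    if not positive.any():
        raise ValueError("all component means are zero; cannot anchor CN 2")
    w_pos = np.where(positive, weights, -np.inf)
    modal_mean = float(means[int(np.argmax(w_pos))])

    candidates = [modal_mean / 2.0]
    if len(means) >= 2:
        spacing = float(np.median(np.diff(means)))
        if spacing > 0:
            candidates.append(spacing)
    candidates.append(modal_mean)

    modal_idx = int(np.argmax(w_pos))
    evaluated: list[tuple[float, int, int, float, list[Component]]] = []
    for rank, u in enumerate(candidates):
        labels = _labels_for_unit(means, u)
        # the modal/median individual must land near the diploid anchor;
        # units that label it far from 2 are implausible splits
        if labels[modal_idx] not in (1, 2, 3):
            continue
        # a unit that is an integer fraction of the true spacing labels every
        # substantial cluster with a common factor (0, 2, 4, ...): reject it
        weighty = sorted(
            {int(l) for l, w in zip(labels, weights) if l > 0 and w >= 0.01}
        )
        if len(weighty) >= 2 and np.gcd.reduce(weighty) >= 2:
            continue
        merged = _merge_by_label(means, variances, weights, labels)
        cns = [c.cn for c in merged]
        holes = (max(cns) - min(cns) + 1) - len(cns)
        nonzero = labels > 0
        residual = float(
            np.sum(weights[nonzero] * (means[nonzero] / u - labels[nonzero]) ** 2)
        )
        evaluated.append((residual, holes, rank, u, merged))
    if evaluated:
        # lattice misfit decides; unpopulated interior classes are tolerated
        # and only break residual ties, then candidate priority
        _, _, _, u, merged = min(evaluated, key=lambda t: (t[0], t[1], t[2]))
    else:  # fall back to the plain modal anchor
        warnings.warn("no plausible copy-number lattice found; using modal anchor")
        u = modal_mean / 2.0
        merged = _merge_by_label(means, variances, weights, _labels_for_unit(means, u))
    if len({c.cn for c in merged}) < len(means):
        warnings.warn("mixture components share an integer label; merged", stacklevel=3)
    return merged, float(u)


def _typical_rel_sd(comps: list[Component], unit: float) -> float:
    """Weighted-typical per-copy relative spread from well-populated classes."""
    vals = [
        np.sqrt(c.var) / c.mean
        for c in comps
        if c.mean > 0.5 * unit and c.weight >= 0.05
    ]
    if not vals:
        vals = [np.sqrt(c.var) / c.mean for c in comps if c.mean > 0]
    return float(np.median(vals)) if vals else 0.05


def _recalibrate_tail_variances(comps: list[Component], rel_sd: float) -> list[Component]:
    """Shrink implausibly broad components back to the typical spread.

    A sparse high-copy tail absorbed into one mixture component inflates its
    variance far beyond the multiplicative-noise expectation, letting it
    swallow neighboring lattice positions during assignment; such components
    get their assignment variance reset to (rel_sd * mean)^2.
    """
    out = []
    for c in comps:
        sd = np.sqrt(c.var)
        if c.mean > 0 and sd > 2 * rel_sd * c.mean:
            out.append(Component(c.mean, max((rel_sd * c.mean) ** 2, 1e-12), c.weight, c.cn))
        else:
            out.append(c)
    return out


def _extrapolate_lattice(
    comps: list[Component], unit: float, max_cn: int, n_samples: int, rel_sd: float
) -> list[Component]:
    """Low-weight integer-lattice components at unfitted copy numbers.

    Classes too rare to earn a mixture component (interior holes or counts
    above the fitted range) still get a lattice position so that extreme
    ratios are called on the integer grid rather than absorbed by the
    nearest fitted cluster.
    """
    if comps[-1].mean <= 0:
        return []
    floor_w = 0.5 / n_samples
    fitted = {c.cn for c in comps}
    out = []
    for cn in range(min(fitted) + 1, max_cn + 1):
        if cn in fitted:
            continue
        mean = cn * unit
        out.append(
            Component(mean=mean, var=max((rel_sd * mean) ** 2, 1e-12), weight=floor_w, cn=cn)
        )
    return out


def _atom_model(values: np.ndarray, reg_covar: float) -> tuple[np.ndarray, ...]:
    """Degenerate (noise-free) input: one component per distinct value."""
    uniq, counts = np.unique(values, return_counts=True)
    weights = counts / counts.sum()
    variances = np.full_like(uniq, reg_covar, dtype=float)
    return uniq.astype(float), variances, weights


def fit_ratio_clusters(
    ratios: Sequence[float] | np.ndarray,
    probe_id: str = "",
    max_cn: int = 6,
    seed: int = 0,
    reg_covar: float = 1e-4,
) -> ClusterModel:
    """Fit and label a 1-D copy-number mixture for one probe.

    Candidate component counts K = 1 .. max_cn + 1 are fitted with
    k-means++-initialized Gaussian mixtures (several restarts, seeded) and
    scored by BIC; ties within ``BIC_TIE_WINDOW`` resolve toward the smaller
    K.  Candidates requiring more than n/2 components are skipped (too few
    samples per component).  Inputs with at most max_cn + 1 distinct values
    (noise-free data) are modeled directly as point masses.
    """
    x = np.asarray(ratios, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need >=10 passing samples to cluster, got {x.size}")
    if (x < 0).any():
        raise ValueError("ratios must be nonnegative")

    uniq = np.unique(x)
    bic_table: dict[int, float] = {}
    if uniq.size <= max_cn + 1:
        means, variances, weights = _atom_model(x, reg_covar)
    else:
        fits: dict[int, GaussianMixture] = {}
        k_max = min(max_cn + 1, x.size // 2)
        for k in range(1, k_max + 1):
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                init_params="k-means++",
                reg_covar=reg_covar,
                random_state=seed,
                n_init=5,
                max_iter=500,
            )
            gm.fit(x.reshape(-1, 1))
            fits[k] = gm
            bic_table[k] = float(gm.bic(x.reshape(-1, 1)))
        best = min(bic_table.values())
        k_sel = min(k for k, b in bic_table.items() if b <= best + BIC_TIE_WINDOW)
        gm = fits[k_sel]
        means = gm.means_.ravel()
        variances = gm.covariances_.reshape(-1)
        weights = gm.weights_.ravel()

    comps, unit = _label_components(means, variances, weights)
    no_cnv = len(comps) == 1
    extrapolated: list[Component] = []
    if no_cnv:
        comps = [Component(comps[0].mean, comps[0].var, 1.0, 2)]
        unit = comps[0].mean / 2.0
    else:
        rel_sd = _typical_rel_sd(comps, unit)
        comps = _recalibrate_tail_variances(comps, rel_sd)
        extrapolated = _extrapolate_lattice(comps, unit, max_cn, int(x.size), rel_sd)
    return ClusterModel(
        probe_id=probe_id,
        components=tuple(comps),
        unit=unit,
        no_cnv=no_cnv,
        bic_table=bic_table,
        n_samples=int(x.size),
        seed=seed,
        extrapolated=tuple(extrapolated),
    )


def flag_no_cnv(model: ClusterModel) -> bool:
    """True iff the probe shows a single copy-number class (no CNV evidence)."""
    return model.no_cnv


def _posteriors(model: ClusterModel, ratios: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    comps = model.assignment_components
    logp = np.stack(
        [
            np.log(c.weight) + norm.logpdf(ratios, loc=c.mean, scale=np.sqrt(c.var))
            for c in comps
        ],
        axis=1,
    )
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    labels = np.array([c.cn for c in comps])
    return p, labels


def assign_integer_cn(
    model: ClusterModel,
    ratio: float,
    sample_id: str = "",
    posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
) -> CopyNumberCall:
    """Assign one ratio to its maximum-posterior component's copy number.

    A ratio below ``0.3 * unit`` is called CN 0 outright (a signal that low
    cannot arise from a present copy); no-CNV probes call a constant CN 2.
    """
    p, labels = _posteriors(model, np.asarray([float(ratio)]))
    idx = int(np.argmax(p[0]))
    post = float(p[0][idx])
    cn = int(labels[idx])
    if model.no_cnv:
        cn, post = 2, 1.0
    elif ratio < ZERO_COPY_FRACTION * model.unit:
        cn = 0
    return CopyNumberCall(
        sample_id=sample_id,
        probe_id=model.probe_id,
        ratio=float(ratio),
        cn=cn,
        posterior=post,
        low_confidence=post < posterior_threshold,
    )


def call_samples(
    model: ClusterModel,
    ratios: pd.DataFrame,
    ratio_col: str = "normalized_ratio",
    posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
) -> pd.DataFrame:
    """Vectorized calls for a table with ``sample_id`` and a ratio column.

    Samples with non-finite ratios (QC failures upstream) receive no call
    (cn = NA) but stay in the output.
    """
    out = ratios[["sample_id", ratio_col]].copy()
    out = out.rename(columns={ratio_col: "ratio"})
    out["probe_id"] = model.probe_id
    vals = out["ratio"].to_numpy(float)
    ok = np.isfinite(vals)
    cn = np.full(vals.shape, np.nan)
    post = np.full(vals.shape, np.nan)
    if ok.any():
        if model.no_cnv:
            cn[ok] = 2.0
            post[ok] = 1.0
        else:
            p, labels = _posteriors(model, vals[ok])
            idx = np.argmax(p, axis=1)
            cn[ok] = labels[idx]
            post[ok] = p[np.arange(idx.size), idx]
            cn[ok & (vals < ZERO_COPY_FRACTION * model.unit)] = 0.0
    out["cn"] = cn
    out["posterior"] = post
    out["low_confidence"] = post < posterior_threshold
    out["no_cnv_probe"] = model.no_cnv
    return out
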