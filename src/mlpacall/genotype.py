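"""Two-probe indel genotyping from paired copy-number calls.

Probe #2's junction is untouched by the -256A>TG indel and counts every gene
copy; probe #1's junction is destroyed by it and counts wild-type copies
only.  For each sample, wt = CN(probe #1) and mt = CN(probe #2) - CN(probe #1).
A sample whose wild-type-only call exceeds its total call is physically
impossible and is excluded as a technical error (but reported, never
silently dropped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

WT_GT_MT = "WT>MT"
WT_EQ_MT = "WT=MT"
WT_LT_MT = "WT<MT"
GENOTYPE_CLASSES = (WT_GT_MT, WT_EQ_MT, WT_LT_MT)


@dataclass(frozen=True)
class IndelGenotype:
    sample_id: str
    wt_copies: int
    mt_copies: int
    genotype_class: str | None  # None when invalid
    valid: bool


def classify_genotype(wt: int, mt: int) -> str:
    """Genotype class from per-individual wild-type and mutant copy counts."""
    if wt > mt:
        return WT_GT_MT
    if wt == mt:
        return WT_EQ_MT
    return WT_LT_MT


def derive_genotype(sample_id: str, cn_wt_probe: int, cn_total_probe: int) -> IndelGenotype:
    """Combine the WT-only and total-CN probe calls into an indel genotype.

    mt = total - wt.  cn_wt_probe > cn_total_probe is impossible if both
    calls are correct, so such pairs are flagged invalid.
    """
    if cn_wt_probe < 0 or cn_total_probe < 0:
        raise ValueError("copy-number calls must be nonnegative")
    if cn_wt_probe > cn_total_probe:
        return IndelGenotype(sample_id, int(cn_wt_probe), 0, None, False)
    wt = int(cn_wt_probe)
    mt = int(cn_total_probe - cn_wt_probe)
    return IndelGenotype(sample_id, wt, mt, classify_genotype(wt, mt), True)


def derive_genotypes(pairs: pd.DataFrame) -> pd.DataFrame:
    """Vectorized genotyping of a ``sample_id, cn_wt_probe, cn_total_probe`` table.

    Rows with a missing call on either probe are skipped with a warning
    (these samples remain usable for CNV-only analyses upstream).
    """
    for col in ("sample_id", "cn_wt_probe", "cn_total_probe"):
        if col not in pairs.columns:
            raise ValueError(f"pair table lacks column {col!r}")
    present = pairs[["cn_wt_probe", "cn_total_probe"]].notna().all(axis=1)
    n_missing = int((~present).sum())
    if n_missing:
        warnings.warn(f"{n_missing} sample(s) missing a probe call; skipped")
    rows = [
        derive_genotype(r.sample_id, int(r.cn_wt_probe), int(r.cn_total_probe))
        for r in pairs[present].itertuples()
    ]
    return pd.DataFrame(
        {
            "sample_id": [g.sample_id for g in rows],
            "wt_copies": [g.wt_copies for g in rows],
            "mt_copies": [g.mt_copies for g in rows],
            "genotype_class": [g.genotype_class for g in rows],
            "valid": [g.valid for g in rows],
        }
    )


def exclusion_report(pairs: pd.DataFrame) -> tuple[int, float]:
    """(number, fraction) of typed pairs failing the wt <= total consistency rule."""
    g = derive_genotypes(pairs)
    n = len(g)
    if n == 0:
        return 0, 0.0
    excluded = int((~g["valid"]).sum())
    rate = excluded / n
    if excluded == n:
        warnings.warn("every typed pair is discordant: data-integrity alarm")
    return excluded, rate


def cohort_allele_table(genotypes: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-group allele totals and genotype-class counts.

    Allele totals sum per-individual copy counts (a CNV locus does not obey
    the 2n diploid accounting).  Only valid genotypes enter.  ``phenotypes``
    must carry ``sample_id`` and ``status``.

    Returns a frame indexed by status with columns ``n, wt_alleles,
    mt_alleles, WT>MT, WT=MT, WT<MT``.
    """
    for col in ("sample_id", "status"):
        if col not in phenotypes.columns:
            raise ValueError(f"phenotype table lacks column {col!r}")
    merged = genotypes[genotypes["valid"]].merge(
        phenotypes[["sample_id", "status"]], on="sample_id", how="inner"
    )
    if merged.empty:
        raise ValueError("no valid genotype overlaps the phenotype table")
    rows = {}
    for status, grp in merged.groupby("status"):
        if grp.empty:
            raise ValueError(f"group {status!r} has no valid genotypes")
        row = {
            "n": len(grp),
            "wt_alleles": int(grp["wt_copies"].sum()),
            "mt_alleles": int(grp["mt_copies"].sum()),
        }
        counts = grp["genotype_class"].value_counts()
        for cls in GENOTYPE_CLASSES:
            row[cls] = int(counts.get(cls, 0))
        rows[status] = row
    out = pd.DataFrame(rows).T
    out.index.name = "status"
    return out


def mt_allele_frequency(allele_table: pd.DataFrame) -> pd.Series:
    """Per-group mutant-allele fraction mt / (wt + mt)."""
    tot = allele_table["wt_alleles"] + allele_table["mt_alleles"]
    return allele_table["mt_alleles"] / tot
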