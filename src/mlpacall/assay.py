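"""The FCGR3B promoter MLPA assay: published probe sequences and a synthetic
reference for exercising the ligation model.

The three FCGR3B probes target paralogous sequence variants in the promoter
that distinguish *FCGR3B* from its near-identical paralog *FCGR3A*; peaks are
normalized against probes in three autosomal genes without copy-number
variation (*CREBBP*, *EXT1*, *EP300*).  Probe #1's ligation junction falls on
the adenine at promoter position -256; the -256A>TG indel (the A replaced by
TG, net +1 base) destroys that nick and silences the probe on mutant alleles,
so probe #1 counts wild-type copies only while probe #2 counts all copies.

The genomic promoter sequence between the probe binding sites is not bundled
here; :func:`synthetic_promoter_reference` builds a synthetic stand-in that
embeds the real half-probe target sequences at plausible spacings and is
guaranteed free of spurious junction matches.
"""

from __future__ import annotations

import numpy as np

from .ligation import HalfProbePair, PromoterSequence, Variant, apply_variant

CONTROL_GENES = ("CREBBP", "EXT1", "EP300")

PROBE_WT_ONLY = "FCGR3B_1"  # silenced by -256A>TG: counts wild-type copies
PROBE_TOTAL = "FCGR3B_2"  # junction far from the indel: counts all copies
PROBE_NO_CNV = "FCGR3B_3"  # empirically uninformative for CNV

#: probe -> behavior keys understood by the simulator
DEFAULT_PROBE_BEHAVIOR = {
    PROBE_WT_ONLY: "counts_wt_only",
    PROBE_TOTAL: "counts_all",
    PROBE_NO_CNV: "no_cnv",
}

# Published half-probe target-matching sequences (promoter sense strand).
_HALF_SEQS = {
    PROBE_WT_ONLY: (
        "CGTGGAGATAATATTGAGGCAGAGACACTGCTAGTGGTCA",
        "AAGATTTGAAAGGACAACTTTCTGTGTGCAGGCAGGGC",
    ),
    PROBE_TOTAL: (
        "CCGACGTACGTATCTAAATCCAGGAGATGGGGGCAAGCATCCTGGGAA",
        "AGCTGAGGGCACACTCTGGCAGATTCTGTGTG",
    ),
    PROBE_NO_CNV: (
        "CCCCACCTTGCCTCCAGGCTCTTTCCTTCCTA",
        "TTCCTGTTCTATGGTGGGGCTCCATTGCGAGA",
    ),
}

#: junction coordinate (last base of the upstream half-probe) per probe.
#: Probe #1's junction adenine sits at -256 (the indel position); the other
#: two junctions are synthetic placements within a few hundred bases.
JUNCTIONS = {PROBE_WT_ONLY: -256, PROBE_TOTAL: -380, PROBE_NO_CNV: -500}

#: the -256A>TG indel: the adenine 256 bases upstream of the TSS deleted and
#: a TG dinucleotide inserted (net +1 base)
INDEL_256 = Variant(position=-256, ref="A", alt="TG", label="-256A>TG")

REFERENCE_LENGTH = 600


def fcgr3b_probes(window: int = 10) -> list[HalfProbePair]:
    """The three FCGR3B half-probe pairs with their junction coordinates."""
    return [
        HalfProbePair(
            probe_id=pid,
            upstream=_HALF_SEQS[pid][0],
            downstream=_HALF_SEQS[pid][1],
            junction=JUNCTIONS[pid],
            window=window,
        )
        for pid in (PROBE_WT_ONLY, PROBE_TOTAL, PROBE_NO_CNV)
    ]


def _count(haystack: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def _checks(ref: PromoterSequence, probes: list[HalfProbePair]) -> bool:
    alt = apply_variant(ref, INDEL_256)
    for p in probes:
        target = p.upstream + p.downstream
        if _count(ref.seq, target) != 1:
            return False
        for w in (4, 8, 10):
            if _count(ref.seq, p.junction_kmer(w)) != 1:
                return False
            n_alt = _count(alt.seq, p.junction_kmer(w))
            if p.probe_id == PROBE_WT_ONLY and n_alt != 0:
                return False
            if p.probe_id != PROBE_WT_ONLY and n_alt != 1:
                return False
    return True


def synthetic_promoter_reference(seed: int = 0) -> PromoterSequence:
    """Synthetic wild-type promoter segment spanning coordinates -600..-1.

    The published half-probe targets are embedded at their junction
    coordinates (probe #1's upstream half ends on the A at -256) with seeded
    random sequence elsewhere.  The construction is rejected and redrawn
    until every probe's full target and every junction window (w = 4, 8, 10)
    occur exactly once on the wild-type allele, and the -256A>TG allele
    retains probes #2/#3 junctions while losing probe #1's.  Deterministic
    for a given seed.  This is a synthetic stand-in: real inter-probe spacer
    sequence is not reproduced.
    """
    probes = fcgr3b_probes()
    rng = np.random.default_rng(seed)
    for _ in range(100):
        bases = rng.choice(list("ACGT"), size=REFERENCE_LENGTH)
        seq = np.array(bases, dtype="U1")
        for p in probes:
            end_idx = p.junction + REFERENCE_LENGTH + 1  # index after junction base
            start_idx = end_idx - len(p.upstream)
            seq[start_idx:end_idx] = list(p.upstream)
            seq[end_idx : end_idx + len(p.downstream)] = list(p.downstream)
        ref = PromoterSequence(
            id="FCGR3B_promoter_synthetic", seq="".join(seq), start=-REFERENCE_LENGTH
        )
        if ref.base_at(INDEL_256.position) != INDEL_256.ref:
            raise AssertionError("probe #1 junction base is not the -256 adenine")
        if _checks(ref, probes):
            return ref
    raise RuntimeError("could not build a collision-free synthetic reference")


def wild_type_allele(seed: int = 0) -> PromoterSequence:
    return synthetic_promoter_reference(seed)


def mutant_allele(seed: int = 0) -> PromoterSequence:
    """The -256A>TG allele of the synthetic reference."""
    return apply_variant(synthetic_promoter_reference(seed), INDEL_256)
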