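"""Mechanistic model of MLPA half-probe ligation on promoter alleles.

An MLPA probe is two half-oligos that hybridize side by side on the target;
only if the ligase can seal the nick between them does the probe amplify and
produce a peak.  A sequence change at or near the nick (the ligation
junction) abolishes the seal, so an allele carrying such a variant yields no
signal from that probe and is misread as a deletion.  The model is binary:
both half-probes must hybridize (approximate match anywhere on the allele)
and the ``w`` bases on each side of the junction must match the allele
exactly and contiguously.  No hybridization thermodynamics are modeled; the
nick-sealing requirement alone reproduces allele-specific probe dropout.

Promoter coordinates are anchored at the transcription start site: position
-1 is the base immediately upstream of the TSS, more negative is further
upstream, and there is no position 0.  Applying an indel keeps the TSS
anchor fixed, so bases 3' of the edit keep their coordinates while the 5'
end extends or shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import edlib
import pandas as pd
from Bio import SeqIO

VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class PromoterSequence:
    """A promoter-strand sequence spanning coordinates ``start .. -1``."""

    id: str
    seq: str
    start: int  # promoter coordinate of seq[0]; always negative

    def __post_init__(self):
        if set(self.seq) - VALID_BASES:
            raise ValueError("sequence contains non-ACGTN characters")
        if self.start != -len(self.seq):
            raise ValueError(
                "coordinate map must be bijective: start must equal -len(seq) "
                "for a TSS-anchored promoter segment"
            )

    def index_of(self, coord: int) -> int:
        """0-based index of promoter coordinate ``coord`` (no position 0)."""
        if coord == 0:
            raise ValueError("promoter coordinates have no position 0")
        if not (self.start <= coord <= -1):
            raise ValueError(f"coordinate {coord} outside span [{self.start}, -1]")
        return coord - self.start

    def base_at(self, coord: int) -> str:
        return self.seq[self.index_of(coord)]


@dataclass(frozen=True)
class Variant:
    """Replacement of ``ref`` by ``alt`` at a promoter coordinate."""

    position: int  # coordinate of the first ref base
    ref: str
    alt: str
    label: str = ""

    @property
    def net_length_change(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass(frozen=True)
class HalfProbePair:
    """Target-matching sense sequences of the two half-probes of one MLPA probe.

    ``junction`` is the promoter coordinate of the last base covered by the
    upstream (5') half-probe on the reference; the downstream half-probe
    starts at the next base.
    """

    probe_id: str
    upstream: str
    downstream: str
    junction: int
    window: int = 10  # bases on each side of the nick requiring exact match

    def __post_init__(self):
        if not self.upstream or not self.downstream:
            raise ValueError("half-probe sequences must be nonempty")

    def junction_kmer(self, window: int | None = None) -> str:
        w = self.window if window is None else window
        w_up = min(w, len(self.upstream))
        w_down = min(w, len(self.downstream))
        return self.upstream[-w_up:] + self.downstream[:w_down]


def apply_variant(seq: PromoterSequence, v: Variant) -> PromoterSequence:
    """Return the allele carrying ``v``; the ref span must match the input.

    The TSS anchor (-1 at the right end) is preserved: positions 3' of the
    edit keep their coordinates and the 5' end of the map shifts by the net
    length change.
    """
    i = seq.index_of(v.position)
    found = seq.seq[i : i + len(v.ref)]
    if found != v.ref:
        raise ValueError(
            f"reference mismatch at {v.position}: expected {v.ref!r}, found {found!r}"
        )
    new_seq = seq.seq[:i] + v.alt + seq.seq[i + len(v.ref) :]
    label = v.label or f"{v.position}{v.ref}>{v.alt}"
    new_id = f"{seq.id}|{label}" if v.ref != v.alt else seq.id
    return PromoterSequence(id=new_id, seq=new_seq, start=-len(new_seq))


LIGATION_OK = "ok"
JUNCTION_MISMATCH = "junction_mismatch"
NO_HYBRIDIZATION = "probe_does_not_hybridize"


@dataclass(frozen=True)
class LigationResult:
    success: bool
    reason: str


def _hybridizes(half: str, allele: str, max_edit_frac: float) -> bool:
    k = max(2, int(len(half) * max_edit_frac))
    res = edlib.align(half, allele, mode="HW", task="distance", k=k)
    return res["editDistance"] != -1


def ligation_result(
    probe: HalfProbePair,
    allele: PromoterSequence,
    window: int | None = None,
    max_edit_frac: float = 0.2,
) -> LigationResult:
    """Detailed ligation verdict for one probe on one allele sequence.

    Success requires the 2w-base junction window (last w bases of the
    upstream half + first w of the downstream half) to occur contiguously in
    the allele — a perfectly apposed, sealable nick.  When the junction
    window is absent the verdict distinguishes a disrupted junction (both
    halves still hybridize within ``max_edit_frac`` edits) from a probe that
    does not hybridize at all.
    """
    if probe.junction_kmer(window) in allele.seq:
        return LigationResult(True, LIGATION_OK)
    up_ok = _hybridizes(probe.upstream, allele.seq, max_edit_frac)
    down_ok = _hybridizes(probe.downstream, allele.seq, max_edit_frac)
    if up_ok and down_ok:
        return LigationResult(False, JUNCTION_MISMATCH)
    return LigationResult(False, NO_HYBRIDIZATION)


def ligation_success(
    probe: HalfProbePair,
    allele: PromoterSequence,
    window: int | None = None,
    max_edit_frac: float = 0.2,
) -> bool:
    """True iff the probe yields signal from this allele (sealable nick)."""
    return ligation_result(probe, allele, window, max_edit_frac).success


def expected_probe_signal(
    copies: Iterable[PromoterSequence],
    probe: HalfProbePair,
    window: int | None = None,
) -> int:
    """Number of gene copies from which the probe produces signal."""
    return sum(ligation_success(probe, c, window) for c in copies)


# ---------------------------------------------------------------------------
# File interfaces


def read_promoter_fasta(path, start: int | None = None) -> PromoterSequence:
    """Read a single promoter segment; coordinates anchored so it ends at -1."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if start is not None and start != -len(seq):
        raise ValueError("start coordinate inconsistent with sequence length")
    return PromoterSequence(id=rec.id, seq=seq, start=-len(seq))


def read_probes_tsv(path) -> list[HalfProbePair]:
    """TSV with columns probe_id, upstream_seq, downstream_seq, junction_pos."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    return [
        HalfProbePair(
            probe_id=r.probe_id,
            upstream=r.upstream_seq,
            downstream=r.downstream_seq,
            junction=int(r.junction_pos),
        )
        for r in df.itertuples()
    ]


def read_variants_tsv(path) -> list[Variant]:
    """TSV with columns pos, ref, alt and optional label (promoter coords)."""
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    df["alt"] = df["alt"].fillna("")
    return [
        Variant(
            position=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            label=getattr(r, "label", "") or "",
        )
        for r in df.itertuples()
    ]
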