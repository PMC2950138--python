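"""Half-probe ligation model: variant application, nick sealing, probe signal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlpacall import assay
from mlpacall.assay import INDEL_256, PROBE_NO_CNV, PROBE_TOTAL, PROBE_WT_ONLY
from mlpacall.ligation import (
    JUNCTION_MISMATCH,
    NO_HYBRIDIZATION,
    HalfProbePair,
    PromoterSequence,
    Variant,
    apply_variant,
    expected_probe_signal,
    ligation_result,
    ligation_success,
    read_probes_tsv,
    read_promoter_fasta,
    read_variants_tsv,
)


class TestCoordinates:
    def test_tss_anchored_map(self, wt_allele):
        assert wt_allele.start == -len(wt_allele.seq)
        assert wt_allele.base_at(-1) == wt_allele.seq[-1]
        assert wt_allele.base_at(wt_allele.start) == wt_allele.seq[0]

    def test_no_position_zero(self, wt_allele):
        with pytest.raises(ValueError, match="position 0"):
            wt_allele.index_of(0)

    def test_indel_site_is_adenine(self, wt_allele):
        assert wt_allele.base_at(-256) == "A"


class TestApplyVariant:
    def test_indel_net_plus_one_base(self, wt_allele):
        mut = apply_variant(wt_allele, INDEL_256)
        assert len(mut.seq) == len(wt_allele.seq) + 1
        i = wt_allele.index_of(-256)
        assert wt_allele.seq[i - 4 : i + 1].endswith("A")
        assert mut.seq[i - 4 : i + 2].endswith("TG")
        # bases 3' of the edit keep their TSS-anchored coordinates
        assert mut.base_at(-1) == wt_allele.base_at(-1)

    def test_pure_deletion_shortens(self, wt_allele):
        ref2 = wt_allele.seq[wt_allele.index_of(-50) : wt_allele.index_of(-48)]
        out = apply_variant(wt_allele, Variant(-50, ref2, ""))
        assert len(out.seq) == len(wt_allele.seq) - 2

    def test_identity_variant_is_noop(self, wt_allele):
        out = apply_variant(wt_allele, Variant(-256, "A", "A"))
        assert out.seq == wt_allele.seq

    def test_ref_mismatch_raises(self, wt_allele):
        wrong = "C" if wt_allele.base_at(-100) != "C" else "G"
        with pytest.raises(ValueError, match="mismatch"):
            apply_variant(wt_allele, Variant(-100, wrong, "T"))


class TestLigation:
    @pytest.mark.parametrize("window", [4, 8, 10])
    def test_all_probes_seal_on_reference(self, probes, wt_allele, window):
        for p in probes.values():
            assert ligation_success(p, wt_allele, window=window)

    @pytest.mark.parametrize("window", [4, 8, 10])
    def test_indel_silences_only_wt_probe(self, probes, mut_allele, window):
        res = ligation_result(probes[PROBE_WT_ONLY], mut_allele, window=window)
        assert not res.success and res.reason == JUNCTION_MISMATCH
        assert ligation_success(probes[PROBE_TOTAL], mut_allele, window=window)
        assert ligation_success(probes[PROBE_NO_CNV], mut_allele, window=window)

    def test_foreign_probe_does_not_hybridize(self, wt_allele):
        probe = HalfProbePair("X", "ACGT" * 8, "TGCA" * 8, junction=-300)
        res = ligation_result(probe, wt_allele)
        assert not res.success and res.reason == NO_HYBRIDIZATION


class TestExpectedSignal:
    def test_heterozygous_two_copy_individual(self, probes, wt_allele, mut_allele):
        copies = [wt_allele, mut_allele]
        assert expected_probe_signal(copies, probes[PROBE_WT_ONLY]) == 1
        assert expected_probe_signal(copies, probes[PROBE_TOTAL]) == 2

    def test_zero_copies(self, probes):
        for p in probes.values():
            assert expected_probe_signal([], p) == 0

    def test_three_copies_two_wild_type(self, probes, wt_allele, mut_allele):
        copies = [wt_allele, wt_allele, mut_allele]
        assert expected_probe_signal(copies, probes[PROBE_WT_ONLY]) == 2

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.booleans(), max_size=5))
    def test_probe_difference_counts_mutant_copies(
        self, probes, wt_allele, mut_allele, tags
    ):
        copies = [mut_allele if t else wt_allele for t in tags]
        total = expected_probe_signal(copies, probes[PROBE_TOTAL])
        wt_only = expected_probe_signal(copies, probes[PROBE_WT_ONLY])
        assert total == len(copies)
        assert total - wt_only == sum(tags)
        assert wt_only <= total


class TestFileInterfaces:
    def test_fasta_roundtrip(self, wt_allele, tmp_path):
        path = tmp_path / "ref.fa"
        path.write_text(f">{wt_allele.id}\n{wt_allele.seq}\n")
        back = read_promoter_fasta(path)
        assert back.seq == wt_allele.seq and back.start == wt_allele.start

    def test_probe_and_variant_tsv_readers(self, probes, tmp_path):
        ptsv = tmp_path / "probes.tsv"
        p = probes[PROBE_WT_ONLY]
        ptsv.write_text(
            "probe_id\tupstream_seq\tdownstream_seq\tjunction_pos\n"
            f"{p.probe_id}\t{p.upstream}\t{p.downstream}\t{p.junction}\n"
        )
        (loaded,) = read_probes_tsv(ptsv)
        assert loaded.upstream == p.upstream and loaded.junction == p.junction
        vtsv = tmp_path / "variants.tsv"
        vtsv.write_text("pos\tref\talt\tlabel\n-256\tA\tTG\t-256A>TG\n")
        (v,) = read_variants_tsv(vtsv)
        assert v == INDEL_256
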