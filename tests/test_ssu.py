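import numpy as np
import pytest

from its2delim import ssu, synth
from its2delim.seqio import SeqRecord


@pytest.fixture(scope="module")
def reference():
    return synth.default_reference()


class TestCoordinateMap:
    def test_identity(self, reference):
        m = ssu.map_to_reference(reference, reference)
        assert m.identity == 1.0
        assert not m.insertions
        assert m.query_to_ref[1] == 1
        assert m.query_to_ref[len(reference)] == len(reference)

    def test_deletion_shifts_downstream_positions(self, reference):
        seq = reference.sequence
        query = SeqRecord("del", seq[:200] + seq[210:])
        m = ssu.map_to_reference(query, reference)
        assert m.query_to_ref[100] == 100
        assert m.query_to_ref[300] == 310  # positions after the gap shift by 10

    def test_insertion_block_anchored(self, reference):
        q, truth = synth.gen_ssu(seed=1, introns=[(323, 400)])
        m = ssu.map_to_reference(q, reference)
        assert [(a, qs, qe) for a, qs, qe in m.insertions] == [(323, 324, 723)]

    def test_monotone_mapping(self, reference):
        q, _ = synth.gen_ssu(seed=2, sub_rate=0.03, introns=[(943, 300)])
        m = ssu.map_to_reference(q, reference)
        ordered = sorted(m.query_to_ref)
        refs = [m.query_to_ref[k] for k in ordered]
        assert refs == sorted(refs)


class TestDetectIntrons:
    def test_intron_free(self, reference):
        q, _ = synth.gen_ssu(seed=3, sub_rate=0.02)
        assert ssu.detect_introns(q, reference) == []

    def test_planted_anchors_recovered(self, reference):
        q, truth = synth.gen_ssu(seed=4, sub_rate=0.02, introns=[(323, 410), (1046, 395)])
        calls = ssu.detect_introns(q, reference)
        assert [c.ecoli_position for c in calls] == [323, 1046]
        assert [c.length for c in calls] == [410, 395]

    def test_excise_round_trip(self, reference):
        q, truth = synth.gen_ssu(
            seed=5, sub_rate=0.04, introns=[(323, 400), (943, 380), (1046, 420), (1512, 390)]
        )
        calls = ssu.detect_introns(q, reference)
        assert [c.ecoli_position for c in calls] == [323, 943, 1046, 1512]
        assert ssu.excise_introns(q, calls).sequence == truth.exon.sequence

    def test_anchor_invariant_to_truncated_flanks(self, reference):
        q, _ = synth.gen_ssu(seed=6, introns=[(1046, 400)])
        trimmed = SeqRecord("trim", q.sequence[60:-60])
        calls = ssu.detect_introns(trimmed, reference)
        assert [c.ecoli_position for c in calls] == [1046]

    def test_min_length_filter(self, reference):
        q, _ = synth.gen_ssu(seed=7, introns=[(323, 120), (1046, 80)])
        calls = ssu.detect_introns(q, reference, min_intron_len=100)
        assert [c.ecoli_position for c in calls] == [323]

    def test_overlapping_calls_rejected(self, reference):
        q, _ = synth.gen_ssu(seed=8, introns=[(323, 200)])
        bad = [
            ssu.IntronCall(324, 523, 200, 323),
            ssu.IntronCall(400, 450, 51, 399),
        ]
        with pytest.raises(ssu.SsuError, match="overlap"):
            ssu.excise_introns(q, bad)


class TestExtractRegion:
    def test_reference_window_verbatim(self, reference):
        seg, coords = ssu.extract_region(reference, reference, "V9")
        lo, hi = ssu.DEFAULT_WINDOWS["V9"]
        assert coords == (lo, hi)
        assert seg.sequence == reference.sequence[lo - 1 : hi]

    def test_insertion_inside_window_lengthens_segment(self, reference):
        lo, hi = ssu.DEFAULT_WINDOWS["V9"]
        seq = reference.sequence
        cut = lo + 60  # inside the window, outside the hairpin
        query = SeqRecord("ins", seq[:cut] + "GU" + seq[cut:])
        seg, _ = ssu.extract_region(query, reference, "V9")
        assert len(seg.sequence) == (hi - lo + 1) + 2

    def test_identical_queries_identical_segments(self, reference):
        q1, _ = synth.gen_ssu(seed=9, sub_rate=0.01)
        q2 = SeqRecord("copy", q1.sequence)
        s1, _ = ssu.extract_region(q1, reference, "V4")
        s2, _ = ssu.extract_region(q2, reference, "V4")
        assert s1.sequence == s2.sequence

    def test_unknown_region(self, reference):
        with pytest.raises(ssu.SsuError, match="unknown region"):
            ssu.extract_region(reference, reference, "V2")


class TestVariableSites:
    def test_single_variable_column(self):
        assert ssu.count_variable_sites(["ACGU", "ACGA", "ACGU"]) == (1, 4, 0.25)

    def test_all_identical(self):
        v, total, frac = ssu.count_variable_sites(["ACGU"] * 3)
        assert (v, total, frac) == (0, 4, 0.0)

    def test_gaps_and_ambiguity_ignored(self):
        v, _, _ = ssu.count_variable_sites(["AAAA", "A-NA", "AAAA"])
        assert v == 0

    def test_ragged_error(self):
        with pytest.raises(ssu.SsuError, match="ragged"):
            ssu.count_variable_sites(["ACGU", "ACG"])

    def test_row_permutation_invariance(self):
        rows = ["ACGUA", "AGGUA", "ACGUC"]
        base = ssu.count_variable_sites(rows)
        assert ssu.count_variable_sites(rows[::-1]) == base

    def test_additive_over_column_partition(self):
        rows = ["ACGUAC", "AGGUAC", "ACGUCC"]
        whole = ssu.count_variable_sites(rows)[0]
        left = ssu.count_variable_sites([r[:3] for r in rows])[0]
        right = ssu.count_variable_sites([r[3:] for r in rows])[0]
        assert whole == left + right


class TestCompareV9:
    def test_identical_all_identical(self, v9_panel):
        hap = ssu.fold_v9(v9_panel[0][0])
        rep = ssu.compare_v9(hap, hap)
        assert set(rep.totals.values()) - {0} == {rep.totals["identical"]}

    def test_planted_single_hcbc(self, v9_panel):
        h1 = ssu.fold_v9(v9_panel[0][0])
        h2 = ssu.fold_v9(v9_panel[1][0])
        rep = ssu.compare_v9(h1, h2)
        assert rep.totals["HCBC"] == 1
        assert rep.totals["CBC"] == 0

    def test_planted_single_cbc(self, v9_panel):
        h3 = ssu.fold_v9(v9_panel[2][0])
        h4 = ssu.fold_v9(v9_panel[3][0])
        rep = ssu.compare_v9(h3, h4)
        assert rep.totals["CBC"] == 1
        assert rep.totals["HCBC"] == 0

    def test_unpaired_input_rejected(self):
        a = ssu.fold_v9(SeqRecord("a", "ACACACAACC"))
        with pytest.raises(ssu.SsuError, match="helix"):
            ssu.compare_v9(a, a)


class TestHaplotypeLabels:
    def test_identical_share_label(self, v9_panel):
        recs = [r for r, _ in v9_panel]
        twin = SeqRecord("twin", recs[0].sequence)
        labels = ssu.assign_v9_haplotypes(recs + [twin])
        assert labels["twin"] == labels[recs[0].id]

    def test_five_distinct_labels(self, v9_panel):
        labels = ssu.assign_v9_haplotypes([r for r, _ in v9_panel])
        assert sorted(labels.values()) == ["1", "2", "3", "4", "5"]

    def test_lowercase_variants_within_profile(self, v9_panel):
        base = v9_panel[0][0]
        var_seq = list(base.sequence)
        var_seq[2] = "C" if var_seq[2] == "A" else "A"  # unpaired flank change
        variant = SeqRecord("flankvar", "".join(var_seq))
        labels = ssu.assign_v9_haplotypes([base, base, variant])
        assert labels[base.id] == "1a"
        assert labels["flankvar"] == "1b"
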