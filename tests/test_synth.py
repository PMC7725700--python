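import networkx as nx
import numpy as np
import pytest

from its2delim import synth
from its2delim.barcode import compare_barcodes, extract_barcode
from its2delim.fold import validate_constraints
from its2delim.seqio import read_fasta
from its2delim.synth import SynthError


class TestGenIts2Cassette:
    def test_same_seed_identical(self):
        r1, t1 = synth.gen_its2_cassette(seed=21)
        r2, t2 = synth.gen_its2_cassette(seed=21)
        assert r1.sequence == r2.sequence
        assert t1.structure.pairs == t2.structure.pairs
        assert t1.barcode.codes == t2.barcode.codes

    def test_different_seed_differs(self):
        r1, _ = synth.gen_its2_cassette(seed=22)
        r2, _ = synth.gen_its2_cassette(seed=23)
        assert r1.sequence != r2.sequence

    def test_truth_is_constraint_compliant(self):
        for seed in range(5):
            _, truth = synth.gen_its2_cassette(seed=seed)
            assert validate_constraints(truth.structure) == []

    def test_barcode_length_arithmetic(self):
        _, truth = synth.gen_its2_cassette(seed=24, helix_lens=(16, 11, 8))
        # quotas cap STEM/I/II; Helix III contributes all its rungs
        assert len(truth.barcode) == 16 + 5 + 11 + 8
        _, truth = synth.gen_its2_cassette(seed=24, helix_lens=(5, 11, 12))
        assert len(truth.barcode) == 16 + 5 + 11 + 12

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"helix_lens": (4, 11, 8)},
            {"helix_lens": (5, 9, 8)},
            {"mismatch_pos": 0},
            {"mismatch_pos": 10},
            {"motif_offset": 7},
            {"loop_len": 2},
        ],
    )
    def test_infeasible_params_rejected(self, kwargs):
        with pytest.raises(SynthError):
            synth.gen_its2_cassette(seed=1, **kwargs)


class TestPlantChanges:
    def test_empty_spec_unchanged(self, base_cassette):
        _, truth = base_cassette
        rec, mut = synth.plant_changes(truth, [], seed=1)
        assert rec.sequence == truth.record.sequence
        assert mut.barcode.codes == truth.barcode.codes

    def test_barcode_differs_exactly_per_spec(self, base_cassette):
        _, truth = base_cassette
        spec = [("STEM", 4, "CBC"), ("I", 3, "HCBC"), ("III", 5, "indel")]
        _, mut = synth.plant_changes(truth, spec, seed=2)
        rep = compare_barcodes(truth.barcode, mut.barcode)
        assert rep.totals["CBC"] == 1
        assert rep.totals["HCBC"] == 1
        assert rep.totals["indel"] == 1

    def test_mismatch_rung_rejected(self, base_cassette):
        _, truth = base_cassette
        with pytest.raises(SynthError, match="mismatch"):
            synth.plant_changes(truth, [("II", 7, "CBC")], seed=3)

    def test_stem_indel_rejected(self, base_cassette):
        _, truth = base_cassette
        with pytest.raises(SynthError, match="stem"):
            synth.plant_changes(truth, [("STEM", 2, "indel")], seed=4)

    def test_out_of_range_rejected(self, base_cassette):
        _, truth = base_cassette
        with pytest.raises(SynthError, match="outside"):
            synth.plant_changes(truth, [("I", 9, "CBC")], seed=5)

    def test_loop_changes_leave_barcode_alone(self, base_cassette):
        _, truth = base_cassette
        rec, var = synth.plant_loop_changes(truth, 2, seed=6)
        assert rec.sequence != truth.record.sequence
        assert var.barcode.codes == truth.barcode.codes
        assert compare_barcodes(truth.barcode, var.barcode).n_cbc == 0


class TestGenSsu:
    def test_no_mutation_no_intron_is_reference(self):
        ref = synth.default_reference()
        q, truth = synth.gen_ssu(seed=1, sub_rate=0.0)
        assert q.sequence == ref.sequence
        assert truth.introns == []

    def test_excision_round_trip_by_coordinates(self):
        q, truth = synth.gen_ssu(seed=2, sub_rate=0.02, introns=[(323, 150), (1046, 200)])
        seq = q.sequence
        for a, qs, qe, length in truth.introns:
            assert qe - qs + 1 == length
        exon = []
        prev = 0
        for _, qs, qe, _ in truth.introns:
            exon.append(seq[prev : qs - 1])
            prev = qe
        exon.append(seq[prev:])
        assert "".join(exon) == truth.exon.sequence

    def test_duplicate_anchor_rejected(self):
        with pytest.raises(SynthError, match="duplicate"):
            synth.gen_ssu(seed=3, introns=[(323, 100), (323, 100)])

    def test_anchor_outside_reference_rejected(self):
        with pytest.raises(SynthError, match="outside"):
            synth.gen_ssu(seed=4, introns=[(2000, 100)])

    def test_deterministic(self):
        a, _ = synth.gen_ssu(seed=5, sub_rate=0.05, introns=[(943, 300)])
        b, _ = synth.gen_ssu(seed=5, sub_rate=0.05, introns=[(943, 300)])
        assert a.sequence == b.sequence


class TestReferenceFile:
    def test_shipped_file_matches_generator(self):
        from importlib import resources

        rec, _ = synth.make_reference()
        with resources.as_file(
            resources.files("its2delim.data") / "ssu_reference_synthetic.fasta"
        ) as path:
            (shipped,) = read_fasta(path)
        assert shipped.sequence == rec.sequence
        assert shipped.id == rec.id


class TestHaplotypeSample:
    def test_counts_sum_to_n(self):
        recs, meta, truth = synth.gen_haplotype_sample(seed=1, n=37, length=50)
        assert len(recs) == 37
        assert sum(c for _, c in truth.values()) == 37
        assert set(meta.ids) == {r.id for r in recs}

    def test_every_haplotype_observed(self):
        recs, _, truth = synth.gen_haplotype_sample(
            seed=2, n=12, length=40, step_graph=nx.star_graph(4)
        )
        seqs = {r.sequence for r in recs}
        assert {s for s, _ in truth.values()} <= seqs

    def test_pairwise_distances_match_tree_paths(self):
        tree = nx.balanced_tree(2, 2)
        recs, _, truth = synth.gen_haplotype_sample(
            seed=3, n=20, length=60, step_graph=tree
        )
        tree = nx.relabel_nodes(tree, {v: str(v) for v in tree})
        for u in tree:
            for v in tree:
                d = sum(
                    a != b for a, b in zip(truth[u][0], truth[v][0])
                )
                assert d == nx.shortest_path_length(tree, u, v)

    def test_non_tree_rejected(self):
        with pytest.raises(SynthError, match="tree"):
            synth.gen_haplotype_sample(seed=4, n=10, length=20, step_graph=nx.cycle_graph(3))

    def test_too_small_sample_rejected(self):
        with pytest.raises(SynthError, match="n >="):
            synth.gen_haplotype_sample(seed=5, n=2, length=20, step_graph=nx.path_graph(4))


class TestV9Panel:
    def test_deterministic(self):
        a = synth.gen_v9_panel(seed=1)
        b = synth.gen_v9_panel(seed=1)
        assert [(r.sequence, l) for r, l in a] == [(r.sequence, l) for r, l in b]

    def test_five_distinct_sequences(self, v9_panel):
        assert len({r.sequence for r, _ in v9_panel}) == 5
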