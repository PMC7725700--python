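import numpy as np
import pytest

from its2delim import synth
from its2delim.barcode import (
    align_barcodes,
    classify_changes,
    compare_barcodes,
    decode,
    delimit_species,
    encode_pair,
    extract_barcode,
    union_and_sum_tallies,
)


class TestEncodePair:
    @pytest.mark.parametrize(
        "b5,b3,code",
        [
            ("A", "U", "1"), ("U", "A", "2"), ("G", "C", "3"), ("C", "G", "4"),
            ("G", "U", "5"), ("U", "G", "6"),
            ("C", "U", "7"), ("U", "U", "7"), ("A", "G", "7"),
            ("A", None, "8"), (None, "C", "8"), ("A", "-", "8"),
        ],
    )
    def test_code_table(self, b5, b3, code):
        assert encode_pair(b5, b3) == code

    def test_ambiguity_rejected(self):
        with pytest.raises(ValueError, match="ambiguity"):
            encode_pair("N", "U")

    def test_decode_inverts_canonical_codes(self):
        for code in "123456":
            assert encode_pair(*decode(code)) == code
        with pytest.raises(ValueError):
            decode("7")


class TestExtractBarcode:
    def test_full_quota_length_40(self, base_cassette):
        _, truth = base_cassette
        bc = extract_barcode(truth.structure)
        assert len(bc) == 40
        assert bc.segment_lengths == {
            "STEM": 16, "HELIX_I": 5, "HELIX_II": 11, "HELIX_III": 8,
        }
        assert not bc.partial

    def test_mismatch_encoded_as_7(self, base_cassette):
        _, truth = base_cassette
        bc = extract_barcode(truth.structure)
        h2 = bc.segment("HELIX_II")
        assert h2[6].code == "7"  # mismatch after the 6 basal pairs
        assert all(p.code != "7" for p in h2[:6])

    def test_short_stem_padded_and_partial(self):
        _, truth = synth.gen_its2_cassette(seed=3, stem_len=14)
        bc = extract_barcode(truth.structure)
        stem = bc.segment("STEM")
        assert [p.code for p in stem[14:]] == ["8", "8"]
        assert bc.partial

    def test_requires_decomposition(self, base_cassette):
        from its2delim.fold import SecondaryStructure

        rec, truth = base_cassette
        bare = SecondaryStructure(rec, truth.structure.pairs)
        with pytest.raises(ValueError, match="decomposed"):
            extract_barcode(bare)


class TestAlignBarcodes:
    def test_identical_no_gaps(self, base_cassette):
        _, truth = base_cassette
        bc = extract_barcode(truth.structure)
        aligned = align_barcodes(bc, bc)
        assert all(c.a is not None and c.b is not None for c in aligned.columns)
        assert len(aligned.columns) == len(bc)

    def test_helix3_length_difference_one_gap_column(self):
        _, truth9 = synth.gen_its2_cassette(seed=12, helix_lens=(5, 11, 9))
        _, truth8 = synth.plant_changes(truth9, [("III", 9, "indel")], seed=12)
        a = extract_barcode(truth9.structure)
        b = extract_barcode(truth8.structure)
        aligned = align_barcodes(a, b)
        gap_cols = [c for c in aligned.columns if c.a is None or c.b is None]
        assert len(gap_cols) == 1
        assert gap_cols[0].segment == "HELIX_III"

    def test_single_substitution_pairs_without_gap(self, base_cassette):
        _, truth = base_cassette
        _, mut = synth.plant_changes(truth, [("III", 5, "CBC")], seed=4)
        aligned = align_barcodes(
            extract_barcode(truth.structure), extract_barcode(mut.structure)
        )
        assert all(c.a is not None and c.b is not None for c in aligned.columns)
        rep = classify_changes(aligned)
        assert rep.totals["CBC"] == 1
        assert rep.totals["indel"] == 0


class TestClassifyChanges:
    def test_definitional_columns(self, base_cassette):
        _, truth = base_cassette
        _, mut = synth.plant_changes(
            truth, [("I", 3, "CBC"), ("III", 6, "HCBC")], seed=5
        )
        rep = compare_barcodes(
            extract_barcode(truth.structure), extract_barcode(mut.structure)
        )
        assert rep.totals["CBC"] == 1
        assert rep.totals["HCBC"] == 1
        by = {(c.segment, c.position): c.klass for c in rep.changes()}
        assert by == {("HELIX_I", 3): "CBC", ("HELIX_III", 6): "HCBC"}

    def test_symmetry(self, base_cassette):
        _, truth = base_cassette
        rng = np.random.default_rng(0)
        for k in range(10):
            spec = [
                ("III", int(rng.integers(4, 9)), "CBC"),
                ("II", int(rng.integers(1, 6)), "HCBC"),
            ]
            _, mut = synth.plant_changes(truth, spec, seed=50 + k)
            a = extract_barcode(truth.structure)
            b = extract_barcode(mut.structure)
            assert compare_barcodes(a, b).totals == compare_barcodes(b, a).totals

    def test_classes_partition_columns(self, base_cassette):
        _, truth = base_cassette
        _, mut = synth.plant_changes(
            truth, [("III", 4, "indel"), ("II", 3, "CBC")], seed=6
        )
        rep = compare_barcodes(
            extract_barcode(truth.structure), extract_barcode(mut.structure)
        )
        assert sum(rep.totals.values()) == len(rep.columns)

    def test_planted_counts_recovered(self, base_cassette):
        _, truth = base_cassette
        rng = np.random.default_rng(1)
        for k in range(25):
            cbc_pos = rng.choice(np.arange(4, 9), size=2, replace=False)
            hcbc_pos = rng.choice(np.arange(1, 7), size=2, replace=False)
            spec = [("III", int(p), "CBC") for p in cbc_pos]
            spec += [("II", int(p), "HCBC") for p in hcbc_pos if p != 7]
            _, mut = synth.plant_changes(truth, spec, seed=100 + k)
            rep = compare_barcodes(
                extract_barcode(truth.structure), extract_barcode(mut.structure)
            )
            want_cbc = sum(1 for s in spec if s[2] == "CBC")
            want_hcbc = sum(1 for s in spec if s[2] == "HCBC")
            assert rep.totals["CBC"] == want_cbc
            assert rep.totals["HCBC"] == want_hcbc

    def test_two_indels_two_gap_columns(self, base_cassette):
        _, truth = base_cassette
        _, mut = synth.plant_changes(
            truth, [("III", 4, "indel"), ("III", 6, "indel")], seed=7
        )
        rep = compare_barcodes(
            extract_barcode(truth.structure), extract_barcode(mut.structure)
        )
        assert rep.totals["indel"] == 2


class TestDelimit:
    def test_identical_one_component(self, base_cassette):
        _, truth = base_cassette
        bc = extract_barcode(truth.structure)
        bc2 = extract_barcode(truth.structure)
        bc2 = type(bc2)("copy", bc2.positions)
        res = delimit_species([bc, bc2])
        assert res.n_species == 1

    def test_single_cbc_splits(self, base_cassette):
        _, truth = base_cassette
        _, mut = synth.plant_changes(truth, [("III", 5, "CBC")], seed=8)
        res = delimit_species(
            [extract_barcode(truth.structure), extract_barcode(mut.structure)]
        )
        assert res.n_species == 2

    def test_hcbc_alone_does_not_split(self, base_cassette):
        _, truth = base_cassette
        _, mut = synth.plant_changes(truth, [("II", 4, "HCBC")], seed=9)
        res = delimit_species(
            [extract_barcode(truth.structure), extract_barcode(mut.structure)]
        )
        assert res.n_species == 1

    def test_three_species_with_conspecific_variant(self, species_scenario):
        barcodes = [extract_barcode(t.structure) for t in species_scenario["truths"]]
        res = delimit_species(barcodes)
        assert res.n_species == 3
        comp_of = {rid: k for k, comp in enumerate(res.components) for rid in comp}
        assert comp_of["speciesA"] == comp_of["speciesA_var"]

    def test_rationale_table_consistent(self, species_scenario):
        barcodes = [extract_barcode(t.structure) for t in species_scenario["truths"]]
        res = delimit_species(barcodes)
        table = res.rationale()
        same = table[table.same_species]
        assert ((same.component_a == same.component_b)).all()


class TestUnionAndSum:
    def test_union_counts_columns_once(self, species_scenario):
        barcodes = [
            extract_barcode(t.structure)
            for t in species_scenario["truths"]
            if t.record.id != "speciesA_var"
        ]
        tallies = union_and_sum_tallies(barcodes)
        assert tallies["union"] == {"CBC": 4, "HCBC": 8, "indel": 0}
        # every changed column separates exactly two of the three pairs
        assert tallies["sum"] == {"CBC": 8, "HCBC": 16, "indel": 0}

    def test_degenerate_inputs(self, base_cassette):
        _, truth = base_cassette
        bc = extract_barcode(truth.structure)
        assert union_and_sum_tallies([bc])["union"]["CBC"] == 0
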