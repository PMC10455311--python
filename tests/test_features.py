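import numpy as np
import pytest

from foldrate.constants import AMINO_ACIDS, SIX_GROUPS, WINDOW_GROUPS
from foldrate.features import (
    FAMILY_SIZES,
    TOTAL_FEATURES,
    FeatureError,
    featurize,
    load_feature_subset,
    neighborhood_features,
    relative_position,
    select_named_subset,
    structural_features,
    variation_type_features,
)
from foldrate.features.aaindex import AAIndexError, load_default_table
from foldrate.features.conservation import ConservationAnnotation, coupling_summaries
from foldrate.features.featurize import feature_names, load_residue_groups
from foldrate.features.structure import MissingStructureError, StructuralAnnotation

import pandas as pd


@pytest.fixture(scope="module")
def table():
    return load_default_table()


@pytest.fixture()
def one_variant(small_synth):
    data = small_synth
    rec = data.dataset.records[0]
    return rec, data


class TestAAIndexFeatures:
    def test_counts(self, table):
        assert len(table.single_indices) == 553
        assert len(table.pair_indices) == 135
        assert len(table.feature_names) == 688

    def test_wt_equals_var_single_indices_zero(self, table):
        # only meaningful in tests; real records forbid wt == var
        vals = table.features("A", "A")
        assert np.allclose(vals[: len(table.single_indices)], 0.0)

    def test_difference_sign_flips(self, table):
        n_single = len(table.single_indices)
        fwd = table.features("A", "V")[:n_single]
        rev = table.features("V", "A")[:n_single]
        assert np.allclose(fwd, -rev)

    def test_symmetric_pair_index(self, table):
        sym_ids = [i for i in table.pair_ids if table.is_symmetric(i)]
        assert sym_ids
        n_single = len(table.single_indices)
        fwd = table.features("A", "V")[n_single:]
        rev = table.features("V", "A")[n_single:]
        for iid, f, r in zip(table.pair_ids, fwd, rev):
            if table.is_symmetric(iid):
                assert f == r

    def test_every_index_covers_all_residues(self, table):
        for wt in "AW":
            for var in "CV":
                assert np.isfinite(table.features(wt, var)).all()

    def test_unknown_residue(self, table):
        with pytest.raises(AAIndexError):
            table.features("A", "X")


class TestVariationType:
    def test_sums_to_two(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            wt, var = rng.choice(list(AMINO_ACIDS), 2, replace=False)
            assert variation_type_features(wt, var).sum() == 2.0

    def test_cell_names(self):
        names = feature_names()
        vec = variation_type_features("V", "A")
        start = FAMILY_SIZES["amino_acid"] + FAMILY_SIZES["conservation"]
        hot = [names[start + i] for i in np.nonzero(vec)[0]]
        assert "V_A" in hot

    def test_group_cell_d_to_a(self):
        # D (negatively charged, g2) to A (other group, g6)
        names = feature_names()
        vec = variation_type_features("D", "A")
        start = FAMILY_SIZES["amino_acid"] + FAMILY_SIZES["conservation"]
        hot = [names[start + i] for i in np.nonzero(vec)[0]]
        assert "g2_g6" in hot

    def test_partition_covers_and_disjoint(self):
        groups = load_residue_groups()
        assert groups["g2"] == frozenset("DE")
        assert frozenset("AT") <= groups["g6"]
        all_members = sorted(aa for g in groups.values() for aa in g)
        assert "".join(sorted(AMINO_ACIDS)) == "".join(all_members)

    def test_unknown_residue(self):
        with pytest.raises(FeatureError):
            variation_type_features("A", "X")


class TestNeighborhood:
    def test_homopolymer(self):
        vec = neighborhood_features("A" * 50, 25)
        assert vec[AMINO_ACIDS.index("A")] == 1.0
        assert vec[:20].sum() == 1.0
        assert np.count_nonzero(vec[:20]) == 1

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list(AMINO_ACIDS), 80))
        for pos in (1, 5, 40, 80):
            vec = neighborhood_features(seq, pos)
            assert vec[:20].sum() == pytest.approx(1.0)
            assert (vec[20:] <= 1.0 + 1e-12).all()

    def test_positive_charge_brute_force(self):
        # window of 25 around position 13 in a 30-mer: count K/R/H directly
        seq = "KKKRH" + "A" * 25
        vec = neighborhood_features(seq, 13)
        window = seq[0:25]
        expected = sum(1 for aa in window if aa in WINDOW_GROUPS["PosAA"]) / 25
        pos_idx = 20 + 3  # NonPolar, Polar, Charged, Pos
        assert vec[pos_idx] == pytest.approx(expected)

    def test_truncation_at_ends(self):
        seq = "W" + "A" * 40
        vec = neighborhood_features(seq, 1)  # window is positions 1..13
        assert vec[AMINO_ACIDS.index("W")] == pytest.approx(1 / 13)

    def test_position_out_of_range(self):
        with pytest.raises(FeatureError):
            neighborhood_features("AAAA", 9)


class TestRelativePosition:
    def test_terminal(self):
        assert relative_position(100, 100) == 1.0

    def test_first(self):
        assert relative_position(1, 100) == 0.01

    def test_midpoint_odd(self):
        length = 101
        mid = (length + 1) // 2
        assert relative_position(mid, length) == pytest.approx(
            (length + 1) / (2 * length)
        )

    def test_out_of_range(self):
        with pytest.raises(FeatureError):
            relative_position(0, 10)
        with pytest.raises(FeatureError):
            relative_position(11, 10)


class TestStructuralFeatures:
    def test_rsa_definitional(self):
        from foldrate.constants import MAX_ASA

        ann = StructuralAnnotation(ss={1: "H"}, asa={1: MAX_ASA["W"]})
        vec = structural_features(ann, 1, "W")
        assert vec[-1] == pytest.approx(1.0)

    def test_helix_one_hot(self):
        ann = StructuralAnnotation(ss={1: "H"}, asa={1: 10.0})
        vec = structural_features(ann, 1, "A")
        assert vec[:7].sum() == 1.0
        assert vec[0] == 1.0  # H is the first state

    def test_missing_position_raises(self):
        ann = StructuralAnnotation(ss={1: "H"}, asa={1: 10.0})
        with pytest.raises(MissingStructureError):
            structural_features(ann, 2, "A")

    def test_unknown_ss_class_rejected(self):
        from foldrate.features.structure import StructureError

        with pytest.raises(StructureError):
            StructuralAnnotation(ss={1: "Z"}, asa={1: 1.0})


class TestFeaturize:
    def test_total_length_and_families(self, one_variant):
        rec, data = one_variant
        fv = featurize(
            rec,
            data.dataset.sequences[rec.protein_id],
            data.structures[rec.protein_id],
            data.conservations[rec.protein_id],
        )
        assert len(fv) == TOTAL_FEATURES == 1161
        sizes = {fam: len(fv.family(fam)) for fam in FAMILY_SIZES}
        assert sizes == {
            "amino_acid": 688,
            "conservation": 3,
            "variation_type": 436,
            "neighborhood": 25,
            "protein_type": 1,
            "structural": 8,
        }
        # family ranges are disjoint and cover the vector
        spans = sorted(fv.families.values())
        assert spans[0][0] == 0 and spans[-1][1] == len(fv)
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b == c

    def test_deterministic(self, one_variant):
        rec, data = one_variant
        args = (
            rec,
            data.dataset.sequences[rec.protein_id],
            data.structures[rec.protein_id],
            data.conservations[rec.protein_id],
        )
        a = featurize(*args)
        b = featurize(*args)
        assert np.array_equal(a.values, b.values)
        assert a.names == b.names

    def test_missing_annotation_names_family(self, one_variant):
        rec, data = one_variant
        empty = ConservationAnnotation(scores={})
        with pytest.raises(FeatureError, match="conservation"):
            featurize(
                rec,
                data.dataset.sequences[rec.protein_id],
                data.structures[rec.protein_id],
                empty,
            )

    def test_name_lookup(self, one_variant):
        rec, data = one_variant
        fv = featurize(
            rec,
            data.dataset.sequences[rec.protein_id],
            data.structures[rec.protein_id],
            data.conservations[rec.protein_id],
        )
        assert fv["rp"] == pytest.approx(
            rec.position / len(data.dataset.sequences[rec.protein_id])
        )


class TestNamedSubsets:
    def test_bundled_sizes(self):
        assert len(load_feature_subset("classifier31")) == 31
        assert len(load_feature_subset("regressor21")) == 21

    def test_overlap_of_bundled_lists(self):
        # the two published selected-feature tables share 10 names
        # (their accompanying text counts nine; the tables disagree)
        c31 = set(load_feature_subset("classifier31"))
        r21 = set(load_feature_subset("regressor21"))
        assert len(c31 & r21) == 10
        assert {"rsa", "C-score", "rp"} <= (c31 & r21)

    def test_projection_order_and_values(self, one_variant):
        rec, data = one_variant
        fv = featurize(
            rec,
            data.dataset.sequences[rec.protein_id],
            data.structures[rec.protein_id],
            data.conservations[rec.protein_id],
        )
        sub = select_named_subset(fv, ("rsa", "rp"))
        assert sub.names == ("rsa", "rp")
        assert sub.values[0] == fv["rsa"]
        assert sub.values[1] == fv["rp"]

    def test_unknown_name(self, one_variant):
        rec, data = one_variant
        fv = featurize(
            rec,
            data.dataset.sequences[rec.protein_id],
            data.structures[rec.protein_id],
            data.conservations[rec.protein_id],
        )
        with pytest.raises(FeatureError, match="nope"):
            select_named_subset(fv, ("nope",))


class TestConservation:
    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "cons.tsv"
        path.write_text(
            "protein_id\tposition\tc_score\tcoev_max\tcoev_partners\n"
            "P1\t1\t0.5\t1.2\t3\n"
        )
        ann = ConservationAnnotation.from_tsv(path, "P1")
        assert ann.features(1).tolist() == [0.5, 1.2, 3.0]

    def test_exactly_three_features(self, small_synth):
        ann = next(iter(small_synth.conservations.values()))
        pos = next(iter(ann.scores))
        assert ann.features(pos).shape == (3,)

    def test_alignment_entropy_fallback(self, tmp_path):
        aln = tmp_path / "aln.fasta"
        # column 1 fully conserved, column 2 maximally varied
        aln.write_text(">s1\nAC\n>s2\nAD\n>s3\nAE\n>s4\nAF\n")
        ann = ConservationAnnotation.from_alignment(aln)
        c1 = ann.features(1)[0]
        c2 = ann.features(2)[0]
        assert c1 == pytest.approx(1.0)
        assert c2 < c1

    def test_coupling_summaries(self):
        coupling = pd.DataFrame(
            {
                "pos_i": [1, 1, 2],
                "pos_j": [2, 3, 3],
                "strength": [0.9, 0.1, 0.2],
            }
        )
        out = coupling_summaries(coupling, 3, quantile=0.5)
        row1 = out[out.position == 1].iloc[0]
        assert row1.coev_max == pytest.approx(0.9)
        assert row1.coev_partners == 1
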