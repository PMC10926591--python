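"""Pairwise similarity channels: motif Jaccard, co-expression, structure,
orthogroups, STRING selection, and pair-vector assembly."""

import numpy as np
import pandas as pd
import pytest

from pufannot import features as ft


class TestShannonWeights:
    def test_hand_computed_weights(self):
        mat = pd.DataFrame(
            {
                "all": [1, 1, 1, 1],
                "half": [1, 1, 0, 0],
                "quarter": [1, 0, 0, 0],
            },
            index=list("abcd"),
        )
        w = ft.shannon_weights(mat)
        assert w["all"] == pytest.approx(0.0)  # -log2(1)
        assert w["half"] == pytest.approx(1.0)  # -log2(1/2)
        assert w["quarter"] == pytest.approx(2.0)  # -log2(1/4)

    def test_zero_count_feature_rejected(self):
        mat = pd.DataFrame({"f": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="zero"):
            ft.shannon_weights(mat)


class TestWeightedJaccard:
    W = {"f1": 1.0, "f2": 2.0, "f3": 0.0}

    def test_identical_vectors(self):
        assert ft.weighted_jaccard_distance({"f1", "f2"}, {"f1", "f2"}, self.W) == 0

    def test_disjoint_vectors(self):
        assert ft.weighted_jaccard_distance({"f1"}, {"f2"}, self.W) == 1

    def test_hand_computed_case(self):
        # intersection {f1,f3} weight 1; union weight 3 -> 1 - 1/3
        d = ft.weighted_jaccard_distance({"f1", "f2", "f3"}, {"f1", "f3"}, self.W)
        assert d == pytest.approx(2 / 3)

    def test_degenerate_zero_union(self):
        assert ft.weighted_jaccard_distance({"f3"}, {"f3"}, self.W) == 0.0
        assert (
            ft.weighted_jaccard_distance(
                {"f3"}, {"f3"}, self.W, degenerate_value=0.5
            )
            == 0.5
        )

    def test_equals_unweighted_when_weights_equal(self):
        rng = np.random.default_rng(0)
        feats = [f"f{i}" for i in range(8)]
        w = {f: 1.0 for f in feats}
        for _ in range(20):
            a = set(rng.choice(feats, size=rng.integers(1, 6), replace=False))
            b = set(rng.choice(feats, size=rng.integers(1, 6), replace=False))
            expected = 1 - len(a & b) / len(a | b)
            assert ft.weighted_jaccard_distance(a, b, w) == pytest.approx(expected)

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(1)
        feats = list(self.W)
        for _ in range(20):
            a = set(rng.choice(feats, size=rng.integers(1, 3), replace=False))
            b = set(rng.choice(feats, size=rng.integers(1, 3), replace=False))
            d_ab = ft.weighted_jaccard_distance(a, b, self.W)
            assert 0 <= d_ab <= 1
            assert d_ab == ft.weighted_jaccard_distance(b, a, self.W)


def make_experiment(data, conditions=("c1", "c2", "c3")):
    samples = {f"s{i}": c for i, c in enumerate(conditions)}
    mat = pd.DataFrame(data, columns=list(samples), index=list(data.keys())) \
        if isinstance(data, dict) else None
    frame = pd.DataFrame.from_dict(data, orient="index", columns=list(samples))
    return ft.QuantExperiment("e1", frame, samples)


class TestCoexpression:
    def test_perfect_antirank(self):
        exp = make_experiment({"A": [1, 2, 3], "B": [3, 2, 1]})
        spearman, _ = ft.coexpression_features([exp], ["A", "B"])
        assert spearman.at["A", "B"] == pytest.approx(-1.0)

    def test_missing_protein_gets_zero_correlation(self):
        exp = make_experiment({"A": [1, 2, 3]})
        spearman, _ = ft.coexpression_features([exp], ["A", "B"])
        assert spearman.at["A", "B"] == 0.0

    def test_presence_jaccard_hand_case(self):
        # A present in conditions {1,2}, B in {2,3}: distance 1 - 1/3
        exp = make_experiment({"A": [5, 5, 0], "B": [0, 5, 5]})
        _, jacc = ft.coexpression_features([exp], ["A", "B"])
        assert jacc.at["A", "B"] == pytest.approx(2 / 3)

    def test_never_observed_protein_distance_one(self):
        exp = make_experiment({"A": [1, 2, 3]})
        _, jacc = ft.coexpression_features([exp], ["A", "B"])
        assert jacc.at["A", "B"] == 1.0

    def test_rank_invariance_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        vals = {p: list(rng.uniform(1, 100, 4)) for p in "ABCD"}
        exp1 = make_experiment(vals, conditions=("c1", "c2", "c3", "c4"))
        exp2 = make_experiment(
            {p: list(np.exp(np.array(v) / 20)) for p, v in vals.items()},
            conditions=("c1", "c2", "c3", "c4"),
        )
        s1, _ = ft.coexpression_features([exp1], list("ABCD"))
        s2, _ = ft.coexpression_features([exp2], list("ABCD"))
        assert np.allclose(s1.to_numpy(), s2.to_numpy())

    def test_condition_averaging_of_nonzero_samples(self):
        samples = {"s1": "c1", "s2": "c1", "s3": "c2"}
        frame = pd.DataFrame([[4.0, 0.0, 6.0]], index=["A"], columns=samples)
        exp = ft.QuantExperiment("e", frame, samples)
        prof = exp.condition_profiles()
        assert prof.at["A", "c1"] == 4.0  # zero samples excluded from the mean
        assert prof.at["A", "c2"] == 6.0

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError, match="2 conditions"):
            make_experiment({"A": [1, 1, 1]}, conditions=("c1", "c1", "c1"))

    def test_bounded(self, small_data):
        spearman, jacc = ft.coexpression_features(
            small_data.experiments, small_data.proteins[:30]
        )
        assert spearman.to_numpy().min() >= -1 and spearman.to_numpy().max() <= 1
        assert jacc.to_numpy().min() >= 0 and jacc.to_numpy().max() <= 1


class TestTrimStructure:
    def test_low_head_trimmed_and_kept(self):
        model = ft.ResidueConfidenceModel("p", [50] * 5 + [80] * 35)
        trimmed = ft.trim_structure(model)
        assert trimmed is not None and len(trimmed) == 35

    def test_all_low_rejected(self):
        model = ft.ResidueConfidenceModel("p", [60] * 40)
        assert ft.trim_structure(model) is None

    def test_boundary_exactly_min_length_rejected(self):
        # 25 retained residues <= 30: rejected (strict >)
        model = ft.ResidueConfidenceModel("p", [80] * 25 + [60] * 10)
        assert ft.trim_structure(model) is None

    def test_interior_low_confidence_untouched(self):
        model = ft.ResidueConfidenceModel(
            "p", [80] * 20 + [50] * 5 + [80] * 20
        )
        trimmed = ft.trim_structure(model)
        assert len(trimmed) == 45

    def test_output_is_contiguous_subsequence(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            plddt = rng.uniform(30, 100, size=rng.integers(31, 80))
            model = ft.ResidueConfidenceModel("p", plddt)
            trimmed = ft.trim_structure(model)
            if trimmed is None:
                continue
            n = len(trimmed)
            assert n > 30
            found = any(
                np.array_equal(trimmed.plddt, plddt[i : i + n])
                for i in range(len(plddt) - n + 1)
            )
            assert found

    def test_pdb_roundtrip(self, tmp_path, small_data):
        from pufannot.synthetic_data import _write_pdb

        p = small_data.proteins[0]
        path = tmp_path / "m.pdb"
        _write_pdb(small_data.structures[p], small_data.sequences[p], path)
        model = ft.read_plddt_model(path, p)
        assert np.allclose(model.plddt, small_data.structures[p].plddt)


class TestTmPair:
    def test_max_of_two_normalizations(self):
        assert ft.tm_pair_feature(0.5, 0.7, 2.1) == (0.7, 2.1)

    def test_equal_case_and_symmetry(self):
        assert ft.tm_pair_feature(0.4, 0.4, 1.0) == (0.4, 1.0)
        assert ft.tm_pair_feature(0.2, 0.9, 3.0) == ft.tm_pair_feature(0.9, 0.2, 3.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ft.tm_pair_feature(1.2, 0.5, 1.0)


class TestOrthogroups:
    def test_intersection_size(self):
        table = {"a": frozenset("123"), "b": frozenset("234")}
        assert ft.orthogroup_overlap(table, "a", "b") == 2

    def test_same_orthogroup(self):
        s = frozenset("12345")
        assert ft.orthogroup_overlap({"a": s, "b": s}, "a", "b") == 5

    def test_missing_orthogroup_gives_zero(self):
        assert ft.orthogroup_overlap({"a": frozenset("12")}, "a", "x") == 0


class TestStringSelection:
    def make_table(self):
        return pd.DataFrame(
            {
                "protein1": ["a", "b"],
                "protein2": ["b", "c"],
                "coexpression": [500, 100],
                "coexpression_transferred": [400, 0],
                "experiments": [300, 0],
                "textmining": [200, 900],
                "combined_score": [800, 900],
            }
        )

    def test_excluded_subscores_absent(self):
        out = ft.select_string_scores(self.make_table())
        assert "coexpression" not in out.columns
        assert "experiments" not in out.columns

    def test_transferred_variants_retained(self):
        out = ft.select_string_scores(self.make_table())
        assert "coexpression_transferred" in out.columns

    def test_rescaled_to_unit_interval(self):
        out = ft.select_string_scores(self.make_table())
        row = out[(out.protein_a == "a") & (out.protein_b == "b")].iloc[0]
        assert row["combined_score"] == pytest.approx(0.8)

    def test_missing_columns_listed(self):
        with pytest.raises(ValueError, match="combined_score"):
            ft.select_string_scores(
                pd.DataFrame({"protein1": [], "protein2": []})
            )


class TestAssembly:
    def test_pair_count(self):
        frame = ft.assemble_pair_features(list("abcde"))
        assert len(frame) == 10  # 5 choose 2

    def test_no_evidence_pair_uses_fill_policy(self):
        frame = ft.assemble_pair_features(["a", "b"])
        row = frame.iloc[0]
        assert row["motif_weighted_jaccard"] == 1.0
        assert row["presence_jaccard"] == 1.0
        assert row["bitscore"] == 0.0
        assert row["tm_max"] == 0.0

    def test_symmetric_under_pair_order(self):
        bit = pd.DataFrame(
            {"protein_a": ["b"], "protein_b": ["a"], "value": [42.0]}
        )
        frame = ft.assemble_pair_features(["a", "b"], bitscore_table=bit)
        assert frame.iloc[0]["bitscore"] == 42.0
        assert (frame.iloc[0]["protein_a"], frame.iloc[0]["protein_b"]) == ("a", "b")

    def test_channel_values_match_direct_lookup(self, small_data):
        import pufannot.features as ftt

        frame = ft.assemble_pair_features(
            small_data.proteins,
            bitscore_table=small_data.bitscore_table,
            tm_table=small_data.tm_table,
            orthogroups=small_data.orthogroups,
        )
        lookup = {
            ftt.pair_key(r.protein_a, r.protein_b): r.value
            for r in small_data.bitscore_table.itertuples(index=False)
        }
        sample = frame.sample(50, random_state=0)
        for row in sample.itertuples(index=False):
            key = (row.protein_a, row.protein_b)
            assert row.bitscore == lookup.get(key, 0.0)
            assert row.orthogroup_overlap == ft.orthogroup_overlap(
                small_data.orthogroups, row.protein_a, row.protein_b
            )

    def test_stray_ids_warned_and_dropped(self, caplog):
        bit = pd.DataFrame(
            {"protein_a": ["z"], "protein_b": ["a"], "value": [1.0]}
        )
        with caplog.at_level("WARNING"):
            frame = ft.assemble_pair_features(["a", "b"], bitscore_table=bit)
        assert "outside the protein universe" in caplog.text
        assert (frame["bitscore"] == 0).all()
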