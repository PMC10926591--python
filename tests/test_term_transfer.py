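"""Candidate enumeration, labeling precedence, FDR calibration, closure."""

import numpy as np
import pandas as pd
import pytest

from pufannot import ontology as onto
from pufannot import term_transfer as tt

from conftest import CHAIN, ROOT, W, X, Y, Z


def hit(hid, annotations, **scores):
    return tt.Hit(hid, scores, frozenset(annotations))


class TestEnumerate:
    def test_union_of_hit_annotations(self):
        hs = tt.HitSet("q", [hit("p1", {X, Y}), hit("p2", {Y, Z})])
        assert tt.enumerate_candidates(hs) == {X, Y, Z}

    def test_no_hits_gives_empty(self):
        assert tt.enumerate_candidates(tt.HitSet("q", [])) == set()

    def test_query_excluded_from_its_own_hits(self):
        hs = tt.HitSet("q", [hit("q", {X}), hit("p", {Y})])
        assert tt.enumerate_candidates(hs) == {Y}


class TestSummarize:
    def test_sum_and_max_of_tm(self):
        hs = tt.HitSet(
            "q", [hit("a", {X}, tm=0.6), hit("b", {X}, tm=0.8), hit("c", {Y}, tm=0.1)]
        )
        vec = tt.summarize_hits(hs, X, ["tm"])
        assert vec["tm_sum"] == pytest.approx(1.4)
        assert vec["tm_max"] == pytest.approx(0.8)
        assert vec["tm_count"] == 2

    def test_single_hit_statistics_coincide(self):
        hs = tt.HitSet("q", [hit("a", {X}, s=0.3)])
        vec = tt.summarize_hits(hs, X, ["s"])
        assert vec["s_sum"] == vec["s_max"] == vec["s_mean"] == pytest.approx(0.3)
        assert vec["s_count"] == 1

    def test_invariant_to_hit_order(self):
        hits = [hit(f"h{i}", {X}, s=v) for i, v in enumerate([0.1, 0.9, 0.4])]
        v1 = tt.summarize_hits(tt.HitSet("q", hits), X, ["s"])
        v2 = tt.summarize_hits(tt.HitSet("q", hits[::-1]), X, ["s"])
        assert v1 == v2

    def test_missing_measure_uses_fill(self):
        hs = tt.HitSet("q", [hit("a", {X}, s=0.5), hit("b", {X})])
        vec = tt.summarize_hits(hs, X, ["s"])
        assert vec["s_mean"] == pytest.approx(0.25)


class TestLabeling:
    def build(self, diamond_graph):
        depths = onto.term_depth(diamond_graph)
        known = onto.AnnotationStore()
        # pkf annotated to W (depth 2 path root->Y->W)
        for t in onto.ancestral_closure(diamond_graph, {W}):
            known.add("pkf", t, "src")
        known.add("puf", ROOT, "src")
        hit_sets = [
            tt.HitSet("pkf", [hit("n1", {W, Z}, s=1.0), hit("n2", {X}, s=0.5)]),
            tt.HitSet("puf", [hit("n1", {W}, s=1.0)]),
            tt.HitSet("tst", [hit("n1", {W}, s=1.0)]),
        ]
        table = tt.build_candidate_table(hit_sets, ["s"])
        return tt.label_candidates(
            table, known, depths, {"puf"}, {"tst"}, fdr_holdout_fraction=0.0
        )

    def test_precedence_rules(self, diamond_graph):
        labeled = self.build(diamond_graph).set_index(["protein_id", "term_id"])
        assert labeled.loc[("tst", W), "unlabeled_reason"] == "test_protein"
        assert labeled.loc[("puf", W), "unlabeled_reason"] == "puf"
        # Z at depth 3 > pkf's max known depth 2 -> deeper_than_known
        assert labeled.loc[("pkf", Z), "unlabeled_reason"] == "deeper_than_known"
        assert labeled.loc[("pkf", W), "label"] == "positive"
        assert labeled.loc[("pkf", X), "label"] == "negative"

    def test_holdout_sampled_from_labeled_only(self, diamond_graph):
        depths = onto.term_depth(diamond_graph)
        known = onto.AnnotationStore()
        for t in onto.ancestral_closure(diamond_graph, {W}):
            known.add("pkf", t, "src")
        hits = [hit(f"n{i}", {W, Y}, s=0.5) for i in range(20)]
        table = tt.build_candidate_table(
            [tt.HitSet(f"pkf", hits)], ["s"]
        )
        big = pd.concat(
            [table.assign(protein_id=f"pkf")] * 1, ignore_index=True
        )
        labeled = tt.label_candidates(
            big, known, depths, set(), set(), fdr_holdout_fraction=0.5, seed=1
        )
        holdout = labeled[labeled.unlabeled_reason == "fdr_holdout"]
        assert (holdout["private_label"].isin(["positive", "negative"])).all()

    def test_holdout_deterministic(self, diamond_graph):
        l1 = self.build(diamond_graph)
        l2 = self.build(diamond_graph)
        pd.testing.assert_frame_equal(l1, l2)


class TestCalibrateFdr:
    def test_worked_example(self):
        cal = tt.calibrate_fdr(
            np.array([0.9, 0.85, 0.8]), np.array([True, False, True]), 0.01
        )
        assert cal.threshold == 0.9
        assert cal.realized_fdr_calibration == 0.0

    def test_all_positive_holdout(self):
        cal = tt.calibrate_fdr(np.array([0.3, 0.7]), np.array([True, True]), 0.01)
        assert cal.threshold == 0.3
        assert cal.realized_fdr_calibration == 0.0

    def test_vacuous_target_accepts_everything(self):
        cal = tt.calibrate_fdr(
            np.array([0.2, 0.5, 0.9]), np.array([False, True, False]), 1.0
        )
        assert cal.threshold == 0.2

    def test_infeasible_target_gives_no_calls(self):
        cal = tt.calibrate_fdr(np.array([0.9, 0.8]), np.array([False, False]), 0.5)
        assert cal.threshold == np.inf

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_scan(self, seed):
        """Threshold equals a brute-force scan over every observed score on
        random instances of <= 200 candidates."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 201))
        scores = np.round(rng.random(n), 2)  # ties likely
        labels = rng.random(n) < 0.6
        target = float(rng.choice([0.01, 0.1, 0.3]))
        cal = tt.calibrate_fdr(scores, labels, target)

        feasible = []
        for t in np.unique(scores):
            sel = scores >= t
            tp = int((labels & sel).sum())
            fp = int((~labels & sel).sum())
            if tp + fp and fp / (tp + fp) <= target:
                feasible.append(t)
        if not feasible:
            assert cal.threshold == np.inf
        else:
            assert cal.threshold == pytest.approx(min(feasible))
            sel = scores >= cal.threshold
            fp = int((~labels & sel).sum())
            assert cal.realized_fdr_calibration == pytest.approx(
                fp / sel.sum()
            )
            assert cal.realized_fdr_calibration <= target

    def test_empty_holdout_rejected(self):
        with pytest.raises(ValueError):
            tt.calibrate_fdr(np.array([]), np.array([]), 0.1)


class TestClassifier:
    def make_candidates(self, rng, n=300, separable=True):
        pos = rng.random(n // 2) * 0.4 + (0.6 if separable else 0.0)
        neg = rng.random(n - n // 2) * (0.4 if separable else 1.0)
        table = pd.DataFrame(
            {
                "protein_id": [f"p{i}" for i in range(n)],
                "term_id": ["GO:1"] * n,
                "f_sum": np.concatenate([pos, neg]),
                "f_max": np.concatenate([pos, neg]) + 0.05 * rng.random(n),
                "label": ["positive"] * (n // 2) + ["negative"] * (n - n // 2),
                "unlabeled_reason": ["none"] * n,
                "private_label": ["positive"] * (n // 2)
                + ["negative"] * (n - n // 2),
            }
        )
        return table

    def test_separable_data_ranks_positives_first(self):
        rng = np.random.default_rng(0)
        table = self.make_candidates(rng, separable=True)
        model = tt.train_candidate_classifier(
            table, tt.CandidateClassifierConfig(n_estimators=100), seed=0
        )
        scored = tt.score_candidates(model, table)
        pos_min = scored[scored.label == "positive"]["score"].min()
        neg_max = scored[scored.label == "negative"]["score"].max()
        assert pos_min > neg_max

    def test_single_class_rejected(self):
        rng = np.random.default_rng(1)
        table = self.make_candidates(rng)
        table["label"] = "positive"
        with pytest.raises(ValueError, match="both classes"):
            tt.train_candidate_classifier(table)

    def test_deterministic_scores(self):
        rng = np.random.default_rng(2)
        table = self.make_candidates(rng)
        m1 = tt.train_candidate_classifier(
            table, tt.CandidateClassifierConfig(n_estimators=50), seed=3
        )
        m2 = tt.train_candidate_classifier(
            table, tt.CandidateClassifierConfig(n_estimators=50), seed=3
        )
        s1 = tt.score_candidates(m1, table)["score"]
        s2 = tt.score_candidates(m2, table)["score"]
        assert np.allclose(s1, s2)

    def test_unlabeled_strata_excluded_from_fit(self):
        """Dropping unlabeled rows from the table leaves the fitted model
        unchanged: fitting provably uses labeled candidates only."""
        rng = np.random.default_rng(3)
        table = self.make_candidates(rng)
        extra = table.iloc[:40].copy()
        extra["label"] = "unlabeled"
        extra["unlabeled_reason"] = "puf"
        extra["f_sum"] += 100  # would distort the fit if used
        with_unlabeled = pd.concat([table, extra], ignore_index=True)
        m1 = tt.train_candidate_classifier(
            with_unlabeled, tt.CandidateClassifierConfig(n_estimators=50), seed=0
        )
        m2 = tt.train_candidate_classifier(
            table, tt.CandidateClassifierConfig(n_estimators=50), seed=0
        )
        assert np.allclose(
            tt.score_candidates(m1, table)["score"],
            tt.score_candidates(m2, table)["score"],
        )


class TestFinalize:
    def test_accepted_term_closure_present(self, diamond_graph):
        scored = pd.DataFrame(
            {
                "protein_id": ["q"],
                "term_id": [Z],
                "score": [0.99],
            }
        )
        store = tt.finalize_annotations(scored, 0.9, diamond_graph, arm="gba")
        assert store.terms_of("q") == {Z, X, W, Y, ROOT}

    def test_ancestors_inherit_max_descendant_score(self, diamond_graph):
        scored = pd.DataFrame(
            {
                "protein_id": ["q", "q"],
                "term_id": [Z, W],
                "score": [0.95, 0.99],
            }
        )
        store = tt.finalize_annotations(scored, 0.9, diamond_graph, arm="gba")
        # Y is an ancestor of both Z (0.95) and W (0.99): inherits 0.99
        assert store.score_of("q", Y, "gba:closure") == pytest.approx(0.99)
        assert store.score_of("q", Z, "gba") == pytest.approx(0.95)

    def test_nothing_above_threshold(self, diamond_graph):
        scored = pd.DataFrame(
            {"protein_id": ["q"], "term_id": [Z], "score": [0.1]}
        )
        store = tt.finalize_annotations(scored, 0.9, diamond_graph, arm="gba")
        assert store.n_assignments() == 0

    def test_output_closed_and_idempotent(self, diamond_graph):
        scored = pd.DataFrame(
            {"protein_id": ["q", "r"], "term_id": [Z, W], "score": [1.0, 1.0]}
        )
        store = tt.finalize_annotations(scored, 0.5, diamond_graph, arm="s")
        for p in store.proteins:
            terms = store.terms_of(p)
            assert onto.ancestral_closure(diamond_graph, terms) == terms


class TestUnionArms:
    def build(self, assignments):
        store = onto.AnnotationStore()
        for p, t, src in assignments:
            store.add(p, t, src)
        return store

    def test_disjoint_sizes_add(self):
        a = self.build([("p", X, "gba")])
        b = self.build([("q", Y, "structural")])
        u = tt.union_arms(a, b)
        assert u.n_assignments() == 2

    def test_identical_stores_idempotent(self):
        a = self.build([("p", X, "gba")])
        u = tt.union_arms(a, a)
        assert u.terms_of("p") == {X}

    def test_overlap_keeps_both_provenances(self):
        a = self.build([("p", X, "gba")])
        b = self.build([("p", X, "structural")])
        u = tt.union_arms(a, b)
        assert u.sources_of("p", X) == {"gba", "structural"}
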