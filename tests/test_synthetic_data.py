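"""Generator invariants: determinism, planted structure, masking, coupling
between evidence channels and the hidden truth, and the truth evaluator."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from pufannot import ontology as onto
from pufannot import synthetic_data as sd
from pufannot.features import pair_key


class TestOntologyGeneration:
    def test_requested_depth_reached(self, small_data):
        assert max(small_data.depths.values()) == small_data.config.max_depth

    def test_acyclic_and_three_namespaces(self, small_data):
        import networkx as nx

        assert nx.is_directed_acyclic_graph(small_data.graph.graph)
        assert set(small_data.graph.roots) == set(onto.NAMESPACES)

    def test_contains_a_diamond(self, small_data):
        g = small_data.graph.graph
        multi_parent = [n for n in g.nodes if g.out_degree(n) >= 2]
        assert multi_parent  # at least one diamond by construction

    def test_deep_terms_exercise_oversampling_strata(self, small_data):
        # group terms at max_depth - 1 and deep terms at max_depth (> 8)
        for t in small_data.plan.deep_terms:
            assert small_data.depths[t] == small_data.config.max_depth >= 9


class TestProteome:
    def test_masked_proteins_classify_as_puf(self, small_data):
        depths = small_data.depths
        for p in small_data.truth.masked_proteins:
            terms = small_data.known_store.terms_of(p)
            assert onto.classify_puf(small_data.graph, depths, terms) == "PUF"

    def test_unmasked_proteins_classify_as_pkf(self, small_data):
        depths = small_data.depths
        unmasked = [
            p
            for p in small_data.proteins
            if p not in small_data.truth.masked_proteins
        ]
        for p in unmasked:
            terms = small_data.known_store.terms_of(p)
            assert onto.classify_puf(small_data.graph, depths, terms) == "PKF"

    def test_truth_retained_for_masked_proteins(self, small_data):
        for p in small_data.truth.masked_proteins:
            truth_terms = small_data.truth.full_store.terms_of(p)
            assert max(small_data.depths[t] for t in truth_terms) >= 2

    def test_four_sources_with_scores_on_netgo(self, small_data):
        assert set(small_data.source_tables) == {
            "biocyc",
            "pgdb",
            "uniprot",
            "netgo",
        }
        assert small_data.source_tables["netgo"]["score"].notna().any()


class TestDeterminism:
    def test_regenerate_identical(self, small_config):
        d1 = sd.generate(small_config)
        d2 = sd.generate(small_config)
        assert d1.obo_text == d2.obo_text
        pd.testing.assert_frame_equal(d1.tm_table, d2.tm_table)
        assert d1.truth.masked_proteins == d2.truth.masked_proteins
        assert d1.sequences == d2.sequences

    def test_written_files_byte_identical(self, small_config, tmp_path):
        m1 = sd.write_dataset(sd.generate(small_config), tmp_path / "a")
        m2 = sd.write_dataset(sd.generate(small_config), tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_different_seed_differs(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        assert sd.generate(other).obo_text != sd.generate(small_config).obo_text


def truth_depth_vector(data, pairs):
    store = data.truth.full_store
    depths = data.depths
    out = []
    for a, b in pairs:
        shared = store.terms_of(a) & store.terms_of(b)
        out.append(max((depths[t] for t in shared), default=0))
    return np.array(out)


class TestChannelCoupling:
    def sample_pairs(self, data, rng, n=400):
        idx = rng.choice(len(data.proteins), size=(n, 2))
        return [
            (data.proteins[i], data.proteins[j]) for i, j in idx if i != j
        ]

    def test_alpha_zero_channels_decorrelated(self):
        config = sd.SyntheticConfig(
            seed=11, alpha=0.0, n_proteins=60, n_terms=100, n_families=4
        )
        data = sd.generate(config)
        rng = np.random.default_rng(0)
        pairs = self.sample_pairs(data, rng)
        depth = truth_depth_vector(data, pairs)
        tm = {
            pair_key(r.protein_a, r.protein_b): r.tm_norm_a
            for r in data.tm_table.itertuples(index=False)
        }
        vals = np.array([tm.get(pair_key(a, b), 0.0) for a, b in pairs])
        rho = spearmanr(depth, vals).statistic
        assert abs(rho) < 0.15

    def test_large_alpha_monotone_coupling(self):
        config = sd.SyntheticConfig(
            seed=11, alpha=1.0, noise_sd=0.02, n_proteins=60, n_terms=100,
            n_families=4,
        )
        data = sd.generate(config)
        rng = np.random.default_rng(0)
        pairs = self.sample_pairs(data, rng)
        depth = truth_depth_vector(data, pairs)
        tm = {
            pair_key(r.protein_a, r.protein_b): r.tm_norm_a
            for r in data.tm_table.itertuples(index=False)
        }
        vals = np.array([tm.get(pair_key(a, b), 0.0) for a, b in pairs])
        rho = spearmanr(depth, vals).statistic
        assert rho > 0.8

    def test_quant_within_group_pairs_correlate_more(self):
        from pufannot.features import coexpression_features

        config = sd.SyntheticConfig(
            seed=13, alpha=1.0, noise_sd=0.05, n_proteins=60, n_terms=100,
            n_families=4,
        )
        data = sd.generate(config)
        spearman, _ = coexpression_features(data.experiments, data.proteins)
        same, diff = [], []
        group = data.truth.group_of
        for i, a in enumerate(data.proteins):
            for b in data.proteins[i + 1 :]:
                (same if group[a] == group[b] else diff).append(
                    spearman.at[a, b]
                )
        assert np.mean(same) > np.mean(diff) + 0.2


class TestStructureHits:
    def test_high_tm_hits_share_deepest_term(self):
        config = sd.SyntheticConfig(
            seed=17, alpha=0.95, n_proteins=80, n_terms=100, n_families=4,
            hits_per_query_mean=12.0, n_foreign=60,
        )
        data = sd.generate(config)
        deep_of = {
            p: sd_deep
            for p, g in data.truth.group_of.items()
            for sd_deep in [data.plan.deep_terms[g]]
        }
        # condition on annotated hits: a fraction of the foreign pool is
        # deliberately unannotated, which is orthogonal to the coupling
        high = [
            h for h in data.structure_hits if h.tm_score > 0.9 and h.terms
        ]
        share = [deep_of[h.query_id] in h.terms for h in high]
        assert len(share) >= 15
        assert np.mean(share) > 0.9

    def test_sub_cutoff_hits_present(self, small_data):
        assert any(h.tm_score <= 0.3 for h in small_data.structure_hits)

    def test_lineages_cover_all_ranks(self, small_data):
        from pufannot.structural_arm import taxonomic_rank_similarity

        ranks = {
            taxonomic_rank_similarity(small_data.query_lineage, h.lineage)
            for h in small_data.structure_hits
        }
        assert ranks >= set(range(1, 7))


class TestEvaluator:
    def test_perfect_predictions(self, small_data):
        truth = small_data.truth
        pred = onto.AnnotationStore()
        for p in truth.masked_proteins:
            for t in truth.full_store.terms_of(p):
                pred.add(p, t, "gba")
        ev = sd.evaluate_against_truth(pred, truth, small_data.depths)
        assert ev.fdr == 0.0
        assert ev.recall == 1.0

    def test_root_only_predictions_zero_recall(self, small_data):
        truth = small_data.truth
        pred = onto.AnnotationStore()
        root = small_data.plan.roots["biological_process"]
        for p in truth.masked_proteins:
            pred.add(p, root, "gba")
        ev = sd.evaluate_against_truth(pred, truth, small_data.depths)
        assert ev.recall == 0.0

    def test_empty_predictions_flagged(self, small_data):
        ev = sd.evaluate_against_truth(
            onto.AnnotationStore(), small_data.truth, small_data.depths
        )
        assert ev.fdr is None
        assert ev.recall == 0.0

    def test_hand_built_tally(self, diamond_graph):
        from conftest import CHAIN, ROOT, W, X, Y, Z

        depths = onto.term_depth(diamond_graph)
        full = onto.AnnotationStore()
        for t in onto.ancestral_closure(diamond_graph, {Z}):
            full.add("p1", t, "truth")
        truth = sd.GroundTruth(
            full_store=full,
            masked_proteins=frozenset({"p1"}),
            group_of={"p1": 0},
            family_of_group={0: 0},
            planted_or=1.0,
        )
        pred = onto.AnnotationStore()
        # predict Z (true, depth 3), W (true, depth 2), chain[2] (false)
        for t, src in ((Z, "gba"), (W, "gba"), (CHAIN[2], "gba")):
            pred.add("p1", t, src)
        ev = sd.evaluate_against_truth(pred, truth, depths)
        # 3 predictions, 1 false
        assert ev.n_predictions == 3 and ev.n_false == 1
        assert ev.fdr == pytest.approx(1 / 3)
        # true terms at depth >= 2: Z (3) and W (2); both recovered -> 1.0
        assert ev.recall == pytest.approx(1.0)

    def test_planted_or_term_counts(self):
        counts = sd.make_term_counts(50, 5000, 5000, planted_or=3.0, seed=1)
        odds_puf = counts.k_puf / (counts.n_puf - counts.k_puf)
        odds_pkf = counts.k_pkf / (counts.n_pkf - counts.k_pkf)
        ratio = (odds_puf / odds_pkf).median()
        assert ratio == pytest.approx(3.0, rel=0.15)
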