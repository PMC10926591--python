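"""End-to-end orchestration of the two-arm annotation pipeline.

Wires the modules together on a dataset bundle: classify PUFs, assemble
pair features, train the pair regressor, build the hit network, run the
guilt-by-association transfer arm, run the structural arm, take the union
of the two arms' predictions, and (for synthetic data) evaluate against
the masked ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from . import ontology as onto
from . import pair_model, term_transfer
from .features import (
    assemble_pair_features,
    feature_columns,
    pair_key,
    select_string_scores,
    trim_structure,
)
from .structural_arm import (
    STRUCTURAL_MEASURES,
    build_structural_hit_sets,
    filter_structure_hits,
)
from .synthetic_data import SyntheticData, TruthEvaluation, evaluate_against_truth
from .term_transfer import ArmResult, Hit, HitSet


def pairwise_target_depths(
    known: onto.AnnotationStore,
    depths,
    proteins: list[str],
) -> dict[tuple[str, str], int]:
    """True deepest-shared-term depth for every unordered pair of annotated
    proteins, from their (closed) known annotation sets."""
    closed = {p: known.terms_of(p) for p in proteins}
    out = {}
    for i, a in enumerate(proteins):
        ca = closed[a]
        for b in proteins[i + 1 :]:
            shared = ca & closed[b]
            out[pair_key(a, b)] = (
                max((depths[t] for t in shared), default=0) if shared else 0
            )
    return out


def gba_hit_sets(
    network: nx.Graph,
    known: onto.AnnotationStore,
    measures: list[str],
) -> list[HitSet]:
    """Per-protein hit sets from the hit network: neighbors with their edge
    feature payload as similarity scores and their (closed) known
    annotations. Unannotated neighbors contribute no candidate terms."""
    hit_sets = []
    for query in sorted(network.nodes()):
        hits = []
        for neighbor in network.neighbors(query):
            data = network.edges[query, neighbor]
            scores = {m: float(data.get(m, 0.0)) for m in measures}
            hits.append(Hit(neighbor, scores, known.terms_of(neighbor)))
        if hits:
            hit_sets.append(HitSet(query, hits))
    return hit_sets


@dataclass
class PipelineResult:
    train_proteins: list[str]
    test_proteins: list[str]
    puf_set: set[str]
    pair_eval: pair_model.PairModelEvaluation
    hit_network: nx.Graph
    gba: ArmResult | None
    structural: ArmResult | None
    combined: onto.AnnotationStore
    truth_eval: TruthEvaluation | None


def run_pipeline(
    data: SyntheticData,
    seed: int = 0,
    *,
    test_fraction: float = 0.1,
    target_fdr: float = 0.01,
    fdr_holdout_fraction: float = 0.1,
    hit_cutoff: float = pair_model.HIT_DEPTH_CUTOFF,
    pair_config: pair_model.PairRegressorConfig | None = None,
    candidate_config: term_transfer.CandidateClassifierConfig | None = None,
    run_structural_arm: bool = True,
    evaluate_truth: bool = True,
) -> PipelineResult:
    """Run both arms end to end on a dataset bundle.

    The truth inside *data* is consulted only by the final evaluator (and
    only when *evaluate_truth* is set); every model stage sees the masked
    annotation store alone.
    """
    graph, depths, known = data.graph, data.depths, data.known_store
    pufs = {
        p
        for p in data.proteins
        if onto.classify_puf(graph, depths, known.terms_of(p)) == "PUF"
    }
    pkfs = [p for p in data.proteins if p not in pufs]

    # --- pair model ---------------------------------------------------
    pair_features = assemble_pair_features(
        data.proteins,
        feature_matrix=data.feature_matrix,
        bitscore_table=data.bitscore_table,
        operon_table=data.operon_table,
        orthogroups=data.orthogroups,
        tree_distance_table=data.tree_distance_table,
        experiments=data.experiments,
        tm_table=data.tm_table,
        string_scores=select_string_scores(data.string_table),
    )
    targets = pairwise_target_depths(known, depths, pkfs)
    train, test = pair_model.split_proteins(pkfs, test_fraction, seed)
    training = pair_model.build_training_table(pair_features, targets, train)
    training = pair_model.oversample(training)
    regressor = pair_model.train_pair_regressor(training, pair_config, seed)

    test_set = set(test)
    both_pkf = pair_features["protein_a"].isin(set(pkfs)) & pair_features[
        "protein_b"
    ].isin(set(pkfs))
    tainted = pair_features["protein_a"].isin(test_set) | pair_features[
        "protein_b"
    ].isin(test_set)
    eval_table = pair_features[both_pkf & tainted]
    pair_eval = pair_model.evaluate_pair_model(
        regressor, eval_table, targets, hit_cutoff
    )

    network = pair_model.predict_hits(regressor, pair_features, hit_cutoff)

    # --- GBA transfer arm ---------------------------------------------
    gba_measures = feature_columns(pair_features) + ["predicted_depth"]
    hit_sets = gba_hit_sets(network, known, gba_measures)
    gba = term_transfer.run_arm(
        hit_sets,
        gba_measures,
        known,
        graph,
        depths,
        pufs,
        test_set,
        arm="gba",
        target_fdr=target_fdr,
        fdr_holdout_fraction=fdr_holdout_fraction,
        classifier_config=candidate_config,
        seed=seed,
    )

    # --- structural arm -----------------------------------------------
    structural = None
    if run_structural_arm:
        kept_queries = {
            p
            for p, model in data.structures.items()
            if trim_structure(model) is not None
        }
        hits = [h for h in data.structure_hits if h.query_id in kept_queries]
        hits = filter_structure_hits(hits)
        s_hit_sets = build_structural_hit_sets(
            hits, data.sequences, data.query_lineage, graph
        )
        structural = term_transfer.run_arm(
            s_hit_sets,
            list(STRUCTURAL_MEASURES),
            known,
            graph,
            depths,
            pufs,
            test_set,
            arm="structural",
            target_fdr=target_fdr,
            fdr_holdout_fraction=fdr_holdout_fraction,
            classifier_config=candidate_config,
            seed=seed,
        )

    combined = (
        term_transfer.union_arms(gba.predictions, structural.predictions)
        if structural is not None
        else gba.predictions
    )
    truth_eval = (
        evaluate_against_truth(combined, data.truth, depths)
        if evaluate_truth
        else None
    )
    return PipelineResult(
        train_proteins=train,
        test_proteins=test,
        puf_set=pufs,
        pair_eval=pair_eval,
        hit_network=network,
        gba=gba,
        structural=structural,
        combined=combined,
        truth_eval=truth_eval,
    )
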