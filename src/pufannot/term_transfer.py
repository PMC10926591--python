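"""Annotation transfer from hit sets with FDR-calibrated thresholds.

Shared engine for both arms of the pipeline. A query protein's *hits*
(predicted-similar neighbors or structure-search matches) propose candidate
GO terms: a term is assessed only if it appears among the hits' (closed)
annotation sets. Each (protein, term) candidate is described by summary
statistics — count, sum, max, mean — of every similarity measure over the
hits annotated with that term. A random forest classifier, fit on the
labeled candidates only, scores every candidate in [0, 1].

Candidates are left unlabeled (excluded from fitting) when the protein is a
test protein, when it is a PUF, or when the term is deeper than the deepest
term in the protein's known annotation; in addition a random 10% of labeled
training candidates are deliberately unlabeled and used solely to choose the
score threshold that achieves the target false discovery rate (default 1%).
Terms passing the threshold are propagated to all their ancestors.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .ontology import AnnotationStore, OntologyGraph, ancestral_closure

DEFAULT_STAT_REGISTRY = ("count", "sum", "max", "mean")

LABEL_POSITIVE = "positive"
LABEL_NEGATIVE = "negative"
LABEL_UNLABELED = "unlabeled"

REASON_TEST = "test_protein"
REASON_PUF = "puf"
REASON_DEEPER = "deeper_than_known"
REASON_HOLDOUT = "fdr_holdout"
REASON_NONE = "none"


@dataclass
class Hit:
    """One neighbor of a query protein, with its similarity scores and
    ancestor-closed annotation set."""

    hit_id: str
    scores: Mapping[str, float]
    annotations: frozenset[str]


@dataclass
class HitSet:
    """All hits of one query protein; hits never include the query itself."""

    query: str
    hits: list[Hit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hits = [h for h in self.hits if h.hit_id != self.query]


@dataclass
class FDRCalibration:
    """Result of threshold selection on the deliberately unlabeled holdout."""

    target_fdr: float
    threshold: float
    realized_fdr_calibration: float
    n_calibration: int
    realized_fdr_test: float | None = None
    precision: float | None = None
    recall: float | None = None


# ---------------------------------------------------------------------------
# candidate construction
# ---------------------------------------------------------------------------

def enumerate_candidates(hit_set: HitSet) -> set[str]:
    """Candidate terms for a query: the union of its hits' annotation sets."""
    out: set[str] = set()
    for hit in hit_set.hits:
        out |= hit.annotations
    return out


def summarize_hits(
    hit_set: HitSet,
    term: str,
    measures: Sequence[str],
    stat_registry: Sequence[str] = DEFAULT_STAT_REGISTRY,
    *,
    fill_value: float = 0.0,
) -> dict[str, float]:
    """Summary-statistic feature vector for one (query, term) candidate.

    Statistics are computed over the hits annotated with *term* only; a
    measure missing on a hit contributes *fill_value*. Invariant to hit
    ordering.
    """
    relevant = [h for h in hit_set.hits if term in h.annotations]
    if not relevant:
        raise ValueError(f"term {term!r} not among hit annotations")
    out: dict[str, float] = {}
    for measure in measures:
        # sorted so the statistics are exactly invariant to hit ordering
        vals = np.sort(
            [float(h.scores.get(measure, fill_value)) for h in relevant]
        )
        for stat in stat_registry:
            if stat == "count":
                out[f"{measure}_count"] = float(vals.size)
            elif stat == "sum":
                out[f"{measure}_sum"] = float(vals.sum())
            elif stat == "max":
                out[f"{measure}_max"] = float(vals.max())
            elif stat == "mean":
                out[f"{measure}_mean"] = float(vals.mean())
            else:
                raise ValueError(f"unknown summary statistic {stat!r}")
    return out


def build_candidate_table(
    hit_sets: Iterable[HitSet],
    measures: Sequence[str],
    stat_registry: Sequence[str] = DEFAULT_STAT_REGISTRY,
) -> pd.DataFrame:
    """One row per (query protein, candidate term) with summary features."""
    rows = []
    for hit_set in hit_sets:
        for term in sorted(enumerate_candidates(hit_set)):
            row = {"protein_id": hit_set.query, "term_id": term}
            row.update(summarize_hits(hit_set, term, measures, stat_registry))
            rows.append(row)
    cols = ["protein_id", "term_id"] + [
        f"{m}_{s}" for m in measures for s in stat_registry
    ]
    return pd.DataFrame(rows, columns=cols)


def label_candidates(
    candidates: pd.DataFrame,
    annotations: AnnotationStore,
    depths: Mapping[str, int],
    puf_set: set[str],
    test_set: set[str],
    fdr_holdout_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign positive/negative/unlabeled labels with precedence.

    Precedence: test protein -> PUF -> term deeper than the protein's
    deepest known term -> positive iff annotated, else negative. A seeded
    random *fdr_holdout_fraction* of the remaining labeled candidates is
    then relabeled unlabeled(fdr_holdout); their true label is kept in the
    ``private_label`` column for calibration only.

    *annotations* must be ancestor-closed.
    """
    labels, reasons, private = [], [], []
    max_known: dict[str, int] = {}
    for row in candidates.itertuples(index=False):
        protein, term = row.protein_id, row.term_id
        if protein in test_set:
            labels.append(LABEL_UNLABELED)
            reasons.append(REASON_TEST)
            private.append(None)
            continue
        if protein in puf_set:
            labels.append(LABEL_UNLABELED)
            reasons.append(REASON_PUF)
            private.append(None)
            continue
        if protein not in max_known:
            known = annotations.terms_of(protein)
            max_known[protein] = max((depths[t] for t in known), default=-1)
        if depths[term] > max_known[protein]:
            labels.append(LABEL_UNLABELED)
            reasons.append(REASON_DEEPER)
            private.append(None)
            continue
        lab = (
            LABEL_POSITIVE
            if term in annotations.terms_of(protein)
            else LABEL_NEGATIVE
        )
        labels.append(lab)
        reasons.append(REASON_NONE)
        private.append(lab)

    out = candidates.copy()
    out["label"] = labels
    out["unlabeled_reason"] = reasons
    out["private_label"] = private

    rng = np.random.default_rng(seed)
    labeled_idx = np.flatnonzero((out["label"] != LABEL_UNLABELED).to_numpy())
    n_holdout = int(round(fdr_holdout_fraction * labeled_idx.size))
    if n_holdout > 0:
        chosen = rng.choice(labeled_idx, size=n_holdout, replace=False)
        out.iloc[chosen, out.columns.get_loc("label")] = LABEL_UNLABELED
        out.iloc[chosen, out.columns.get_loc("unlabeled_reason")] = REASON_HOLDOUT
    return out


# ---------------------------------------------------------------------------
# scoring & calibration
# ---------------------------------------------------------------------------

@dataclass
class CandidateClassifierConfig:
    n_estimators: int = 500
    max_depth: int | None = None
    max_features: str | float = "sqrt"
    n_jobs: int = 1


def candidate_feature_columns(table: pd.DataFrame) -> list[str]:
    meta = {
        "protein_id",
        "term_id",
        "label",
        "unlabeled_reason",
        "private_label",
        "score",
    }
    return [c for c in table.columns if c not in meta]


def train_candidate_classifier(
    labeled: pd.DataFrame,
    config: CandidateClassifierConfig | None = None,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the candidate scorer on positive/negative candidates only; all
    unlabeled strata (test, PUF, deeper-than-known, FDR holdout) are
    excluded from fitting. Deterministic under *seed*."""
    config = config or CandidateClassifierConfig()
    train = labeled[labeled["label"].isin([LABEL_POSITIVE, LABEL_NEGATIVE])]
    y = (train["label"] == LABEL_POSITIVE).to_numpy(dtype=int)
    if len(train) == 0 or y.min() == y.max():
        raise ValueError("training data must contain both classes")
    cols = candidate_feature_columns(labeled)
    model = RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        max_features=config.max_features,
        random_state=seed,
        n_jobs=config.n_jobs,
    )
    model.fit(train[cols], y)
    model.feature_names_ = cols
    return model


def score_candidates(
    model: RandomForestClassifier, candidates: pd.DataFrame
) -> pd.DataFrame:
    """Attach the classifier's positive-class probability as ``score``."""
    out = candidates.copy()
    proba = model.predict_proba(candidates[model.feature_names_])
    positive_col = int(np.flatnonzero(model.classes_ == 1)[0])
    out["score"] = proba[:, positive_col]
    return out


def calibrate_fdr(
    scores: np.ndarray,
    is_positive: np.ndarray,
    target: float,
) -> FDRCalibration:
    """Choose the lowest observed score threshold meeting the target FDR.

    Among candidates with score >= t, FDR = FP / (FP + TP). The returned
    threshold is the smallest observed score t with FDR <= *target*
    (maximizing calls); if no observed score qualifies the threshold is
    +inf (no calls are made) with realized FDR 0. The realized calibration
    FDR is <= target by construction and asserted.
    """
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    if scores.size == 0:
        raise ValueError("empty calibration holdout")
    if not 0.0 < target <= 1.0:
        raise ValueError("target FDR must be in (0, 1]")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    pos_sorted = is_positive[order]
    tp = np.cumsum(pos_sorted)
    fp = np.cumsum(~pos_sorted)
    fdr = fp / np.maximum(tp + fp, 1)
    # last index of each distinct score when sweeping downward
    is_last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    feasible = np.flatnonzero(is_last & (fdr <= target))
    if feasible.size == 0:
        return FDRCalibration(target, np.inf, 0.0, int(scores.size))
    best = feasible[-1]  # smallest feasible observed threshold
    threshold = float(s_sorted[best])
    realized = float(fdr[best])
    assert realized <= target, "calibration FDR exceeds target"
    return FDRCalibration(target, threshold, realized, int(scores.size))


def calibrate_from_candidates(
    scored: pd.DataFrame, target: float
) -> FDRCalibration:
    """Run :func:`calibrate_fdr` on the FDR-holdout stratum of a scored
    candidate table (requires >= 1 positive in the holdout)."""
    holdout = scored[scored["unlabeled_reason"] == REASON_HOLDOUT]
    if len(holdout) == 0:
        raise ValueError("no FDR-holdout candidates present")
    is_pos = (holdout["private_label"] == LABEL_POSITIVE).to_numpy()
    if not is_pos.any():
        raise ValueError("calibration holdout has no positives")
    return calibrate_fdr(holdout["score"].to_numpy(), is_pos, target)


def evaluate_on_test(
    scored: pd.DataFrame,
    known: AnnotationStore,
    threshold: float,
) -> tuple[float | None, float | None, float | None]:
    """Realized FDR / precision / recall on test-protein candidates.

    Truth is the (closed) known annotation of the held-out proteins, which
    the model never saw as labels. Returns (fdr, precision, recall); None
    when undefined (no calls or no positives).
    """
    test = scored[scored["unlabeled_reason"] == REASON_TEST]
    if len(test) == 0:
        return None, None, None
    truth = np.array(
        [
            row.term_id in known.terms_of(row.protein_id)
            for row in test.itertuples(index=False)
        ]
    )
    called = test["score"].to_numpy() >= threshold
    n_called = int(called.sum())
    n_true = int(truth.sum())
    fdr = precision = recall = None
    if n_called > 0:
        tp = int((called & truth).sum())
        fdr = (n_called - tp) / n_called
        precision = tp / n_called
    if n_true > 0:
        recall = int((called & truth).sum()) / n_true
    return fdr, precision, recall


# ---------------------------------------------------------------------------
# finalization
# ---------------------------------------------------------------------------

def finalize_annotations(
    scored: pd.DataFrame,
    threshold: float,
    graph: OntologyGraph,
    *,
    arm: str,
    proteins: set[str] | None = None,
) -> AnnotationStore:
    """Accept candidates with score >= threshold and propagate to ancestors.

    Ancestors added by closure carry provenance ``{arm}:closure`` and inherit
    the maximum score of the accepting descendants below them. Restricted to
    *proteins* when given (e.g. the PUFs). The output is ancestor-closed.
    """
    store = AnnotationStore()
    accepted = scored[scored["score"] >= threshold]
    if proteins is not None:
        accepted = accepted[accepted["protein_id"].isin(proteins)]
    for protein, group in accepted.groupby("protein_id"):
        direct = dict(zip(group["term_id"], group["score"]))
        ancestor_score: dict[str, float] = {}
        for term, score in direct.items():
            for anc in ancestral_closure(graph, [term]):
                if anc not in direct:
                    ancestor_score[anc] = max(
                        ancestor_score.get(anc, 0.0), float(score)
                    )
        for term, score in direct.items():
            store.add(protein, term, arm, float(score))
        for term, score in ancestor_score.items():
            store.add(protein, term, f"{arm}:closure", score)
    return store


def union_arms(
    store_gba: AnnotationStore, store_structural: AnnotationStore
) -> AnnotationStore:
    """Final predictions: per-protein set union of the two arms' (closed)
    stores; provenance records every contributing arm."""
    return store_gba.union(store_structural)


# ---------------------------------------------------------------------------
# end-to-end arm runner
# ---------------------------------------------------------------------------

@dataclass
class ArmResult:
    predictions: AnnotationStore
    calibration: FDRCalibration
    scored_candidates: pd.DataFrame
    model: RandomForestClassifier


def run_arm(
    hit_sets: Iterable[HitSet],
    measures: Sequence[str],
    known: AnnotationStore,
    graph: OntologyGraph,
    depths: Mapping[str, int],
    puf_set: set[str],
    test_set: set[str],
    *,
    arm: str,
    target_fdr: float = 0.01,
    fdr_holdout_fraction: float = 0.1,
    stat_registry: Sequence[str] = DEFAULT_STAT_REGISTRY,
    classifier_config: CandidateClassifierConfig | None = None,
    predict_for: set[str] | None = None,
    seed: int = 0,
) -> ArmResult:
    """Run one arm end to end: candidates -> labels -> scorer -> calibrated
    threshold -> closed predicted annotations (for *predict_for*, default
    the PUFs and test proteins)."""
    table = build_candidate_table(hit_sets, measures, stat_registry)
    labeled = label_candidates(
        table, known, depths, puf_set, test_set, fdr_holdout_fraction, seed
    )
    model = train_candidate_classifier(labeled, classifier_config, seed)
    scored = score_candidates(model, labeled)
    calibration = calibrate_from_candidates(scored, target_fdr)
    fdr_t, prec, rec = evaluate_on_test(scored, known, calibration.threshold)
    calibration.realized_fdr_test = fdr_t
    calibration.precision = prec
    calibration.recall = rec
    if predict_for is None:
        predict_for = puf_set | test_set
    predictions = finalize_annotations(
        scored, calibration.threshold, graph, arm=arm, proteins=predict_for
    )
    return ArmResult(predictions, calibration, scored, model)
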