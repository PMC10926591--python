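"""Pairwise functional-similarity regression and the hit network.

A random forest regresses the depth of the deepest shared GO term for a
protein pair onto the pair's similarity-feature vector. Pairs predicted
deeper than the hit cutoff (default 6, strict) become edges of the hit
network, which feeds both the annotation-transfer engine and the network
modularity analysis.

Leakage control is per protein: 10% of annotated (PKF) proteins are held
out, and any pair touching a held-out protein is excluded from training.
Deep pairs are oversampled to counter class imbalance: multiplicity 2 for
target depth in (6, 8], 4 for depth > 8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import roc_curve

from .features import feature_columns

#: Predicted-depth cutoff above which a pair is a hit (strict inequality).
HIT_DEPTH_CUTOFF = 6.0


@dataclass
class PairRegressorConfig:
    """Random-forest hyperparameters (defaults exposed, not prescribed)."""

    n_estimators: int = 500
    max_depth: int | None = None
    max_features: str | float = "sqrt"
    n_jobs: int = 1


def split_proteins(
    annotated_proteins: Sequence[str], fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Split annotated (PKF) proteins into disjoint train/test sets.

    *fraction* of proteins go to the test set (at least one). Reproducible
    under *seed*; the union is the input and the intersection empty.
    """
    proteins = sorted(annotated_proteins)
    if len(proteins) < 10:
        raise ValueError("need at least 10 annotated proteins to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_test = max(1, round(fraction * len(proteins)))
    test_idx = rng.choice(len(proteins), size=n_test, replace=False)
    test = sorted(proteins[i] for i in test_idx)
    train = sorted(set(proteins) - set(test))
    return train, test


def oversample_multiplicity(depths: np.ndarray) -> np.ndarray:
    """Training multiplicity per pair: 1 for depth <= 6, 2 for 6 < depth <= 8,
    4 for depth > 8 (the deeper stratum's factor replaces, not compounds)."""
    depths = np.asarray(depths)
    mult = np.ones(depths.shape, dtype=int)
    mult[depths > 6] = 2
    mult[depths > 8] = 4
    return mult


def oversample(
    pair_table: pd.DataFrame, depth_col: str = "target_depth"
) -> pd.DataFrame:
    """Replicate rows of a pair training table per the multiplicity rule."""
    mult = oversample_multiplicity(pair_table[depth_col].to_numpy())
    return pair_table.loc[pair_table.index.repeat(mult)].reset_index(drop=True)


def build_training_table(
    pair_features: pd.DataFrame,
    target_depths: dict[tuple[str, str], int],
    train_proteins: Sequence[str],
) -> pd.DataFrame:
    """Attach targets and keep only pairs with both proteins in the training
    set (a pair is test-tainted if either protein is held out)."""
    train_set = set(train_proteins)
    mask = pair_features["protein_a"].isin(train_set) & pair_features[
        "protein_b"
    ].isin(train_set)
    table = pair_features.loc[mask].copy()
    keys = list(zip(table["protein_a"], table["protein_b"]))
    table["target_depth"] = [target_depths.get(k) for k in keys]
    return table.dropna(subset=["target_depth"]).reset_index(drop=True)


def train_pair_regressor(
    training_table: pd.DataFrame,
    config: PairRegressorConfig | None = None,
    seed: int = 0,
) -> RandomForestRegressor:
    """Fit the random-forest depth regressor on an (oversampled) training
    table. Deterministic under *seed*; raises on an empty table."""
    if len(training_table) == 0:
        raise ValueError("empty training set")
    config = config or PairRegressorConfig()
    cols = [c for c in feature_columns(training_table) if c != "target_depth"]
    model = RandomForestRegressor(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        max_features=config.max_features,
        random_state=seed,
        n_jobs=config.n_jobs,
    )
    model.fit(training_table[cols], training_table["target_depth"])
    model.feature_names_ = cols
    return model


def predict_depths(
    model: RandomForestRegressor, pair_features: pd.DataFrame
) -> pd.DataFrame:
    """Score every pair; returns the table plus a ``predicted_depth`` column."""
    out = pair_features.copy()
    out["predicted_depth"] = model.predict(pair_features[model.feature_names_])
    return out


def predict_hits(
    model: RandomForestRegressor,
    pair_features: pd.DataFrame,
    hit_cutoff: float = HIT_DEPTH_CUTOFF,
) -> nx.Graph:
    """Build the hit network: an edge per pair with predicted depth strictly
    above *hit_cutoff*. PUFs and test proteins are scored (never trained on).

    Edge payload: ``predicted_depth`` plus the pair's feature vector.
    """
    scored = predict_depths(model, pair_features)
    network = nx.Graph()
    network.add_nodes_from(
        pd.unique(scored[["protein_a", "protein_b"]].to_numpy().ravel())
    )
    hit_rows = scored[scored["predicted_depth"] > hit_cutoff]
    feat_cols = model.feature_names_
    for row in hit_rows.itertuples(index=False):
        a, b = row.protein_a, row.protein_b
        if a == b:
            continue
        payload = {c: getattr(row, c) for c in feat_cols}
        payload["predicted_depth"] = row.predicted_depth
        network.add_edge(a, b, **payload)
    return network


@dataclass
class PairModelEvaluation:
    auc: float | None
    roc_points: pd.DataFrame  # columns fpr, tpr, threshold
    n_pairs: int
    n_positive: int


def evaluate_pair_model(
    model: RandomForestRegressor,
    test_table: pd.DataFrame,
    target_depths: dict[tuple[str, str], int],
    cutoff: float = HIT_DEPTH_CUTOFF,
) -> PairModelEvaluation:
    """ROC/AUC of the regressor as a detector of true depth > *cutoff*.

    AUC is the trapezoid-rule area under the full threshold sweep of the
    predicted depth. A single-class test set leaves AUC undefined (None).
    """
    scored = predict_depths(model, test_table)
    keys = list(zip(scored["protein_a"], scored["protein_b"]))
    truth = np.array([target_depths[k] > cutoff for k in keys], dtype=int)
    scores = scored["predicted_depth"].to_numpy()
    if len(truth) == 0 or truth.min() == truth.max():
        return PairModelEvaluation(
            None,
            pd.DataFrame(columns=["fpr", "tpr", "threshold"]),
            len(truth),
            int(truth.sum()),
        )
    fpr, tpr, thr = roc_curve(truth, scores)
    auc = float(np.trapezoid(tpr, fpr))
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return PairModelEvaluation(auc, roc_points, len(truth), int(truth.sum()))


def write_hit_network(network: nx.Graph, path) -> None:
    """Serialize the hit network as an edge-list TSV (one column per edge
    attribute)."""
    rows = []
    for a, b, data in network.edges(data=True):
        row = {"protein_a": min(a, b), "protein_b": max(a, b)}
        row.update(data)
        rows.append(row)
    pd.DataFrame(rows).sort_values(["protein_a", "protein_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_hit_network(path) -> nx.Graph:
    frame = pd.read_csv(path, sep="\t")
    network = nx.Graph()
    attr_cols = [c for c in frame.columns if c not in ("protein_a", "protein_b")]
    for row in frame.itertuples(index=False):
        network.add_edge(
            row.protein_a,
            row.protein_b,
            **{c: getattr(row, c) for c in attr_cols},
        )
    return network
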