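"""Within-species pairwise similarity measures feeding the pair model.

Each protein pair gets a named vector of evidence channels: motif-based
weighted Jaccard distance, sequence bitscore, operon co-membership,
orthogroup species-set overlap, phylogenetic tree distance, proteomic
co-expression (mean per-experiment Spearman and presence/absence Jaccard
distance), structure similarity (max-normalized TM-score and RMSD), and
STRING-style association sub-scores.

Missing-evidence policy: numeric channels default to 0 for pairs without
evidence (matching the explicit zero rules for Spearman and sparse STRING
link lists); distance-type channels default to 1 (maximally dissimilar)
when a protein has no features or observations. The registry records each
channel's fill value.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: STRING sub-scores dropped for their extremely sparse link coverage;
#: the "transferred" variants are retained.
STRING_EXCLUDED = ("coexpression", "experiments")

STRING_SUBSCORES = (
    "neighborhood",
    "neighborhood_transferred",
    "fusion",
    "cooccurence",
    "homology",
    "coexpression",
    "coexpression_transferred",
    "experiments",
    "experiments_transferred",
    "database",
    "database_transferred",
    "textmining",
    "textmining_transferred",
)


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered protein pair."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# sequence-motif channel
# ---------------------------------------------------------------------------

def shannon_weights(feature_matrix: pd.DataFrame) -> dict[str, float]:
    """Shannon information content of each binary sequence feature, in bits.

    ``weight(f) = -log2(n_f / N)`` with ``n_f`` the number of proteins
    carrying feature *f* and ``N`` the total number of proteins. Features
    carried by every protein are uninformative and get weight 0.
    """
    if feature_matrix.empty:
        raise ValueError("feature matrix is empty")
    n_total = feature_matrix.shape[0]
    counts = feature_matrix.sum(axis=0)
    if (counts == 0).any():
        missing = counts.index[counts == 0].tolist()
        raise ValueError(f"features carried by zero proteins: {missing}")
    return dict(-np.log2(counts / n_total))


def weighted_jaccard_distance(
    vec_a: Iterable[str],
    vec_b: Iterable[str],
    weights: Mapping[str, float],
    *,
    degenerate_value: float = 0.0,
) -> float:
    """Weighted Jaccard distance between two feature-identifier sets.

    ``1 - sum(w over intersection) / sum(w over union)``. When the union has
    total weight 0 the vectors are indistinguishable under the weighting and
    the configured *degenerate_value* (default 0) is returned.
    """
    set_a, set_b = set(vec_a), set(vec_b)
    # summed in sorted order so the distance is exactly symmetric and
    # exactly 0 for identical supports despite float rounding
    union_w = sum(weights[f] for f in sorted(set_a | set_b))
    if union_w == 0:
        logger.debug("weighted Jaccard union weight 0; returning degenerate value")
        return degenerate_value
    inter_w = sum(weights[f] for f in sorted(set_a & set_b))
    return 1.0 - inter_w / union_w


# ---------------------------------------------------------------------------
# proteomic co-expression channel
# ---------------------------------------------------------------------------

@dataclass
class QuantExperiment:
    """One label-free quantification experiment.

    ``intensities`` is a protein x sample matrix of non-negative intensities
    (absent proteins simply lack a row); ``sample_condition`` maps every
    sample column to a condition label.
    """

    experiment_id: str
    intensities: pd.DataFrame
    sample_condition: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(self.intensities.columns) - set(self.sample_condition)
        if missing:
            raise ValueError(f"samples without condition mapping: {sorted(missing)}")
        if len(set(self.sample_condition.values())) < 2:
            raise ValueError(
                f"experiment {self.experiment_id!r} has fewer than 2 conditions"
            )

    def condition_profiles(self) -> pd.DataFrame:
        """Protein x condition matrix: mean of nonzero sample intensities per
        condition, 0 where the protein was not observed in the condition."""
        mat = self.intensities
        cond_of = {s: self.sample_condition[s] for s in mat.columns}
        vals = mat.to_numpy(dtype=float)
        cond_arr = np.array([cond_of[s] for s in mat.columns])
        cond_labels = sorted(set(cond_arr))
        out = np.zeros((mat.shape[0], len(cond_labels)))
        for j, c in enumerate(cond_labels):
            sub = vals[:, cond_arr == c]
            nonzero = sub > 0
            counts = nonzero.sum(axis=1)
            sums = np.where(nonzero, sub, 0.0).sum(axis=1)
            out[:, j] = np.divide(
                sums, counts, out=np.zeros_like(sums), where=counts > 0
            )
        return pd.DataFrame(out, index=mat.index, columns=cond_labels)


def _spearman_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """All-pairs Spearman correlation of rows; constant rows give 0."""
    vals = profiles.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, vals)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    safe = np.where(norms > 0, norms, 1.0)
    unit = ranks / safe[:, None]
    corr = unit @ unit.T
    corr[norms == 0, :] = 0.0  # constant profile: undefined rho -> 0
    corr[:, norms == 0] = 0.0
    return np.clip(corr, -1.0, 1.0)


def coexpression_features(
    experiments: Sequence[QuantExperiment],
    universe: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair (mean Spearman, presence Jaccard distance) over experiments.

    Per experiment, profiles are condition-level (nonzero sample mean, zero
    imputed); a pair's correlation in an experiment missing either protein is
    0, and the mean is taken over all experiments. Presence/absence is the
    concatenated condition-level presence vector across all experiments;
    pairs where a protein is never observed get distance 1.

    Returns two square DataFrames indexed by *universe*.
    """
    if not experiments:
        raise ValueError("at least one experiment required")
    universe = list(universe)
    n = len(universe)
    idx = {p: i for i, p in enumerate(universe)}
    corr_sum = np.zeros((n, n))
    presence_cols = []
    for exp in experiments:
        profiles = exp.condition_profiles()
        present = [p for p in profiles.index if p in idx]
        profiles = profiles.loc[present]
        corr = _spearman_matrix(profiles)
        rows = np.array([idx[p] for p in present], dtype=int)
        if rows.size:
            corr_sum[np.ix_(rows, rows)] += corr
        pres = np.zeros((n, profiles.shape[1]), dtype=bool)
        if rows.size:
            pres[rows] = profiles.to_numpy() > 0
        presence_cols.append(pres)
    mean_spearman = corr_sum / len(experiments)
    np.fill_diagonal(mean_spearman, 1.0)

    presence = np.concatenate(presence_cols, axis=1)
    inter = (presence[:, None, :] & presence[None, :, :]).sum(axis=2)
    union = (presence[:, None, :] | presence[None, :, :]).sum(axis=2)
    jacc_dist = 1.0 - np.divide(
        inter, union, out=np.zeros_like(inter, dtype=float), where=union > 0
    )
    jacc_dist[union == 0] = 1.0  # no observations anywhere -> maximally distant
    np.fill_diagonal(jacc_dist, 0.0)
    return (
        pd.DataFrame(mean_spearman, index=universe, columns=universe),
        pd.DataFrame(jacc_dist, index=universe, columns=universe),
    )


# ---------------------------------------------------------------------------
# structure channel
# ---------------------------------------------------------------------------

@dataclass
class ResidueConfidenceModel:
    """A predicted structure reduced to its per-residue pLDDT trace."""

    protein_id: str
    plddt: np.ndarray  # ordered per-residue confidence in [0, 100]

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        if self.plddt.size < 1:
            raise ValueError("structure must have at least one residue")
        if self.plddt.min() < 0 or self.plddt.max() > 100:
            raise ValueError("pLDDT values must lie in [0, 100]")

    def __len__(self) -> int:
        return int(self.plddt.size)


def read_plddt_model(pdb_path, protein_id: str | None = None) -> ResidueConfidenceModel:
    """Read per-residue pLDDT from the B-factor column of a PDB file
    (AlphaFold database convention). Uses the CA atom of each residue."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(pdb_path))
    plddt = []
    for residue in next(structure.get_models()).get_residues():
        if "CA" in residue:
            plddt.append(residue["CA"].get_bfactor())
    return ResidueConfidenceModel(protein_id or structure.id, np.array(plddt))


def trim_structure(
    model: ResidueConfidenceModel,
    *,
    plddt_cutoff: float = 70.0,
    min_retained_length: int = 30,
) -> ResidueConfidenceModel | None:
    """Trim low-confidence termini; keep only sufficiently long cores.

    Residues are removed from each terminus up to (exclusive) the first
    residue with pLDDT strictly above *plddt_cutoff*; interior low-confidence
    residues are untouched. The model is kept iff the remaining length is
    strictly greater than *min_retained_length*; otherwise ``None``.
    """
    above = np.flatnonzero(model.plddt > plddt_cutoff)
    if above.size == 0:
        return None
    start, stop = above[0], above[-1] + 1
    if stop - start <= min_retained_length:
        return None
    return ResidueConfidenceModel(model.protein_id, model.plddt[start:stop])


def tm_pair_feature(
    tm_norm_by_a: float, tm_norm_by_b: float, rmsd: float
) -> tuple[float, float]:
    """Summarize a structure alignment: max of the two length-normalized
    TM-scores, plus RMSD. Order-invariant in the two normalizations."""
    for tm in (tm_norm_by_a, tm_norm_by_b):
        if not 0.0 <= tm <= 1.0:
            raise ValueError(f"TM-score {tm} outside [0, 1]")
    if rmsd < 0:
        raise ValueError(f"negative RMSD {rmsd}")
    return (max(tm_norm_by_a, tm_norm_by_b), rmsd)


# ---------------------------------------------------------------------------
# evolutionary channel
# ---------------------------------------------------------------------------

def orthogroup_overlap(
    orthogroup_table: Mapping[str, frozenset[str] | set[str]],
    protein_a: str,
    protein_b: str,
) -> int:
    """Size of the species-set intersection of the two proteins' orthogroups;
    0 when either protein lacks an orthogroup."""
    sp_a = orthogroup_table.get(protein_a)
    sp_b = orthogroup_table.get(protein_b)
    if sp_a is None or sp_b is None:
        return 0
    return len(set(sp_a) & set(sp_b))


# ---------------------------------------------------------------------------
# STRING channel
# ---------------------------------------------------------------------------

def select_string_scores(
    string_table: pd.DataFrame,
    *,
    excluded: Sequence[str] = STRING_EXCLUDED,
) -> pd.DataFrame:
    """Select STRING sub-scores, excluding the sparse direct co-expression
    and experiments channels (their transferred variants are retained).

    Input columns: ``protein1, protein2`` plus integer scores on STRING's
    0-1000 scale including ``combined_score``. Scores are rescaled to [0,1].
    Returns a frame keyed by canonical pair (``protein_a, protein_b``) with
    one column per retained score; pairs absent from the table are simply
    absent (fill value 0 at assembly).
    """
    required = {"protein1", "protein2", "combined_score"}
    missing = required - set(string_table.columns)
    if missing:
        raise ValueError(f"STRING table missing columns: {sorted(missing)}")
    score_cols = [
        c for c in string_table.columns if c not in ("protein1", "protein2")
    ]
    kept = [c for c in score_cols if c not in excluded]
    out = string_table[["protein1", "protein2"] + kept].copy()
    pairs = [pair_key(a, b) for a, b in zip(out["protein1"], out["protein2"])]
    out["protein_a"] = [p[0] for p in pairs]
    out["protein_b"] = [p[1] for p in pairs]
    out = out.drop(columns=["protein1", "protein2"])
    out[kept] = out[kept].astype(float) / 1000.0
    return out.groupby(["protein_a", "protein_b"], as_index=False)[kept].max()


# ---------------------------------------------------------------------------
# registry & assembly
# ---------------------------------------------------------------------------

@dataclass
class ChannelSpec:
    """One entry of the similarity-measure registry."""

    name: str
    fill_value: float  # value used for pairs with no evidence


def default_registry(string_columns: Sequence[str] | None = None) -> list[ChannelSpec]:
    """The default similarity-measure registry (~20 measures): the in-module
    channels plus the retained STRING combined and sub-scores. Config-editable
    so the count is not hard-coded."""
    channels = [
        ChannelSpec("motif_weighted_jaccard", 1.0),
        ChannelSpec("bitscore", 0.0),
        ChannelSpec("operon_comembership", 0.0),
        ChannelSpec("orthogroup_overlap", 0.0),
        ChannelSpec("tree_distance", 0.0),
        ChannelSpec("mean_spearman", 0.0),
        ChannelSpec("presence_jaccard", 1.0),
        ChannelSpec("tm_max", 0.0),
        ChannelSpec("rmsd", 0.0),
    ]
    if string_columns is None:
        string_columns = ["combined_score"] + [
            c for c in STRING_SUBSCORES if c not in STRING_EXCLUDED
        ]
    channels += [ChannelSpec(f"string_{c}", 0.0) for c in string_columns]
    return channels


def _pair_table_to_map(table: pd.DataFrame, value_col: str = "value") -> dict:
    out = {}
    for row in table.itertuples(index=False):
        out[pair_key(row.protein_a, row.protein_b)] = float(getattr(row, value_col))
    return out


def assemble_pair_features(
    universe: Sequence[str],
    *,
    feature_matrix: pd.DataFrame | None = None,
    bitscore_table: pd.DataFrame | None = None,
    operon_table: pd.DataFrame | None = None,
    orthogroups: Mapping[str, frozenset[str]] | None = None,
    tree_distance_table: pd.DataFrame | None = None,
    experiments: Sequence[QuantExperiment] | None = None,
    tm_table: pd.DataFrame | None = None,
    string_scores: pd.DataFrame | None = None,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Build the named feature vector for every unordered protein pair.

    All channels are optional; absent channels keep their registry fill
    value. Bitscore, operon flag and tree distance are consumed from generic
    pair-score tables (``protein_a, protein_b, value``) as-is; the TM table
    carries ``tm_norm_a, tm_norm_b, rmsd``. IDs appearing in a channel but
    not in *universe* are dropped with a warning.

    Returns a DataFrame with ``protein_a, protein_b`` in canonical order plus
    one column per registry channel; symmetric under pair order by
    construction.
    """
    universe = list(universe)
    uset = set(universe)
    if pairs is None:
        pair_list = [
            (universe[i], universe[j])
            for i in range(len(universe))
            for j in range(i + 1, len(universe))
        ]
    else:
        pair_list = [pair_key(a, b) for a, b in pairs]

    string_cols = None
    if string_scores is not None:
        string_cols = [
            c for c in string_scores.columns if c not in ("protein_a", "protein_b")
        ]
    registry = default_registry(string_cols)
    frame = pd.DataFrame(pair_list, columns=["protein_a", "protein_b"])
    for spec in registry:
        frame[spec.name] = spec.fill_value

    def keep_in_universe(ids: Iterable[str], channel: str) -> None:
        stray = set(ids) - uset
        if stray:
            logger.warning(
                "%s: dropping %d ids outside the protein universe",
                channel,
                len(stray),
            )

    if feature_matrix is not None:
        keep_in_universe(feature_matrix.index, "feature_matrix")
        fm = feature_matrix.loc[[p for p in feature_matrix.index if p in uset]]
        weights = shannon_weights(fm)
        feats = {p: set(fm.columns[fm.loc[p] > 0]) for p in fm.index}
        vals = []
        for a, b in pair_list:
            fa, fb = feats.get(a), feats.get(b)
            if fa is None or fb is None:
                vals.append(1.0)  # protein with no feature data -> max distance
            else:
                vals.append(weighted_jaccard_distance(fa, fb, weights))
        frame["motif_weighted_jaccard"] = vals

    simple_tables = {
        "bitscore": bitscore_table,
        "operon_comembership": operon_table,
        "tree_distance": tree_distance_table,
    }
    for name, table in simple_tables.items():
        if table is None:
            continue
        keep_in_universe(
            list(table["protein_a"]) + list(table["protein_b"]), name
        )
        lookup = _pair_table_to_map(table)
        fill = next(s.fill_value for s in registry if s.name == name)
        frame[name] = [lookup.get(p, fill) for p in pair_list]

    if orthogroups is not None:
        keep_in_universe(orthogroups.keys(), "orthogroups")
        frame["orthogroup_overlap"] = [
            float(orthogroup_overlap(orthogroups, a, b)) for a, b in pair_list
        ]

    if experiments is not None and len(experiments) > 0:
        spearman, presence = coexpression_features(experiments, universe)
        frame["mean_spearman"] = [spearman.at[a, b] for a, b in pair_list]
        frame["presence_jaccard"] = [presence.at[a, b] for a, b in pair_list]

    if tm_table is not None:
        tm_map = {}
        for row in tm_table.itertuples(index=False):
            tm_max, rmsd = tm_pair_feature(row.tm_norm_a, row.tm_norm_b, row.rmsd)
            tm_map[pair_key(row.protein_a, row.protein_b)] = (tm_max, rmsd)
        frame["tm_max"] = [tm_map.get(p, (0.0, 0.0))[0] for p in pair_list]
        frame["rmsd"] = [tm_map.get(p, (0.0, 0.0))[1] for p in pair_list]

    if string_scores is not None:
        merged = frame[["protein_a", "protein_b"]].merge(
            string_scores, on=["protein_a", "protein_b"], how="left"
        )
        for col in string_cols:
            frame[f"string_{col}"] = merged[col].fillna(0.0).to_numpy()

    return frame


def feature_columns(frame: pd.DataFrame) -> list[str]:
    """Names of the similarity-measure columns of an assembled pair table."""
    return [c for c in frame.columns if c not in ("protein_a", "protein_b")]
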