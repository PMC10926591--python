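"""Structural-similarity arm: structure-search hits -> transfer candidates.

Hits from a structure search (TM-score, RMSD, hit sequence, taxonomy,
annotations) are filtered at TM-score > 0.3, augmented with global sequence
alignment statistics (percent identity, percent non-gap) and a coarse
taxonomic-rank similarity, then handed to the shared term-transfer engine.

The global alignment is Needleman–Wunsch with affine gaps (Gotoh): a gap of
length L costs ``gap_open + (L - 1) * gap_extend``. Defaults are BLOSUM62
with gap open 11 and extend 1. Traceback ties are broken deterministically:
diagonal, then up (gap in the second sequence), then left.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Align import substitution_matrices

from .ontology import OntologyGraph, ancestral_closure
from .term_transfer import Hit, HitSet

#: Taxonomic ranks, most specific first. Shared-species maps to 0 (the
#: published scale starts at genus = 1); no shared level maps to 7.
TAXONOMIC_RANKS = (
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "superkingdom",
)
NO_SHARED_RANK = len(TAXONOMIC_RANKS)  # sentinel: 7

#: Similarity measures of the structural arm's hit score map.
STRUCTURAL_MEASURES = (
    "tm_score",
    "rmsd",
    "percent_identity",
    "percent_non_gap",
    "taxonomic_rank",
)

TM_CUTOFF = 0.3

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

_NEG = float("-inf")


@dataclass
class StructureHit:
    """One structure-search hit for a query protein."""

    query_id: str
    hit_id: str
    tm_score: float
    rmsd: float
    hit_sequence: str
    lineage: tuple[str, ...]  # one name per TAXONOMIC_RANKS level
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not 0.0 <= self.tm_score <= 1.0:
            raise ValueError(f"TM-score {self.tm_score} outside [0, 1]")
        if len(self.lineage) != len(TAXONOMIC_RANKS):
            raise ValueError(
                f"lineage must have {len(TAXONOMIC_RANKS)} levels, "
                f"got {len(self.lineage)}"
            )


@dataclass
class AlignmentStats:
    """Global-alignment summary for a query/hit sequence pair."""

    score: float
    aligned_a: str
    aligned_b: str
    alignment_length: int
    percent_identity: float  # identical aligned pairs / alignment length * 100
    percent_non_gap: float  # columns with residues on both rows / length * 100


def filter_structure_hits(
    hits: Iterable[StructureHit], tm_cutoff: float = TM_CUTOFF
) -> list[StructureHit]:
    """Keep hits with TM-score strictly above *tm_cutoff*; drop self-hits."""
    return [
        h for h in hits if h.tm_score > tm_cutoff and h.hit_id != h.query_id
    ]


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} is empty")
    for pos, ch in enumerate(seq):
        if ch not in AMINO_ALPHABET:
            raise ValueError(
                f"{name} has invalid character {ch!r} at position {pos}"
            )


def global_align(
    seq_a: str,
    seq_b: str,
    substitution_matrix: Mapping | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentStats:
    """Optimal global alignment with affine gap penalties (Gotoh).

    Percent identity and percent non-gap are both normalized by the
    alignment length. The score and both percentages are symmetric in the
    two sequences; the traceback itself prefers diagonal over up over left.
    """
    _check_sequence(seq_a, "seq_a")
    _check_sequence(seq_b, "seq_b")
    if substitution_matrix is None:
        substitution_matrix = load_blosum62()
    sub = substitution_matrix
    n, m = len(seq_a), len(seq_b)

    # state matrices: M diag, X up (gap in seq_b), Y left (gap in seq_a)
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    ptr: dict[tuple[int, int, int], tuple[int, int, int]] = {}
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
        ptr[(0, i, 0)] = (0, i - 1, 0) if i > 1 else (2, i - 1, 0)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)
        ptr[(1, 0, j)] = (1, 0, j - 1) if j > 1 else (2, 0, j - 1)
    # state codes for ptr keys: 0 = X, 1 = Y, 2 = M

    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            s = sub[(ai, seq_b[j - 1])]
            # M: tie-break prefers M (diag chain), then X, then Y
            best, src = M[i - 1][j - 1], 2
            if X[i - 1][j - 1] > best:
                best, src = X[i - 1][j - 1], 0
            if Y[i - 1][j - 1] > best:
                best, src = Y[i - 1][j - 1], 1
            M[i][j] = best + s
            ptr[(2, i, j)] = (src, i - 1, j - 1)
            # X (up): open from M, extend X
            open_x = M[i - 1][j] - gap_open
            ext_x = X[i - 1][j] - gap_extend
            if open_x >= ext_x:
                X[i][j] = open_x
                ptr[(0, i, j)] = (2, i - 1, j)
            else:
                X[i][j] = ext_x
                ptr[(0, i, j)] = (0, i - 1, j)
            # Y (left): open from M, extend Y
            open_y = M[i][j - 1] - gap_open
            ext_y = Y[i][j - 1] - gap_extend
            if open_y >= ext_y:
                Y[i][j] = open_y
                ptr[(1, i, j)] = (2, i, j - 1)
            else:
                Y[i][j] = ext_y
                ptr[(1, i, j)] = (1, i, j - 1)

    # final state: prefer M, then X, then Y
    score, state = M[n][m], 2
    if X[n][m] > score:
        score, state = X[n][m], 0
    if Y[n][m] > score:
        score, state = Y[n][m], 1

    out_a, out_b = [], []
    i, j = n, m
    while (i, j) != (0, 0):
        prev = ptr[(state, i, j)]
        if state == 2:
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i, j = i - 1, j - 1
        elif state == 0:
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            j -= 1
        state = prev[0]
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))

    length = len(aligned_a)
    identical = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    non_gap = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-"
    )
    return AlignmentStats(
        score=float(score),
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        alignment_length=length,
        percent_identity=100.0 * identical / length,
        percent_non_gap=100.0 * non_gap / length,
    )


_blosum_cache: dict | None = None


def load_blosum62() -> dict[tuple[str, str], float]:
    """BLOSUM62 as a plain dict for fast lookup."""
    global _blosum_cache
    if _blosum_cache is None:
        mat = substitution_matrices.load("BLOSUM62")
        _blosum_cache = {
            (a, b): float(mat[a, b])
            for a in mat.alphabet
            for b in mat.alphabet
        }
    return _blosum_cache


def taxonomic_rank_similarity(
    lineage_a: Sequence[str], lineage_b: Sequence[str]
) -> int:
    """Rank index of the most specific shared taxonomic level.

    Same species -> 0, same genus -> 1, family -> 2, order -> 3, class -> 4,
    phylum -> 5, superkingdom -> 6; nothing shared -> 7. Symmetric, and
    smaller means more similar.
    """
    if len(lineage_a) != len(TAXONOMIC_RANKS) or len(lineage_b) != len(
        TAXONOMIC_RANKS
    ):
        raise ValueError(
            f"lineages must have {len(TAXONOMIC_RANKS)} levels "
            f"({len(lineage_a)} and {len(lineage_b)} given)"
        )
    for rank_idx, (a, b) in enumerate(zip(lineage_a, lineage_b)):
        if a == b:
            return rank_idx
    return NO_SHARED_RANK


def build_structural_hit_sets(
    hits: Iterable[StructureHit],
    query_sequences: Mapping[str, str],
    query_lineage: Sequence[str],
    graph: OntologyGraph,
) -> list[HitSet]:
    """Turn filtered structure hits into per-query HitSets for the transfer
    engine. Per-hit score map: TM-score and RMSD from the hit table verbatim,
    alignment percent identity / percent non-gap, and taxonomic rank
    similarity against the (single-organism) query lineage. Hit annotation
    sets are ancestor-closed; hits with no annotations contribute no
    candidates downstream."""
    by_query: dict[str, list[Hit]] = {}
    for hit in hits:
        stats = global_align(query_sequences[hit.query_id], hit.hit_sequence)
        scores = {
            "tm_score": hit.tm_score,
            "rmsd": hit.rmsd,
            "percent_identity": stats.percent_identity,
            "percent_non_gap": stats.percent_non_gap,
            "taxonomic_rank": float(
                taxonomic_rank_similarity(query_lineage, hit.lineage)
            ),
        }
        annotations = (
            ancestral_closure(graph, hit.terms) if hit.terms else frozenset()
        )
        by_query.setdefault(hit.query_id, []).append(
            Hit(hit.hit_id, scores, frozenset(annotations))
        )
    return [
        HitSet(query, hit_list) for query, hit_list in sorted(by_query.items())
    ]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_structure_hits(hits: Iterable[StructureHit], path: str | Path) -> None:
    rows = [
        {
            "query_id": h.query_id,
            "hit_id": h.hit_id,
            "tm_score": h.tm_score,
            "rmsd": h.rmsd,
            "hit_sequence": h.hit_sequence,
            "lineage": ";".join(h.lineage),
            "terms": "|".join(sorted(h.terms)),
        }
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "hit_id",
            "tm_score",
            "rmsd",
            "hit_sequence",
            "lineage",
            "terms",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_structure_hits(path: str | Path) -> list[StructureHit]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    hits = []
    for row in frame.itertuples(index=False):
        terms = frozenset(t for t in str(row.terms).split("|") if t)
        hits.append(
            StructureHit(
                query_id=row.query_id,
                hit_id=row.hit_id,
                tm_score=float(row.tm_score),
                rmsd=float(row.rmsd),
                hit_sequence=row.hit_sequence,
                lineage=tuple(str(row.lineage).split(";")),
                terms=terms,
            )
        )
    return hits
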