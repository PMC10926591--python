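"""Synthetic multi-omics inputs with planted functional structure.

The generator emulates every input the pipeline consumes — an OBO ontology,
four overlapping annotation sources (one score-bearing), all pairwise
similarity channels, label-free quantification experiments, per-residue
confidence-annotated structures, and cross-species structure-search hits —
with a controllable planted signal and a masked ground truth for honest
end-to-end FDR/recall assessment.

Planted structure
-----------------
Proteins belong to functional *groups* nested in term *families*: each
family owns a term at depth ``max_depth - 2`` and each of its groups a
deeper term chain below it (depths ``max_depth - 1`` and ``max_depth``).
Proteins are annotated with their group's deepest term plus a couple of
random shallow background terms, so the true deepest-shared depth is
``max_depth`` within a group, ``max_depth - 2`` across groups of one
family, and shallow otherwise.

Signal strength ``alpha`` couples every evidence channel to this structure
through a per-channel *channel group*: a protein's channel group equals its
true group with probability ``alpha`` and is uniform otherwise, so at
``alpha = 0`` every channel is exactly independent of the planted truth
while retaining realistic within-channel structure.

PUF masking selects groups (keeping at least one group per family
untouched) and masks most members of each selected group: masked proteins
keep only their namespace root in the emitted annotation sources — making
them PUFs under the depth-below-two rule — while the full truth is
retained for the evaluator only. Masking by group makes the PUF set a
planted community of the hit network, while the remaining annotated
group-mates and sibling groups carry the annotations needed for recovery.
"""

from __future__ import annotations

import itertools
import json
from collections.abc import Mapping
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ontology as onto
from .features import QuantExperiment, ResidueConfidenceModel
from .ontology import AnnotationStore, OntologyGraph
from .structural_arm import TAXONOMIC_RANKS, StructureHit

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

QUERY_LINEAGE = (
    "synthetic species 0",
    "synthetic genus 0",
    "synthetic family 0",
    "synthetic order 0",
    "synthetic class 0",
    "synthetic phylum 0",
    "Bacteria",
)


@dataclass
class SyntheticConfig:
    """All knobs of the generator; presets select coherent bundles."""

    seed: int = 0
    # ontology
    n_terms: int = 150
    max_depth: int = 9
    n_families: int = 8
    groups_per_family: int = 2
    dual_parent_prob: float = 0.3
    # proteome & annotation sources
    n_proteins: int = 300
    extra_terms_max: int = 2
    source_dropout: float = 0.15
    netgo_noise_rate: float = 0.3
    puf_fraction: float = 0.2
    group_mask_fraction: float = 0.7
    # planted signal
    alpha: float = 0.9
    noise_sd: float = 0.1
    # proteomics
    n_experiments: int = 2
    n_conditions: int = 5
    samples_per_condition: int = 2
    quant_dropout: float = 0.25
    # structures
    seq_len_range: tuple[int, int] = (50, 90)
    low_tail_mean: float = 5.0
    bad_structure_rate: float = 0.05
    # structural hits
    n_foreign: int = 80
    hits_per_query_mean: float = 6.0
    # enrichment helper
    planted_or: float = 1.0


PRESETS: dict[str, dict] = {
    "strong": {"alpha": 0.9, "noise_sd": 0.05, "n_proteins": 300, "n_terms": 150},
    "noisy": {"alpha": 0.5, "noise_sd": 0.25, "n_proteins": 160, "n_terms": 120},
    "null": {"alpha": 0.0, "noise_sd": 0.25, "n_proteins": 160, "n_terms": 120},
}


def preset_config(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    params = dict(PRESETS[name])
    params.update(overrides)
    return SyntheticConfig(seed=seed, **params)


@dataclass
class GroundTruth:
    """Pre-masking annotations and masking plan; evaluator-only."""

    full_store: AnnotationStore  # ancestor-closed, every protein
    masked_proteins: frozenset[str]
    group_of: dict[str, int]
    family_of_group: dict[int, int]
    planted_or: float


@dataclass
class TermPlan:
    """Bookkeeping of the generated ontology's planted scaffold."""

    n_terms: int
    n_edges: int
    roots: dict[str, str]
    family_terms: list[str]  # per family, depth max_depth - 2
    group_terms: list[str]  # per group, depth max_depth - 1
    deep_terms: list[str]  # per group, depth max_depth
    group_namespace: list[str]
    extras_pool: list[str]  # background terms at depths 3..6


@dataclass
class SyntheticData:
    """Everything the pipeline consumes, plus the evaluator-only truth."""

    config: SyntheticConfig
    obo_text: str
    graph: OntologyGraph
    depths: dict[str, int]
    plan: TermPlan
    proteins: list[str]
    source_tables: dict[str, pd.DataFrame]
    known_store: AnnotationStore  # merged + closed, masked proteins at roots
    truth: GroundTruth
    feature_matrix: pd.DataFrame
    bitscore_table: pd.DataFrame
    operon_table: pd.DataFrame
    tree_distance_table: pd.DataFrame
    orthogroups: dict[str, frozenset[str]]
    experiments: list[QuantExperiment]
    tm_table: pd.DataFrame
    string_table: pd.DataFrame
    structures: dict[str, ResidueConfidenceModel]
    sequences: dict[str, str]
    structure_hits: list[StructureHit]
    query_lineage: tuple[str, ...] = QUERY_LINEAGE


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def make_ontology(config: SyntheticConfig, rng: np.random.Generator):
    """Build a three-namespace DAG with the family/group scaffold, random
    background terms (with occasional dual parents, guaranteeing diamonds),
    and one obsolete term. Returns (obo_text, TermPlan)."""
    if config.max_depth < 9:
        raise ValueError("max_depth must be >= 9 to exercise deep strata")
    counter = itertools.count(1)
    terms: dict[str, dict] = {}

    def new_term(namespace: str, parents: list[str], depth: int) -> str:
        tid = f"GO:{next(counter):07d}"
        terms[tid] = {
            "namespace": namespace,
            "parents": list(parents),
            "part_of": [],
            "depth": depth,
        }
        return tid

    roots = {ns: new_term(ns, [], 0) for ns in onto.NAMESPACES}
    trunk2: dict[str, str] = {}
    for ns in onto.NAMESPACES:
        t1 = new_term(ns, [roots[ns]], 1)
        trunk2[ns] = new_term(ns, [t1], 2)

    depth_family = config.max_depth - 2
    family_terms, group_terms, deep_terms, group_ns = [], [], [], []
    for fam in range(config.n_families):
        ns = onto.NAMESPACES[fam % 3]
        parent = trunk2[ns]
        for d in range(3, depth_family + 1):
            parent = new_term(ns, [parent], d)
        family_terms.append(parent)
        for _ in range(config.groups_per_family):
            g = new_term(ns, [parent], depth_family + 1)
            deep = new_term(ns, [g], depth_family + 2)
            group_terms.append(g)
            deep_terms.append(deep)
            group_ns.append(ns)

    # explicit diamond: two depth-2 siblings with a common child
    ns0 = onto.NAMESPACES[0]
    t1_parent = terms[trunk2[ns0]]["parents"][0]
    a = new_term(ns0, [t1_parent], 2)
    b = new_term(ns0, [t1_parent], 2)
    new_term(ns0, [a, b], 3)

    # background terms under random shallow parents
    n_extra = max(0, config.n_terms - len(terms))
    extras_pool: list[str] = []
    for _ in range(n_extra):
        candidates = [t for t, d in terms.items() if 1 <= d["depth"] <= 5]
        parent = candidates[rng.integers(len(candidates))]
        ns = terms[parent]["namespace"]
        depth = terms[parent]["depth"] + 1
        tid = new_term(ns, [parent], depth)
        if rng.random() < config.dual_parent_prob:
            shallower = [
                t
                for t, d in terms.items()
                if d["namespace"] == ns and d["depth"] < depth and t != parent
            ]
            second = shallower[rng.integers(len(shallower))]
            terms[tid]["part_of"].append(second)
        if 3 <= depth <= 6:
            extras_pool.append(tid)

    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    n_edges = 0
    for tid in sorted(terms):
        info = terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: synthetic term {tid[3:].lstrip('0') or '0'}")
        lines.append(f"namespace: {info['namespace']}")
        for p in info["parents"]:
            lines.append(f"is_a: {p}")
            n_edges += 1
        for p in info["part_of"]:
            lines.append(f"relationship: part_of {p}")
            n_edges += 1
        lines.append("")
    # one obsolete term, excluded on load
    lines += [
        "[Term]",
        f"id: GO:{next(counter):07d}",
        "name: synthetic obsolete term",
        f"namespace: {onto.NAMESPACES[0]}",
        "is_obsolete: true",
        "",
    ]
    plan = TermPlan(
        n_terms=len(terms),
        n_edges=n_edges,
        roots=roots,
        family_terms=family_terms,
        group_terms=group_terms,
        deep_terms=deep_terms,
        group_namespace=group_ns,
        extras_pool=extras_pool,
    )
    return "\n".join(lines), plan


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def make_proteome(
    config: SyntheticConfig,
    graph: OntologyGraph,
    plan: TermPlan,
    rng: np.random.Generator,
):
    """Assign proteins to groups, draw annotations, emit four source tables
    with per-source dropout (NetGO-like source score-bearing), and mask
    whole groups to roots. Returns (proteins, source_tables, truth)."""
    n_groups = config.n_families * config.groups_per_family
    proteins = [f"P{i:04d}" for i in range(config.n_proteins)]
    group_of = {p: i % n_groups for i, p in enumerate(proteins)}
    family_of_group = {g: g // config.groups_per_family for g in range(n_groups)}

    true_terms: dict[str, list[str]] = {}
    for p in proteins:
        terms = [plan.deep_terms[group_of[p]]]
        k = int(rng.integers(1, config.extra_terms_max + 1))
        if plan.extras_pool:
            picks = rng.choice(len(plan.extras_pool), size=k, replace=False)
            terms += [plan.extras_pool[i] for i in picks]
        true_terms[p] = terms

    # mask most members of selected groups (PUF analogs): under-annotated
    # functions cluster, so the masked set is a planted community, while the
    # remaining annotated group-mates keep recovery possible. At least one
    # group per family is left untouched.
    target = config.puf_fraction * config.n_proteins
    order = rng.permutation(n_groups)
    masked: set[str] = set()
    fam_untouched = {
        f: config.groups_per_family for f in range(config.n_families)
    }
    for g in order:
        if len(masked) >= target:
            break
        fam = family_of_group[int(g)]
        if fam_untouched[fam] <= 1:
            continue
        fam_untouched[fam] -= 1
        members = [p for p in proteins if group_of[p] == int(g)]
        n_mask = int(np.ceil(config.group_mask_fraction * len(members)))
        picks = rng.choice(len(members), size=n_mask, replace=False)
        masked |= {members[i] for i in picks}

    full_store = AnnotationStore()
    for p in proteins:
        for t in true_terms[p]:
            full_store.add(p, t, "truth")
    truth = GroundTruth(
        full_store=full_store.closed(graph),
        masked_proteins=frozenset(masked),
        group_of=group_of,
        family_of_group=family_of_group,
        planted_or=config.planted_or,
    )

    sources = ["biocyc", "pgdb", "uniprot", "netgo"]
    rows: dict[str, list[dict]] = {s: [] for s in sources}
    all_terms = sorted(graph.terms)
    for p in proteins:
        if p in masked:
            ns = plan.group_namespace[group_of[p]]
            root = plan.roots[ns]
            rows["pgdb"].append(
                {"protein_id": p, "term_id": root, "score": None}
            )
            continue
        covered = set()
        for s in sources[:3]:
            for t in true_terms[p]:
                if rng.random() > config.source_dropout:
                    rows[s].append({"protein_id": p, "term_id": t, "score": None})
                    covered.add(t)
        for t in true_terms[p]:
            if rng.random() < 0.9:
                score = float(rng.uniform(0.85, 1.0))
                rows["netgo"].append(
                    {"protein_id": p, "term_id": t, "score": round(score, 4)}
                )
                if score > 0.9:
                    covered.add(t)
        if rng.random() < config.netgo_noise_rate:
            t = all_terms[rng.integers(len(all_terms))]
            rows["netgo"].append(
                {
                    "protein_id": p,
                    "term_id": t,
                    "score": round(float(rng.uniform(0.4, 0.95)), 4),
                }
            )
        # guarantee the deep term survives somewhere (PKFs stay PKFs)
        if true_terms[p][0] not in covered:
            rows["biocyc"].append(
                {"protein_id": p, "term_id": true_terms[p][0], "score": None}
            )
    source_tables = {
        s: pd.DataFrame(rows[s], columns=["protein_id", "term_id", "score"])
        for s in sources
    }
    return proteins, source_tables, truth


# ---------------------------------------------------------------------------
# similarity channels
# ---------------------------------------------------------------------------

def _channel_groups(
    proteins: list[str],
    group_of: Mapping[str, int],
    n_groups: int,
    alpha: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-protein channel group: the true group w.p. alpha, else uniform.
    At alpha = 0 the channel is exactly independent of the planted truth."""
    true = np.array([group_of[p] for p in proteins])
    random = rng.integers(0, n_groups, size=len(proteins))
    keep = rng.random(len(proteins)) < alpha
    return np.where(keep, true, random)


def _pair_relation(
    cg: np.ndarray, fam_of: Mapping[int, int], idx_a: np.ndarray, idx_b: np.ndarray
) -> np.ndarray:
    """Relatedness under a channel grouping: 1 same group, 0.5 same family,
    0 otherwise."""
    ga, gb = cg[idx_a], cg[idx_b]
    fam = np.vectorize(fam_of.__getitem__)
    rel = np.where(ga == gb, 1.0, np.where(fam(ga) == fam(gb), 0.5, 0.0))
    return rel


def make_similarity_channels(
    config: SyntheticConfig,
    proteins: list[str],
    truth: GroundTruth,
    plan: TermPlan,
    depths: Mapping[str, int],
    rng: np.random.Generator,
):
    """Generate all within-species evidence channels coupled to the planted
    structure with strength ``alpha`` (see module docstring)."""
    n = len(proteins)
    n_groups = config.n_families * config.groups_per_family
    fam_of = truth.family_of_group
    idx_a, idx_b = np.triu_indices(n, k=1)
    pa = np.array(proteins)[idx_a]
    pb = np.array(proteins)[idx_b]
    a, ns = config.alpha, config.noise_sd

    def cgroups() -> np.ndarray:
        return _channel_groups(proteins, truth.group_of, n_groups, a, rng)

    # true deepest-shared depth per pair, normalized; continuous channels
    # blend it in scaled by alpha so the alpha = 0 null stays exact while
    # large alpha yields a monotone depth-score relationship across the
    # whole depth range (not just the group/family strata)
    closed = [truth.full_store.terms_of(p) for p in proteins]
    depth_of = depths
    d_true = np.empty(idx_a.size)
    for k in range(idx_a.size):
        shared = closed[idx_a[k]] & closed[idx_b[k]]
        d_true[k] = max((depth_of[t] for t in shared), default=0)
    s_true = a * d_true / config.max_depth

    def blend(rel: np.ndarray) -> np.ndarray:
        return np.maximum(rel, s_true)

    # --- sequence-motif feature matrix -------------------------------
    cg = cgroups()
    n_bg = 40
    marker_cols = [f"MOTIF_G{g}_{k}" for g in range(n_groups) for k in range(3)]
    bg_cols = [f"MOTIF_BG{k}" for k in range(n_bg)]
    mat = np.zeros((n, len(marker_cols) + n_bg), dtype=int)
    for i in range(n):
        for k in range(3):
            if rng.random() < 0.85:
                mat[i, cg[i] * 3 + k] = 1
        picks = rng.choice(n_bg, size=4, replace=False)
        mat[i, len(marker_cols) + picks] = 1
    feature_matrix = pd.DataFrame(
        mat, index=proteins, columns=marker_cols + bg_cols
    )
    # drop all-zero features (never observed -> not part of the dataset)
    feature_matrix = feature_matrix.loc[:, feature_matrix.sum(axis=0) > 0]

    # --- bitscore ------------------------------------------------------
    cg = cgroups()
    rel = blend(_pair_relation(cg, fam_of, idx_a, idx_b))
    base = np.clip(0.1 + 0.8 * rel + ns * rng.standard_normal(rel.size), 0, 1)
    keep = base > 0.35
    bitscore_table = pd.DataFrame(
        {
            "protein_a": pa[keep],
            "protein_b": pb[keep],
            "value": np.round(700 * base[keep], 1),
        }
    )

    # --- operon co-membership -----------------------------------------
    cg = cgroups()
    rel = _pair_relation(cg, fam_of, idx_a, idx_b)
    keep = (rel == 1.0) & (rng.random(rel.size) < 0.5)
    operon_table = pd.DataFrame(
        {"protein_a": pa[keep], "protein_b": pb[keep], "value": 1.0}
    )

    # --- tree distance -------------------------------------------------
    cg = cgroups()
    rel = blend(_pair_relation(cg, fam_of, idx_a, idx_b))
    keep = (rel >= 0.5) & (rng.random(rel.size) < 0.8)
    keep |= rng.random(rel.size) < 0.03
    dist = np.clip(
        1.5 - 1.2 * rel + ns * rng.standard_normal(rel.size), 0.0, 2.0
    )
    tree_distance_table = pd.DataFrame(
        {
            "protein_a": pa[keep],
            "protein_b": pb[keep],
            "value": np.round(dist[keep], 4),
        }
    )

    # --- orthogroups ---------------------------------------------------
    cg = cgroups()
    species = [f"sp{j:02d}" for j in range(40)]
    fam_base = {
        f: frozenset(
            species[i] for i in rng.choice(40, size=8, replace=False)
        )
        for f in range(config.n_families)
    }
    group_extra = {
        g: frozenset(
            species[i] for i in rng.choice(40, size=7, replace=False)
        )
        for g in range(n_groups)
    }
    orthogroups = {}
    for i, p in enumerate(proteins):
        if rng.random() < 0.1:
            continue  # protein without an orthogroup
        g = int(cg[i])
        orthogroups[p] = fam_base[fam_of[g]] | group_extra[g]

    # --- quantification experiments ------------------------------------
    cg = cgroups()
    experiments = []
    for e in range(config.n_experiments):
        latent = rng.lognormal(
            mean=7.0, sigma=1.0, size=(n_groups, config.n_conditions)
        )
        sample_condition = {}
        cols = []
        for c in range(config.n_conditions):
            for s in range(config.samples_per_condition):
                name = f"e{e}_c{c}_s{s}"
                cols.append(name)
                sample_condition[name] = f"cond{c}"
        present = rng.random(n) >= config.quant_dropout
        data = {}
        for i, p in enumerate(proteins):
            if not present[i]:
                continue
            prof = latent[cg[i]] * np.exp(
                0.5 * ns * rng.standard_normal(config.n_conditions)
                + 0.3 * rng.standard_normal()
            )
            row = []
            for c in range(config.n_conditions):
                for _ in range(config.samples_per_condition):
                    row.append(prof[c] * np.exp(0.1 * rng.standard_normal()))
            data[p] = row
        intensities = pd.DataFrame.from_dict(
            data, orient="index", columns=cols
        )
        experiments.append(
            QuantExperiment(f"exp{e}", intensities, sample_condition)
        )

    # --- TM/RMSD --------------------------------------------------------
    cg = cgroups()
    rel = blend(_pair_relation(cg, fam_of, idx_a, idx_b))
    tm_base = np.clip(
        0.25 + 0.55 * rel + ns * rng.standard_normal(rel.size), 0.0, 1.0
    )
    jitter = 0.05 * rng.standard_normal(rel.size)
    tm_table = pd.DataFrame(
        {
            "protein_a": pa,
            "protein_b": pb,
            "tm_norm_a": np.round(np.clip(tm_base, 0, 1), 4),
            "tm_norm_b": np.round(np.clip(tm_base + jitter, 0, 1), 4),
            "rmsd": np.round(
                np.clip(9 - 7 * rel + 2 * rng.standard_normal(rel.size), 0.3, 12),
                3,
            ),
        }
    )

    # --- STRING ---------------------------------------------------------
    cg = cgroups()
    rel = blend(_pair_relation(cg, fam_of, idx_a, idx_b))
    keep = ((rel == 1.0) & (rng.random(rel.size) < 0.85)) | (
        (rel >= 0.5) & (rel < 1.0) & (rng.random(rel.size) < 0.4)
    )
    keep |= rng.random(rel.size) < 0.02
    rel_k = rel[keep]
    m = rel_k.size

    def sub(scale: float) -> np.ndarray:
        raw = np.clip(
            scale * rel_k * rng.uniform(0.3, 0.9, m)
            + ns * rng.standard_normal(m),
            0,
            1,
        )
        return (1000 * raw).astype(int)

    string_table = pd.DataFrame(
        {
            "protein1": pa[keep],
            "protein2": pb[keep],
            "neighborhood": sub(0.8),
            "fusion": sub(0.3),
            "cooccurence": sub(0.6),
            "coexpression": sub(0.7),
            "coexpression_transferred": sub(0.6),
            "experiments": sub(0.7),
            "experiments_transferred": sub(0.6),
            "database": sub(0.8),
            "textmining": sub(0.5),
            "combined_score": (
                1000
                * np.clip(
                    0.35 + 0.5 * rel_k + ns * rng.standard_normal(m), 0, 1
                )
            ).astype(int),
        }
    )
    return (
        feature_matrix,
        bitscore_table,
        operon_table,
        tree_distance_table,
        orthogroups,
        experiments,
        tm_table,
        string_table,
    )


# ---------------------------------------------------------------------------
# structures & structural hits
# ---------------------------------------------------------------------------

def make_structures(
    config: SyntheticConfig, proteins: list[str], rng: np.random.Generator
):
    """Per-protein sequence and pLDDT trace with low-confidence termini;
    a small fraction is entirely low-confidence (rejected by trimming)."""
    structures, sequences = {}, {}
    lo, hi = config.seq_len_range
    for p in proteins:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(
            AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)
        )
        sequences[p] = seq
        if rng.random() < config.bad_structure_rate:
            plddt = rng.uniform(30, 65, size=length)
        else:
            plddt = rng.uniform(75, 95, size=length)
            head = int(rng.poisson(config.low_tail_mean))
            tail = int(rng.poisson(config.low_tail_mean))
            if head:
                plddt[: min(head, length)] = rng.uniform(
                    40, 65, size=min(head, length)
                )
            if tail:
                plddt[length - min(tail, length) :] = rng.uniform(
                    40, 65, size=min(tail, length)
                )
        structures[p] = ResidueConfidenceModel(p, np.round(plddt, 2))
    return structures, sequences


def _mutate_sequence(
    seq: str, identity: float, rng: np.random.Generator
) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() > identity:
            chars[i] = AMINO_ACIDS[rng.integers(0, 20)]
    if rng.random() < 0.3 and len(chars) > 20:  # occasional deletion
        start = int(rng.integers(0, len(chars) - 8))
        del chars[start : start + int(rng.integers(3, 9))]
    return "".join(chars)


def _hit_lineage(tm: float, rng: np.random.Generator, hit_idx: int):
    """Hit lineage sharing the query's upper ranks from a TM-coupled level."""
    max_rank = len(TAXONOMIC_RANKS)
    # higher TM -> more specific shared level on average
    mean_rank = (1.0 - tm) * max_rank
    shared_from = int(np.clip(round(rng.normal(mean_rank, 1.5)), 0, max_rank))
    lineage = []
    for r in range(max_rank):
        if r >= shared_from:
            lineage.append(QUERY_LINEAGE[r])
        else:
            lineage.append(f"foreign {TAXONOMIC_RANKS[r]} {hit_idx}_{r}")
    return tuple(lineage)


def make_structure_hits(
    config: SyntheticConfig,
    proteins: list[str],
    sequences: Mapping[str, str],
    truth: GroundTruth,
    plan: TermPlan,
    known_proteins: list[str],
    rng: np.random.Generator,
) -> list[StructureHit]:
    """Structure-search hit table against a synthetic foreign protein pool.

    Queries are all PUFs plus a matching number of annotated proteins. A
    hit's probability of sharing the query's true deep function rises with
    its TM-score: ``p_share = 1 - (1 - alpha) * (1 - tm)`` for TM > 0.6.
    Hit sequences are query mutants with identity coupled to TM; lineages
    share the query's upper ranks from a TM-coupled level. TM <= 0.3 decoy
    hits are included to exercise the downstream filter.
    """
    n_groups = config.n_families * config.groups_per_family
    foreign_group = rng.integers(0, n_groups, size=config.n_foreign)
    foreign_terms = []
    for i in range(config.n_foreign):
        terms = {plan.deep_terms[int(foreign_group[i])]}
        if plan.extras_pool and rng.random() < 0.2:
            terms.add(plan.extras_pool[rng.integers(len(plan.extras_pool))])
        if rng.random() < 0.1:
            terms = set()  # unannotated foreign protein
        foreign_terms.append(frozenset(terms))

    pufs = sorted(truth.masked_proteins)
    pkf_pool = [p for p in known_proteins if p not in truth.masked_proteins]
    n_match = min(len(pufs), len(pkf_pool))
    picks = rng.choice(len(pkf_pool), size=n_match, replace=False)
    queries = pufs + sorted(pkf_pool[i] for i in picks)

    by_group: dict[int, list[int]] = {}
    for i, g in enumerate(foreign_group):
        by_group.setdefault(int(g), []).append(i)

    hits = []
    for q in queries:
        n_hits = 1 + int(rng.poisson(config.hits_per_query_mean))
        used: set[int] = set()  # a database protein is returned at most once
        for _ in range(n_hits):
            tm = float(rng.uniform(0.2, 0.98))
            same = by_group.get(truth.group_of[q], [])
            if tm > 0.6:
                p_share = 1 - (1 - config.alpha) * (1 - tm)
            else:
                p_share = config.alpha * max(tm - 0.3, 0.0) / 0.6
            if same and rng.random() < p_share:
                f_idx = same[rng.integers(len(same))]
            else:
                f_idx = int(rng.integers(config.n_foreign))
            if f_idx in used:
                continue
            used.add(f_idx)
            identity = float(np.clip(0.15 + 0.75 * tm, 0.05, 0.98))
            hits.append(
                StructureHit(
                    query_id=q,
                    hit_id=f"F{f_idx:03d}",
                    tm_score=round(tm, 4),
                    rmsd=round(
                        float(np.clip(10 * (1 - tm) + rng.normal(0, 1), 0.3, 12)),
                        3,
                    ),
                    hit_sequence=_mutate_sequence(sequences[q], identity, rng),
                    lineage=_hit_lineage(tm, rng, f_idx),
                    terms=foreign_terms[f_idx],
                )
            )
    return hits


# ---------------------------------------------------------------------------
# evaluation against masked truth
# ---------------------------------------------------------------------------

@dataclass
class TruthEvaluation:
    fdr: float | None  # None when no predictions were made
    recall: float  # over masked true terms at depth >= 2
    n_predictions: int
    n_false: int
    per_depth: pd.DataFrame  # depth, n_true, n_recovered, n_predicted, n_false


def evaluate_against_truth(
    predicted: AnnotationStore,
    truth: GroundTruth,
    depths: Mapping[str, int],
) -> TruthEvaluation:
    """Realized FDR and recall of predictions for the masked proteins.

    A prediction is false when the term is absent from the protein's closed
    true set; recall counts recovered true terms of depth >= 2.
    """
    n_pred = n_false = n_true = n_recovered = 0
    per_depth: dict[int, list[int]] = {}
    for p in sorted(truth.masked_proteins):
        true_set = truth.full_store.terms_of(p)
        pred_set = predicted.terms_of(p)
        for t in pred_set:
            d = depths[t]
            row = per_depth.setdefault(d, [0, 0, 0, 0])
            row[2] += 1
            n_pred += 1
            if t not in true_set:
                n_false += 1
                row[3] += 1
        for t in true_set:
            if depths[t] < 2:
                continue
            row = per_depth.setdefault(depths[t], [0, 0, 0, 0])
            row[0] += 1
            n_true += 1
            if t in pred_set:
                row[1] += 1
                n_recovered += 1
    table = pd.DataFrame(
        [
            {
                "depth": d,
                "n_true": v[0],
                "n_recovered": v[1],
                "n_predicted": v[2],
                "n_false": v[3],
            }
            for d, v in sorted(per_depth.items())
        ],
        columns=["depth", "n_true", "n_recovered", "n_predicted", "n_false"],
    )
    return TruthEvaluation(
        fdr=(n_false / n_pred) if n_pred else None,
        recall=(n_recovered / n_true) if n_true else 0.0,
        n_predictions=n_pred,
        n_false=n_false,
        per_depth=table,
    )


# ---------------------------------------------------------------------------
# term-count simulation (for the enrichment models)
# ---------------------------------------------------------------------------

def make_term_counts(
    n_terms: int,
    n_puf: int,
    n_pkf: int,
    planted_or: float,
    seed: int,
    depth_range: tuple[int, int] = (2, 8),
    base_rate_range: tuple[float, float] = (0.1, 0.5),
) -> pd.DataFrame:
    """Simulate a term-count table with a known planted odds ratio.

    PKF frequencies are drawn per term; PUF counts are binomial with odds
    multiplied by *planted_or*. Used for parameter-recovery checks of the
    enrichment models.
    """
    rng = np.random.default_rng(seed)
    p_pkf = rng.uniform(*base_rate_range, size=n_terms)
    odds = p_pkf / (1 - p_pkf) * planted_or
    p_puf = odds / (1 + odds)
    return pd.DataFrame(
        {
            "term_id": [f"GO:{i + 1:07d}" for i in range(n_terms)],
            "k_puf": rng.binomial(n_puf, p_puf),
            "n_puf": n_puf,
            "k_pkf": rng.binomial(n_pkf, p_pkf),
            "n_pkf": n_pkf,
            "depth": rng.integers(depth_range[0], depth_range[1] + 1, n_terms),
        }
    )


# ---------------------------------------------------------------------------
# top-level generation & serialization
# ---------------------------------------------------------------------------

def generate(config: SyntheticConfig) -> SyntheticData:
    """Generate the full synthetic dataset in memory (deterministic under
    ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    obo_text, plan = make_ontology(config, rng)
    graph = onto.load_ontology(obo_text)
    depths = onto.term_depth(graph)
    proteins, source_tables, truth = make_proteome(config, graph, plan, rng)
    known_store = onto.merge_annotation_sources(source_tables, graph)
    channels = make_similarity_channels(
        config, proteins, truth, plan, depths, rng
    )
    (
        feature_matrix,
        bitscore_table,
        operon_table,
        tree_distance_table,
        orthogroups,
        experiments,
        tm_table,
        string_table,
    ) = channels
    structures, sequences = make_structures(config, proteins, rng)
    pkfs = [
        p
        for p in proteins
        if onto.classify_puf(graph, depths, known_store.terms_of(p)) == "PKF"
    ]
    structure_hits = make_structure_hits(
        config, proteins, sequences, truth, plan, pkfs, rng
    )
    return SyntheticData(
        config=config,
        obo_text=obo_text,
        graph=graph,
        depths=depths,
        plan=plan,
        proteins=proteins,
        source_tables=source_tables,
        known_store=known_store,
        truth=truth,
        feature_matrix=feature_matrix,
        bitscore_table=bitscore_table,
        operon_table=operon_table,
        tree_distance_table=tree_distance_table,
        orthogroups=orthogroups,
        experiments=experiments,
        tm_table=tm_table,
        string_table=string_table,
        structures=structures,
        sequences=sequences,
        structure_hits=structure_hits,
    )


def _write_pdb(model: ResidueConfidenceModel, seq: str, path: Path) -> None:
    """Minimal CA-trace PDB with pLDDT in the B-factor column."""
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }
    lines = []
    for i, plddt in enumerate(model.plddt, start=1):
        res = three.get(seq[i - 1], "GLY") if i - 1 < len(seq) else "GLY"
        x = 3.8 * i
        lines.append(
            f"ATOM  {i:5d}  CA  {res} A{i:4d}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{plddt:6.2f}           C"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_dataset(data: SyntheticData, outdir: str | Path) -> dict:
    """Write every pipeline input to *outdir* in its standard text format;
    the evaluator-only truth goes under ``truth/``. Returns the manifest
    (config + per-file SHA-256) that is also written as ``manifest.json``."""
    import hashlib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "structures").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    (outdir / "ontology.obo").write_text(data.obo_text)
    for name, table in sorted(data.source_tables.items()):
        table.to_csv(outdir / f"annotations_{name}.tsv", sep="\t", index=False)
    data.feature_matrix.reset_index(names="protein_id").melt(
        id_vars="protein_id", var_name="feature_id", value_name="present"
    ).query("present > 0").drop(columns="present").sort_values(
        ["protein_id", "feature_id"]
    ).to_csv(outdir / "feature_matrix.tsv", sep="\t", index=False)
    for name in ("bitscore", "operon", "tree_distance"):
        getattr(data, f"{name}_table").to_csv(
            outdir / f"{name}.tsv", sep="\t", index=False
        )
    pd.DataFrame(
        [
            {"protein_id": p, "species": ",".join(sorted(s))}
            for p, s in sorted(data.orthogroups.items())
        ]
    ).to_csv(outdir / "orthogroups.tsv", sep="\t", index=False)
    for exp in data.experiments:
        exp.intensities.to_csv(outdir / f"quant_{exp.experiment_id}.csv")
        pd.DataFrame(
            sorted(exp.sample_condition.items()), columns=["sample", "condition"]
        ).to_csv(outdir / f"samples_{exp.experiment_id}.tsv", sep="\t", index=False)
    data.tm_table.to_csv(outdir / "tm_scores.tsv", sep="\t", index=False)
    data.string_table.to_csv(outdir / "string_links.tsv", sep="\t", index=False)
    for p in sorted(data.structures):
        _write_pdb(data.structures[p], data.sequences[p], outdir / "structures" / f"{p}.pdb")
    with open(outdir / "queries.fasta", "w") as fh:
        for p in sorted(data.sequences):
            fh.write(f">{p}\n{data.sequences[p]}\n")
    from .structural_arm import write_structure_hits

    write_structure_hits(data.structure_hits, outdir / "structure_hits.tsv")
    data.truth.full_store.write_tsv(outdir / "truth" / "full_annotations.tsv")
    (outdir / "truth" / "masked_proteins.txt").write_text(
        "\n".join(sorted(data.truth.masked_proteins)) + "\n"
    )

    manifest = {"config": asdict(data.config), "files": {}}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest["files"][str(path.relative_to(outdir))] = digest
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
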