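"""Gene Ontology handling: DAG parsing, depths, closures, and annotation stores.

The ontology is a directed acyclic graph of terms with child->parent edges
(``is_a`` and, by default, ``part_of``), one root per namespace. Term *depth*
is the number of edges on the longest path from the namespace root down to the
term; the three namespaces are treated equivalently, each root at depth 0.

A protein is a PUF (protein of unknown function) when its annotation reaches
no deeper than depth 1 — i.e. it is unannotated or carries only uninformative
near-root terms. Everything else is a PKF (protein of known function).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from io import StringIO
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: Annotation depth below which a protein counts as a PUF.
PUF_DEPTH_CUTOFF = 2


class OntologyGraph:
    """GO DAG with child->parent edges and per-namespace roots.

    Parameters
    ----------
    digraph:
        ``networkx.DiGraph`` whose edges point from child term to parent term.
        Every node must carry a ``namespace`` attribute.
    """

    def __init__(self, digraph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(digraph):
            cycle = nx.find_cycle(digraph)
            raise ValueError(f"ontology contains a cycle through {cycle[0][0]!r}")
        self.graph = digraph
        self.roots: dict[str, str] = {}
        for node, data in digraph.nodes(data=True):
            if digraph.out_degree(node) == 0:
                ns = data.get("namespace")
                if ns in self.roots:
                    raise ValueError(f"namespace {ns!r} has multiple roots")
                self.roots[ns] = node
        for child, parent in digraph.edges():
            ns_c = digraph.nodes[child].get("namespace")
            ns_p = digraph.nodes[parent].get("namespace")
            if ns_c != ns_p:
                raise ValueError(
                    f"edge {child!r}->{parent!r} crosses namespaces {ns_c!r}/{ns_p!r}"
                )
        # every non-root term must reach its namespace root
        for node in digraph.nodes():
            ns = digraph.nodes[node].get("namespace")
            if node == self.roots.get(ns):
                continue
            if digraph.out_degree(node) == 0:
                raise ValueError(f"term {node!r} has no parents and is not a root")
        self._depths: dict[str, int] | None = None
        self._ancestors: dict[str, frozenset[str]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes())

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term]["namespace"]

    def parents(self, term: str) -> list[str]:
        return list(self.graph.successors(term))


def load_ontology(
    obo_source, *, include_part_of: bool = True
) -> OntologyGraph:
    """Parse an OBO 1.2 stream/path into an :class:`OntologyGraph`.

    Obsolete terms are excluded. ``is_a`` edges are always retained;
    ``part_of`` relationship edges are retained when *include_part_of* is
    true. Unknown parent references and cycles are hard errors.
    """
    if isinstance(obo_source, str) and "\n" in obo_source:
        obo_source = StringIO(obo_source)
    multi = obonet.read_obo(obo_source, ignore_obsolete=True)
    keep = {"is_a"}
    if include_part_of:
        keep.add("part_of")
    dag = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        dag.add_node(node, namespace=data.get("namespace"), name=data.get("name"))
    for child, parent, key in multi.edges(keys=True):
        if key not in keep:
            continue
        if parent not in multi.nodes or not multi.nodes[parent]:
            raise ValueError(f"term {child!r} references unknown parent {parent!r}")
        dag.add_edge(child, parent)
    # drop nodes created solely by excluded relationship targets
    dag.remove_nodes_from([n for n in dag.nodes if n not in multi.nodes])
    return OntologyGraph(dag)


def term_depth(graph: OntologyGraph) -> dict[str, int]:
    """Longest-path depth from the namespace root for every term (memoized).

    Roots have depth 0; ``depth(child) = 1 + max(depth(parent))`` over all
    parents, i.e. the number of steps on the longest root->term path.
    """
    if graph._depths is not None:
        return graph._depths
    depths: dict[str, int] = {}
    # child->parent edges: process parents before children (reverse topo order)
    for node in reversed(list(nx.topological_sort(graph.graph))):
        parents = list(graph.graph.successors(node))
        depths[node] = 0 if not parents else 1 + max(depths[p] for p in parents)
    graph._depths = depths
    return depths


def ancestral_closure(graph: OntologyGraph, terms: Iterable[str]) -> frozenset[str]:
    """Close a term set under the parent relation ("true path" propagation).

    Returns the input terms plus every ancestor reachable through the
    retained edges. Idempotent; raises ``KeyError`` on unknown terms.
    """
    out: set[str] = set()
    for term in terms:
        if term not in graph.graph:
            raise KeyError(f"unknown ontology term {term!r}")
        cached = graph._ancestors.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(graph.graph, term)) | {term}
            graph._ancestors[term] = cached
        out |= cached
    return frozenset(out)


def deepest_shared_depth(
    graph: OntologyGraph,
    annots_a: Iterable[str],
    annots_b: Iterable[str],
    *,
    depths: Mapping[str, int] | None = None,
) -> int:
    """Depth of the deepest term shared by two (closure-applied) term sets.

    The sets are ancestor-closed internally; the result is the maximum depth
    over their intersection, 0 when they share only roots or when either set
    is empty. Symmetric in its arguments.
    """
    set_a = set(annots_a)
    set_b = set(annots_b)
    if not set_a or not set_b:
        return 0
    if depths is None:
        depths = term_depth(graph)
    shared = ancestral_closure(graph, set_a) & ancestral_closure(graph, set_b)
    if not shared:
        return 0
    return max(depths[t] for t in shared)


def classify_puf(
    graph: OntologyGraph,
    depths: Mapping[str, int],
    protein_terms: Iterable[str],
) -> str:
    """Classify a protein as ``"PUF"`` or ``"PKF"`` from its term set.

    PUF iff the protein has no terms, or the maximum depth of its terms is
    below :data:`PUF_DEPTH_CUTOFF`. Closure cannot raise the maximum depth,
    so the call is invariant to closing the set first.
    """
    terms = list(protein_terms)
    if not terms:
        return "PUF"
    max_depth = max(depths[t] for t in terms)
    return "PUF" if max_depth < PUF_DEPTH_CUTOFF else "PKF"


class AnnotationStore:
    """Protein -> GO term assignments with source provenance and scores.

    Internally ``protein -> term -> set of source labels`` plus an optional
    score per (protein, term, source). ``via_closure`` provenance is recorded
    for assignments added by ancestor closure.
    """

    def __init__(self) -> None:
        self._data: dict[str, dict[str, set[str]]] = {}
        self._scores: dict[tuple[str, str, str], float] = {}

    # -- construction -------------------------------------------------
    def add(
        self, protein: str, term: str, source: str, score: float | None = None
    ) -> None:
        self._data.setdefault(protein, {}).setdefault(term, set()).add(source)
        if score is not None:
            self._scores[(protein, term, source)] = float(score)

    # -- access -------------------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return list(self._data.keys())

    def terms_of(self, protein: str) -> frozenset[str]:
        return frozenset(self._data.get(protein, {}))

    def sources_of(self, protein: str, term: str) -> frozenset[str]:
        return frozenset(self._data.get(protein, {}).get(term, ()))

    def score_of(self, protein: str, term: str, source: str) -> float | None:
        return self._scores.get((protein, term, source))

    def assignments(self):
        """Yield (protein, term, source, score-or-None) tuples."""
        for protein, terms in self._data.items():
            for term, sources in terms.items():
                for source in sorted(sources):
                    yield protein, term, source, self._scores.get(
                        (protein, term, source)
                    )

    def n_assignments(self) -> int:
        return sum(len(terms) for terms in self._data.values())

    # -- transforms ---------------------------------------------------
    def closed(self, graph: OntologyGraph) -> "AnnotationStore":
        """Return a copy closed under the ancestor relation."""
        out = AnnotationStore()
        for protein, terms in self._data.items():
            closure = ancestral_closure(graph, terms) if terms else frozenset()
            for term in closure:
                if term in terms:
                    for source in terms[term]:
                        score = self._scores.get((protein, term, source))
                        out.add(protein, term, source, score)
                else:
                    out.add(protein, term, "via_closure")
            if not terms:
                out._data.setdefault(protein, {})
        return out

    def union(self, other: "AnnotationStore") -> "AnnotationStore":
        out = AnnotationStore()
        for store in (self, other):
            for protein, term, source, score in store.assignments():
                out.add(protein, term, source, score)
            for protein in store.proteins:
                out._data.setdefault(protein, {})
        return out

    # -- serialization ------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein_id": p, "term_id": t, "source": s, "score": sc}
            for p, t, s, sc in self.assignments()
        ]
        return pd.DataFrame(
            rows, columns=["protein_id", "term_id", "source", "score"]
        ).sort_values(["protein_id", "term_id", "source"], ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AnnotationStore":
        store = cls()
        has_score = "score" in frame.columns
        for row in frame.itertuples(index=False):
            score = getattr(row, "score", None) if has_score else None
            if score is not None and pd.isna(score):
                score = None
            store.add(row.protein_id, row.term_id, getattr(row, "source", "?"), score)
        return store

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AnnotationStore":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def merge_annotation_sources(
    source_tables: Mapping[str, pd.DataFrame],
    graph: OntologyGraph,
    *,
    netgo_cutoff: float = 0.9,
) -> AnnotationStore:
    """Merge per-source annotation tables into one closed store.

    Score-bearing assignments are kept only when score > *netgo_cutoff*
    (strict). Assignments to terms absent from the ontology are dropped with
    a warning. The union across sources keeps per-source provenance; the
    result is ancestor-closed.
    """
    store = AnnotationStore()
    for source, table in source_tables.items():
        has_score = "score" in table.columns
        for row in table.itertuples(index=False):
            term = row.term_id
            if term not in graph:
                logger.warning(
                    "dropping %s->%s from %s: term not in ontology",
                    row.protein_id, term, source,
                )
                continue
            score = getattr(row, "score", None) if has_score else None
            if score is not None and pd.isna(score):
                score = None
            if score is not None and score <= netgo_cutoff:
                continue
            store.add(row.protein_id, term, source, score)
    return store.closed(graph)
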