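"""Binary-partition modularity of the hit network.

The functional coherence of a protein set S is measured as the generalized
(Newman) modularity of the two-way partition {S, complement} of the
unweighted hit network:

    Q = sum_c [ e_c / m  -  gamma * (d_c / 2m)^2 ]

with e_c the intra-set edge count, d_c the total degree of the set, m the
network's edge count, and gamma the resolution (default 0.81). The PUF set
is compared against size-matched uniformly random node sets and against
partitions defined by GO terms annotated to many proteins.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import networkx as nx
import numpy as np
from networkx.algorithms.community import modularity as _nx_modularity

from .ontology import AnnotationStore

DEFAULT_RESOLUTION = 0.81


def modularity(
    network: nx.Graph,
    node_set: Iterable,
    resolution: float = DEFAULT_RESOLUTION,
) -> float:
    """Generalized modularity of the binary partition {S, V \\ S}.

    *node_set* must be a non-empty proper subset of the network's nodes;
    the score is symmetric under swapping the set with its complement.
    Raises on an edgeless network (modularity undefined).
    """
    if network.number_of_edges() == 0:
        raise ValueError("modularity undefined on an edgeless network")
    s = set(node_set)
    nodes = set(network.nodes())
    if not s or not s <= nodes or s == nodes:
        raise ValueError("node set must be a non-empty proper subset of nodes")
    return float(
        _nx_modularity(network, [s, nodes - s], resolution=resolution)
    )


def random_partition_null(
    network: nx.Graph,
    size: int,
    n_reps: int = 1000,
    seed: int = 0,
    resolution: float = DEFAULT_RESOLUTION,
) -> np.ndarray:
    """Null modularity distribution over uniform node subsets of *size*.

    Subsets are drawn without replacement within each draw; seeded and
    reproducible. Raises if *size* is not smaller than the node count.
    """
    nodes = sorted(network.nodes())
    if size >= len(nodes):
        raise ValueError("partition size must be below the node count")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for k in range(n_reps):
        idx = rng.choice(len(nodes), size=size, replace=False)
        out[k] = modularity(network, (nodes[i] for i in idx), resolution)
    return out


def term_partitions(
    network: nx.Graph,
    annotations: AnnotationStore,
    min_proteins: int = 400,
    resolution: float = DEFAULT_RESOLUTION,
) -> dict[str, float]:
    """Modularity of the partition defined by each well-annotated GO term.

    A term qualifies when strictly more than *min_proteins* network nodes
    carry it (counted within the network; *annotations* must be closed).
    Terms annotating every node are skipped (no proper partition exists).
    """
    nodes = set(network.nodes())
    term_counts: dict[str, set] = {}
    for protein in annotations.proteins:
        if protein not in nodes:
            continue
        for term in annotations.terms_of(protein):
            term_counts.setdefault(term, set()).add(protein)
    out = {}
    for term, members in sorted(term_counts.items()):
        if len(members) > min_proteins and len(members) < len(nodes):
            out[term] = modularity(network, members, resolution)
    return out


def modularity_table(
    labeled_sets: Mapping[str, Iterable],
    network: nx.Graph,
    resolution: float = DEFAULT_RESOLUTION,
):
    """Convenience: (label, size, Q) rows for a set of named partitions."""
    import pandas as pd

    rows = []
    for label, node_set in labeled_sets.items():
        s = set(node_set)
        rows.append(
            {
                "label": label,
                "size": len(s),
                "Q": modularity(network, s, resolution),
            }
        )
    return pd.DataFrame(rows, columns=["label", "size", "Q"])
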