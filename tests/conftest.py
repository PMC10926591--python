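import numpy as np
import pytest

from pufannot import ontology as onto
from pufannot import synthetic_data as sd

DIAMOND_OBO = """\
format-version: 1.2
ontology: test-go

[Term]
id: GO:0000001
name: bp root
namespace: biological_process

[Term]
id: GO:0000002
name: X
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: Y
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000004
name: W
namespace: biological_process
is_a: GO:0000003

[Term]
id: GO:0000005
name: Z
namespace: biological_process
is_a: GO:0000002
is_a: GO:0000004

[Term]
id: GO:0000010
name: mf root
namespace: molecular_function

[Term]
id: GO:0000011
name: chain 1
namespace: molecular_function
is_a: GO:0000010

[Term]
id: GO:0000012
name: chain 2
namespace: molecular_function
is_a: GO:0000011

[Term]
id: GO:0000013
name: chain 3
namespace: molecular_function
is_a: GO:0000012

[Term]
id: GO:0000014
name: chain 4
namespace: molecular_function
is_a: GO:0000013

[Term]
id: GO:0000015
name: chain 5
namespace: molecular_function
is_a: GO:0000014

[Term]
id: GO:0000016
name: chain 6
namespace: molecular_function
is_a: GO:0000015

[Term]
id: GO:0000017
name: chain 7
namespace: molecular_function
is_a: GO:0000016

[Term]
id: GO:0000099
name: gone
namespace: biological_process
is_obsolete: true
"""

ROOT, X, Y, W, Z = (
    "GO:0000001",
    "GO:0000002",
    "GO:0000003",
    "GO:0000004",
    "GO:0000005",
)
CHAIN = [f"GO:00000{i}" for i in range(10, 18)]
OBSOLETE = "GO:0000099"


@pytest.fixture(scope="session")
def diamond_graph():
    return onto.load_ontology(DIAMOND_OBO)


@pytest.fixture(scope="session")
def diamond_depths(diamond_graph):
    return onto.term_depth(diamond_graph)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale generator configuration for unit tests."""
    return sd.SyntheticConfig(
        seed=7, n_terms=100, n_proteins=60, n_families=4, n_foreign=40
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return sd.generate(small_config)


def random_dag(rng: np.random.Generator, n_terms: int):
    """Random single-namespace DAG (child->parent edge dict) for oracles."""
    parents = {0: []}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(i, 2) + 1))
        choices = rng.choice(i, size=k, replace=False)
        parents[i] = sorted(int(c) for c in choices)
    return parents


def dag_to_obo(parents) -> str:
    lines = ["format-version: 1.2", "ontology: random-test", ""]
    for node, ps in parents.items():
        lines.append("[Term]")
        lines.append(f"id: GO:{node + 1:07d}")
        lines.append(f"name: node {node}")
        lines.append("namespace: biological_process")
        for p in ps:
            lines.append(f"is_a: GO:{p + 1:07d}")
        lines.append("")
    return "\n".join(lines)
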