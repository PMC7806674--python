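"""Shared fixtures: hand-built ontologies, random DAGs, and a synthetic world."""

from __future__ import annotations

import io

import numpy as np
import pytest

import gotransfer as gt
from gotransfer.ontology import GoTerm, Ontology

BPO_ROOT = "GO:0008150"

# Diamond: A is_a B, A part_of C, B is_a root, C is_a root; X is obsolete.
DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:9000002
name: B
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:9000003
name: C
namespace: biological_process
alt_id: GO:9000033
is_a: GO:0008150 ! biological_process

[Term]
id: GO:9000001
name: A
namespace: biological_process
is_a: GO:9000002 ! B
relationship: part_of GO:9000003 ! C

[Term]
id: GO:9000009
name: X
namespace: biological_process
is_obsolete: true
"""

A, B, C = "GO:9000001", "GO:9000002", "GO:9000003"
OBSOLETE = "GO:9000009"


@pytest.fixture
def diamond_ontology() -> Ontology:
    return gt.parse_obo(io.StringIO(DIAMOND_OBO), dialect="obo")


@pytest.fixture(scope="session")
def fixture_spec() -> gt.FixtureSpec:
    return gt.FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def fixture_world(fixture_spec):
    """Default synthetic world: ontology, database, queries, truth."""
    ont = gt.make_ontology(fixture_spec)
    db = gt.make_database(fixture_spec, ont)
    queries, truth, families = gt.make_queries(fixture_spec, ont, db)
    return ont, db, queries, truth, families


def random_dag_terms(rng: np.random.Generator, n_nodes: int) -> list[GoTerm]:
    """A random single-namespace DAG rooted at the BPO root.

    Node i > 0 gets 1-3 parents among nodes 0..i-1, so every node reaches
    the root and the edge relation is acyclic by construction.
    """
    ids = [BPO_ROOT] + [f"GO:{9100000 + i:07d}" for i in range(1, n_nodes)]
    terms = [GoTerm(id=BPO_ROOT, namespace="BPO")]
    for i in range(1, n_nodes):
        n_parents = int(rng.integers(1, min(i, 3) + 1))
        parent_idx = rng.choice(i, size=n_parents, replace=False)
        parents = frozenset(
            (ids[j], "is_a" if rng.random() < 0.8 else "part_of")
            for j in parent_idx
        )
        terms.append(GoTerm(id=ids[i], namespace="BPO", parents=parents))
    return terms


def reachability_oracle(terms: list[GoTerm], start: str) -> frozenset[str]:
    """Brute-force ancestor closure by repeated edge expansion."""
    parents = {t.id: {p for p, rel in t.parents if rel in ("is_a", "part_of")}
               for t in terms}
    reached: set[str] = set()
    frontier = set(parents[start])
    while frontier:
        reached |= frontier
        frontier = set().union(*(parents[x] for x in frontier)) - reached
    return frozenset(reached)
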