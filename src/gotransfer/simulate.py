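"""Synthetic test worlds: toy ontologies, function families, clustered embeddings.

The generator builds a self-contained stand-in for a real lookup database
plus benchmark: per namespace a rooted DAG of GO-style terms, a set of
"function families" each owning a distinct leaf-term set, and per-family
Gaussian clusters of protein embeddings.  The single difficulty knob is the
ratio of inter-family mean separation ``s`` to within-family spread ``σ``:
family means sit on mutually orthogonal directions scaled so every pair of
means is exactly ``s`` apart, so at ``s ≫ σ`` nearest-neighbor retrieval
recovers the family almost surely while at ``s = 0`` it is at chance.
Label noise reassigns a fraction of database proteins the term set of a
*different* family (whole-set swaps, mimicking transfer from a wrong
homolog) while leaving their embeddings in place.

Everything is deterministic in the spec's seed; queries draw from an
independent seed stream so they never collide with database proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .annotations import AnnotationSet, propagate_annotations
from .embeddings import EmbeddingStore
from .errors import ConfigError
from .ontology import NAMESPACE_ROOTS, GoTerm, Ontology

__all__ = [
    "FixtureSpec",
    "SyntheticDatabase",
    "make_ontology",
    "make_database",
    "make_queries",
    "make_residue_matrices",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic world.

    Defaults give 3 namespaces × 40 terms (depth-3, branching-3 trees plus
    diamonds), 6 families × 20 proteins in D = 32 with σ = 1 and mean
    separation s = 10 — small enough for sub-second tests yet hard enough
    that transfer quality responds to the s/σ knob.
    """

    seed: int = 0
    namespaces: tuple[str, ...] = ("BPO", "MFO", "CCO")
    depth: int = 3
    branching: int = 3
    diamond_fraction: float = 0.15
    n_families: int = 6
    leaves_per_family: int = 2
    proteins_per_family: int = 20
    dim: int = 32
    sigma: float = 1.0
    separation: float = 10.0
    queries_per_family: int = 10
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigError("sigma must be > 0")
        if self.separation < 0:
            raise ConfigError("separation must be >= 0")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ConfigError("noise_rate must be in [0, 1]")
        for name in ("depth", "branching", "n_families", "leaves_per_family",
                     "proteins_per_family", "dim", "queries_per_family"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_families > self.dim:
            raise ConfigError("need n_families <= dim for orthogonal cluster means")
        unknown = set(self.namespaces) - set(NAMESPACE_ROOTS)
        if unknown:
            raise ConfigError(f"unknown namespaces {sorted(unknown)}")


@dataclass
class SyntheticDatabase:
    """A generated lookup world: embeddings, annotations, family structure."""

    store: EmbeddingStore
    annotations: AnnotationSet  # propagated, root-free
    families: dict[str, int]  # protein id -> true family index
    family_terms: dict[int, dict[str, frozenset[str]]]  # family -> ns -> leaf set
    means: np.ndarray  # (n_families, dim) cluster means


def _term_id(namespace_index: int, counter: int) -> str:
    # Synthetic accessions: 7 digits, namespace-banded, clear of real roots.
    return f"GO:{9000000 + namespace_index * 100000 + counter:07d}"


def make_ontology(spec: FixtureSpec) -> Ontology:
    """Rooted per-namespace DAGs: a (depth, branching) tree plus diamond edges.

    Diamond edges add a second parent from a strictly shallower level, which
    keeps the graph acyclic by construction.  Deterministic in the seed.
    """
    rng = np.random.default_rng([spec.seed, 0xD1A])
    terms: list[GoTerm] = []
    for ns_i, ns in enumerate(spec.namespaces):
        root = NAMESPACE_ROOTS[ns]
        terms.append(GoTerm(id=root, namespace=ns))
        levels: list[list[str]] = [[root]]
        counter = 0
        for _ in range(spec.depth):
            level: list[str] = []
            for parent in levels[-1]:
                for _ in range(spec.branching):
                    counter += 1
                    child = _term_id(ns_i, counter)
                    relation = "part_of" if rng.random() < 0.2 else "is_a"
                    parents = {(parent, relation)}
                    level.append(child)
                    terms.append(GoTerm(id=child, namespace=ns, parents=frozenset(parents)))
            levels.append(level)
        # add diamond (second-parent) edges to a fraction of deep nodes
        by_id = {t.id: t for t in terms}
        for depth_i in range(2, len(levels)):
            for node in levels[depth_i]:
                if rng.random() >= spec.diamond_fraction:
                    continue
                shallow_level = levels[int(rng.integers(1, depth_i))]
                extra = shallow_level[int(rng.integers(len(shallow_level)))]
                term = by_id[node]
                if any(p == extra for p, _ in term.parents):
                    continue
                by_id[node] = replace(
                    term, parents=term.parents | {(extra, "is_a")}
                )
        terms = [by_id.get(t.id, t) for t in terms]
    return Ontology(terms)


def _tree_leaves(ont: Ontology, namespace: str) -> list[str]:
    has_child: set[str] = set()
    for tid in ont.terms:
        has_child.update(ont.parents(tid))
    return sorted(
        t for t in ont.terms
        if ont.terms[t].namespace == namespace and t not in has_child
        and t not in NAMESPACE_ROOTS.values()
    )


def _family_means(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """Cluster means on random orthonormal directions, pairwise ``s`` apart."""
    gauss = rng.normal(size=(spec.dim, spec.dim))
    q, _ = np.linalg.qr(gauss)
    directions = q[:, : spec.n_families].T  # orthonormal rows
    return directions * (spec.separation / np.sqrt(2.0))


def _assign_family_terms(
    spec: FixtureSpec, ont: Ontology, rng: np.random.Generator
) -> dict[int, dict[str, frozenset[str]]]:
    family_terms: dict[int, dict[str, frozenset[str]]] = {
        f: {} for f in range(spec.n_families)
    }
    for ns in spec.namespaces:
        leaves = _tree_leaves(ont, ns)
        needed = spec.n_families * spec.leaves_per_family
        if len(leaves) < needed:
            raise ConfigError(
                f"{ns}: {len(leaves)} leaves < {needed} needed for distinct families"
            )
        order = rng.permutation(len(leaves))
        for f in range(spec.n_families):
            picked = order[f * spec.leaves_per_family : (f + 1) * spec.leaves_per_family]
            family_terms[f][ns] = frozenset(leaves[i] for i in picked)
    return family_terms


def _annotate(
    protein: str,
    family: int,
    family_terms: Mapping[int, Mapping[str, frozenset[str]]],
    ann: AnnotationSet,
) -> None:
    for ns, leaf_set in family_terms[family].items():
        for term in leaf_set:
            ann.add(protein, ns, term, "IDA")


def make_database(spec: FixtureSpec, ont: Ontology) -> SyntheticDatabase:
    """Generate the lookup store, its propagated annotations, and family map."""
    rng = np.random.default_rng([spec.seed, 0xDB])
    means = _family_means(spec, rng)
    family_terms = _assign_family_terms(spec, ont, rng)
    store = EmbeddingStore()
    raw = AnnotationSet()
    families: dict[str, int] = {}
    for f in range(spec.n_families):
        for i in range(spec.proteins_per_family):
            pid = f"P{f:02d}_{i:03d}"
            store.add(pid, means[f] + spec.sigma * rng.normal(size=spec.dim))
            families[pid] = f
            label_family = f
            if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
                others = [g for g in range(spec.n_families) if g != f]
                label_family = int(others[int(rng.integers(len(others)))])
            _annotate(pid, label_family, family_terms, raw)
    ann = propagate_annotations(raw, ont)
    return SyntheticDatabase(store, ann, families, family_terms, means)


def make_queries(
    spec: FixtureSpec, ont: Ontology, database: SyntheticDatabase
) -> tuple[EmbeddingStore, AnnotationSet, dict[str, int]]:
    """Queries from the same clusters (fresh seed stream) plus their truth.

    Truth annotations are the query's *true* family term sets (no label
    noise), propagated and root-free; query ids never collide with database
    ids.
    """
    rng = np.random.default_rng([spec.seed, 0x0E5])
    store = EmbeddingStore()
    raw = AnnotationSet()
    families: dict[str, int] = {}
    for f in range(spec.n_families):
        for i in range(spec.queries_per_family):
            qid = f"Q{f:02d}_{i:03d}"
            store.add(qid, database.means[f] + spec.sigma * rng.normal(size=spec.dim))
            families[qid] = f
            _annotate(qid, f, database.family_terms, raw)
    truth = propagate_annotations(raw, ont)
    return store, truth, families


@dataclass(frozen=True)
class ResidueFixture:
    """An L×D per-residue matrix with column means/maxima known by construction."""

    protein_id: str
    matrix: np.ndarray
    column_means: np.ndarray
    column_maxima: np.ndarray


def make_residue_matrices(
    spec: FixtureSpec, count: int = 5, min_length: int = 2, max_length: int = 12
) -> list[ResidueFixture]:
    """Per-residue matrices built from (v, −v) row pairs plus a planted top row.

    The paired rows contribute zero to every column mean; the planted row
    strictly dominates every column, so means and maxima are known without
    running any pooling code.
    """
    rng = np.random.default_rng([spec.seed, 0xAA])
    out: list[ResidueFixture] = []
    for i in range(count):
        pairs = int(rng.integers(min_length, max_length + 1))
        base = rng.normal(size=(pairs, spec.dim))
        planted = np.abs(base).max(axis=0) + rng.uniform(0.5, 1.5, size=spec.dim)
        matrix = np.vstack([base, -base, planted[None, :]])
        matrix = matrix[rng.permutation(matrix.shape[0])]
        length = 2 * pairs + 1
        out.append(
            ResidueFixture(
                protein_id=f"R{i:02d}",
                matrix=matrix,
                column_means=planted / length,
                column_maxima=planted,
            )
        )
    return out
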