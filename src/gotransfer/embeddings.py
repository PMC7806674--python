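"""Fixed-size protein embeddings: storage, residue pooling, distance metrics.

A protein language model turns a sequence of length L into an L×D matrix of
per-residue representations; pooling over the length dimension (mean, or
componentwise maximum) yields a fixed D-dimensional vector per protein
(D = 1024 for the models the method was developed with, but nothing here
depends on a particular D).  The embedding computation itself is external —
this module only stores vectors, pools matrices, and computes the two
distances used for neighbor search:

* Euclidean:  d(n, m) = sqrt(Σ_i (n_i − m_i)²)
* cosine:     d(n, m) = 1 − (n·m)/(‖n‖‖m‖)

All arithmetic accumulates in double precision regardless of how vectors
were stored on disk.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

import h5py
import numpy as np
from scipy.spatial.distance import cdist

from .errors import ValidationError

METRICS = ("euclidean", "cosine")


class EmbeddingStore:
    """Keyed collection of equal-length float vectors, one per protein id.

    Iteration and :attr:`ids` follow sorted id order, which makes every
    downstream computation deterministic regardless of insertion order.
    """

    def __init__(self, vectors: Mapping[str, np.ndarray] | None = None) -> None:
        self._vectors: dict[str, np.ndarray] = {}
        self.dim: int | None = None
        if vectors:
            for pid, vec in vectors.items():
                self.add(pid, vec)

    def add(self, protein_id: str, vector: Iterable[float]) -> None:
        if protein_id in self._vectors:
            raise ValidationError(f"duplicate embedding id {protein_id!r}")
        vec = np.asarray(vector, dtype=np.float64)
        if vec.ndim != 1 or vec.size == 0:
            raise ValidationError(f"embedding for {protein_id!r} must be a 1-D vector")
        if not np.all(np.isfinite(vec)):
            raise ValidationError(f"non-finite values in embedding {protein_id!r}")
        if self.dim is None:
            self.dim = vec.size
        elif vec.size != self.dim:
            raise ValidationError(
                f"dimension mismatch for {protein_id!r}: {vec.size} != {self.dim}"
            )
        self._vectors[protein_id] = vec

    def __len__(self) -> int:
        return len(self._vectors)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._vectors

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __getitem__(self, protein_id: str) -> np.ndarray:
        return self._vectors[protein_id]

    @property
    def ids(self) -> list[str]:
        return sorted(self._vectors)

    def matrix(self, ids: Iterable[str] | None = None) -> np.ndarray:
        """Stacked (n, D) matrix in the given (default: sorted) id order."""
        order = self.ids if ids is None else list(ids)
        if not order:
            return np.empty((0, self.dim or 0))
        return np.stack([self._vectors[i] for i in order])

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        for pid in self.ids:
            yield pid, self._vectors[pid]


# -- persistence -----------------------------------------------------------


def read_store(path: str, dialect: str = "hdf5") -> EmbeddingStore:
    """Read a store: HDF5 (one dataset per id) or TSV (``id<TAB>v1,...,vD``)."""
    store = EmbeddingStore()
    if dialect == "hdf5":
        with h5py.File(path, "r") as fh:
            for pid in sorted(fh):
                store.add(pid, np.asarray(fh[pid], dtype=np.float64))
    elif dialect == "tsv":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                try:
                    pid, values = line.split("\t")
                    vec = np.array([float(v) for v in values.split(",")])
                except ValueError as exc:
                    raise ValidationError(f"line {lineno}: bad embedding row") from exc
                store.add(pid, vec)
    else:
        raise ValidationError(f"unknown embedding dialect {dialect!r} (expected hdf5|tsv)")
    return store


def write_store(store: EmbeddingStore, path: str, dialect: str = "hdf5") -> None:
    if dialect == "hdf5":
        with h5py.File(path, "w") as fh:
            for pid, vec in store.items():
                fh.create_dataset(pid, data=vec)
    elif dialect == "tsv":
        with open(path, "w") as fh:
            for pid, vec in store.items():
                fh.write(pid + "\t" + ",".join(repr(v) for v in vec.tolist()) + "\n")
    else:
        raise ValidationError(f"unknown embedding dialect {dialect!r} (expected hdf5|tsv)")


# -- pooling ---------------------------------------------------------------


def _check_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 1:
        raise ValidationError("per-residue embedding must be a non-empty L x D matrix")
    if not np.all(np.isfinite(m)):
        raise ValidationError("non-finite values in per-residue embedding")
    return m


def mean_pool(matrix: np.ndarray) -> np.ndarray:
    """Average an L×D per-residue matrix over the length dimension."""
    return _check_matrix(matrix).mean(axis=0)


def max_pool(matrix: np.ndarray) -> np.ndarray:
    """Componentwise maximum of an L×D per-residue matrix over residues."""
    return _check_matrix(matrix).max(axis=0)


# -- distances -------------------------------------------------------------


def _check_pair(n: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(n, dtype=np.float64)
    b = np.asarray(m, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return a, b


def euclidean(n: np.ndarray, m: np.ndarray) -> float:
    """Euclidean distance between two embeddings."""
    a, b = _check_pair(n, m)
    return float(np.sqrt(np.sum((a - b) ** 2)))


def cosine(n: np.ndarray, m: np.ndarray) -> float:
    """Cosine distance 1 − cos(n, m); undefined (error) for zero vectors."""
    a, b = _check_pair(n, m)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValidationError("cosine distance undefined for zero-norm vectors")
    return float(1.0 - np.dot(a, b) / (na * nb))


def pairwise_distances(
    queries: np.ndarray, targets: np.ndarray, metric: str = "euclidean"
) -> np.ndarray:
    """(n_queries, n_targets) distance matrix under the named metric."""
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r} (expected euclidean|cosine)")
    q = np.asarray(queries, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if metric == "cosine" and (
        np.any(np.linalg.norm(q, axis=1) == 0) or np.any(np.linalg.norm(t, axis=1) == 0)
    ):
        raise ValidationError("cosine distance undefined for zero-norm vectors")
    return cdist(q, t, metric=metric)
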