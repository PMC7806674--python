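"""Annotation transfer by embedding proximity — the core method.

For a query protein Q with embedding q, the k proteins of the lookup
database closest to q (Euclidean by default) are retrieved; when several
targets tie with the k-th distance, all of them are kept, so more than k
hits may be considered.  Every GO term annotated to any hit is transferred
to the query, scored with a reliability index

    RI(p) = (1/k) · Σ_{i=1..l} 0.5 / (0.5 + d(q, n_i))

where k is the number of neighbors requested, l the number of hits carrying
term p, and d the embedding distance.  A hit identical to the query (d = 0)
yields RI = 1; terms shared by more hits score higher.  Because tie
expansion can make the number of contributing hits exceed k, RI is clamped
to 1.0 (logged) to preserve its documented (0, 1] range.

Default k = 1 and per-namespace RI cut-offs 0.35 (BPO) / 0.28 (MFO) /
0.29 (CCO) follow the calibration of the method on the CAFA3 targets; the
cut-offs are meaningful only for Euclidean distances on the embedding scale
they were calibrated on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .annotations import AnnotationSet, TermFrequencies
from .embeddings import EmbeddingStore, pairwise_distances
from .errors import ValidationError
from .ontology import Ontology, ROOT_IDS

logger = logging.getLogger(__name__)

#: Two distances are tied when equal within this relative tolerance.
TIE_RTOL = 1e-9

#: Reliability-index cut-offs per namespace (Euclidean metric, k = 1).
DEFAULT_RI_THRESHOLDS: Mapping[str, float] = {"BPO": 0.35, "MFO": 0.28, "CCO": 0.29}


@dataclass(frozen=True)
class Hit:
    """One retrieved lookup protein: id, distance to the query, 1-based rank."""

    id: str
    distance: float
    rank: int


@dataclass(frozen=True, order=True)
class Prediction:
    """A transferred GO term for one query, scored by reliability index."""

    query: str
    namespace: str
    term: str
    ri: float


# -- nearest-neighbor search ----------------------------------------------


def nearest_neighbors(
    query: np.ndarray,
    store: EmbeddingStore,
    k: int = 1,
    metric: str = "euclidean",
    exclude: Iterable[str] = (),
    drop_zero_distance: bool = False,
) -> list[Hit]:
    """The k nearest lookup proteins, expanded to include distance ties.

    A single pass of distance evaluations over the store suffices (no
    index); candidates are ordered by (distance, id) so results are
    deterministic.  ``exclude`` removes ids (e.g. the query itself);
    ``drop_zero_distance`` additionally removes exact embedding matches,
    emulating lookup sets purged of identical sequences.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    excluded = set(exclude)
    ids = [i for i in store.ids if i not in excluded]
    if not ids:
        raise ValidationError("empty lookup store after exclusion")
    dists = pairwise_distances(
        np.asarray(query, dtype=np.float64)[None, :], store.matrix(ids), metric
    )[0]
    order = sorted(zip(dists.tolist(), ids))
    if drop_zero_distance:
        order = [(d, i) for d, i in order if not _tied(d, 0.0)]
        if not order:
            raise ValidationError("empty lookup store after dropping zero-distance hits")
    if k >= len(order):
        if k > len(order):
            logger.warning("k=%d exceeds store size %d; returning all", k, len(order))
        kept = order
    else:
        kth = order[k - 1][0]
        kept = [(d, i) for d, i in order if d <= kth or _tied(d, kth)]
    return [Hit(i, d, rank) for rank, (d, i) in enumerate(kept, start=1)]


def _tied(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=TIE_RTOL, abs_tol=1e-12)


# -- reliability index -----------------------------------------------------


def reliability_index(
    hits: Sequence[Hit], annotated: Sequence[bool], k: int
) -> float:
    """Distance-weighted support for one term over the hit list.

    ``annotated[i]`` flags whether ``hits[i]`` carries the term.  Normalised
    by the requested k; clamped to 1.0 when tie expansion pushes the sum
    above 1 (logged).
    """
    if not hits:
        raise ValidationError("reliability_index requires at least one hit")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if len(annotated) != len(hits):
        raise ValidationError("annotated flags must align with hits")
    total = 0.0
    for hit, flag in zip(hits, annotated):
        if hit.distance < 0:
            raise ValidationError(f"negative distance on hit {hit.id}")
        if flag:
            total += 0.5 / (0.5 + hit.distance)
    ri = total / k
    if ri > 1.0:
        logger.debug("RI %.4f > 1 after tie expansion; clamped", ri)
        ri = 1.0
    return ri


# -- transfer --------------------------------------------------------------


def transfer_annotations(
    query_id: str,
    query_vector: np.ndarray,
    store: EmbeddingStore,
    ann: AnnotationSet,
    k: int = 1,
    metric: str = "euclidean",
    exclude: Iterable[str] = (),
    drop_zero_distance: bool = False,
) -> list[Prediction]:
    """Transfer the (propagated) GO terms of the nearest hits to one query.

    Per namespace, the predicted set is the union of the hits' term sets,
    each term scored by :func:`reliability_index`; namespace roots are never
    predicted.  Output is sorted by (namespace, −RI, term id).  Because a
    term's carriers always include its children's carriers in a propagated
    database, parent RIs dominate child RIs and the prediction set stays
    propagation-consistent.
    """
    if not ann.propagated:
        raise ValidationError("transfer requires a propagated AnnotationSet")
    hits = nearest_neighbors(query_vector, store, k, metric, exclude, drop_zero_distance)
    return _score_hits(query_id, hits, ann, k)


def _score_hits(
    query_id: str, hits: Sequence[Hit], ann: AnnotationSet, k: int
) -> list[Prediction]:
    preds: list[Prediction] = []
    namespaces = set()
    for hit in hits:
        namespaces.update(ann.namespaces(hit.id))
    for ns in namespaces:
        term_union: set[str] = set()
        hit_terms = [ann.terms(h.id, ns) for h in hits]
        for terms in hit_terms:
            term_union.update(terms)
        term_union -= ROOT_IDS
        for term in term_union:
            flags = [term in terms for terms in hit_terms]
            preds.append(Prediction(query_id, ns, term, reliability_index(hits, flags, k)))
    preds.sort(key=lambda p: (p.namespace, -p.ri, p.term))
    return preds


def transfer_all(
    queries: EmbeddingStore,
    store: EmbeddingStore,
    ann: AnnotationSet,
    k: int = 1,
    metric: str = "euclidean",
    exclude_self: bool = True,
    drop_zero_distance: bool = False,
) -> list[Prediction]:
    """Run the transfer for every query in a store (sorted id order).

    ``exclude_self`` removes a lookup entry sharing the query's id, so a
    query already present in the database cannot trivially retrieve itself.
    """
    preds: list[Prediction] = []
    for qid, vec in queries.items():
        exclude = {qid} if exclude_self else ()
        preds.extend(
            transfer_annotations(
                qid, vec, store, ann, k, metric, exclude, drop_zero_distance
            )
        )
    return preds


def apply_threshold(
    preds: Iterable[Prediction], thresholds: Mapping[str, float]
) -> list[Prediction]:
    """Keep predictions with RI ≥ their namespace's threshold.

    Namespaces missing from ``thresholds`` default to 0 (keep everything).
    Propagation consistency is preserved automatically because a parent's RI
    is never below a child's.
    """
    for ns, tau in thresholds.items():
        if not 0.0 <= tau <= 1.0:
            raise ValidationError(f"threshold for {ns} out of [0,1]: {tau}")
    return [p for p in preds if p.ri >= thresholds.get(p.namespace, 0.0)]


# -- naive baseline --------------------------------------------------------


def naive_predict(
    freqs: TermFrequencies, query_ids: Iterable[str] = ("*",)
) -> list[Prediction]:
    """Frequency baseline: every term scored by its database frequency.

    The prediction is identical for every query; roots are excluded already
    by the frequency computation on a root-free propagated database.
    """
    preds: list[Prediction] = []
    for qid in query_ids:
        for ns, table in sorted(freqs.per_namespace.items()):
            for term, freq in table.items():
                if term in ROOT_IDS:
                    continue
                preds.append(Prediction(qid, ns, term, freq))
    preds.sort(key=lambda p: (p.query, p.namespace, -p.ri, p.term))
    return preds


# -- CAFA-style prediction files ------------------------------------------


def write_predictions(
    preds: Iterable[Prediction], stream: TextIO, decimals: int | None = 2
) -> None:
    """Write ``query<TAB>GO id<TAB>score`` lines (CAFA submission style).

    Scores are rounded to ``decimals`` places (CAFA uses 2); pass ``None``
    to keep full precision, e.g. before an in-file evaluation round-trip.
    """
    for p in sorted(preds):
        score = repr(p.ri) if decimals is None else f"{p.ri:.{decimals}f}"
        stream.write(f"{p.query}\t{p.term}\t{score}\n")


def read_predictions(stream: TextIO, ontology: Ontology) -> list[Prediction]:
    """Read a CAFA-style prediction file; namespaces come from the ontology."""
    preds: list[Prediction] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "AUTHOR", "MODEL", "KEYWORDS", "END")):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValidationError(f"line {lineno}: expected 3 fields")
        query, term, score = fields
        preds.append(
            Prediction(query, ontology.namespace_of(term), ontology.resolve(term),
                       float(score))
        )
    return preds
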