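"""Protein→GO annotation databases: reading, filtering, propagation, summaries.

Annotation databases (GOA releases, or the TSV dialect used by the synthetic
fixtures) map protein accessions to GO terms with evidence codes.  The
standard preparation pipeline before annotation transfer is:

1. read the database, optionally keeping only experimentally supported
   records (evidence codes EXP, IDA, IPI, IMP, IGI, IEP, TAS, IC);
2. drop proteins annotated only at the namespace roots (uninformative);
3. close every term set under the ancestor relation and remove the roots.

This module also computes database term frequencies (the naive baseline's
scores) and the NK/LK benchmark partition used in CAFA-style assessment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from .errors import ConfigError, ParseError
from .ontology import NAMESPACE_ROOTS, ROOT_IDS, Ontology

logger = logging.getLogger(__name__)

#: The eight experimentally supported evidence codes (CAFA definition).
EXPERIMENTAL_EVIDENCE = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC"}
)
EVIDENCE_PRESETS: Mapping[str, frozenset[str]] = {"experimental": EXPERIMENTAL_EVIDENCE}

#: GO evidence-code vocabulary, strongest first.  Used both to validate
#: filters and to keep the strongest code when duplicate rows collapse.
EVIDENCE_PRECEDENCE = (
    "EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "HTP", "HDA", "HMP", "HGI",
    "HEP", "IC", "TAS", "ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "IBD",
    "IKR", "IRD", "RCA", "NAS", "ND", "IEA",
)
KNOWN_EVIDENCE_CODES = frozenset(EVIDENCE_PRECEDENCE)
_PRECEDENCE_RANK = {c: i for i, c in enumerate(EVIDENCE_PRECEDENCE)}

_ASPECT_TO_NAMESPACE = {"F": "MFO", "P": "BPO", "C": "CCO"}


@dataclass
class AnnotationSet:
    """Protein → namespace → GO term sets, with per-record evidence codes.

    ``propagated`` marks whether every term set is closed under the ancestor
    relation (with namespace roots removed).  Evidence is tracked per
    directly annotated ``(protein, term)`` pair; propagated parents inherit
    membership only.
    """

    records: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)
    propagated: bool = False

    def add(self, protein: str, namespace: str, term: str, evidence: str | None = None) -> None:
        ns_map = self.records.setdefault(protein, {})
        ns_map.setdefault(namespace, set()).add(term)
        if evidence is not None:
            key = (protein, term)
            old = self.evidence.get(key)
            if old is None or _PRECEDENCE_RANK.get(evidence, len(EVIDENCE_PRECEDENCE)) < \
                    _PRECEDENCE_RANK.get(old, len(EVIDENCE_PRECEDENCE)):
                self.evidence[key] = evidence

    def proteins(self) -> list[str]:
        return sorted(self.records)

    def terms(self, protein: str, namespace: str) -> frozenset[str]:
        return frozenset(self.records.get(protein, {}).get(namespace, set()))

    def namespaces(self, protein: str) -> frozenset[str]:
        return frozenset(
            ns for ns, ts in self.records.get(protein, {}).items() if ts
        )

    def n_proteins(self) -> int:
        return len(self.records)


def _resolve_filter(evidence_filter: Iterable[str] | str | None) -> frozenset[str] | None:
    if evidence_filter is None:
        return None
    if isinstance(evidence_filter, str):
        try:
            return EVIDENCE_PRESETS[evidence_filter]
        except KeyError:
            raise ConfigError(f"unknown evidence preset {evidence_filter!r}") from None
    codes = frozenset(evidence_filter)
    unknown = codes - KNOWN_EVIDENCE_CODES
    if unknown:
        raise ConfigError(f"unknown evidence codes in filter: {sorted(unknown)}")
    return codes


def read_annotations(
    stream: TextIO,
    ontology: Ontology,
    dialect: str = "tsv",
    evidence_filter: Iterable[str] | str | None = None,
    strip_isoforms: bool = True,
) -> AnnotationSet:
    """Read an unpropagated annotation set from GAF 2.x or the TSV dialect.

    TSV lines are ``protein<TAB>GO id[<TAB>evidence]``.  GAF rows with a
    ``NOT`` qualifier are dropped; aspect letters F/P/C map to MFO/BPO/CCO
    but the ontology's own namespace assignment wins.  GO ids absent from
    the ontology are skipped with a counted warning; ``alt_id`` accessions
    resolve to their primary id.
    """
    codes = _resolve_filter(evidence_filter)
    ann = AnnotationSet()
    skipped_unknown = 0

    def _add(protein: str, go_id: str, evidence: str | None, lineno: int) -> None:
        nonlocal skipped_unknown
        if strip_isoforms and "-" in protein:
            protein = protein.split("-", 1)[0]
        if codes is not None and (evidence is None or evidence not in codes):
            return
        if go_id not in ontology:
            skipped_unknown += 1
            return
        go_id = ontology.resolve(go_id)
        ann.add(protein, ontology.namespace_of(go_id), go_id, evidence)

    if dialect == "tsv":
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ParseError(f"line {lineno}: expected 2-3 fields, got {len(fields)}")
            protein, go_id = fields[0], fields[1]
            evidence = fields[2] if len(fields) == 3 else None
            _add(protein, go_id, evidence, lineno)
    elif dialect == "gaf":
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"line {lineno}: GAF row has {len(fields)} columns (<9)")
            qualifier = fields[3]
            if "NOT" in qualifier.split("|"):
                continue
            _add(fields[1], fields[4], fields[6] or None, lineno)
    else:
        raise ParseError(f"unknown annotation dialect {dialect!r} (expected gaf|tsv)")

    if skipped_unknown:
        logger.warning("skipped %d records with GO ids absent from the ontology",
                       skipped_unknown)
    return ann


def write_annotations_tsv(ann: AnnotationSet, stream: TextIO) -> None:
    """Write the TSV dialect (protein, term, evidence where known)."""
    for protein in ann.proteins():
        for ns in sorted(ann.records[protein]):
            for term in sorted(ann.records[protein][ns]):
                ev = ann.evidence.get((protein, term))
                if ev is None:
                    stream.write(f"{protein}\t{term}\n")
                else:
                    stream.write(f"{protein}\t{term}\t{ev}\n")


def drop_root_only(ann: AnnotationSet, ont: Ontology) -> AnnotationSet:
    """Remove proteins annotated only at namespace roots; strip roots elsewhere.

    A protein whose entire annotation (across all namespaces) is a subset of
    the three roots carries no information and is dropped outright.
    """
    out = AnnotationSet(propagated=ann.propagated)
    dropped = 0
    for protein, ns_map in ann.records.items():
        all_terms = set().union(*ns_map.values()) if ns_map else set()
        if all_terms <= ROOT_IDS:
            dropped += 1
            continue
        for ns, terms in ns_map.items():
            for term in terms - ROOT_IDS:
                out.add(protein, ns, term, ann.evidence.get((protein, term)))
    if dropped:
        logger.info("dropped %d root-only proteins", dropped)
    return out


def propagate_annotations(ann: AnnotationSet, ont: Ontology) -> AnnotationSet:
    """Close every term set under the ancestor relation, minus the roots.

    Idempotent; sets the ``propagated`` flag.  Obsolete terms never gain
    ancestors, so they survive only as themselves.
    """
    out = AnnotationSet(propagated=True)
    for protein, ns_map in ann.records.items():
        for ns, terms in ns_map.items():
            closed = ont.propagate(terms) - ROOT_IDS
            for term in closed:
                out.add(protein, ns, term, ann.evidence.get((protein, term)))
    return out


@dataclass(frozen=True)
class NamespaceSummary:
    n_proteins: int
    mean_terms: float
    mean_leaf_terms: float


def summarize(ann: AnnotationSet, ont: Ontology) -> dict[str, NamespaceSummary]:
    """Per-namespace mean term and leaf-term counts over annotated proteins.

    Means are taken over proteins with at least one term in the namespace; a
    namespace with no annotated protein reports NaN means, not zero.
    """
    out: dict[str, NamespaceSummary] = {}
    for ns in NAMESPACE_ROOTS:
        counts: list[int] = []
        leaf_counts: list[int] = []
        for protein, ns_map in ann.records.items():
            terms = ns_map.get(ns)
            if not terms:
                continue
            counts.append(len(terms))
            leaf_counts.append(len(ont.leaves(terms)))
        if counts:
            out[ns] = NamespaceSummary(
                len(counts),
                sum(counts) / len(counts),
                sum(leaf_counts) / len(leaf_counts),
            )
        else:
            out[ns] = NamespaceSummary(0, math.nan, math.nan)
    return out


@dataclass(frozen=True)
class TermFrequencies:
    """Relative term frequencies per namespace over a propagated database."""

    per_namespace: Mapping[str, Mapping[str, float]]

    def get(self, namespace: str) -> Mapping[str, float]:
        return self.per_namespace.get(namespace, {})


def term_frequencies(ann: AnnotationSet) -> TermFrequencies:
    """Fraction of (namespace-annotated) proteins carrying each term.

    Requires a propagated set so that parent frequencies dominate children.
    """
    if not ann.propagated:
        raise ValueError("term_frequencies requires a propagated AnnotationSet")
    freqs: dict[str, dict[str, float]] = {}
    for ns in NAMESPACE_ROOTS:
        counts: dict[str, int] = {}
        n = 0
        for ns_map in ann.records.values():
            terms = ns_map.get(ns)
            if not terms:
                continue
            n += 1
            for term in terms:
                counts[term] = counts.get(term, 0) + 1
        if n:
            freqs[ns] = {t: c / n for t, c in counts.items()}
    return TermFrequencies(freqs)


@dataclass(frozen=True)
class BenchmarkLabel:
    """NK/LK/excluded status of a benchmark protein.

    For LK proteins, ``namespaces`` lists the newly annotated namespaces the
    protein is benchmarked in.
    """

    status: str  # "NK" | "LK" | "excluded"
    namespaces: frozenset[str] = frozenset()


def partition_nk_lk(
    earlier: AnnotationSet, later: AnnotationSet
) -> dict[str, BenchmarkLabel]:
    """CAFA benchmark modes from two database snapshots.

    NK (no knowledge): no experimental annotation in any namespace at the
    earlier snapshot.  LK (limited knowledge): experimental annotations in
    one or two namespaces earlier, gaining terms in a previously empty
    namespace later.  Everything else is excluded.
    """
    labels: dict[str, BenchmarkLabel] = {}
    for protein in set(earlier.records) | set(later.records):
        ns_later = later.namespaces(protein)
        if not ns_later:
            logger.warning("%s present earlier but not later; excluded", protein)
            labels[protein] = BenchmarkLabel("excluded")
            continue
        ns_earlier = earlier.namespaces(protein)
        if not ns_earlier:
            labels[protein] = BenchmarkLabel("NK", ns_later)
        elif len(ns_earlier) <= 2 and (ns_later - ns_earlier):
            labels[protein] = BenchmarkLabel("LK", frozenset(ns_later - ns_earlier))
        else:
            labels[protein] = BenchmarkLabel("excluded")
    return labels
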