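"""Gene Ontology term graph: parsing, ancestor closure, and leaf extraction.

The Gene Ontology (GO) is a directed acyclic graph of terms in three
namespaces — biological process (BPO), molecular function (MFO) and cellular
component (CCO) — each rooted at a single term.  Annotating a protein with a
term implies annotation with every ancestor of that term (the true-path
rule), so annotation sets are compared only after closing them under the
``is_a`` / ``part_of`` parent relations.  This module provides the graph
container, the two supported serialisations (OBO 1.2 and a minimal TSV
dialect used by the synthetic fixtures) and the closure operations every
downstream module builds on.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx
import obonet

from .errors import ParseError, UnknownTermError, ValidationError

logger = logging.getLogger(__name__)

#: Namespace roots: molecular function, biological process, cellular component.
NAMESPACE_ROOTS: Mapping[str, str] = {
    "MFO": "GO:0003674",
    "BPO": "GO:0008150",
    "CCO": "GO:0005575",
}
ROOT_IDS = frozenset(NAMESPACE_ROOTS.values())
ROOT_NAMESPACES: Mapping[str, str] = {v: k for k, v in NAMESPACE_ROOTS.items()}

#: OBO namespace names mapped to the three-letter codes used throughout.
OBO_NAMESPACES: Mapping[str, str] = {
    "molecular_function": "MFO",
    "biological_process": "BPO",
    "cellular_component": "CCO",
}
_CODE_TO_OBO = {v: k for k, v in OBO_NAMESPACES.items()}

#: Relations followed when propagating annotations up the graph (standard GO
#: practice is_a + part_of; restrict to {"is_a"} if desired).
DEFAULT_PROPAGATION_RELATIONS = frozenset({"is_a", "part_of"})

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class GoTerm:
    """A single GO term with its outgoing parent edges.

    ``parents`` holds ``(parent_id, relation)`` pairs; only relations in the
    ontology's propagation set are followed for closure.  Obsolete terms are
    kept for lookup but never take part in propagation.
    """

    id: str
    namespace: str
    parents: frozenset[tuple[str, str]] = frozenset()
    obsolete: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not GO_ID_PATTERN.match(self.id):
            raise ValidationError(f"not a GO accession: {self.id!r}")
        if self.namespace not in NAMESPACE_ROOTS:
            raise ValidationError(
                f"unknown namespace {self.namespace!r} for {self.id}"
            )


class Ontology:
    """Validated GO term graph with memoised ancestor closure.

    Parameters
    ----------
    terms:
        Iterable of :class:`GoTerm`.
    alt_ids:
        Map of secondary (``alt_id``) accessions to primary ids; resolved
        transparently by :meth:`resolve`.
    relations:
        Parent relations followed during propagation.
    validate:
        Check acyclicity and single-root reachability (on by default).
    """

    def __init__(
        self,
        terms: Iterable[GoTerm],
        alt_ids: Mapping[str, str] | None = None,
        relations: Iterable[str] = DEFAULT_PROPAGATION_RELATIONS,
        validate: bool = True,
    ) -> None:
        self.terms: dict[str, GoTerm] = {}
        for term in terms:
            if term.id in self.terms:
                raise ValidationError(f"duplicate term {term.id}")
            self.terms[term.id] = term
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self.relations = frozenset(relations)
        self._ancestors: dict[str, frozenset[str]] = {}
        if validate:
            self._validate()

    # -- basic queries ----------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_ids

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    @property
    def roots(self) -> Mapping[str, str]:
        return {ns: r for ns, r in NAMESPACE_ROOTS.items() if r in self.terms}

    def resolve(self, term_id: str) -> str:
        """Map an alt_id to its primary accession (identity for primary ids)."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise UnknownTermError(f"unknown GO term {term_id}")

    def namespace_of(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].namespace

    def is_root(self, term_id: str) -> bool:
        return self.resolve(term_id) in ROOT_IDS

    def parents(self, term_id: str) -> frozenset[str]:
        """Direct parents reachable via propagation relations.

        Edges from or into obsolete terms, via unlisted relations, or across
        namespaces are not followed.
        """
        term = self.terms[self.resolve(term_id)]
        if term.obsolete:
            return frozenset()
        out = set()
        for parent_id, relation in term.parents:
            if relation not in self.relations:
                continue
            parent = self.terms.get(parent_id)
            if parent is None or parent.obsolete:
                continue
            if parent.namespace != term.namespace:
                continue  # keep each term inside one ontology
            out.add(parent_id)
        return frozenset(out)

    # -- closure ----------------------------------------------------------

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable from ``term_id`` via propagation relations.

        Excludes the term itself; empty for roots and obsolete terms.
        """
        term_id = self.resolve(term_id)
        cached = self._ancestors.get(term_id)
        if cached is not None:
            return cached
        # Iterative DFS with memoisation; the graph is validated acyclic.
        stack = [term_id]
        while stack:
            node = stack[-1]
            if node in self._ancestors:
                stack.pop()
                continue
            pending = [p for p in self.parents(node) if p not in self._ancestors]
            if pending:
                stack.extend(pending)
                continue
            acc: set[str] = set()
            for p in self.parents(node):
                acc.add(p)
                acc.update(self._ancestors[p])
            self._ancestors[node] = frozenset(acc)
            stack.pop()
        return self._ancestors[term_id]

    def propagate(self, terms: Iterable[str]) -> frozenset[str]:
        """Close a term set under the ancestor relation (idempotent)."""
        closed: set[str] = set()
        for t in terms:
            t = self.resolve(t)
            closed.add(t)
            closed.update(self.ancestors(t))
        return frozenset(closed)

    def leaves(self, terms: Iterable[str]) -> frozenset[str]:
        """Members of a closed set that are not an ancestor of any other member.

        Non-closed input is closed first (logged), so the result is always the
        frontier of the closure.
        """
        term_set = frozenset(self.resolve(t) for t in terms)
        closed = self.propagate(term_set)
        if closed != term_set:
            logger.warning(
                "leaves() received a non-closed set (%d terms, closure %d); "
                "closing it first",
                len(term_set),
                len(closed),
            )
            term_set = closed
        covered: set[str] = set()
        for t in term_set:
            covered.update(self.ancestors(t))
        return frozenset(term_set - covered)

    # -- validation -------------------------------------------------------

    def _propagation_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term_id in self.terms:
            for parent in self.parents(term_id):
                g.add_edge(term_id, parent)
        return g

    def _validate(self) -> None:
        g = self._propagation_graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise ValidationError(f"propagation edges contain a cycle: {path}")
        for term_id, term in self.terms.items():
            if term.obsolete or term_id in ROOT_IDS:
                continue
            reached = self.ancestors(term_id) & ROOT_IDS
            if len(reached) != 1:
                raise ValidationError(
                    f"{term_id} reaches {len(reached)} namespace roots "
                    "(expected exactly 1)"
                )
            root = next(iter(reached))
            if ROOT_NAMESPACES[root] != term.namespace:
                raise ValidationError(
                    f"{term_id} declared {term.namespace} but reaches "
                    f"{ROOT_NAMESPACES[root]} root {root}"
                )


# -- module-level operation aliases (functional surface) -------------------


def ancestors(ont: Ontology, term_id: str) -> frozenset[str]:
    return ont.ancestors(term_id)


def propagate_terms(ont: Ontology, terms: Iterable[str]) -> frozenset[str]:
    return ont.propagate(terms)


def leaf_terms(ont: Ontology, terms: Iterable[str]) -> frozenset[str]:
    return ont.leaves(terms)


# -- parsing ---------------------------------------------------------------


def parse_obo(
    stream: TextIO | str,
    dialect: str = "obo",
    relations: Iterable[str] = DEFAULT_PROPAGATION_RELATIONS,
) -> Ontology:
    """Parse an ontology from OBO 1.2 or from the internal TSV dialect.

    The TSV dialect (used by fixtures) has two record shapes::

        term_id <TAB> namespace [<TAB> obsolete]   # term declaration
        child   <TAB> relation  <TAB> parent        # edge (is_a / part_of)

    ``#``-prefixed lines are comments.  In both dialects ``alt_id`` entries
    are resolved to primary ids at parse time.
    """
    if dialect == "obo":
        return _parse_obo_flat(stream, relations)
    if dialect == "tsv":
        return _parse_tsv(stream, relations)
    raise ParseError(f"unknown ontology dialect {dialect!r} (expected obo|tsv)")


def _parse_obo_flat(stream: TextIO | str, relations: Iterable[str]) -> Ontology:
    try:
        graph = obonet.read_obo(stream, ignore_obsolete=False)
    except Exception as exc:  # malformed stanza
        raise ParseError(f"malformed OBO input: {exc}") from exc

    terms: list[GoTerm] = []
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        ns_name = data.get("namespace")
        if ns_name not in OBO_NAMESPACES:
            raise ParseError(f"term {node} has missing/unknown namespace {ns_name!r}")
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents: set[tuple[str, str]] = set()
        if not obsolete:
            for _, parent, relation in graph.out_edges(node, keys=True):
                parents.add((parent, relation))
        terms.append(
            GoTerm(
                id=node,
                namespace=OBO_NAMESPACES[ns_name],
                parents=frozenset(parents),
                obsolete=obsolete,
                name=data.get("name", ""),
            )
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    return Ontology(terms, alt_ids=alt_ids, relations=relations)


def _parse_tsv(stream: TextIO, relations: Iterable[str]) -> Ontology:
    namespaces: dict[str, str] = {}
    obsolete: set[str] = set()
    edges: dict[str, set[tuple[str, str]]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 2 or (len(fields) == 3 and fields[2] == "obsolete"):
            term_id, ns = fields[0], fields[1]
            if ns not in NAMESPACE_ROOTS:
                raise ParseError(f"line {lineno}: unknown namespace {ns!r}")
            namespaces[term_id] = ns
            if len(fields) == 3:
                obsolete.add(term_id)
        elif len(fields) == 3:
            child, relation, parent = fields
            if relation not in {"is_a", "part_of"}:
                raise ParseError(f"line {lineno}: unknown relation {relation!r}")
            edges.setdefault(child, set()).add((parent, relation))
        else:
            raise ParseError(f"line {lineno}: expected 2 or 3 tab-separated fields")
    for child in edges:
        if child not in namespaces:
            raise ParseError(f"edge references undeclared term {child}")
    terms = [
        GoTerm(
            id=tid,
            namespace=ns,
            parents=frozenset(edges.get(tid, set())) if tid not in obsolete else frozenset(),
            obsolete=tid in obsolete,
        )
        for tid, ns in namespaces.items()
    ]
    return Ontology(terms, relations=relations)


def write_tsv(ont: Ontology, stream: TextIO) -> None:
    """Serialise an ontology in the internal TSV dialect (round-trips)."""
    stream.write("# gotransfer ontology TSV dialect\n")
    for term_id in sorted(ont.terms):
        term = ont.terms[term_id]
        suffix = "\tobsolete" if term.obsolete else ""
        stream.write(f"{term_id}\t{term.namespace}{suffix}\n")
    for term_id in sorted(ont.terms):
        for parent, relation in sorted(ont.terms[term_id].parents):
            stream.write(f"{term_id}\t{relation}\t{parent}\n")
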