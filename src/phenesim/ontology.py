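"""Typed ontology DAG with ancestor-closure queries.

Multiple OBO ontologies (PO, GO, PATO, ChEBI, RO, ...) are parsed and merged
into a single directed acyclic graph of terms connected by ``is_a`` and
``part_of`` edges, optionally extended with ``bridge`` edges that link
biological-process terms to the plant structures they act on.  Transitive
ancestor closure over this graph is the primitive that stands behind phene
inference and subsumption: a term's ancestors are its generalisations, so an
EQ statement built from ancestors of another statement's terms describes a
more general phene.

Obsolete terms are retained for id/label validation but never participate in
edges or closure; ``alt_id`` aliases are resolved to canonical ids at parse
time so downstream code only ever sees canonical identifiers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

IS_A = "is_a"
PART_OF = "part_of"
BRIDGE = "bridge"

#: relations traversed by closure unless the caller opts into bridges
DEFAULT_RELATIONS = frozenset({IS_A, PART_OF})

_CURIE_RE = re.compile(r"^[A-Za-z]+:[A-Za-z_0-9]+$")


class OntologyError(Exception):
    """Base class for ontology construction and query failures."""


class OboParseError(OntologyError):
    pass


class MergeError(OntologyError):
    pass


class CycleError(OntologyError):
    pass


class UnknownTermError(OntologyError, KeyError):
    pass


class ObsoleteTermError(OntologyError):
    pass


@dataclass(frozen=True)
class Term:
    """A single ontology term (class)."""

    id: str
    label: str = ""
    namespace: str = ""
    obsolete: bool = False
    alt_ids: frozenset[str] = frozenset()
    replaced_by: str | None = None

    def __post_init__(self) -> None:
        if not _CURIE_RE.match(self.id):
            raise OntologyError(f"invalid term id (not a CURIE): {self.id!r}")

    @property
    def prefix(self) -> str:
        return self.id.split(":", 1)[0]


class Ontology:
    """Immutable merged term graph supporting ancestor closure.

    Edges are stored as ``(child, parent, relation)`` triples; closure walks
    child -> parent.  The graph restricted to is_a/part_of must be acyclic.
    """

    def __init__(
        self,
        terms: Mapping[str, Term] | Iterable[Term],
        edges: Iterable[tuple[str, str, str]],
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        if not isinstance(terms, Mapping):
            terms = {t.id: t for t in terms}
        self.terms: dict[str, Term] = dict(terms)
        self.edges: frozenset[tuple[str, str, str]] = frozenset(edges)

        for child, parent, rel in self.edges:
            for endpoint in (child, parent):
                term = self.terms.get(endpoint)
                if term is None:
                    raise OntologyError(
                        f"edge endpoint {endpoint} not among terms"
                    )
                if term.obsolete:
                    raise OntologyError(
                        f"obsolete term {endpoint} may not be an edge endpoint"
                    )
            if rel not in (IS_A, PART_OF, BRIDGE):
                raise OntologyError(f"unsupported edge relation {rel!r}")

        self._alt: dict[str, str] = dict(alt_ids or {})
        for alt, canonical in self._alt.items():
            if canonical not in self.terms:
                raise OntologyError(f"alt_id {alt} maps to unknown id {canonical}")

        self._check_acyclic()
        # parent adjacency: child -> tuple of (parent, relation)
        self._parents: dict[str, tuple[tuple[str, str], ...]] = {}
        adj: dict[str, list[tuple[str, str]]] = {}
        for child, parent, rel in sorted(self.edges):
            adj.setdefault(child, []).append((parent, rel))
        self._parents = {c: tuple(ps) for c, ps in adj.items()}
        self._anc_cache: dict[tuple[str, frozenset[str]], frozenset[str]] = {}

    # -- construction helpers -------------------------------------------------

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(
            (c, p) for c, p, rel in self.edges if rel in (IS_A, PART_OF)
        )
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CycleError(f"is_a/part_of cycle detected: {cycle}")

    # -- lookup ---------------------------------------------------------------

    def __contains__(self, curie: str) -> bool:
        return curie in self.terms or curie in self._alt

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, curie: str) -> str:
        """Map a possibly-alternate id to its canonical id."""
        if curie in self.terms:
            return curie
        if curie in self._alt:
            return self._alt[curie]
        raise UnknownTermError(curie)

    def is_alt(self, curie: str) -> bool:
        return curie not in self.terms and curie in self._alt

    def term(self, curie: str) -> Term:
        return self.terms[self.resolve(curie)]

    @property
    def roots(self) -> frozenset[str]:
        """Non-obsolete terms with no outgoing is_a/part_of edge."""
        children = {c for c, _, rel in self.edges if rel in (IS_A, PART_OF)}
        return frozenset(
            t for t, term in self.terms.items()
            if not term.obsolete and t not in children
        )

    def stats(self) -> dict[str, int]:
        return {
            "terms": len(self.terms),
            "obsolete_terms": sum(t.obsolete for t in self.terms.values()),
            "edges": len(self.edges),
            "roots": len(self.roots),
        }

    # -- closure --------------------------------------------------------------

    def ancestors(
        self,
        term: str,
        relations: Iterable[str] = DEFAULT_RELATIONS,
        reflexive: bool = False,
    ) -> frozenset[str]:
        """Transitive closure of ``term`` over edges whose relation is allowed.

        Raises :class:`UnknownTermError` / :class:`ObsoleteTermError` for ids
        that cannot take part in closure.
        """
        canonical = self.resolve(term)
        if self.terms[canonical].obsolete:
            raise ObsoleteTermError(
                f"{canonical} is obsolete and excluded from closure"
            )
        rels = frozenset(relations)
        key = (canonical, rels)
        cached = self._anc_cache.get(key)
        if cached is None:
            seen: set[str] = set()
            stack = [canonical]
            while stack:
                node = stack.pop()
                for parent, rel in self._parents.get(node, ()):
                    if rel in rels and parent not in seen:
                        seen.add(parent)
                        stack.append(parent)
            cached = frozenset(seen)
            self._anc_cache[key] = cached
        return cached | {canonical} if reflexive else cached


# -- OBO ingestion -------------------------------------------------------------


def _scan_duplicate_ids(path: Path) -> None:
    """Reject files in which two [Term] stanzas declare the same id."""
    seen: dict[str, int] = {}
    in_term = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("["):
                in_term = line == "[Term]"
            elif in_term and line.startswith("id:"):
                term_id = line[3:].split("!")[0].strip()
                if term_id in seen:
                    raise OboParseError(
                        f"{path}:{lineno}: duplicate term id {term_id} "
                        f"(first declared on line {seen[term_id]})"
                    )
                seen[term_id] = lineno


def parse_obo(path: str | Path) -> Ontology:
    """Parse one OBO 1.2 flat file into an :class:`Ontology`.

    Only ``is_a`` and ``relationship: part_of`` lines become edges; obsolete
    terms are kept in the term map but contribute no edges.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _scan_duplicate_ids(path)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # obonet raises ValueError with stanza context
        raise OboParseError(f"{path}: malformed OBO file: {exc}") from exc

    header_ns = graph.graph.get("default-namespace")
    default_ns = header_ns[0] if header_ns else graph.graph.get("ontology", path.stem)

    terms: dict[str, Term] = {}
    alt: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        replaced = data.get("replaced_by")
        try:
            term = Term(
                id=node,
                label=data.get("name", ""),
                namespace=data.get("namespace", default_ns),
                obsolete=str(data.get("is_obsolete", "")).lower() == "true",
                alt_ids=frozenset(data.get("alt_id", ())),
                replaced_by=replaced[0] if replaced else None,
            )
        except OntologyError as exc:
            raise OboParseError(f"{path}: {exc}") from exc
        terms[node] = term
        for a in term.alt_ids:
            if a in alt and alt[a] != node:
                raise OboParseError(
                    f"{path}: alt_id {a} claimed by both {alt[a]} and {node}"
                )
            alt[a] = node

    edges = set()
    for child, parent, rel in graph.edges(keys=True):
        if rel not in (IS_A, PART_OF):
            continue  # other relationship types are out of closure scope
        if terms[child].obsolete or terms[parent].obsolete:
            continue
        edges.add((child, parent, rel))
    return Ontology(terms, edges, alt)


# -- merging -------------------------------------------------------------------


def read_bridges(path: str | Path) -> list[tuple[str, str]]:
    """Read bridge axioms: 2-column TSV ``process_id<TAB>structure_id``."""
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise OboParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            rows.append((parts[0].strip(), parts[1].strip()))
    return rows


def merge(
    ontologies: Sequence[Ontology],
    bridges: str | Path | Iterable[tuple[str, str]] | None = None,
) -> Ontology:
    """Combine several ontologies (and optional bridge axioms) into one.

    Shared term ids must carry identical labels; each bridge row
    ``(process, structure)`` adds one ``bridge`` edge process -> structure.
    """
    terms: dict[str, Term] = {}
    alt: dict[str, str] = {}
    edges: set[tuple[str, str, str]] = set()
    for ont in ontologies:
        for tid, term in ont.terms.items():
            existing = terms.get(tid)
            if existing is not None and existing.label != term.label:
                raise MergeError(
                    f"id collision for {tid}: label {existing.label!r} vs "
                    f"{term.label!r}"
                )
            terms.setdefault(tid, term)
        for a, canonical in ont._alt.items():
            if a in alt and alt[a] != canonical:
                raise MergeError(f"alt_id {a} resolves to both {alt[a]} and {canonical}")
            alt[a] = canonical
        edges |= ont.edges

    if bridges is not None:
        if isinstance(bridges, (str, Path)):
            bridges = read_bridges(bridges)
        missing = []
        for process_id, structure_id in bridges:
            if process_id not in terms or structure_id not in terms:
                missing.extend(
                    i for i in (process_id, structure_id) if i not in terms
                )
                continue
            edges.add((process_id, structure_id, BRIDGE))
        if missing:
            raise MergeError(
                "bridge axioms reference unknown ids: " + ", ".join(sorted(set(missing)))
            )
    return Ontology(terms, edges, alt)
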