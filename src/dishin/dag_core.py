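"""Ontology DAG model: OBO ingestion, ancestor sets, and distinct-path counting.

Concepts are nodes of a directed acyclic graph whose edges point from child
to parent along the hierarchical (subsumption) relations ``is_a`` and
``part_of``.  "Path from c to a" always means an upward walk along these
edges.  The transitive closure is augmented with the number of distinct
directed paths between every (descendant, ancestor) pair, which is the raw
material for path-difference based disjunctive-ancestor detection.

Conventions (applied uniformly across the package):

* ancestor sets are reflexive — ``ancestors(c)`` contains ``c`` itself, and
  the path table holds ``count(c, c) = 1`` (the empty path).  This makes
  self-comparison well defined (``Share(c, c) = IC(c)``).
* cross-namespace queries are legal and simply yield empty common-ancestor
  sets; they are never an error.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Mapping

import networkx as nx
import obonet

from .errors import CycleError, OboParseError, UnknownConceptError

#: Hierarchical relations usable for ancestor computations.  ``regulates``
#: and other cross-cutting relations are deliberately unsupported.
HIERARCHICAL_RELATIONS = frozenset({"is_a", "part_of"})

DEFAULT_RELATIONS = frozenset({"is_a"})


@dataclass(frozen=True)
class Concept:
    """A single ontology term."""

    id: str
    name: str = ""
    namespace: str = "default"


class OntologyDAG:
    """Immutable rooted DAG of concepts with child→parent hierarchical edges.

    Parameters
    ----------
    concepts:
        Iterable of :class:`Concept`; ids must be unique.
    edges:
        Iterable of ``(child_id, parent_id, relation)`` triples.  Endpoints
        must exist among *concepts* and the resulting graph must be acyclic.
    """

    def __init__(
        self,
        concepts: Iterable[Concept],
        edges: Iterable[tuple[str, str, str]],
    ) -> None:
        self._concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.id in self._concepts:
                raise ValueError(f"duplicate concept id {c.id!r}")
            if not c.namespace:
                raise ValueError(f"concept {c.id!r} has an empty namespace")
            self._concepts[c.id] = c
        g = nx.DiGraph()
        g.add_nodes_from(self._concepts)
        for child, parent, relation in edges:
            for endpoint in (child, parent):
                if endpoint not in self._concepts:
                    raise UnknownConceptError(
                        f"edge endpoint {endpoint!r} is not a declared concept"
                    )
            if not g.has_edge(child, parent):
                g.add_edge(child, parent, relation=relation)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CycleError(f"hierarchical relation graph contains a cycle: {cycle}")
        self._graph = g

    # -- basic accessors ---------------------------------------------------

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def __len__(self) -> int:
        return len(self._concepts)

    def __iter__(self) -> Iterator[str]:
        return iter(self._concepts)

    def concept(self, concept_id: str) -> Concept:
        try:
            return self._concepts[concept_id]
        except KeyError:
            raise UnknownConceptError(f"unknown concept id {concept_id!r}") from None

    @property
    def concepts(self) -> tuple[Concept, ...]:
        return tuple(self._concepts.values())

    @property
    def edges(self) -> tuple[tuple[str, str, str], ...]:
        return tuple(
            (c, p, d["relation"]) for c, p, d in self._graph.edges(data=True)
        )

    def parents(self, concept_id: str) -> set[str]:
        self.concept(concept_id)
        return set(self._graph.successors(concept_id))

    def children(self, concept_id: str) -> set[str]:
        self.concept(concept_id)
        return set(self._graph.predecessors(concept_id))

    def roots(self, namespace: str | None = None) -> set[str]:
        """Concepts with no parents, optionally restricted to one namespace."""
        out = {c for c in self._concepts if self._graph.out_degree(c) == 0}
        if namespace is not None:
            out = {c for c in out if self._concepts[c].namespace == namespace}
        return out

    def namespaces(self) -> set[str]:
        return {c.namespace for c in self._concepts.values()}

    def subgraph(self, namespace: str) -> "OntologyDAG":
        """Restriction to the concepts of one namespace (edges within it)."""
        keep = {c.id for c in self._concepts.values() if c.namespace == namespace}
        return OntologyDAG(
            (c for c in self._concepts.values() if c.id in keep),
            (e for e in self.edges if e[0] in keep and e[1] in keep),
        )

    def topological_order(self) -> list[str]:
        """Concept ids ordered so that every child precedes its parents."""
        return list(nx.topological_sort(self._graph))

    # -- ancestor computations --------------------------------------------

    def ancestors(self, concept_id: str) -> set[str]:
        """All concepts reachable upward from ``concept_id``, itself included."""
        self.concept(concept_id)
        return nx.descendants(self._graph, concept_id) | {concept_id}

    def descendants(self, concept_id: str) -> set[str]:
        """All concepts from which ``concept_id`` is reachable, itself included."""
        self.concept(concept_id)
        return nx.ancestors(self._graph, concept_id) | {concept_id}

    def common_ancestors(self, c1: str, c2: str) -> set[str]:
        """CA(c1, c2) = Anc(c1) ∩ Anc(c2); empty under disjoint roots."""
        return self.ancestors(c1) & self.ancestors(c2)

    def upward_paths(self, concept_id: str, ancestor_id: str) -> Iterator[list[str]]:
        """Every distinct directed path from a concept to an ancestor.

        Exponential in the worst case; used by the GraSM comparator and by
        brute-force oracles, never by the DiShIn pipeline.
        """
        self.concept(concept_id)
        self.concept(ancestor_id)
        if concept_id == ancestor_id:
            yield [concept_id]
            return
        yield from nx.all_simple_paths(self._graph, concept_id, ancestor_id)


class PathTable:
    """Distinct-path counts over the reflexive transitive closure.

    ``count(c, a)`` is the number of distinct directed child→parent paths
    from ``c`` to ``a``; zero when ``a`` is not an ancestor of ``c``.
    Reflexive entries ``count(c, c) = 1`` are always present, so the
    predicate ``count(c1, a) > 0 and count(c2, a) > 0`` characterises the
    common ancestors of a pair.
    """

    def __init__(self, counts: Mapping[tuple[str, str], int]) -> None:
        self._counts = dict(counts)
        self._by_concept: dict[str, set[str]] = {}
        for (c, a), k in self._counts.items():
            if k <= 0:
                raise ValueError(f"non-positive path count for ({c!r}, {a!r})")
            self._by_concept.setdefault(c, set()).add(a)

    def count(self, concept_id: str, ancestor_id: str) -> int:
        return self._counts.get((concept_id, ancestor_id), 0)

    def ancestors(self, concept_id: str) -> set[str]:
        try:
            return set(self._by_concept[concept_id])
        except KeyError:
            raise UnknownConceptError(
                f"concept {concept_id!r} absent from path table"
            ) from None

    def common_ancestors(self, c1: str, c2: str) -> set[str]:
        return self.ancestors(c1) & self.ancestors(c2)

    def items(self) -> Iterator[tuple[str, str, int]]:
        for (c, a), k in self._counts.items():
            yield c, a, k

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._counts


def transitive_closure_paths(dag: OntologyDAG) -> PathTable:
    """Count distinct upward paths for every (concept, ancestor) pair.

    Dynamic programming over a topological order: a directly connected pair
    has one path per edge, and ``count(c, a) = Σ_p count(p, a)`` over the
    parents ``p`` of ``c`` — each path from ``c`` leaves through exactly one
    parent.  Reflexive entries are fixed at 1 (the empty path).  Runs in
    O(Σ_c |Anc(c)|) time.
    """
    counts: dict[tuple[str, str], int] = {}
    per_concept: dict[str, dict[str, int]] = {}
    # children precede parents in topological order; walk parents-first
    for c in reversed(dag.topological_order()):
        acc: dict[str, int] = {c: 1}
        for p in dag.parents(c):
            for a, k in per_concept[p].items():
                acc[a] = acc.get(a, 0) + k
        per_concept[c] = acc
        for a, k in acc.items():
            counts[(c, a)] = k
    return PathTable(counts)


# -- OBO ingestion and export ---------------------------------------------


def _validate_obo_lines(text: str) -> None:
    """Cheap structural check so malformed input fails with a line number."""
    in_stanza = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise OboParseError(f"line {lineno}: unterminated stanza header {raw!r}")
            in_stanza = True
            continue
        if ":" not in line:
            where = "stanza" if in_stanza else "header"
            raise OboParseError(f"line {lineno}: malformed {where} line {raw!r}")


def parse_obo(
    source: IO[str] | str,
    relations: frozenset[str] | set[str] = DEFAULT_RELATIONS,
) -> OntologyDAG:
    """Read an OBO 1.2/1.4 flat file into an :class:`OntologyDAG`.

    Only non-obsolete ``[Term]`` stanzas are kept, and only edges whose
    relation is in *relations* (a subset of ``{is_a, part_of}``).  Term
    namespaces come from each stanza's ``namespace`` tag, falling back to
    the file's ``default-namespace`` header.
    """
    unknown = set(relations) - HIERARCHICAL_RELATIONS
    if unknown:
        raise ValueError(
            f"unsupported relations {sorted(unknown)}; "
            f"choose from {sorted(HIERARCHICAL_RELATIONS)}"
        )
    text = source if isinstance(source, str) else source.read()
    _validate_obo_lines(text)
    try:
        graph = obonet.read_obo(io.StringIO(text))
    except Exception as exc:  # obonet raises bare ValueError on bad stanzas
        raise OboParseError(f"unreadable OBO input: {exc}") from exc
    default_ns = (graph.graph.get("default-namespace") or ["default"])[0]
    concepts = [
        Concept(
            id=node,
            name=data.get("name", ""),
            namespace=data.get("namespace", default_ns),
        )
        for node, data in graph.nodes(data=True)
    ]
    edges = [
        (child, parent, rel)
        for child, parent, rel in graph.edges(keys=True)
        if rel in relations
    ]
    return OntologyDAG(concepts, edges)


def parse_edge_list(source: IO[str] | str, namespace: str = "default") -> OntologyDAG:
    """Read the internal edge-list TSV dialect: ``child<TAB>parent<TAB>relation``.

    Concepts are inferred from edge endpoints; lines starting with ``#`` are
    ignored.  Intended for hand-written fixtures, not for real ontologies.
    """
    text = source if isinstance(source, str) else source.read()
    ids: dict[str, None] = {}
    edges = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise OboParseError(
                f"line {lineno}: expected 3 tab-separated fields, got {len(fields)}"
            )
        child, parent, relation = fields
        ids.setdefault(child)
        ids.setdefault(parent)
        edges.append((child, parent, relation))
    concepts = [Concept(id=i, name=i, namespace=namespace) for i in ids]
    return OntologyDAG(concepts, edges)


def write_obo(dag: OntologyDAG, stream: IO[str]) -> None:
    """Serialise a DAG as a minimal OBO 1.2 document (stable ordering)."""
    stream.write("format-version: 1.2\n\n")
    by_child: dict[str, list[tuple[str, str]]] = {}
    for child, parent, relation in dag.edges:
        by_child.setdefault(child, []).append((parent, relation))
    for concept in sorted(dag.concepts, key=lambda c: c.id):
        stream.write("[Term]\n")
        stream.write(f"id: {concept.id}\n")
        stream.write(f"name: {concept.name or concept.id}\n")
        stream.write(f"namespace: {concept.namespace}\n")
        for parent, relation in sorted(by_child.get(concept.id, [])):
            if relation == "is_a":
                stream.write(f"is_a: {parent}\n")
            else:
                stream.write(f"relationship: {relation} {parent}\n")
        stream.write("\n")
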