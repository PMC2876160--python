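"""Gene Ontology DAG: parsing, ancestor closure, depth, and shared-function labeling.

The ontology is modeled as a rooted directed acyclic graph per namespace
(biological_process, molecular_function, cellular_component) whose edges are the
``is_a`` and ``part_of`` relations, both treated as equivalent for reachability
and depth.  A term's *depth* is the length of the shortest path from its
namespace root, the root itself sitting at depth zero.  Two genes' annotation
sets are combined into the pair's *most specific shared functions*: the minimal
elements of the intersection of their reflexive ancestor closures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import obonet

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: relations kept when loading; every other edge type is dropped
EDGE_WHITELIST = frozenset({"is_a", "part_of"})


class OntologyError(ValueError):
    """Raised for structural problems in an ontology or annotation input."""


@dataclass(frozen=True)
class OntologyTerm:
    id: str
    name: str
    namespace: str
    obsolete: bool = False


@dataclass
class OntologyGraph:
    """Rooted DAG of ontology terms with typed is_a/part_of edges.

    ``parents`` maps a term to its ``(parent_id, relation)`` pairs; ``roots``
    maps each namespace to its single parentless term.  Alternate ids are kept
    so annotation files referring to merged terms resolve to primary ids.
    """

    terms: dict[str, OntologyTerm]
    parents: dict[str, tuple[tuple[str, str], ...]]
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.children: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, rels in self.parents.items():
            for parent, _ in rels:
                if parent not in self.terms:
                    raise OntologyError(
                        f"term {child!r} references unknown parent {parent!r}"
                    )
                self.children[parent].add(child)
        self._assert_acyclic()
        self.roots: dict[str, str] = {}
        for tid, term in self.terms.items():
            if not self.parents.get(tid):
                if term.namespace in self.roots:
                    raise OntologyError(
                        f"namespace {term.namespace!r} has multiple roots: "
                        f"{self.roots[term.namespace]!r} and {tid!r}"
                    )
                self.roots[term.namespace] = tid
        for child, rels in self.parents.items():
            ns = self.terms[child].namespace
            for parent, _ in rels:
                if self.terms[parent].namespace != ns:
                    raise OntologyError(
                        f"edge {child!r} -> {parent!r} crosses namespaces"
                    )
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._depth_cache: dict[str, int] = {}

    def _assert_acyclic(self) -> None:
        # iterative three-color DFS; names one cycle member on failure
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {t: WHITE for t in self.terms}
        for start in self.terms:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            while stack:
                node, idx = stack[-1]
                if idx == 0:
                    color[node] = GRAY
                rels = self.parents.get(node, ())
                if idx < len(rels):
                    stack[-1] = (node, idx + 1)
                    nxt = rels[idx][0]
                    if color[nxt] == GRAY:
                        raise OntologyError(f"cycle detected involving term {nxt!r}")
                    if color[nxt] == WHITE:
                        stack.append((nxt, 0))
                else:
                    color[node] = BLACK
                    stack.pop()

    # -- lookups -----------------------------------------------------------

    def resolve(self, term_id: str) -> str | None:
        """Primary id for ``term_id`` (itself, via alt_id, or None if unknown)."""
        if term_id in self.terms:
            return term_id
        return self.alt_ids.get(term_id)

    def namespace_of(self, term_id: str) -> str:
        return self.terms[self._require(term_id)].namespace

    def _require(self, term_id: str) -> str:
        primary = self.resolve(term_id)
        if primary is None:
            raise OntologyError(f"unknown term {term_id!r}")
        return primary

    # -- relations ---------------------------------------------------------

    def reflexive_ancestors(self, term_id: str) -> frozenset[str]:
        """The term itself plus everything reachable via is_a/part_of parents."""
        tid = self._require(term_id)
        cached = self._ancestor_cache.get(tid)
        if cached is not None:
            return cached
        out = {tid}
        stack = [tid]
        while stack:
            node = stack.pop()
            for parent, _ in self.parents.get(node, ()):
                if parent not in out:
                    out.add(parent)
                    stack.append(parent)
        result = frozenset(out)
        self._ancestor_cache[tid] = result
        return result

    def depth(self, term_id: str) -> int:
        """Minimum number of edges from the namespace root, both edge types."""
        tid = self._require(term_id)
        if not self._depth_cache:
            self._compute_depths()
        return self._depth_cache[tid]

    def _compute_depths(self) -> None:
        from collections import deque

        for root in self.roots.values():
            queue = deque([(root, 0)])
            while queue:
                node, d = queue.popleft()
                if node in self._depth_cache:
                    continue
                self._depth_cache[node] = d
                for child in self.children.get(node, ()):
                    if child not in self._depth_cache:
                        queue.append((child, d + 1))

    def namespace_terms(self, namespace: str) -> list[str]:
        return sorted(t for t, term in self.terms.items() if term.namespace == namespace)


def parse_obo(source) -> OntologyGraph:
    """Load an OBO 1.2 stream or path into an :class:`OntologyGraph`.

    Keeps non-obsolete terms, ``is_a`` and ``relationship: part_of`` edges only;
    alternate ids are recorded for later resolution.  Fails on empty input,
    references to unknown parents, and cycles.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    graph = obonet.read_obo(source, ignore_obsolete=True)
    if graph.number_of_nodes() == 0:
        raise OntologyError("empty ontology: no term stanzas found")

    terms: dict[str, OntologyTerm] = {}
    alt_ids: dict[str, str] = {}
    for tid, data in graph.nodes(data=True):
        if "name" not in data or "namespace" not in data:
            # node materialized only as an edge target
            raise OntologyError(f"term {tid!r} referenced but never defined")
        terms[tid] = OntologyTerm(id=tid, name=data["name"], namespace=data["namespace"])
        for alt in data.get("alt_id", ()):
            alt_ids[alt] = tid

    parents: dict[str, list[tuple[str, str]]] = {t: [] for t in terms}
    for child, parent, rel in graph.edges(keys=True):
        if rel in EDGE_WHITELIST:
            parents[child].append((parent, rel))
    return OntologyGraph(
        terms=terms,
        parents={t: tuple(sorted(p)) for t, p in parents.items()},
        alt_ids=alt_ids,
    )


def most_specific_shared_terms(
    graph: OntologyGraph,
    terms_a: Iterable[str],
    terms_b: Iterable[str],
    min_depth: int = 1,
) -> frozenset[str]:
    """Minimal common (reflexive) ancestors of two annotation sets.

    Computes the intersection of the union-of-ancestor closures of the two
    sets, drops terms shallower than ``min_depth``, and keeps only the minimal
    elements (terms with no proper descendant also in the intersection).
    Raises on empty input; an empty *result* means "no shared functions".
    """
    terms_a, terms_b = list(terms_a), list(terms_b)
    if not terms_a or not terms_b:
        raise OntologyError("most_specific_shared_terms requires nonempty term sets")
    closure_a: set[str] = set().union(*(graph.reflexive_ancestors(t) for t in terms_a))
    closure_b: set[str] = set().union(*(graph.reflexive_ancestors(t) for t in terms_b))
    common = {t for t in closure_a & closure_b if graph.depth(t) >= min_depth}
    minimal = {
        t
        for t in common
        if not any(t in graph.reflexive_ancestors(o) for o in common if o != t)
    }
    return frozenset(minimal)
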