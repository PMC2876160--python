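"""Information content, Resnik term similarity, and optimal-assignment profile similarity.

IC of a term is the negative natural log of its annotation probability in the
corpus, counted descendant-inclusively: p(t) = genes annotated to t or any
descendant / genes annotated anywhere in t's namespace.  Resnik similarity of
two terms is the IC of their most informative common ancestor.  Two
shared-function profiles are compared by maximum-weight injective matching of
the smaller profile into the larger (optimal assignment), averaged over the
number of matched terms, and finally normalized by the geometric mean of the
profiles' self-similarities so coefficients live on [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .ontology import OntologyError, OntologyGraph
from .annotations import AnnotationSet
from .pairs import DuplicatePair


@dataclass
class InformationContentTable:
    """Per-term IC (natural-log units) with the underlying inclusive counts."""

    ic: dict[str, float]
    counts: dict[str, int]
    corpus_size: dict[str, int]  # per namespace

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __getitem__(self, term: str) -> float:
        if term not in self.ic:
            raise KeyError(f"term {term!r} has no annotated descendants; IC undefined")
        return self.ic[term]

    def get(self, term: str, default: float | None = None) -> float | None:
        return self.ic.get(term, default)


def information_content(
    annotations: AnnotationSet, graph: OntologyGraph
) -> InformationContentTable:
    """IC(t) = -ln p(t) with descendant-inclusive annotation counts per namespace."""
    ic: dict[str, float] = {}
    counts: dict[str, int] = {}
    corpus: dict[str, int] = {}
    for ns, root in graph.roots.items():
        index = annotations.inclusive_gene_index(graph, ns)
        n_genes = len(annotations.genes(ns))
        if n_genes == 0:
            raise OntologyError(f"namespace {ns!r} has no annotated genes")
        corpus[ns] = n_genes
        for term, genes in index.items():
            counts[term] = len(genes)
            ic[term] = -math.log(len(genes) / n_genes)
        # the root subsumes every annotated gene, so IC(root) is exactly 0
        if root in ic:
            ic[root] = 0.0
    return InformationContentTable(ic=ic, counts=counts, corpus_size=corpus)


def resnik_similarity(
    ic: InformationContentTable, graph: OntologyGraph, t1: str, t2: str
) -> float:
    """IC of the most informative common (reflexive) ancestor of t1 and t2.

    Ancestors without a defined IC (no annotated descendants) are skipped; the
    namespace root, which always has IC 0, keeps the value well defined.
    """
    if graph.namespace_of(t1) != graph.namespace_of(t2):
        raise OntologyError(f"terms {t1!r} and {t2!r} are in different namespaces")
    common = graph.reflexive_ancestors(t1) & graph.reflexive_ancestors(t2)
    return max((ic.ic[a] for a in common if a in ic.ic), default=0.0)


def optimal_assignment_similarity(
    profile1,
    profile2,
    ic: InformationContentTable,
    graph: OntologyGraph,
) -> float:
    """Maximum-weight injective matching of the smaller profile into the larger.

    Returns the best achievable sum of Resnik term-term similarities over all
    injective assignments, divided by the number of matched terms.  Terms are
    sorted lexicographically before matching so ties resolve reproducibly.
    """
    p1, p2 = sorted(profile1), sorted(profile2)
    if not p1 or not p2:
        raise OntologyError("optimal_assignment_similarity requires nonempty profiles")
    if len(p1) > len(p2):
        p1, p2 = p2, p1
    weights = np.array(
        [[resnik_similarity(ic, graph, a, b) for b in p2] for a in p1]
    )
    rows, cols = linear_sum_assignment(-weights)
    return float(weights[rows, cols].sum()) / len(p1)


@dataclass
class ProfileSimilarityMatrix:
    """Symmetric pairwise functional-similarity coefficients over duplicate pairs."""

    pair_ids: list[str]
    values: np.ndarray  # normalized, in [0, 1], unit diagonal
    raw: np.ndarray  # unnormalized optimal-assignment values (kept for audit)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.pair_ids), len(self.pair_ids)):
            raise ValueError("similarity matrix shape does not match pair ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")


def profile_similarity_matrix(
    pairs: list[DuplicatePair],
    ic: InformationContentTable,
    graph: OntologyGraph,
    namespace: str,
) -> ProfileSimilarityMatrix:
    """All-vs-all optimal-assignment similarity of the pairs' shared-function profiles.

    Entries are normalized by the geometric mean of the two self-similarities
    (and capped at 1, which unequal profile sizes can otherwise exceed); the
    diagonal is exactly 1.  Pairs whose profile carries zero total IC cannot be
    normalized and are rejected.
    """
    profiles = []
    for p in pairs:
        prof = sorted(p.shared_functions.get(namespace, ()))
        if not prof:
            raise OntologyError(f"pair {p.pair_id} has an empty profile in {namespace}")
        profiles.append(prof)
    # precompute term-term Resnik over the profile term universe once
    universe = sorted(set().union(*profiles))
    tidx = {t: k for k, t in enumerate(universe)}
    tsim = np.zeros((len(universe), len(universe)))
    for a_i, a in enumerate(universe):
        for b_i in range(a_i, len(universe)):
            b = universe[b_i]
            tsim[a_i, b_i] = tsim[b_i, a_i] = resnik_similarity(ic, graph, a, b)
    idx_profiles = [np.array([tidx[t] for t in prof]) for prof in profiles]

    def _oa(i: int, j: int) -> float:
        a, b = idx_profiles[i], idx_profiles[j]
        if len(a) > len(b):
            a, b = b, a
        weights = tsim[np.ix_(a, b)]
        rows, cols = linear_sum_assignment(-weights)
        return float(weights[rows, cols].sum()) / len(a)

    n = len(pairs)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            raw[i, j] = raw[j, i] = _oa(i, j)
    self_sim = np.diag(raw)
    zero = [pairs[i].pair_id for i in np.flatnonzero(self_sim <= 0.0)]
    if zero:
        raise OntologyError(
            "pairs with zero self-similarity (profiles of only IC-0 terms): "
            + ", ".join(zero)
        )
    norm = raw / np.sqrt(np.outer(self_sim, self_sim))
    np.fill_diagonal(norm, 1.0)
    norm = np.minimum(norm, 1.0)
    return ProfileSimilarityMatrix(
        pair_ids=[p.pair_id for p in pairs], values=norm, raw=raw
    )
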