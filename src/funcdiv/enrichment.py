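"""GO term over-representation per functional group: parent-child union test.

Classic term-for-term enrichment treats a term's study count against the whole
population, which inflates significance for terms whose parents are themselves
enriched.  The parent-child union statistic conditions on the genes annotated
to the union of the term's parents: within that gene set U, the study's draw of
term-annotated genes is compared with a hypergeometric upper tail,

    p = P(X >= k),  X ~ Hypergeom(|U ∩ pop|, |term ∩ pop|, |U ∩ study|).

Per group, every term annotated to at least one study gene (and having a
parent) is tested and Bonferroni-corrected by the number of tests in that run.
A classic Fisher mode is available behind a flag for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom

from .annotations import AnnotationSet
from .cluster import FunctionalGroup
from .ontology import OntologyGraph
from .pairs import DuplicatePair

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    name: str
    study_count: int  # study genes annotated to the term
    study_union: int  # study genes annotated to the parents' union
    population_count: int  # population genes annotated to the term (within U)
    population_union: int  # population genes in the parents' union
    p_raw: float
    p_adjusted: float
    skipped: bool = False  # root terms (no parents) are not testable


def parent_child_union_test(
    term: str,
    study_genes: frozenset,
    population_genes: frozenset,
    annotations: AnnotationSet,
    graph: OntologyGraph,
) -> EnrichmentRecord:
    """Hypergeometric upper-tail p for one term under parent-child union conditioning."""
    tid = graph.resolve(term)
    if tid is None:
        raise EnrichmentError(f"unknown term {term!r}")
    if not study_genes <= population_genes:
        raise EnrichmentError("study genes must be a subset of the population")
    namespace = graph.namespace_of(tid)
    parents = [p for p, _ in graph.parents.get(tid, ())]
    name = graph.terms[tid].name
    if not parents:
        return EnrichmentRecord(tid, name, 0, 0, 0, 0, 1.0, 1.0, skipped=True)
    index = annotations.inclusive_gene_index(graph, namespace)
    union_genes = frozenset().union(*(index.get(p, frozenset()) for p in parents))
    term_genes = index.get(tid, frozenset())
    m_pop = len(union_genes & population_genes)
    n_succ = len(term_genes & population_genes & union_genes)
    n_draw = len(union_genes & study_genes)
    k_obs = len(term_genes & study_genes)
    if n_draw == 0 or k_obs == 0:
        p_raw = 1.0
    else:
        p_raw = float(hypergeom.sf(k_obs - 1, m_pop, n_succ, n_draw))
    return EnrichmentRecord(
        term=tid,
        name=name,
        study_count=k_obs,
        study_union=n_draw,
        population_count=n_succ,
        population_union=m_pop,
        p_raw=min(max(p_raw, 0.0), 1.0),
        p_adjusted=p_raw,  # corrected by the caller once the test count is known
    )


def term_for_term_test(
    term: str,
    study_genes: frozenset,
    population_genes: frozenset,
    annotations: AnnotationSet,
    graph: OntologyGraph,
) -> EnrichmentRecord:
    """Classic Fisher/hypergeometric enrichment (comparison mode)."""
    tid = graph.resolve(term)
    if tid is None:
        raise EnrichmentError(f"unknown term {term!r}")
    namespace = graph.namespace_of(tid)
    index = annotations.inclusive_gene_index(graph, namespace)
    term_genes = index.get(tid, frozenset())
    m_pop = len(population_genes)
    n_succ = len(term_genes & population_genes)
    n_draw = len(study_genes)
    k_obs = len(term_genes & study_genes)
    p_raw = 1.0 if k_obs == 0 else float(hypergeom.sf(k_obs - 1, m_pop, n_succ, n_draw))
    return EnrichmentRecord(
        term=tid,
        name=graph.terms[tid].name,
        study_count=k_obs,
        study_union=n_draw,
        population_count=n_succ,
        population_union=m_pop,
        p_raw=min(max(p_raw, 0.0), 1.0),
        p_adjusted=p_raw,
    )


@dataclass
class GroupEnrichment:
    group_id: str
    records: list[EnrichmentRecord]  # sorted by adjusted p, then term id
    n_tested: int

    @property
    def top3(self) -> list[EnrichmentRecord]:
        return self.records[:3]


def enrich_groups(
    groups: list[FunctionalGroup],
    pairs_by_id: dict[str, DuplicatePair],
    annotations: AnnotationSet,
    graph: OntologyGraph,
    population_genes: frozenset,
    namespace: str,
    method: str = "parent_child_union",
) -> list[GroupEnrichment]:
    """Run per-group enrichment over all terms annotated to >=1 study gene.

    The study set of a group is the union of both genes of its member pairs;
    Bonferroni multiplicity is the number of terms actually tested per group.
    """
    test = {
        "parent_child_union": parent_child_union_test,
        "term_for_term": term_for_term_test,
    }[method]
    index = annotations.inclusive_gene_index(graph, namespace)
    root = graph.roots[namespace]
    results = []
    for group in groups:
        study: set = set()
        for pid in group.members:
            study |= pairs_by_id[pid].genes
        study = frozenset(study) & population_genes
        if not study:
            logger.warning("group %s has no study genes; skipped", group.group_id)
            continue
        candidate_terms = sorted(
            t for t, genes in index.items() if t != root and genes & study
        )
        records = []
        for term in candidate_terms:
            rec = test(term, study, population_genes, annotations, graph)
            if not rec.skipped:
                records.append(rec)
        m = len(records)
        records = [
            EnrichmentRecord(
                term=r.term,
                name=r.name,
                study_count=r.study_count,
                study_union=r.study_union,
                population_count=r.population_count,
                population_union=r.population_union,
                p_raw=r.p_raw,
                p_adjusted=min(1.0, r.p_raw * m),
            )
            for r in records
        ]
        records.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term))
        results.append(GroupEnrichment(group_id=group.group_id, records=records, n_tested=m))
    return results
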