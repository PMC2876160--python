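"""GAF annotation parsing and the gene/term indexes used downstream.

Annotations are kept as flat (gene, term, evidence, namespace) records.  Two
views matter downstream: per-gene term sets after an evidence-code filter (for
shared-function labeling) and per-term *descendant-inclusive* gene sets (for
information content and enrichment), where a gene annotated to a term also
counts for every ancestor of that term.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

from .ontology import OntologyError, OntologyGraph

logger = logging.getLogger(__name__)

ASPECT_TO_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}

#: evidence codes treated as "not curated or experimentally assigned"
DEFAULT_EVIDENCE_BLACKLIST = frozenset({"IEA", "ND"})


@dataclass(frozen=True)
class AnnotationRecord:
    gene: str
    term: str
    evidence: str
    namespace: str


@dataclass
class AnnotationSet:
    records: tuple[AnnotationRecord, ...]
    dropped_unknown_terms: int = 0
    _gene_index: dict = field(default_factory=dict, repr=False)
    _inclusive_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        # collapse duplicate (gene, term, evidence) triples, keep stable order
        seen: dict[tuple[str, str, str], AnnotationRecord] = {}
        for rec in self.records:
            seen.setdefault((rec.gene, rec.term, rec.evidence), rec)
        object.__setattr__(self, "records", tuple(seen.values()))
        for rec in self.records:
            self._gene_index.setdefault(rec.gene, []).append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def genes(self, namespace: str | None = None) -> frozenset[str]:
        return frozenset(
            r.gene for r in self.records if namespace in (None, r.namespace)
        )

    def terms_for_gene(
        self,
        gene: str,
        namespace: str | None = None,
        exclude_evidence: frozenset[str] = frozenset(),
    ) -> frozenset[str]:
        return frozenset(
            r.term
            for r in self._gene_index.get(gene, ())
            if namespace in (None, r.namespace) and r.evidence not in exclude_evidence
        )

    def has_curated_annotation(
        self, gene: str, blacklist: frozenset[str] = DEFAULT_EVIDENCE_BLACKLIST
    ) -> bool:
        return any(r.evidence not in blacklist for r in self._gene_index.get(gene, ()))

    def inclusive_gene_index(
        self, graph: OntologyGraph, namespace: str
    ) -> dict[str, frozenset[str]]:
        """term -> genes annotated to the term or any of its descendants."""
        if namespace not in self._inclusive_cache:
            acc: dict[str, set[str]] = {}
            for rec in self.records:
                if rec.namespace != namespace:
                    continue
                for anc in graph.reflexive_ancestors(rec.term):
                    acc.setdefault(anc, set()).add(rec.gene)
            self._inclusive_cache[namespace] = {
                t: frozenset(g) for t, g in acc.items()
            }
        return self._inclusive_cache[namespace]


def parse_gaf(source, graph: OntologyGraph) -> AnnotationSet:
    """Parse GAF 2.x tab-separated lines against a loaded ontology.

    Uses the DB_Object_ID, GO_ID, Evidence and Aspect columns; rows whose
    qualifier contains NOT are dropped, alternate ids are resolved, and rows
    naming terms absent from the graph are dropped with a logged count.
    """
    if isinstance(source, str) and ("\n" in source or "\t" in source):
        source = io.StringIO(source)
    if isinstance(source, (str, bytes)):
        handle = open(source)
        close = True
    else:
        handle, close = source, False
    records: list[AnnotationRecord] = []
    dropped_unknown = 0
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                raise OntologyError(
                    f"GAF line {lineno}: expected >=15 tab-separated columns, got {len(cols)}"
                )
            gene, qualifier, go_id, evidence, aspect = (
                cols[1],
                cols[3],
                cols[4],
                cols[6],
                cols[8],
            )
            if "NOT" in qualifier.split("|"):
                continue
            primary = graph.resolve(go_id)
            if primary is None:
                dropped_unknown += 1
                continue
            namespace = ASPECT_TO_NAMESPACE.get(aspect) or graph.namespace_of(primary)
            records.append(
                AnnotationRecord(
                    gene=gene, term=primary, evidence=evidence, namespace=namespace
                )
            )
    finally:
        if close:
            handle.close()
    if not records:
        raise OntologyError("GAF stream contained no usable annotation records")
    if dropped_unknown:
        logger.info("parse_gaf: dropped %d records to unknown terms", dropped_unknown)
    return AnnotationSet(records=tuple(records), dropped_unknown_terms=dropped_unknown)
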