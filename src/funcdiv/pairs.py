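"""Duplicate gene pairs: the clustered units of the analysis.

A duplicate pair carries two gene ids (canonically ordered), a per-namespace
shared-function profile, and a copy-number class ("single" if neither gene has
further duplicates after the whole-genome duplication, "multiple" otherwise).

``filter_pairs`` applies the two quality stages: pairs where either gene lacks
a curated/experimental annotation are dropped first; then, per namespace, a
pair whose most specific shared functions (at the required minimum depth) are
empty drops out of that namespace's analysis.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

from .annotations import DEFAULT_EVIDENCE_BLACKLIST, AnnotationSet
from .ontology import NAMESPACES, OntologyError, OntologyGraph, most_specific_shared_terms

logger = logging.getLogger(__name__)

COPY_NUMBER_CLASSES = ("single", "multiple")


@dataclass(frozen=True)
class DuplicatePair:
    gene1: str
    gene2: str
    shared_functions: dict = field(default_factory=dict, compare=False)
    copy_number_class: str = "single"

    def __post_init__(self) -> None:
        if self.gene1 == self.gene2:
            raise ValueError(f"degenerate pair: {self.gene1!r} duplicated with itself")
        if self.gene1 > self.gene2:  # canonical unordered representation
            g1, g2 = self.gene2, self.gene1
            object.__setattr__(self, "gene1", g1)
            object.__setattr__(self, "gene2", g2)
        if self.copy_number_class not in COPY_NUMBER_CLASSES:
            raise ValueError(f"unknown copy-number class {self.copy_number_class!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene1, self.gene2)

    @property
    def pair_id(self) -> str:
        return f"{self.gene1}--{self.gene2}"

    @property
    def genes(self) -> frozenset[str]:
        return frozenset((self.gene1, self.gene2))


def read_pairs(source) -> list[DuplicatePair]:
    """Two-column TSV of gene ids; optional third column is the copy-number class.

    A header line is tolerated (detected as a first line whose third column, if
    any, is not a known class and whose genes never reappear); comments start
    with ``#``.
    """
    if isinstance(source, str) and ("\n" in source or "\t" in source):
        source = io.StringIO(source)
    if isinstance(source, (str, bytes)):
        handle, close = open(source), True
    else:
        handle, close = source, False
    pairs: list[DuplicatePair] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"pair list line {lineno}: expected >=2 columns")
            if lineno == 1 and cols[0].lower() in {"gene1", "gene_1", "gene_a"}:
                continue
            copy_class = cols[2] if len(cols) > 2 and cols[2] else "single"
            pairs.append(
                DuplicatePair(gene1=cols[0], gene2=cols[1], copy_number_class=copy_class)
            )
    finally:
        if close:
            handle.close()
    return pairs


@dataclass
class FilterResult:
    """Retained pairs with populated shared-function profiles plus funnel counts."""

    pairs: list[DuplicatePair]
    counts: dict

    def pairs_for_namespace(self, namespace: str) -> list[DuplicatePair]:
        return [p for p in self.pairs if p.shared_functions.get(namespace)]


def filter_pairs(
    pairs: list[DuplicatePair],
    annotations: AnnotationSet,
    graph: OntologyGraph,
    evidence_blacklist: frozenset[str] = DEFAULT_EVIDENCE_BLACKLIST,
    min_depth: int = 1,
) -> FilterResult:
    """Evidence-code filter, then per-namespace shared-function labeling.

    Stage 1 removes a pair when either gene has no annotation outside the
    evidence blacklist (genes absent from the annotation index count as
    unannotated).  Stage 2 labels each surviving pair with its most specific
    shared functions per namespace, at depth >= ``min_depth``; a pair with an
    empty profile in a namespace leaves that namespace's analysis set.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    counts: dict = {"input": len(pairs)}
    stage1: list[DuplicatePair] = []
    unannotated = 0
    for pair in pairs:
        ok = True
        for gene in (pair.gene1, pair.gene2):
            if not annotations.terms_for_gene(gene):
                unannotated += 1
                ok = False
            elif not annotations.has_curated_annotation(gene, evidence_blacklist):
                ok = False
        if ok:
            stage1.append(pair)
    if unannotated:
        logger.info("filter_pairs: %d genes absent from the annotation index", unannotated)
    counts["after_evidence"] = len(stage1)
    counts["dropped_evidence"] = len(pairs) - len(stage1)

    labeled: list[DuplicatePair] = []
    per_ns = {ns: 0 for ns in NAMESPACES}
    for pair in stage1:
        shared: dict[str, frozenset[str]] = {}
        for ns in NAMESPACES:
            t1 = annotations.terms_for_gene(pair.gene1, ns, evidence_blacklist)
            t2 = annotations.terms_for_gene(pair.gene2, ns, evidence_blacklist)
            if not t1 or not t2:
                shared[ns] = frozenset()
                continue
            try:
                shared[ns] = most_specific_shared_terms(graph, t1, t2, min_depth)
            except OntologyError:
                shared[ns] = frozenset()
            if shared[ns]:
                per_ns[ns] += 1
        labeled.append(replace(pair, shared_functions=shared))

    retained = [p for p in labeled if any(p.shared_functions.values())]
    counts["after_shared"] = {ns: per_ns[ns] for ns in NAMESPACES}
    counts["retained_any_namespace"] = len(retained)
    counts["dropped_no_shared"] = len(stage1) - len(retained)
    return FilterResult(pairs=retained, counts=counts)
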