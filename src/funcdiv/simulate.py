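"""Synthetic studies with planted structure for every downstream stage.

A study consists of: a layered random ontology per namespace with K designated
"family anchor" terms (pairwise non-ancestral, depth 3); duplicate pairs whose
genes are annotated to the descendants of their family's anchor (so planted
family membership is recoverable from functional profiles); per-pair dN/dS
values drawn from family-dependent truncated normals; diverged coding-sequence
pairs carrying controlled counts of synonymous and nonsynonymous single-base
substitutions; and a genome layout for the chromosomal-location analysis.

Every generator is a pure function of (config, seed), so studies are fully
reproducible, and every generated study passes the real pipeline's validators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .annotations import AnnotationRecord, AnnotationSet
from .divergence import BASES, CODON_TO_AA, SENSE_CODONS, STOP_CODONS, _SYN_SITES
from .ontology import NAMESPACES, OntologyGraph, OntologyTerm
from .pairs import DuplicatePair

CURATED_EVIDENCE = ("IDA", "IMP", "TAS", "IGI")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-level knobs; defaults give a seconds-scale study with 6 x 30 pairs.

    The electronic-annotation fraction of 0.08 per gene drops roughly 15% of
    pairs at the evidence filter while keeping planted families of 30 pairs
    above the min-size-20 grouping threshold with high probability, so the
    planted partition stays recoverable.  Family omega means span
    [0.03, 0.45] (SD 0.06, truncated to [0, 0.8]), echoing the contrast
    between slowly evolving translation-machinery genes and fast
    defense-response genes.
    """

    n_terms: int = 300  # per namespace
    n_layer1: int = 8
    n_layer2: int = 16
    n_background_layer3: int = 8
    anchor_block_size: int = 12
    part_of_fraction: float = 0.2
    n_families: int = 6
    pairs_per_family: int = 30
    iea_fraction: float = 0.08
    annotations_per_gene: int = 3
    background_annotation_prob: float = 0.5
    family_omega_means: tuple = ()
    omega_sd: float = 0.06
    omega_bounds: tuple = (0.0, 0.8)
    cds_codons: int = 300
    syn_substitutions: int = 25
    multiple_duplicate_probs: tuple = ()
    chromosome_lengths: tuple = (30_000_000,) * 5
    centromere_fraction: float = 0.5
    gene_length: int = 2000
    planted_location_correlation: float = 0.0

    def __post_init__(self) -> None:
        k = self.n_families
        if not self.family_omega_means:
            self.family_omega_means = tuple(np.linspace(0.03, 0.45, k))
        if not self.multiple_duplicate_probs:
            self.multiple_duplicate_probs = tuple(np.linspace(0.1, 0.7, k))
        if len(self.family_omega_means) != k or len(self.multiple_duplicate_probs) != k:
            raise SimulationError("per-family parameter lengths must equal n_families")
        lo, hi = self.omega_bounds
        if not (0 <= lo < hi < 2):
            raise SimulationError("omega bounds must satisfy 0 <= lo < hi < 2")
        for m in self.family_omega_means:
            if not lo <= m <= hi:
                raise SimulationError(f"family omega mean {m} outside bounds {self.omega_bounds}")
        for p in (self.part_of_fraction, self.iea_fraction, *self.multiple_duplicate_probs):
            if not 0 <= p <= 1:
                raise SimulationError(f"probability {p} outside [0, 1]")
        if self.pairs_per_family < 1:
            raise SimulationError("family sizes must be >= 1")
        fixed = (
            1 + self.n_layer1 + self.n_layer2 + self.n_background_layer3
            + k * (1 + self.anchor_block_size)
        )
        if self.n_terms < fixed:
            raise SimulationError(
                f"n_terms={self.n_terms} too small for {k} anchored families (need >= {fixed})"
            )


# --------------------------------------------------------------------------
# ontology
# --------------------------------------------------------------------------


def simulate_ontology(config: SimulationConfig, seed: int):
    """Layered random DAG per namespace; returns (graph, anchors per namespace).

    Layers: root (depth 0), layer 1, layer 2 "hub" terms, then K anchors at
    depth 3 whose parents are hubs shared between neighboring families (so
    anchors stay distinguishable from their own ancestors under enrichment),
    a block of dedicated descendants per anchor, background layer-3 terms,
    and remaining background terms attached under layers 1-3.  Non-root terms
    get a second parent (a part_of edge) with the configured probability.
    """
    rng = np.random.default_rng(seed)
    terms: dict[str, OntologyTerm] = {}
    parents: dict[str, list[tuple[str, str]]] = {}
    anchors: dict[str, list[str]] = {}
    counter = 0

    def new_term(ns: str, label: str) -> str:
        nonlocal counter
        counter += 1
        tid = f"SY:{counter:07d}"
        terms[tid] = OntologyTerm(id=tid, name=f"{label} {counter}", namespace=ns)
        parents[tid] = []
        return tid

    def rel() -> str:
        return "part_of" if rng.random() < config.part_of_fraction else "is_a"

    for ns in NAMESPACES:
        root = new_term(ns, f"{ns} root")
        layer1 = [new_term(ns, "broad process") for _ in range(config.n_layer1)]
        for t in layer1:
            parents[t].append((root, "is_a"))
        layer2 = [new_term(ns, "hub") for _ in range(config.n_layer2)]
        for t in layer2:
            parents[t].append((rng.choice(layer1), rel()))
            if rng.random() < config.part_of_fraction:
                other = rng.choice(layer1)
                if (other, "part_of") not in parents[t] and other != parents[t][0][0]:
                    parents[t].append((other, "part_of"))

        # anchors: two families share each hub parent so that an anchor's
        # parents are never family-specific
        ns_anchors = []
        hub_order = list(rng.permutation(layer2))
        for k in range(config.n_families):
            anchor = new_term(ns, "family anchor")
            parents[anchor].append((hub_order[k // 2 % len(hub_order)], "is_a"))
            ns_anchors.append(anchor)
        anchors[ns] = ns_anchors

        # each anchor hosts two subfamily branches (duplicated genes tend to
        # subfunctionalize, and the split keeps family subtrees balanced)
        blocks: dict[str, list[str]] = {}
        for anchor in ns_anchors:
            block = []
            n_sub = (config.anchor_block_size - 2) // 2
            for _ in range(2):
                sub_anchor = new_term(ns, "family subprocess")
                parents[sub_anchor].append((anchor, "is_a"))
                branch = [sub_anchor]
                for _ in range(n_sub):
                    t = new_term(ns, "family function")
                    parents[t].append((branch[rng.integers(len(branch))], rel()))
                    if rng.random() < config.part_of_fraction and len(branch) > 1:
                        other = branch[rng.integers(len(branch))]
                        if other != parents[t][0][0]:
                            parents[t].append((other, "part_of"))
                    branch.append(t)
                block.extend(branch)
            blocks[anchor] = block

        bg3 = [new_term(ns, "background") for _ in range(config.n_background_layer3)]
        for t in bg3:
            parents[t].append((rng.choice(layer2), rel()))

        n_left = config.n_terms - (
            1 + len(layer1) + len(layer2) + len(ns_anchors)
            + sum(len(b) for b in blocks.values()) + len(bg3)
        )
        shallow_pool = layer1 + layer2 + bg3
        background = []
        for _ in range(n_left):
            t = new_term(ns, "background")
            pool = shallow_pool + background
            parents[t].append((pool[rng.integers(len(pool))], rel()))
            if rng.random() < config.part_of_fraction:
                other = pool[rng.integers(len(pool))]
                if other != parents[t][0][0]:
                    parents[t].append((other, "part_of"))
            background.append(t)

    graph = OntologyGraph(
        terms=terms, parents={t: tuple(p) for t, p in parents.items()}
    )
    return graph, anchors


# --------------------------------------------------------------------------
# annotations, pairs, truth labels
# --------------------------------------------------------------------------


def _anchor_block(graph: OntologyGraph, anchor: str) -> list[str]:
    out = [t for t in graph.terms if anchor in graph.reflexive_ancestors(t)]
    if len(out) <= 1:
        raise SimulationError(f"anchor {anchor} has no descendants")
    return sorted(out)


def simulate_annotated_pairs(
    graph: OntologyGraph,
    anchors: dict[str, list[str]],
    config: SimulationConfig,
    seed: int,
):
    """Generate annotated duplicate pairs organized into planted families.

    Each gene of a family-k pair is annotated (in every namespace) to a few
    descendants of the family's anchor, plus occasional shallow background
    terms; a configurable fraction of genes carries only IEA evidence.
    Returns (AnnotationSet, pairs, truth labels pair_id -> family index).
    """
    rng = np.random.default_rng(seed)

    def branches(ns: str, anchor: str) -> list[list[str]]:
        subs = sorted(graph.children[anchor])
        out = [_anchor_block(graph, s) for s in subs]
        return out if out else [_anchor_block(graph, anchor)]

    blocks = {ns: [branches(ns, a) for a in anchors[ns]] for ns in NAMESPACES}
    background_pool = {
        ns: [
            t
            for t in graph.namespace_terms(ns)
            if graph.depth(t) in (1, 2)
            and not any(
                a in graph.reflexive_ancestors(t) for a in anchors[ns]
            )
        ]
        for ns in NAMESPACES
    }
    records: list[AnnotationRecord] = []
    pairs: list[DuplicatePair] = []
    truth: dict[str, int] = {}
    gene_idx = 0
    for fam in range(config.n_families):
        for j in range(config.pairs_per_family):
            gene_idx += 1
            g1, g2 = f"G{gene_idx:04d}A", f"G{gene_idx:04d}B"
            # both genes of a pair annotate within the same subfamily branch
            sub = j % 2
            for gene in (g1, g2):
                iea_only = rng.random() < config.iea_fraction
                for ns in NAMESPACES:
                    fam_branches = blocks[ns][fam]
                    block = fam_branches[sub % len(fam_branches)]
                    n_ann = min(config.annotations_per_gene, len(block))
                    chosen = rng.choice(block, size=n_ann, replace=False)
                    gene_terms = list(chosen)
                    if rng.random() < config.background_annotation_prob:
                        gene_terms.append(rng.choice(background_pool[ns]))
                    for t in gene_terms:
                        evidence = (
                            "IEA"
                            if iea_only
                            else CURATED_EVIDENCE[rng.integers(len(CURATED_EVIDENCE))]
                        )
                        records.append(
                            AnnotationRecord(
                                gene=gene,
                                term=str(t),
                                evidence=evidence,
                                namespace=ns,
                            )
                        )
            copy_class = (
                "multiple"
                if rng.random() < config.multiple_duplicate_probs[fam]
                else "single"
            )
            pair = DuplicatePair(gene1=g1, gene2=g2, copy_number_class=copy_class)
            pairs.append(pair)
            truth[pair.pair_id] = fam
    return AnnotationSet(records=tuple(records)), pairs, truth


# --------------------------------------------------------------------------
# omega values
# --------------------------------------------------------------------------


def simulate_omega(
    truth: dict[str, int], config: SimulationConfig, seed: int
) -> dict[str, float]:
    """Per-pair dN/dS from a truncated normal with the family's mean and SD."""
    rng = np.random.default_rng(seed)
    lo, hi = config.omega_bounds
    out: dict[str, float] = {}
    for pair_id in sorted(truth):
        mu = config.family_omega_means[truth[pair_id]]
        if not lo <= mu <= hi:
            raise SimulationError(f"family mean {mu} outside omega bounds")
        sd = config.omega_sd
        if sd == 0:
            out[pair_id] = float(mu)
        else:
            a, b = (lo - mu) / sd, (hi - mu) / sd
            out[pair_id] = float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
    return out


# --------------------------------------------------------------------------
# coding sequences
# --------------------------------------------------------------------------

_SYN_NEIGHBORS: dict[str, list[str]] = {}
_NONSYN_NEIGHBORS: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    syn, non = [], []
    for _pos in range(3):
        for _b in BASES:
            if _b == _c[_pos]:
                continue
            _n = _c[:_pos] + _b + _c[_pos + 1 :]
            if _n in STOP_CODONS:
                continue
            (syn if CODON_TO_AA[_n] == CODON_TO_AA[_c] else non).append(_n)
    _SYN_NEIGHBORS[_c] = sorted(syn)
    _NONSYN_NEIGHBORS[_c] = sorted(non)

_SYN_CAPABLE = tuple(c for c in SENSE_CODONS if _SYN_NEIGHBORS[c])
_NONSYN_CAPABLE = tuple(c for c in SENSE_CODONS if _NONSYN_NEIGHBORS[c])


def _translate(cds: str) -> str:
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


def simulate_cds_pair(n_codons: int, n_syn: int, n_nonsyn: int, seed: int):
    """Diverged CDS pair with exact single-base substitution counts.

    Copy 2 differs from copy 1 by exactly ``n_syn`` synonymous and ``n_nonsyn``
    nonsynonymous single-base changes at distinct codons; no stop codons are
    ever created.  Returns (cds1, cds2, protein1, protein2, truth) where truth
    carries the planted counts and the per-site proportions computed on the
    ancestral sequence's site counts.
    """
    if n_syn + n_nonsyn > n_codons:
        raise SimulationError("more substitutions requested than codons available")
    rng = np.random.default_rng(seed)
    ancestor = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    positions = rng.permutation(n_codons)
    syn_pos = positions[:n_syn]
    nonsyn_pos = positions[n_syn : n_syn + n_nonsyn]
    # ensure targeted codons can host the requested change type
    for p in syn_pos:
        if not _SYN_NEIGHBORS[ancestor[p]]:
            ancestor[p] = _SYN_CAPABLE[rng.integers(len(_SYN_CAPABLE))]
    for p in nonsyn_pos:
        if not _NONSYN_NEIGHBORS[ancestor[p]]:
            ancestor[p] = _NONSYN_CAPABLE[rng.integers(len(_NONSYN_CAPABLE))]
    derived = list(ancestor)
    for p in syn_pos:
        opts = _SYN_NEIGHBORS[ancestor[p]]
        derived[p] = opts[rng.integers(len(opts))]
    for p in nonsyn_pos:
        opts = _NONSYN_NEIGHBORS[ancestor[p]]
        derived[p] = opts[rng.integers(len(opts))]
    cds1, cds2 = "".join(ancestor), "".join(derived)
    s_sites = sum(_SYN_SITES[c] for c in ancestor)
    n_sites = 3 * n_codons - s_sites
    truth = {
        "n_syn": n_syn,
        "n_nonsyn": n_nonsyn,
        "s_sites": s_sites,
        "n_sites": n_sites,
        "p_syn": n_syn / s_sites if s_sites else 0.0,
        "p_nonsyn": n_nonsyn / n_sites if n_sites else 0.0,
    }
    return cds1, cds2, _translate(cds1), _translate(cds2), truth


# --------------------------------------------------------------------------
# genome layout
# --------------------------------------------------------------------------


def simulate_layout(
    genes: list[str],
    config: SimulationConfig,
    seed: int,
    omega_by_gene: dict[str, float] | None = None,
):
    """Uniform gene placement on linear chromosomes with central centromeres.

    Returns (layout DataFrame with gene/chrom/start/end/centromere_distance,
    centromere positions).  With a planted correlation rho and per-gene omega
    values, centromere distances are re-assigned to genes by the rank of the
    latent variable rho*z(omega) + sqrt(1-rho^2)*noise, leaving the positional
    marginals untouched.
    """
    rng = np.random.default_rng(seed)
    lengths = [int(x) for x in config.chromosome_lengths]
    if min(lengths) <= config.gene_length:
        raise SimulationError("chromosome shorter than one gene")
    centromeres = {i + 1: int(config.centromere_fraction * L) for i, L in enumerate(lengths)}
    chroms = rng.integers(1, len(lengths) + 1, size=len(genes))
    starts = np.array(
        [rng.integers(0, lengths[c - 1] - config.gene_length) for c in chroms]
    )
    ends = starts + config.gene_length
    mid = (starts + ends) // 2
    dist = np.abs(mid - np.array([centromeres[c] for c in chroms]))

    rho = config.planted_location_correlation
    if rho != 0.0 and omega_by_gene is not None:
        omega = np.array([omega_by_gene[g] for g in genes])
        z = (omega - omega.mean()) / (omega.std() or 1.0)
        latent = rho * z + math.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(len(genes))
        order = np.argsort(np.argsort(latent))
        sorted_rows = np.argsort(dist)
        take = sorted_rows[order]
        chroms, starts, ends, dist = chroms[take], starts[take], ends[take], dist[take]
    layout = pd.DataFrame(
        {
            "gene": genes,
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "centromere_distance": dist,
        }
    )
    return layout, centromeres


# --------------------------------------------------------------------------
# whole studies
# --------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    graph: OntologyGraph
    anchors: dict[str, list[str]]
    annotations: AnnotationSet
    pairs: list[DuplicatePair]
    truth: dict[str, int]  # pair_id -> family index
    omega: dict[str, float]  # pair_id -> planted dN/dS
    proteins: dict[str, str]
    cds: dict[str, str]
    cds_truth: dict[str, dict]
    layout: pd.DataFrame
    centromeres: dict[int, int]

    @property
    def genes(self) -> list[str]:
        return sorted({g for p in self.pairs for g in (p.gene1, p.gene2)})


def simulate_study(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a complete synthetic study, deterministically from (config, seed)."""
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    s_ont, s_ann, s_omega, s_cds, s_layout = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    ]
    graph, anchors = simulate_ontology(config, s_ont)
    annotations, pairs, truth = simulate_annotated_pairs(graph, anchors, config, s_ann)
    omega = simulate_omega(truth, config, s_omega)

    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    cds_truth: dict[str, dict] = {}
    # nonsynonymous count targets the planted omega through the site-count ratio
    ratio = 3.0  # typical N/S site ratio of random sense-codon sequences
    cds_rng = np.random.default_rng(s_cds)
    for pair in pairs:
        w = omega[pair.pair_id]
        n_syn = config.syn_substitutions
        n_nonsyn = int(round(w * n_syn * ratio))
        c1, c2, p1, p2, tr = simulate_cds_pair(
            config.cds_codons, n_syn, n_nonsyn, int(cds_rng.integers(2**31))
        )
        proteins[pair.gene1], proteins[pair.gene2] = p1, p2
        cds[pair.gene1], cds[pair.gene2] = c1, c2
        cds_truth[pair.pair_id] = tr

    genes = sorted({g for p in pairs for g in (p.gene1, p.gene2)})
    omega_by_gene = {
        g: omega[p.pair_id] for p in pairs for g in (p.gene1, p.gene2)
    }
    layout, centromeres = simulate_layout(genes, config, s_layout, omega_by_gene)
    return SyntheticStudy(
        config=config,
        graph=graph,
        anchors=anchors,
        annotations=annotations,
        pairs=pairs,
        truth=truth,
        omega=omega,
        proteins=proteins,
        cds=cds,
        cds_truth=cds_truth,
        layout=layout,
        centromeres=centromeres,
    )
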