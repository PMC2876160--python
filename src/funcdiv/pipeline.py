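"""End-to-end orchestration: filter -> profiles -> similarity -> cluster -> dN/dS ->
ANOVA/Tukey -> enrichment -> report, per GO namespace.

Every stage writes its table under the output directory with a provenance
header; rerunning with the same inputs and configuration reproduces the files
byte for byte.  dN/dS comes from the built-in counting estimator on the
supplied protein/CDS FASTA files unless an externally computed table is given,
which then takes precedence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .annotations import DEFAULT_EVIDENCE_BLACKLIST, parse_gaf
from .cluster import (
    FunctionalGroup,
    cut_by_height,
    cut_by_min_size,
    similarity_to_distance,
    ward_linkage,
)
from .divergence import (
    DivergenceError,
    backtranslate_alignment,
    global_protein_align,
    import_divergence_table,
    ng86_divergence,
)
from .enrichment import enrich_groups
from .ontology import NAMESPACES, parse_obo
from .pairs import filter_pairs, read_pairs
from .semsim import information_content, profile_similarity_matrix
from .stats import (
    omega_histogram,
    one_way_anova,
    pearson_correlation,
    tukey_hsd,
    two_way_anova,
)

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    obo: str
    gaf: str
    pairs: str
    proteins: str | None = None
    cds: str | None = None
    omega_table: str | None = None
    layout: str | None = None
    out_dir: str = "results/pipeline"
    namespaces: tuple = NAMESPACES
    min_depth: int = 1
    evidence_blacklist: frozenset = DEFAULT_EVIDENCE_BLACKLIST
    min_group_size: int | None = 20
    cut_height: float | None = None
    alpha: float = 0.05
    gap_open: float = 10.0
    gap_extend: float = 0.5
    scoring: str = "BLOSUM62"
    omega_threshold: float = 0.3  # reported "fraction below" cut in the histogram
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.min_group_size is None) == (self.cut_height is None):
            raise PipelineError("select exactly one of min_group_size / cut_height")
        if self.omega_table is None and (self.proteins is None or self.cds is None):
            raise PipelineError("need protein+CDS FASTA files or an omega table")
        for path in (self.obo, self.gaf, self.pairs, self.proteins, self.cds,
                     self.omega_table, self.layout):
            if path is not None and not Path(path).exists():
                raise PipelineError(f"input path does not exist: {path}")


@dataclass
class NamespaceReport:
    namespace: str
    n_pairs: int
    n_groups: int
    anova: object
    tukey: object
    extreme_groups: list
    two_way: object | None
    enrichment_top3: dict


@dataclass
class RunReport:
    funnel: dict
    namespaces: dict[str, NamespaceReport]
    histogram: object
    fraction_below: float
    omega_flagged: int
    location_correlation: object | None
    config: PipelineConfig = field(repr=False, default=None)


def compute_divergence(pairs, proteins, cds, config) -> dict:
    """Per-pair divergence estimates from sequences (align, backtranslate, count)."""
    out = {}
    for pair in pairs:
        try:
            aln = global_protein_align(
                proteins[pair.gene1],
                proteins[pair.gene2],
                scoring=config.scoring,
                gap_open=config.gap_open,
                gap_extend=config.gap_extend,
            )
            codon_aln = backtranslate_alignment(aln, cds[pair.gene1], cds[pair.gene2])
            out[pair.key] = ng86_divergence(codon_aln)
        except (KeyError, DivergenceError) as exc:
            raise PipelineError(f"divergence failed for pair {pair.pair_id}: {exc}") from exc
    return out


def _divergence_frame(pairs, estimates) -> pd.DataFrame:
    rows = []
    for p in sorted(pairs, key=lambda p: p.key):
        e = estimates[p.key]
        rows.append(
            {
                "gene1": p.gene1,
                "gene2": p.gene2,
                "dN": e.dn,
                "dS": e.ds,
                "omega": e.omega,
                "N": e.n_sites,
                "S": e.s_sites,
                "Nd": e.nd,
                "Sd": e.sd,
                "flags": ";".join(e.flags),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    graph = parse_obo(config.obo)
    annotations = parse_gaf(config.gaf, graph)
    all_pairs = read_pairs(config.pairs)

    filtered = filter_pairs(
        all_pairs, annotations, graph,
        evidence_blacklist=config.evidence_blacklist,
        min_depth=config.min_depth,
    )
    if not filtered.pairs:
        fio.write_json(filtered.counts, out / "funnel.json", config=config)
        raise PipelineError(f"no pairs left after filtering; funnel: {filtered.counts}")
    fio.write_json(filtered.counts, out / "funnel.json", config=config)
    shared_rows = [
        {"pair": p.pair_id, "namespace": ns, "term": t}
        for p in filtered.pairs
        for ns in NAMESPACES
        for t in sorted(p.shared_functions.get(ns, ()))
    ]
    fio.write_tsv(pd.DataFrame(shared_rows), out / "shared_functions.tsv", config=config)

    # divergence (imported table takes precedence over the built-in estimator)
    if config.omega_table is not None:
        estimates = import_divergence_table(config.omega_table)
        missing = [p.pair_id for p in filtered.pairs if p.key not in estimates]
        if missing:
            raise PipelineError(f"omega table lacks pairs: {missing[:5]} ...")
    else:
        proteins = fio.read_fasta(config.proteins)
        cds = fio.read_fasta(config.cds)
        estimates = compute_divergence(filtered.pairs, proteins, cds, config)
    fio.write_tsv(
        _divergence_frame(filtered.pairs, estimates), out / "divergence.tsv", config=config
    )

    omega = {}
    flagged = 0
    for p in filtered.pairs:
        e = estimates[p.key]
        if e.omega is None or "saturated" in e.flags:
            flagged += 1
        else:
            omega[p.pair_id] = e.omega
    if flagged:
        logger.info("excluded %d pairs with undefined/saturated omega", flagged)

    hist = omega_histogram(list(omega.values()), bin_width=0.1)
    fio.write_tsv(hist.to_frame(), out / "omega_histogram.tsv", config=config)
    fraction_below = hist.fraction_below(config.omega_threshold)

    ic = information_content(annotations, graph)
    ic_rows = [
        {
            "term": t,
            "count": ic.counts[t],
            "p": ic.counts[t],
            "IC": ic.ic[t],
        }
        for t in sorted(ic.ic)
    ]
    fio.write_tsv(pd.DataFrame(ic_rows), out / "information_content.tsv", config=config)

    population = frozenset(g for p in filtered.pairs for g in (p.gene1, p.gene2))
    pairs_by_id = {p.pair_id: p for p in filtered.pairs}

    ns_reports: dict[str, NamespaceReport] = {}
    for ns in config.namespaces:
        pairs_ns = [p for p in filtered.pairs_for_namespace(ns) if p.pair_id in omega]
        if len(pairs_ns) < 2:
            logger.warning("namespace %s has <2 usable pairs; skipped", ns)
            continue
        sim = profile_similarity_matrix(pairs_ns, ic, graph, ns)
        sim_df = pd.DataFrame(sim.values, columns=sim.pair_ids)
        sim_df.insert(0, "pair", sim.pair_ids)
        fio.write_tsv(sim_df, out / f"{ns}_similarity.tsv", config=config)

        tree = ward_linkage(similarity_to_distance(sim))
        (out / f"{ns}_tree.nwk").write_text(tree.to_newick() + "\n")
        if config.min_group_size is not None:
            groups = cut_by_min_size(tree, config.min_group_size, ns)
        else:
            groups = cut_by_height(tree, config.cut_height, ns)
        fio.write_tsv(
            pd.DataFrame(
                [
                    {"pair": m, "group": g.group_id, "namespace": ns, "height": g.height}
                    for g in groups
                    for m in g.members
                ]
            ),
            out / f"{ns}_groups.tsv",
            config=config,
        )

        label_of = {m: g.group_id for g in groups for m in g.members}
        values = np.array([omega[p.pair_id] for p in pairs_ns])
        labels = np.array([label_of[p.pair_id] for p in pairs_ns])
        anova = tukey = None
        extremes: list = []
        if len(set(labels)) >= 2:
            anova = one_way_anova(values, labels)
            fio.write_tsv(anova.to_frame(), out / f"{ns}_anova.tsv", config=config)
            tukey = tukey_hsd(values, labels, alpha=config.alpha)
            fio.write_tsv(tukey.to_frame(), out / f"{ns}_group_means.tsv", config=config)
            extremes = tukey.extreme_groups()
            if config.make_plots:
                from .stats import plot_group_means

                plot_group_means(tukey, out / f"{ns}_group_means.png", title=ns)
        two_way = None
        copy_labels = np.array([pairs_by_id[p.pair_id].copy_number_class for p in pairs_ns])
        if len(set(labels)) >= 2 and len(set(copy_labels)) >= 2:
            two_way = two_way_anova(values, labels, copy_labels)
            fio.write_tsv(two_way.to_frame(), out / f"{ns}_anova_two_way.tsv", config=config)

        enr = enrich_groups(groups, pairs_by_id, annotations, graph, population, ns)
        enr_rows = [
            {
                "group": ge.group_id,
                "term": r.term,
                "name": r.name,
                "study_count": r.study_count,
                "population_count": r.population_count,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
            }
            for ge in enr
            for r in ge.records
        ]
        fio.write_tsv(pd.DataFrame(enr_rows), out / f"{ns}_enrichment.tsv", config=config)
        top3 = {ge.group_id: [(r.term, r.p_adjusted) for r in ge.top3] for ge in enr}

        ns_reports[ns] = NamespaceReport(
            namespace=ns,
            n_pairs=len(pairs_ns),
            n_groups=len(groups),
            anova=anova,
            tukey=tukey,
            extreme_groups=extremes,
            two_way=two_way,
            enrichment_top3=top3,
        )

    correlation = None
    if config.layout is not None:
        layout, _ = fio.read_layout(config.layout)
        dist = dict(zip(layout["gene"], layout["centromere_distance"]))
        xs, ys = [], []
        for p in filtered.pairs:
            if p.pair_id not in omega:
                continue
            for g in (p.gene1, p.gene2):
                if g in dist:
                    xs.append(float(dist[g]))
                    ys.append(omega[p.pair_id])
        if len(xs) >= 3:
            correlation = pearson_correlation(xs, ys)
            fio.write_json(
                {"r": correlation.r, "p": correlation.p, "n": correlation.n},
                out / "location_correlation.json",
                config=config,
            )

    report = RunReport(
        funnel=filtered.counts,
        namespaces=ns_reports,
        histogram=hist,
        fraction_below=fraction_below,
        omega_flagged=flagged,
        location_correlation=correlation,
        config=config,
    )
    _write_report(report, out)
    return report


def _write_report(report: RunReport, out: Path) -> None:
    payload = {
        "funnel": report.funnel,
        "fraction_omega_below_threshold": report.fraction_below,
        "omega_flagged": report.omega_flagged,
        "namespaces": {
            ns: {
                "n_pairs": r.n_pairs,
                "n_groups": r.n_groups,
                "anova_F": None if r.anova is None else r.anova.f,
                "anova_p": None if r.anova is None else r.anova.p,
                "extreme_groups": [str(g) for g in r.extreme_groups],
                "two_way_p_groups": None if r.two_way is None else r.two_way.row("Groups").p,
                "two_way_p_copy": None if r.two_way is None else r.two_way.row("CopyNumber").p,
                "enrichment_top3": r.enrichment_top3,
            }
            for ns, r in report.namespaces.items()
        },
    }
    if report.location_correlation is not None:
        payload["location_correlation"] = {
            "r": report.location_correlation.r,
            "p": report.location_correlation.p,
            "n": report.location_correlation.n,
        }
    fio.write_json(payload, out / "report.json", config=report.config)
    lines = [f"pairs: {report.funnel}"]
    for ns, r in report.namespaces.items():
        f_txt = "n/a" if r.anova is None else f"F={r.anova.f:.3g} p={r.anova.p:.3g}"
        lines.append(
            f"{ns}: {r.n_pairs} pairs -> {r.n_groups} groups; ANOVA {f_txt}; "
            f"extreme groups: {', '.join(map(str, r.extreme_groups)) or 'none'}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


def sensitivity_scan(
    config: PipelineConfig, heights=(), min_sizes=()
) -> pd.DataFrame:
    """Re-cut cached similarity matrices at alternative parameters.

    Requires a prior :func:`run_pipeline` with the same output directory (the
    similarity and divergence tables are reused); reports group count and
    ANOVA F/p per (namespace, parameter) setting.
    """
    if not heights and not min_sizes:
        raise PipelineError("provide at least one height or min_size")
    out = Path(config.out_dir)
    div_path = out / "divergence.tsv"
    if not div_path.exists():
        raise PipelineError("cached divergence table missing: run the pipeline first")
    div = pd.read_csv(div_path, sep="\t", comment="#")
    omega = {
        f"{r.gene1}--{r.gene2}": r.omega
        for r in div.itertuples()
        if pd.notna(r.omega) and "saturated" not in str(r.flags)
    }
    rows = []
    for ns in config.namespaces:
        sim_path = out / f"{ns}_similarity.tsv"
        if not sim_path.exists():
            raise PipelineError(
                f"cached similarity matrix missing for {ns}: run the pipeline first"
            )
        sim_df = pd.read_csv(sim_path, sep="\t", comment="#")
        pair_ids = list(sim_df["pair"])
        from .semsim import ProfileSimilarityMatrix

        values = sim_df[pair_ids].to_numpy()
        values = (values + values.T) / 2.0  # round-trip symmetrization
        sim = ProfileSimilarityMatrix(pair_ids=pair_ids, values=values, raw=values)
        tree = ward_linkage(similarity_to_distance(sim))
        settings = [("min_size", m) for m in min_sizes] + [("height", h) for h in heights]
        for kind, value in settings:
            groups = (
                cut_by_min_size(tree, int(value), ns)
                if kind == "min_size"
                else cut_by_height(tree, float(value), ns)
            )
            label_of = {m: g.group_id for g in groups for m in g.members}
            usable = [p for p in pair_ids if p in omega]
            values_w = np.array([omega[p] for p in usable])
            labels = np.array([label_of[p] for p in usable])
            f_stat, p = np.nan, np.nan
            if len(set(labels)) >= 2:
                try:
                    anova = one_way_anova(values_w, labels)
                    f_stat, p = anova.f, anova.p
                except Exception:
                    pass  # degenerate cuts (e.g. all-singleton) have no residual df
            rows.append(
                {
                    "namespace": ns,
                    "parameter": kind,
                    "value": value,
                    "n_groups": len(groups),
                    "F": f_stat,
                    "p": p,
                }
            )
    frame = pd.DataFrame(rows)
    fio.write_tsv(frame, out / "sensitivity_scan.tsv", config=config)
    return frame
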