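# funcdiv

Functional bias in the molecular evolution rate of whole-genome-duplicated
gene pairs.

After a whole-genome duplication, surviving paralog pairs diverge at rates set
partly by selective constraint on their biological function: defense-response
genes tolerate (or favor) change, translation-machinery genes do not.
`funcdiv` tests this by (1) labeling each duplicate pair with the most
specific Gene Ontology functions its two genes share, (2) clustering pairs by
semantic similarity of those profiles into functional groups, (3) estimating
each pair's dN/dS — nonsynonymous vs synonymous substitutions per site, where
ω = dN/dS ≪ 1 indicates purifying selection — and (4) testing whether mean
ω differs across groups.

The core quantities:

- **IC(t) = −ln p(t)** — information content of a GO term from annotation
  frequency (descendant-inclusive).
- **sim(t, t′) = max IC over common ancestors** — Resnik term similarity;
  profiles are compared by maximum-weight injective matching (optimal
  assignment), normalized to [0, 1].
- **Ward clustering** of 1 − similarity, cut bottom-up so every group holds
  ≥ 20 pairs (the lowest internal node reaching the size floor defines a
  group).
- **dN/dS** by Nei–Gojobori counting with Jukes–Cantor correction:
  d = −(3/4) ln(1 − (4/3)p) applied to the synonymous and nonsynonymous
  difference proportions; external (e.g. maximum-likelihood) tables can be
  imported instead.
- **One-way ANOVA + Tukey HSD** across groups, a two-factor model for
  single/multiple duplicates, and **parent–child union enrichment** with
  Bonferroni correction to name what each group does.

Everything runs end-to-end on synthetic studies with planted families, so
every stage is testable against known ground truth; the same code consumes
real OBO/GAF/FASTA inputs.

## Worked example

```sh
python analysis/01_simulate_study.py     # synthetic inputs under results/data/study
python analysis/02_run_pipeline.py       # full analysis under results/pipeline
python analysis/03_evaluate_recovery.py  # score against planted truth
python analysis/04_divergence_calibration.py
python analysis/05_sensitivity_scan.py
```

The simulated study plants 6 functional families × 30 duplicate pairs with
family ω means spanning 0.03–0.45.  The pipeline run prints:

```
pairs: {'input': 180, 'after_evidence': 155, ... 'retained_any_namespace': 155}
biological_process: 155 pairs -> 6 groups; ANOVA F=171 p=7.33e-60; extreme groups: G01, ..., G06
fraction of pairs with dN/dS < 0.3: 0.671
centromere-distance correlation: r=-0.0947 (p=0.0962, n=310)
```

25 of 180 pairs fall to the evidence filter (a gene annotated only
electronically), the remaining 155 pairs cluster into exactly the 6 planted
families in every namespace (adjusted Rand index 1.0, see
`results/tables/recovery.tsv`), the group effect on ω is overwhelming
(F = 171 on 5 and 149 df), and location on the chromosome shows no real
signal, as planted.  The recovery evaluation also confirms that each family's
anchor term (or a descendant) ranks in its group's top-3 enrichment and that
the fastest-evolving family is flagged extreme by Tukey's HSD.  The
divergence calibration reports mean dS 0.097 vs planted 0.091 (6.8% relative,
the Jukes–Cantor correction's expected excess) and mean dN 0.046 vs 0.044
(3.0%).  The sensitivity scan re-cuts the trees at fixed heights 0.1/0.001
and min-sizes 10/20/40: group counts range from 3 to 57, yet the group effect
stays at p < 1e-3 in 15/15 settings.

The same pipeline runs from the shell on real data:

```sh
funcdiv run --obo go.obo --gaf tair.gaf --pairs alpha_pairs.tsv \
            --pep pep.fasta --cds cds.fasta --min-size 20 --out results/real
funcdiv run ... --import yn00_table.tsv   # use externally computed dN/dS
```

## Layout

```
src/funcdiv/        library: ontology, annotations, pairs, semsim, divergence,
                    cluster, stats, enrichment, simulate, pipeline, io, cli
analysis/           numbered narrative drivers for the study above
tests/              pytest suite (unit, property, calibration, end-to-end)
scripts/            acceptance script
docs/methods.md     model, assumptions, parameter defaults, limitations
```
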