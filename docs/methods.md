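# Methods

`funcdiv` asks whether the rate of molecular evolution of gene pairs retained
from a whole-genome duplication depends on the pairs' biological function.
The unit of analysis is the duplicate **pair**: each pair carries one
functional profile (the most specific GO functions its two genes share) and
one divergence estimate (dN/dS between its two coding sequences).  The
pipeline groups pairs by functional similarity and tests whether mean dN/dS
differs between groups.

## Shared-function labeling and pair filtering

Annotations are screened by evidence code: a pair is dropped when either gene
has no annotation outside a configurable blacklist (default `{IEA, ND}`,
i.e. only electronically inferred or no-data annotations).  Surviving pairs
are labeled, per namespace, with their **most specific shared functions**:
the minimal elements of the intersection of the two genes' reflexive
is_a/part_of ancestor closures.  Shared terms must sit at depth >= 1, where
depth is the minimum edge distance from the namespace root (the root itself
has depth 0); a pair may stay in one namespace's analysis and drop out of
another.  Ancestor sets are reflexive so that two genes annotated to the same
leaf share that leaf itself rather than a strictly more general parent.
`is_a` and `part_of` are pooled as equivalent for reachability and depth; all
other GO relations are ignored.

## Profile similarity

Information content is corpus-based: IC(t) = -ln p(t), with p(t) the fraction
of the namespace's annotated genes annotated to t or any descendant
(natural-log units; only ratios and orderings matter downstream).  Term-term
similarity is Resnik's: the IC of the most informative common ancestor.
Profile-profile similarity uses the optimal-assignment construction: the
smaller profile is injectively matched to the larger so the summed Resnik
similarities are maximal (a maximum-weight bipartite matching), and the sum is
divided by the number of matched terms.  Pair-pair coefficients are then
normalized by the geometric mean of the two self-similarities, which makes
clustering heights scale-free; both raw and normalized matrices are written.
For profiles of unequal size this ratio can marginally exceed 1 (a small
profile nested inside a larger one whose extra terms carry little IC), so
values are capped at 1.  Ties in the matching are resolved by lexicographic
term order for reproducibility.

## Clustering and group definition

Similarities become distances (d = 1 - s) and are clustered with Ward's
method via the Lance-Williams recursion on squared dissimilarities.  Recorded
merge heights are the Ward merge cost — the increase in within-group sum of
squares — so two singletons at distance d merge at height d^2/2.  The variant
matters for fixed-height cuts and is recorded in output metadata.

Groups come from the minimum-size cut (default 20): every leaf is claimed by
its lowest ancestor holding at least `min_size` leaves; leaves claimed by the
same node form a candidate group; undersized candidates (left over when a
qualifying node contains a qualifying child) are merged upward into the next
qualifying ancestor's candidate, and a residual remaining at the root is
absorbed into the deepest emitted group.  The output is therefore always a
partition with every group at or above the floor.  A fixed-height cut
(maximal subtrees merging at or below h) is available for sensitivity
analysis; group counts are monotone in both parameters.

## Divergence estimation

Protein pairs are aligned globally (Needleman-Wunsch, BLOSUM62, affine gaps:
a gap of length L costs 10.0 + 0.5L, end gaps free — the defaults of the
classic `needle` program).  Unknown residues (X) score 0 against everything.
The CDS pair is threaded through the protein alignment codon by codon
(terminal stop codons stripped; internal stops or translation mismatches are
errors naming the codon index).

dN and dS come from the Nei-Gojobori counting method: per codon, the
synonymous site count is the fraction of single-base changes that are
synonymous; S is the mean of the two rows' totals and N = 3L - S.  Observed
differences are partitioned by averaging over all minimal substitution paths
between differing codons with equal weights, excluding paths through stop
codons.  Proportions are corrected for multiple hits with Jukes-Cantor,
d = -(3/4) ln(1 - (4/3)p); p >= 3/4 is flagged saturated, and omega = dN/dS
is undefined when dS = 0.  Codon columns with gaps or ambiguous bases are
excluded from both site and difference counts.  This counting estimator
ignores transition/transversion and codon-frequency bias; externally computed
dN/dS tables (e.g. from a maximum-likelihood estimator) can be imported and
then take precedence, which is the recommended route for real-data runs.
Calibration on simulated pairs (300 codons, 20 synonymous + 30 nonsynonymous
single-base changes, 200 replicates) recovers the planted per-site
proportions within a few percent (the Jukes-Cantor correction slightly
exceeds the raw proportion by design).

## Group statistics

A fixed-effects one-way ANOVA decomposes dN/dS into between-group and
residual components (SS/df/MS/F and the upper-tail F probability).  Pairs
with undefined or saturated omega are excluded with logged counts.  Tukey's
HSD compares all group means simultaneously with the Tukey-Kramer statistic
q = |mean_i - mean_j| / sqrt((MSE/2)(1/n_i + 1/n_j)); a pair of groups
differs when its adjusted p falls below alpha, equivalently when the
difference interval +/- q_crit * se excludes zero.  Group means are reported
with simultaneous half-widths (q_crit/sqrt(2)) * sqrt(MSE/n_i) — the exact
interval convention is a documented parameter since plotting conventions vary.
A group is called *extreme* when it differs significantly from every other
group.

Studentized-range probabilities are computed by direct two-dimensional
Gauss-Legendre quadrature of P(Q <= q) = ∫ f_S(s) · k ∫ φ(z)[Φ(z)-Φ(z-qs)]^(k-1)
dz ds (64 z-nodes on [-9, 9], 40 s-nodes on a df-adaptive interval with the
chi density computed in log space).  The absolute CDF error is near 1e-5 —
ample for p-values — and the quadrature is vectorized over q, which keeps
simulation calibrations with thousands of Tukey calls affordable.  Quantiles
invert the CDF by bracketed root finding.

The copy-number analysis fits a main-effects two-factor model (functional
group + single/multiple duplicate) with Type II sums of squares, appropriate
for the highly unbalanced design; no interaction term is fitted because one
p-value per factor is reported.  The chromosomal-location check correlates
per-gene centromere distance (base pairs from the centromere to the gene
midpoint) with the pair's omega — each pair contributes two observations, one
per gene; a pair-level mean-distance variant is a one-line change.  The
dN/dS histogram uses half-open bins [kw, (k+1)w) with w = 0.1 and reports the
fraction of pairs below a threshold (default 0.3).

## Enrichment

Each group is characterized by GO over-representation of its member genes
(the union of both genes of every member pair) against all genes of the
retained pair set.  The statistic is the parent-child union test: for term t
with parent set Pa(t), the study's draw from U = genes annotated to the union
of Pa(t) is compared with a hypergeometric upper tail
P(X >= k; |U ∩ pop|, |t ∩ pop|, |U ∩ study|).  Conditioning on the parents'
union avoids the classic test's inflation for terms whose parents are
themselves enriched.  Root terms (no parents) are skipped.  Bonferroni
correction multiplies by the number of terms actually tested in that group's
run (every term annotated to at least one study gene), and the top three
terms per group are extracted.  A classic term-for-term mode exists behind a
flag for comparison only.

## Synthetic studies

The generator produces complete studies with known ground truth for every
stage:

- **Ontology**: per namespace, a layered random DAG (root, 8 broad terms, 16
  "hub" terms, then K = 6 family anchor terms at depth 3).  Anchors are
  pairwise non-ancestral; two neighboring families share each hub parent so
  an anchor's parents are never family-specific (otherwise the parent-child
  statistic would correctly discount the anchor itself).  Each anchor hosts
  two subfamily branches of 5 descendants (duplicated genes tend to
  subfunctionalize); remaining terms attach as background under layers 1-3.
  Non-root terms gain a second `part_of` parent with probability 0.2.
- **Annotations/pairs**: 30 pairs per family; both genes of a pair annotate
  to ~3 terms of the same subfamily branch (alternating branches within a
  family) plus an occasional shallow background term; evidence codes are
  curated (IDA/IMP/TAS/IGI) except for an 8% fraction of genes annotated
  only by IEA, which exercises the evidence filter (~15% of pairs drop)
  while keeping families above the min-size-20 threshold with high
  probability, so the planted partition remains recoverable.  The two-branch
  structure also keeps each family subtree's top Ward split balanced
  (~13/14), below the size floor on both sides — with i.i.d. profiles the
  top split is almost always lopsided (e.g. 6/21), and the
  lowest-qualifying-node cut then strands the minority side in a residual
  group.
- **omega**: truncated normal per family; means span [0.03, 0.45] with SD
  0.06 on [0, 0.8], echoing the contrast between slowly evolving
  translation-machinery families and fast defense-like families.
- **CDS pairs**: a random sense-codon ancestor; the derived copy receives an
  exact number of synonymous and nonsynonymous single-base changes at
  distinct codons, never creating stops.  In whole studies the nonsynonymous
  count targets the pair's planted omega through a nominal N/S site ratio of
  3, and 25 synonymous changes per 300 codons set dS around 0.1.
- **Layout**: uniform gene placement on five 30-Mb chromosomes with central
  centromeres; an optional planted location-omega correlation re-assigns
  distances by the rank of a Gaussian latent variable.
- **Copy number**: per-family multiple-duplicate probabilities rise with the
  family's omega mean (0.1 to 0.7), echoing the observed retention bias of
  fast-evolving duplicates.

Every generator is a pure function of (config, seed).  What the synthetic
data does **not** emulate: real GO topology and annotation sparsity, indels,
transition/transversion and codon-usage bias, expression covariates, and
genuinely overlapping family memberships — so passing tests demonstrate that
the machinery recovers planted structure, not that real duplicate sets have
this structure.

## Numerical and design choices

- Deterministic tie-breaking throughout (lexicographic term order in
  matchings, cluster-index order in Ward, first-alignment traceback).
- All output tables carry a provenance header with a configuration hash;
  identical inputs/config/seed reproduce files byte for byte.
- Degenerate inputs fail loudly: empty ontologies, unknown parents, cycles,
  cross-namespace edges, empty profiles, zero-variance correlation inputs,
  single-group ANOVA.
- Default problem sizes (3 x 300-term namespaces, 180 pairs, 300-codon
  CDS) keep a full study and pipeline run in the low seconds while leaving
  groups large enough for the min-size-20 cut.

## Known limitations

- The counting dN/dS estimator understates divergence under strong
  transition/transversion bias relative to maximum-likelihood estimators;
  import externally computed tables when fidelity matters.
- The min-size cut's residual handling (absorb into the deepest group) is one
  of several defensible readings of "lowest node achieving the minimum size";
  alternative readings change group counts near the root but not the
  detectability of a strong group effect (see the sensitivity scan).
- The optimal-assignment normalization caps at 1 for nested unequal-size
  profiles; uncapped raw values are written alongside for audit.
- Tukey interval conventions differ between plotting packages; the
  simultaneous intervals here are consistent with the pairwise test by
  construction.
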