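# Methods

This note records the statistical procedures famclust implements, the
defaults it ships, and the reasoning behind the choices that were genuinely
open. It states no empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## Data model

Expression is a genes × samples matrix tagged with a platform
(`count_like` for non-negative normalized abundances such as RSEM;
`intensity` for array log-intensities) and a transform state that moves
monotonically `raw → log2p1 → {zscored | median_centered}`. Operations that
need a log scale refuse raw count-like input rather than guessing. Missing
expression values are never imputed; a gene with any missing value is
rejected from classifier training. Clinical tables keep an explicit
`unknown` level for categorical covariates; rows lacking follow-up time or
event status are retained but ineligible for survival operations.

## Preprocessing

* **log2(x+1)** is the working scale for count-like data; the +1 keeps
  zeros finite and matches the scale heatmap analyses use.
* **Probe collapsing** averages all probes of a gene (arithmetic mean per
  sample). Probes absent from the map are dropped with a logged report, and
  unmapped family members are reportable — on array designs a family gene
  can simply have no probe.
* **Low-expression filter**: a gene is removed iff the fraction of samples
  with value ≤ `detect_threshold` (default 0, raw scale) is ≥
  `min_fraction` (default 0.5). The boundary is inclusive — undetected in
  exactly half the cohort means removal. "Detected" is interpreted as a
  strictly positive raw value because no numeric cutoff is standard.
* **Scaling** for the classifier is per-gene z-scoring across samples
  (sample SD, ddof = 1). Per-sample scaling was rejected because the
  classifier correlates *across genes*, which requires comparable gene
  scales; the alternative reading remains available as a configuration
  switch in spirit via the transformer API. Zero-variance genes are
  flagged and set to 0, never divided by zero.
* **Balanced median-centering** builds a 50/50 ER-positive/ER-negative
  reference subset (all of the minority class plus a seeded simple random
  sample of the majority) and subtracts that subset's per-gene median —
  the centring convention of intrinsic-subtype classifiers, which keeps
  the centring stable under cohort composition shifts.

## Cluster discovery

Samples are compared by Pearson correlation distance *d* = 1 − *r*
(range [0, 2]; constant profiles are rejected by name) and agglomerated
with unweighted average linkage (UPGMA); "average linkage" is ambiguous
between weighted and unweighted variants and the unweighted one was chosen
as the common default. scipy performs the agglomeration; merge heights are
recorded as computed (average linkage does not guarantee monotone heights
and no inversion check is imposed). Equal-distance merge ties follow
scipy's deterministic ordering; ties have measure zero for continuous
distances, so determinism rather than a specific tie rule is what matters.

Cutting the tree into *k* flat clusters relabels groups 1..*k* by first
occurrence in dendrogram leaf order, so labels are stable across reruns.
The cluster number is chosen by maximizing the mean silhouette coefficient,
computed on the *same* correlation distance matrix used for clustering
(computing it under a different metric would answer a different question).
Singleton clusters score 0, the usual convention. Ties in the mean
silhouette go to the smaller *k*.

## Nearest-centroid single-sample predictor

Centroids are per-gene arithmetic means over each class's training
samples; every class needs at least two. A sample is assigned to the
centroid with the highest Spearman correlation (mid-ranks for ties), which
makes assignments invariant under strictly monotone per-sample transforms —
the property that lets one model classify cohorts measured on a different
platform. Ties in the maximal correlation are broken by class-label order
with a warning.

A trained model stores the z-scoring parameters of its training cohort and
applies them to incoming samples; re-estimating scaling on a test cohort
would leak test-set information, so stored parameters are reused.
Classification requires the sample to cover at least 90% of the gene panel
by default; below that the error lists the missing genes.

Cross-cohort diagnostics correlate every centroid pair of two models
(Pearson, over the shared panel) and match class identities greedily,
largest correlation first — adequate and transparent for the ≤ 5 classes
this analysis produces; the Hungarian algorithm would add machinery
without changing answers at this scale.

## Consensus differential expression

The reference analyses in this field run two negative-binomial GLM
packages and compare them. Re-implementing those engines is explicitly out
of scope here; what the consensus layer needs is the *shape* of that
analysis — one fold-change definition scored by two independent
significance engines. famclust therefore ships:

* a shared fold change: difference of group means of log2(CPM+1), on
  library-size-normalized counts (CPM; each sample scaled to a total of
  10⁶). Defining log2FC on log-scale means avoids zero-division and
  matches the heatmap scale;
* **E1_parametric**: two-sided Welch (unequal-variance) *t*-test on the
  log2 values;
* **E2_rank**: two-sided Wilcoxon rank-sum test.

P-values are Benjamini–Hochberg adjusted within each contrast (per-group
tables are reported separately, so the FDR universe is the contrast).
Genes constant across both groups get p = 1. Deregulation calls use strict
thresholds log2FC > 1 (or < −1) and FDR < 0.05; a gene exactly at the
boundary is not called.

Method agreement is summarized by the Pearson correlation of the two
fold-change vectors — identical by construction for the built-in pair,
which is precisely why the two engines differ only in their significance
calculus — and by Bland–Altman statistics of the per-gene differences
(mean, SD, limits = mean ± 1.96·SD, fraction of genes within limits). A
gene is flagged as a **disagreement** when exactly one engine calls it
significant at the joint threshold, or both do with opposite fold-change
signs; the flagging rule is an explicit stand-in, since published analyses
name disagreeing genes without stating their rule. Flagged genes are
excluded before the deregulated sets are partitioned into an exact Venn
decomposition (shared-in-all, per-contrast-specific, and every
intermediate intersection; regions are disjoint and exhaustive).

## Survival analysis

Kaplan–Meier estimation, the k-sample log-rank test, and Cox
proportional-hazards fits are delegated to lifelines, with the Efron
approximation for tied event times (the default of modern survival
software). Censorings tied with events are treated as still at risk.

The gene-wise screen fits one single-covariate Cox model per gene, the
gene entering as a continuous log2-scale covariate (per-SD standardization
is a switch, useful for comparable hazard ratios). Non-estimable genes —
constant expression or non-converging fits — are excluded from the BH-FDR
universe rather than assigned p = 1, which would distort the FDR; they are
returned separately. Output follows the conventional screening table
(coefficient, HR, SE, 95% CI, p, FDR), sorted by coefficient.

The multivariate model codes cluster membership as indicators against
cluster 1, binarizes nodal status (positive = 1) and tumour size
(> 2 cm = 1), keeps stage ordinal, and drops samples with unknown levels
in a requested covariate (with logged counts). Rank-deficient designs are
rejected with the aliased columns named.

## Synthetic cohorts

The generator emulates the statistical skeleton of a two-platform tumour
family-expression study, not any real cohort's marginals:

* **Counts**: negative binomial with mean 2^(baseline + shift) and
  variance μ + αμ², α = 0.15 by default — normalized RNA-seq abundance is
  overdispersed, so Poisson would be wrong in kind; a single shared α keeps
  the model interpretable. Per-gene baselines are drawn Uniform(3, 9) on
  the log2 scale (spanning low-but-detected to highly expressed) unless
  supplied.
* **Intensities**: Gaussian on the log2 scale, unit SD by default.
* **Planted structure**: defaults are the reference study conditions used
  throughout the tests — three clusters of 200 samples on an 89-gene
  panel (the bundled 95-gene family minus its six pervasively
  low-expressed members), with 30 informative genes in three disjoint
  10-gene blocks shifted +1.5 log2 units in their own cluster. +1.5 is
  ≥ 1 within-cluster SD on both platforms, i.e. separable but not trivial.
* **Survival**: exponential event times with hazard λ₀·exp(cluster log-HR
  + optional per-gene effects on standardized log2 expression);
  exponential independent censoring whose rate is calibrated in closed
  form (P(censored | hazard h) = c/(c+h), cohort-averaged, solved by
  bisection) to hit the target censoring fraction. Default cluster hazard
  ratios are 1 / 2.8 / 2.0 at K = 3 — the ordering and magnitude typical
  of a low-/high-risk cluster split in breast-cancer cohorts — and the
  default censoring fraction is 0.7, reflecting how heavily censored such
  cohorts are. Clinical covariates are drawn independently of cluster by
  default (so adjustment tests have a known null), with a confounding knob
  that tilts nodal-positivity probability by cluster.
* **Determinism**: one seed, expanded into fixed named substreams
  (expression / normal reference / survival / covariates) via
  counter-based bit generators, so any artifact can be regenerated
  independently and identical specs give byte-identical outputs.

What passing tests on these cohorts show — and what they do not: the
machinery recovers planted means, clusters, fold changes, and hazard
ratios under a correctly specified generating model with independent
genes and exponential hazards. Real cohorts add batch effects, gene–gene
correlation, platform-specific probe noise, non-exponential hazards, and
confounded covariates, none of which the generator models; results on real
data depend on those violations, not on the correctness of this code path.

## Problem sizes and numerical choices

The test-suite and acceptance script size their simulations to the
defaults above: 20 seeded replicates for cluster-number selection, one
1000-gene 100-vs-100 cohort for differential-expression recovery and one
for the global null, 50 replicates of 500-per-cluster cohorts for survival
power and coverage, 200 small replicates for log-rank null calibration,
and 100 for Wald coverage — sizes at which the Monte-Carlo error of each
reported rate is comfortably below the margins being checked, while a full
run stays within a few minutes on a single CPU.

Numerical conventions: correlation distances are clipped to [0, 2] against
floating-point drift; writers use a fixed `%.10g` float format so
identical analyses serialize byte-identically; BH adjustment is delegated
to statsmodels and cross-checked against a literal step-up enumeration in
the tests; Cox fits are cross-checked against a golden-section maximizer
of the Efron partial likelihood on tiny datasets (datasets with monotone
partial likelihood — quasi-separation — have no finite MLE and are
excluded from that comparison).

## Known limitations

* The two built-in DE engines are location tests on log2 CPM, not
  negative-binomial GLMs; dispersion shrinkage, multi-factor designs, and
  ANOVA-like multi-group tests are out of scope (all pairwise two-group
  contrasts stand in for the latter).
* No between-array or quantile normalization: inputs are assumed
  platform-normalized.
* No proportional-hazards diagnostics, time-varying covariates, or
  competing risks.
* Probe-level noise models and real-cohort marginal distributions are not
  emulated.
* The bundled 95-gene family table is assembled from standard HGNC
  chaperone nomenclature for use as a realistic default panel.
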