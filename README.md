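# famclust

Tools for asking a recurring question in tumour transcriptomics: does the
expression of one gene family — here, the 95-member heat-shock-protein (HSP)
chaperone family in its five subfamilies (CHAP, HSP70, HSPB, HSPC, DNAJ) —
stratify patients into reproducible groups with different outcomes?

The package implements the complete analysis chain as a tested, reusable
library with a CLI:

1. **Preprocessing** — log2(x+1) for count-like abundances (e.g. RSEM),
   probe-to-gene collapsing by averaging, low-expression filtering (a gene
   undetected in ≥ 50% of the cohort is dropped), per-gene z-scoring, and
   ER-balanced median-centering.
2. **Cluster discovery** — hierarchical clustering of samples with Pearson
   correlation distance *d* = 1 − *r* and unweighted average linkage; the
   number of clusters *k* is chosen by maximizing the mean silhouette
   coefficient *s(i)* = (*b* − *a*)/max(*a*, *b*) over a candidate range.
3. **Single-sample predictor** — a nearest-centroid classifier: each class
   centroid is the per-gene mean of its training samples, and a new sample is
   assigned to the centroid with the highest Spearman rank correlation, which
   makes the assignment invariant to monotone transforms and therefore
   portable across measurement platforms. Cross-cohort centroid correlation
   matrices match cluster identities between independently analysed cohorts.
4. **Consensus differential expression** — each tumour group versus a normal
   reference with one fold-change definition (difference of group means of
   log2(CPM+1)) and two independent significance engines (Welch *t* and
   Wilcoxon rank-sum), Benjamini–Hochberg FDR per contrast, |log2FC| > 1 and
   FDR < 0.05 calls, Pearson + Bland–Altman inter-method agreement with
   per-gene disagreement flags, and an exact Venn partition of deregulated
   genes into shared and group-specific sets.
5. **Survival analysis** — Kaplan–Meier curves and the log-rank test across
   clusters, a gene-wise univariate Cox proportional-hazards screen with FDR,
   and a multivariate Cox model for cluster membership adjusted for clinical
   covariates (age, nodal status, tumour size, stage), cluster 1 as reference.
6. **Synthetic cohorts** — a seeded generator with planted cluster structure
   (negative-binomial counts or Gaussian log-intensities), planted fold
   changes versus a normal reference, and exponential proportional-hazards
   survival with calibrated independent censoring, so every stage has a
   ground-truth recovery test.

The fit/predict-shaped pieces are also exposed as scikit-learn estimators
(`CorrelationClusterer`, `CorrelationNearestCentroid`, `GeneStandardScaler`)
that compose with sklearn pipelines and model selection.

## Worked example

Run the full pipeline on the default synthetic cohort (three planted
clusters of 200 samples on an 89-gene family panel, cluster hazard ratios
1 / 2.8 / 2.0, 70% censoring):

```python
import famclust as fc

cfg = fc.PipelineConfig(seed=1, outdir="demo")
result = fc.run_discovery(cfg)

print("chosen k:", result["k"])
print("mean silhouette per k:",
      {k: round(v, 3) for k, v in result["silhouette"].scores.items()})
print("held-out classifier accuracy:", round(result["test_accuracy"], 3))
lr = result["logrank"]
print(f"log-rank: chi2={lr.statistic:.2f}, df={lr.df}, p={lr.pvalue:.2e}")
```

which prints:

```
chosen k: 3
mean silhouette per k: {2: 0.266, 3: 0.355, 4: 0.325, 5: 0.296, 6: 0.234}
held-out classifier accuracy: 1.0
log-rank: chi2=44.66, df=2, p=2.01e-10
```

The silhouette profile peaks at *k* = 3, the planted number of clusters; the
nearest-centroid model trained on half the cohort reproduces the discovered
labels perfectly on the held-out half; and the log-rank test confirms the
clusters separate survival. The multivariate Cox table
(`result["cox_multivariate"]`) reports, for this run,

```
cluster_2: HR=1.74 (95% CI 1.24-2.45), p=0.0015
cluster_3: HR=0.49 (95% CI 0.32-0.74), p=0.0008
```

Discovered labels are ordered by dendrogram position, not by the generator's
cluster indices, so the hazard ratios are expressed relative to whichever
discovered cluster came out first — here the planted ratios (1, 2.8, 2.0)
reappear, permuted, as (1.74, 0.49) against a reference that is itself a
high-risk group. The gene-wise Cox screen (`result["cox_screen"]`) lists
per-gene coefficients, hazard ratios, and FDR in the usual screening-table
layout.

The same run writes flat TSV artifacts (cluster labels, silhouette table,
Newick dendrogram, centroid model, DGE tables, concordance report, KM
curves, Cox tables) plus a `manifest.json` with the seed and config hash;
re-running the identical config reproduces every file byte-for-byte.

Command-line equivalent:

```bash
famclust run-all --seed 1 --outdir demo
```

with subcommands `simulate`, `preprocess`, `discover`, `train`, `classify`,
`dge`, `survive` for the individual stages.

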