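"""Two-estimator differential expression with a concordance layer.

Each tumour group is contrasted against a normal reference with one shared
fold-change definition — difference of group means of log2(CPM + 1) — and
two independent significance engines:

* ``E1_parametric``: two-sided Welch (unequal-variance) t-test on the log2
  values, and
* ``E2_rank``: two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

P-values are Benjamini–Hochberg adjusted within each contrast.  The
consensus layer quantifies inter-method agreement (Pearson r of the
fold-change vectors, Bland–Altman mean difference and 95% limits of
agreement) and flags genes on which the two engines disagree; flagged
genes are excluded before deregulated-gene sets are partitioned into
shared and group-specific regions (the Venn-diagram view).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import ExpressionMatrix, StateError, ValidationError

ESTIMATORS = ("E1_parametric", "E2_rank")


@dataclass
class DGEResult:
    """Per-gene differential-expression table for one contrast/estimator.

    ``table`` columns: log2fc, pvalue, fdr, mean_abundance (gene-indexed).
    """

    contrast: str
    estimator: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"log2fc", "pvalue", "fdr", "mean_abundance"}
        if not need <= set(self.table.columns):
            raise ValidationError(f"DGE table missing columns {need - set(self.table.columns)}")


@dataclass
class ConcordanceReport:
    """Bland–Altman + correlation agreement between two DGE estimators."""

    contrast: str
    pearson_r: float
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    frac_within_limits: float
    table: pd.DataFrame  # per gene: log2fc_E1, log2fc_E2, mean_fc, diff_fc,
    #                       sig_E1, sig_E2, disagreement

    @property
    def disagreeing_genes(self) -> list[str]:
        return self.table.index[self.table["disagreement"]].tolist()


@dataclass
class SetPartition:
    """Exact Venn partition of per-contrast gene sets.

    ``regions`` maps a frozenset of contrast names (the membership pattern)
    to the genes belonging to exactly those contrasts; regions are disjoint
    and their union is the union of the input sets.
    """

    contrasts: list[str]
    regions: dict[frozenset, set]

    @property
    def shared_in_all(self) -> set:
        return set(self.regions.get(frozenset(self.contrasts), set()))

    def specific(self, contrast: str) -> set:
        return set(self.regions.get(frozenset([contrast]), set()))

    def counts(self) -> pd.DataFrame:
        rows = [
            {"region": "+".join(sorted(k)), "n_genes": len(v)}
            for k, v in sorted(self.regions.items(), key=lambda kv: sorted(kv[0]))
            if v
        ]
        return pd.DataFrame(rows)


def cpm_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every sample (column) to a common total of 1e6 (counts per
    million); the standard library-size normalization for count data."""
    if expr.platform != "count_like" or expr.transform_state != "raw":
        raise StateError("cpm_normalize expects raw count_like data")
    totals = expr.values.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"zero-total samples cannot be normalized: {zero}")
    return expr.with_values(expr.values.div(totals, axis=1) * 1e6, "raw")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log_scale_values(expr: ExpressionMatrix) -> pd.DataFrame:
    if expr.platform == "count_like" and expr.transform_state == "raw":
        return np.log2(expr.values + 1.0)
    return expr.values


def dge_two_group(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    reference: Sequence[str],
    estimator: str = "E1_parametric",
    contrast: str | None = None,
) -> DGEResult:
    """Differential expression of ``group_a`` versus ``reference``.

    Both estimators share the fold-change definition (difference of group
    means on the log2(x+1) scale, computed on library-size-normalized
    counts); they differ only in the significance engine.  Genes constant
    across both groups get p = 1 (no evidence either way).
    """
    if estimator not in ESTIMATORS:
        raise ValidationError(f"unknown estimator {estimator!r}")
    a_set, r_set = set(group_a), set(reference)
    overlap = a_set & r_set
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)}")
    if len(a_set) < 2 or len(r_set) < 2:
        raise ValidationError("both groups need at least 2 samples")
    vals = _log_scale_values(expr)
    A = vals[list(group_a)].to_numpy()
    R = vals[list(reference)].to_numpy()
    log2fc = A.mean(axis=1) - R.mean(axis=1)
    mean_abundance = np.concatenate([A, R], axis=1).mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        if estimator == "E1_parametric":
            p = stats.ttest_ind(A, R, axis=1, equal_var=False).pvalue
        else:
            p = stats.mannwhitneyu(A, R, axis=1, alternative="two-sided").pvalue
    p = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": p,
            "fdr": bh_adjust(p),
            "mean_abundance": mean_abundance,
        },
        index=expr.gene_ids,
    )
    return DGEResult(
        contrast=contrast or "groupA_vs_reference", estimator=estimator, table=table
    )


def threshold_deg(
    res: DGEResult, lfc_cut: float = 1.0, fdr_cut: float = 0.05
) -> tuple[set, set]:
    """Deregulated-gene calls with strict cuts: up = {log2fc > lfc_cut,
    fdr < fdr_cut}; down = {log2fc < -lfc_cut, fdr < fdr_cut}."""
    t = res.table
    up = set(t.index[(t["log2fc"] > lfc_cut) & (t["fdr"] < fdr_cut)])
    down = set(t.index[(t["log2fc"] < -lfc_cut) & (t["fdr"] < fdr_cut)])
    return up, down


def method_concordance(
    a: DGEResult,
    b: DGEResult,
    lfc_cut: float = 1.0,
    fdr_cut: float = 0.05,
) -> ConcordanceReport:
    """Agreement between two estimators of the same contrast.

    Reports Pearson r of the fold-change vectors and the Bland–Altman
    summary of their differences (mean, SD, limits = mean ± 1.96 SD,
    fraction of genes within the limits).  A gene is flagged as a
    disagreement when exactly one estimator calls it significant at the
    joint threshold, or both do with opposite fold-change signs.
    """
    if a.contrast != b.contrast:
        raise ValidationError("concordance requires the same contrast")
    if list(a.table.index) != list(b.table.index):
        raise ValidationError("gene universes differ between the two results")
    fa, fb = a.table["log2fc"], b.table["log2fc"]
    diffs = fa - fb
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    lo, hi = mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff
    within = float(((diffs >= lo) & (diffs <= hi)).mean())
    if float(fa.std(ddof=0)) == 0 or float(fb.std(ddof=0)) == 0:
        r = 1.0 if np.allclose(fa, fb) else float("nan")
    else:
        r = float(np.corrcoef(fa, fb)[0, 1])
    sig_a = (fa.abs() > lfc_cut) & (a.table["fdr"] < fdr_cut)
    sig_b = (fb.abs() > lfc_cut) & (b.table["fdr"] < fdr_cut)
    disagreement = (sig_a ^ sig_b) | (sig_a & sig_b & (np.sign(fa) != np.sign(fb)))
    table = pd.DataFrame(
        {
            "log2fc_E1": fa,
            "log2fc_E2": fb,
            "mean_fc": (fa + fb) / 2.0,
            "diff_fc": diffs,
            "sig_E1": sig_a,
            "sig_E2": sig_b,
            "disagreement": disagreement,
        }
    )
    return ConcordanceReport(
        contrast=a.contrast,
        pearson_r=r,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_lower=lo,
        loa_upper=hi,
        frac_within_limits=within,
        table=table,
    )


def partition_deg_sets(
    sets: Mapping[str, Iterable],
    excluded: Iterable = (),
) -> SetPartition:
    """Exact Venn partition of per-contrast gene sets.

    ``excluded`` genes (e.g. concordance disagreements) are removed from
    every set first.  Every membership pattern over the contrasts becomes a
    disjoint region; the union of regions equals the union of the cleaned
    input sets.
    """
    if len(sets) < 2:
        raise ValidationError("partition needs at least 2 contrasts")
    excl = set(excluded)
    clean = {c: set(g) - excl for c, g in sets.items()}
    contrasts = list(clean)
    regions: dict[frozenset, set] = {}
    for gene in set().union(*clean.values()):
        pattern = frozenset(c for c in contrasts if gene in clean[c])
        regions.setdefault(pattern, set()).add(gene)
    return SetPartition(contrasts=contrasts, regions=regions)


def dge_all_contrasts(
    expr: ExpressionMatrix,
    groups: Mapping[str, Sequence[str]],
    reference: Sequence[str],
    lfc_cut: float = 1.0,
    fdr_cut: float = 0.05,
) -> tuple[dict[str, dict[str, DGEResult]], dict[str, ConcordanceReport]]:
    """Run both estimators for every group-vs-reference contrast and the
    per-contrast concordance reports (the full DGE stage)."""
    results: dict[str, dict[str, DGEResult]] = {}
    concordance: dict[str, ConcordanceReport] = {}
    for name, members in groups.items():
        contrast = f"{name}_vs_normal"
        pair = {
            est: dge_two_group(expr, members, reference, estimator=est, contrast=contrast)
            for est in ESTIMATORS
        }
        results[name] = pair
        concordance[name] = method_concordance(
            pair["E1_parametric"], pair["E2_rank"], lfc_cut=lfc_cut, fdr_cut=fdr_cut
        )
    return results, concordance


def write_dge_tables(results: Mapping[str, Mapping[str, DGEResult]], path) -> None:
    """Flat TSV with columns gene_id, contrast, estimator, log2fc, pvalue,
    fdr, mean_abundance."""
    frames = []
    for pair in results.values():
        for res in pair.values():
            t = res.table.copy()
            t.insert(0, "estimator", res.estimator)
            t.insert(0, "contrast", res.contrast)
            frames.append(t.rename_axis("gene_id").reset_index())
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.10g")
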