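"""Survival analysis: Kaplan–Meier, log-rank, and Cox proportional hazards.

Gene-wise univariate Cox screening (one continuous log2-expression
covariate per gene, Benjamini–Hochberg FDR across the family) and a
multivariate fit adjusting cluster membership for clinical covariates.
lifelines performs the fits (Efron handling of tied event times); this
module fixes the cohort plumbing: eligibility, design construction with
cluster 1 as the reference level, rank checks, and the tabular outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .core_data import ClinicalTable, ExpressionMatrix, ValidationError
from .dge import bh_adjust

logger = logging.getLogger("famclust")


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    One row per observed time (events and censorings), with the survival
    probability just after that time, the size of the risk set at it, and
    the number of events at it.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


@dataclass
class LogRankResult:
    statistic: float
    df: int
    pvalue: float


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Censorings tied with events at the same time are treated as still at
    risk for those events (the standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape or times.ndim != 1 or len(times) == 0:
        raise ValidationError("times and events must be equal-length non-empty vectors")
    if (times < 0).any():
        raise ValidationError("negative survival time")
    if not np.isin(events, [0, 1]).all():
        raise ValidationError("events must be 0/1")
    kmf = KaplanMeierFitter().fit(times, events)
    tab = kmf.event_table
    tab = tab[tab.index > 0] if 0 not in times else tab
    sf = kmf.survival_function_["KM_estimate"]
    out_times = tab.index.to_numpy(dtype=float)
    return KMCurve(
        times=out_times,
        survival=sf.loc[out_times].to_numpy(dtype=float),
        at_risk=tab["at_risk"].to_numpy(dtype=int),
        events=tab["observed"].to_numpy(dtype=int),
    )


def logrank(times, events, groups) -> LogRankResult:
    """k-sample log-rank test (k-1 degrees of freedom)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("log-rank needs at least 2 non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    return LogRankResult(
        statistic=float(res.test_statistic),
        df=len(labels) - 1,
        pvalue=float(res.p_value),
    )


def km_by_group(times, events, groups) -> dict:
    """One KM curve per group label."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    return {
        g: km_estimate(times[groups == g], events[groups == g]) for g in pd.unique(groups)
    }


def _fit_cox(df: pd.DataFrame) -> CoxPHFitter:
    cph = CoxPHFitter()
    cph.fit(df, duration_col="os_time", event_col="os_event")
    return cph


def cox_univariate_screen(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    standardize: bool = False,
    fdr_method: str = "fdr_bh",
) -> tuple[pd.DataFrame, list[str]]:
    """One single-gene Cox proportional-hazards fit per gene.

    The gene enters as a continuous log2-scale covariate (optionally
    standardized to per-SD hazard ratios).  Non-estimable genes (constant
    expression or non-converging fits) are excluded from the FDR universe
    and returned separately.  Output columns follow the classic screening
    table — coefficient, HR, SE, 95% CI, p, FDR — sorted by coefficient,
    descending.
    """
    expr.require_log_scale("cox_univariate_screen")
    surv = clin.survival_frame()
    shared = [s for s in expr.sample_ids if s in surv.index]
    if len(shared) < 3:
        raise ValidationError("too few eligible samples with expression data")
    base = surv.loc[shared, ["os_time", "os_event"]].astype(float)
    rows = []
    skipped: list[str] = []
    for gene in expr.gene_ids:
        x = expr.values.loc[gene, shared].astype(float)
        if x.isna().any() or x.std(ddof=1) == 0:
            skipped.append(gene)
            continue
        if standardize:
            x = (x - x.mean()) / x.std(ddof=1)
        df = base.copy()
        df["x"] = x.to_numpy()
        try:
            cph = _fit_cox(df)
        except (ConvergenceError, ValueError):  # pragma: no cover - degenerate fits
            skipped.append(gene)
            continue
        s = cph.summary.loc["x"]
        rows.append(
            {
                "gene": gene,
                "coefficient": s["coef"],
                "HR": s["exp(coef)"],
                "coeff_SE": s["se(coef)"],
                "ci_lower": s["exp(coef) lower 95%"],
                "ci_upper": s["exp(coef) upper 95%"],
                "p_value": s["p"],
            }
        )
    if skipped:
        logger.info("cox screen: %d genes non-estimable: %s", len(skipped), skipped[:10])
    out = pd.DataFrame(rows)
    if len(out):
        out["FDR"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values("coefficient", ascending=False).reset_index(drop=True)
    return out, skipped


def build_design(
    clin: ClinicalTable,
    cluster_labels: pd.Series | None = None,
    covariates: tuple[str, ...] = ("age", "node_status", "tumour_size", "stage"),
) -> pd.DataFrame:
    """Numeric design frame for the multivariate Cox model.

    Cluster membership is coded as indicator columns against cluster 1
    (the reference level); node status and tumour size are binarized
    (positive = 1, > 2 cm = 1); stage stays ordinal; rows with unknown
    levels in a requested covariate are dropped with a logged count.
    """
    surv = clin.survival_frame()
    df = surv[["os_time", "os_event"]].astype(float).copy()
    for cov in covariates:
        if cov == "age":
            df["age"] = pd.to_numeric(surv["age"], errors="coerce")
        elif cov == "node_status":
            df["node_positive"] = surv["node_status"].map({"positive": 1.0, "negative": 0.0})
        elif cov == "tumour_size":
            df["size_gt2cm"] = surv["tumour_size"].map({"gt2cm": 1.0, "le2cm": 0.0})
        elif cov == "stage":
            df["stage"] = pd.to_numeric(surv["stage"], errors="coerce")
        elif cov in ("er", "pr", "her2"):
            df[cov + "_pos"] = surv[cov].map({"pos": 1.0, "neg": 0.0})
        else:
            raise ValidationError(f"unknown covariate {cov!r}")
    if cluster_labels is not None:
        lab = cluster_labels.reindex(df.index)
        df = df[lab.notna()]
        lab = lab.dropna()
        levels = sorted(pd.unique(lab))
        for lvl in levels[1:]:
            df[f"cluster_{lvl}"] = (lab == lvl).astype(float)
    n0 = len(df)
    df = df.dropna()
    if n0 - len(df):
        logger.info("build_design: dropped %d samples with unknown covariate levels", n0 - len(df))
    return df


def cox_multivariate(design: pd.DataFrame) -> pd.DataFrame:
    """Joint Cox fit of a numeric design frame (os_time, os_event + covariates).

    Rejects rank-deficient designs, naming the aliased columns.  Returns a
    per-covariate table with coefficient, HR, SE, 95% CI and Wald p, plus
    ``n`` and ``events`` in ``DataFrame.attrs``.
    """
    covs = [c for c in design.columns if c not in ("os_time", "os_event")]
    if not covs:
        raise ValidationError("design has no covariates")
    X = design[covs].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < len(covs):
        from scipy.linalg import qr

        _, R, piv = qr(Xc, pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xc.shape) * np.finfo(float).eps if diag.size else 0
        aliased = [covs[piv[i]] for i in range(len(covs)) if i >= rank or diag[i] <= tol]
        raise ValidationError(f"rank-deficient design; aliased columns: {sorted(set(aliased))}")
    cph = _fit_cox(design)
    s = cph.summary
    out = pd.DataFrame(
        {
            "covariate": s.index,
            "coefficient": s["coef"].to_numpy(),
            "HR": s["exp(coef)"].to_numpy(),
            "coeff_SE": s["se(coef)"].to_numpy(),
            "ci_lower": s["exp(coef) lower 95%"].to_numpy(),
            "ci_upper": s["exp(coef) upper 95%"].to_numpy(),
            "p_value": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    out.attrs["n"] = int(len(design))
    out.attrs["events"] = int(design["os_event"].sum())
    return out
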