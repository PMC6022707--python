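"""Nearest-centroid single-sample predictor.

A sample is assigned to the class whose centroid (per-gene mean profile of
the class's training samples) it correlates with best, by Spearman rank
correlation over the gene panel.  Because the assignment only uses ranks,
it is invariant to any strictly monotone per-sample transform — the
property that lets one model classify samples from a different measurement
platform.

Cross-cohort diagnostics compare the centroids of two independently
trained models by Pearson correlation over the shared panel and match
class identities greedily.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .core_data import ExpressionMatrix, ValidationError, FLOAT_FORMAT
from .preprocess import ScalingParams

logger = logging.getLogger("famclust")


def spearman(x, y) -> float:
    """Spearman rho: Pearson correlation of mid-ranks (ties get average
    ranks).  Constant input has undefined rank correlation and raises."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman needs two equal-length vectors")
    if len(x) < 3:
        raise ValidationError("spearman needs length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("spearman undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class CentroidModel:
    """Gene panel, per-class centroid vectors, and the training scaling.

    ``centroids`` is a genes x classes frame in panel order.  ``scaling``
    (if present) is applied to incoming raw profiles before correlation so
    new cohorts are scaled exactly as the training cohort was.
    """

    gene_panel: list[str]
    class_labels: list
    centroids: pd.DataFrame
    scaling: ScalingParams | None = None
    correlation: str = "spearman"

    def __post_init__(self) -> None:
        if len(set(self.class_labels)) != len(self.class_labels):
            raise ValidationError("class labels must be distinct")
        if list(self.centroids.index) != list(self.gene_panel):
            raise ValidationError("centroid rows must equal the gene panel, in order")
        if list(self.centroids.columns) != list(self.class_labels):
            raise ValidationError("centroid columns must equal class_labels")
        if self.centroids.isna().any().any():
            raise ValidationError("centroids contain missing values")
        if self.correlation not in ("spearman", "pearson"):
            raise ValidationError(f"unknown correlation {self.correlation!r}")

    # -- persistence ----------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.centroids.rename_axis("gene_id").to_csv(
            path / "centroids.tsv", sep="\t", float_format=FLOAT_FORMAT
        )
        header = {
            "correlation": self.correlation,
            "class_labels": [str(c) for c in self.class_labels],
            "scaling": self.scaling.method if self.scaling else None,
        }
        (path / "model.json").write_text(json.dumps(header, indent=1))
        if self.scaling is not None:
            self.scaling.to_tsv(path / "scaling.tsv")

    @classmethod
    def from_dir(cls, path: str | Path) -> "CentroidModel":
        path = Path(path)
        centroids = pd.read_csv(path / "centroids.tsv", sep="\t", index_col="gene_id")
        centroids.index.name = None
        header = json.loads((path / "model.json").read_text())
        scaling = None
        if (path / "scaling.tsv").exists():
            scaling = ScalingParams.from_tsv(path / "scaling.tsv")
        return cls(
            gene_panel=list(centroids.index),
            class_labels=list(centroids.columns),
            centroids=centroids,
            scaling=scaling,
            correlation=header.get("correlation", "spearman"),
        )


@dataclass
class Assignment:
    """One classified sample: winning label and all centroid correlations."""

    sample_id: str
    label: object
    correlation_to_winner: float
    correlations_to_all: pd.Series


def train_centroids(
    expr: ExpressionMatrix,
    labels: pd.Series,
    scaling: ScalingParams | None = None,
    correlation: str = "spearman",
) -> CentroidModel:
    """Per-class arithmetic-mean centroids from a scaled training matrix.

    ``expr`` should already be restricted to the intended gene panel and
    scaled; pass the :class:`ScalingParams` used so the model can scale
    future cohorts identically.  Every class needs >= 2 samples; genes with
    missing values are rejected (they would poison the means).
    """
    lab = labels.reindex(expr.sample_ids)
    if lab.isna().any():
        raise ValidationError("every sample needs a class label")
    counts = lab.value_counts()
    if len(counts) < 2:
        raise ValidationError("need at least 2 classes")
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(f"classes with < 2 samples: {small.index.tolist()}")
    if expr.values.isna().any().any():
        bad = expr.values.index[expr.values.isna().any(axis=1)].tolist()
        raise ValidationError(f"genes with missing values: {bad}")
    class_labels = sorted(counts.index.tolist())
    centroids = pd.DataFrame(
        {c: expr.values.loc[:, (lab == c).to_numpy()].mean(axis=1) for c in class_labels}
    )
    return CentroidModel(
        gene_panel=list(expr.gene_ids),
        class_labels=class_labels,
        centroids=centroids,
        scaling=scaling,
        correlation=correlation,
    )


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        return spearman(x, y)
    r = np.corrcoef(x, y)[0, 1]
    return float(r)


def classify(
    sample: pd.Series,
    model: CentroidModel,
    min_coverage: float = 0.9,
    apply_scaling: bool = True,
) -> Assignment:
    """Assign one sample to the best-correlated class centroid.

    The correlation is computed over the intersection of the sample's
    non-missing genes with the model panel; coverage below ``min_coverage``
    is an error listing the missing genes.  Ties in the maximal correlation
    are broken by class-label order with a logged warning.
    """
    present = [g for g in model.gene_panel if g in sample.index and pd.notna(sample[g])]
    coverage = len(present) / len(model.gene_panel)
    if coverage < min_coverage:
        missing = [g for g in model.gene_panel if g not in present]
        raise ValidationError(
            f"sample {sample.name!r} covers {coverage:.2f} < {min_coverage} "
            f"of the panel; missing genes: {missing}"
        )
    vec = sample[present].astype(float)
    if apply_scaling and model.scaling is not None:
        vec = model.scaling.apply(vec.to_frame()).iloc[:, 0]
        present = [g for g in present if g in vec.index]
        vec = vec[present]
    cors = pd.Series(
        {
            c: _corr(vec.to_numpy(), model.centroids.loc[present, c].to_numpy(), model.correlation)
            for c in model.class_labels
        }
    )
    best = cors.max()
    winners = [c for c in model.class_labels if cors[c] == best]
    if len(winners) > 1:
        warnings.warn(
            f"correlation tie for sample {sample.name!r} between {winners}; "
            "choosing first by class-label order"
        )
    return Assignment(
        sample_id=str(sample.name),
        label=winners[0],
        correlation_to_winner=float(best),
        correlations_to_all=cors,
    )


def classify_matrix(
    expr: ExpressionMatrix,
    model: CentroidModel,
    min_coverage: float = 0.9,
    apply_scaling: bool = True,
) -> pd.DataFrame:
    """Classify every column of a matrix; returns a sample-indexed frame
    with the winning label, its correlation, and one column per class."""
    rows = []
    for s in expr.sample_ids:
        a = classify(expr.values[s], model, min_coverage=min_coverage, apply_scaling=apply_scaling)
        row = {"sample_id": a.sample_id, "label": a.label,
               "correlation_to_winner": a.correlation_to_winner}
        row.update({f"corr_{c}": a.correlations_to_all[c] for c in model.class_labels})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def centroid_crosscorrelation(
    a: CentroidModel, b: CentroidModel
) -> tuple[pd.DataFrame, list[tuple]]:
    """Pearson correlation between every pair of class centroids of two
    models over their shared gene panel, plus a greedy one-to-one matching
    of class identities (largest correlation first).
    """
    shared = [g for g in a.gene_panel if g in set(b.gene_panel)]
    if len(shared) < 3:
        raise ValidationError("shared gene panel has fewer than 3 genes")
    ca = a.centroids.loc[shared]
    cb = b.centroids.loc[shared]
    mat = pd.DataFrame(index=a.class_labels, columns=b.class_labels, dtype=float)
    for i in a.class_labels:
        for j in b.class_labels:
            mat.loc[i, j] = np.corrcoef(ca[i], cb[j])[0, 1]
    # greedy bipartite matching, adequate for the handful of classes here
    matching: list[tuple] = []
    work = mat.copy()
    while work.shape[0] and work.shape[1]:
        idx = np.unravel_index(np.argmax(work.to_numpy()), work.shape)
        i, j = work.index[idx[0]], work.columns[idx[1]]
        matching.append((i, j, float(work.loc[i, j])))
        work = work.drop(index=i, columns=j)
    logger.info("centroid matching: %s", matching)
    return mat, matching


class CorrelationNearestCentroid(BaseEstimator, ClassifierMixin):
    """sklearn-style nearest-centroid classifier with rank correlation.

    fit(X, y) computes per-class feature means (X is samples x genes);
    predict assigns each row to the class centroid with the highest
    Spearman (or Pearson) correlation.  Ties go to the first class in
    ``classes_`` order.

    Attributes
    ----------
    classes_ : ndarray of sorted class labels
    centroids_ : ndarray (n_classes, n_features)
    n_features_in_ : int
    """

    def __init__(self, correlation: str = "spearman"):
        self.correlation = correlation

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != len(y):
            raise ValidationError("X and y length mismatch")
        self.classes_, inv = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValidationError("need at least 2 classes")
        counts = np.bincount(inv)
        if (counts < 2).any():
            raise ValidationError("every class needs at least 2 samples")
        self.n_features_in_ = X.shape[1]
        self.centroids_ = np.vstack(
            [X[inv == k].mean(axis=0) for k in range(len(self.classes_))]
        )
        return self

    def correlation_matrix(self, X) -> np.ndarray:
        """(n_samples, n_classes) correlations of each row to each centroid."""
        check_is_fitted(self, "centroids_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError("feature count differs from training")
        if self.correlation == "spearman":
            Xr = stats.rankdata(X, axis=1)
            Cr = stats.rankdata(self.centroids_, axis=1)
        else:
            Xr, Cr = X, self.centroids_
        Xs = (Xr - Xr.mean(axis=1, keepdims=True))
        Cs = (Cr - Cr.mean(axis=1, keepdims=True))
        denom = np.sqrt((Xs**2).sum(axis=1))[:, None] * np.sqrt((Cs**2).sum(axis=1))[None, :]
        if (denom == 0).any():
            raise ValidationError("constant vector: correlation undefined")
        return (Xs @ Cs.T) / denom

    def predict(self, X):
        cors = self.correlation_matrix(X)
        return self.classes_[np.argmax(cors, axis=1)]
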