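"""Deterministic transforms from raw matrices to analysis-ready ones.

log2(x+1), probe collapsing, low-expression filtering, per-gene z-scoring,
and balanced median-centering (the centring step intrinsic-subtype
classifiers use, with an ER-balanced reference subset).

Per-gene scaling is captured in :class:`ScalingParams` so a classifier
trained on one cohort can be applied to another with bit-identical scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .core_data import ExpressionMatrix, ProbeMap, StateError, ValidationError, _sep_for, FLOAT_FORMAT

logger = logging.getLogger("famclust")


@dataclass
class ScalingParams:
    """Per-gene centring/scaling learned on a reference cohort.

    ``center`` and ``scale`` are indexed by gene; zero-variance genes are
    listed in ``zero_variance_genes`` (their scale is set to 1 and their
    scaled values to 0 rather than dividing by zero).
    """

    center: pd.Series
    scale: pd.Series
    method: str  # "zscore" | "median_center_balanced"
    reference_description: str = ""
    zero_variance_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.scale <= 0).any():
            bad = self.scale.index[self.scale <= 0].tolist()
            raise ValidationError(f"non-positive scale for genes {bad}")

    def apply(self, values: pd.DataFrame) -> pd.DataFrame:
        """Scale a genes x samples frame using the stored parameters
        (restricted to genes the parameters know)."""
        genes = values.index.intersection(self.center.index)
        out = values.loc[genes].sub(self.center[genes], axis=0).div(self.scale[genes], axis=0)
        zv = [g for g in self.zero_variance_genes if g in out.index]
        out.loc[zv] = 0.0
        return out

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"center": self.center, "scale": self.scale})
        df["zero_variance"] = df.index.isin(self.zero_variance_genes).astype(int)
        with open(path, "w") as fh:
            fh.write(f"# method={self.method}\n# reference={self.reference_description}\n")
            df.rename_axis("gene_id").to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScalingParams":
        header: dict[str, str] = {}
        lines = Path(path).read_text().splitlines(keepends=True)
        n_header = 0
        for line in lines:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = val
            n_header += 1
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[n_header:])), sep="\t", index_col="gene_id")
        return cls(
            center=df["center"],
            scale=df["scale"],
            method=header.get("method", "zscore"),
            reference_description=header.get("reference", ""),
            zero_variance_genes=tuple(df.index[df["zero_variance"] == 1]),
        )


def log2p1(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(v + 1) for raw count-like data; records state ``log2p1``."""
    if expr.platform != "count_like":
        raise StateError("log2p1 applies to count_like data only")
    if expr.transform_state != "raw":
        raise StateError(f"log2p1 requires raw input, got {expr.transform_state}")
    return expr.with_values(np.log2(expr.values + 1.0), "log2p1")


def collapse_probes(expr: ExpressionMatrix, pmap: ProbeMap) -> ExpressionMatrix:
    """Average probe rows belonging to one gene into a single gene row.

    Probe rows absent from the map are dropped (logged); genes with no
    probe never appear in the output.
    """
    if pmap.df.empty:
        raise ValidationError("probe map is empty")
    mapping = pmap.df.set_index("probe_id")["gene_id"]
    present = expr.values.index.intersection(mapping.index)
    unmapped = expr.values.index.difference(mapping.index)
    if len(unmapped):
        logger.info("collapse_probes: dropping %d unmapped probes: %s",
                    len(unmapped), list(unmapped[:10]))
    if not len(present):
        raise ValidationError("no probes in the matrix are covered by the map")
    collapsed = expr.values.loc[present].groupby(mapping[present]).mean()
    collapsed.index.name = expr.values.index.name
    return expr.with_values(collapsed, expr.transform_state)


def filter_low_expression(
    expr: ExpressionMatrix,
    detect_threshold: float = 0.0,
    min_fraction: float = 0.5,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes not detected in at least ``min_fraction`` of samples.

    A gene is removed iff the fraction of samples with value <=
    ``detect_threshold`` is >= ``min_fraction`` (inclusive boundary: a gene
    undetected in exactly half the cohort is removed under the defaults).
    """
    if not 0 < min_fraction <= 1:
        raise ValidationError("min_fraction must lie in (0, 1]")
    if expr.transform_state not in ("raw", "log2p1"):
        raise StateError("filter_low_expression expects raw or log2p1 data")
    frac_undetected = (expr.values <= detect_threshold).mean(axis=1)
    removed = expr.values.index[frac_undetected >= min_fraction].tolist()
    kept = expr.values.drop(index=removed)
    return expr.with_values(kept, expr.transform_state), removed


def zscore(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, ScalingParams]:
    """Per-gene standardization across samples (mean 0, sample SD 1).

    Zero-variance genes are flagged in the returned params and set to 0.
    """
    expr.require_log_scale("zscore")
    center = expr.values.mean(axis=1)
    sd = expr.values.std(axis=1, ddof=1)
    zero_var = sd.index[(sd == 0) | sd.isna()].tolist()
    scale = sd.where(~sd.index.isin(zero_var), 1.0)
    params = ScalingParams(
        center=center,
        scale=scale,
        method="zscore",
        reference_description=f"{expr.n_samples} samples",
        zero_variance_genes=tuple(zero_var),
    )
    return expr.with_values(params.apply(expr.values), "zscored"), params


def median_center_balanced(
    expr: ExpressionMatrix,
    er_status: pd.Series,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ScalingParams]:
    """Subtract the per-gene median of an ER-balanced reference subset.

    The reference takes all samples of the minority ER class and an
    equally-sized seeded simple random sample of the majority class, so the
    centring reference is 50% ER-positive / 50% ER-negative regardless of
    cohort composition.
    """
    expr.require_log_scale("median_center_balanced")
    er = er_status.reindex(expr.sample_ids)
    pos = er.index[er == "pos"].tolist()
    neg = er.index[er == "neg"].tolist()
    if not pos or not neg:
        raise ValidationError("median_center_balanced needs both ER classes present")
    m = min(len(pos), len(neg))
    rng = np.random.default_rng(seed)
    take_pos = pos if len(pos) == m else sorted(rng.choice(pos, size=m, replace=False))
    take_neg = neg if len(neg) == m else sorted(rng.choice(neg, size=m, replace=False))
    subset = take_pos + take_neg
    medians = expr.values[subset].median(axis=1)
    params = ScalingParams(
        center=medians,
        scale=pd.Series(1.0, index=medians.index),
        method="median_center_balanced",
        reference_description=f"balanced ER subset of {2 * m} samples (seed={seed})",
    )
    return expr.with_values(params.apply(expr.values), "median_centered"), params


class GeneStandardScaler(BaseEstimator, TransformerMixin):
    """Per-feature standardization with sample SD (ddof=1).

    sklearn-compatible counterpart of :func:`zscore` for samples x genes
    arrays; zero-variance features are flagged and transformed to 0.

    Attributes
    ----------
    mean_ : ndarray of shape (n_features,)
    scale_ : ndarray of shape (n_features,)
    zero_variance_mask_ : ndarray of bool, shape (n_features,)
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        self.zero_variance_mask_ = sd == 0
        self.scale_ = np.where(self.zero_variance_mask_, 1.0, sd)
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = check_array(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        Z[:, self.zero_variance_mask_] = 0.0
        return Z

    def inverse_transform(self, Z):
        check_is_fitted(self, "mean_")
        Z = check_array(Z, dtype=float)
        return Z * self.scale_ + self.mean_
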