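"""Unsupervised discovery of expression clusters.

Pearson correlation distance (d = 1 - r), unweighted average-linkage
(UPGMA-style) agglomeration, dendrogram cutting with stable 1..k labels,
and silhouette-based selection of the cluster number — the classic
heatmap-clustering stack for tumour cohorts.

scipy.cluster.hierarchy performs the agglomeration and sklearn the
silhouette computation; the functions here fix conventions (label order,
singleton silhouette = 0, the distance definition) and validate inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_samples
from sklearn.utils.validation import check_array

from .core_data import ExpressionMatrix, ValidationError


@dataclass
class DistanceMatrix:
    """Symmetric correlation-distance matrix over named observations."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        if d.min() < -1e-12 or d.max() > 2 + 1e-12:
            raise ValidationError("correlation distances must lie in [0, 2]")
        self.d = np.clip(d, 0.0, 2.0)
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class Dendrogram:
    """Agglomeration result: a scipy linkage matrix plus the leaf ids.

    Merge heights are recorded as computed; average linkage does not
    guarantee monotone heights in general and no inversion check is made.
    """

    linkage: np.ndarray  # scipy (n-1, 4) linkage matrix
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def leaf_order(self) -> list[str]:
        """Leaves in dendrogram (plot) order."""
        return [self.leaf_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.leaf_ids[node.id]}:{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{max(length, 0.0):.10g}"

        left = rec(tree.left, tree.dist)
        right = rec(tree.right, tree.dist)
        return f"({left},{right});"


@dataclass
class SilhouetteReport:
    """Mean silhouette per candidate k and the maximizing choice."""

    scores: dict[int, float]
    chosen_k: int

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"k": list(self.scores), "mean_silhouette": list(self.scores.values())}
        )
        df["chosen"] = df["k"] == self.chosen_k
        return df


def _vectors(expr: ExpressionMatrix | pd.DataFrame, axis: str) -> pd.DataFrame:
    vals = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if axis == "samples":
        return vals.T  # observations in rows
    if axis == "genes":
        return vals
    raise ValidationError(f"axis must be 'samples' or 'genes', got {axis!r}")


def pearson_distance(expr: ExpressionMatrix | pd.DataFrame, axis: str = "samples") -> DistanceMatrix:
    """d(i, j) = 1 - Pearson r between observation vectors.

    ``axis="samples"`` compares samples across genes (the patient-clustering
    direction); ``axis="genes"`` compares genes across samples.  Constant
    vectors have undefined correlation and are rejected by name.
    """
    obs = _vectors(expr, axis)
    if obs.shape[1] < 3:
        raise ValidationError("need at least 3 entries per vector for a correlation")
    sd = obs.std(axis=1, ddof=0)
    constant = obs.index[sd == 0].tolist()
    if constant:
        raise ValidationError(f"constant vectors have undefined correlation: {constant}")
    r = np.corrcoef(obs.to_numpy())
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(obs.index), d=np.clip(d, 0.0, 2.0))


def average_linkage(dm: DistanceMatrix) -> Dendrogram:
    """Unweighted average-linkage (UPGMA) agglomeration of a distance matrix."""
    if dm.n < 2:
        raise ValidationError("need at least 2 observations to cluster")
    condensed = squareform(dm.d, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=Z, leaf_ids=list(dm.ids))


def cut_tree(dend: Dendrogram, k: int) -> pd.Series:
    """Cut into k flat clusters; labels 1..k in dendrogram-leaf order of
    first occurrence (stable across runs)."""
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside [1, {n}]")
    raw = hierarchy.cut_tree(dend.linkage, n_clusters=k).ravel()
    order = hierarchy.leaves_list(dend.linkage)
    relabel: dict[int, int] = {}
    for leaf in order:
        if raw[leaf] not in relabel:
            relabel[raw[leaf]] = len(relabel) + 1
    labels = pd.Series([relabel[c] for c in raw], index=dend.leaf_ids, name="cluster")
    return labels


def silhouette_values(dm: DistanceMatrix, labels: pd.Series) -> pd.Series:
    """Per-observation silhouette s(i) = (b - a) / max(a, b) on the given
    distance matrix; singleton clusters score 0 by convention."""
    lab = labels.reindex(dm.ids).to_numpy()
    vals = silhouette_samples(dm.d, lab, metric="precomputed")
    return pd.Series(vals, index=dm.ids, name="silhouette")


def silhouette_select_k(
    dm: DistanceMatrix,
    dend: Dendrogram,
    k_range: tuple[int, ...] | range = (2, 3, 4, 5, 6),
) -> SilhouetteReport:
    """Mean silhouette for each candidate k (clusters from cutting the
    dendrogram); chosen k maximizes the mean, smallest k winning ties."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValidationError("empty k_range")
    n = dend.n_leaves
    for k in ks:
        if not 2 <= k <= n - 1:
            raise ValidationError(f"k={k} outside [2, {n - 1}]")
    scores = {
        k: float(silhouette_values(dm, cut_tree(dend, k)).mean()) for k in ks
    }
    chosen = max(scores, key=lambda k: (scores[k], -k))
    return SilhouetteReport(scores=scores, chosen_k=chosen)


class CorrelationClusterer(BaseEstimator, ClusterMixin):
    """Hierarchical clustering with Pearson correlation distance and
    average linkage, sklearn-style.

    Rows of X are observations (samples), columns features (genes).  With
    ``n_clusters=None`` the number of clusters is chosen by maximizing the
    mean silhouette over ``k_range``.

    Attributes
    ----------
    labels_ : ndarray of int (1..k)
    n_clusters_ : int
    linkage_ : scipy linkage matrix
    silhouette_report_ : SilhouetteReport or None
    """

    def __init__(self, n_clusters: int | None = 3, k_range: tuple[int, ...] = (2, 3, 4, 5, 6)):
        self.n_clusters = n_clusters
        self.k_range = k_range

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
        dm = pearson_distance(pd.DataFrame(X.T, columns=ids), axis="samples")
        dend = average_linkage(dm)
        self.silhouette_report_ = None
        if self.n_clusters is None:
            self.silhouette_report_ = silhouette_select_k(dm, dend, self.k_range)
            k = self.silhouette_report_.chosen_k
        else:
            k = int(self.n_clusters)
        labels = cut_tree(dend, k)
        self.n_clusters_ = k
        self.linkage_ = dend.linkage
        self.labels_ = labels.to_numpy()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
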