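"""Seeded synthetic cohorts with planted structure for ground-truth tests.

The generator emulates the statistical skeleton of a multi-platform tumour
transcriptomics study: K patient groups with group-specific mean shifts on a
subset of "informative" genes, a normal-tissue reference at baseline,
count-like (negative binomial) or intensity-like (Gaussian on log2 scale)
measurements, and overall survival following proportional hazards with
group-dependent hazard ratios and independent exponential censoring.

Everything is deterministic given ``CohortSpec.seed``: the seed is expanded
into named substreams (expression / normal reference / survival /
covariates) so each artifact can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_data import ClinicalTable, ExpressionMatrix, ValidationError

_STREAMS = {"expression": 0, "normal": 1, "survival": 2, "covariates": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=seed, counter=[_STREAMS[stream], 0, 0, 0]))


def default_shift_matrix(n_informative: int, n_clusters: int, shift: float = 1.5) -> np.ndarray:
    """Block-diagonal planted shifts: the informative genes are split into
    ``n_clusters`` contiguous blocks and block *j* is shifted by ``shift``
    log2 units in cluster *j* only."""
    m = np.zeros((n_informative, n_clusters))
    bounds = np.linspace(0, n_informative, n_clusters + 1).astype(int)
    for j in range(n_clusters):
        m[bounds[j]:bounds[j + 1], j] = shift
    return m


@dataclass
class CohortSpec:
    """Generating parameters of one synthetic cohort.

    Defaults describe the reference study conditions used throughout the
    test-suite: three patient clusters of 200 samples on an 89-gene family
    panel, 30 informative genes carrying +1.5 log2 shifts in disjoint
     10-gene blocks (well above one within-cluster SD on either platform),
    overdispersed counts, and cluster hazard ratios of 1 / 2.8 / 2.0 with
    70% censoring — the hazard-ratio ordering and heavy censoring typical
    of breast-cancer cohorts.
    """

    n_samples_per_cluster: tuple[int, ...] = (200, 200, 200)
    n_genes: int = 89
    n_informative_genes: int = 30
    shift_matrix: np.ndarray | None = None  # (n_informative, K) log2 shifts
    platform: str = "count_like"
    nb_dispersion: float = 0.15  # var = mu + alpha * mu^2
    baseline_log2_mean: np.ndarray | float | None = None  # None -> Uniform(3, 9)
    intensity_sd: float = 1.0
    censoring_rate: float = 0.7
    cluster_log_hr: tuple[float, ...] | None = None  # None: (0, log 2.8, log 2) at K=3, else zeros
    baseline_hazard_scale: float = 1.0 / 3000.0  # events per day
    covariate_confounding: float = 0.0  # shifts node-positive odds by cluster
    seed: int = 0
    gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_samples_per_cluster):
            raise ValidationError("cluster sizes must be positive")
        if self.platform not in ("count_like", "intensity"):
            raise ValidationError(f"unknown platform {self.platform!r}")
        if self.n_informative_genes > self.n_genes:
            raise ValidationError("n_informative_genes > n_genes")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must lie in [0, 1)")
        if self.nb_dispersion <= 0 or self.intensity_sd <= 0:
            raise ValidationError("dispersions must be strictly positive")
        if self.cluster_log_hr is None:
            self.cluster_log_hr = (
                (0.0, math.log(2.8), math.log(2.0))
                if self.n_clusters == 3
                else tuple(0.0 for _ in range(self.n_clusters))
            )
        if len(self.cluster_log_hr) != self.n_clusters:
            raise ValidationError("cluster_log_hr length must equal number of clusters")
        if self.shift_matrix is None:
            self.shift_matrix = default_shift_matrix(self.n_informative_genes, self.n_clusters)
        self.shift_matrix = np.asarray(self.shift_matrix, dtype=float)
        if self.shift_matrix.shape != (self.n_informative_genes, self.n_clusters):
            raise ValidationError(
                f"shift_matrix shape {self.shift_matrix.shape} != "
                f"({self.n_informative_genes}, {self.n_clusters})"
            )
        if self.gene_ids is not None and len(self.gene_ids) != self.n_genes:
            raise ValidationError("gene_ids length must equal n_genes")

    @property
    def n_clusters(self) -> int:
        return len(self.n_samples_per_cluster)

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_samples_per_cluster))

    def resolved_gene_ids(self) -> list[str]:
        if self.gene_ids is not None:
            return list(self.gene_ids)
        width = len(str(self.n_genes))
        return [f"gene_{i + 1:0{width}d}" for i in range(self.n_genes)]

    def resolved_baselines(self) -> np.ndarray:
        """Per-gene baseline log2 mean; drawn Uniform(3, 9) from the seed's
        expression substream when not supplied."""
        if self.baseline_log2_mean is None:
            rng = _rng(self.seed, "expression")
            return rng.uniform(3.0, 9.0, size=self.n_genes)
        b = np.asarray(self.baseline_log2_mean, dtype=float)
        if b.ndim == 0:
            return np.full(self.n_genes, float(b))
        if b.shape != (self.n_genes,):
            raise ValidationError("baseline_log2_mean must be scalar or per-gene")
        return b

    def full_shift_matrix(self) -> np.ndarray:
        """(n_genes, K) shifts; non-informative genes all zero."""
        full = np.zeros((self.n_genes, self.n_clusters))
        full[: self.n_informative_genes] = self.shift_matrix
        return full


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    true_cluster: pd.Series  # sample_id -> label in 1..K
    true_log2fc: pd.DataFrame  # genes x clusters, shift vs baseline (= vs normal)
    cluster_log_hr: pd.Series  # cluster label -> log hazard ratio vs cluster 1
    gene_log_hr: pd.Series | None = None  # per-gene log HR used in survival, if any

    @property
    def n_clusters(self) -> int:
        return int(self.true_cluster.max())


def _draw(spec: CohortSpec, rng: np.random.Generator, mean_log2: np.ndarray) -> np.ndarray:
    """Sample a (genes x samples) block with the given per-cell log2 means."""
    if spec.platform == "count_like":
        mu = np.exp2(mean_log2)
        size = 1.0 / spec.nb_dispersion  # NB shape: var = mu + mu^2 / size
        p = size / (size + mu)
        return rng.negative_binomial(size, p).astype(float)
    return rng.normal(mean_log2, spec.intensity_sd)


def simulate_expression(spec: CohortSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate the tumour cohort matrix plus its planted truth.

    Count-like platform: NB(mean = 2**(baseline + shift), var = mu + alpha
    mu^2).  Intensity platform: Gaussian on log2 scale with the same mean
    structure and SD ``intensity_sd``.
    """
    rng = _rng(spec.seed, "expression")
    baselines = spec.resolved_baselines() if spec.baseline_log2_mean is not None else None
    if baselines is None:
        # keep the baseline draw and the value draws on one substream so a
        # spec is a single reproducible object
        baselines = rng.uniform(3.0, 9.0, size=spec.n_genes)
    shifts = spec.full_shift_matrix()
    genes = spec.resolved_gene_ids()

    labels: list[int] = []
    blocks: list[np.ndarray] = []
    for k, n_k in enumerate(spec.n_samples_per_cluster):
        mean_log2 = (baselines + shifts[:, k])[:, None] * np.ones((1, n_k))
        blocks.append(_draw(spec, rng, mean_log2))
        labels.extend([k + 1] * n_k)
    values = np.concatenate(blocks, axis=1)
    width = len(str(spec.n_samples))
    sample_ids = [f"T{i + 1:0{width}d}" for i in range(spec.n_samples)]
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids),
        platform=spec.platform,
        transform_state="raw",
    )
    truth = SyntheticTruth(
        true_cluster=pd.Series(labels, index=sample_ids, name="true_cluster"),
        true_log2fc=pd.DataFrame(
            shifts, index=genes, columns=[f"cluster_{k + 1}" for k in range(spec.n_clusters)]
        ),
        cluster_log_hr=pd.Series(
            spec.cluster_log_hr, index=range(1, spec.n_clusters + 1), name="log_hr"
        ),
    )
    return expr, truth


def simulate_normal_reference(spec: CohortSpec, n_normal: int) -> ExpressionMatrix:
    """Baseline-only samples on the same platform (a normal-tissue reference).

    Requires ``n_normal >= 2`` — differential expression needs replication.
    """
    if n_normal < 2:
        raise ValidationError("need at least 2 normal samples")
    # baselines must match the tumour matrix: re-derive them the same way
    rng_b = _rng(spec.seed, "expression")
    if spec.baseline_log2_mean is None:
        baselines = rng_b.uniform(3.0, 9.0, size=spec.n_genes)
    else:
        baselines = spec.resolved_baselines()
    rng = _rng(spec.seed, "normal")
    mean_log2 = baselines[:, None] * np.ones((1, n_normal))
    values = _draw(spec, rng, mean_log2)
    width = len(str(n_normal))
    sample_ids = [f"N{i + 1:0{width}d}" for i in range(n_normal)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=spec.resolved_gene_ids(), columns=sample_ids),
        platform=spec.platform,
        transform_state="raw",
    )


def _calibrate_censoring(hazards: np.ndarray, rate: float) -> float:
    """Rate of the independent exponential censoring process such that the
    expected censored fraction equals ``rate``.

    For exponential event and censoring times, P(censored | hazard h) =
    c / (c + h); the cohort-level rate is the mean over samples, solved for
    c by bisection (monotone in c).
    """
    if rate == 0:
        return 0.0

    def f(log_c: float) -> float:
        c = math.exp(log_c)
        return float(np.mean(c / (c + hazards))) - rate

    lo, hi = math.log(hazards.min()) - 30, math.log(hazards.max()) + 30
    return math.exp(brentq(f, lo, hi, xtol=1e-12))


def simulate_survival(
    truth: SyntheticTruth,
    spec: CohortSpec,
    gene_log_hr: pd.Series | None = None,
    expr_log2: pd.DataFrame | None = None,
) -> ClinicalTable:
    """Exponential proportional-hazards survival with independent censoring.

    Each sample's event hazard is ``baseline_hazard_scale *
    exp(cluster_log_hr[cluster] + sum_g gene_log_hr[g] * z_g)`` where
    ``z_g`` is the per-gene standardized log2 expression (only when
    ``gene_log_hr`` is supplied together with ``expr_log2``, a genes x
    samples log-scale frame).  Censoring is exponential, independent, with
    its rate calibrated in closed form so the expected censored fraction
    equals ``spec.censoring_rate``.  Clinical covariates are drawn
    independently of cluster unless ``spec.covariate_confounding`` is set.
    """
    labels = truth.true_cluster
    n = len(labels)
    lhr = truth.cluster_log_hr.reindex(labels.to_numpy()).to_numpy()
    eta = lhr.copy()
    if gene_log_hr is not None:
        if expr_log2 is None:
            raise ValidationError("gene_log_hr requires expr_log2")
        sub = expr_log2.loc[gene_log_hr.index, labels.index]
        z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
        eta = eta + gene_log_hr.to_numpy() @ z.to_numpy()
        truth.gene_log_hr = gene_log_hr
    hazards = spec.baseline_hazard_scale * np.exp(eta)

    rng = _rng(spec.seed, "survival")
    event_t = rng.exponential(1.0 / hazards)
    c_rate = _calibrate_censoring(hazards, spec.censoring_rate)
    if c_rate > 0:
        censor_t = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor_t = np.full(n, np.inf)
    os_time = np.minimum(event_t, censor_t)
    os_event = (event_t <= censor_t).astype(int)

    rng_c = _rng(spec.seed, "covariates")
    k = labels.to_numpy() - 1
    p_node = np.clip(0.45 + spec.covariate_confounding * k, 0.02, 0.98)
    df = pd.DataFrame(
        {
            "sample_id": labels.index,
            "os_time": os_time,
            "os_event": os_event,
            "age": np.clip(np.round(rng_c.normal(58, 12, n)), 25, 90),
            "node_status": np.where(rng_c.random(n) < p_node, "positive", "negative"),
            "tumour_size": np.where(rng_c.random(n) < 0.5, "gt2cm", "le2cm"),
            "stage": rng_c.choice([1, 2, 3, 4], size=n, p=[0.18, 0.45, 0.27, 0.10]),
            "er": np.where(rng_c.random(n) < 0.75, "pos", "neg"),
            "pr": np.where(rng_c.random(n) < 0.65, "pos", "neg"),
            "her2": np.where(rng_c.random(n) < 0.15, "pos", "neg"),
            "subtype_label": [f"cluster_{c}" for c in labels],
        }
    )
    return ClinicalTable(df)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Planted labels as TSV for external harnesses."""
    truth.true_cluster.rename_axis("sample_id").to_frame().to_csv(path, sep="\t")
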