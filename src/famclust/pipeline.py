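"""End-to-end orchestration of the analysis stages.

simulate/ingest -> preprocess -> cluster discovery -> centroid classifier
(train/test split) -> differential expression + concordance + set
partition -> survival, all driven by one :class:`PipelineConfig` and one
seed, writing flat TSV/JSON artifacts plus a run manifest.  Re-running the
same config and seed reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import centroid as ct
from . import cluster as cl
from . import dge as dg
from . import preprocess as pp
from . import survival as sv
from .core_data import (
    ClinicalTable,
    ExpressionMatrix,
    ValidationError,
    align_cohort,
    load_gene_family,
    read_clinical,
    read_expression,
    write_clinical,
    write_expression,
)
from .synthetic import CohortSpec, simulate_expression, simulate_normal_reference, simulate_survival, write_truth

logger = logging.getLogger("famclust")

#: family genes excluded from classifier training because of pervasively
#: low expression, plus the member unmatched on array platforms
DEFAULT_EXCLUSIONS = ("DNAJB8", "DNAJC5G", "DNAJB3", "ODF1", "CRYAA", "HSPB3")
DEFAULT_UNMAPPED = ("HSPA7",)


@dataclass
class PipelineConfig:
    """Everything one analysis run depends on.

    ``expression_path``/``clinical_path`` switch the pipeline to ingested
    data; otherwise a synthetic cohort is generated from ``synthetic``
    (overrides applied to :class:`CohortSpec` defaults).
    """

    seed: int = 0
    outdir: str = "famclust_run"
    expression_path: str | None = None
    clinical_path: str | None = None
    platform: str = "count_like"
    synthetic: dict = field(default_factory=dict)
    n_normal: int = 114
    gene_panel_path: str | None = None  # None -> bundled family annotation
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS
    lfc_cut: float = 1.0
    fdr_cut: float = 0.05
    detect_threshold: float = 0.0
    min_fraction: float = 0.5
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_clusters: int | None = None  # None -> silhouette selection
    split_fraction: float = 0.5
    survival_covariates: tuple[str, ...] = ("age", "node_status", "tumour_size", "stage")
    min_coverage: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValidationError("split_fraction must lie in (0, 1)")
        if not 0 < self.min_fraction <= 1:
            raise ValidationError("min_fraction must lie in (0, 1]")
        if self.fdr_cut <= 0 or self.fdr_cut >= 1:
            raise ValidationError("fdr_cut must lie in (0, 1)")
        if self.lfc_cut < 0:
            raise ValidationError("lfc_cut must be non-negative")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("exclusions", "k_range", "survival_covariates"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("exclusions", "k_range", "survival_covariates"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(outdir: Path, config: PipelineConfig, artifacts: list[str]) -> None:
    from . import __version__

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "famclust_version": __version__,
        "artifacts": sorted(artifacts),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _load_or_simulate(
    config: PipelineConfig, outdir: Path, artifacts: list[str]
):
    """Returns (expr raw, clinical, normal reference or None, truth or None)."""
    if config.expression_path:
        expr = read_expression(config.expression_path, platform=config.platform)
        clin = read_clinical(config.clinical_path) if config.clinical_path else None
        return expr, clin, None, None
    family = load_gene_family(config.gene_panel_path)
    overrides = dict(config.synthetic)
    overrides.setdefault("platform", config.platform)
    overrides.setdefault("seed", config.seed)
    if "n_genes" not in overrides:
        # default panel: the family minus its low-expression members
        panel = [g for g in family.gene_ids if g not in config.exclusions]
        overrides["n_genes"] = len(panel)
        overrides["gene_ids"] = tuple(panel)
    spec = CohortSpec(**overrides)
    expr, truth = simulate_expression(spec)
    normal = simulate_normal_reference(spec, config.n_normal)
    clin = simulate_survival(truth, spec)
    write_expression(expr, outdir / "expression_raw.tsv")
    write_expression(normal, outdir / "normal_reference.tsv")
    write_clinical(clin, outdir / "clinical.tsv")
    write_truth(truth, outdir / "truth_clusters.tsv")
    artifacts += ["expression_raw.tsv", "normal_reference.tsv", "clinical.tsv", "truth_clusters.tsv"]
    return expr, clin, normal, truth


def _to_log_scale(expr: ExpressionMatrix) -> ExpressionMatrix:
    if expr.platform == "count_like" and expr.transform_state == "raw":
        return pp.log2p1(expr)
    return expr


def _split_samples(sample_ids, fraction: float, seed: int) -> tuple[list, list]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD15C]).generate_state(1)[0])
    ids = list(sample_ids)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


def run_discovery(config: PipelineConfig) -> dict:
    """Full discovery pass; returns the in-memory artifacts and writes
    everything under ``config.outdir``.

    Stages: (1) simulate or ingest; (2) low-expression filter + log2;
    (3) correlation-distance average-linkage clustering with silhouette
    selection of k; (4) train/test split, per-gene z-scaling, centroid
    training and held-out classification; (5) two-estimator DGE vs the
    normal reference with concordance and Venn partition (when a reference
    exists); (6) KM/log-rank across clusters, gene-wise Cox screen,
    multivariate Cox adjusted for clinical covariates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    result: dict = {}

    expr_raw, clin, normal, truth = _load_or_simulate(config, outdir, artifacts)
    result["truth"] = truth

    # -- preprocessing --------------------------------------------------
    if expr_raw.platform == "count_like":
        filtered, removed = pp.filter_low_expression(
            expr_raw, config.detect_threshold, config.min_fraction
        )
    else:
        filtered, removed = expr_raw, []
    (outdir / "low_expression_removed.txt").write_text("\n".join(map(str, removed)) + "\n")
    artifacts.append("low_expression_removed.txt")
    log_expr = _to_log_scale(filtered)
    result["log_expr"] = log_expr

    # -- cluster discovery ---------------------------------------------
    dm = cl.pearson_distance(log_expr, axis="samples")
    dend = cl.average_linkage(dm)
    if config.n_clusters is None:
        ks = [k for k in config.k_range if 2 <= k <= dm.n - 1]
        report = cl.silhouette_select_k(dm, dend, tuple(ks))
        k = report.chosen_k
        report.as_frame().to_csv(outdir / "silhouette.tsv", sep="\t", index=False, float_format="%.10g")
        artifacts.append("silhouette.tsv")
        result["silhouette"] = report
    else:
        k = config.n_clusters
    labels = cl.cut_tree(dend, k)
    labels.rename_axis("sample_id").to_frame().to_csv(outdir / "cluster_labels.tsv", sep="\t")
    (outdir / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
    artifacts += ["cluster_labels.tsv", "dendrogram.nwk"]
    result["labels"] = labels
    result["k"] = k

    # -- centroid classifier -------------------------------------------
    train_ids, test_ids = _split_samples(log_expr.sample_ids, config.split_fraction, config.seed)
    train = log_expr.subset(samples=train_ids)
    scaled_train, scaling = pp.zscore(train)
    model = ct.train_centroids(scaled_train, labels[train_ids], scaling=scaling)
    model.to_dir(outdir / "centroid_model")
    artifacts.append("centroid_model")
    test = log_expr.subset(samples=test_ids)
    assignments = ct.classify_matrix(test, model, min_coverage=config.min_coverage)
    assignments.to_csv(outdir / "test_assignments.tsv", sep="\t", float_format="%.10g")
    artifacts.append("test_assignments.tsv")
    test_acc = float((assignments["label"] == labels[test_ids]).mean())
    result["model"] = model
    result["assignments"] = assignments
    result["test_accuracy"] = test_acc

    # -- differential expression ---------------------------------------
    if normal is not None:
        if expr_raw.platform == "count_like":
            combined = ExpressionMatrix(
                pd.concat([expr_raw.values, normal.values], axis=1),
                platform="count_like",
            )
            norm = dg.cpm_normalize(combined)
        else:
            norm = ExpressionMatrix(
                pd.concat([expr_raw.values, normal.values], axis=1),
                platform="intensity",
            )
        groups = {
            f"cluster_{c}": labels.index[labels == c].tolist()
            for c in sorted(labels.unique())
        }
        results, concordance = dg.dge_all_contrasts(
            norm, groups, list(normal.sample_ids), config.lfc_cut, config.fdr_cut
        )
        dg.write_dge_tables(results, outdir / "dge_tables.tsv")
        artifacts.append("dge_tables.tsv")
        flagged = set().union(*(c.disagreeing_genes for c in concordance.values()))
        up_sets = {}
        down_sets = {}
        for name, pair in results.items():
            up, down = dg.threshold_deg(pair["E1_parametric"], config.lfc_cut, config.fdr_cut)
            up2, down2 = dg.threshold_deg(pair["E2_rank"], config.lfc_cut, config.fdr_cut)
            up_sets[name] = up & up2
            down_sets[name] = down & down2
        partitions = {}
        if len(up_sets) >= 2:
            partitions["up"] = dg.partition_deg_sets(up_sets, excluded=flagged)
            partitions["down"] = dg.partition_deg_sets(down_sets, excluded=flagged)
            rows = []
            for direction, part in partitions.items():
                for pattern, genes in sorted(part.regions.items(), key=lambda kv: sorted(kv[0])):
                    rows.append(
                        {
                            "direction": direction,
                            "region": "+".join(sorted(pattern)),
                            "genes": ",".join(sorted(genes)),
                        }
                    )
            pd.DataFrame(rows).to_csv(outdir / "deg_partition.tsv", sep="\t", index=False)
            artifacts.append("deg_partition.tsv")
        conc_rows = [
            {
                "contrast": c.contrast,
                "pearson_r": c.pearson_r,
                "mean_diff": c.mean_diff,
                "loa_lower": c.loa_lower,
                "loa_upper": c.loa_upper,
                "frac_within_limits": c.frac_within_limits,
                "n_disagreements": len(c.disagreeing_genes),
            }
            for c in concordance.values()
        ]
        pd.DataFrame(conc_rows).to_csv(
            outdir / "method_concordance.tsv", sep="\t", index=False, float_format="%.10g"
        )
        artifacts.append("method_concordance.tsv")
        result["dge"] = results
        result["concordance"] = concordance
        result["partitions"] = partitions
        result["up_sets"], result["down_sets"] = up_sets, down_sets

    # -- survival -------------------------------------------------------
    if clin is not None:
        expr_s, clin_s = align_cohort(log_expr, clin)
        surv = clin_s.survival_frame()
        lab = labels.reindex(surv.index).dropna()
        surv = surv.loc[lab.index]
        lr = sv.logrank(surv["os_time"], surv["os_event"], lab.to_numpy())
        curves = sv.km_by_group(surv["os_time"], surv["os_event"], lab.to_numpy())
        km_frames = []
        for g, curve in sorted(curves.items()):
            f = curve.as_frame()
            f.insert(0, "cluster", g)
            km_frames.append(f)
        pd.concat(km_frames, ignore_index=True).to_csv(
            outdir / "km_curves.tsv", sep="\t", index=False, float_format="%.10g"
        )
        screen, skipped = sv.cox_univariate_screen(expr_s, clin_s)
        screen.to_csv(outdir / "cox_screen.tsv", sep="\t", index=False, float_format="%.10g")
        design = sv.build_design(clin_s, cluster_labels=lab, covariates=config.survival_covariates)
        multi = sv.cox_multivariate(design)
        multi.to_csv(outdir / "cox_multivariate.tsv", sep="\t", index=False, float_format="%.10g")
        (outdir / "logrank.json").write_text(
            json.dumps(
                {"statistic": lr.statistic, "df": lr.df, "pvalue": lr.pvalue}, indent=1
            )
        )
        artifacts += ["km_curves.tsv", "cox_screen.tsv", "cox_multivariate.tsv", "logrank.json"]
        result["logrank"] = lr
        result["cox_screen"] = screen
        result["cox_multivariate"] = multi

    config.to_yaml(outdir / "config.yaml")
    artifacts.append("config.yaml")
    _write_manifest(outdir, config, artifacts)
    return result


def run_validation(
    config: PipelineConfig,
    model: ct.CentroidModel,
    expr: ExpressionMatrix,
    clin: ClinicalTable | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Apply a trained centroid model to a new cohort.

    Writes the assignment table, per-cluster KM curves + log-rank test,
    and the cross-cohort centroid-correlation matrix (new-cohort centroids
    retrained from its own assignments, then matched to the model's).
    """
    outdir = Path(outdir or Path(config.outdir) / "validation")
    outdir.mkdir(parents=True, exist_ok=True)
    log_expr = _to_log_scale(expr)
    covered = [g for g in model.gene_panel if g in log_expr.gene_ids]
    coverage = len(covered) / len(model.gene_panel)
    if coverage < config.min_coverage:
        missing = [g for g in model.gene_panel if g not in covered]
        raise ValidationError(
            f"cohort covers {coverage:.2f} < {config.min_coverage} of the model panel; "
            f"missing genes: {missing}"
        )
    panel_expr = log_expr.subset(genes=covered)
    assignments = ct.classify_matrix(panel_expr, model, min_coverage=config.min_coverage)
    assignments.to_csv(outdir / "assignments.tsv", sep="\t", float_format="%.10g")
    result: dict = {"assignments": assignments}

    # retrain centroids on the new cohort's own assignments for the
    # cross-cohort correlation diagnostic
    scaled, scaling = pp.zscore(panel_expr)
    labels = assignments["label"]
    if labels.nunique() >= 2 and labels.value_counts().min() >= 2:
        local_model = ct.train_centroids(scaled, labels, scaling=scaling)
        mat, matching = ct.centroid_crosscorrelation(model, local_model)
        mat.rename_axis("model_class").to_csv(
            outdir / "centroid_crosscorrelation.tsv", sep="\t", float_format="%.10g"
        )
        result["crosscorrelation"] = mat
        result["matching"] = matching

    if clin is not None:
        _, clin_a = align_cohort(panel_expr, clin)
        surv = clin_a.survival_frame()
        lab = labels.reindex(surv.index).dropna()
        surv = surv.loc[lab.index]
        if lab.nunique() >= 2:
            lr = sv.logrank(surv["os_time"], surv["os_event"], lab.to_numpy())
            (outdir / "logrank.json").write_text(
                json.dumps({"statistic": lr.statistic, "df": lr.df, "pvalue": lr.pvalue}, indent=1)
            )
            result["logrank"] = lr
        curves = sv.km_by_group(surv["os_time"], surv["os_event"], lab.to_numpy())
        km_frames = []
        for g, curve in sorted(curves.items()):
            f = curve.as_frame()
            f.insert(0, "cluster", g)
            km_frames.append(f)
        pd.concat(km_frames, ignore_index=True).to_csv(
            outdir / "km_curves.tsv", sep="\t", index=False, float_format="%.10g"
        )
    return result
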