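"""Domain containers and flat-file IO for expression and clinical data.

Conventions
-----------
* Expression matrices are oriented genes x samples (rows = genes), the
  orientation heatmap-style analyses use.  Readers never guess orientation;
  transposed input must be fixed explicitly by the caller.
* Files are plain TSV/CSV, delimiter chosen by extension (``.tsv`` -> tab,
  anything else -> comma), UTF-8.
* All validation failures raise :class:`ValidationError`; using a matrix in
  the wrong transform state raises :class:`StateError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("famclust")

PLATFORMS = ("count_like", "intensity")
TRANSFORM_STATES = ("raw", "log2p1", "zscored", "median_centered")

#: genes x samples float format used by every writer, so that identical
#: in-memory objects always serialize to byte-identical files
FLOAT_FORMAT = "%.10g"


class ValidationError(ValueError):
    """Input data violates a container invariant."""


class StateError(RuntimeError):
    """Operation applied to a matrix in an incompatible transform state."""


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A gene x sample abundance matrix with platform and transform state.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample ids as columns.
    platform
        ``"count_like"`` for non-negative abundance (e.g. normalized RSEM)
        or ``"intensity"`` for values already on a log scale (microarray).
    transform_state
        One of ``raw``, ``log2p1``, ``zscored``, ``median_centered``.
        Transitions are monotone: raw -> log2p1 -> {zscored, median_centered}.
    """

    values: pd.DataFrame
    platform: str = "count_like"
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(f"unknown platform {self.platform!r}")
        if self.transform_state not in TRANSFORM_STATES:
            raise ValidationError(f"unknown transform state {self.transform_state!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if self.platform == "count_like" and self.transform_state == "raw":
            finite = np.isfinite(arr) | np.isnan(arr)
            if not finite.all():
                raise ValidationError("count_like raw values must be finite")
            neg = arr < 0
            if arr.size and np.any(neg):
                g, s = np.argwhere(neg)[0]
                raise ValidationError(
                    f"negative value {arr[g, s]} for gene {self.values.index[g]!r} "
                    f"sample {self.values.columns[s]!r} on count_like platform"
                )

    # -- views ----------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def is_log_scale(self) -> bool:
        """True when values live on a log2-like scale.

        Intensity platforms are log scale from the start; count-like data
        only after log2(x+1).
        """
        return self.platform == "intensity" or self.transform_state != "raw"

    def require_log_scale(self, op: str) -> None:
        if not self.is_log_scale:
            raise StateError(
                f"{op} requires log-scale input; got raw count_like data "
                "(apply log2p1 first)"
            )

    def subset(
        self,
        genes: Sequence | None = None,
        samples: Sequence | None = None,
    ) -> "ExpressionMatrix":
        vals = self.values
        if genes is not None:
            missing = [g for g in genes if g not in vals.index]
            if missing:
                raise ValidationError(f"genes absent from matrix: {missing}")
            vals = vals.loc[list(genes)]
        if samples is not None:
            missing = [s for s in samples if s not in vals.columns]
            if missing:
                raise ValidationError(f"samples absent from matrix: {missing}")
            vals = vals[list(samples)]
        return replace(self, values=vals)

    def with_values(self, values: pd.DataFrame, transform_state: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, platform=self.platform, transform_state=transform_state)


def read_expression(path: str | Path, platform: str = "count_like") -> ExpressionMatrix:
    """Read a genes-in-rows TSV/CSV into a raw :class:`ExpressionMatrix`.

    First column holds gene ids, header row holds sample ids.  Non-numeric
    cells raise a parse error naming the offending row and column; empty
    cells become NaN (missing, never imputed).
    """
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cell = raw[col].replace("", np.nan)
        num = pd.to_numeric(cell, errors="coerce")
        bad = cell.notna() & num.isna()
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise ValidationError(
                f"non-numeric value {cell[bad].iloc[0]!r} at gene {gene!r}, "
                f"sample {col!r} in {path}"
            )
        out[col] = num
    return ExpressionMatrix(out, platform=platform, transform_state="raw")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FORMAT, index_label="gene_id")


# ---------------------------------------------------------------------------
# ClinicalTable
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = (
    "sample_id",
    "os_time",
    "os_event",
    "age",
    "node_status",
    "tumour_size",
    "stage",
    "er",
    "pr",
    "her2",
    "subtype_label",
)

_TRISTATE = {"node_status": ("positive", "negative"), "er": ("pos", "neg"),
             "pr": ("pos", "neg"), "her2": ("pos", "neg"),
             "tumour_size": ("gt2cm", "le2cm")}


@dataclass
class ClinicalTable:
    """Per-sample survival outcome and clinical covariates.

    ``os_time`` is overall-survival follow-up in days, ``os_event`` 1 for a
    death and 0 for censoring.  Categorical covariates keep an explicit
    ``"unknown"`` level rather than NaN.  Rows lacking os_time/os_event are
    retained but flagged ineligible for survival operations.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if "sample_id" not in df.columns:
            raise ValidationError("clinical table needs a sample_id column")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        for col in _CLINICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col in ("os_time", "os_event", "age") else "unknown"
        df["os_time"] = pd.to_numeric(df["os_time"], errors="raise")
        df["os_event"] = pd.to_numeric(df["os_event"], errors="raise")
        if (df["os_time"].dropna() < 0).any():
            raise ValidationError("negative os_time")
        ev = df["os_event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValidationError(f"os_event outside {{0,1}}: {sorted(ev[~ev.isin([0,1])].unique())}")
        for col, levels in _TRISTATE.items():
            vals = df[col].astype(str).str.strip().str.lower()
            df[col] = vals.where(vals.isin(levels), "unknown")
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.df["sample_id"])

    @property
    def eligible(self) -> pd.Series:
        """Boolean mask of rows usable in survival operations."""
        return (self.df["os_time"].notna() & self.df["os_event"].notna()).rename("eligible")

    def survival_frame(self) -> pd.DataFrame:
        """Eligible rows indexed by sample id, with numeric os_time/os_event."""
        sub = self.df.loc[self.eligible].set_index("sample_id")
        return sub


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep=_sep_for(path))
    df["sample_id"] = df["sample_id"].astype(str)
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.df.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FORMAT, index=False)


def align_cohort(expr: ExpressionMatrix, clin: ClinicalTable) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict matrix and clinical table to shared samples, same order.

    Samples lacking clinical data (or expression) are dropped and the counts
    logged, mirroring the usual cohort-assembly exclusion step.
    """
    shared = [s for s in expr.sample_ids if s in set(clin.sample_ids)]
    if not shared:
        raise ValidationError("no samples shared between expression and clinical data")
    n_expr_drop = expr.n_samples - len(shared)
    n_clin_drop = len(clin.df) - len(shared)
    if n_expr_drop or n_clin_drop:
        logger.info(
            "align_cohort: dropped %d expression-only and %d clinical-only samples",
            n_expr_drop, n_clin_drop,
        )
    expr2 = expr.subset(samples=shared)
    clin_df = clin.df.set_index("sample_id").loc[shared].reset_index()
    return expr2, ClinicalTable(clin_df)


# ---------------------------------------------------------------------------
# Gene family annotation and probe maps
# ---------------------------------------------------------------------------

SUBFAMILIES = ("CHAP", "HSP70", "HSPB", "HSPC", "DNAJ")


@dataclass
class GeneFamilyAnnotation:
    """Mapping of family genes to subfamilies (one subfamily per gene)."""

    df: pd.DataFrame  # columns: gene_id, subfamily

    def __post_init__(self) -> None:
        if list(self.df.columns[:2]) != ["gene_id", "subfamily"]:
            raise ValidationError("annotation needs columns gene_id, subfamily")
        if self.df["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene in family annotation")
        bad = set(self.df["subfamily"]) - set(SUBFAMILIES)
        if bad:
            raise ValidationError(f"unknown subfamilies: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return self.df["gene_id"].tolist()

    def genes_in(self, subfamily: str) -> list[str]:
        return self.df.loc[self.df["subfamily"] == subfamily, "gene_id"].tolist()


def load_gene_family(path: str | Path | None = None) -> GeneFamilyAnnotation:
    """Load a gene-family annotation TSV; default is the bundled 95-gene
    heat-shock-protein family table (five subfamilies)."""
    if path is None:
        src = resources.files("famclust.data").joinpath("hsp_family.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep=_sep_for(path))
    return GeneFamilyAnnotation(df)


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene mapping (array platforms)."""

    df: pd.DataFrame  # columns: probe_id, gene_id

    def __post_init__(self) -> None:
        if list(self.df.columns[:2]) != ["probe_id", "gene_id"]:
            raise ValidationError("probe map needs columns probe_id, gene_id")
        if self.df["probe_id"].duplicated().any():
            raise ValidationError("duplicate probe ids in probe map")

    def unmapped_genes(self, gene_ids: Iterable[str]) -> list[str]:
        """Genes in ``gene_ids`` with no probe at all (reportable, e.g. a
        family member absent from an array design)."""
        covered = set(self.df["gene_id"])
        return [g for g in gene_ids if g not in covered]


def read_probe_map(path: str | Path) -> ProbeMap:
    return ProbeMap(pd.read_csv(path, sep=_sep_for(path), dtype=str))
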