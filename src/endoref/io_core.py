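"""Data model and file I/O for Cq tables and expression matrices.

The package works with two tabular shapes:

* long-format quantification-cycle (Cq) tables with one row per
  (sample, target, technical replicate) measurement, and
* gene x sample expression matrices (raw counts or log2 signal).

Replicate collapsing, the expressed-gene filter and the log2 transform
live here because every downstream module consumes their output.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    FormatError,
    InsufficientDataError,
    ParameterError,
    ScaleError,
    ValidationError,
)

logger = logging.getLogger("endoref")

CQ_COLUMNS = ("sample_id", "group", "target_id", "replicate", "cq")


@dataclass
class Config:
    """Run-wide tuning knobs with validated defaults."""

    sd_threshold: float = 0.5  # replicate-SD flag threshold, Cq units
    min_cpm: float = 1.0
    min_fraction: float = 0.5
    pseudocount: float = 1.0
    seed: int = 0
    align_match: int = 1
    align_mismatch: int = -1
    align_gap: int = -2
    efficiency_rounding: str = "nearest"  # nearest | none

    def __post_init__(self) -> None:
        for name in ("sd_threshold", "min_cpm", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0 < self.min_fraction <= 1):
            raise ParameterError(f"min_fraction must be in (0, 1], got {self.min_fraction}")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ParameterError(f"seed must be a non-negative integer, got {self.seed!r}")
        if self.efficiency_rounding not in ("nearest", "none"):
            raise ParameterError(f"unknown efficiency_rounding {self.efficiency_rounding!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class CqTable:
    """Long-format replicate-level Cq data.

    ``data`` holds the columns ``sample_id, group, target_id, replicate, cq``
    in original file order.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CQ_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"CqTable missing required column(s): {', '.join(missing)}")
        cq = pd.to_numeric(self.data["cq"], errors="coerce")
        bad = ~np.isfinite(cq) | (cq <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"invalid Cq value {self.data['cq'].iloc[row]!r} at data row {row + 1}: "
                "Cq must be finite and > 0"
            )
        self.data = self.data.assign(cq=cq.astype(float), replicate=self.data["replicate"].astype(int))
        if (self.data["replicate"] < 1).any():
            raise ValidationError("replicate indices must be positive integers")
        key = self.data[["sample_id", "target_id", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate measurement for sample={dup['sample_id']!r} "
                f"target={dup['target_id']!r} replicate={dup['replicate']}"
            )

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))

    @property
    def targets(self) -> list[str]:
        return list(dict.fromkeys(self.data["target_id"]))

    def to_file(self, path: str | Path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index=False)


@dataclass
class CqMatrix:
    """Replicate-collapsed Cq data: targets x samples mean, per-cell SD, QC flag."""

    values: pd.DataFrame  # targets x samples, mean Cq
    sd: pd.DataFrame  # same shape, replicate SD (ddof=1; 0 for n=1)
    groups: pd.Series  # indexed by sample id
    flags: pd.DataFrame  # True where SD > threshold
    sd_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (self.values.index.equals(self.sd.index) and self.values.columns.equals(self.sd.columns)):
            raise ValidationError("mean and SD matrices must share shape and labels")
        if (self.sd.to_numpy() < -1e-12).any():
            raise ValidationError("replicate SD must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def targets(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix on a declared scale.

    scale ``counts``: non-negative raw counts; ``log2``: real log2 signal.
    """

    values: pd.DataFrame
    scale: str = "counts"
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "log2"):
            raise ScaleError(f"scale must be 'counts' or 'log2', got {self.scale!r}")
        if self.scale == "counts" and (self.values.to_numpy() < 0).any():
            raise ValidationError("counts-scale matrix must be non-negative")
        if self.values.index.duplicated().any():
            raise ValidationError("gene ids must be unique")

    @property
    def mean_read_count(self) -> pd.Series:
        if self.scale != "counts":
            raise ScaleError("mean read count is defined for counts-scale matrices only")
        return self.values.mean(axis=1)

    def cpm(self) -> pd.DataFrame:
        """Counts per million; columns with zero library size map to 0."""
        if self.scale != "counts":
            raise ScaleError("CPM requires a counts-scale matrix")
        lib = self.values.sum(axis=0)
        safe = lib.replace(0, np.nan)
        return (self.values / safe * 1e6).fillna(0.0)

    def to_file(self, path: str | Path, sep: str = "\t") -> None:
        self.values.to_csv(path, sep=sep, index_label="gene_id")


def _sniff_delimiter(path: Path, dialect: str | None) -> str:
    if dialect in ("\t", "tab", "tsv"):
        return "\t"
    if dialect in (",", "comma", "csv"):
        return ","
    sample = path.read_text().splitlines()[0] if path.stat().st_size else ""
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_cq_table(
    path: str | Path,
    dialect: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> CqTable:
    """Read a long-format Cq table from TSV/CSV.

    Header names are matched case-insensitively; ``column_map`` renames
    non-standard headers (e.g. ``{"well_group": "group"}``) before matching.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    sep = _sniff_delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {', '.join(missing)} "
            f"(found: {', '.join(df.columns)})"
        )
    return CqTable(df[list(CQ_COLUMNS)].copy())


def read_expression_matrix(
    path: str | Path,
    scale: str = "counts",
    groups: Mapping[str, str] | pd.Series | None = None,
    dialect: str | None = None,
) -> ExpressionMatrix:
    """Read a gene x sample matrix (gene ids in the first column)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    sep = _sniff_delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric matrix entry ({exc})") from exc
    g = pd.Series(dict(groups)) if isinstance(groups, Mapping) else groups
    return ExpressionMatrix(values, scale=scale, groups=g)


def collapse_replicates(table: CqTable, sd_threshold: float = 0.5) -> CqMatrix:
    """Collapse technical replicates to per-(target, sample) mean Cq.

    SD uses the n-1 denominator (0 for a single replicate); a cell is
    flagged when its replicate SD exceeds ``sd_threshold``.
    """
    if sd_threshold <= 0:
        raise ParameterError(f"sd_threshold must be > 0, got {sd_threshold}")
    df = table.data
    if df.empty:
        raise InsufficientDataError("cannot collapse an empty Cq table")
    grouped = df.groupby(["target_id", "sample_id"], sort=False)["cq"]
    mean = grouped.mean().unstack("sample_id")
    sd = grouped.std(ddof=1).unstack("sample_id").fillna(0.0)
    # preserve first-appearance order of targets and samples
    mean = mean.reindex(index=table.targets, columns=table.samples)
    sd = sd.reindex(index=mean.index, columns=mean.columns)
    sd = sd.where(~mean.isna())
    groups = df.drop_duplicates("sample_id").set_index("sample_id")["group"]
    groups = groups.reindex(mean.columns)
    n_missing = int(mean.isna().to_numpy().sum())
    if n_missing:
        logger.warning(
            "collapse_replicates: %d (target, sample) cells are missing; "
            "stability algorithms will subset to complete cases",
            n_missing,
        )
    flags = sd.gt(sd_threshold).fillna(False)
    return CqMatrix(mean, sd, groups, flags, sd_threshold=sd_threshold)


def filter_expressed(
    m: ExpressionMatrix, min_cpm: float = 1.0, min_fraction: float = 0.5
) -> ExpressionMatrix:
    """Keep genes with CPM >= min_cpm in at least min_fraction of samples."""
    if m.scale != "counts":
        raise ScaleError("filter_expressed requires a counts-scale matrix")
    if min_cpm <= 0:
        raise ParameterError(f"min_cpm must be > 0, got {min_cpm}")
    if not (0 < min_fraction <= 1):
        raise ParameterError(f"min_fraction must be in (0, 1], got {min_fraction}")
    cpm = m.cpm()
    keep = (cpm >= min_cpm).mean(axis=1) >= min_fraction
    logger.info("filter_expressed: retained %d / %d genes", int(keep.sum()), len(keep))
    return ExpressionMatrix(m.values.loc[keep].copy(), scale="counts", groups=m.groups)


def to_log2(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(CPM + pseudocount) transform; preserves gene/sample order."""
    if m.scale != "counts":
        raise ScaleError("to_log2 requires a counts-scale matrix")
    if pseudocount <= 0:
        raise ParameterError(f"pseudocount must be > 0, got {pseudocount}")
    return ExpressionMatrix(
        np.log2(m.cpm() + pseudocount), scale="log2", groups=m.groups
    )


def matrix_from_cq(m: CqMatrix, complete_cases: bool = True) -> pd.DataFrame:
    """Mean-Cq frame for stability analysis, optionally complete-case subset.

    Cq values are already log-scale (one cycle = one doubling), so they feed
    the log-domain estimators unchanged.
    """
    values = m.values
    if complete_cases and values.isna().any().any():
        keep = values.notna().all(axis=0)
        logger.warning(
            "subsetting to %d / %d complete-case samples", int(keep.sum()), len(keep)
        )
        values = values.loc[:, keep]
    return values
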