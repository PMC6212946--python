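"""Standard-curve efficiency, multi-reference relative quantification and
group-uniformity screening for RT-qPCR Cq data."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, InsufficientDataError, ParameterError
from .io_core import CqMatrix

logger = logging.getLogger("endoref")


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Cq on log10(dilution) and the implied efficiency."""

    slope: float
    intercept: float
    r2: float
    efficiency_pct: float  # raw (unrounded) percent
    n_points: int

    @property
    def efficiency_pct_rounded(self) -> int:
        return int(round(self.efficiency_pct))


def efficiency_from_slope(slope: float) -> float:
    """Percent amplification efficiency E = (10^(-1/slope) - 1) * 100.

    A perfect doubling assay has slope -1/log10(2) ~ -3.3219 and E = 100%.
    Report ``round()`` of the returned value; keep the raw value for JSON.
    """
    if not np.isfinite(slope) or slope >= 0:
        raise ParameterError(f"slope must be finite and < 0, got {slope}")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def fit_standard_curve(points) -> StandardCurve:
    """Fit a dilution series of (dilution factor, mean Cq) pairs.

    ``points`` is any iterable of pairs or a 2-column DataFrame. Requires
    >= 3 distinct dilution levels; dilution factors must be positive.
    """
    if isinstance(points, pd.DataFrame):
        arr = points.iloc[:, :2].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ParameterError("points must be (dilution, cq) pairs")
    dilution, cq = arr[:, 0], arr[:, 1]
    if (dilution <= 0).any():
        raise ParameterError("dilution factors must be > 0")
    if len(np.unique(dilution)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct dilution levels, got {len(np.unique(dilution))}"
        )
    x = np.log10(dilution)
    fit = stats.linregress(x, cq)
    r2 = float(fit.rvalue**2)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        efficiency_pct=efficiency_from_slope(float(fit.slope)),
        n_points=len(arr),
    )


@dataclass
class RelQuantResult:
    """Delta-delta-Cq relative quantification against a calibrator group.

    ``per_sample``: rows (target, sample) with dCq and relative expression
    2^-(dCq - mean calibrator dCq). ``per_group``: one row per (target,
    test group) with ddCq, RQ = 2^-ddCq, log2 fold change and t-test p.
    """

    per_sample: pd.DataFrame
    per_group: pd.DataFrame
    calibrator_group: str
    references: tuple[str, ...]


def relative_quantification(
    m: CqMatrix,
    targets,
    refs,
    calibrator_group: str,
    equal_var: bool = True,
) -> RelQuantResult:
    """Quantify ``targets`` relative to the mean of ``refs``.

    The per-sample reference aggregate is the arithmetic mean of the
    reference Cq values (geometric mean of linear expression); ddCq is the
    difference of group-mean dCq versus the calibrator group, and p comes
    from a 2-tailed t-test on dCq (Student by default, Welch optional).
    """
    refs = list(refs)
    targets = list(targets)
    if not refs:
        raise ParameterError("at least one reference gene is required")
    values = m.values
    missing = [g for g in refs + targets if g not in values.index]
    if missing:
        raise ConsistencyError(f"genes absent from the Cq matrix: {', '.join(missing)}")
    ref_block = values.loc[refs]
    if ref_block.isna().any().any():
        bad = ref_block.columns[ref_block.isna().any(axis=0)]
        raise ConsistencyError(
            f"reference gene(s) missing in sample(s): {', '.join(map(str, bad))}"
        )
    groups = m.groups
    if calibrator_group not in set(groups):
        raise ParameterError(f"calibrator group {calibrator_group!r} not present")
    aggregate = ref_block.mean(axis=0)
    cal_mask = (groups == calibrator_group).reindex(values.columns).fillna(False)

    sample_rows, group_rows = [], []
    for target in targets:
        dcq = values.loc[target] - aggregate
        cal_dcq = dcq[cal_mask].dropna()
        cal_mean = float(cal_dcq.mean())
        rel = 2.0 ** (-(dcq - cal_mean))
        for s in values.columns:
            sample_rows.append(
                {
                    "target_id": target,
                    "sample_id": s,
                    "group": groups.get(s),
                    "dcq": dcq[s],
                    "rel_expression": rel[s],
                }
            )
        for grp in dict.fromkeys(groups):
            if grp == calibrator_group:
                continue
            grp_dcq = dcq[(groups == grp).reindex(values.columns).fillna(False)].dropna()
            ddcq = float(grp_dcq.mean()) - cal_mean
            t_stat, p = _two_sample_t(grp_dcq.to_numpy(), cal_dcq.to_numpy(), equal_var)
            group_rows.append(
                {
                    "target_id": target,
                    "group": grp,
                    "calibrator": calibrator_group,
                    "ddcq": ddcq,
                    "rq": 2.0**-ddcq,
                    "log2_fold_change": -ddcq,
                    "t_statistic": t_stat,
                    "p_value": p,
                    "n_test": len(grp_dcq),
                    "n_calibrator": len(cal_dcq),
                }
            )
    return RelQuantResult(
        per_sample=pd.DataFrame(sample_rows),
        per_group=pd.DataFrame(group_rows),
        calibrator_group=calibrator_group,
        references=tuple(refs),
    )


def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    if len(a) < 2 or len(b) < 2:
        logger.warning("t-test skipped: a group has < 2 samples")
        return (np.nan, np.nan)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        # degenerate: no within-group variation
        if np.isclose(a.mean(), b.mean()):
            return (0.0, 1.0)
        logger.warning("t-test degenerate: zero variance with unequal means")
        return (np.inf, 0.0)
    t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return (float(t_stat), float(p))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up false-discovery-rate adjustment."""
    p = np.asarray(p_values, dtype=float)
    return stats.false_discovery_control(p, method="bh")


@dataclass
class GroupUniformityResult:
    """Per-gene one-way ANOVA across groups with BH-adjusted p-values."""

    table: pd.DataFrame  # gene rows: per-group mean/SD, F, p, p_adj, degenerate flag


def group_uniformity_test(m: CqMatrix, groups=None) -> GroupUniformityResult:
    """Screen genes for expression differences between sample groups.

    Groups with < 2 samples are dropped with a warning; genes with zero
    variance everywhere report p = 1 by convention and are flagged.
    """
    values = m.values
    g = (pd.Series(groups) if groups is not None else m.groups).reindex(values.columns)
    counts = g.value_counts()
    usable = [lab for lab in dict.fromkeys(g) if counts.get(lab, 0) >= 2]
    dropped = sorted(set(g.dropna()) - set(usable))
    if dropped:
        logger.warning("dropping group(s) with < 2 samples: %s", ", ".join(map(str, dropped)))
    if len(usable) < 2:
        raise InsufficientDataError("need >= 2 groups with >= 2 samples each")

    rows = []
    for gene in values.index:
        row: dict = {"target_id": gene}
        arrays = []
        for lab in usable:
            x = values.loc[gene, (g == lab).to_numpy()].dropna()
            arrays.append(x.to_numpy())
            row[f"mean_{lab}"] = float(x.mean()) if len(x) else np.nan
            row[f"sd_{lab}"] = float(x.std(ddof=1)) if len(x) > 1 else np.nan
        if any(len(a) < 2 for a in arrays):
            logger.warning("gene %s skipped: a group has < 2 usable values", gene)
            row.update(f_statistic=np.nan, p_value=np.nan, degenerate=True)
        elif np.ptp(np.concatenate(arrays)) == 0:
            row.update(f_statistic=np.nan, p_value=1.0, degenerate=True)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                f_stat, p = stats.f_oneway(*arrays)
            if not np.isfinite(p):
                row.update(f_statistic=np.nan, p_value=1.0, degenerate=True)
            else:
                row.update(f_statistic=float(f_stat), p_value=float(p), degenerate=False)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("target_id")
    mask = table["p_value"].notna()
    table["p_adj"] = np.nan
    if mask.any():
        table.loc[mask, "p_adj"] = benjamini_hochberg(table.loc[mask, "p_value"])
    return GroupUniformityResult(table)
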