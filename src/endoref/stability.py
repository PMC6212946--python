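"""Expression-stability estimators and their comprehensive rank aggregate.

Four estimators operate on a genes x samples frame of log-scale signals
(mean Cq, or log2 expression):

* model-based residual-variation score (NormFinder-style),
* mean pairwise variation M with stepwise exclusion (geNorm-style),
* raw-Cq descriptive statistics against a composite index (BestKeeper-style),
* mean SD of pairwise Cq differences (comparative delta-Ct).

Lower is more stable for every score. The comprehensive score is the
geometric mean of the four per-method ranks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, InsufficientDataError, ParameterError
from .io_core import CqMatrix, ExpressionMatrix, matrix_from_cq

METHODS = ("normfinder", "genorm", "bestkeeper", "delta_ct")


def as_frame(m) -> pd.DataFrame:
    """Coerce CqMatrix / ExpressionMatrix / DataFrame to a complete-case frame."""
    if isinstance(m, CqMatrix):
        return matrix_from_cq(m)
    if isinstance(m, ExpressionMatrix):
        return m.values
    return pd.DataFrame(m)


def _groups_of(m, groups) -> pd.Series | None:
    if groups is not None:
        return pd.Series(groups)
    if isinstance(m, CqMatrix):
        return m.groups
    if isinstance(m, ExpressionMatrix):
        return m.groups
    return None


def _double_center(values: np.ndarray) -> np.ndarray:
    """Residuals of the additive gene + sample model fitted by mean centering."""
    grand = values.mean()
    row = values.mean(axis=1, keepdims=True)
    col = values.mean(axis=0, keepdims=True)
    return values - row - col + grand


def normfinder_stability(m, groups=None, grouped: bool = False) -> pd.Series:
    """Per-gene model-based stability score; lower = more stable.

    Ungrouped (default): fit value = gene effect + sample effect + residual
    by row/column mean centering; score = SD (ddof=1) of the gene's residuals.

    Grouped: score = sqrt(mean within-group residual variance + variance of
    the gene's per-group mean residuals after global centering) — a
    simplification of the published model, kept behind the ``grouped`` flag.
    """
    df = as_frame(m)
    if df.shape[0] < 3 or df.shape[1] < 3:
        raise InsufficientDataError(
            f"need >= 3 genes and >= 3 samples, got {df.shape[0]} x {df.shape[1]}"
        )
    values = df.to_numpy(dtype=float)
    if not grouped:
        resid = _double_center(values)
        return pd.Series(resid.std(axis=1, ddof=1), index=df.index, name="normfinder")

    g = _groups_of(m, groups)
    if g is None:
        raise ParameterError("grouped mode requires group labels")
    g = g.reindex(df.columns)
    labels = list(dict.fromkeys(g))
    intra = np.zeros((df.shape[0], len(labels)))
    for j, lab in enumerate(labels):
        sub = values[:, (g == lab).to_numpy()]
        if sub.shape[1] < 2:
            raise InsufficientDataError(f"group {lab!r} has < 2 samples")
        intra[:, j] = _double_center(sub).var(axis=1, ddof=1)
    resid = _double_center(values)
    group_means = np.column_stack(
        [resid[:, (g == lab).to_numpy()].mean(axis=1) for lab in labels]
    )
    inter = group_means.var(axis=1, ddof=1) if len(labels) > 1 else np.zeros(df.shape[0])
    score = np.sqrt(intra.mean(axis=1) + inter)
    return pd.Series(score, index=df.index, name="normfinder")


@dataclass
class GeNormResult:
    """M values on the full gene set plus the stepwise-exclusion ranking."""

    m: pd.Series  # full-set M per gene
    ranking: list[str]  # best -> worst by iterative exclusion
    ranks: pd.Series = field(init=False)  # 1 = most stable

    def __post_init__(self) -> None:
        self.ranks = pd.Series(
            {g: i + 1 for i, g in enumerate(self.ranking)}, name="genorm_rank"
        ).reindex(self.m.index)


def _genorm_m_values(df: pd.DataFrame) -> pd.Series:
    values = df.to_numpy(dtype=float)
    n = values.shape[0]
    m = np.zeros(n)
    for j in range(n):
        diffs = values - values[j]  # per-sample Cq_k - Cq_j for all k
        v = diffs.std(axis=1, ddof=1)
        m[j] = np.delete(v, j).mean()
    return pd.Series(m, index=df.index, name="genorm_m")


def genorm_m(m) -> GeNormResult:
    """Pairwise-variation M per gene and ranking by iterative exclusion.

    V(j,k) is the SD (ddof=1) across samples of the per-sample difference
    Cq_k - Cq_j; M_j is the mean over k != j. The gene with the highest M is
    removed and M recomputed until two remain; the final pair is ordered by
    its last-round M. Ties resolve by gene id order.
    """
    df = as_frame(m)
    if df.shape[0] < 2:
        raise InsufficientDataError(f"need >= 2 genes, got {df.shape[0]}")
    if df.shape[1] < 2:
        raise InsufficientDataError(f"need >= 2 samples, got {df.shape[1]}")
    full_m = _genorm_m_values(df)
    current = df.copy()
    removed: list[str] = []
    while current.shape[0] > 2:
        m_now = _genorm_m_values(current)
        # among ties for worst, remove the lexicographically last gene
        worst_val = m_now.max()
        worst = sorted(m_now.index[m_now == worst_val])[-1]
        removed.append(worst)
        current = current.drop(index=worst)
    m_last = _genorm_m_values(current)
    final_pair = sorted(m_last.index, key=lambda g: (m_last[g], g))
    ranking = final_pair + removed[::-1]
    return GeNormResult(full_m, ranking)


def bestkeeper_stats(m, use_mad: bool = False) -> pd.DataFrame:
    """Raw-Cq dispersion, CV% and correlation with the composite index.

    The index is the per-sample arithmetic mean Cq over genes (geometric
    mean of linear expression). Dispersion defaults to sample SD (ddof=1);
    ``use_mad`` switches to the mean absolute deviation from the mean.
    """
    df = as_frame(m)
    if df.shape[1] < 2:
        raise InsufficientDataError(f"need >= 2 samples, got {df.shape[1]}")
    values = df.to_numpy(dtype=float)
    if use_mad:
        disp = np.abs(values - values.mean(axis=1, keepdims=True)).mean(axis=1)
    else:
        disp = values.std(axis=1, ddof=1)
    mean = values.mean(axis=1)
    cv = 100.0 * disp / mean
    index = values.mean(axis=0)
    r = np.full(len(df), np.nan)
    if np.ptp(index) > 0:
        for i in range(len(df)):
            if np.ptp(values[i]) > 0:
                r[i] = stats.pearsonr(values[i], index)[0]
    elif len(df) == 1:
        r[0] = 1.0
    out = pd.DataFrame(
        {"bestkeeper_sd": disp, "bestkeeper_cv_pct": cv, "bestkeeper_r": r},
        index=df.index,
    )
    # a gene perfectly tracking itself: single-gene index is the gene itself
    if len(df) == 1:
        out.loc[df.index[0], "bestkeeper_r"] = 1.0
    return out


def delta_ct_stability(m) -> pd.Series:
    """Mean SD of pairwise Cq differences per gene; lower = more stable."""
    df = as_frame(m)
    if df.shape[0] < 2:
        raise InsufficientDataError(f"need >= 2 genes, got {df.shape[0]}")
    if df.shape[1] < 2:
        raise InsufficientDataError(f"need >= 2 samples, got {df.shape[1]}")
    values = df.to_numpy(dtype=float)
    n = values.shape[0]
    score = np.zeros(n)
    for g in range(n):
        diffs = values[g] - values  # Cq_g - Cq_h per sample
        sds = diffs.std(axis=1, ddof=1)
        score[g] = np.delete(sds, g).mean()
    return pd.Series(score, index=df.index, name="delta_ct")


@dataclass
class StabilityResult:
    """Per-gene scores, per-method ranks and the comprehensive aggregate."""

    table: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def top_k(self, method: str, k: int) -> set[str]:
        col = f"{method}_rank"
        return set(self.table.index[self.table[col] <= k])


def _rank(scores: pd.Series) -> pd.Series:
    """Ascending rank, ties share the minimum rank."""
    return scores.rank(method="min", ascending=True).astype(int)


def comprehensive_rank(
    normfinder: pd.Series,
    genorm: GeNormResult,
    bestkeeper: pd.DataFrame,
    delta_ct: pd.Series,
) -> StabilityResult:
    """Aggregate the four methods into a geometric-mean-of-ranks score.

    Ranks ascend with score (1 = most stable); the geNorm rank is its
    stepwise-exclusion ranking. Comprehensive ties break by gene id order.
    """
    idx = normfinder.index
    for other in (genorm.m.index, bestkeeper.index, delta_ct.index):
        if set(other) != set(idx):
            raise ConsistencyError("all four methods must score the same gene set")
    table = pd.DataFrame(index=idx)
    table["normfinder"] = normfinder
    table["genorm_m"] = genorm.m.reindex(idx)
    table = table.join(bestkeeper.reindex(idx))
    table["delta_ct"] = delta_ct.reindex(idx)
    table["normfinder_rank"] = _rank(table["normfinder"])
    table["genorm_rank"] = genorm.ranks.reindex(idx)
    table["bestkeeper_rank"] = _rank(table["bestkeeper_sd"])
    table["delta_ct_rank"] = _rank(table["delta_ct"])
    ranks = table[[f"{m}_rank" for m in METHODS]].to_numpy(dtype=float)
    table["comprehensive_score"] = np.exp(np.log(ranks).mean(axis=1))
    # stable sort after an index sort -> score ties break by gene id order
    order = table.sort_index(kind="mergesort").sort_values(
        "comprehensive_score", kind="mergesort"
    )
    table["comprehensive_rank"] = pd.Series(
        np.arange(1, len(order) + 1), index=order.index
    ).reindex(idx)
    return StabilityResult(table)


def stability_table(m, groups=None, grouped: bool = False, use_mad: bool = False) -> StabilityResult:
    """Run all four estimators on one input and aggregate."""
    df = as_frame(m)
    return comprehensive_rank(
        normfinder_stability(df if not grouped else m, groups=groups, grouped=grouped),
        genorm_m(df),
        bestkeeper_stats(df, use_mad=use_mad),
        delta_ct_stability(df),
    )


@dataclass
class TopKOverlap:
    """Top-k gene sets per method and exclusive Venn-region counts."""

    k: int
    sets: dict[str, set[str]]
    regions: dict[frozenset[str], set[str]]  # method subset -> genes exactly there

    def counts(self) -> dict[frozenset[str], int]:
        return {key: len(genes) for key, genes in self.regions.items()}

    def intersection(self, *methods: str) -> set[str]:
        out = set.intersection(*(self.sets[m] for m in methods))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "methods": ",".join(sorted(key)),
                "n_methods": len(key),
                "count": len(genes),
                "genes": ",".join(sorted(genes)),
            }
            for key, genes in sorted(
                self.regions.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["methods", "n_methods", "count", "genes"])


def top_k_overlap(result: StabilityResult, k: int) -> TopKOverlap:
    """Per-method top-k sets and all exclusive intersection cardinalities."""
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k > len(result.genes):
        raise ParameterError(f"k={k} exceeds the number of genes ({len(result.genes)})")
    sets = {m: result.top_k(m, k) for m in METHODS}
    union = set().union(*sets.values())
    regions: dict[frozenset[str], set[str]] = {}
    for r in range(1, len(METHODS) + 1):
        for combo in itertools.combinations(METHODS, r):
            key = frozenset(combo)
            members = {
                g
                for g in union
                if all(g in sets[m] for m in combo)
                and all(g not in sets[m] for m in METHODS if m not in combo)
            }
            regions[key] = members
    return TopKOverlap(k=k, sets=sets, regions=regions)
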