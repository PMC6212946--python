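"""Greedy forward selection of a reference-gene set of increasing size.

Starting from the single most stable gene, each iteration averages the
current set's log2 signals with every remaining candidate in turn, rescores
the combined pseudo-gene against the genes outside the set, and keeps the
candidate giving the lowest score. The per-iteration minimum and mean
candidate scores form the trace used to decide how many references to use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError
from .stability import as_frame, normfinder_stability

PSEUDO_GENE = "__set__"


@dataclass(frozen=True)
class IterationRecord:
    k: int
    added: str
    members: tuple[str, ...]
    min_score: float
    mean_score: float


@dataclass
class IterationTrace:
    records: list[IterationRecord]

    def __post_init__(self) -> None:
        ks = [r.k for r in self.records]
        if ks != list(range(1, len(ks) + 1)):
            raise ParameterError("iteration indices must be 1..K")
        for prev, cur in zip(self.records, self.records[1:]):
            if not set(prev.members) < set(cur.members):
                raise ParameterError("selected sets must be strictly nested")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def selected(self) -> tuple[str, ...]:
        return self.records[-1].members

    def min_scores(self) -> list[float]:
        return [r.min_score for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [r.k for r in self.records],
                "added_gene": [r.added for r in self.records],
                "set": [",".join(r.members) for r in self.records],
                "min_score": [r.min_score for r in self.records],
                "mean_score": [r.mean_score for r in self.records],
            }
        )


def _argmin_by_id(scores: pd.Series) -> str:
    """Index of the minimum score; ties resolve to the smallest gene id."""
    best = scores.min()
    return sorted(scores.index[scores == best])[0]


def combined_profile(df: pd.DataFrame, members: list[str]) -> pd.Series:
    """Per-sample arithmetic mean of the members' log2 signals."""
    return df.loc[members].mean(axis=0)


def score_candidate_set(df: pd.DataFrame, members: list[str]) -> float:
    """Stability score of the averaged set inside its background matrix.

    The pseudo-gene replaces its constituent genes: the background is every
    gene outside the set plus the averaged profile, so a combination is
    never scored against its own members.
    """
    background = df.drop(index=members)
    matrix = pd.concat([background, combined_profile(df, members).to_frame(PSEUDO_GENE).T])
    if matrix.shape[0] < 3:
        raise InsufficientDataError("background too small to score the candidate set")
    return float(normfinder_stability(matrix).loc[PSEUDO_GENE])


def iterative_selection(m, max_k: int = 100) -> IterationTrace:
    """Build nested reference sets S_1 .. S_max_k greedily.

    Deterministic given the input; score ties break by gene id order. Stops
    early when the candidate pool or the background matrix is exhausted.
    """
    df = as_frame(m)
    if max_k < 1:
        raise ParameterError(f"max_k must be >= 1, got {max_k}")
    if df.shape[0] < 3 or df.shape[1] < 3:
        raise InsufficientDataError(
            f"need >= 3 genes and >= 3 samples, got {df.shape[0]} x {df.shape[1]}"
        )
    scores = normfinder_stability(df)
    first = _argmin_by_id(scores)
    records = [
        IterationRecord(
            k=1,
            added=first,
            members=(first,),
            min_score=float(scores.min()),
            mean_score=float(scores.mean()),
        )
    ]
    selected = [first]
    while len(selected) < min(max_k, df.shape[0]):
        candidates = [g for g in df.index if g not in selected]
        # need >= 2 background genes besides the pseudo-gene
        if not candidates or df.shape[0] - (len(selected) + 1) < 2:
            break
        cand_scores = pd.Series(
            {c: score_candidate_set(df, selected + [c]) for c in candidates}
        )
        best = _argmin_by_id(cand_scores)
        selected.append(best)
        records.append(
            IterationRecord(
                k=len(selected),
                added=best,
                members=tuple(selected),
                min_score=float(cand_scores.min()),
                mean_score=float(cand_scores.mean()),
            )
        )
    return IterationTrace(records)


def suggest_set_size(trace: IterationTrace, rel_gain_threshold: float = 0.05) -> int:
    """Smallest k whose next addition improves the minimum score by less
    than ``rel_gain_threshold`` (relative); last k if never satisfied.

    Advisory only — report it alongside the full trace. Non-monotone or
    zero minima clamp the relative gain at 0.
    """
    if len(trace) < 2:
        raise InsufficientDataError("trace needs >= 2 iterations")
    if rel_gain_threshold < 0:
        raise ParameterError("rel_gain_threshold must be >= 0")
    mins = trace.min_scores()
    for i in range(len(mins) - 1):
        if mins[i] <= 0:
            gain = 0.0
        else:
            gain = max(0.0, (mins[i] - mins[i + 1]) / mins[i])
        if gain < rel_gain_threshold:
            return trace.records[i].k
    return trace.records[-1].k
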