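"""Sequence-similarity screen for cross-hybridization risk between mature
miRNAs: global alignment, seed identity and expression correlation."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlphabetError, FormatError, ParameterError
from .stability import as_frame

RNA_ALPHABET = frozenset("ACGU")
SEED_START, SEED_END = 2, 7  # 1-based inclusive positions of the seed


@dataclass
class MiRNASequence:
    """A mature miRNA sequence over the ACGU alphabet.

    DNA-style input (T) is auto-converted to U with a warning. The seed is
    the hexamer at 1-based positions 2-7.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.strip().upper()
        if not seq:
            raise ParameterError(f"{self.id}: empty sequence")
        if "T" in seq:
            warnings.warn(f"{self.id}: converting T to U (DNA-style input)", stacklevel=2)
            seq = seq.replace("T", "U")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"{self.id}: invalid character(s) {''.join(sorted(bad))} (alphabet ACGU)"
            )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def seed(self) -> str:
        if len(self.sequence) < SEED_END:
            raise ParameterError(
                f"{self.id}: sequence shorter than {SEED_END} nt has no seed"
            )
        return self.sequence[SEED_START - 1 : SEED_END]


def read_fasta(path: str | Path) -> list[MiRNASequence]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    records = [MiRNASequence(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    identity_pct: float  # 100 * matches / alignment columns
    aligned_a: str
    aligned_b: str


def global_align(
    a, b, match: int = 1, mismatch: int = -1, gap: int = -2
) -> AlignmentResult:
    """Optimal global alignment with linear gap penalty.

    Traceback is deterministic with tie precedence diagonal > up > left
    (up = gap in the second sequence). Identity counts matched columns over
    all alignment columns, gaps included.
    """
    sa = a.sequence if isinstance(a, MiRNASequence) else str(a)
    sb = b.sequence if isinstance(b, MiRNASequence) else str(b)
    if not sa or not sb:
        raise ParameterError("cannot align an empty sequence")
    for name, s in (("a", sa), ("b", sb)):
        bad = set(s.upper()) - RNA_ALPHABET
        if bad:
            raise AlphabetError(f"sequence {name}: invalid character(s) {''.join(sorted(bad))}")
    sa, sb = sa.upper(), sb.upper()
    n, m = len(sa), len(sb)
    f = np.empty((n + 1, m + 1), dtype=np.int64)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    f[0, :] = gap * np.arange(m + 1)
    f[:, 0] = gap * np.arange(n + 1)
    ptr[0, 1:] = 2
    ptr[1:, 0] = 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = f[i - 1, j - 1] + (match if sa[i - 1] == sb[j - 1] else mismatch)
            up = f[i - 1, j] + gap
            left = f[i, j - 1] + gap
            best = max(diag, up, left)
            f[i, j] = best
            ptr[i, j] = 0 if diag == best else (1 if up == best else 2)
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0:
            ra.append(sa[i - 1])
            rb.append(sb[j - 1])
            i, j = i - 1, j - 1
        elif move == 1:
            ra.append(sa[i - 1])
            rb.append("-")
            i -= 1
        else:
            ra.append("-")
            rb.append(sb[j - 1])
            j -= 1
    aligned_a = "".join(reversed(ra))
    aligned_b = "".join(reversed(rb))
    matches = sum(x == y for x, y in zip(aligned_a, aligned_b))
    return AlignmentResult(
        score=int(f[n, m]),
        identity_pct=100.0 * matches / len(aligned_a),
        aligned_a=aligned_a,
        aligned_b=aligned_b,
    )


def seed_identical(a: MiRNASequence, b: MiRNASequence) -> bool:
    """True iff the hexamers at positions 2-7 match exactly."""
    return a.seed == b.seed


def expression_correlation(m, pairs) -> pd.Series:
    """Pearson r across samples on log2 values for each (id, id) pair.

    Zero-variance genes yield NaN with a warning.
    """
    df = as_frame(m)
    out = {}
    for ga, gb in pairs:
        for g in (ga, gb):
            if g not in df.index:
                raise ParameterError(f"gene {g!r} absent from expression matrix")
        x = df.loc[ga].to_numpy(dtype=float)
        y = df.loc[gb].to_numpy(dtype=float)
        if len(x) < 3:
            raise ParameterError("correlation requires >= 3 samples")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"zero-variance gene in pair ({ga}, {gb}); r undefined", stacklevel=2)
            out[(ga, gb)] = np.nan
        else:
            out[(ga, gb)] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="pearson_r")


def pairwise_similarity(
    sequences: list[MiRNASequence],
    expression=None,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> pd.DataFrame:
    """One row per unordered sequence pair: alignment score, percent
    identity, seed identity and (optionally) expression Pearson r."""
    rows = []
    expr = as_frame(expression) if expression is not None else None
    for a, b in itertools.combinations(sequences, 2):
        aln = global_align(a, b, match=match, mismatch=mismatch, gap=gap)
        row = {
            "id_a": a.id,
            "id_b": b.id,
            "score": aln.score,
            "identity_pct": aln.identity_pct,
            "seed_identical": seed_identical(a, b),
        }
        if expr is not None and a.id in expr.index and b.id in expr.index:
            row["pearson_r"] = expression_correlation(expr, [(a.id, b.id)]).iloc[0]
        else:
            row["pearson_r"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
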