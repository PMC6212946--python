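"""Seeded generators for Cq tables, count matrices and dilution series.

Every generator is a pure function of its parameters and seed, and returns
the dataset together with a ground-truth manifest so planted-gene recovery
and parameter recovery can be asserted without external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_core import CqTable, ExpressionMatrix

# group sizes echoing an unbalanced 4-material design:
# patient samples / control lymphocytes / thymocytes / cell lines
PAPER_LIKE_GROUP_SIZES = (34, 5, 4, 9)


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every generated dataset."""

    stable_genes: dict[str, float] = field(default_factory=dict)  # id -> noise SD
    noisy_genes: dict[str, float] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)  # id -> log2 group effect
    shift_sd: float = 0.0
    tech_sd: float = 0.0
    dispersion: float = 0.0
    library_sizes: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.stable_genes) & (set(self.noisy_genes) | set(self.de_genes))
        if overlap:
            raise ParameterError(f"stable genes overlap other sets: {sorted(overlap)}")
        for name in ("shift_sd", "tech_sd", "dispersion"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticTruth":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls(**json.loads(text))


def simulate_cq_dataset(
    n_groups: int = 2,
    n_samples_per_group: int | Sequence[int] = 10,
    n_stable: int = 3,
    n_noisy: int = 12,
    n_de: int = 0,
    stable_sd: float = 0.05,
    noisy_sd: float = 0.5,
    de_effect: float = 2.0,
    shift_sd: float = 0.2,
    tech_sd: float = 0.1,
    n_replicates: int = 3,
    baseline_range: tuple[float, float] = (18.0, 28.0),
    seed: int = 0,
) -> tuple[CqTable, SyntheticTruth]:
    """Simulate a replicate-level Cq table with planted stable genes.

    Cq(g, s, rep) = baseline_g + shift_s + group effect + biological noise
    (per sample, SD sigma_g) + technical noise (per replicate, SD tech_sd).
    Stable genes have sigma_g = stable_sd and zero group effect; de genes
    carry a +de_effect Cq offset in every non-first group.
    """
    if n_groups < 1 or n_stable < 0 or n_noisy < 0 or n_de < 0 or n_replicates < 1:
        raise ParameterError("counts must be >= 1 where used")
    if n_stable + n_noisy + n_de < 1:
        raise ParameterError("at least one gene is required")
    sizes = (
        [int(n_samples_per_group)] * n_groups
        if np.isscalar(n_samples_per_group)
        else list(n_samples_per_group)
    )
    if len(sizes) != n_groups or any(s < 1 for s in sizes):
        raise ParameterError("n_samples_per_group must give >= 1 sample per group")
    rng = np.random.default_rng(seed)

    genes = (
        [f"stable_{i+1:02d}" for i in range(n_stable)]
        + [f"noisy_{i+1:02d}" for i in range(n_noisy)]
        + [f"de_{i+1:02d}" for i in range(n_de)]
    )
    sigma = dict(
        zip(
            genes,
            [stable_sd] * n_stable + [noisy_sd] * n_noisy + [noisy_sd] * n_de,
        )
    )
    baseline = dict(zip(genes, rng.uniform(*baseline_range, size=len(genes))))
    group_labels = [f"grp{i+1}" for i in range(n_groups)]
    samples = [
        (f"{lab}_s{j+1:02d}", lab) for lab, size in zip(group_labels, sizes) for j in range(size)
    ]
    shift = dict(zip([s for s, _ in samples], rng.normal(0.0, shift_sd, size=len(samples))))

    rows = []
    for gene in genes:
        is_de = gene.startswith("de_")
        for sample_id, lab in samples:
            effect = de_effect if (is_de and lab != group_labels[0]) else 0.0
            bio = rng.normal(0.0, sigma[gene])
            level = baseline[gene] + shift[sample_id] + effect + bio
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group": lab,
                        "target_id": gene,
                        "replicate": rep,
                        "cq": level + rng.normal(0.0, tech_sd),
                    }
                )
    table = CqTable(pd.DataFrame(rows))
    truth = SyntheticTruth(
        stable_genes={g: stable_sd for g in genes if g.startswith("stable_")},
        noisy_genes={g: noisy_sd for g in genes if g.startswith("noisy_")},
        de_genes={g: de_effect for g in genes if g.startswith("de_")},
        shift_sd=shift_sd,
        tech_sd=tech_sd,
        seed=int(seed),
    )
    return table, truth


def simulate_count_dataset(
    n_samples: int = 20,
    n_genes: int = 50,
    n_stable: int = 10,
    n_de: int = 0,
    de_log2fc: float = 2.0,
    jitter_sd: float = 0.5,
    dispersion: float = 0.1,
    stable_dispersion: float = 0.005,
    lib_size_mean: float = 1e6,
    lib_size_cv: float = 0.3,
    n_groups: int = 2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Negative-binomial count matrix with planted stable genes.

    Expected count = library size x relative abundance. Stable genes keep
    constant relative abundance (dispersion ``stable_dispersion``); other
    genes get per-sample log2-normal abundance jitter (SD ``jitter_sd`` in
    log2 units) and dispersion ``dispersion``. DE genes additionally gain
    ``de_log2fc`` in every non-first group.
    """
    if dispersion < 0 or stable_dispersion < 0:
        raise ParameterError("dispersion must be >= 0")
    if n_stable + n_de > n_genes:
        raise ParameterError("n_stable + n_de must not exceed n_genes")
    if n_samples < 1 or n_genes < 1:
        raise ParameterError("n_samples and n_genes must be >= 1")
    rng = np.random.default_rng(seed)

    n_noisy = n_genes - n_stable - n_de
    genes = (
        [f"stable_{i+1:02d}" for i in range(n_stable)]
        + [f"noisy_{i+1:02d}" for i in range(n_noisy)]
        + [f"de_{i+1:02d}" for i in range(n_de)]
    )
    base_ab = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base_ab /= base_ab.sum()
    lib = rng.lognormal(
        mean=np.log(lib_size_mean), sigma=np.sqrt(np.log(1 + lib_size_cv**2)), size=n_samples
    )
    group_labels = [f"grp{(i * n_groups) // n_samples + 1}" for i in range(n_samples)]
    samples = [f"s{i+1:03d}" for i in range(n_samples)]

    counts = np.zeros((n_genes, n_samples), dtype=np.int64)
    for gi, gene in enumerate(genes):
        stable = gene.startswith("stable_")
        disp = stable_dispersion if stable else dispersion
        for si in range(n_samples):
            ab = base_ab[gi]
            if not stable:
                ab *= 2.0 ** rng.normal(0.0, jitter_sd)
            if gene.startswith("de_") and group_labels[si] != "grp1":
                ab *= 2.0**de_log2fc
            mu = lib[si] * ab
            if disp <= 1e-12:
                counts[gi, si] = rng.poisson(mu)
            else:
                r = 1.0 / disp
                counts[gi, si] = rng.negative_binomial(r, r / (r + mu))
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        scale="counts",
        groups=pd.Series(group_labels, index=samples),
    )
    truth = SyntheticTruth(
        stable_genes={g: 0.0 for g in genes if g.startswith("stable_")},
        noisy_genes={g: jitter_sd for g in genes if g.startswith("noisy_")},
        de_genes={g: de_log2fc for g in genes if g.startswith("de_")},
        dispersion=dispersion,
        library_sizes=[float(x) for x in lib],
        seed=int(seed),
    )
    return matrix, truth


def simulate_dilution_series(
    true_efficiency_pct: float,
    intercept: float = 20.0,
    n_levels: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """10-fold dilution series with Cq rising by 1/log10(1+E) per decade.

    Cq(d) = intercept - log10(d) / log10(1 + E) + Normal(0, noise_sd) at
    dilutions 10^0 .. 10^-(n_levels-1); slope of the ideal fit is
    -1/log10(1+E).
    """
    if not (50.0 < true_efficiency_pct <= 150.0):
        raise ParameterError(
            f"true_efficiency_pct must be in (50, 150], got {true_efficiency_pct}"
        )
    if n_levels < 3:
        raise ParameterError(f"n_levels must be >= 3, got {n_levels}")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    e = true_efficiency_pct / 100.0
    dilutions = 10.0 ** -np.arange(n_levels)
    cq = intercept - np.log10(dilutions) / np.log10(1.0 + e)
    cq = cq + rng.normal(0.0, noise_sd, size=n_levels)
    return pd.DataFrame({"dilution": dilutions, "cq": cq})
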