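import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def worked_matrix() -> pd.DataFrame:
    """3x3 hand-checkable matrix: A and B share a profile, C deviates."""
    return pd.DataFrame(
        [[20.0, 21.0, 22.0], [20.0, 21.0, 22.0], [20.0, 22.0, 21.0]],
        index=["A", "B", "C"],
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_matrix(rng, n_genes=4, n_samples=6, spread=2.0, base=22.0) -> pd.DataFrame:
    values = base + spread * rng.standard_normal((n_genes, n_samples))
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


@pytest.fixture
def cq_tsv(tmp_path):
    """Write a small valid long-format Cq table and return its path."""
    path = tmp_path / "cq.tsv"
    rows = ["sample_id\tgroup\ttarget_id\treplicate\tcq"]
    for rep, cq in zip((1, 2, 3), (20.0, 20.5, 21.0)):
        rows.append(f"s1\tctrl\tmiR-1\t{rep}\t{cq}")
    path.write_text("\n".join(rows) + "\n")
    return path
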