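import itertools
import statistics

import numpy as np
import pandas as pd
import pytest

from endoref import (
    ConsistencyError,
    InsufficientDataError,
    ParameterError,
    bestkeeper_stats,
    comprehensive_rank,
    delta_ct_stability,
    genorm_m,
    normfinder_stability,
    simulate_cq_dataset,
    collapse_replicates,
    stability_table,
    top_k_overlap,
)
from conftest import random_matrix

# ---------------------------------------------------------------------------
# independent oracles (direct enumeration, no shared code with the package)
# ---------------------------------------------------------------------------


def oracle_normfinder(df: pd.DataFrame) -> dict:
    """Residual SD of the additive model fitted by least squares."""
    genes, samples = list(df.index), list(df.columns)
    rows = []
    y = []
    for gi, g in enumerate(genes):
        for si, s in enumerate(samples):
            row = np.zeros(1 + len(genes) + len(samples))
            row[0] = 1.0
            row[1 + gi] = 1.0
            row[1 + len(genes) + si] = 1.0
            rows.append(row)
            y.append(df.loc[g, s])
    coef, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
    fitted = np.array(rows) @ coef
    resid = (np.array(y) - fitted).reshape(len(genes), len(samples))
    return {g: statistics.stdev(resid[i]) for i, g in enumerate(genes)}


def oracle_genorm(df: pd.DataFrame) -> dict:
    out = {}
    for g in df.index:
        vs = []
        for h in df.index:
            if h == g:
                continue
            diffs = [df.loc[h, s] - df.loc[g, s] for s in df.columns]
            vs.append(statistics.stdev(diffs))
        out[g] = sum(vs) / len(vs)
    return out


def oracle_delta_ct(df: pd.DataFrame) -> dict:
    out = {}
    for g in df.index:
        sds = []
        for h in df.index:
            if h == g:
                continue
            diffs = [df.loc[g, s] - df.loc[h, s] for s in df.columns]
            sds.append(statistics.stdev(diffs))
        out[g] = sum(sds) / len(sds)
    return out


def oracle_bestkeeper(df: pd.DataFrame) -> dict:
    index = [sum(df[s]) / len(df) for s in df.columns]
    out = {}
    for g in df.index:
        x = list(df.loc[g])
        sd = statistics.stdev(x)
        r = statistics.correlation(x, index)
        out[g] = (sd, 100 * sd / statistics.mean(x), r)
    return out


# ---------------------------------------------------------------------------
# worked 3x3 matrix
# ---------------------------------------------------------------------------


class TestWorkedMatrix:
    def test_normfinder(self, worked_matrix):
        scores = normfinder_stability(worked_matrix)
        assert scores["A"] == pytest.approx(1 / 3, abs=1e-9)
        assert scores["B"] == pytest.approx(1 / 3, abs=1e-9)
        assert scores["C"] == pytest.approx(2 / 3, abs=1e-9)
        oracle = oracle_normfinder(worked_matrix)
        for g in worked_matrix.index:
            assert scores[g] == pytest.approx(oracle[g], abs=1e-9)

    def test_genorm(self, worked_matrix):
        result = genorm_m(worked_matrix)
        assert result.m.tolist() == pytest.approx([0.5, 0.5, 1.0], abs=1e-9)

    def test_delta_ct(self, worked_matrix):
        scores = delta_ct_stability(worked_matrix)
        assert scores.tolist() == pytest.approx([0.5, 0.5, 1.0], abs=1e-9)

    def test_genorm_and_delta_ct_coincide_here(self, worked_matrix):
        # regression: both methods report (0.5, 0.5, 1.0) on this matrix
        g = genorm_m(worked_matrix).m
        d = delta_ct_stability(worked_matrix)
        assert np.allclose(g.to_numpy(), d.to_numpy(), atol=1e-12)


# ---------------------------------------------------------------------------
# brute-force oracle equivalence on random matrices
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(5))
def test_oracle_equivalence_random_matrices(seed):
    df = random_matrix(np.random.default_rng(seed), n_genes=4, n_samples=6)
    nf = normfinder_stability(df)
    for g, expected in oracle_normfinder(df).items():
        assert nf[g] == pytest.approx(expected, abs=1e-9)
    gm = genorm_m(df).m
    for g, expected in oracle_genorm(df).items():
        assert gm[g] == pytest.approx(expected, abs=1e-9)
    dc = delta_ct_stability(df)
    for g, expected in oracle_delta_ct(df).items():
        assert dc[g] == pytest.approx(expected, abs=1e-9)
    bk = bestkeeper_stats(df)
    for g, (sd, cv, r) in oracle_bestkeeper(df).items():
        assert bk.loc[g, "bestkeeper_sd"] == pytest.approx(sd, abs=1e-9)
        assert bk.loc[g, "bestkeeper_cv_pct"] == pytest.approx(cv, abs=1e-9)
        assert bk.loc[g, "bestkeeper_r"] == pytest.approx(r, abs=1e-9)


# ---------------------------------------------------------------------------
# per-method behaviour
# ---------------------------------------------------------------------------


class TestNormFinder:
    def test_perfectly_stable_gene_scores_zero(self, rng):
        df = random_matrix(rng, n_genes=4, n_samples=5)
        df.loc["g0"] = df.iloc[1:].mean(axis=0) + 3.0  # tracks the sample effect
        scores = normfinder_stability(df)
        # g0 follows sample means of the others plus a constant -> near-zero residual
        assert scores["g0"] == scores.min()

    def test_exact_zero_for_additive_gene(self):
        # build a matrix that is exactly additive for one gene
        sample_effect = np.array([0.0, 1.0, -1.0, 2.0])
        df = pd.DataFrame(
            [20 + sample_effect, 22 + sample_effect, 25 + sample_effect + [0, 0.5, -0.5, 0]],
            index=["a", "b", "c"],
            columns=list("wxyz"),
        )
        assert normfinder_stability(df)["a"] == pytest.approx(
            normfinder_stability(df)["b"], abs=1e-12
        )

    def test_too_small(self, worked_matrix):
        with pytest.raises(InsufficientDataError):
            normfinder_stability(worked_matrix.iloc[:2])
        with pytest.raises(InsufficientDataError):
            normfinder_stability(worked_matrix.iloc[:, :2])

    def test_grouped_mode_penalizes_group_effect(self, rng):
        df = random_matrix(rng, n_genes=5, n_samples=8, spread=0.1)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=df.columns)
        shifted = df.copy()
        shifted.loc["g0", groups == "b"] += 3.0
        flat = normfinder_stability(df, groups=groups, grouped=True)
        biased = normfinder_stability(shifted, groups=groups, grouped=True)
        assert biased["g0"] > flat["g0"]

    def test_grouped_requires_groups(self, worked_matrix):
        with pytest.raises(ParameterError):
            normfinder_stability(worked_matrix, grouped=True)


class TestGeNorm:
    def test_constant_offset_pair(self):
        df = pd.DataFrame([[20.0, 21, 23], [22.0, 23, 25]], index=["a", "b"], columns=list("xyz"))
        result = genorm_m(df)
        assert result.m.tolist() == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_stepwise_ranking_orders_worst_last(self, worked_matrix):
        result = genorm_m(worked_matrix)
        assert result.ranking[-1] == "C"
        assert set(result.ranking[:2]) == {"A", "B"}
        assert result.ranks["C"] == 3

    def test_insufficient(self, worked_matrix):
        with pytest.raises(InsufficientDataError):
            genorm_m(worked_matrix.iloc[:1])


class TestBestKeeper:
    def test_sd_and_cv(self):
        df = pd.DataFrame([[20.0, 21, 22]], index=["g"], columns=list("xyz"))
        bk = bestkeeper_stats(df)
        assert bk.loc["g", "bestkeeper_sd"] == pytest.approx(1.0)
        assert bk.loc["g", "bestkeeper_cv_pct"] == pytest.approx(100.0 / 21.0)
        # a single gene correlates perfectly with its own index
        assert bk.loc["g", "bestkeeper_r"] == pytest.approx(1.0)

    def test_constant_gene_ranks_first(self, worked_matrix):
        df = worked_matrix.copy()
        df.loc["D"] = 24.0
        bk = bestkeeper_stats(df)
        assert bk["bestkeeper_sd"].idxmin() == "D"
        assert bk.loc["D", "bestkeeper_sd"] == 0.0

    def test_mad_option(self):
        df = pd.DataFrame([[20.0, 21, 22]], index=["g"], columns=list("xyz"))
        bk = bestkeeper_stats(df, use_mad=True)
        assert bk.loc["g", "bestkeeper_sd"] == pytest.approx(2 / 3)

    def test_single_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            bestkeeper_stats(pd.DataFrame([[20.0]], index=["g"], columns=["s"]))


class TestDeltaCt:
    def test_identical_profiles_score_zero(self):
        df = pd.DataFrame([[20.0, 21, 22]] * 3, index=list("abc"), columns=list("xyz"))
        assert delta_ct_stability(df).tolist() == pytest.approx([0, 0, 0], abs=1e-12)

    def test_insufficient(self, worked_matrix):
        with pytest.raises(InsufficientDataError):
            delta_ct_stability(worked_matrix.iloc[:1])


# ---------------------------------------------------------------------------
# shift invariance contrast
# ---------------------------------------------------------------------------


def test_per_sample_shift_invariance_contrast(rng):
    df = random_matrix(rng, n_genes=5, n_samples=6)
    shifted = df.copy()
    shifted.iloc[:, 2] += 5.0  # +5 Cq to every gene of one sample
    assert np.allclose(
        normfinder_stability(df).to_numpy(),
        normfinder_stability(shifted).to_numpy(),
        atol=1e-12,
    )
    assert np.allclose(genorm_m(df).m.to_numpy(), genorm_m(shifted).m.to_numpy(), atol=1e-12)
    assert np.allclose(
        delta_ct_stability(df).to_numpy(), delta_ct_stability(shifted).to_numpy(), atol=1e-12
    )
    # BestKeeper dispersion is NOT shift-invariant: documented contrast
    before = bestkeeper_stats(df)["bestkeeper_sd"].to_numpy()
    after = bestkeeper_stats(shifted)["bestkeeper_sd"].to_numpy()
    assert not np.allclose(before, after, atol=1e-9)


# ---------------------------------------------------------------------------
# comprehensive rank + overlap
# ---------------------------------------------------------------------------


class TestComprehensiveRank:
    def test_unanimous_best_scores_one(self, worked_matrix):
        result = stability_table(worked_matrix)
        assert result.table.loc["A", "comprehensive_score"] == pytest.approx(1.0)
        assert result.table.loc["A", "comprehensive_rank"] == 1

    def test_geometric_mean_formula(self):
        ranks = np.array([1, 2, 4, 8], dtype=float)
        assert np.exp(np.log(ranks).mean()) == pytest.approx(64 ** 0.25, abs=1e-12)
        assert 64 ** 0.25 == pytest.approx(2.8284271247, abs=1e-9)

    def test_score_bounded_by_rank_extremes(self, rng):
        df = random_matrix(rng, n_genes=8, n_samples=10)
        table = stability_table(df).table
        ranks = table[[c for c in table.columns if c.endswith("_rank") and c != "comprehensive_rank"]]
        assert (table["comprehensive_score"] >= ranks.min(axis=1) - 1e-12).all()
        assert (table["comprehensive_score"] <= ranks.max(axis=1) + 1e-12).all()

    def test_mismatched_gene_sets_rejected(self, worked_matrix):
        nf = normfinder_stability(worked_matrix)
        gm = genorm_m(worked_matrix)
        bk = bestkeeper_stats(worked_matrix)
        dc = delta_ct_stability(worked_matrix).rename(index={"C": "Z"})
        with pytest.raises(ConsistencyError):
            comprehensive_rank(nf, gm, bk, dc)

    def test_tie_ranks_share_minimum(self, worked_matrix):
        table = stability_table(worked_matrix).table
        # A and B tie on every method -> both rank 1, C rank 3
        assert table.loc["A", "normfinder_rank"] == table.loc["B", "normfinder_rank"] == 1
        assert table.loc["C", "normfinder_rank"] == 3


class TestTopKOverlap:
    def test_full_agreement(self, rng):
        df = random_matrix(rng, n_genes=6, n_samples=30, spread=1.0)
        result = stability_table(df)
        overlap = top_k_overlap(result, 3)
        union = set().union(*overlap.sets.values())
        assert sum(overlap.counts().values()) == len(union)

    def test_identical_rankings_four_way(self):
        # construct a result where all methods agree exactly
        idx = ["a", "b", "c", "d"]
        scores = pd.Series([0.1, 0.2, 0.3, 0.4], index=idx)
        from endoref.stability import GeNormResult, comprehensive_rank as cr

        gm = GeNormResult(scores.rename("genorm_m"), idx)
        bk = pd.DataFrame(
            {"bestkeeper_sd": scores, "bestkeeper_cv_pct": scores, "bestkeeper_r": 1.0}
        )
        result = cr(scores.rename("normfinder"), gm, bk, scores.rename("delta_ct"))
        overlap = top_k_overlap(result, 2)
        assert overlap.intersection(*overlap.sets.keys()) == {"a", "b"}
        four_way = overlap.regions[frozenset(overlap.sets.keys())]
        assert four_way == {"a", "b"}

    def test_bad_k(self, worked_matrix):
        result = stability_table(worked_matrix)
        with pytest.raises(ParameterError):
            top_k_overlap(result, 0)
        with pytest.raises(ParameterError):
            top_k_overlap(result, 99)


# ---------------------------------------------------------------------------
# planted-gene recovery (small version; full version in acceptance suite)
# ---------------------------------------------------------------------------


def test_planted_gene_recovery_smoke():
    table, truth = simulate_cq_dataset(
        n_groups=2, n_samples_per_group=10, n_stable=3, n_noisy=12,
        stable_sd=0.05, noisy_sd=0.5, seed=11,
    )
    matrix = collapse_replicates(table)
    result = stability_table(matrix)
    planted = set(truth.stable_genes)
    for method in ("normfinder", "genorm", "bestkeeper", "delta_ct"):
        assert result.top_k(method, 3) == planted
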