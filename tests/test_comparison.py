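import numpy as np
import pytest
from scipy import stats

from conftest import make_posterior
from isodiet.comparison import (
    RANK_GRID,
    build_paired_table,
    icc,
    mean_differences,
    posterior_difference_test,
    rank_categories,
    weighted_kappa,
)
from isodiet.mixing_model import summarize_posterior
from isodiet.types import CATEGORIES, DietProportions, ValidationError


class TestRankCategories:
    def test_strict_ordering(self):
        np.testing.assert_array_equal(
            rank_categories([0.4, 0.3, 0.15, 0.1, 0.05]), [1, 2, 3, 4, 5]
        )

    def test_full_tie(self):
        np.testing.assert_array_equal(rank_categories([0.2] * 5), [3, 3, 3, 3, 3])

    def test_pairwise_ties(self):
        np.testing.assert_array_equal(
            rank_categories([0.3, 0.3, 0.2, 0.1, 0.1]), [1.5, 1.5, 3, 4.5, 4.5]
        )

    def test_rejects_non_simplex(self):
        with pytest.raises(ValidationError):
            rank_categories([0.5, 0.5, 0.5, 0.2, 0.1])


def brute_force_kappa(a, b, weighting):
    """Direct evaluation of Kw = 1 - sum(w O)/sum(w E) over all cells."""
    levels = sorted(set(a) | set(b))
    L = len(levels)
    idx = {v: i for i, v in enumerate(levels)}
    n = len(a)
    O = np.zeros((L, L))
    for x, y in zip(a, b):
        O[idx[x], idx[y]] += 1 / n
    pi, qj = O.sum(axis=1), O.sum(axis=0)
    num = den = 0.0
    for i in range(L):
        for j in range(L):
            d = abs(i - j) / (L - 1)
            w = d if weighting == "linear" else d**2
            num += w * O[i, j]
            den += w * pi[i] * qj[j]
    return 1 - num / den


class TestWeightedKappa:
    def test_identical_ranks(self):
        kw, se, p = weighted_kappa([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert kw == pytest.approx(1.0)
        assert p < 0.05

    def test_reversed_ranks_negative(self):
        kw, _, _ = weighted_kappa([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert kw < 0

    @pytest.mark.parametrize("weighting", ["linear", "quadratic"])
    def test_brute_force_oracle(self, weighting):
        rng = np.random.default_rng(8)
        a = rng.integers(1, 4, size=60).tolist()
        b = rng.integers(1, 4, size=60).tolist()
        kw, _, _ = weighted_kappa(a, b, weighting=weighting)
        assert kw == pytest.approx(brute_force_kappa(a, b, weighting), abs=1e-12)

    @pytest.mark.parametrize("weighting,wt", [("linear", "linear"), ("quadratic", "quadratic")])
    def test_statsmodels_oracle(self, weighting, wt):
        from statsmodels.stats.inter_rater import cohens_kappa

        rng = np.random.default_rng(9)
        a = rng.integers(0, 4, size=80)
        b = np.clip(a + rng.integers(-1, 2, size=80), 0, 3)
        table = np.zeros((4, 4))
        np.add.at(table, (a, b), 1)
        res = cohens_kappa(table, wt=f"{'linear' if wt == 'linear' else 'quadratic'}")
        kw, se, p = weighted_kappa(a.tolist(), b.tolist(), weighting=weighting,
                                   levels=[0, 1, 2, 3])
        assert kw == pytest.approx(res.kappa, abs=1e-10)
        assert se == pytest.approx(np.sqrt(res.var_kappa0), abs=1e-10)
        assert p == pytest.approx(res.pvalue_two_sided, abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(10)
        a = rng.integers(1, 6, size=40).tolist()
        b = rng.integers(1, 6, size=40).tolist()
        assert weighted_kappa(a, b)[0] == pytest.approx(weighted_kappa(b, a)[0])

    def test_degenerate_marginals_flagged(self):
        kw, se, p = weighted_kappa([2, 2, 2, 2], [2, 2, 2, 2])
        assert np.isnan(kw)

    def test_random_rankings_near_zero_in_expectation(self):
        rng = np.random.default_rng(11)
        kappas = []
        for _ in range(300):
            a = rng.permutation([1, 2, 3, 4, 5]).tolist() * 4
            b = rng.permutation([1, 2, 3, 4, 5]).tolist() * 4
            kappas.append(weighted_kappa(a, b, levels=[1, 2, 3, 4, 5])[0])
        assert abs(np.mean(kappas)) < 0.02

    def test_half_grid_levels(self):
        a = [1.5, 1.5, 3.0, 4.5, 4.5]
        kw, _, _ = weighted_kappa(a, a, levels=RANK_GRID)
        assert kw == pytest.approx(1.0)


def brute_force_icc1(a, b):
    """One-way ANOVA mean squares computed from definitions."""
    x = np.column_stack([a, b])
    n, k = x.shape
    grand = x.mean()
    msb = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msw = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw), msb / msw


class TestICC:
    def test_identical_vectors(self):
        v = [0.1, 0.4, 0.2, 0.8, 0.3]
        val, f, p = icc(v, v)
        assert val == pytest.approx(1.0)

    def test_large_noise_near_zero(self):
        rng = np.random.default_rng(12)
        vals = []
        for _ in range(200):
            a = rng.uniform(0, 1, size=30)
            b = a + rng.normal(0, 50, size=30)
            vals.append(icc(a, b)[0])
        assert abs(np.mean(vals)) < 0.05

    def test_six_pair_anova_oracle(self):
        a = [0.12, 0.45, 0.33, 0.80, 0.21, 0.05]
        b = [0.15, 0.40, 0.35, 0.75, 0.30, 0.10]
        val, f, p = icc(a, b)
        exp_val, exp_f = brute_force_icc1(a, b)
        assert val == pytest.approx(exp_val, rel=1e-9)
        assert f == pytest.approx(exp_f, rel=1e-9)

    def test_pingouin_oracle(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(13)
        a = rng.uniform(0, 1, size=12)
        b = a + rng.normal(0, 0.1, size=12)
        df = pd.DataFrame(
            {
                "targets": list(range(12)) * 2,
                "raters": ["A"] * 12 + ["B"] * 12,
                "scores": np.concatenate([a, b]),
            }
        )
        res = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        icc1 = res[res["Type"] == "ICC(1,1)"].iloc[0]
        val, f, _ = icc(a, b, variant="oneway")
        assert val == pytest.approx(icc1["ICC"], rel=1e-9)
        assert f == pytest.approx(icc1["F"], rel=1e-9)
        icc_a1 = res[res["Type"] == "ICC(A,1)"].iloc[0]
        val2, _, _ = icc(a, b, variant="twoway")
        assert val2 == pytest.approx(icc_a1["ICC"], rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(14)
        a = rng.uniform(size=10)
        b = rng.uniform(size=10)
        assert icc(a, b)[0] == pytest.approx(icc(b, a)[0])

    def test_zero_variance_flagged(self):
        assert np.isnan(icc([0.2] * 5, [0.2] * 5)[0])


def paired_from_draws(draws, conv_rows, names=("a", "b")):
    post = make_posterior(draws, names=names)
    summary = summarize_posterior(post)
    conv = [
        DietProportions(f"N{i}", 2012, dict(zip(names, row)))
        for i, row in enumerate(conv_rows)
    ]
    return build_paired_table(summary, conv, posterior=post, categories=names)


class TestPosteriorDifferenceTest:
    def test_all_draws_above_zero_conventional(self):
        # conventional = 0 while every posterior draw is positive: the
        # mixing-model estimate always exceeds it -> fraction 1
        draws = np.full((1, 2, 100, 2), 0.5)
        draws[..., 0], draws[..., 1] = 0.4, 0.6
        paired = paired_from_draws(draws, [[0.0, 1.0]])
        per_nest, _ = posterior_difference_test(paired, n_draws=500, seed=0)
        assert per_nest[per_nest["category"] == "a"]["p_below_0"].iloc[0] == 1.0

    def test_conventional_at_posterior_median(self):
        rng = np.random.default_rng(15)
        u = rng.uniform(0.2, 0.8, size=(1, 2, 5000, 1))
        draws = np.concatenate([u, 1 - u], axis=-1)
        med = float(np.median(draws[..., 0]))
        paired = paired_from_draws(draws, [[med, 1 - med]])
        per_nest, _ = posterior_difference_test(paired, n_draws=1000, seed=1)
        assert per_nest[per_nest["category"] == "a"]["p_below_0"].iloc[0] == pytest.approx(
            0.5, abs=3 * np.sqrt(0.25 / 1000)
        )

    def test_uniform_binomial_oracle(self):
        # draws ~ U(0,1), conventional 0.25 -> P(draw > 0.25) = 0.75
        rng = np.random.default_rng(16)
        u = rng.uniform(size=(1, 2, 20000, 1))
        draws = np.concatenate([u, 1 - u], axis=-1)
        paired = paired_from_draws(draws, [[0.25, 0.75]])
        per_nest, _ = posterior_difference_test(paired, n_draws=1000, seed=2)
        got = per_nest[per_nest["category"] == "a"]["p_below_0"].iloc[0]
        assert got == pytest.approx(0.75, abs=3 * np.sqrt(0.25 * 0.75 / 1000))

    def test_deterministic_and_bounded(self):
        rng = np.random.default_rng(17)
        u = rng.uniform(size=(3, 2, 500, 1))
        draws = np.concatenate([u, 1 - u], axis=-1)
        paired = paired_from_draws(draws, [[0.3, 0.7]] * 3)
        a1, s1 = posterior_difference_test(paired, n_draws=200, seed=5)
        a2, s2 = posterior_difference_test(paired, n_draws=200, seed=5)
        assert a1.equals(a2)
        assert s1["median"].between(0, 1).all()


class TestMeanDifferences:
    def test_identical_tables(self):
        rng = np.random.default_rng(18)
        u = rng.uniform(0.2, 0.8, size=(4, 2, 200, 1))
        draws = np.concatenate([u, 1 - u], axis=-1)
        post = make_posterior(draws)
        summary = summarize_posterior(post)
        sia_means = (
            summary.table.pivot_table(index=["territory_id", "year"], columns="source",
                                      values="mean").sort_index()
        )
        conv = [
            DietProportions(f"N{i}", 2012, {"a": row["a"] / (row["a"] + row["b"]),
                                            "b": row["b"] / (row["a"] + row["b"])})
            for i, (_, row) in enumerate(sia_means.iterrows())
        ]
        paired = build_paired_table(summary, conv, categories=("a", "b"))
        out = mean_differences(paired)
        np.testing.assert_allclose(out["mean_diff"], 0.0, atol=1e-12)

    def test_constant_offset(self):
        draws = np.zeros((3, 2, 100, 2))
        draws[..., 0], draws[..., 1] = 0.6, 0.4
        paired = paired_from_draws(draws, [[0.5, 0.5]] * 3)
        out = mean_differences(paired)
        row = out[out["category"] == "a"].iloc[0]
        assert row["mean_diff"] == pytest.approx(0.1)
        assert row["se_diff"] == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_ten_pairs(self):
        rng = np.random.default_rng(19)
        means = rng.uniform(0.2, 0.8, size=10)
        draws = np.zeros((10, 2, 100, 2))
        draws[..., 0] = means[:, None, None]
        draws[..., 1] = 1 - means[:, None, None]
        conv = rng.uniform(0.2, 0.8, size=10)
        paired = paired_from_draws(draws, [[c, 1 - c] for c in conv])
        out = mean_differences(paired)
        d = means - conv
        row = out[out["category"] == "a"].iloc[0]
        assert row["mean_diff"] == pytest.approx(d.mean())
        assert row["se_diff"] == pytest.approx(d.std(ddof=1) / np.sqrt(10))


class TestBuildPairedTable:
    def test_category_mismatch_raises(self):
        draws = np.full((1, 2, 50, 2), 0.5)
        post = make_posterior(draws, names=("x", "y"))
        summary = summarize_posterior(post)
        conv = [DietProportions("N0", 2012, dict(zip(CATEGORIES, [0.2] * 5)))]
        with pytest.raises(ValidationError):
            build_paired_table(summary, conv)  # default 5 categories not in sources

    def test_unmatched_nest_years_dropped(self):
        draws = np.full((2, 2, 50, 2), 0.5)
        post = make_posterior(draws)
        summary = summarize_posterior(post)
        conv = [DietProportions("N0", 2012, {"a": 0.4, "b": 0.6})]
        paired = build_paired_table(summary, conv, posterior=post, categories=("a", "b"))
        assert paired.nests == (("N0", 2012),)
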