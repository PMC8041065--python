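"""WIR transform and the nonparametric test battery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsgm_popmap.meta import (
    ContrastSpec,
    compute_wir,
    compute_wir_by_model,
    contrast_tests,
    dunn_posthoc,
    holm_adjust,
    kruskal_wallis,
    summarize_boxplots,
    wilcoxon_one_sample,
    wir_difference_table,
)


def records(values):
    return pd.DataFrame({"per_inc_mse": values})


class TestComputeWir:
    def test_four_covariates(self):
        out = compute_wir(records([5.0, 2.0, 1.0, 0.5]))
        assert out["wir"].tolist() == [0.25, 0.5, 0.75, 1.0]

    def test_least_important_is_exactly_one(self):
        out = compute_wir(records([3.0, 9.0, 0.1, 4.0, 2.0]))
        assert out.loc[out.per_inc_mse.idxmin(), "wir"] == 1.0

    def test_top_of_ten(self):
        out = compute_wir(records(list(range(10, 0, -1))))
        assert out["wir"].iloc[0] == pytest.approx(0.1)

    def test_ties_get_average_rank(self):
        out = compute_wir(records([5.0, 5.0, 1.0, 0.5]))
        assert out["wir"].tolist() == [0.375, 0.375, 0.75, 1.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_wir(records([]))

    @given(st.lists(st.integers(-35, 35), min_size=2, max_size=12, unique=True),
           st.sampled_from([np.exp, np.tanh, lambda x: 3 * x + 1]))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_monotone_transform(self, ints, f):
        # well-separated values so the transform cannot create float ties
        vals = [v / 7 for v in ints]
        base = compute_wir(records(vals))["wir"]
        transformed = compute_wir(records(list(f(np.array(vals)))))["wir"]
        assert np.allclose(base, transformed)


class TestKruskalWallis:
    def test_two_groups_hand_value(self):
        h, df, p = kruskal_wallis([1, 2, 3, 4, 5, 6], list("aaabbb"))
        assert h == pytest.approx(3.857143, abs=1e-6)
        assert df == 1

    def test_interleaved_hand_value(self):
        h, df, _ = kruskal_wallis([1, 3, 2, 4], list("aabb"))
        assert h == pytest.approx(0.6)

    def test_df_is_groups_minus_one(self, rng):
        values = rng.random(33)
        groups = np.repeat(np.arange(11), 3)
        _, df, _ = kruskal_wallis(values, groups)
        assert df == 10

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([2.0, 2.0, 2.0, 2.0], list("aabb"))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_direct_rank_formula(self, seed):
        """H agrees with the tie-corrected textbook formula computed directly."""
        rng = np.random.default_rng(seed)
        values = np.round(rng.random(8), 1)  # coarse rounding forces ties
        groups = np.array(list("aabbccdd"))
        if np.all(values == values[0]):
            return
        from scipy.stats import rankdata

        ranks = rankdata(values)
        n = len(values)
        h = 12 / (n * (n + 1)) * sum(
            (groups == g).sum() * (ranks[groups == g].mean() - (n + 1) / 2) ** 2
            for g in "abcd"
        )
        _, counts = np.unique(values, return_counts=True)
        h /= 1 - np.sum(counts**3 - counts) / (n**3 - n)
        got, _, _ = kruskal_wallis(values, groups)
        assert got == pytest.approx(h)


class TestWilcoxon:
    def test_symmetric_diffs_p_one(self):
        v, p = wilcoxon_one_sample([1, -1, 2, -2])
        assert p == pytest.approx(1.0)

    def test_all_positive_exact(self):
        v, p = wilcoxon_one_sample([1, 2, 3, 4, 5])
        assert v == 15 and p == pytest.approx(0.0625)

    def test_shift_invariance(self, rng):
        x = rng.normal(size=10)
        assert wilcoxon_one_sample(x, mu=0.3) == wilcoxon_one_sample(x - 0.3)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_one_sample([0.0, 0.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_sign_enumeration(self, seed):
        """Exact p equals brute force over all 2^n sign assignments (n <= 8)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        x = np.round(rng.normal(size=n), 1)
        x = x[x != 0]
        if x.size == 0:
            return
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(x))
        v_obs = ranks[x > 0].sum()
        mean = ranks.sum() / 2
        count = 0
        for signs in itertools.product([0, 1], repeat=x.size):
            v = sum(r for s, r in zip(signs, ranks) if s)
            count += abs(v - mean) >= abs(v_obs - mean) - 1e-9
        _, p = wilcoxon_one_sample(x)
        assert p == pytest.approx(count / 2 ** x.size)

    def test_normal_approximation_close_to_exact(self, rng):
        x = rng.normal(0.4, 1.0, size=20)
        _, p_exact = wilcoxon_one_sample(x)
        _, p_approx = wilcoxon_one_sample(x, exact_max_n=0)
        assert p_approx == pytest.approx(p_exact, abs=0.02)


class TestHolm:
    def test_hand_stepdown(self):
        assert holm_adjust([0.01, 0.04]).tolist() == [0.02, 0.04]

    def test_single_p_unchanged(self):
        assert holm_adjust([0.3]).tolist() == [0.3]

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    @settings(max_examples=40, deadline=None)
    def test_bounds_and_monotonicity(self, pvals):
        adj = holm_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(7)
        assert np.allclose(holm_adjust(p), multipletests(p, method="holm")[1])


class TestDunn:
    def test_two_groups_single_row_holm_noop(self):
        out = dunn_posthoc([1, 2, 3, 10, 11, 12], list("aaabbb"))
        assert len(out) == 1
        assert out["p_holm"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_two_groups_z_squared_equals_h(self):
        vals, groups = [1, 2, 3, 4, 5, 6], list("aaabbb")
        out = dunn_posthoc(vals, groups)
        h, _, _ = kruskal_wallis(vals, groups)
        assert out["z"].iloc[0] ** 2 == pytest.approx(h)

    def test_identical_groups_z_zero_p_one(self):
        out = dunn_posthoc([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert out["z"].iloc[0] == pytest.approx(0.0)
        assert out["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_three_groups_three_rows_stepdown(self, rng):
        vals = rng.random(12)
        groups = np.repeat(list("abc"), 4)
        out = dunn_posthoc(vals, groups)
        assert len(out) == 3
        srt = out.sort_values("p_raw")
        assert (np.diff(srt["p_holm"]) >= -1e-12).all()


def wir_fixture():
    rows = []
    rng = np.random.default_rng(0)
    for country in range(6):
        for year in (2001, 2002):
            # year-specific covariate systematically more important
            imps = {
                "dte_bs_year": 5 + rng.normal(0, 0.5),
                "dte_bs_t0": 1 + rng.normal(0, 0.5),
                "dte_bs_coarse": 2 + rng.normal(0, 0.5),
                "lan": 4 + rng.normal(0, 0.5),
            }
            for cov, v in imps.items():
                rows.append({"country_id": country, "year": year, "covariate": cov,
                             "per_inc_mse": v, "region": f"r{country % 2}"})
    return compute_wir_by_model(pd.DataFrame(rows))


class TestDifferencesAndSummaries:
    def test_difference_sign_convention(self):
        recs = pd.DataFrame(
            [
                {"country_id": 0, "year": 2001, "covariate": "a", "per_inc_mse": 1.0},
                {"country_id": 0, "year": 2001, "covariate": "b", "per_inc_mse": 5.0},
            ]
        )
        wir = compute_wir_by_model(recs)
        out = wir_difference_table(wir, ContrastSpec("a", "b"))
        # a less important (wir 1.0) than b (wir 0.5): positive difference
        assert out["difference"].iloc[0] == pytest.approx(0.5)

    def test_identical_wirs_zero_difference(self):
        wir = wir_fixture()
        out = wir_difference_table(wir, ContrastSpec("lan", "lan"))
        assert np.allclose(out["difference"], 0.0)

    def test_row_counts_models_with_both(self):
        wir = wir_fixture()
        out = wir_difference_table(wir, ContrastSpec("dte_bs_t0", "dte_bs_year"))
        assert len(out) == 12  # 6 countries x 2 years

    def test_absent_covariate_errors(self):
        with pytest.raises(ValueError, match="absent"):
            wir_difference_table(wir_fixture(), ContrastSpec("nope", "dte_bs_year"))

    def test_contrast_tests_detect_direction(self):
        out = contrast_tests(wir_fixture(), [ContrastSpec("dte_bs_t0", "dte_bs_year")])
        assert (out["median_difference"] > 0).all()
        assert (out["p_holm"] <= 1).all()

    def test_boxplot_singleton(self):
        df = pd.DataFrame({"wir": [0.1], "year": [2001]})
        out = summarize_boxplots(df, by="year")
        assert out["median"].iloc[0] == 0.1 and out["iqr"].iloc[0] == 0.0

    def test_boxplot_textbook_quartiles(self):
        df = pd.DataFrame({"wir": [1, 2, 3, 4, 5], "year": [2001] * 5})
        out = summarize_boxplots(df, by="year")
        assert out["median"].iloc[0] == 3 and out["iqr"].iloc[0] == 2

    def test_whiskers_within_data_range(self, rng):
        df = pd.DataFrame({"wir": rng.random(50), "year": np.repeat([1, 2], 25)})
        out = summarize_boxplots(df, by="year")
        for _, row in out.iterrows():
            sub = df.loc[df.year == row.year, "wir"]
            assert sub.min() <= row.whisker_low <= row.whisker_high <= sub.max()
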