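"""Statistical battery: MVC averaging, IQR fences, Lilliefors normality,
paired t, Holm-Bonferroni, Cohen's d and the orchestrated trial analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exoresist import (
    EffectConfig,
    TrialAnalyzer,
    analyze_trial,
    cohens_d,
    generate_cohort,
    holm_bonferroni,
    iqr_outliers,
    lilliefors_normality,
    paired_t,
)
from exoresist.datatypes import MEASURES
from exoresist.errors import ValidationError
from exoresist.outcomes import average_mvc


class TestAverageMvc:
    def test_symmetric_limbs(self):
        assert average_mvc([100, 110, 120], [100, 110, 120], 50.0) == pytest.approx(2.2)

    def test_asymmetric_limbs(self):
        assert average_mvc([90, 90, 90], [110, 110, 110], 50.0) == pytest.approx(2.0)

    def test_wrong_trial_count_warns_but_computes(self):
        with pytest.warns(UserWarning):
            v = average_mvc([100, 110], [100, 110, 120], 50.0)
        assert v == pytest.approx((105 + 110) / 2 / 50)


class TestIqrOutliers:
    def test_identical_values_have_no_outliers(self):
        mask, _ = iqr_outliers(np.full(8, 3.0))
        assert not mask.any()

    def test_extreme_cot_value_flagged(self):
        # fences by hand (linear-interpolation quartiles): Q1=4.625,
        # Q3=5.875, IQR=1.25 -> fences (2.75, 7.75); only 16.9 escapes
        values = np.array([4.0, 4.5, 5.0, 5.5, 6.0, 16.9])
        mask, (lo, hi) = iqr_outliers(values)
        assert lo == pytest.approx(2.75)
        assert hi == pytest.approx(7.75)
        assert mask.tolist() == [False] * 5 + [True]

    def test_low_extreme_flagged_high_values_kept(self):
        values = np.array([-20.0, 9.0, 10.0, 10.5, 11.0, 11.5, 12.0])
        mask, _ = iqr_outliers(values)
        assert mask[0]
        assert not mask[1:].any()

    def test_small_sample_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            mask, fences = iqr_outliers([1.0, 2.0, 50.0])
        assert not mask.any()
        assert np.isnan(fences[0])


class TestLilliefors:
    def test_returns_probability_at_study_sample_size(self, rng):
        _, p = lilliefors_normality(rng.standard_normal(6), n_sims=2000)
        assert 0.0 <= p <= 1.0

    def test_type_i_error_calibrated(self):
        # 200 normal samples: rejection rate at alpha=0.05 should be ~5%
        rng = np.random.default_rng(77)
        rejections = sum(
            lilliefors_normality(rng.standard_normal(20), n_sims=4000)[1] < 0.05
            for _ in range(200)
        )
        assert 0.02 <= rejections / 200 <= 0.08

    def test_power_against_exponential(self):
        rng = np.random.default_rng(78)
        rejections = sum(
            lilliefors_normality(rng.exponential(size=50), n_sims=2000)[1] < 0.05
            for _ in range(50)
        )
        assert rejections / 50 > 0.5

    def test_zero_variance_degenerate(self):
        with pytest.warns(UserWarning):
            _, p = lilliefors_normality(np.full(6, 2.0))
        assert p == 0.0

    def test_agrees_with_statsmodels_reference(self, rng):
        # statsmodels' table-based Lilliefors p as an independent check
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        x = rng.standard_normal(25)
        d, p = lilliefors_normality(x, n_sims=20_000)
        d_ref, p_ref = sm_lilliefors(x, dist="norm")
        assert d == pytest.approx(d_ref, abs=1e-10)
        assert p == pytest.approx(min(p_ref, 1.0), abs=0.05)


class TestPairedT:
    def test_no_change_gives_t_zero_p_one(self):
        t, p, df = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and df == 2

    def test_constant_nonzero_differences_flagged_infinite(self):
        with pytest.warns(UserWarning):
            t, p, _ = paired_t([0, 0, 0, 0], [1, 1, 1, 1])
        assert np.isinf(t) and p == 0.0

    def test_hand_computed_example(self):
        # diffs [2,4,6,8]: mean 5, sd 2.5820, t = 3.872983, df=3,
        # p = 0.0304663 (two-sided)
        t, p, df = paired_t([1, 2, 3, 4], [3, 6, 9, 12])
        assert t == pytest.approx(3.872983346207417, abs=1e-10)
        assert p == pytest.approx(0.030466291662170977, abs=1e-10)
        assert df == 3

    def test_matches_textbook_formula_on_random_inputs(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 12))
            pre = rng.normal(10, 2, n)
            post = pre + rng.normal(0.5, 1, n)
            t, p, df = paired_t(pre, post)
            d = post - pre
            t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            p_ref = 2 * stats.t.sf(abs(t_ref), n - 1)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            paired_t([1.0], [2.0])


class TestHolmBonferroni:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.03])[0] == pytest.approx(0.03)

    def test_step_down_hand_example(self):
        np.testing.assert_allclose(
            holm_bonferroni([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04], atol=1e-12
        )

    def test_all_ones_capped(self):
        np.testing.assert_array_equal(holm_bonferroni([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_adjusted_dominates_raw_and_is_monotone(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(2, 10)))
            adj = holm_bonferroni(p)
            assert np.all(adj >= p - 1e-15)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            holm_bonferroni([0.5, 1.2])


class TestCohensD:
    def test_no_change_is_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0] ) == 0.0

    def test_dz_hand_example(self):
        assert cohens_d([1, 2, 3, 4], [3, 6, 9, 12], "dz") == pytest.approx(
            1.9364916731037085, abs=1e-10
        )

    def test_antisymmetry(self, rng):
        pre = rng.normal(size=8)
        post = pre + rng.normal(0.3, 1, 8)
        assert cohens_d(pre, post) == pytest.approx(-cohens_d(post, pre), abs=1e-12)

    def test_dav_uses_mean_of_sds(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        post = np.array([2.0, 4.0, 5.0, 8.0])
        d = post - pre
        expected = d.mean() / (0.5 * (pre.std(ddof=1) + post.std(ddof=1)))
        assert cohens_d(pre, post, "dav") == pytest.approx(expected, abs=1e-12)


def _table_from_cohort(n=6, effects=None, seed=0):
    table, _ = generate_cohort(n, effects, seed=seed)
    return table


class TestAnalyzeTrial:
    def test_all_measures_reported_with_adjusted_p(self):
        results = analyze_trial(_table_from_cohort(), lilliefors_sims=500)
        assert [r.measure for r in results] == list(MEASURES)
        for r in results:
            assert 0 <= r.p_raw <= 1
            assert r.p_adjusted >= r.p_raw - 1e-15
            assert r.n_used == 6 - len(r.outliers_removed)

    def test_planted_extreme_cot_is_excluded_and_listed(self):
        table = _table_from_cohort()
        idx = table[(table["measure"] == "cot")].index[2]
        participant = table.loc[idx, "participant"]
        table.loc[idx, "pre"] = 16.9  # far outside the cohort's CoT spread
        results = analyze_trial(table, lilliefors_sims=500)
        cot = next(r for r in results if r.measure == "cot")
        assert participant in cot.outliers_removed
        assert cot.n_used == 5

    def test_missing_post_handled_by_listwise_deletion(self):
        table = _table_from_cohort()
        idx = table[(table["measure"] == "sixmwt")].index[3]
        table.loc[idx, "post"] = np.nan
        results = analyze_trial(table, lilliefors_sims=500)
        walk = next(r for r in results if r.measure == "sixmwt")
        assert walk.n_used == 5

    def test_effect_recovery_at_study_scale(self):
        # cohorts generated at the configured effect sizes recover the
        # mean percent changes over replicates
        reps = 200
        means = {m: [] for m in MEASURES}
        for seed in range(reps):
            results = analyze_trial(
                _table_from_cohort(seed=seed), lilliefors_sims=200
            )
            for r in results:
                means[r.measure].append(r.pct_change_mean)
        cfg = EffectConfig()
        for m in MEASURES:
            grand = np.mean(means[m])
            se = np.std(means[m]) / np.sqrt(reps)
            assert abs(grand - cfg.effects[m]) < max(4 * se, 0.01)

    def test_familywise_error_controlled_under_null(self):
        reps = 200
        fw = 0
        for seed in range(reps):
            table = _table_from_cohort(effects=EffectConfig.null(), seed=seed)
            results = analyze_trial(table, lilliefors_sims=200)
            fw += any(r.p_adjusted < 0.05 for r in results)
        assert fw / reps <= 0.09  # Holm guarantees <= 0.05 + MC noise

    def test_deterministic_given_table_and_seed(self):
        table = _table_from_cohort()
        a = analyze_trial(table, lilliefors_sims=500, seed=1)
        b = analyze_trial(table, lilliefors_sims=500, seed=1)
        assert [(r.t, r.p_raw, r.p_adjusted, r.d) for r in a] == [
            (r.t, r.p_raw, r.p_adjusted, r.d) for r in b
        ]

    def test_estimator_wrapper_exposes_report(self):
        analyzer = TrialAnalyzer(lilliefors_sims=500).fit(_table_from_cohort())
        assert len(analyzer.results_) == 5
        assert "measure" in analyzer.report_.splitlines()[0]
        assert analyzer.frame_.shape[0] == 5

    def test_duplicate_rows_rejected(self):
        table = _table_from_cohort()
        dup = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError):
            analyze_trial(dup)
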