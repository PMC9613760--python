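"""MR estimators: IVW, medians, Egger, Cochran's Q, OR transformation."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from perimr import (
    AnalysisError,
    HarmonizedDataset,
    HarmonizedVariant,
    RatioEstimate,
    cochran_q,
    egger,
    ivw,
    median_estimate,
    run_all_methods,
    to_odds_ratio,
    wald_ratios,
    ztest_p,
)

from conftest import harmonized_sim


def ratio(vid, theta, se):
    return RatioEstimate(variant_id=vid, theta=theta, se=se)


def pair(vid, bx, by, sy, sx=0.01, eaf=0.3):
    return HarmonizedVariant(
        variant_id=vid, effect_allele="A", other_allele="G",
        beta_x=bx, se_x=sx, beta_y=by, se_y=sy, eaf_x=eaf, eaf_y=eaf,
        action="none", palindromic=False,
    )


class TestWaldRatios:
    def test_unit_exposure(self):
        data = HarmonizedDataset(pairs=[pair("rs1", 1.0, -0.7, 0.3)])
        [r] = wald_ratios(data)
        assert (r.theta, r.se) == (-0.7, 0.3)

    def test_sign_and_scale(self):
        data = HarmonizedDataset(pairs=[pair("rs1", -0.5, 0.2, 0.1)])
        [r] = wald_ratios(data)
        assert r.theta == pytest.approx(-0.4)
        assert r.se == pytest.approx(0.2)

    def test_zero_exposure_effect_dropped(self):
        data = HarmonizedDataset(pairs=[pair("rs1", 0.0, 0.2, 0.1), pair("rs2", 1.0, 0.2, 0.1)])
        assert [r.variant_id for r in wald_ratios(data)] == ["rs2"]

    def test_mean_ratio_recovers_theta_in_simulation(self):
        data, truth = harmonized_sim(seed=41, n_instruments=200, tau=0.05)
        thetas = [r.theta for r in wald_ratios(data)]
        sem = np.std(thetas) / np.sqrt(len(thetas))
        assert abs(np.mean(thetas) - truth.theta) < 3 * sem


class TestIVW:
    def test_hand_computed_two_ratio_case(self):
        ratios = [ratio("a", 1.0, 1.0), ratio("b", 3.0, 1.0)]
        fixed = ivw(ratios, "fixed")
        assert fixed.beta == pytest.approx(2.0)
        assert fixed.se == pytest.approx(1 / np.sqrt(2))
        rand = ivw(ratios, "random")
        assert rand.beta == pytest.approx(2.0)
        # Q = 2, J-1 = 1, so SE_random = SE_fixed * sqrt(2) = 1
        assert rand.se == pytest.approx(1.0)

    def test_equal_weights_reduce_to_arithmetic_mean(self):
        ratios = [ratio(str(i), t, 0.5) for i, t in enumerate([0.1, 0.4, 0.9, -0.2])]
        assert ivw(ratios, "fixed").beta == pytest.approx(np.mean([0.1, 0.4, 0.9, -0.2]))

    def test_single_ratio_degenerate(self):
        est = ivw([ratio("a", 0.5, 0.2)], "random")
        assert (est.beta, est.se) == (0.5, 0.2)
        assert est.degenerate

    def test_empty_input_is_error(self):
        with pytest.raises(AnalysisError):
            ivw([], "fixed")

    def test_random_se_relation_exact_and_shrinks_under_homogeneity(self):
        """SE_random = SE_fixed * sqrt(Q/(J-1)), unfloored: with nearly
        identical ratios the random SE drops below the fixed SE."""
        ratios = [ratio(str(i), 0.5 + 1e-6 * i, 0.3) for i in range(10)]
        fixed = ivw(ratios, "fixed")
        rand = ivw(ratios, "random")
        q, df, _ = cochran_q(ratios, fixed.beta)
        assert rand.se == pytest.approx(fixed.se * np.sqrt(q / df), rel=1e-12)
        assert rand.se < fixed.se

    def test_floor_dispersion_restores_floored_convention(self):
        ratios = [ratio(str(i), 0.5, 0.3) for i in range(5)]
        rand = ivw(ratios, "random", floor_dispersion=True)
        fixed = ivw(ratios, "fixed")
        assert rand.se == pytest.approx(fixed.se)

    def test_matches_weighted_regression_through_origin(self):
        """IVW equals WLS of beta_y on beta_x (no intercept, weights 1/se_y^2)."""
        data, _ = harmonized_sim(seed=43)
        ratios = wald_ratios(data)
        est = ivw(ratios, "fixed")
        bx = np.array([p.beta_x for p in data.pairs])
        by = np.array([p.beta_y for p in data.pairs])
        w = np.array([1 / p.se_y**2 for p in data.pairs])
        fit = sm.WLS(by, bx[:, None], weights=w).fit()
        assert est.beta == pytest.approx(float(fit.params[0]), rel=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.randoms(use_true_random=False), st.sets(st.integers(0, 17)))
    def test_invariant_to_order_and_joint_sign_flips(self, rnd, flip_idx):
        data, _ = harmonized_sim(seed=43)
        ratios = wald_ratios(data)
        est0 = ivw(ratios, "random")
        shuffled = list(ratios)
        rnd.shuffle(shuffled)
        est1 = ivw(shuffled, "random")
        assert est1.beta == pytest.approx(est0.beta, rel=1e-12)
        assert est1.se == pytest.approx(est0.se, rel=1e-12)
        # Jointly negating (beta_x, beta_y) on any subset of SNPs leaves
        # every Wald ratio, and hence the pooled estimate, unchanged.
        flipped_pairs = [
            HarmonizedVariant(
                variant_id=p.variant_id, effect_allele=p.effect_allele,
                other_allele=p.other_allele, beta_x=-p.beta_x, se_x=p.se_x,
                beta_y=-p.beta_y, se_y=p.se_y, eaf_x=p.eaf_x, eaf_y=p.eaf_y,
                action=p.action, palindromic=p.palindromic,
            ) if i in flip_idx else p
            for i, p in enumerate(data.pairs)
        ]
        est2 = ivw(wald_ratios(HarmonizedDataset(pairs=flipped_pairs)), "random")
        assert est2.beta == pytest.approx(est0.beta, rel=1e-12)
        assert est2.se == pytest.approx(est0.se, rel=1e-12)


class TestZTestAndOddsRatio:
    @pytest.mark.parametrize(
        "beta, se, expected",
        [(-0.039, 0.272, 0.886), (-0.248, 0.383, 0.517), (0.0, 1.0, 1.0)],
    )
    def test_two_sided_normal_p(self, beta, se, expected):
        assert ztest_p(beta, se) == pytest.approx(expected, abs=5e-4)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            ztest_p(0.1, 0.0)

    def test_headline_or_and_ci(self):
        or_, lo, hi = to_odds_ratio(-0.731, 0.258)
        assert round(or_, 2) == 0.48
        assert round(lo, 2) == 0.29
        assert round(hi, 2) == 0.80

    def test_null_beta_symmetric_about_one(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.2)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_ci_bounds_direct_evaluation(self):
        _, lo, hi = to_odds_ratio(0.5, 0.1)
        assert lo == pytest.approx(np.exp(0.5 - 1.959964 * 0.1), rel=1e-6)
        assert hi == pytest.approx(np.exp(0.5 + 1.959964 * 0.1), rel=1e-6)
        assert lo == pytest.approx(1.3553, abs=2e-4)
        assert hi == pytest.approx(2.0057, abs=2e-4)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            to_odds_ratio(0.1, 0.1, level=1.5)


class TestMedianEstimators:
    def test_simple_median_odd_count_equal_weights(self):
        ratios = [ratio("a", 1.0, 1.0), ratio("b", 2.0, 1.0), ratio("c", 10.0, 1.0)]
        est = median_estimate(ratios, weighted=False, n_boot=200, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_weighted_median_hand_computed_interpolation(self):
        # weights {10,1,1}, theta {0.1,5,9}: cumulative midpoints
        # s = (5/12, 21/24, 23/24); interpolating at 1/2 gives
        # 0.1 + (1/12)/(11/24)*(5-0.1) = 0.990909...
        ratios = [
            ratio("a", 0.1, np.sqrt(1 / 10)),
            ratio("b", 5.0, 1.0),
            ratio("c", 9.0, 1.0),
        ]
        est = median_estimate(ratios, weighted=True, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.1 + (2 / 11) * 4.9, rel=1e-12)

    def test_equal_weights_weighted_equals_simple(self):
        ratios = [ratio(str(i), t, 0.7) for i, t in enumerate([0.3, -1.2, 0.8, 2.0, 0.1])]
        simple = median_estimate(ratios, weighted=False, n_boot=100, seed=2)
        weighted = median_estimate(ratios, weighted=True, n_boot=100, seed=2)
        assert weighted.beta == simple.beta

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=3, max_size=15,
        )
    )
    def test_simple_median_equals_numpy_median_for_odd_counts(self, thetas):
        if len(thetas) % 2 == 0:
            thetas = thetas[:-1]
        ratios = [ratio(str(i), t, 1.0) for i, t in enumerate(thetas)]
        est = median_estimate(ratios, weighted=False, n_boot=10, seed=0)
        assert est.beta == pytest.approx(float(np.median(thetas)), abs=1e-12)

    def test_fewer_than_three_ratios_is_error(self):
        with pytest.raises(AnalysisError):
            median_estimate([ratio("a", 1, 1), ratio("b", 2, 1)], weighted=False)

    def test_bootstrap_se_is_seed_reproducible(self):
        ratios = [ratio(str(i), t, 0.5) for i, t in enumerate([0.1, 0.5, 0.9, 1.5])]
        a = median_estimate(ratios, weighted=True, n_boot=300, seed=9)
        b = median_estimate(ratios, weighted=True, n_boot=300, seed=9)
        assert a.se == b.se


class TestEgger:
    def test_exact_line_recovered_from_noise_free_fixture(self):
        """Directional pleiotropy fixture beta_y = 0.01 + 0.5*beta_x exactly."""
        bx = np.array([0.02, 0.05, 0.11, 0.17, 0.23])
        pairs = [pair(f"rs{i}", b, 0.01 + 0.5 * b, 0.05 + 0.01 * i)
                 for i, b in enumerate(bx)]
        result = egger(HarmonizedDataset(pairs=pairs))
        assert result.slope.beta == pytest.approx(0.5, abs=1e-8)
        assert result.intercept == pytest.approx(0.01, abs=1e-8)
        assert result.q == pytest.approx(0.0, abs=1e-12)

    def test_orientation_negates_negative_exposure_effects(self):
        pairs_pos = [pair(f"rs{i}", b, 0.01 + 0.5 * b, 0.05)
                     for i, b in enumerate([0.02, 0.05, 0.11, 0.17])]
        pairs_mix = [
            HarmonizedVariant(
                variant_id=p.variant_id, effect_allele="A", other_allele="G",
                beta_x=-p.beta_x, se_x=p.se_x, beta_y=-p.beta_y, se_y=p.se_y,
                eaf_x=0.3, eaf_y=0.3, action="none", palindromic=False,
            ) if i % 2 else p
            for i, p in enumerate(pairs_pos)
        ]
        a = egger(HarmonizedDataset(pairs=pairs_pos))
        b = egger(HarmonizedDataset(pairs=pairs_mix))
        assert b.slope.beta == pytest.approx(a.slope.beta, rel=1e-12)
        assert b.intercept == pytest.approx(a.intercept, rel=1e-12)

    def test_two_points_is_error(self):
        pairs = [pair("rs1", 0.1, 0.2, 0.1), pair("rs2", 0.2, 0.3, 0.1)]
        with pytest.raises(AnalysisError):
            egger(HarmonizedDataset(pairs=pairs))

    def test_intercept_p_calibrated_under_balanced_pleiotropy(self):
        """Under balanced pleiotropy the intercept test p-values should be
        roughly uniform across replicates."""
        ps = []
        for seed in range(60):
            data, _ = harmonized_sim(
                seed=700 + seed, n_instruments=30, tau=0.05,
                pleiotropy_mode="balanced", pleiotropy_sd=0.02,
            )
            ps.append(egger(data).intercept_p)
        stat, p_ks = stats.kstest(ps, "uniform")
        assert p_ks > 0.01


class TestCochranQ:
    def test_identical_ratios_give_zero_q_unit_p(self):
        ratios = [ratio(str(i), 0.4, 0.2) for i in range(4)]
        q, df, p = cochran_q(ratios, 0.4)
        assert q == 0.0
        assert df == 3
        assert p == 1.0

    def test_hand_computed_chi_square_tail(self):
        ratios = [ratio("a", 1.0, 1.0), ratio("b", 3.0, 1.0)]
        q, df, p = cochran_q(ratios, 2.0)
        assert q == pytest.approx(2.0)
        assert df == 1
        assert p == pytest.approx(0.15730, abs=1e-4)

    def test_homogeneous_simulation_q_over_df_near_one(self):
        vals = []
        for seed in range(40):
            data, _ = harmonized_sim(seed=900 + seed, n_instruments=25, tau=0.05)
            ratios = wald_ratios(data)
            est = ivw(ratios, "fixed")
            q, df, _ = cochran_q(ratios, est.beta)
            vals.append(q / df)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)

    def test_df_below_one_is_error(self):
        with pytest.raises(AnalysisError):
            cochran_q([ratio("a", 1.0, 1.0)], 1.0)


class TestRunAllMethods:
    def test_estimator_panel_is_complete_and_bookkept(self):
        data, _ = harmonized_sim(seed=47)
        estimates, diag = run_all_methods(data, n_boot=200, seed=5)
        methods = [e.method for e in estimates]
        assert methods == [
            "ivw_random", "ivw_fixed", "simple_median", "weighted_median", "egger_slope",
        ]
        assert all(e.n_snp == len(data.pairs) for e in estimates)
        assert diag.df_ivw == len(data.pairs) - 1
        assert diag.df_egger == len(data.pairs) - 2
        assert diag.q_ivw >= 0 and diag.q_egger >= 0

    def test_concordant_signs_with_strong_effect_no_pleiotropy(self):
        data, _ = harmonized_sim(seed=53, tau=0.05)
        estimates, _ = run_all_methods(data, n_boot=200, seed=5)
        headline = [e for e in estimates if e.method != "egger_slope"]
        assert all(e.beta < 0 for e in headline)

    def test_null_scenario_p_values_mostly_nonsignificant(self):
        significant = 0
        n_rep = 40
        for seed in range(n_rep):
            data, _ = harmonized_sim(seed=1200 + seed, theta=0.0, tau=0.05)
            estimates, _ = run_all_methods(data, n_boot=100, seed=5)
            headline = [e for e in estimates if e.method != "egger_slope"]
            significant += any(e.pvalue < 0.05 for e in headline)
        # family-wise over four correlated tests; generous ceiling
        assert significant / n_rep < 0.35
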