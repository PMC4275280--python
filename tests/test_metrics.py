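"""Statistical core against independent oracles: brute-force concordance,
generic ML optimization, closed-form 2x2 log-odds, beta quantiles."""

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.special import expit

from asthmapred.metrics import (
    SeparationError,
    SingleClassError,
    auc,
    bootstrap_proportion_ci,
    calibration_table,
    fit_logistic,
    nagelkerke_r2,
    odds_ratio_per_point,
    recover_distribution_from_sens_spec,
    scaled_brier,
    threshold_metrics,
)


def pairwise_auc(scores, outcomes):
    """Exhaustive case-control pair loop: I(case > control) + 1/2 I(=)."""
    s = np.asarray(scores, float)
    y = np.asarray(outcomes, int)
    cases, controls = s[y == 1], s[y == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


def optimizer_logistic(scores, outcomes):
    """Generic ML oracle: Nelder-Mead refinement of BFGS on the exact nll."""
    X = np.column_stack([np.ones(len(scores)), scores])
    y = np.asarray(outcomes, float)

    def nll(beta):
        eta = X @ beta
        return np.sum(np.logaddexp(0, eta)) - y @ eta

    res = optimize.minimize(nll, x0=np.zeros(2), method="BFGS")
    res = optimize.minimize(nll, x0=res.x, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    return res.x


def random_dataset(rng, n=100):
    s = rng.integers(0, 16, size=n)
    p = expit(-2.0 + 0.35 * s)
    y = (rng.random(n) < p).astype(int)
    if y.sum() in (0, n):  # ensure both classes
        y[0], y[-1] = 0, 1
    return s, y


class TestLogisticFit:
    def test_constant_scores_collapse_to_intercept_only(self):
        fit = fit_logistic([5] * 10, [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        assert fit.slope == 0.0
        assert fit.intercept == pytest.approx(np.log(0.2 / 0.8))

    def test_two_level_design_matches_2x2_log_odds(self):
        # score 0: 10 cases / 40 controls; score 1: 30 cases / 20 controls
        s = np.array([0] * 50 + [1] * 50)
        y = np.array([1] * 10 + [0] * 40 + [1] * 30 + [0] * 20)
        fit = fit_logistic(s, y)
        assert fit.intercept == pytest.approx(np.log(10 / 40), abs=1e-9)
        assert fit.slope == pytest.approx(np.log((30 / 20) / (10 / 40)), abs=1e-9)

    def test_matches_generic_optimizer_on_random_data(self):
        rng = np.random.default_rng(12345)
        for _ in range(10):
            s, y = random_dataset(rng)
            fit = fit_logistic(s, y)
            beta = optimizer_logistic(s, y)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-6)
            assert fit.slope == pytest.approx(beta[1], abs=1e-6)

    def test_matches_statsmodels_coefficients_and_covariance(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        s, y = random_dataset(rng, n=300)
        fit = fit_logistic(s, y)
        X = sm.add_constant(s.astype(float))
        ref = sm.Logit(y, X).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-6)
        assert np.allclose(fit.cov, ref.cov_params(), atol=1e-6)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-8)
        assert fit.null_log_likelihood == pytest.approx(ref.llnull, abs=1e-8)

    def test_slope_recovery_within_three_se(self):
        rng = np.random.default_rng(99)
        n, b = 10_000, np.log(1.7)
        s = rng.integers(0, 16, size=n)
        y = (rng.random(n) < expit(-3.3 + b * s)).astype(int)
        fit = fit_logistic(s, y)
        assert abs(fit.slope - b) < 3 * fit.slope_se

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            fit_logistic([1, 2, 3], [1, 1, 1])

    def test_separation_flagged_and_or_suppressed(self):
        s = np.array([0] * 20 + [10] * 20)
        y = np.array([0] * 20 + [1] * 20)
        fit = fit_logistic(s, y)
        assert fit.separated
        with pytest.raises(SeparationError):
            odds_ratio_per_point(fit)


class TestOddsRatio:
    def test_zero_slope_gives_or_one_with_ci_containing_one(self):
        rng = np.random.default_rng(1)
        s = rng.integers(0, 16, 500)
        y = rng.integers(0, 2, 500)
        fit = fit_logistic(s, y)
        orr, (lo, hi) = odds_ratio_per_point(fit)
        assert lo < 1 < hi

    def test_wald_interval_is_hand_exponentiation(self):
        rng = np.random.default_rng(2)
        s, y = random_dataset(rng, 200)
        fit = fit_logistic(s, y)
        orr, (lo, hi) = odds_ratio_per_point(fit)
        z = 1.959963984540054
        assert orr == pytest.approx(np.exp(fit.slope))
        assert lo == pytest.approx(np.exp(fit.slope - z * fit.slope_se))
        assert hi == pytest.approx(np.exp(fit.slope + z * fit.slope_se))


class TestThresholdMetrics:
    def test_perfect_separation_at_cutoff(self):
        s = [1, 2, 8, 9]
        y = [0, 0, 1, 1]
        tm = threshold_metrics(s, y, cutoff=5)
        assert tm.sensitivity == 1.0 and tm.specificity == 1.0

    def test_known_2x2_table(self):
        # TP=23 FN=5 TN=77 FP=35
        s = [6] * 23 + [1] * 5 + [0] * 77 + [7] * 35
        y = [1] * 23 + [1] * 5 + [0] * 77 + [0] * 35
        tm = threshold_metrics(s, y, cutoff=5)
        assert tm.sensitivity == pytest.approx(23 / 28)
        assert tm.specificity == pytest.approx(77 / 112)
        assert tm.ppv == pytest.approx(23 / 58)
        assert tm.lr_plus == pytest.approx((23 / 28) / (35 / 112))

    def test_cutoff_below_minimum_catches_everyone(self):
        tm = threshold_metrics([3, 4, 5], [1, 0, 1], cutoff=0)
        assert tm.sensitivity == 1.0 and tm.specificity == 0.0

    def test_empty_margin_yields_nan_not_exception(self):
        tm = threshold_metrics([3, 4], [0, 0], cutoff=5)
        assert np.isnan(tm.sensitivity)

    def test_sens_nonincreasing_spec_nondecreasing_in_cutoff(self):
        rng = np.random.default_rng(3)
        s, y = random_dataset(rng, 150)
        rows = [threshold_metrics(s, y, cutoff=c) for c in range(0, 16)]
        sens = [r.sensitivity for r in rows]
        spec = [r.specificity for r in rows]
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))

    def test_predicted_probability_is_inverse_logit_at_cutoff(self):
        rng = np.random.default_rng(4)
        s, y = random_dataset(rng, 150)
        fit = fit_logistic(s, y)
        tm = threshold_metrics(s, y, fit, cutoff=5)
        assert tm.predicted_probability == pytest.approx(expit(fit.intercept + 5 * fit.slope))


class TestAuc:
    def test_perfectly_ordered_scores_give_one(self):
        a, _ = auc([1, 2, 8, 9], [0, 0, 1, 1])
        assert a == 1.0

    def test_identical_scores_give_half(self):
        a, _ = auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert a == 0.5

    def test_equals_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        s, y = random_dataset(rng, 200)
        a, _ = auc(s, y)
        assert abs(a - pairwise_auc(s, y)) < 1e-12

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(6)
        s, y = random_dataset(rng, 120)
        a1, _ = auc(s, y)
        a2, _ = auc(np.exp(0.3 * s.astype(float)), y)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_auc_on_scores_equals_auc_on_fitted_probabilities(self):
        rng = np.random.default_rng(8)
        s, y = random_dataset(rng, 150)
        fit = fit_logistic(s, y)
        a1, _ = auc(s, y)
        a2, _ = auc(fit.predict(s), y)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_delong_ci_brackets_auc_and_bootstrap_agrees(self):
        rng = np.random.default_rng(9)
        s, y = random_dataset(rng, 200)
        a, (lo, hi) = auc(s, y)
        assert lo < a < hi
        _, (blo, bhi) = auc(s, y, ci_method="bootstrap", n_boot=500, seed=1)
        assert abs(blo - lo) < 0.1 and abs(bhi - hi) < 0.1

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            auc([1, 2], [1, 1])


class TestOverallPerformance:
    def test_nagelkerke_zero_for_intercept_only(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        fit = fit_logistic(np.full(100, 3), y)
        assert nagelkerke_r2(fit) == pytest.approx(0.0, abs=1e-9)

    def test_nagelkerke_approaches_one_near_separation(self):
        s = np.array([0] * 30 + [10] * 30)
        y = np.array([0] * 30 + [1] * 30)
        fit = fit_logistic(s, y)
        assert nagelkerke_r2(fit) > 0.99

    def test_nagelkerke_matches_hand_formula_on_fixture(self):
        rng = np.random.default_rng(11)
        s, y = random_dataset(rng, 80)
        fit = fit_logistic(s, y)
        n = len(y)
        cs = 1 - np.exp((2 / n) * (fit.null_log_likelihood - fit.log_likelihood))
        expected = cs / (1 - np.exp((2 / n) * fit.null_log_likelihood))
        assert nagelkerke_r2(fit) == pytest.approx(expected, abs=1e-12)

    def test_scaled_brier_anchors(self):
        y = np.array([1, 0, 0, 0, 1])
        prev = y.mean()
        assert scaled_brier(np.full(5, prev), y) == pytest.approx(0.0, abs=1e-9)
        assert scaled_brier(y.astype(float), y) == pytest.approx(1.0)

    def test_scaled_brier_hand_value(self):
        # prevalence 0.2, Brier 0.125 -> 1 - 0.125/0.16 = 0.21875
        y = np.array([1, 0, 0, 0, 0])
        p = np.full(5, 0.25)
        # Brier = (0.75^2 + 4*0.25^2)/5 = 0.1625 -> scaled = 1-0.1625/0.16
        assert scaled_brier(p, y) == pytest.approx(1 - 0.1625 / 0.16, abs=1e-12)

    def test_scaled_brier_nan_for_degenerate_prevalence(self):
        assert np.isnan(scaled_brier([0.5, 0.5], [1, 1]))


class TestCalibration:
    def test_groups_partition_with_sizes_differing_by_at_most_one(self):
        rng = np.random.default_rng(12)
        p = rng.random(109)
        y = (rng.random(109) < p).astype(int)
        groups = calibration_table(p, y)
        sizes = [g.n for g in groups]
        assert sum(sizes) == 109
        assert max(sizes) - min(sizes) <= 1
        means = [g.mean_predicted for g in groups]
        assert means == sorted(means)

    def test_zero_events_lower_bound_zero(self):
        groups = calibration_table(np.linspace(0, 1, 80), np.zeros(80, int))
        assert all(g.ci_low == 0.0 for g in groups)

    def test_exact_ci_matches_beta_quantile_oracle(self):
        p = np.linspace(0.1, 0.9, 80)
        y = np.zeros(80, int)
        y[:41] = 1  # group 1 (first 10 sorted) -> events vary; use direct check
        groups = calibration_table(p, y)
        for g in groups:
            lo = 0.0 if g.events == 0 else stats.beta.ppf(0.025, g.events, g.n - g.events + 1)
            hi = 1.0 if g.events == g.n else stats.beta.ppf(0.975, g.events + 1, g.n - g.events)
            assert g.ci_low == pytest.approx(lo, abs=1e-12)
            assert g.ci_high == pytest.approx(hi, abs=1e-12)

    def test_five_of_ten_events_interval(self):
        p = np.repeat(np.linspace(0.1, 0.8, 8), 10)
        y = np.zeros(80, int)
        y[:5] = 1  # first sorted group has exactly 5/10 events
        groups = calibration_table(p, y)
        assert groups[0].events == 5
        assert groups[0].ci_low == pytest.approx(0.187, abs=1e-3)
        assert groups[0].ci_high == pytest.approx(0.813, abs=1e-3)

    def test_well_calibrated_simulation_covered_by_cis(self):
        rng = np.random.default_rng(4)
        p = rng.beta(2, 5, 10_000)
        y = (rng.random(10_000) < p).astype(int)
        for g in calibration_table(p, y):
            assert g.ci_low <= g.mean_predicted <= g.ci_high


class TestDistributionRecovery:
    @staticmethod
    def forward(case_dist, ctrl_dist, prev, max_score=15):
        """sens/spec by cutoff implied by per-class score distributions."""
        cutoffs = list(range(1, max_score + 1))
        sens = [sum(p for s, p in case_dist.items() if s >= c) for c in cutoffs]
        spec = [sum(p for s, p in ctrl_dist.items() if s < c) for c in cutoffs]
        return cutoffs, sens, spec

    def test_point_mass_recovered_exactly(self):
        case = {7: 1.0}
        ctrl = {7: 1.0}
        cutoffs, sens, spec = self.forward(case, ctrl, 0.3)
        masses = recover_distribution_from_sens_spec(sens, spec, 0.3, cutoffs)
        assert masses[7] == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_on_random_distributions(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            prev = rng.uniform(0.05, 0.95)
            case = rng.dirichlet(np.ones(16))
            ctrl = rng.dirichlet(np.ones(16))
            case_d = {s: case[s] for s in range(16)}
            ctrl_d = {s: ctrl[s] for s in range(16)}
            mix = {s: prev * case[s] + (1 - prev) * ctrl[s] for s in range(16)}
            cutoffs, sens, spec = self.forward(case_d, ctrl_d, prev)
            masses = recover_distribution_from_sens_spec(sens, spec, prev, cutoffs)
            for s in range(16):
                assert masses[s] == pytest.approx(mix[s], abs=1e-9)

    def test_zero_prevalence_returns_control_distribution(self):
        ctrl = {0: 0.5, 1: 0.3, 2: 0.2}
        cutoffs, sens, spec = self.forward({2: 1.0}, ctrl, 0.0, max_score=2)
        masses = recover_distribution_from_sens_spec(sens, spec, 0.0, cutoffs)
        for s, p in ctrl.items():
            assert masses[s] == pytest.approx(p, abs=1e-12)

    def test_non_monotone_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            recover_distribution_from_sens_spec([0.5, 0.9], [0.2, 0.4], 0.3, [1, 2])


class TestBootstrapProportion:
    def test_zero_successes_lower_bound_zero(self):
        lo, hi = bootstrap_proportion_ci(0, 50, seed=1)
        assert lo == 0.0

    def test_half_matches_binomial_oracle(self):
        lo, hi = bootstrap_proportion_ci(50, 100, n_boot=20_000, seed=2)
        # exact binomial 2.5%/97.5% quantiles of X/n at p=0.5, n=100: 0.40, 0.60
        assert lo == pytest.approx(0.40, abs=0.02)
        assert hi == pytest.approx(0.60, abs=0.02)

    def test_fixed_seed_reproducible(self):
        assert bootstrap_proportion_ci(20, 80, seed=3) == bootstrap_proportion_ci(20, 80, seed=3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_proportion_ci(0, 0)
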