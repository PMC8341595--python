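"""Binomial-logistic time-mortality model, sampler and lethal times."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from irsefficacy import (
    FitDataset,
    FitError,
    TimeMortalityModel,
    lethal_time_point,
    log_likelihood,
    mortality_curve,
)


def make_dataset(beta1=5.2, beta2=-0.55, months=None, n=180, noise_seed=None):
    """Counts on (or binomially around) the logistic curve."""
    if months is None:
        months = np.arange(1.5, 11.5, 1.0)
    months = np.asarray(months, dtype=float)
    m = mortality_curve(months, beta1, beta2)
    if noise_seed is None:
        dead = np.rint(m * n).astype(int)
    else:
        dead = np.random.default_rng(noise_seed).binomial(n, m)
    return FitDataset(months, dead, np.full_like(months, n, dtype=int))


class TestMortalityCurve:
    def test_logistic_at_zero(self):
        assert mortality_curve(3.0, 0.0, 0.0) == 0.5

    def test_hand_value(self):
        # beta1 + beta2 * t = 2 - 0.5 * 4 = 0
        assert mortality_curve(4.0, 2.0, -0.5) == pytest.approx(0.5)

    def test_limits_saturate(self):
        assert mortality_curve(1e6, 0.0, -0.5) == 0.0
        assert mortality_curve(1e6, 0.0, 0.5) == 1.0

    def test_strictly_decreasing_iff_negative_slope(self):
        t = np.linspace(0, 24, 50)
        decaying = mortality_curve(t, 3.0, -0.4)
        assert np.all(np.diff(decaying) < 0)
        growing = mortality_curve(t, -3.0, 0.4)
        assert np.all(np.diff(growing) > 0)


class TestLogLikelihood:
    def test_matches_scipy_binom_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            data = make_dataset(noise_seed=int(rng.integers(1 << 30)))
            # keep |logit| <~ 10 so the reference pmf is itself accurate
            b1, b2 = rng.uniform(-3, 3), rng.uniform(-0.6, 0.6)
            m = mortality_curve(data.months, b1, b2)
            expected = stats.binom.logpmf(data.n_dead, data.n_total, m).sum()
            assert log_likelihood(data, b1, b2) == pytest.approx(expected, abs=1e-9)

    def test_certain_outcome_has_zero_loglik(self):
        data = FitDataset([2.0], [0], [10])
        # curve forced to ~0 mortality: outcome is certain
        assert log_likelihood(data, -40.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_half_dead_at_half_probability(self):
        data = FitDataset([4.0], [5], [10])
        expected = math.log(math.comb(10, 5)) + 10 * math.log(0.5)
        assert log_likelihood(data, 2.0, -0.5) == pytest.approx(expected, abs=1e-9)

    def test_additive_over_observations(self):
        d1 = FitDataset([2.0], [3], [10])
        d2 = FitDataset([5.0], [7], [30])
        both = FitDataset([2.0, 5.0], [3, 7], [10, 30])
        assert log_likelihood(both, 1.0, -0.3) == pytest.approx(
            log_likelihood(d1, 1.0, -0.3) + log_likelihood(d2, 1.0, -0.3))

    def test_finite_at_extreme_parameters(self):
        data = make_dataset(noise_seed=1)
        assert np.isfinite(log_likelihood(data, 200.0, -40.0))


class TestLethalTimeInversion:
    def test_lt50_is_ratio(self):
        assert lethal_time_point(0.5, 6.0, -0.5) == pytest.approx(12.0)

    def test_hand_values(self):
        assert lethal_time_point(0.9, 2.0, -0.5) == pytest.approx(
            (math.log(9) - 2) / -0.5)
        assert lethal_time_point(0.1, 6.0, -0.5) == pytest.approx(
            (-math.log(9) - 6) / -0.5)

    def test_matches_root_finding(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            b1 = rng.uniform(2, 8)
            b2 = rng.uniform(-1.5, -0.1)
            p = rng.uniform(0.05, 0.95)
            root = optimize.brentq(
                lambda t: mortality_curve(t, b1, b2) - p, -100, 200, xtol=1e-12)
            assert lethal_time_point(p, b1, b2) == pytest.approx(root, abs=1e-9)


class TestMLE:
    def test_recovers_noise_free_parameters(self):
        data = make_dataset(beta1=5.2, beta2=-0.55, n=100000)
        est, _ = TimeMortalityModel(data).fit_mle()
        assert est == pytest.approx([5.2, -0.55], rel=2e-3)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        data = make_dataset(noise_seed=11)
        est, _ = TimeMortalityModel(data).fit_mle()
        exog = sm.add_constant(data.months)
        endog = np.column_stack([data.n_dead, data.n_total - data.n_dead])
        glm = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        assert est == pytest.approx(glm.params, abs=1e-5)

    def test_single_time_point_not_identifiable(self):
        data = FitDataset([2.0, 2.0], [3, 4], [10, 10])
        with pytest.raises(FitError, match="single distinct time point"):
            TimeMortalityModel(data).fit_mle()

    def test_separable_data_flagged_and_diverges(self):
        data = FitDataset([1.0, 2.0, 3.0], [10, 10, 10], [10, 10, 10])
        with pytest.warns(RuntimeWarning, match="separable"):
            model = TimeMortalityModel(data)
        assert model.separable
        with pytest.raises(FitError):
            model.fit_mle()


@pytest.fixture(scope="module")
def fitted():
    """Default-shape fit of one noisy dataset, shared across test classes."""
    data = make_dataset(noise_seed=5)
    return TimeMortalityModel(data).fit(seed=42)


class TestBayesianFit:
    def test_default_run_shape(self, fitted):
        assert fitted.chains == 4
        assert fitted.iterations == 1000
        assert fitted.burn_in == 500
        assert fitted.draws.shape == (4, 500, 2)
        assert fitted.flat_draws.shape == (2000, 2)

    def test_diagnostics_present_and_converged(self, fitted):
        assert set(fitted.diagnostics["rhat"]) == {"beta1", "beta2"}
        assert fitted.converged
        assert max(fitted.diagnostics["rhat"].values()) <= 1.05
        assert min(fitted.diagnostics["ess"].values()) > 50

    def test_seed_reproducibility(self, fitted):
        data = make_dataset(noise_seed=5)
        again = TimeMortalityModel(data).fit(seed=42)
        np.testing.assert_array_equal(again.draws, fitted.draws)
        other = TimeMortalityModel(data).fit(seed=43)
        assert not np.array_equal(other.draws, fitted.draws)

    def test_posterior_brackets_mle(self, fitted):
        est, _ = fitted.model.fit_mle()
        ci = fitted.credible_interval(0.90)
        assert ci[0, 0] <= est[0] <= ci[0, 1]
        assert ci[1, 0] <= est[1] <= ci[1, 1]

    def test_duplicated_data_concentrates_posterior(self, fitted):
        data = fitted.model.data
        doubled = FitDataset(np.tile(data.months, 2), np.tile(data.n_dead, 2),
                             np.tile(data.n_total, 2))
        res2 = TimeMortalityModel(doubled).fit(seed=42)
        w1 = np.diff(fitted.credible_interval(0.90), axis=1)
        w2 = np.diff(res2.credible_interval(0.90), axis=1)
        assert np.all(w2 < w1)
        # same point estimates within Monte-Carlo error
        se = fitted.flat_draws.std(axis=0) / 4
        assert np.all(np.abs(res2.params - fitted.params) < 4 * se + 0.05)

    def test_posterior_predictive_brackets_observations(self, fitted):
        # calibration: observed fractions lie inside the pointwise 99% band
        data = fitted.model.data
        cf = fitted.curve_frame(t_grid=data.months, level=0.99)
        frac = data.n_dead / data.n_total
        n = data.n_total
        band_lo = cf["mortality_low"] - 3 * np.sqrt(frac * (1 - frac) / n + 1e-6)
        band_hi = cf["mortality_high"] + 3 * np.sqrt(frac * (1 - frac) / n + 1e-6)
        assert np.all(frac >= band_lo) and np.all(frac <= band_hi)

    def test_too_few_time_points_rejected(self):
        data = FitDataset([1.0, 2.0], [9, 5], [10, 10])
        with pytest.raises(FitError, match="at least 3"):
            TimeMortalityModel(data).fit(seed=0)

    def test_matches_emcee_posterior(self):
        import emcee

        data = make_dataset(noise_seed=5)
        model = TimeMortalityModel(data)
        res = model.fit(seed=0)
        sampler = emcee.EnsembleSampler(16, 2, model.logposterior)
        start, _ = model.fit_mle()
        rng = np.random.default_rng(0)
        p0 = start + 0.05 * rng.standard_normal((16, 2))
        sampler.run_mcmc(p0, 800, progress=False)
        ref = sampler.get_chain(discard=300, flat=True)
        ref_med = np.median(ref, axis=0)
        ref_sd = ref.std(axis=0)
        assert np.all(np.abs(res.params - ref_med) < 0.35 * ref_sd)
        assert np.all(np.abs(res.flat_draws.std(axis=0) / ref_sd - 1) < 0.25)


class TestLethalTimeEstimates:
    def test_ordering_on_decaying_draws(self, fitted):
        b = fitted.flat_draws
        neg = b[:, 1] < 0
        lt90 = lethal_time_point(0.9, b[neg, 0], b[neg, 1])
        lt50 = lethal_time_point(0.5, b[neg, 0], b[neg, 1])
        lt10 = lethal_time_point(0.1, b[neg, 0], b[neg, 1])
        assert np.all(lt90 <= lt50) and np.all(lt50 <= lt10)

    def test_summary_interval_ordering(self, fitted):
        for p in (0.9, 0.5, 0.1):
            lt = fitted.lethal_time(p)
            assert lt.ci_low <= lt.median_months <= lt.ci_high
            assert lt.defined
            assert lt.excluded_fraction < 0.5

    def test_p_out_of_range_rejected(self, fitted):
        with pytest.raises(ValueError):
            fitted.lethal_time(0.0)
        with pytest.raises(ValueError):
            fitted.lethal_time(1.2)

    def test_unattained_target_flagged(self):
        # curve starts below 90% mortality: LT90 is negative, hence undefined
        data = make_dataset(beta1=2.0, beta2=-0.5, noise_seed=8)
        res = TimeMortalityModel(data).fit(seed=0)
        lt = res.lethal_time(0.9)
        assert not lt.defined

    def test_horizon_bounds_defined_flag(self, fitted):
        lt = fitted.lethal_time(0.5, horizon=1.0)
        assert not lt.defined

    def test_summary_and_to_dict(self, fitted):
        summ = fitted.summary()
        assert list(summ.index) == ["beta1", "beta2"]
        assert (summ["ci_low"] <= summ["median"]).all()
        d = fitted.to_dict()
        assert set(d["lethal_times"]) == {"LT90", "LT50", "LT10"}
        assert d["converged"] is True
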