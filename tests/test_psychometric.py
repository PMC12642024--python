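import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from emobias.errors import DegenerateDataError, InsufficientDataError
from emobias.psychometric import (FitOptions, LevelCounts, PsychometricFit,
                                  aggregate_levels, bootstrap_pse_ci,
                                  deviance_gof, fit_psychometric, grid_search,
                                  pse_of, slope_at_pse)
from emobias.qc import count_valid_trials
from emobias.simulate import (ObserverParams, psychometric_probability,
                              simulate_observer)

from conftest import make_trials


def counts_from_probs(levels, n_per_level, mu, sigma):
    """Noise-free counts: k = round(n * F(x)) -- for recovery oracles."""
    params = ObserverParams(mu=mu, sigma=sigma)
    k = [int(round(n_per_level * psychometric_probability(x, params)))
         for x in levels]
    return LevelCounts(levels=tuple(float(x) for x in levels),
                       n_valid=tuple([n_per_level] * len(levels)),
                       k_happy=tuple(k))


def make_fit(mu, sigma, guess=0.0, lapse=0.0):
    return PsychometricFit(mu=mu, sigma=sigma, guess=guess, lapse=lapse,
                           loglik=0.0, deviance=0.0, converged=True,
                           n_valid_trials=64,
                           pse=float("nan"), slope_at_pse=float("nan"))


class TestAggregateLevels:
    def test_counts_at_one_level(self):
        trials = make_trials("p", [(0, "happy", 4), (0, "angry", 4)])
        counts = aggregate_levels(trials)
        i = counts.levels.index(0.0)
        assert counts.n_valid[i] == 8 and counts.k_happy[i] == 4

    def test_omitted_dropped_from_numerator_and_denominator(self):
        trials = make_trials("p", [(10, "happy", 3), (10, "omitted", 5)])
        counts = aggregate_levels(trials)
        i = counts.levels.index(10.0)
        assert counts.n_valid[i] == 3 and counts.k_happy[i] == 3

    def test_design_levels_present_with_zero_counts(self):
        trials = make_trials("p", [(0, "happy", 8)])
        counts = aggregate_levels(trials)
        assert len(counts.levels) == 9
        assert sum(counts.n_valid) == 8

    def test_cross_module_total_matches_qc_count(self,
                                                 synthetic_observer_trials):
        counts = aggregate_levels(synthetic_observer_trials)
        assert counts.n_total == count_valid_trials(synthetic_observer_trials)

    def test_zero_valid_trials_error(self):
        trials = make_trials("p", [(0, "omitted", 8)])
        with pytest.raises(DegenerateDataError):
            aggregate_levels(trials)


class TestFitPsychometric:
    def test_noise_free_recovery_vs_grid_oracle(self):
        # Oracle: exhaustive grid search of the same likelihood at 0.1
        # resolution around the truth.
        levels = [-80, -40, -20, -10, 0, 10, 20, 40, 80]
        counts = counts_from_probs(levels, 1000, mu=0.0, sigma=10.0)
        fit = fit_psychometric(counts)
        assert fit.converged
        assert -0.5 <= fit.mu <= 0.5
        assert 9.5 <= fit.sigma <= 10.5
        mu_grid = np.arange(-2, 2.001, 0.1)
        sigma_grid = np.arange(8.0, 12.001, 0.1)
        mu_g, sigma_g, ll_g = grid_search(counts, mu_grid, sigma_grid)
        assert fit.loglik >= ll_g - 1e-9
        assert abs(fit.mu - mu_g) <= 0.1 and abs(fit.sigma - sigma_g) <= 0.1

    def test_mirror_symmetry(self):
        levels = [-40.0, -10.0, 0.0, 10.0, 40.0]
        counts = LevelCounts(levels=tuple(levels),
                             n_valid=(8, 8, 8, 8, 8),
                             k_happy=(1, 3, 5, 6, 8))
        mirrored = LevelCounts(levels=tuple(levels),
                               n_valid=(8, 8, 8, 8, 8),
                               k_happy=tuple(8 - k for k in (8, 6, 5, 3, 1)))
        fit = fit_psychometric(counts)
        fit_m = fit_psychometric(mirrored)
        assert fit_m.mu == pytest.approx(-fit.mu, abs=1e-3)
        assert fit_m.sigma == pytest.approx(fit.sigma, rel=1e-3)

    def test_degenerate_all_happy_flagged_not_raised(self):
        counts = LevelCounts(levels=(-80.0, 0.0, 80.0),
                             n_valid=(8, 8, 8), k_happy=(8, 8, 8))
        fit = fit_psychometric(counts)
        assert not fit.converged

    def test_insufficient_levels(self):
        counts = LevelCounts(levels=(0.0,), n_valid=(8,), k_happy=(4,))
        with pytest.raises(InsufficientDataError):
            fit_psychometric(counts)

    def test_shift_equivariance(self):
        levels = [-40, -10, 0, 10, 40]
        counts = counts_from_probs(levels, 200, mu=2.0, sigma=12.0)
        shifted = LevelCounts(
            levels=tuple(x + 7.0 for x in counts.levels),
            n_valid=counts.n_valid, k_happy=counts.k_happy)
        fit = fit_psychometric(counts)
        fit_s = fit_psychometric(shifted)
        assert fit_s.mu == pytest.approx(fit.mu + 7.0, abs=1e-2)
        assert fit_s.sigma == pytest.approx(fit.sigma, rel=1e-3)

    def test_scale_equivariance(self):
        levels = [-40, -10, 0, 10, 40]
        counts = counts_from_probs(levels, 200, mu=2.0, sigma=12.0)
        scaled = LevelCounts(
            levels=tuple(2.0 * x for x in counts.levels),
            n_valid=counts.n_valid, k_happy=counts.k_happy)
        fit = fit_psychometric(counts)
        fit_s = fit_psychometric(scaled)
        assert fit_s.mu == pytest.approx(2.0 * fit.mu, abs=2e-2)
        assert fit_s.sigma == pytest.approx(2.0 * fit.sigma, rel=1e-2)

    def test_lapse_variant_bounds(self):
        params = ObserverParams(mu=0.0, sigma=10.0, lapse=0.04, guess=0.0)
        trials = simulate_observer(params, seed=21)
        counts = aggregate_levels(trials)
        fit = fit_psychometric(counts, FitOptions(fit_lapse=True))
        assert 0.0 <= fit.lapse <= 0.05

    def test_refined_loglik_beats_internal_grid(self, rng):
        # Oracle equivalence on simulated observers.
        for _ in range(20):
            params = ObserverParams(mu=float(rng.uniform(-20, 20)),
                                    sigma=float(rng.uniform(5, 20)))
            counts = aggregate_levels(
                simulate_observer(params, seed=rng))
            fit = fit_psychometric(counts)
            lo = min(counts.levels)
            hi = max(counts.levels)
            mu_g, sg, ll = grid_search(counts, np.linspace(lo, hi, 21),
                                       np.geomspace(0.1, 100.0, 25))
            assert fit.loglik >= ll - 1e-9


class TestPseAndSlope:
    def test_pse_parameter_echo(self):
        # With symmetric asymptotes the PSE is mu itself.
        assert pse_of(make_fit(21.95, 8.0)) == pytest.approx(21.95)
        assert pse_of(make_fit(8.0, 5.0)) == pytest.approx(8.0)
        assert pse_of(make_fit(0.0, 33.0, guess=0.1, lapse=0.1)) == \
            pytest.approx(0.0)

    def test_pse_with_guess_bisection_oracle(self):
        fit = make_fit(0.0, 10.0, guess=0.1, lapse=0.0)
        # bisection on F(x) = 0.5
        lo, hi = -100.0, 100.0
        for _ in range(200):
            mid = (lo + hi) / 2
            f = 0.1 + 0.9 * norm.cdf(mid / 10.0)
            lo, hi = (mid, hi) if f < 0.5 else (lo, mid)
        assert pse_of(fit) == pytest.approx((lo + hi) / 2, abs=1e-9)
        assert pse_of(fit) == pytest.approx(10 * norm.ppf(4 / 9), abs=1e-9)

    def test_slope_closed_forms(self):
        assert slope_at_pse(make_fit(0.0, 1.0)) == pytest.approx(
            1 / math.sqrt(2 * math.pi), abs=1e-9)
        assert slope_at_pse(make_fit(0.0, 0.5249)) == pytest.approx(
            0.760, abs=5e-4)

    def test_slope_matches_central_difference(self, rng):
        for _ in range(50):
            fit = make_fit(float(rng.uniform(-30, 30)),
                           float(rng.uniform(0.5, 50)),
                           guess=float(rng.uniform(0, 0.2)),
                           lapse=float(rng.uniform(0, 0.2)))
            pse = pse_of(fit)
            h = 1e-5 * fit.sigma

            def f(x):
                return fit.guess + (1 - fit.guess - fit.lapse) * \
                    norm.cdf((x - fit.mu) / fit.sigma)

            numeric = (f(pse + h) - f(pse - h)) / (2 * h)
            assert slope_at_pse(fit) == pytest.approx(numeric, abs=1e-6)

    def test_fit_row_carries_consistent_pse_slope(self):
        counts = counts_from_probs([-40, -10, 0, 10, 40], 100, 3.0, 9.0)
        fit = fit_psychometric(counts)
        assert fit.pse == pytest.approx(pse_of(fit))
        assert fit.slope_at_pse == pytest.approx(slope_at_pse(fit))
        assert fit.slope_at_pse == pytest.approx(
            (1 - fit.guess - fit.lapse) / (fit.sigma * math.sqrt(2 * math.pi)))


class TestDeviance:
    def test_saturated_agreement_is_zero(self):
        # empirical proportions are 0.5 at every level and F ~ 0.5
        # everywhere (sigma -> infinity), so the deviance vanishes
        counts = LevelCounts(levels=(-10.0, 0.0, 10.0),
                             n_valid=(2, 2, 2), k_happy=(1, 1, 1))
        fit_flat = make_fit(0.0, 1e9)
        deviance, _ = deviance_gof(fit_flat, counts)
        assert deviance == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_three_level_toy(self):
        counts = LevelCounts(levels=(-10.0, 0.0, 10.0),
                             n_valid=(8, 8, 8), k_happy=(2, 4, 7))
        fit = make_fit(0.0, 10.0)
        # independent recomputation from the formula
        expected = 0.0
        for x, n, k in zip(counts.levels, counts.n_valid, counts.k_happy):
            f = norm.cdf(x / 10.0)
            if k > 0:
                expected += 2 * k * math.log(k / (n * f))
            if n - k > 0:
                expected += 2 * (n - k) * math.log((n - k) / (n * (1 - f)))
        deviance, residuals = deviance_gof(fit, counts)
        assert deviance == pytest.approx(expected, abs=1e-10)
        assert residuals.shape == (3,)
        # signed residuals follow the direction of misfit
        assert residuals[2] > 0   # 7/8 > Phi(1)

    def test_deviance_non_negative_sweep(self, rng):
        # any-parameter deviance is >= 0: the saturated model dominates
        for _ in range(1000):
            n = rng.integers(1, 30, size=5)
            k = rng.integers(0, n + 1)
            counts = LevelCounts(levels=(-40.0, -10.0, 0.0, 10.0, 40.0),
                                 n_valid=tuple(int(v) for v in n),
                                 k_happy=tuple(int(v) for v in k))
            fit = make_fit(float(rng.uniform(-50, 50)),
                           float(rng.uniform(0.1, 60)))
            deviance, _ = deviance_gof(fit, counts)
            assert deviance >= 0.0

    def test_fitted_deviance_stored(self, synthetic_observer_trials):
        counts = aggregate_levels(synthetic_observer_trials)
        fit = fit_psychometric(counts)
        deviance, _ = deviance_gof(fit, counts)
        assert fit.deviance == pytest.approx(deviance)
        assert fit.deviance >= 0


class TestParameterRecoveryProperty:
    def test_recovery_sweep_small(self, rng):
        # small version of the acceptance sweep: unbiased mu recovery
        errors = []
        for _ in range(60):
            mu = float(rng.uniform(-20, 20))
            sigma = float(rng.uniform(5, 20))
            trials = simulate_observer(ObserverParams(mu=mu, sigma=sigma),
                                       seed=rng)
            fit = fit_psychometric(aggregate_levels(trials))
            errors.append(fit.mu - mu)
        assert np.median(np.abs(errors)) <= 3.0


class TestBootstrap:
    def test_bootstrap_ci_brackets_estimate(self):
        counts = counts_from_probs([-80, -40, -20, -10, 0, 10, 20, 40, 80],
                                   8, mu=5.0, sigma=12.0)
        fit = fit_psychometric(counts)
        ci = bootstrap_pse_ci(counts, fit, n_boot=50, seed=3)
        lo, hi = ci["pse_ci"]
        assert lo <= fit.pse <= hi
        assert ci["n_boot_used"] > 0
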