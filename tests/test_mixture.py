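"""Mixture MLE, Monte Carlo estimator, kappa conversions, linear slopes."""

import numpy as np
import pytest

from crowdreport import (
    KAPPA_FIT_MIN, KAPPA_MAX, KAPPA_MIN,
    circ_sd_to_kappa, fit_averaging_mixture, fit_standard_mixture,
    kappa_to_circ_sd, kuiper_two_sample, linear_slope,
    monte_carlo_proportions, simulate_validation_dataset, wrap_deg,
)
from crowdreport.mixture import _vm_pdf_deg


class TestKappaConversion:
    def test_limits(self):
        assert kappa_to_circ_sd(KAPPA_MAX) < 3.0       # high concentration -> tiny SD
        assert kappa_to_circ_sd(0.0) == np.inf         # R = 0 -> unbounded SD

    def test_round_trip(self):
        assert kappa_to_circ_sd(circ_sd_to_kappa(kappa_to_circ_sd(2.0))) == \
            pytest.approx(kappa_to_circ_sd(2.0), abs=1e-6)
        for kappa in np.geomspace(0.1, 100, 15):
            assert circ_sd_to_kappa(kappa_to_circ_sd(kappa)) == \
                pytest.approx(kappa, rel=1e-6)

    def test_strictly_decreasing(self):
        grid = np.geomspace(KAPPA_MIN, KAPPA_MAX, 50)
        sds = kappa_to_circ_sd(grid)
        assert np.all(np.diff(sds) < 0)

    def test_out_of_range_sd_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert circ_sd_to_kappa(0.5) == KAPPA_MAX
        with pytest.warns(UserWarning):
            assert circ_sd_to_kappa(1e5) == KAPPA_MIN

    def test_vm_density_integrates_to_one(self):
        x = np.linspace(-180, 180, 100_001)
        for kappa in (0.5, 5.0, 50.0):
            assert np.trapezoid(_vm_pdf_deg(x, kappa), x) == pytest.approx(1.0, abs=1e-6)


class TestStandardMixture:
    def test_recovery_separated_components(self):
        """Well-separated design: proportions and kappa recovered closely."""
        df = simulate_validation_dataset(0.7, 0.3, 15.0, n_trials=10_000,
                                         seed=21, fixed_delta_deg=90.0)
        fit = fit_standard_mixture(df["error_deg"], df["delta1_deg"],
                                   n_restarts=10, seed=0)
        assert fit.p_target == pytest.approx(0.7, abs=0.02)
        assert fit.p_substitution == pytest.approx(0.3, abs=0.02)
        assert fit.p_guess == pytest.approx(0.0, abs=0.02)
        kappa_true = circ_sd_to_kappa(15.0)
        assert fit.kappa == pytest.approx(kappa_true, rel=0.05)
        assert fit.converged

    def test_uniform_reports_are_all_guess(self, rng):
        errors = rng.uniform(-180, 180, size=2000)
        deltas = rng.normal(0, 22.5, size=2000)
        fit = fit_standard_mixture(errors, deltas, n_restarts=10, seed=1)
        assert fit.p_guess > 0.95

    def test_simplex_and_determinism(self):
        df = simulate_validation_dataset(0.5, 0.5, 10.0, n_trials=200, seed=22)
        a = fit_standard_mixture(df["error_deg"], df["delta1_deg"], seed=5)
        b = fit_standard_mixture(df["error_deg"], df["delta1_deg"], seed=5)
        assert a.p_target + a.p_substitution + a.p_guess == pytest.approx(1.0, abs=1e-6)
        assert KAPPA_FIT_MIN <= a.kappa <= KAPPA_MAX
        assert (a.p_target, a.kappa, a.log_likelihood) == \
            (b.p_target, b.kappa, b.log_likelihood)

    def test_mle_dominates_generating_parameters(self):
        """Fitted log-likelihood is at least the truth's log-likelihood."""
        for seed in (31, 32, 33):
            df = simulate_validation_dataset(0.6, 0.4, 12.0, n_trials=300, seed=seed)
            e, d = df["error_deg"].to_numpy(), df["delta1_deg"].to_numpy()
            fit = fit_standard_mixture(e, d, n_restarts=10, seed=0)
            kappa = circ_sd_to_kappa(12.0)
            ll_truth = np.sum(np.log(0.6 * _vm_pdf_deg(e, kappa)
                                     + 0.4 * _vm_pdf_deg(wrap_deg(e - d), kappa)))
            assert fit.log_likelihood >= ll_truth - 1e-6


class TestAveragingMixture:
    def test_degenerate_averaging_data(self, rng):
        """Errors exactly at half the offset: the averaging component with
        w = 0.5 explains everything."""
        deltas = rng.normal(0, 22.5, size=500)
        errors = 0.5 * deltas
        fit = fit_averaging_mixture(errors, deltas, n_restarts=20, seed=2)
        assert fit.p_average > 0.9
        assert fit.average_weight == pytest.approx(0.5, abs=0.02)

    def test_unreliable_on_two_component_data(self):
        """On 100-trial target+substitution data the extra parameters are
        not identified and the instability flag fires."""
        df = simulate_validation_dataset(0.5, 0.5, 10.0, n_trials=100, seed=23)
        fit = fit_averaging_mixture(df["error_deg"], df["delta1_deg"],
                                    n_restarts=20, seed=3)
        assert fit.unstable

    def test_determinism(self):
        df = simulate_validation_dataset(0.5, 0.5, 10.0, n_trials=100, seed=24)
        a = fit_averaging_mixture(df["error_deg"], df["delta1_deg"], n_restarts=10, seed=4)
        b = fit_averaging_mixture(df["error_deg"], df["delta1_deg"], n_restarts=10, seed=4)
        assert a.log_likelihood == b.log_likelihood
        assert a.p_average == b.p_average
        assert a.p_target + a.p_substitution + a.p_average + a.p_guess == \
            pytest.approx(1.0, abs=1e-6)


class TestMonteCarlo:
    def test_pure_target(self):
        df = simulate_validation_dataset(1.0, 0.0, 5.0, n_trials=500, seed=25)
        fit = monte_carlo_proportions(df["error_deg"], df["delta1_deg"],
                                      noise_sd_deg=5.0, seed=0)
        assert fit.p_target == pytest.approx(1.0, abs=0.05)

    def test_within_one_grid_step_of_truth(self):
        df = simulate_validation_dataset(0.5, 0.5, 10.0, n_trials=1000,
                                         seed=26, fixed_delta_deg=90.0)
        fit = monte_carlo_proportions(df["error_deg"], df["delta1_deg"],
                                      noise_sd_deg=10.0, seed=1)
        assert fit.p_target == pytest.approx(0.5, abs=0.05 + 1e-9)

    def test_zero_substitution_at_large_separation_regime(self):
        """An observer unaffected by the flanker yields an estimated
        substitution proportion of 0 under the two-component analysis."""
        df = simulate_validation_dataset(1.0, 0.0, 10.0, n_trials=1000, seed=27)
        fit = monte_carlo_proportions(df["error_deg"], df["delta1_deg"],
                                      noise_sd_deg=10.0, seed=2)
        assert fit.p_substitution == 0.0

    def test_kuiper_rotation_invariance(self, rng):
        x = rng.uniform(0, 360, size=400)
        y = rng.uniform(0, 360, size=300)
        v0 = kuiper_two_sample(x, y)
        v1 = kuiper_two_sample((x + 117.0) % 360, (y + 117.0) % 360)
        assert v1 == pytest.approx(v0, abs=0.02)
        assert kuiper_two_sample(x, x) <= 2.0 / 400 + 1e-12


class TestLinearSlope:
    def test_pure_target_slope_zero(self, rng):
        deltas = rng.normal(0, 22.5, size=100)
        fit = linear_slope(np.zeros(100), deltas)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_pure_substitution_slope_one(self, rng):
        deltas = rng.normal(0, 22.5, size=100)
        fit = linear_slope(deltas, deltas)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_spurious_averaging_slope(self):
        """A 50/50 target+substitution mix yields slope ~0.5 with zero
        generative averaging — the documented misinterpretation hazard."""
        df = simulate_validation_dataset(0.5, 0.5, 10.0, n_trials=10_000, seed=28)
        fit = linear_slope(df["error_deg"], df["delta1_deg"])
        assert fit.slope == pytest.approx(0.5, abs=0.05)

    def test_degenerate_inputs(self, rng):
        with pytest.raises(ValueError):
            linear_slope([1.0, 2.0], [3.0, 4.0])           # n < 3
        with pytest.raises(ValueError):
            linear_slope([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])  # no delta variance
        with pytest.warns(UserWarning):
            linear_slope(rng.normal(size=10), np.linspace(-120, 120, 10))
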