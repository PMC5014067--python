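"""Closed-form gamma solutions against the independent ODE oracle."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from gammachain import (
    CascadeSpec,
    GammaModule,
    InputSignal,
    delta_solution,
    exponential_solution,
    filter_summary,
    gaussian_solution,
    integrate_linear,
    periodic_asymptotic,
    periodic_solution,
    step_solution,
)


def _oracle(spec, signal, t):
    return integrate_linear(spec, signal, t, tol=1e-11).values[:, -1]


class TestStepSolution:
    def test_single_stage_formula(self):
        m = GammaModule(2.0, 2.0, 1.0)
        t = np.linspace(0, 5, 50)
        assert np.allclose(step_solution(m, t), 1.0 - np.exp(-2 * t), atol=1e-12)

    def test_monotone_and_bounded(self, fig_module, grid):
        out = step_solution(fig_module, grid)
        assert np.all(np.diff(out) >= -1e-12)
        assert np.all(out <= fig_module.amplification + 1e-12)
        assert step_solution(fig_module, 1e4) == pytest.approx(768 / 243, rel=1e-9)

    def test_matches_ode_oracle(self, fig_cascade, fig_module, grid, step):
        assert np.max(np.abs(step_solution(fig_module, grid) - _oracle(fig_cascade, step, grid))) < 1e-6

    def test_negative_time_rejected(self, fig_module):
        with pytest.raises(ValueError):
            step_solution(fig_module, -0.5)


class TestExponentialSolution:
    def test_single_stage_confluent(self):
        m = GammaModule(2.0, 3.0, 1.0)
        t = np.linspace(0, 6, 60)
        assert np.allclose(exponential_solution(m, 3.0, t), 2.0 * t * np.exp(-3 * t), atol=1e-12)

    def test_slow_decay_limit_is_step(self, fig_module, grid):
        slow = exponential_solution(fig_module, 1e-8, grid)
        assert np.max(np.abs(slow - step_solution(fig_module, grid))) < 1e-6

    @pytest.mark.parametrize("lam", [1.0, 3.0, 7.0])
    def test_matches_ode_oracle(self, fig_cascade, fig_module, grid, lam):
        # lam < beta, lam = beta (confluent) and lam > beta (negative gamma argument)
        num = _oracle(fig_cascade, InputSignal.exponential(lam), grid)
        ana = exponential_solution(fig_module, lam, grid)
        assert np.max(np.abs(num - ana)) < 1e-6

    def test_continuity_across_confluence(self, fig_module, grid):
        lo = exponential_solution(fig_module, 3.0 * (1 - 1e-6), grid)
        mid = exponential_solution(fig_module, 3.0, grid)
        hi = exponential_solution(fig_module, 3.0 * (1 + 1e-6), grid)
        scale = np.max(np.abs(mid))
        assert np.max(np.abs(lo - mid)) < 1e-5 * scale
        assert np.max(np.abs(hi - mid)) < 1e-5 * scale

    def test_decays_to_zero(self, fig_module):
        assert exponential_solution(fig_module, 1.0, 200.0) < 1e-12


class TestPeriodicSolution:
    def test_filter_summary_at_matched_frequency(self):
        m = GammaModule(1.0, 2.0, 3.0)
        s = filter_summary(m, 2.0)
        assert s.rho == pytest.approx(1 / math.sqrt(2))
        assert s.theta == pytest.approx(math.pi / 4)
        assert s.rho == pytest.approx(math.cos(s.theta))

    @pytest.mark.parametrize("waveform", ["one_minus_cos", "one_plus_sin"])
    def test_matches_ode_oracle(self, fig_cascade, fig_module, grid, waveform):
        sig = InputSignal.periodic(2.0, waveform=waveform)
        num = _oracle(fig_cascade, sig, grid)
        ana = periodic_solution(fig_module, 2.0, grid, waveform=waveform)
        assert np.max(np.abs(num - ana)) < 1e-6

    def test_asymptotic_band(self, fig_module):
        t = np.linspace(50.0, 80.0, 500)
        out = periodic_asymptotic(fig_module, 1.0, t)
        amp = fig_module.amplification
        assert np.all(out >= -1e-9) and np.all(out <= 2 * amp + 1e-9)

    def test_asymptotic_matches_exact_after_transient(self, fig_module):
        t = np.linspace(15.0, 25.0, 200)
        exact = periodic_solution(fig_module, 1.5, t)
        asym = periodic_asymptotic(fig_module, 1.5, t)
        assert np.max(np.abs(exact - asym)) < 1e-6 * fig_module.amplification

    def test_high_frequency_filters_to_step(self, fig_module):
        t = np.linspace(0.0, 10.0, 300)
        p = periodic_solution(fig_module, 3000.0, t)
        s = step_solution(fig_module, t)
        assert np.max(np.abs(p - s)) / fig_module.amplification < 0.002


class TestDeltaAndGaussian:
    def test_single_stage_delta(self):
        m = GammaModule(2.0, 1.5, 1.0)
        t = np.linspace(0, 5, 50)
        assert np.allclose(delta_solution(m, 0.7, t), 0.7 * 2.0 * np.exp(-1.5 * t), atol=1e-12)

    def test_delta_peak_location(self):
        m = GammaModule(1.0, 2.0, 4.0)
        t = np.linspace(0.0, 6.0, 6001)
        out = delta_solution(m, 1.0, t)
        assert t[np.argmax(out)] == pytest.approx((4.0 - 1.0) / 2.0, abs=2e-3)

    def test_delta_mass(self, fig_module):
        val, _ = quad(lambda s: delta_solution(fig_module, 1.0, s), 0, 60, limit=200)
        assert val == pytest.approx(fig_module.amplification, rel=1e-8)

    def test_delta_matches_ode_oracle(self, fig_cascade, fig_module, grid):
        num = _oracle(fig_cascade, InputSignal.delta(1.0), grid)
        assert np.max(np.abs(num - delta_solution(fig_module, 1.0, grid))) < 1e-6

    def test_gaussian_matches_ode_oracle(self, fig_cascade, fig_module, grid):
        sig = InputSignal.gaussian(2.0, 0.5)
        num = _oracle(fig_cascade, sig, grid)
        ana = gaussian_solution(fig_module, 2.0, 0.5, grid)
        assert np.max(np.abs(num - ana)) < 1e-6

    def test_narrow_gaussian_approaches_shifted_impulse(self, fig_module):
        zeta, mu = 1e-3, 2.0
        t = np.linspace(0.0, 10.0, 101)
        g = gaussian_solution(fig_module, mu, zeta, t)
        shifted = math.sqrt(2 * math.pi) * zeta * delta_solution(fig_module, 1.0, np.maximum(t - mu, 0.0))
        shifted[t < mu] = 0.0
        peak = np.max(g)
        assert np.max(np.abs(g - shifted)) <= 1e-3 * peak

    def test_parameter_validation(self, fig_module):
        with pytest.raises(ValueError):
            gaussian_solution(fig_module, 2.0, -0.1, 1.0)
        with pytest.raises(ValueError):
            delta_solution(fig_module, 0.0, 1.0)
        with pytest.raises(ValueError):
            exponential_solution(fig_module, -1.0, 1.0)
        with pytest.raises(ValueError):
            periodic_solution(fig_module, 0.0, 1.0)


class TestRealValuedLength:
    def test_smooth_in_length(self):
        # the solution is defined for non-integer lengths and varies
        # continuously in n_real
        t = np.linspace(0.0, 10.0, 50)
        base = step_solution(GammaModule(2.0, 2.0, 4.5), t)
        near = step_solution(GammaModule(2.0, 2.0, 4.5 + 1e-7), t)
        assert np.max(np.abs(base - near)) < 1e-5

    @pytest.mark.parametrize("alpha,beta", [(1.0, 1.0), (2.0, 3.0)])
    def test_fractional_length_between_integer_curves(self, alpha, beta):
        # for alpha_gm <= beta both the prefactor and P(n, beta t) are
        # non-increasing in n, so the half-integer curve interpolates
        t = np.linspace(0.01, 12.0, 200)
        f4 = step_solution(GammaModule(alpha, beta, 4.0), t)
        f45 = step_solution(GammaModule(alpha, beta, 4.5), t)
        f5 = step_solution(GammaModule(alpha, beta, 5.0), t)
        assert np.all(f45 <= np.maximum(f4, f5) + 1e-12)
        assert np.all(f45 >= np.minimum(f4, f5) - 1e-12)

    def test_fractional_length_against_ode_bracketing(self):
        # n=4.5 module lies between the n=4 and n=5 cascades built from the
        # same alpha_gm=beta rates, checked against the ODE oracle curves
        t = np.linspace(0.01, 10.0, 100)
        mid = step_solution(GammaModule(1.0, 1.0, 4.5), t)
        lo = _oracle(CascadeSpec(5, (1,) * 5, (1,) * 5), InputSignal.step(), t)
        hi = _oracle(CascadeSpec(4, (1,) * 4, (1,) * 4), InputSignal.step(), t)
        assert np.all(mid >= lo - 1e-8)
        assert np.all(mid <= hi + 1e-8)
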