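"""Numerical solution paths: ODE integration, matrix exponential,
hypoexponential kernel, convolution, and the delayed two-node system."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gammachain import (
    CascadeSpec,
    DDESpec,
    InputSignal,
    NonlinearCascadeSpec,
    asymptotic_gain,
    convolve_response,
    evaluate_kernel,
    hypoexponential_kernel,
    integrate_dde,
    integrate_linear,
    integrate_nonlinear,
    step_response_matrix_form,
)


class TestIntegrateLinear:
    def test_scalar_step_is_exponential_saturation(self, grid):
        spec = CascadeSpec(1, (1.0,), (1.0,))
        out = integrate_linear(spec, InputSignal.step(), grid, tol=1e-11).values[:, -1]
        assert np.max(np.abs(out - (1.0 - np.exp(-grid)))) < 1e-8

    def test_reference_cascade_reaches_asymptotic_gain(self, fig_cascade, step):
        t = np.linspace(0.0, 30.0, 61)
        out = integrate_linear(fig_cascade, step, t, tol=1e-11).values[:, -1]
        assert out[-1] == pytest.approx(768 / 243, abs=1e-6)

    def test_nonzero_x0_zero_input_is_homogeneous_decay(self):
        from scipy.linalg import expm

        from gammachain import build_rate_matrix

        spec = CascadeSpec(3, (1, 2, 3), (1.0, 0.5, 2.0))
        x0 = np.array([1.0, 0.5, 0.2])
        t = np.linspace(0.0, 5.0, 11)
        out = integrate_linear(spec, InputSignal.custom(lambda s: np.zeros_like(s)), t,
                               x0=x0, tol=1e-11).values
        A = build_rate_matrix(spec)
        want = np.array([expm(A * ti) @ x0 for ti in t])
        assert np.max(np.abs(out - want)) < 1e-8


class TestIntegrateNonlinear:
    def test_trajectories_bounded_by_totals(self):
        base = CascadeSpec(3, (0.5, 0.5, 0.5), (0.2, 0.2, 0.2))
        nspec = NonlinearCascadeSpec(base, totals=(1.0, 1.0, 1.0), input_scale=5.0)
        tc, sat = integrate_nonlinear(nspec, InputSignal.step(), np.linspace(0, 20, 41))
        assert np.all(tc.values <= 1.0 + 1e-9)
        assert 0 < sat <= 1.0

    def test_fully_active_start_decays_monotonically(self):
        base = CascadeSpec(2, (1.0, 1.0), (1.0, 1.0))
        nspec = NonlinearCascadeSpec(base, totals=(2.0, 2.0))
        t = np.linspace(0, 15, 61)
        zero = InputSignal.custom(lambda s: np.zeros_like(s))
        tc, _ = integrate_nonlinear(nspec, zero, t, x0=[2.0, 2.0])
        assert np.all(np.diff(tc.values[:, -1]) <= 1e-10)
        assert tc.values[-1, -1] < 1e-4

    def test_weak_activation_limit_approaches_linear(self, fig_cascade, step, grid):
        lin = integrate_linear(fig_cascade, step, grid, tol=1e-10).values[:, -1]
        T = 1e6
        raw = CascadeSpec(5, np.asarray(fig_cascade.activation_rates) / T,
                          fig_cascade.deactivation_rates)
        tc, sat = integrate_nonlinear(NonlinearCascadeSpec(raw, (T,) * 5), step, grid, tol=1e-10)
        assert sat < 1e-4
        assert np.max(np.abs(tc.values[:, -1] - lin)) < 1e-4


class TestStepResponseMatrixForm:
    def test_zero_at_time_zero(self, fig_cascade):
        assert np.allclose(step_response_matrix_form(fig_cascade, 0.0), 0.0)

    def test_large_time_gives_partial_products(self):
        spec = CascadeSpec(3, (2, 3, 4), (1.0, 2.0, 0.5))
        x = step_response_matrix_form(spec, 200.0)
        want = np.cumprod(np.asarray(spec.activation_rates) / np.asarray(spec.deactivation_rates))
        assert x == pytest.approx(want, rel=1e-9)

    def test_agrees_with_ode_path(self, fig_cascade, step, grid):
        mf = step_response_matrix_form(fig_cascade, grid)
        ode = integrate_linear(fig_cascade, step, grid, tol=1e-12).values
        assert np.max(np.abs(mf - ode)) < 1e-8


class TestHypoexponentialKernel:
    def test_two_distinct_rates_textbook_form(self):
        k = hypoexponential_kernel(CascadeSpec(2, (1, 1), (1.0, 2.0)))
        t = np.linspace(0, 8, 100)
        assert np.max(np.abs(evaluate_kernel(k, t) - (np.exp(-t) - np.exp(-2 * t)))) < 1e-12

    def test_equal_rates_confluent_gamma_density(self, fig_cascade):
        k = hypoexponential_kernel(fig_cascade)
        assert len(k.groups) == 1 and k.groups[0][1] == 5
        t = np.linspace(0, 10, 100)
        want = 768.0 * t**4 * np.exp(-3 * t) / math.gamma(5)
        assert np.max(np.abs(evaluate_kernel(k, t) - want)) < 1e-9

    def test_near_equal_rates_cluster(self):
        spec = CascadeSpec(3, (1, 1, 1), (2.0, 2.0 * (1 + 1e-12), 5.0))
        k = hypoexponential_kernel(spec)
        assert sorted(m for _, m in k.groups) == [1, 2]

    def test_kernel_zero_at_origin_for_chains(self):
        for spec in (CascadeSpec(2, (1, 1), (1, 3)), CascadeSpec(4, (1, 2, 1, 2), (1, 2, 3, 4))):
            assert abs(evaluate_kernel(hypoexponential_kernel(spec), 0.0)) < 1e-12

    @given(st.lists(st.floats(0.2, 5.0), min_size=1, max_size=6))
    @settings(deadline=None, max_examples=25)
    def test_mass_conservation(self, beta):
        # well-separated rates: nudge apart to keep partial fractions stable
        beta = sorted(beta)
        beta = [b + 0.11 * i for i, b in enumerate(beta)]
        n = len(beta)
        spec = CascadeSpec(n, (1.5,) * n, beta)
        k = hypoexponential_kernel(spec)
        assert k.mass() == pytest.approx(asymptotic_gain(spec), rel=1e-7)


class TestConvolveResponse:
    def test_delta_sifting(self, fig_cascade, grid):
        k = hypoexponential_kernel(fig_cascade)
        out = convolve_response(k, InputSignal.delta(2.0), grid).output
        assert np.max(np.abs(out - 2.0 * evaluate_kernel(k, grid))) < 1e-12

    def test_step_matches_matrix_form(self, fig_cascade, step):
        t = np.linspace(0.0, 10.0, 41)
        k = hypoexponential_kernel(fig_cascade)
        conv = convolve_response(k, step, t).output
        mf = step_response_matrix_form(fig_cascade, t)[:, -1]
        assert np.max(np.abs(conv - mf)) < 1e-6

    def test_superposition_of_two_steps(self):
        spec = CascadeSpec(2, (1.0, 2.0), (1.0, 0.7))
        k = hypoexponential_kernel(spec)
        t = np.linspace(0.0, 8.0, 33)
        two_steps = InputSignal.custom(lambda s: 1.0 * (s >= 0) + 1.0 * (s >= 2.0))
        combined = convolve_response(k, two_steps, t).output
        s1 = convolve_response(k, InputSignal.step(), t).output
        shifted = np.interp(t - 2.0, t, s1, left=0.0)
        assert np.max(np.abs(combined - (s1 + shifted))) < 1e-5


def _rk4_dde(spec: DDESpec, t_end: float, h: float):
    """Independent fixed-stride RK4 integrator with linear history lookup."""
    n_steps = int(round(t_end / h))
    ts = np.arange(n_steps + 1) * h
    x1 = np.empty(n_steps + 1)
    x2 = np.empty(n_steps + 1)
    x1[0], x2[0] = spec.history, 0.0

    def x1_delayed(t):
        if t - spec.tau <= 0:
            return spec.history
        idx = (t - spec.tau) / h
        i = int(idx)
        w = idx - i
        i = min(i, n_steps - 1)
        return x1[i] * (1 - w) + x1[i + 1] * w

    def f(t, y1, y2):
        r = spec.input.evaluate(t)
        return (r - spec.decay * y1, spec.gain * x1_delayed(t) - spec.decay * y2)

    for k in range(n_steps):
        t = ts[k]
        k1 = f(t, x1[k], x2[k])
        k2 = f(t + h / 2, x1[k] + h / 2 * k1[0], x2[k] + h / 2 * k1[1])
        k3 = f(t + h / 2, x1[k] + h / 2 * k2[0], x2[k] + h / 2 * k2[1])
        k4 = f(t + h, x1[k] + h * k3[0], x2[k] + h * k3[1])
        x1[k + 1] = x1[k] + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        x2[k + 1] = x2[k] + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    return ts, x1, x2


class TestIntegrateDDE:
    def test_delay_free_limit_equals_two_species_cascade(self):
        spec = DDESpec(gain=1.5, decay=0.8, tau=0.0, input=InputSignal.step())
        t = np.linspace(0.0, 12.0, 61)
        dde = integrate_dde(spec, t).values[:, 1]
        casc = integrate_linear(spec.equivalent_cascade(), InputSignal.step(), t,
                                tol=1e-12).values[:, -1]
        assert np.max(np.abs(dde - casc)) < 1e-9

    def test_causality_with_zero_history(self):
        spec = DDESpec(gain=1.0, decay=1.0, tau=3.0, input=InputSignal.step())
        t = np.linspace(0.0, 10.0, 101)
        out = integrate_dde(spec, t).values[:, 1]
        assert np.max(np.abs(out[t < 3.0])) < 1e-12

    def test_step_input_closed_form(self):
        # equal rates: x2(t) = (g/b^2)(1 - e^{-b s}(1 + b s)), s = t - tau
        g, b, tau = 2.0, 1.5, 1.0
        spec = DDESpec(gain=g, decay=b, tau=tau, input=InputSignal.step())
        t = np.linspace(0.0, 12.0, 61)
        out = integrate_dde(spec, t).values[:, 1]
        s = np.maximum(t - tau, 0.0)
        want = g / b**2 * (1.0 - np.exp(-b * s) * (1.0 + b * s))
        assert np.max(np.abs(out - want)) < 1e-8

    def test_against_independent_fixed_stride_integrator(self):
        spec = DDESpec(gain=1.0, decay=1.0, tau=2.0,
                       input=InputSignal.exponential(0.5), history=0.1)
        ts, _, x2_rk = _rk4_dde(spec, 12.0, 0.002)
        out = integrate_dde(spec, ts).values[:, 1]
        assert np.max(np.abs(out - x2_rk)) < 1e-6

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            DDESpec(gain=1.0, decay=0.0, tau=1.0, input=InputSignal.step())
        with pytest.raises(ValueError):
            DDESpec(gain=1.0, decay=1.0, tau=-1.0, input=InputSignal.step())
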