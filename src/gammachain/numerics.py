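"""Numerical solution paths for linear and nonlinear cascades.

These routines are the brute-force counterparts of the closed forms in
:mod:`gammachain.analytic`: direct ODE integration of the nonlinear and
linearized systems, the matrix-exponential step response, the
hypoexponential impulse-response kernel in partial-fraction form (with
confluent handling of repeated deactivation rates), numerical convolution
of that kernel with an arbitrary input, and a method-of-steps integrator
for a two-node delayed-coupling system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg
from scipy.integrate import quad, solve_ivp

from .cascade import (
    CascadeSpec,
    InputSignal,
    NonlinearCascadeSpec,
    TimeCourse,
    build_rate_matrix,
)

__all__ = [
    "KernelRepresentation",
    "DDESpec",
    "integrate_linear",
    "integrate_nonlinear",
    "step_response_matrix_form",
    "hypoexponential_kernel",
    "evaluate_kernel",
    "convolve_response",
    "integrate_dde",
]

DEFAULT_TOL = 1e-9


class SolverError(RuntimeError):
    """Raised when an ODE solver does not converge; carries the report."""


def _delta_initial_condition(spec: CascadeSpec, signal: InputSignal, x0: np.ndarray) -> np.ndarray:
    # An impulse of mass w at t=0 is equivalent to a jump alpha_1*w in x_1.
    x0 = np.array(x0, dtype=float)
    x0[0] += spec.activation_rates[0] * signal.weight
    return x0


def integrate_linear(
    spec: CascadeSpec,
    signal: InputSignal,
    times: Sequence[float],
    x0: Optional[Sequence[float]] = None,
    tol: float = DEFAULT_TOL,
) -> TimeCourse:
    """Integrate the driven linear system ``dx/dt = A x + alpha_1 R(t) e_1``.

    Returns the trajectory of all ``n`` species on the requested grid.  The
    cascade starts from rest unless ``x0`` is given.  A Dirac-delta input is
    folded into the initial condition (the impulse produces an instantaneous
    jump ``alpha_1 * weight`` in the first species).
    """
    times = np.asarray(times, dtype=float)
    A = build_rate_matrix(spec)
    if x0 is None:
        x0 = np.zeros(spec.n)
    else:
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != (spec.n,):
            raise ValueError(f"x0 must have shape ({spec.n},)")

    if signal.kind == "delta":
        x0 = _delta_initial_condition(spec, signal, x0)
        drive = lambda t: 0.0
    else:
        drive = signal.evaluate
    a1 = spec.activation_rates[0]

    def rhs(t, x):
        dx = A @ x
        dx[0] += a1 * drive(t)
        return dx

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        x0,
        t_eval=times,
        method="DOP853",
        rtol=tol,
        atol=tol,
    )
    if not sol.success:
        raise SolverError(f"linear cascade integration failed: {sol.message}")
    return TimeCourse(times, sol.y.T)


def integrate_nonlinear(
    spec: NonlinearCascadeSpec,
    signal: InputSignal,
    times: Sequence[float],
    x0: Optional[Sequence[float]] = None,
    tol: float = DEFAULT_TOL,
) -> tuple[TimeCourse, float]:
    """Integrate the full saturating cascade.

    Dynamics: ``dx_i/dt = alpha_i x_{i-1} (T_i - x_i) - beta_i x_i`` with
    ``x_0 = input_scale * R(t)``.  Returns the trajectory and the
    weak-activation diagnostic ``max_{i,t} x_i(t)/T_i`` (values near zero
    indicate the linearization is accurate).
    """
    times = np.asarray(times, dtype=float)
    base = spec.base
    alpha = base.alpha
    beta = base.beta
    totals = np.asarray(spec.totals)
    if x0 is None:
        x0 = np.zeros(base.n)
    else:
        x0 = np.asarray(x0, dtype=float)

    def rhs(t, x):
        upstream = np.empty_like(x)
        upstream[0] = spec.input_scale * signal.evaluate(t)
        upstream[1:] = x[:-1]
        return alpha * upstream * (totals - x) - beta * x

    sol = solve_ivp(rhs, (times[0], times[-1]), x0, t_eval=times, method="LSODA", rtol=tol, atol=tol)
    if not sol.success:
        raise SolverError(f"nonlinear cascade integration failed: {sol.message}")
    traj = sol.y.T
    saturation = float(np.max(traj / totals)) if traj.size else 0.0
    return TimeCourse(times, traj), saturation


def step_response_matrix_form(spec: CascadeSpec, t, amplitude: float = 1.0) -> np.ndarray:
    """Closed-form step response via the matrix exponential.

    ``x(t) = A^{-1} (e^{At} - I) b`` with ``b = alpha_1 * amplitude * e_1``;
    no time stepping is involved.  ``t`` may be a scalar or a grid; the
    result has shape ``(n,)`` or ``(len(t), n)``.
    """
    A = build_rate_matrix(spec)
    b = np.zeros(spec.n)
    b[0] = spec.activation_rates[0] * amplitude
    scalar = np.isscalar(t)
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(ts < 0):
        raise ValueError("t must be nonnegative")
    out = np.empty((ts.size, spec.n))
    eye = np.eye(spec.n)
    for j, tj in enumerate(ts):
        expm_t = linalg.expm(A * tj)
        out[j] = linalg.solve_triangular(A, (expm_t - eye) @ b, lower=True)
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# hypoexponential kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelRepresentation:
    """Partial-fraction form of the cascade impulse response.

    The transfer function ``prod(alpha_i) / prod(s + beta_i)`` is expanded
    over clusters of near-equal deactivation rates; each cluster of rate
    ``b`` and multiplicity ``m`` contributes ``sum_j c_j t^{j-1} e^{-bt}/(j-1)!``
    with ``c_j`` the coefficient of ``(s+b)^{-j}``.  The kernel evaluates to
    zero at t=0 for n >= 2 and integrates over [0, inf) to the asymptotic
    gain ``prod(alpha)/prod(beta)``.
    """

    prefactor: float
    groups: tuple[tuple[float, int], ...]  # (rate, multiplicity)
    coefficients: tuple[tuple[float, ...], ...]  # per group, c_1..c_m

    @property
    def order(self) -> int:
        return sum(m for _, m in self.groups)

    def mass(self) -> float:
        """Integral of the kernel over [0, inf)."""
        total = 0.0
        for (b, m), coeffs in zip(self.groups, self.coefficients):
            for j, c in enumerate(coeffs, start=1):
                total += c / b**j
        return self.prefactor * total


def _cluster_rates(beta: np.ndarray, rtol: float) -> list[tuple[float, int]]:
    order = np.argsort(beta)
    clusters: list[list[float]] = []
    for b in beta[order]:
        if clusters and abs(b - clusters[-1][-1]) <= rtol * max(abs(b), abs(clusters[-1][-1])):
            clusters[-1].append(b)
        else:
            clusters.append([b])
    return [(float(np.mean(c)), len(c)) for c in clusters]


def hypoexponential_kernel(spec: CascadeSpec, cluster_rtol: float = 1e-8) -> KernelRepresentation:
    """Partial-fraction expansion of the impulse response.

    Deactivation rates within relative distance ``cluster_rtol`` are merged
    into a single confluent group before expansion; naive distinct-rate
    formulas are numerically catastrophic for near-equal rates, whereas the
    confluent (polynomial x exponential) representation is exact in the
    equal-rate limit.
    """
    groups = _cluster_rates(spec.beta, cluster_rtol)
    prefactor = float(np.prod(spec.alpha))
    coeffs: list[tuple[float, ...]] = []
    for g, (b, m) in enumerate(groups):
        # G(s) = prod over other groups of (s + b_h)^{-m_h}; we need its
        # derivatives at s = -b.  log G is a sum of logs, so successive
        # derivatives follow from the Leibniz recursion G^{(k+1)} =
        # sum_i C(k,i) (log G)^{(i+1)} G^{(k-i)}.
        others = [(bh, mh) for h, (bh, mh) in enumerate(groups) if h != g]
        G = [1.0]
        if others:
            G[0] = float(np.prod([(bh - b) ** (-mh) for bh, mh in others]))
        # derivatives of p = log G at s = -b: p^{(j)} = sum_h -m_h * (-1)^{j-1} (j-1)! / (bh - b)^j
        p_derivs = []
        for j in range(1, m + 1):
            pj = 0.0
            for bh, mh in others:
                pj += -mh * ((-1) ** (j - 1)) * math.factorial(j - 1) / (bh - b) ** j
            p_derivs.append(pj)
        for k in range(m - 1):
            nxt = 0.0
            for i in range(k + 1):
                nxt += math.comb(k, i) * p_derivs[i] * G[k - i]
            G.append(nxt)
        # coefficient of (s+b)^{-j} is G^{(m-j)}(-b)/(m-j)!
        cj = tuple(G[m - j] / math.factorial(m - j) for j in range(1, m + 1))
        coeffs.append(cj)
    return KernelRepresentation(prefactor=prefactor, groups=tuple(groups), coefficients=tuple(coeffs))


def evaluate_kernel(kernel: KernelRepresentation, t) -> np.ndarray:
    """Evaluate the impulse-response kernel h(t); zero for t < 0."""
    scalar = np.isscalar(t)
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(ts)
    pos = ts >= 0
    tp = ts[pos]
    acc = np.zeros_like(tp)
    for (b, m), coeffs in zip(kernel.groups, kernel.coefficients):
        decay = np.exp(-b * tp)
        poly = np.zeros_like(tp)
        for j, c in enumerate(coeffs, start=1):
            poly += c * tp ** (j - 1) / math.factorial(j - 1)
        acc += poly * decay
    out[pos] = kernel.prefactor * acc
    return float(out[0]) if scalar else out


def convolve_response(
    kernel: KernelRepresentation,
    signal: InputSignal,
    times: Sequence[float],
    epsabs: float = 1e-10,
    epsrel: float = 1e-10,
) -> TimeCourse:
    """Cascade output by adaptive-quadrature convolution of kernel and input.

    ``x(t) = int_0^t h(u) R(t-u) du``; a delta input short-circuits to
    ``weight * h(t)`` via the sifting property.
    """
    times = np.asarray(times, dtype=float)
    if signal.kind == "delta":
        return TimeCourse(times, signal.weight * np.asarray(evaluate_kernel(kernel, times)))
    vals = np.zeros_like(times)
    for i, t in enumerate(times):
        if t <= 0:
            continue
        integrand = lambda u: evaluate_kernel(kernel, u) * signal.evaluate(t - u)
        points = None
        if signal.kind == "gaussian":
            # concentrate effort around the input bump
            lo = max(0.0, t - (signal.mu + 8 * signal.zeta))
            hi = min(t, max(0.0, t - (signal.mu - 8 * signal.zeta)))
            points = [p for p in (lo, hi) if 0 < p < t]
        val, err = quad(integrand, 0.0, t, epsabs=epsabs, epsrel=epsrel, limit=200, points=points)
        if not np.isfinite(val):
            raise SolverError(f"convolution quadrature failed at t={t}")
        vals[i] = val
    return TimeCourse(times, vals)


# ---------------------------------------------------------------------------
# delayed-coupling system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DDESpec:
    """Two-node signalling motif with a discrete delay.

    An input node integrates the stimulus, ``x1' = R(t) - decay * x1``, and
    the response node reads the upstream state a time ``tau`` in the past,
    ``x2' = gain * x1(t - tau) - decay * x2``.  ``history`` is the constant
    pre-zero state of the upstream node; the response node starts at rest.
    With ``tau = 0`` this is exactly the two-species linear cascade with
    activation rates ``(1, gain)`` and common deactivation rate ``decay``.
    """

    gain: float
    decay: float
    tau: float
    input: InputSignal
    history: float = 0.0

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.decay <= 0:
            raise ValueError("decay must be positive")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")

    def equivalent_cascade(self) -> CascadeSpec:
        """The delay-free (tau=0) limit as a two-species cascade."""
        return CascadeSpec(2, (1.0, self.gain), (self.decay, self.decay))


def integrate_dde(spec: DDESpec, times: Sequence[float], tol: float = 1e-11) -> TimeCourse:
    """Method-of-steps solution of the delayed two-node system.

    The upstream node is solved first as an ordinary driven scalar ODE with
    dense output; the delayed term in the response equation is then a known
    function, so the response node is a scalar linear ODE integrated
    piecewise on ``[0, tau]`` and ``[tau, T]`` (the delayed drive has a
    derivative discontinuity at ``t = tau``).  Returns both species;
    the output is the second column.
    """
    times = np.asarray(times, dtype=float)
    t_end = times[-1]
    beta = spec.decay

    def rhs1(t, x):
        return [spec.input.evaluate(t) - beta * x[0]]

    sol1 = solve_ivp(rhs1, (0.0, t_end), [spec.history], method="DOP853",
                     rtol=tol, atol=tol, dense_output=True)
    if not sol1.success:
        raise SolverError(f"upstream node integration failed: {sol1.message}")

    def x1_at(t):
        if t <= 0.0:
            return spec.history
        return float(sol1.sol(min(t, t_end))[0])

    def rhs2(t, x):
        return [spec.gain * x1_at(t - spec.tau) - beta * x[0]]

    # integrate the response piecewise across the kink at t = tau
    breakpoints = [0.0]
    if 0.0 < spec.tau < t_end:
        breakpoints.append(spec.tau)
    breakpoints.append(t_end)

    x2_vals = np.empty_like(times)
    state = 0.0
    for lo, hi in zip(breakpoints[:-1], breakpoints[1:]):
        mask = (times > lo) & (times <= hi)
        t_eval = times[mask]
        sol2 = solve_ivp(rhs2, (lo, hi), [state], method="DOP853",
                         rtol=tol, atol=tol, t_eval=t_eval if t_eval.size else None,
                         dense_output=False)
        if not sol2.success:
            raise SolverError(f"response node integration failed: {sol2.message}")
        if t_eval.size:
            x2_vals[mask] = sol2.y[0]
        state = float(sol2.y[0, -1]) if sol2.y.size else state
    if times[0] == 0.0:
        x2_vals[0] = 0.0

    x1_vals = np.array([x1_at(t) for t in times])
    return TimeCourse(times, np.column_stack([x1_vals, x2_vals]))
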