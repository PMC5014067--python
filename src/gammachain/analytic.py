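"""Closed-form gamma-function solutions for optimal (equal-rate) cascades.

When all deactivation rates of a weakly activated cascade are equal to
``beta`` — the configuration that achieves a required gain with optimal
efficiency — the output of the ``n``-th species has an exact representation
through the regularized lower incomplete gamma function

    P(a, x) = gamma(a, x) / Gamma(a),

with ``a = n`` allowed to be any positive real.  This module provides that
special function on the domains the solutions require (real argument of
either sign and complex argument), plus the closed-form responses to step,
exponential, periodic, Gaussian and impulse inputs, and the asymptotic
filter description of the periodic response.

Numerical strategy for ``P``:

* real ``x >= 1``: scipy's ``gammainc``;
* ``|x| < 1`` or real ``x < 0``: power series of the entire function
  ``x^{-a} gamma(a,x)/Gamma(a)`` (all terms of one sign for ``x < 0``, so no
  subtractive cancellation — needed for exponential inputs decaying faster
  than the cascade, ``lam > beta``);
* complex ``x`` with moderate ``|x| - Re x``: the ``e^{-x}``-prefactored
  series (positive-definite term growth bounded by ``e^{|x|-Re x}``);
* otherwise: Lentz continued fraction for the regularized upper function.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import special as sps
from scipy.integrate import quad

from .cascade import GammaModule

__all__ = [
    "reg_lower_gamma",
    "reg_lower_gamma_scaled",
    "step_solution",
    "exponential_solution",
    "periodic_solution",
    "periodic_asymptotic",
    "filter_summary",
    "gaussian_solution",
    "delta_solution",
    "PeriodicFilterSummary",
]

_SERIES_MAX_TERMS = 100_000
_SERIES_RTOL = 1e-16


def _scaled_series_direct(a: float, z: complex) -> complex:
    """sum_k (-z)^k / (k! (a+k)) / Gamma(a)  ==  P(a,z)/z^a."""
    term = 1.0 + 0.0j
    total = term / a
    for k in range(1, _SERIES_MAX_TERMS):
        term *= -z / k
        incr = term / (a + k)
        total += incr
        if abs(incr) <= _SERIES_RTOL * abs(total) and k > abs(z):
            break
    return total * math.exp(-math.lgamma(a))


def _scaled_series_prefactored(a: float, z: complex) -> complex:
    """e^{-z} sum_k z^k / Gamma(a+k+1)  ==  P(a,z)/z^a."""
    term = math.exp(-math.lgamma(a + 1.0))
    total = term
    for k in range(_SERIES_MAX_TERMS):
        term *= z / (a + k + 1.0)
        total += term
        if abs(term) <= _SERIES_RTOL * abs(total) and k > abs(z):
            break
    return cmath.exp(-z) * total


def _upper_reg_cf(a: float, z: complex) -> complex:
    """Regularized upper incomplete gamma Q(a,z) by modified Lentz CF.

    Valid away from the negative real axis; efficient for largish ``|z|``.
    """
    tiny = 1e-300
    b = z + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b if b != 0 else 1.0 / tiny
    h = d
    for i in range(1, _SERIES_MAX_TERMS):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-16:
            break
    return cmath.exp(-z + a * cmath.log(z) - math.lgamma(a)) * h


def _scaled_scalar(a: float, z: complex) -> complex:
    """P(a,z)/z^a for scalar z (real or complex), entire in z."""
    if z == 0:
        return math.exp(-math.lgamma(a + 1.0))
    if z.imag == 0.0:
        x = z.real
        if x < 0.0 or abs(x) < 1.0:
            return _scaled_series_direct(a, x)
        # gammainc underflows only for astronomically small x^a; x >= 1 is safe
        return sps.gammainc(a, x) * math.exp(-a * math.log(x))
    d = abs(z) - z.real
    if abs(z) <= 8.0 or d <= 18.0:
        if z.real >= 0.0:
            return _scaled_series_prefactored(a, z)
        return _scaled_series_direct(a, z)
    q = _upper_reg_cf(a, z)
    return (1.0 - q) * cmath.exp(-a * cmath.log(z))


def _scaled_real_array(a: float, z: np.ndarray) -> np.ndarray:
    """Vectorized P(a,z)/z^a for real z of either sign.

    For z >= 1 scipy's ``gammainc`` is rescaled; below 1 (and for all
    negative z) the direct power series is used — its terms all share one
    sign for z < 0, so there is no subtractive cancellation there.  Very
    large negative z (|z| beyond ~700) overflows the series prefactor; the
    closed-form solutions never produce such arguments with their decaying
    exponential prefactors applied.
    """
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    big = z >= 1.0
    if np.any(big):
        zb = z[big]
        out[big] = sps.gammainc(a, zb) * np.exp(-a * np.log(zb))
    if np.any(~big):
        zs = z[~big]
        term = np.ones_like(zs)
        total = term / a
        zmax = float(np.max(np.abs(zs))) if zs.size else 0.0
        for k in range(1, _SERIES_MAX_TERMS):
            term = term * (-zs) / k
            incr = term / (a + k)
            total = total + incr
            if k > zmax and np.all(np.abs(incr) <= _SERIES_RTOL * np.abs(total)):
                break
        out[~big] = total * math.exp(-math.lgamma(a))
    return out


def reg_lower_gamma_scaled(a: float, z) -> Union[float, complex, np.ndarray]:
    """The entire function ``P(a, z) / z^a`` (principal branch removed).

    This is the numerically robust building block for the exponential and
    periodic solutions: it is finite and smooth through ``z = 0`` (where the
    plain ``P(a,z)/z^a`` quotient is 0/0) and has no cancellation for
    negative real ``z``.
    """
    if a <= 0 or not math.isfinite(a):
        raise ValueError(f"shape parameter a must be positive, got {a}")
    arr = np.asarray(z)
    if np.isrealobj(arr):
        out = _scaled_real_array(a, np.atleast_1d(arr).astype(float))
        return float(out[0]) if arr.ndim == 0 else out.reshape(arr.shape)
    flat = np.atleast_1d(arr)
    out = np.array([_scaled_scalar(a, complex(v)) for v in flat.ravel()]).reshape(flat.shape)
    return out.reshape(()).item() if arr.ndim == 0 else out.reshape(arr.shape)


def reg_lower_gamma(a: float, x) -> Union[float, complex, np.ndarray]:
    """Regularized lower incomplete gamma ``P(a, x) = gamma(a,x)/Gamma(a)``.

    Supports real nonnegative ``x`` (values in [0, 1]), negative real ``x``
    (generally complex via the principal branch of ``x^a``) and complex
    ``x``.
    """
    if a <= 0 or not math.isfinite(a):
        raise ValueError(f"shape parameter a must be positive, got {a}")
    arr = np.atleast_1d(np.asarray(x))
    if np.isrealobj(arr) and np.all(arr >= 0):
        out = sps.gammainc(a, arr.astype(float))
        return float(out[0]) if arr.size == 1 and np.asarray(x).ndim == 0 else out
    vals = []
    for v in arr.ravel():
        zc = complex(v)
        g = _scaled_scalar(a, zc)
        vals.append(g * cmath.exp(a * cmath.log(zc)) if zc != 0 else 0.0)
    out = np.array(vals).reshape(arr.shape)
    return out.reshape(()).item() if np.asarray(x).ndim == 0 else out


# ---------------------------------------------------------------------------
# closed-form responses
# ---------------------------------------------------------------------------

def _check_times(t) -> np.ndarray:
    ts = np.asarray(t, dtype=float)
    if np.any(ts < 0):
        raise ValueError("t must be nonnegative")
    return ts


def _maybe_scalar(out: np.ndarray, t) -> Union[float, np.ndarray]:
    return float(out) if np.asarray(t).ndim == 0 else out


def step_solution(m: GammaModule, t, amplitude: float = 1.0):
    """Output under a step input ``R(t) = amplitude`` for ``t >= 0``.

    ``x_n(t) = amplitude * (alpha_gm/beta)^n * P(n, beta t)`` — a rescaled
    gamma CDF: nondecreasing, 0 at t=0, saturating at amplitude times the
    amplification ``(alpha_gm/beta)^n``.
    """
    ts = _check_times(t)
    out = amplitude * m.amplification * sps.gammainc(m.n_real, m.beta * ts)
    return _maybe_scalar(out, t)


def exponential_solution(m: GammaModule, lam: float, t, amplitude: float = 1.0):
    """Output under ``R(t) = amplitude * e^{-lam t}``.

    ``x_n(t) = amplitude * alpha_gm^n e^{-lam t} P(n,(beta-lam)t)/(beta-lam)^n``,
    evaluated through the entire function ``P(n,z)/z^n`` so that the formula
    is a single smooth expression across ``lam = beta`` (where it reduces to
    ``alpha_gm^n t^n e^{-beta t}/Gamma(n+1)``) and for ``lam > beta`` (where
    the gamma argument is negative).
    """
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    ts = _check_times(t)
    n, b, a = m.n_real, m.beta, m.alpha_gm
    g = np.real(np.atleast_1d(np.asarray(reg_lower_gamma_scaled(n, (b - lam) * ts))))
    out = amplitude * np.exp(n * math.log(a) - lam * ts) * ts**n * g
    return _maybe_scalar(out.reshape(np.shape(ts)), t)


@dataclass(frozen=True)
class PeriodicFilterSummary:
    """Asymptotic filter characteristics of the periodic response.

    rho = beta/sqrt(beta^2+omega^2) is the per-stage attenuation (=cos theta),
    theta = atan(omega/beta) the per-stage phase delay, and ``amplification``
    the mean-level gain (alpha_gm/beta)^n.  Long after the transient the
    output is amplification * [1 ± rho^n * sinusoid(omega t - n theta)],
    hence bounded between 0 and twice the amplification.
    """

    rho: float
    theta: float
    amplification: float

    def __post_init__(self):
        if not (0 < self.rho <= 1):
            raise ValueError("rho must lie in (0, 1]")
        if not (0 <= self.theta < math.pi / 2):
            raise ValueError("theta must lie in [0, pi/2)")
        if self.amplification <= 0:
            raise ValueError("amplification must be positive")


def filter_summary(m: GammaModule, omega: float) -> PeriodicFilterSummary:
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    rho = m.beta / math.hypot(m.beta, omega)
    theta = math.atan2(omega, m.beta)
    return PeriodicFilterSummary(rho=rho, theta=theta, amplification=m.amplification)


def _complex_mode_response(m: GammaModule, omega: float, ts: np.ndarray) -> np.ndarray:
    """Response to the complex exponential input ``e^{i omega t}``."""
    n, b, a = m.n_real, m.beta, m.alpha_gm
    z = (b + 1j * omega) * ts
    g = np.atleast_1d(np.asarray(reg_lower_gamma_scaled(n, z), dtype=complex))
    return np.exp(n * math.log(a) + 1j * omega * ts) * ts**n * g


def periodic_solution(m: GammaModule, omega: float, t, waveform: str = "one_minus_cos",
                      amplitude: float = 1.0):
    """Exact output under ``R(t) = amplitude*(1 - cos wt)`` or ``(1 + sin wt)``.

    Built by superposing the step response with the real or imaginary part
    of the complex-rate response ``alpha^n e^{iwt}(beta+iw)^{-n} P(n,(beta+iw)t)``
    (mathematically equivalent to the Chebyshev-polynomial expansion of the
    same solution).
    """
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    ts = _check_times(t)
    mode = _complex_mode_response(m, omega, np.atleast_1d(ts))
    step = amplitude * m.amplification * sps.gammainc(m.n_real, m.beta * np.atleast_1d(ts))
    if waveform == "one_minus_cos":
        out = step - amplitude * mode.real
    elif waveform == "one_plus_sin":
        out = step + amplitude * mode.imag
    else:
        raise ValueError(f"unknown waveform {waveform!r}")
    return _maybe_scalar(out.reshape(np.shape(ts)) if np.shape(ts) else out[0], t)


def periodic_asymptotic(m: GammaModule, omega: float, t, waveform: str = "one_minus_cos",
                        amplitude: float = 1.0):
    """Large-time filter form of the periodic response.

    The cascade passes the mean level with gain ``(alpha_gm/beta)^n`` and
    attenuates the oscillation by ``rho^n`` with phase lag ``n*theta``.
    """
    summ = filter_summary(m, omega)
    ts = _check_times(t)
    att = summ.rho**m.n_real
    phase = omega * ts - m.n_real * summ.theta
    if waveform == "one_minus_cos":
        out = amplitude * summ.amplification * (1.0 - att * np.cos(phase))
    elif waveform == "one_plus_sin":
        out = amplitude * summ.amplification * (1.0 + att * np.sin(phase))
    else:
        raise ValueError(f"unknown waveform {waveform!r}")
    return _maybe_scalar(out, t)


def delta_solution(m: GammaModule, weight: float, t):
    """Response to an impulse of mass ``weight`` at t=0.

    ``x_n(t) = weight * alpha_gm^n t^{n-1} e^{-beta t} / Gamma(n)`` — a gamma
    density in disguise, the confluent limit of the hypoexponential kernel.
    Real ``n`` is supported through the gamma function; the peak sits at
    ``t = (n-1)/beta`` for ``n > 1``.
    """
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    ts = _check_times(t)
    n, b, a = m.n_real, m.beta, m.alpha_gm
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        logt = np.where(ts > 0, np.log(np.where(ts > 0, ts, 1.0)), -np.inf)
        out = weight * np.exp(n * math.log(a) + (n - 1.0) * logt - b * ts - math.lgamma(n))
    if n == 1.0:
        out = np.where(ts == 0, weight * a, out)
    return _maybe_scalar(out, t)


def gaussian_solution(m: GammaModule, mu: float, zeta: float, t, amplitude: float = 1.0,
                      epsabs: float = 1e-12):
    """Response to a Gaussian bump centred at ``mu`` with width ``zeta``.

    Computed by adaptive quadrature of the input against the impulse kernel:
    ``x(t) = int_0^t h(t-u) R(u) du`` with the integration window truncated
    to ``[mu - 8 zeta, mu + 8 zeta]`` where the input has support.  As
    ``zeta -> 0`` this approaches ``sqrt(2 pi) zeta`` times the impulse
    response shifted to ``mu``.
    """
    if zeta <= 0:
        raise ValueError(f"zeta must be positive, got {zeta}")
    ts = _check_times(t)
    flat = np.atleast_1d(ts)
    out = np.zeros_like(flat)
    for i, ti in enumerate(flat):
        lo = max(0.0, mu - 8.0 * zeta)
        hi = min(ti, mu + 8.0 * zeta)
        if hi <= lo:
            continue
        integrand = lambda u: delta_solution(m, 1.0, ti - u) * math.exp(-((u - mu) ** 2) / (2.0 * zeta**2))
        val, _ = quad(integrand, lo, hi, epsabs=epsabs, epsrel=1e-10, limit=200)
        out[i] = amplitude * val
    return _maybe_scalar(out.reshape(np.shape(ts)) if np.shape(ts) else out[0], t)
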