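"""Domain types and scalar summaries for weakly activated cascades.

A linear activation cascade is a chain of species in which each active
species catalyses activation of the next, while every species deactivates
spontaneously.  In the weakly activated regime (active fractions small
compared with total protein amounts) the kinetics reduce to a driven linear
system ``dx/dt = A x + alpha_1 R(t) e_1`` with a lower-bidiagonal rate
matrix ``A``.  This module owns the parameter containers for that system and
the scalar summaries built from them: the rate matrix itself, the
geometric-mean activation rate of the first *k* steps, and the asymptotic
gain under a unit step input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "CascadeSpec",
    "NonlinearCascadeSpec",
    "InputSignal",
    "GammaModule",
    "TimeCourse",
    "build_rate_matrix",
    "geometric_mean_activation",
    "asymptotic_gain",
    "linearize",
]


def _check_rates(name: str, rates: Sequence[float], n: int) -> tuple[float, ...]:
    arr = tuple(float(r) for r in rates)
    if len(arr) != n:
        raise ValueError(f"{name} must have exactly n={n} entries, got {len(arr)}")
    for r in arr:
        if not math.isfinite(r) or r <= 0.0:
            raise ValueError(f"{name} entries must be strictly positive and finite, got {r}")
    return arr


@dataclass(frozen=True)
class CascadeSpec:
    """Linearized cascade of length ``n``.

    Parameters
    ----------
    n : int
        Number of steps (species) in the cascade, ``n >= 1``.
    activation_rates : sequence of float
        Linearized activation rates (reciprocal time); for a species fed by
        an upstream protein this is the raw mass-action rate multiplied by
        that species' total protein amount.
    deactivation_rates : sequence of float
        First-order deactivation rates (reciprocal time).
    """

    n: int
    activation_rates: tuple[float, ...]
    deactivation_rates: tuple[float, ...]

    def __init__(self, n: int, activation_rates: Sequence[float], deactivation_rates: Sequence[float]):
        n = int(n)
        if n < 1:
            raise ValueError(f"cascade length must be >= 1, got {n}")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "activation_rates", _check_rates("activation_rates", activation_rates, n))
        object.__setattr__(self, "deactivation_rates", _check_rates("deactivation_rates", deactivation_rates, n))

    # -- convenience -------------------------------------------------------
    @property
    def alpha(self) -> np.ndarray:
        return np.asarray(self.activation_rates)

    @property
    def beta(self) -> np.ndarray:
        return np.asarray(self.deactivation_rates)

    def has_equal_deactivation(self, rtol: float = 1e-12) -> bool:
        b = self.beta
        return bool(np.all(np.abs(b - b[0]) <= rtol * np.abs(b[0])))

    def with_permuted_beta(self, permutation: Sequence[int]) -> "CascadeSpec":
        """Permute the deactivation rates, keeping activation rates in place.

        The final output of the cascade is invariant under this operation
        (the transfer function is a product over ``1/(s + beta_i)`` factors,
        which commutes), although intermediate trajectories are not.
        """
        perm = list(permutation)
        if sorted(perm) != list(range(self.n)):
            raise ValueError(f"invalid permutation of length {self.n}: {permutation}")
        beta = tuple(self.deactivation_rates[i] for i in perm)
        return CascadeSpec(self.n, self.activation_rates, beta)

    def to_gamma_module(self) -> "GammaModule":
        """Lump an equal-deactivation cascade into its gamma module."""
        if not self.has_equal_deactivation(rtol=1e-9):
            raise ValueError("cascade must have equal deactivation rates to form a single gamma module")
        return GammaModule(
            alpha_gm=geometric_mean_activation(self, self.n),
            beta=float(np.mean(self.beta)),
            n_real=float(self.n),
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "activation_rates": list(self.activation_rates),
            "deactivation_rates": list(self.deactivation_rates),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeSpec":
        return cls(d["n"], d["activation_rates"], d["deactivation_rates"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "CascadeSpec":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class NonlinearCascadeSpec:
    """Full mass-action cascade with saturable activation.

    ``base`` carries the *raw* activation rates; the activation flux into
    species ``i`` is ``alpha_i * x_{i-1} * (T_i - x_i)`` (with the input
    ``input_scale * R(t)`` playing the role of ``x_0``), and deactivation is
    first order.  ``linearize`` produces the weak-activation reduction.
    """

    base: CascadeSpec
    totals: tuple[float, ...]
    input_scale: float = 1.0

    def __init__(self, base: CascadeSpec, totals: Sequence[float], input_scale: float = 1.0):
        object.__setattr__(self, "base", base)
        object.__setattr__(self, "totals", _check_rates("totals", totals, base.n))
        input_scale = float(input_scale)
        if not math.isfinite(input_scale) or input_scale <= 0:
            raise ValueError(f"input_scale must be positive, got {input_scale}")
        object.__setattr__(self, "input_scale", input_scale)


def linearize(spec: NonlinearCascadeSpec) -> CascadeSpec:
    """Weak-activation reduction of a saturating cascade.

    Each activation term ``alpha_i x_{i-1} (T_i - x_i)`` is approximated by
    ``alpha_i T_i x_{i-1}`` when ``x_i << T_i``, so the linearized rate is
    the raw rate multiplied by the total amount of the protein being
    activated.  The input scale is absorbed into the first rate.
    """
    raw = spec.base.alpha
    totals = np.asarray(spec.totals)
    lin = raw * totals
    lin[0] *= spec.input_scale
    return CascadeSpec(spec.base.n, lin, spec.base.deactivation_rates)


_INPUT_KINDS = ("step", "exponential", "periodic", "gaussian", "delta", "custom")
_WAVEFORMS = ("one_minus_cos", "one_plus_sin")


@dataclass(frozen=True)
class InputSignal:
    """Tagged union of the supported input signal classes.

    kinds
    -----
    step         ``R(t) = amplitude`` for ``t >= 0``
    exponential  ``R(t) = amplitude * exp(-lam * t)``
    periodic     ``R(t) = amplitude * (1 - cos(omega t))`` or
                 ``amplitude * (1 + sin(omega t))`` — oscillates between 0
                 and 2*amplitude with mean amplitude
    gaussian     ``R(t) = amplitude * exp(-(t - mu)^2 / (2 zeta^2))``
    delta        impulse of mass ``weight`` at ``t = 0``
    custom       arbitrary integrable ``fn(t)``
    """

    kind: str
    amplitude: float = 1.0
    lam: Optional[float] = None
    omega: Optional[float] = None
    waveform: str = "one_minus_cos"
    mu: Optional[float] = None
    zeta: Optional[float] = None
    weight: Optional[float] = None
    fn: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self):
        if self.kind not in _INPUT_KINDS:
            raise ValueError(f"unknown input kind {self.kind!r}; expected one of {_INPUT_KINDS}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.kind == "exponential" and (self.lam is None or self.lam <= 0):
            raise ValueError("exponential input requires lam > 0")
        if self.kind == "periodic":
            if self.omega is None or self.omega <= 0:
                raise ValueError("periodic input requires omega > 0")
            if self.waveform not in _WAVEFORMS:
                raise ValueError(f"waveform must be one of {_WAVEFORMS}")
        if self.kind == "gaussian":
            if self.mu is None:
                raise ValueError("gaussian input requires mu")
            if self.zeta is None or self.zeta <= 0:
                raise ValueError("gaussian input requires zeta > 0")
        if self.kind == "delta" and (self.weight is None or self.weight <= 0):
            raise ValueError("delta input requires weight > 0")
        if self.kind == "custom" and self.fn is None:
            raise ValueError("custom input requires fn")

    # -- factories ---------------------------------------------------------
    @classmethod
    def step(cls, amplitude: float = 1.0) -> "InputSignal":
        return cls(kind="step", amplitude=amplitude)

    @classmethod
    def exponential(cls, lam: float, amplitude: float = 1.0) -> "InputSignal":
        return cls(kind="exponential", amplitude=amplitude, lam=lam)

    @classmethod
    def periodic(cls, omega: float, waveform: str = "one_minus_cos", amplitude: float = 1.0) -> "InputSignal":
        return cls(kind="periodic", amplitude=amplitude, omega=omega, waveform=waveform)

    @classmethod
    def gaussian(cls, mu: float, zeta: float, amplitude: float = 1.0) -> "InputSignal":
        return cls(kind="gaussian", amplitude=amplitude, mu=mu, zeta=zeta)

    @classmethod
    def delta(cls, weight: float = 1.0) -> "InputSignal":
        return cls(kind="delta", weight=weight)

    @classmethod
    def custom(cls, fn: Callable, amplitude: float = 1.0) -> "InputSignal":
        return cls(kind="custom", amplitude=amplitude, fn=fn)

    # -- evaluation --------------------------------------------------------
    def evaluate(self, t: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        """Pointwise value R(t).  Not defined for the delta kind."""
        t = np.asarray(t, dtype=float)
        if self.kind == "step":
            out = self.amplitude * np.ones_like(t)
        elif self.kind == "exponential":
            out = self.amplitude * np.exp(-self.lam * t)
        elif self.kind == "periodic":
            if self.waveform == "one_minus_cos":
                out = self.amplitude * (1.0 - np.cos(self.omega * t))
            else:
                out = self.amplitude * (1.0 + np.sin(self.omega * t))
        elif self.kind == "gaussian":
            out = self.amplitude * np.exp(-((t - self.mu) ** 2) / (2.0 * self.zeta**2))
        elif self.kind == "custom":
            out = self.amplitude * np.asarray(self.fn(t), dtype=float)
        else:  # delta
            raise ValueError("a Dirac-delta input has no pointwise values; handle it via its weight")
        out = np.where(t < 0, 0.0, out)
        return out if out.ndim else float(out)

    def __call__(self, t):
        return self.evaluate(t)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        if self.kind == "custom":
            raise ValueError("custom inputs are not JSON-serializable")
        d = {"kind": self.kind, "amplitude": self.amplitude}
        if self.kind == "exponential":
            d["lam"] = self.lam
        elif self.kind == "periodic":
            d.update(omega=self.omega, waveform=self.waveform)
        elif self.kind == "gaussian":
            d.update(mu=self.mu, zeta=self.zeta)
        elif self.kind == "delta":
            d["weight"] = self.weight
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "InputSignal":
        return cls(**d)


@dataclass(frozen=True)
class GammaModule:
    """Three-parameter lumped representation of an equal-deactivation cascade.

    The downstream output of an optimal (equal deactivation rate) cascade
    under a step input is ``(alpha_gm/beta)^n * P(n, beta t)`` where ``P`` is
    the regularized lower incomplete gamma function.  Because ``P`` accepts a
    real first argument, the cascade length ``n_real`` is a continuous
    parameter, fitted from data like a Hill coefficient.
    """

    alpha_gm: float
    beta: float
    n_real: float

    def __post_init__(self):
        for name in ("alpha_gm", "beta", "n_real"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {v}")

    @property
    def amplification(self) -> float:
        """Steady-state gain under a unit step: (alpha_gm/beta)^n."""
        log_amp = self.n_real * (math.log(self.alpha_gm) - math.log(self.beta))
        return math.exp(min(log_amp, 700.0))  # saturate instead of overflowing

    def to_dict(self) -> dict:
        return {"alpha_gm": self.alpha_gm, "beta": self.beta, "n": self.n_real}

    @classmethod
    def from_dict(cls, d: dict) -> "GammaModule":
        return cls(alpha_gm=d["alpha_gm"], beta=d["beta"], n_real=d.get("n", d.get("n_real")))


@dataclass(frozen=True)
class TimeCourse:
    """A sampled trajectory: strictly increasing times and matching values.

    ``values`` is 1-D for a single observed output or 2-D ``(len(times), n)``
    for all species (the cascade output is the last column).
    """

    times: np.ndarray
    values: np.ndarray
    noise_sd: Optional[float] = None
    seed: Optional[int] = None

    def __init__(self, times, values, noise_sd=None, seed=None):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise ValueError("times must be a nonempty 1-D array")
        if np.any(times < 0):
            raise ValueError("times must be nonnegative")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if values.shape[0] != times.shape[0] or values.ndim not in (1, 2):
            raise ValueError(f"values shape {values.shape} does not match times shape {times.shape}")
        if noise_sd is not None and noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "noise_sd", None if noise_sd is None else float(noise_sd))
        object.__setattr__(self, "seed", None if seed is None else int(seed))

    @property
    def output(self) -> np.ndarray:
        """The observed output series (last species if all are stored)."""
        return self.values if self.values.ndim == 1 else self.values[:, -1]

    def __len__(self) -> int:
        return int(self.times.size)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_rate_matrix(spec: CascadeSpec) -> np.ndarray:
    """Lower-bidiagonal rate matrix of the driven linear system.

    Diagonal entries are ``-beta_i``; the first subdiagonal holds the
    linearized activation rates ``alpha_2..alpha_n`` coupling each species to
    the one upstream.  The drive ``alpha_1 R(t)`` enters through the first
    canonical basis vector and is handled by the integrators, not here.
    """
    A = np.diag(-spec.beta)
    if spec.n > 1:
        idx = np.arange(1, spec.n)
        A[idx, idx - 1] = spec.alpha[1:]
    return A


def geometric_mean_activation(spec: CascadeSpec, k: Optional[int] = None) -> float:
    """Geometric mean of the first ``k`` activation rates, ``(prod alpha_i)^(1/k)``.

    Computed in log space so that long cascades cannot overflow.
    """
    if k is None:
        k = spec.n
    k = int(k)
    if not 1 <= k <= spec.n:
        raise ValueError(f"k must satisfy 1 <= k <= {spec.n}, got {k}")
    return float(np.exp(np.mean(np.log(spec.alpha[:k]))))


def asymptotic_gain(spec: CascadeSpec) -> float:
    """Steady-state output under a unit step input: ``prod(alpha)/prod(beta)``."""
    return float(np.exp(np.sum(np.log(spec.alpha)) - np.sum(np.log(spec.beta))))
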