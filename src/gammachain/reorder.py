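"""Reordering and lumping of cascades, and perturbed-tail closed forms.

The transfer function of a linear cascade is ``prod(alpha_i) / prod(s +
beta_i)``: a product over stages, so permuting the deactivation rates leaves
the *final* output unchanged (intermediate species do change).  Blocks of
equal (or nearly equal) deactivation rates can therefore be reordered
upstream and lumped into gamma modules; a single stage with a perturbed rate
``beta + eps`` can be moved to the tail, where its response to step and
exponentially decaying inputs has a closed form driven by the lumped block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special as sps

from .analytic import exponential_solution, reg_lower_gamma_scaled, step_solution
from .cascade import CascadeSpec, GammaModule, InputSignal, geometric_mean_activation
from .numerics import convolve_response, hypoexponential_kernel, integrate_linear, step_response_matrix_form

__all__ = [
    "LumpedCascade",
    "reorder_check",
    "lump",
    "evaluate_lumped",
    "perturbed_step_solution",
    "perturbed_exponential_solution",
]

# switch to the confluent series branch when the decay rate of the input is
# this close (relatively) to the tail's total deactivation rate beta + eps,
# the removable singularity of the general formula
_CONFLUENT_RTOL = 1e-8


@dataclass(frozen=True)
class LumpedCascade:
    """Coarse-grained cascade: ordered gamma-module blocks plus optional tail.

    ``blocks`` each summarize a group of stages sharing a deactivation rate;
    ``tail`` holds a single perturbed stage ``(alpha_tail, epsilon)`` whose
    deactivation rate is ``blocks[0].beta + epsilon``.  Block lengths (plus
    the tail) always add up to the original cascade length.
    """

    blocks: tuple[GammaModule, ...]
    tail_alpha: Optional[float] = None
    tail_epsilon: Optional[float] = None

    @property
    def has_tail(self) -> bool:
        return self.tail_alpha is not None

    @property
    def total_length(self) -> float:
        return sum(b.n_real for b in self.blocks) + (1 if self.has_tail else 0)


def reorder_check(
    spec: CascadeSpec,
    permutation: Sequence[int],
    signal: InputSignal,
    times: Sequence[float],
    tol: float = 1e-12,
) -> float:
    """Sup-norm difference of the *final* output under a beta permutation.

    Activation rates stay in place (preserving their product); only the
    deactivation rates are permuted.  The returned difference should be at
    solver tolerance — the Laplace-domain product commutes — even though
    intermediate species trajectories genuinely differ.  Both orderings are
    solved independently (matrix exponential for a step, high-accuracy ODE
    integration otherwise), so the check is not circular.
    """
    permuted = spec.with_permuted_beta(permutation)
    times = np.asarray(times, dtype=float)
    if signal.kind == "step":
        a = step_response_matrix_form(spec, times, amplitude=signal.amplitude)[:, -1]
        b = step_response_matrix_form(permuted, times, amplitude=signal.amplitude)[:, -1]
    else:
        a = integrate_linear(spec, signal, times, tol=tol).values[:, -1]
        b = integrate_linear(permuted, signal, times, tol=tol).values[:, -1]
    return float(np.max(np.abs(a - b)))


def lump(spec: CascadeSpec, rate_tolerance: float = 1e-8) -> LumpedCascade:
    """Group stages with near-equal deactivation rates into gamma modules.

    Rates within relative distance ``rate_tolerance`` form one block whose
    module has the group's common rate, the geometric mean of the activation
    rates assigned to it, and integer length equal to the group size.
    Activation rates are assigned to blocks in their original order (only
    the deactivation rates are reordered, which leaves the final output
    unchanged).  When exactly one stage stands apart from a single main
    block it becomes a perturbed tail with ``epsilon = beta_tail - beta``.
    Blocks are ordered by decreasing size (ties by rate).
    """
    beta = spec.beta
    order = np.argsort(beta)
    clusters: list[list[int]] = []
    for idx in order:
        b = beta[idx]
        if clusters and abs(b - beta[clusters[-1][-1]]) <= rate_tolerance * max(abs(b), abs(beta[clusters[-1][-1]])):
            clusters[-1].append(idx)
        else:
            clusters.append([idx])
    clusters.sort(key=lambda c: (-len(c), float(np.mean(beta[c]))))

    tail_alpha = tail_eps = None
    if len(clusters) == 2 and len(clusters[1]) == 1 and len(clusters[0]) == spec.n - 1:
        tail_cluster = clusters.pop()
        tail_alpha = float(spec.activation_rates[-1])
        tail_eps = float(np.mean(beta[tail_cluster]) - np.mean(beta[clusters[0]]))

    # assign activation rates to blocks in original order
    blocks = []
    alpha = spec.alpha if tail_alpha is None else spec.alpha[:-1]
    start = 0
    for c in clusters:
        m = len(c)
        a_gm = float(np.exp(np.mean(np.log(alpha[start:start + m]))))
        blocks.append(GammaModule(alpha_gm=a_gm, beta=float(np.mean(beta[c])), n_real=float(m)))
        start += m
    return LumpedCascade(blocks=tuple(blocks), tail_alpha=tail_alpha, tail_epsilon=tail_eps)


def evaluate_lumped(lc: LumpedCascade, signal: InputSignal, times: Sequence[float]) -> np.ndarray:
    """Final output of a lumped cascade.

    Single block: gamma closed form (step/exponential) or the equal-rate
    kernel path.  Block plus perturbed tail under step/exponential input:
    the perturbed closed forms.  Anything else falls back to the
    hypoexponential kernel built from the blocks.
    """
    times = np.asarray(times, dtype=float)
    if len(lc.blocks) == 1 and not lc.has_tail:
        m = lc.blocks[0]
        if signal.kind == "step":
            return np.asarray(step_solution(m, times, amplitude=signal.amplitude))
        if signal.kind == "exponential":
            return np.asarray(exponential_solution(m, signal.lam, times, amplitude=signal.amplitude))
    if len(lc.blocks) == 1 and lc.has_tail:
        m = lc.blocks[0]
        if signal.kind == "step":
            return signal.amplitude * np.asarray(
                perturbed_step_solution(m, lc.tail_alpha, lc.tail_epsilon, times))
        if signal.kind == "exponential":
            return signal.amplitude * np.asarray(
                perturbed_exponential_solution(m, lc.tail_alpha, lc.tail_epsilon, signal.lam, times))
    # generic fallback: reassemble an equivalent spec and use the kernel
    rates_a, rates_b = [], []
    for b in lc.blocks:
        mult = int(round(b.n_real))
        rates_a.extend([b.alpha_gm] * mult)
        rates_b.extend([b.beta] * mult)
    if lc.has_tail:
        rates_a.append(lc.tail_alpha)
        rates_b.append(lc.blocks[0].beta + lc.tail_epsilon)
    spec = CascadeSpec(len(rates_a), rates_a, rates_b)
    kern = hypoexponential_kernel(spec)
    return convolve_response(kern, signal, times).output


def _check_tail(block: GammaModule, alpha_tail: float, epsilon: float) -> float:
    if alpha_tail <= 0:
        raise ValueError(f"alpha_tail must be positive, got {alpha_tail}")
    c = block.beta + epsilon
    if c <= 0:
        raise ValueError(f"tail deactivation rate beta + epsilon must be positive, got {c}")
    return c


def perturbed_step_solution(block: GammaModule, alpha_tail: float, epsilon: float, t) -> np.ndarray:
    """Tail species response to a unit step through an n-block plus one
    perturbed stage.

    The tail obeys ``y' = alpha_tail * x_n(t) - (beta+eps) y`` with
    ``x_n(t) = (alpha_gm/beta)^n P(n, beta t)``; variation of constants
    gives

        y(t) = alpha_tail*(alpha_gm/beta)^n/(beta+eps) *
               [ P(n, beta t) - (beta t)^n e^{-(beta+eps)t} S(n, -eps t) ]

    with ``S(n,z) = P(n,z)/z^n`` the entire scaled function.  At ``eps = 0``
    this collapses (via the gamma recurrence) to the step solution of the
    (n+1)-stage module including the tail rate; as ``t -> inf`` it
    approaches ``alpha_tail*(alpha_gm/beta)^n/(beta+eps)``.
    """
    c = _check_tail(block, alpha_tail, epsilon)
    ts = np.asarray(t, dtype=float)
    if np.any(ts < 0):
        raise ValueError("t must be nonnegative")
    n, b = block.n_real, block.beta
    flat = np.atleast_1d(ts)
    s = np.real(np.atleast_1d(np.asarray(reg_lower_gamma_scaled(n, -epsilon * flat))))
    bracket = sps.gammainc(n, b * flat) - (b * flat) ** n * np.exp(-c * flat) * s
    out = alpha_tail * block.amplification / c * bracket
    return float(out[0]) if ts.ndim == 0 else out.reshape(ts.shape)


def perturbed_exponential_solution(block: GammaModule, alpha_tail: float, epsilon: float,
                                   lam: float, t) -> np.ndarray:
    """Tail species response to ``R(t) = e^{-lam t}`` through a perturbed tail.

    With ``x_n`` the block's exponential-input gamma solution, variation of
    constants yields

        y(t) = alpha_tail * alpha_gm^n t^n / (beta+eps-lam) *
               [ e^{-lam t} S(n,(beta-lam)t) - e^{-(beta+eps)t} S(n,-eps t) ]

    whose only removable singularity is at ``lam = beta + eps``; near it the
    confluent branch

        y(t) = alpha_tail * alpha_gm^n e^{-(beta+eps)t} t^{n+1} *
               [ S(n,-eps t) - n S(n+1,-eps t) ]

    is used instead.  The expression is entire in ``eps`` and continuous in
    ``lam`` across ``lam = beta`` (for ``eps = 0`` the two confluences
    coincide, the equal-rate case).
    """
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    c = _check_tail(block, alpha_tail, epsilon)
    ts = np.asarray(t, dtype=float)
    if np.any(ts < 0):
        raise ValueError("t must be nonnegative")
    n, b, a = block.n_real, block.beta, block.alpha_gm
    flat = np.atleast_1d(ts)
    s_eps = np.real(np.atleast_1d(np.asarray(reg_lower_gamma_scaled(n, -epsilon * flat))))
    if abs(c - lam) < _CONFLUENT_RTOL * c:
        s_eps1 = np.real(np.atleast_1d(np.asarray(reg_lower_gamma_scaled(n + 1.0, -epsilon * flat))))
        out = (alpha_tail * np.exp(n * math.log(a) - c * flat) * flat ** (n + 1.0)
               * (s_eps - n * s_eps1))
    else:
        s_lam = np.real(np.atleast_1d(np.asarray(reg_lower_gamma_scaled(n, (b - lam) * flat))))
        out = (alpha_tail * np.exp(n * math.log(a)) * flat**n / (c - lam)
               * (np.exp(-lam * flat) * s_lam - np.exp(-c * flat) * s_eps))
    return float(out[0]) if ts.ndim == 0 else out.reshape(ts.shape)
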