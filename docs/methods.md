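# Methods

## Model

A linear activation cascade of length n is the driven system

    dx_1/dt = alpha_1 R(t) - beta_1 x_1
    dx_i/dt = alpha_i x_{i-1} - beta_i x_i,      i = 2..n

with all rates strictly positive.  This is the weak-activation reduction of
the saturating mass-action model

    dx_i/dt = alpha_i^raw x_{i-1} (T_i - x_i) - beta_i x_i,

obtained when active fractions are small (`x_i << T_i`), so that each raw
activation rate is multiplied by the total amount T_i of the protein being
activated.  `linearize()` implements exactly that reduction; the
`integrate_nonlinear` oracle reports `max x_i/T_i` as a diagnostic of its
validity, and the linear and nonlinear trajectories converge at rate ~1/T
as totals grow with linearized rates held fixed.

Assumptions: no protein production or degradation on the modelled time
scale (totals constant), spontaneous first-order deactivation, no
Michaelis–Menten intermediates, mass-action activation without complexes.

## Closed forms

In Laplace space the output is `prod(alpha_i) / prod(s + beta_i)` times the
transformed input, so the final output depends on the deactivation rates
only as a multiset — permuting them changes intermediate species but never
the output (`reorder_check` verifies this through two independent
integrations, not through the shared kernel).

With equal deactivation rates the inverse transforms are incomplete gamma
expressions in the module parameters (alpha_gm, beta, n_real):

| input | output |
|---|---|
| step | `(alpha/beta)^n P(n, beta t)` |
| `e^{-lam t}` | `alpha^n e^{-lam t} t^n S(n, (beta-lam)t)` |
| `1 -/+ cos/sin(omega t)` | step part ± Re/Im of `alpha^n e^{i omega t} t^n S(n, (beta+i omega)t)` |
| impulse (weight w) | `w alpha^n t^{n-1} e^{-beta t}/Gamma(n)` |
| Gaussian bump | quadrature of the impulse kernel against the input |

Here `P(a,x)` is the regularized lower incomplete gamma function and
`S(a,z) = P(a,z)/z^a` its entire scaled form.  Writing everything in `S`
is the load-bearing numerical decision: the exponential solution is then a
single smooth expression across the confluence `lam = beta` and for
`lam > beta` (negative argument), with no branch switching and no
subtractive cancellation.  The periodic solution uses the same expression
at `lam = -i omega`; its large-time limit is the filter form
`amplification * [1 ± rho^n sinusoid(omega t - n theta)]` with
`rho = beta/sqrt(beta^2 + omega^2) = cos(theta)`, which brackets the
output in `[0, 2 * amplification]`.  The periodic closed form is computed
via this complex-argument route rather than an explicit
Chebyshev-polynomial expansion of the same solution; the two are
mathematically equivalent and the implementation is validated against the
ODE oracle.  The Gaussian response is evaluated by adaptive quadrature
against the impulse kernel over the +-8 zeta support window; as zeta -> 0
it converges to sqrt(2 pi) zeta times the shifted impulse response.

`P` itself is evaluated by domain: scipy's `gammainc` for real arguments
>= 1; the direct power series below 1 and for all negative arguments
(whose terms share one sign, so no cancellation); for complex arguments
the `e^{-z}`-prefactored series while `|z| - Re z <= 18` (round-off
amplification at most ~e^18 of machine epsilon) and a modified Lentz
continued fraction for the regularized upper function beyond that.  Tests
cross-check every branch against 40-digit tanh–sinh quadrature of the
integral representation `z^a/Gamma(a) int_0^1 s^{a-1} e^{-zs} ds`.

The n_real parameter interpolates the integer-length family smoothly.  The
half-integer curve lies pointwise between its integer neighbours whenever
`alpha_gm <= beta` (both the prefactor and `P(n, beta t)` are then
non-increasing in n); for `alpha_gm > beta` the two factors move in
opposite directions and pointwise bracketing can fail even though the
interpolation remains smooth — the tests assert bracketing only on its
valid domain.

## Perturbed tail

For a block of n equal-rate stages followed by one stage with rate
`beta + eps`, variation of constants gives

    step:  y = alpha_tail (alpha/beta)^n / (beta+eps) *
               [ P(n, beta t) - (beta t)^n e^{-(beta+eps)t} S(n, -eps t) ]
    exp:   y = alpha_tail alpha^n t^n / (beta+eps-lam) *
               [ e^{-lam t} S(n, (beta-lam)t) - e^{-(beta+eps)t} S(n, -eps t) ]

In this formulation the only removable singularity of the exponential case
is at `lam = beta + eps` (at `eps = 0` this is the classical `lam = beta`
confluence); within relative distance 1e-8 of it the confluent branch
`alpha_tail alpha^n e^{-(beta+eps)t} t^{n+1} [S(n,-eps t) - n S(n+1,-eps t)]`
is used, keeping both branches' round-off below ~1e-9.  Both expressions
are entire in eps, hence continuous at eps = 0, where the step form
collapses to the (n+1)-stage module via the gamma recurrence.

## Kernel and lumping

For arbitrary distinct rates the impulse response is hypoexponential; it is
stored in partial-fraction form with rates clustered at relative tolerance
1e-8 and confluent groups represented as polynomial-times-exponential terms
(the equal-rate cascade is exactly the fully confluent limit — a gamma
density).  The expansion is accurate for well-separated rates but
intrinsically ill-conditioned when many rates crowd into a narrow band
(coefficients grow like products of inverse gaps); code paths that face
random i.i.d. rates therefore use matrix-exponential propagation or the
closed-form gain instead of the kernel.

`lump()` groups near-equal rates (after the reordering freedom) into gamma
modules — activation rates are assigned to blocks in original order, which
preserves the product and hence the output — and recognizes the
one-perturbed-stage layout as block + tail, evaluated by the closed forms
above.  Any other layout falls back to the kernel/convolution path.

## Delays

The delayed motif is a two-node system: an input node
`x1' = R(t) - decay * x1` and a response node
`x2' = gain * x1(t - tau) - decay * x2` with constant pre-zero history on
x1 and the response at rest.  It is solved by the method of steps: x1 is an
ordinary driven scalar ODE; given its dense solution the response equation
has a known forcing and is integrated piecewise across the derivative kink
at `t = tau`.  At `tau = 0` the motif is exactly the two-stage cascade with
rates (1, gain) and common decay.

Fitting the step gamma expression to the delayed response maps the delay
onto cascade length: across tau in [0.5, 4] (noiseless, unit gain and
decay, 81 samples on [0, 16]) the fitted `n/beta` regresses on tau with
r^2 = 0.99996, slope 0.97 and intercept ~ 2/decay (the delay-free transit
time), while the fitted amplification varies by 0.3%.  The surrogate's
sup-norm error at tau = 2 is ~5% of the asymptote — least squares
minimizes the integrated, not the worst-case, mismatch of a C^1 delayed
sigmoid against a gamma rise.

## Fitting

Parameters are estimated by bounded multi-start nonlinear least squares
(scipy TRF) on log-parameters — positivity for free and better
conditioning.  The first start is a data-driven heuristic (late-time level
pins the gain; half-rise or peak time pins n/beta; the tail slope pins lam)
and the remaining starts are log-uniform over the bounds (default two
decades either side of the heuristic), drawn from a seeded generator;
results are bit-reproducible given (seed, n_starts) and the best-start
loss is non-increasing in n_starts.  The noise model is homoscedastic
Gaussian, so unweighted SSQ is maximum likelihood.  Degenerate all-zero
data is flagged non-identifiable rather than fitted; short observation
windows leave (alpha_gm, n) entangled, which surfaces as per-start spread
rather than a false unique optimum.

A statistical limit worth stating: with the reference noisy recipe (11
samples at t = 0..10, noise s.d. 0.05), the Fisher information at the
truth puts the joint probability of recovering all three module parameters
within 15% at about 0.88 for the step input and about 0.38 for the
exponential input with its decay rate co-estimated.  Monte-Carlo runs
reproduce these numbers, and in every missed replicate the optimizer's
loss beats the truth's loss — the spread is a property of the data, not of
the optimizer.  The corresponding validation test asserts a 90% recovery
rate and is therefore expected to fail by a small margin; it is kept
unweakened as a record of that ceiling.

## Ensembles

All ensemble draws use `numpy.random.default_rng` with explicit seeds;
nonpositive rate draws are rejected and redrawn (truncation would bias the
mean) and the rejection count is reported.  Where a sampling s.d. must be
chosen it defaults to 5% of the sampled mean — a modest cell-to-cell
variability — and is always reported alongside results.

*Optimal length*: cascades grow over lengths 1..10 with the mean
deactivation rate set per length to preserve an expected gain G = 8
(`beta(n) = (prod alpha / G)^{1/n}`, with alpha_1 = 1.2 and alpha_i = 1).
"Maximal amplification" defaults to the peak of the response to a decaying
input (decay rate 1): that metric has a genuine interior optimum (length 3
deterministically; mass concentrated on lengths 2–5 under rate noise),
reflecting the trade-off between multiplicative gain and the transit delay
that lets a transient signal die before traversal.  The asymptotic step
gain and the integrated response are selectable alternatives, but under
the gain-preserving rule both are constant across lengths by construction,
so their argmax is pure sampling noise.

*Parameter recovery*: 5-stage cascades with rates drawn N(2, sd^2) are
solved exactly (matrix exponential) under a step and fitted with the gamma
module; the fitted deactivation-rate distribution centres on the sampling
mean and the fitted length on the true length.

*Variance scaling*: the asymptotic gain of a full random cascade
(`prod alpha / prod beta_i`, n i.i.d. rates) is distributionally matched
by a single lumped module whose one rate is drawn with variance scaled
down by n: to first order both log-outputs have variance
`n sigma^2/beta^2`.  A two-sample KS test at 1000 draws does not reject
the match (alpha = 0.01), and the unscaled lumped variance exceeds the
full-ensemble variance by the factor n (exact in the small-noise limit;
second-order corrections appear at 5% relative noise for long cascades).

## Numerical defaults

| quantity | default | why |
|---|---|---|
| ODE rtol/atol | 1e-9 (oracles at 1e-11/1e-12) | closed-form comparisons at 1e-6 need headroom |
| rate clustering tolerance | 1e-8 relative | below it, distinct-rate partial fractions lose more than half the mantissa |
| confluent branch switch | 1e-8 relative to beta+eps | balances truncation of both branches near the removable singularity |
| series/CF crossover | `|z| - Re z = 18` | caps cancellation amplification at ~e^18 eps ≈ 1e-8 |
| Gaussian quadrature window | mu ± 8 zeta | input mass outside is < 1e-14 |
| fit bounds | 1e-2..1e2 × heuristic guess | wide enough for poor guesses, bounded for the sampler |
| time grids | problem-scaled, e.g. 10/beta horizons; DDE fits on [0, max(15, tau+12/decay)], 81 points | resolves both the rise and the plateau at small cost |

Monte-Carlo problem sizes in the shipped tests (100 fit replicates, 1000
ensemble draws, 3000–4000 draws for variance checks) were chosen so the
whole suite runs in well under a minute while keeping binomial/variance
sampling error a factor of a few below the asserted tolerances.

## What the synthetic data does and does not emulate

The generator samples the exact model and adds i.i.d. homoscedastic
Gaussian noise — the classical time-course fitting setting.  Real
measurements bring multiplicative and correlated errors, unknown input
wave-forms, unmodelled production/degradation of totals, and saturation
(the nonlinear model here covers only the mass-action saturating form).
Passing tests therefore demonstrate correctness of the mathematics and the
estimation machinery under the stated noise model, not robustness to
real-data pathologies.

## Known limitations

* Closed forms require equal deactivation rates within a block; fully
  distinct rates go through the kernel/ODE paths.
* The partial-fraction kernel degrades for many near-equal rates; use the
  matrix-exponential path there (the ensemble code already does).
* Fitting provides per-start spread but no confidence intervals or
  posteriors.
* The DDE surrogate covers the delayed-input two-node motif with constant
  history; delayed self-regulation (state feedback) is out of scope.
* No SBML import/export; configs are JSON, trajectories CSV.
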