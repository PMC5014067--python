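# gammachain

Analytical solutions and gamma-module coarse-graining of weakly activated
signalling cascades.

## The problem

Signal transduction frequently proceeds through *activation cascades*: a
stimulus R(t) activates the first protein of a chain, each active protein
activates the next, and every protein deactivates spontaneously.  In the
weakly activated regime (active fractions small compared with total
protein), the kinetics linearize into the driven system

    dx/dt = A x + alpha_1 R(t) e_1,

where **A** is lower-bidiagonal with `-beta_i` on the diagonal and the
activation rates `alpha_i` on the subdiagonal.  Modellers who need the
*output* of such a chain — for fitting time courses, for embedding a
pathway module in a larger ODE model, or for representing a delay — face an
n-dimensional system with up to n+2 parameters even though the observable
is one curve.

## The core result

When all deactivation rates are equal (`beta_i = beta`, the configuration
that delivers a required gain most efficiently), the entire chain collapses
exactly to a **three-parameter gamma module**.  Under a unit step input the
output of the n-th protein is

    x_n(t) = (alpha_(n) / beta)^n  P(n, beta t),

where `alpha_(n) = (prod_i alpha_i)^(1/n)` is the geometric-mean activation
rate and `P(a, x) = gamma(a, x)/Gamma(a)` is the regularized lower
incomplete gamma function.  Because `P` accepts a *real* first argument,
the cascade length n becomes a continuous parameter, fitted from data
exactly like a Hill coefficient.  Closed forms of the same family cover
exponentially decaying inputs (`P(n, (beta-lam)t)`, valid through and
beyond `lam = beta` via an entire-function formulation), periodic inputs
(complex argument `(beta + i omega)t`, giving low-pass filter behaviour
with attenuation `rho^n = (beta^2/(beta^2+omega^2))^(n/2)` and phase lag
`n atan(omega/beta)`), impulses (the gamma density) and Gaussian bumps.

Around this core the package provides:

* **numerics** — independent oracles: ODE integration of the nonlinear and
  linearized systems, matrix-exponential step responses, the general
  hypoexponential kernel with confluent (repeated-rate) handling, and a
  method-of-steps integrator for a delayed two-node motif;
* **reordering and lumping** — permuting deactivation rates never changes
  the final output, so equal-rate blocks can be lumped into gamma modules
  and a single rate-perturbed protein moved to the tail, where its response
  has its own closed form;
* **fitting** — seeded multi-start nonlinear least squares for the module
  parameters (including the real-valued length) and gamma surrogates for
  delay differential equations: the fitted ratio `n/beta` tracks the true
  delay linearly;
* **ensembles** — Monte-Carlo experiments for cascades with random
  deactivation rates: optimal-length histograms, parameter-recovery
  distributions, and the 1/n variance scaling that lets one lumped module
  reproduce the output variability of a whole random ensemble;
* **io/cli** — CSV time courses, JSON configs, a seeded synthetic-data
  generator and a `gammachain` command-line tool.

## Worked example

Take the reference five-stage cascade with activation rates (3, 4, 4, 4, 4)
and common deactivation rate beta = 3:

```python
import numpy as np
import gammachain as gc

spec = gc.CascadeSpec(5, (3, 4, 4, 4, 4), (3, 3, 3, 3, 3))
m = spec.to_gamma_module()
print(round(m.alpha_gm, 4), round(m.amplification, 4))
# 3.7764 3.1605

# noisy observations of the full model, then a 3-parameter gamma fit
data = gc.generate_synthetic(m, gc.InputSignal.step(), np.arange(0, 11.0),
                             noise_sd=0.05, seed=7)
fit = gc.fit_gamma_model(data, "step", n_starts=10, seed=7)
print({k: round(float(v), 3) for k, v in fit.params.items()})
# {'alpha_gm': 3.567, 'beta': 2.79, 'n_real': 4.68}
```

The geometric-mean rate 3.776 and step amplification 3.1605 are exact
properties of the chain; the fitted `(alpha_gm, beta, n_real)` land within
a few percent of the generating values despite the noise, with the length
estimated as a real number from a single trajectory.

Replacing a delay differential equation with a gamma module:

```python
res = gc.tau_scaling_experiment([0.5, 1, 1.5, 2, 2.5, 3, 3.5, 4],
                                gain=1.0, decay=1.0, n_starts=8, seed=17)
print(round(res.slope, 3), round(res.intercept, 3), round(res.r_squared, 5))
# 0.973 1.957 0.99996
```

The fitted `n/beta` grows linearly with the true delay tau (slope near 1,
intercept the delay-free transit time 2/decay), while the fitted
amplification stays constant to 0.3% — a delay is a cascade of the right
real-valued length.

Equivalent CLI session:

```bash
gammachain synth --config cascade.json --times 0:10:1 --noise-sd 0.05 --seed 7 --out data.csv
gammachain fit --data data.csv --input step --starts 10 --seed 7 --out fit.json
gammachain ddefit --tau-grid 0.5:4:0.5 --seed 17 --out dde.json
```

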