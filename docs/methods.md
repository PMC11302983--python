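# Methods

## Model overview

`effsyn` models synaptic transmission as noisy and asks how a neural
circuit should spend energy on making it precise.  Three layers of
theory are implemented:

1. **Biophysics.** A synaptic connection holds `n` docked vesicles,
   each released with probability `p`, each contributing a quantal PSP
   of size `q`, giving the binomial moments mu = n p q and
   sigma^2 = n p (1 - p) q^2.  Four mechanisms for buying precision at
   fixed mean — calcium-pump work, vesicle membrane surface area, actin
   scaffolding, and per-vesicle trafficking — each induce an energetic
   cost that is an exact power law in the PSP standard deviation,
   cost ∝ sigma^(-rho) with rho = 1/2, 2/3, 4/3 and 2 respectively.
2. **Circuit objective.** A feedforward ReLU rate network with Gaussian
   synapses w_i ~ Normal(mu_i, sigma_i) is trained to minimise
   performance cost (cross-entropy) + lambda * sum|mu_i| (magnitude)
   + c * sum sigma_i^(-rho) (reliability).  Both mu_i and sigma_i are
   learned through the reparameterisation w_i = mu_i + sigma_i * xi.
3. **Bayesian connection.** The optimal noise under a local quadratic
   approximation is sigma*_i = (c rho / H_ii)^(1/(rho+2)), where H_ii is
   the performance-cost curvature at the optimum.  A Laplace posterior
   has sigma_post = H_ii^(-1/2), so log sigma* is linear in
   log sigma_post with slope 2/(rho+2) < 1: energy-efficient
   variability tracks posterior uncertainty but is compressed.
   Moreover the power-law cost with c = s^rho/rho upper-bounds the
   entropic (negative-entropy) penalty of the variational ELBO with
   equality at sigma = s, so the overall cost bounds the negative ELBO
   up to computable constants.

## Cost-curve eliminations

Each cost sweep holds the PSP mean fixed and varies one biophysical
variable:

* **calcium** — sweep `p` (set by calcium through the Hill relation
  p = Ca^m/(K^m + Ca^m)); `n` is held fixed and the quantal size
  q = mu/(n p) absorbs the mean constraint.  Then
  sigma^2 = mu^2 (1-p)/(n p), hence cost ∝ Ca ∝ (p/(1-p))^(1/m)
  = (mu^2/n)^(1/m) sigma^(-2/m): an exact power law for all p, giving
  the exponent -1/2 at the default cooperativity m = 4.  (Eliminating
  the constraint through `n` at fixed `q` instead gives
  sigma^2 = mu q (1-p) and a fitted slope of -1/(2 p-bar), i.e. only
  asymptotically -1/2 as p -> 1; the `q`-elimination is used because
  the exponent is the model's claim, not an asymptote of a particular
  sweep.)  The default fitting window is still the high-p segment
  p in [0.9, 0.999].
* **surface / actin / trafficking** — sweep vesicle radius `r` at fixed
  `p`, with q = r^3 (vesicle volume scales quantal size) and
  n = mu/(p r^3).  Costs n r^2, n r and n give exponents -2/3, -4/3
  and -2.

All proportionality constants are 1 and costs are in arbitrary units:
only the scalings are claimed.  Each curve's constrained mean is
re-checked to 1e-10 relative; tests verify the curves pointwise against
hand-derived closed forms.

## Training

Optimisation is plain minibatch SGD with Adam-style per-parameter
adaptive rates, implemented with explicit reverse-mode gradients for
the fixed MLP architecture (the networks involved are small enough
that a framework would add nothing but a dependency; everything is
numpy and exactly reproducible from the seed).  sigma_i = softplus(phi_i)
keeps noise positive structurally; the gradient of sigma^(-rho) uses a
floor of 1e-8 on sigma *inside the gradient only* to avoid overflow at
the homogeneous initialisation sigma = 1e-4 (reported sigmas are never
floored).  One weight realisation is drawn per minibatch and resampled
every step; per-example sampling is available as an option.  Biases are
deterministic, trained, and excluded from magnitude and reliability
costs (the costs are sums over synapses).  In homogeneous mode a single
shared phi replaces the per-synapse array and accumulates the summed
noise gradient, so all synapses carry exactly one sigma.

Default hyperparameters are the full-scale study settings: base rate
5e-4, minibatch 20, 50 epochs, mu ~ Uniform(-0.1, 0.1), sigma
initialised at 1e-4, lambda = 1e-4, Adam decays (0.9, 0.999).

### Desk-scale study settings

The shipped experiments run a reduced task — 4 classes, 100 features,
4000 samples, widths 100-32-32-4 — chosen so a full c-sweep finishes in
about a minute.  Two optimiser settings are scaled together with the
problem: the base rate is 5e-3 and the second-moment decay is 0.99
(instead of 0.999).  The reason is mechanical: from sigma = 1e-4 the
reliability gradient falls by many orders of magnitude en route to the
optimum, and a long second-moment window makes the adaptive denominator
remember stale gradient scales, throttling each phi step to a small
fraction of the base rate.  The full-scale settings compensate with
~125k steps; at ~8k steps the shorter window and larger rate preserve
the same total parameter travel.  The c grid for the tradeoff runs is
[0, 2e-4, 1e-3, 5e-3] at rho = 2, spanning negligible-to-dominant
reliability pressure for this task.

### Quadratic-toy training

`train_quadratic` optimises (mu, phi) on a diagonal quadratic loss with
known curvature h_i, averaging the reparameterised gradient over 8
draws per step (6000 steps, Adam at 0.01).  Because the stationary
noise jitters around the optimum, the reported sigma is the tail
average over the final quarter of steps.  Recovery of
sigma* = (c rho / h)^(1/(rho+2)) is typically within 0.5% median
relative error across curvatures spanning three decades.

## Synthetic data

The classification generator emulates the two properties of digit-image
data the theory depends on: learnable class structure and per-feature
mean activations ("input rates") spanning orders of magnitude.  Each
class has a Gaussian template over features (deviations centred across
classes so that, without rate scaling, all columns share one mean
level); samples are template + Gaussian noise, clipped to [0, 1], then
multiplied by a per-feature scale drawn log-uniformly from
[10^-h, 1] with heterogeneity h = 3 by default.  What it does *not*
emulate: pixel-to-pixel spatial correlation, stroke geometry, label
noise, or any train/test distribution shift — so passing tests show the
model's qualitative behaviour under controlled rate heterogeneity, not
image-domain performance.  Splits are 80/10/10 train/val/test.  The IDX
reader allows the same pipeline to run on real digit images but nothing
requires it.

## Diagnostics

Synapse importance is the empirical Fisher H_ii ~ <g_i^2>: squared
performance-cost gradients at the noise-free weights w = mu, averaged
over 10 passes of minibatches after training.  The same <g^2> gives the
adaptive rate eta_i = eta_base/(sqrt(<g_i^2>) + eps), so
eta_i ∝ (H_ii + eps')^(-1/2) holds exactly by construction.  Input
rates are mean absolute presynaptic activations at w = mu.  The
analysed layer defaults to the second hidden layer's incoming weights.
Correlations with the optimised variance are Spearman rank coefficients
computed after dropping non-positive pairs (synapses with exactly zero
Fisher — e.g. rows of dead ReLU units — have no logarithm; the dropped
count is reported).  Signs, not magnitudes, are the claim: importance
and input rate correlate negatively with optimised variance, learning
rate positively.  The Fig.-5-style runs use s = 0.001 (hence
c = s^rho/rho) and the learning-rate proxy treats the base rate as the
gamma prefactor.

## Variational baseline

`fit_variational_posterior` runs mean-field Gaussian variational
inference (Bayes-by-backprop) on the same architecture: reparameterised
likelihood gradients plus closed-form Gaussian KL gradients against a
Normal(0, 1) prior by default — the prior is not stated in the source
experiments, and only the relative heterogeneity of sigma_post is
consumed downstream.  The 1-weight linear-Gaussian routine exists
because it has a closed-form conjugate posterior: it validates the ELBO
machinery to ~5% and cross-checks the Laplace relation
sigma_post = H^(-1/2), which is exact in the Gaussian case.  The slope
analysis uses the Laplace route by default (deterministic and cheap);
the variational fit is the cross-check.

## Numerical choices

* softplus and its inverse are computed in overflow-safe forms;
  phi = log(expm1(sigma)) switches to the identity above sigma = 30.
* Cross-entropy uses log-sum-exp; non-finite scores raise immediately,
  and a non-finite cost term aborts training naming the offending term.
* Power-law exponents are fitted by least squares on (log sigma,
  log cost); the constrained curves are exact power laws, so the fit is
  exact to floating point.
* The analytic-sigma test oracle bisects the sign change of the
  derivative of H sigma^2/2 + c sigma^(-rho) rather than minimising the
  value (value minimisers flatten out at ~1e-8 relative precision).
* Seeds: every random draw flows from a `numpy` Generator seeded by the
  caller; identical configurations reproduce bit-identical results.

## Known limitations

* Quantal size is constant within a PSP; quantal variability is not
  modelled, and no mixture of reliability mechanisms is offered.
* The empirical Fisher is a diagonal approximation; off-diagonal
  curvature is ignored throughout.
* At desk scale, many hidden-layer synapses sit behind ReLU units that
  are inactive at the mean weights, giving exactly zero Fisher; they are
  excluded from log-log analyses (counted), which shrinks the sample for
  the importance correlations.
* Homogeneous-noise accuracy collapses quickly once the shared sigma
  passes the scale of the trained weights; c grids should be read with
  that cliff in mind.
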