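"""Bayesian baselines and the analytic variability-versus-posterior theory.

Energy-efficient noise allocation gives each synapse
sigma* = (c rho / H_ii)^(1/(rho+2)) (stationary point of
H sigma^2 / 2 + c sigma^(-rho)), while a Laplace posterior gives
sigma_post = H_ii^(-1/2).  Both are power laws in H, so on log-log axes
sigma* is a linear function of sigma_post with slope exactly

    slope = 2 / (rho + 2)  <  1,

approaching 1 as rho -> 0: efficient variability is always *less*
heterogeneous than the posterior, and tracks it best for shallow
reliability-cost exponents.  A mean-field Gaussian variational fit
(reparameterised ELBO ascent) provides the sampling-based cross-check of
the Laplace route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network as net
from .datasets import Dataset
from .network import NetworkConfig, SynapseParams, sigma_from_phi, sigmoid
from .objective import performance_cost, performance_cost_grad
from .training import TrainConfig, TrainingError, _Adam

__all__ = [
    "GaussianPrior",
    "PosteriorEstimate",
    "SlopeAnalysis",
    "fit_variational_posterior",
    "fit_variational_linear_gaussian",
    "laplace_posterior_sd",
    "analytic_sigma",
    "sigma_vs_posterior_slope",
]


@dataclass(frozen=True)
class GaussianPrior:
    """Factorised Gaussian prior over weights (default standard normal)."""

    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("prior sd must be positive")


@dataclass
class PosteriorEstimate:
    """Per-synapse posterior mean and standard deviation."""

    mean: list  # per layer (or a single array for toy models)
    sd: list
    method: str  # "variational" | "laplace"
    prior: GaussianPrior
    elbo_trace: np.ndarray | None = None

    def all_sd(self) -> np.ndarray:
        return np.concatenate([np.ravel(s) for s in self.sd])


@dataclass
class SlopeAnalysis:
    """Fitted log sigma_efficient vs log sigma_post relation for one (rho, c)."""

    rho: float
    c: float
    log_sigma_post: np.ndarray
    log_sigma_eff: np.ndarray
    slope: float
    intercept: float

    @property
    def theory_slope(self) -> float:
        return 2.0 / (self.rho + 2.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rho": self.rho,
                "c": self.c,
                "log_sigma_post": self.log_sigma_post,
                "log_sigma_eff": self.log_sigma_eff,
            }
        )


def laplace_posterior_sd(H):
    """Laplace posterior standard deviation sigma_post = H^(-1/2)."""
    H = np.asarray(H, dtype=float)
    if np.any(H <= 0):
        raise ValueError("Laplace variance undefined for non-positive curvature")
    out = H**-0.5
    return float(out) if out.ndim == 0 else out


def analytic_sigma(H, c: float, rho: float):
    """Energy-efficient noise sigma* = (c rho / H)^(1/(rho+2)).

    The unique positive stationary point (and minimum) of the local
    quadratic expansion H sigma^2/2 plus the reliability cost
    c sigma^(-rho); decreasing in H, increasing in c.
    """
    H = np.asarray(H, dtype=float)
    if np.any(H <= 0) or c <= 0 or rho <= 0:
        raise ValueError("H, c and rho must be positive")
    out = (c * rho / H) ** (1.0 / (rho + 2.0))
    return float(out) if out.ndim == 0 else out


def sigma_vs_posterior_slope(
    H,
    c: float,
    rho: float,
    *,
    sigma_efficient=None,
) -> SlopeAnalysis:
    """Regress log sigma* on log sigma_post across synapses.

    With the analytic sigma* the relation is exactly linear with slope
    2/(rho+2).  Passing empirically trained sigmas as
    ``sigma_efficient`` fits the same regression on the trained values.
    """
    H = np.asarray(H, dtype=float)
    if H.size < 3:
        raise ValueError("need at least 3 H values")
    if np.unique(H).size < 2:
        raise ValueError("slope undefined when all H are equal")
    sigma_post = laplace_posterior_sd(H)
    if sigma_efficient is None:
        sigma_eff = analytic_sigma(H, c, rho)
    else:
        sigma_eff = np.asarray(sigma_efficient, dtype=float)
        if sigma_eff.shape != H.shape:
            raise ValueError("sigma_efficient must match H in shape")
        if np.any(sigma_eff <= 0):
            raise ValueError("sigma_efficient must be positive")
    lp, le = np.log(sigma_post), np.log(sigma_eff)
    slope, intercept = np.polyfit(lp, le, 1)
    return SlopeAnalysis(rho, c, lp, le, float(slope), float(intercept))


def _gaussian_kl(mu_q, sd_q, prior: GaussianPrior):
    """KL(N(mu_q, sd_q) || prior), elementwise sum, and its gradients."""
    sp2 = prior.sd**2
    d = mu_q - prior.mean
    kl = np.sum(np.log(prior.sd / sd_q) + (sd_q**2 + d**2) / (2 * sp2) - 0.5)
    dmu = d / sp2
    dsd = -1.0 / sd_q + sd_q / sp2
    return float(kl), dmu, dsd


def fit_variational_posterior(
    config: NetworkConfig,
    dataset: Dataset,
    prior: GaussianPrior = GaussianPrior(),
    train_config: TrainConfig = TrainConfig(),
    *,
    likelihood_weight: float = 1.0,
) -> PosteriorEstimate:
    """Mean-field Gaussian variational fit of the network weights.

    Maximises the ELBO = E_q[log p(labels | weights)] - KL(q || prior)
    by reparameterised stochastic ascent on per-synapse means and
    standard deviations (Bayes-by-backprop).  ``likelihood_weight``
    scales the data term; at 0 the optimum is the prior itself.
    Returns per-layer sigma_post with the per-step ELBO trace attached.
    """
    params = net.init_params(
        config,
        seed=train_config.seed,
        mu_range=train_config.mu_range,
        sigma_init=max(train_config.sigma_init, 1e-3),
    )
    x_train, y_train = dataset.subset("train")
    n_data = x_train.shape[0]
    if n_data == 0:
        raise ValueError("dataset has an empty train split")
    rng = np.random.default_rng(train_config.seed)
    shapes = [m.shape for m in params.mu]
    opt_mu = _Adam(shapes, train_config.eta_base, train_config.beta1, train_config.beta2, train_config.eps)
    opt_phi = _Adam(shapes, train_config.eta_base, train_config.beta1, train_config.beta2, train_config.eps)
    opt_bias = _Adam([b.shape for b in params.bias], train_config.eta_base, train_config.beta1, train_config.beta2, train_config.eps)

    steps_per_epoch = max(1, n_data // train_config.batch_size)
    elbo = []
    for epoch in range(train_config.epochs):
        order = rng.permutation(n_data)
        for b in range(steps_per_epoch):
            idx = order[b * train_config.batch_size : (b + 1) * train_config.batch_size]
            sample = net.sample_weights(params, rng)
            scores, acts = net.forward(x_train[idx], sample, params, cache=True)
            perf = performance_cost(scores, y_train[idx])
            delta = performance_cost_grad(scores, y_train[idx])
            gW, gb, gSig = net.backprop(delta, acts, sample)

            g_mu, g_phi = [], []
            kl_total = 0.0
            for l, shape in enumerate(shapes):
                sd = sigma_from_phi(params.phi[l])
                kl, dmu_kl, dsd_kl = _gaussian_kl(params.mu[l], sd, prior)
                kl_total += kl
                # objective per datum: lw * CE_mean + KL / N
                g_mu.append(likelihood_weight * gW[l] + dmu_kl / n_data)
                g_phi.append(
                    (likelihood_weight * gSig[l] + dsd_kl / n_data) * sigmoid(params.phi[l])
                )
            step_elbo = -likelihood_weight * n_data * perf - kl_total
            if not np.isfinite(step_elbo):
                raise TrainingError("ELBO became non-finite during variational fit")
            elbo.append(step_elbo)

            d_mu = opt_mu.step(g_mu)
            d_phi = opt_phi.step(g_phi)
            d_bias = opt_bias.step(gb)
            for l in range(len(shapes)):
                params.mu[l] -= d_mu[l]
                params.phi[l] -= d_phi[l]
                params.bias[l] -= d_bias[l] * likelihood_weight

    return PosteriorEstimate(
        mean=[m.copy() for m in params.mu],
        sd=params.sigmas(),
        method="variational",
        prior=prior,
        elbo_trace=np.asarray(elbo),
    )


def fit_variational_linear_gaussian(
    x,
    y,
    noise_sd: float,
    prior: GaussianPrior = GaussianPrior(),
    *,
    steps: int = 4000,
    lr: float = 0.01,
    n_draws: int = 8,
    seed: int = 0,
    likelihood_weight: float = 1.0,
    tail_fraction: float = 0.25,
) -> PosteriorEstimate:
    """Variational fit of the 1-weight conjugate model y = w x + noise.

    The exact posterior is Gaussian with precision
    1/sd_prior^2 + lw * sum(x^2)/noise_sd^2, so this routine has a
    closed-form oracle; it exists to validate the reparameterised ELBO
    machinery on a case where the answer is known.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size == 0:
        raise ValueError("x and y must be equal-length, non-empty")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    mu = np.array([0.0])
    phi = np.array([float(net.phi_from_sigma(prior.sd))])
    opt = _Adam([(1,), (1,)], lr, 0.9, 0.999, 1e-8)
    n_tail = max(1, int(tail_fraction * steps))
    tail_mu, tail_sd = [], []
    elbo = []
    sn2 = noise_sd**2
    for t in range(steps):
        sd = sigma_from_phi(phi)
        xi = rng.standard_normal((n_draws, 1))
        w = mu + sd * xi
        resid = w * x[None, :] - y[None, :]  # (n_draws, n_data)
        nll = 0.5 * np.sum(resid**2, axis=1) / sn2
        g_w = (resid @ x)[:, None] / sn2  # d nll / d w, per draw
        kl, dmu_kl, dsd_kl = _gaussian_kl(mu, sd, prior)
        g_mu = likelihood_weight * g_w.mean(axis=0) + dmu_kl
        g_phi = (likelihood_weight * (g_w * xi).mean(axis=0) + dsd_kl) * sigmoid(phi)
        elbo.append(float(-likelihood_weight * nll.mean() - kl))
        d_mu, d_phi = opt.step([g_mu, g_phi])
        mu -= d_mu
        phi -= d_phi
        if t >= steps - n_tail:
            tail_mu.append(mu.copy())
            tail_sd.append(sigma_from_phi(phi))
    return PosteriorEstimate(
        mean=[np.mean(tail_mu, axis=0)],
        sd=[np.mean(tail_sd, axis=0)],
        method="variational",
        prior=prior,
        elbo_trace=np.asarray(elbo),
    )


def exact_linear_gaussian_posterior(
    x, y, noise_sd: float, prior: GaussianPrior = GaussianPrior(), likelihood_weight: float = 1.0
) -> tuple[float, float]:
    """Closed-form posterior (mean, sd) of the 1-weight conjugate model."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    precision = 1.0 / prior.sd**2 + likelihood_weight * np.sum(x * x) / noise_sd**2
    mean = (prior.mean / prior.sd**2 + likelihood_weight * np.sum(x * y) / noise_sd**2) / precision
    return float(mean), float(precision**-0.5)
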