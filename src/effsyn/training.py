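"""Joint optimisation of PSP means and noise levels under the overall cost.

Every step draws synaptic weights through the reparameterisation
w = mu + sigma * xi, evaluates performance + magnitude + reliability
costs on a minibatch, and backpropagates to mu and phi.  Updates use an
Adam-style per-parameter adaptive learning rate: the effective rate of
synapse i is eta_base divided by the root-mean-squared gradient at that
synapse, so important synapses (large gradients) move slowly.

Also provides the quadratic-toy trainer used for analytic parameter
recovery — on a diagonal quadratic of curvature h, the optimal noise is
sigma* = (c rho / h)^(1/(rho+2)) — plus accuracy evaluation and the
reliability-multiplier sweep that traces the performance-energy
tradeoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import network as net
from .datasets import Dataset, QuadraticToy
from .network import (
    HETEROGENEOUS,
    HOMOGENEOUS,
    NetworkConfig,
    SynapseParams,
    sigma_from_phi,
    sigmoid,
)
from .objective import (
    ENTROPIC,
    CostBreakdown,
    CostSpec,
    magnitude_cost,
    performance_cost,
    performance_cost_grad,
    reliability_cost,
    entropic_cost,
)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "TrainingError",
    "train",
    "train_quadratic",
    "evaluate_accuracy",
    "sweep_c",
]


class TrainingError(RuntimeError):
    """Raised when the objective diverges; names the offending term."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    Defaults are the full-scale study settings: base rate 5e-4,
    minibatch 20, 50 epochs, mu ~ Uniform(-0.1, 0.1), sigma initialised
    homogeneously at 1e-4.
    """

    eta_base: float = 5e-4
    batch_size: int = 20
    epochs: int = 50
    mu_range: float = 0.1
    sigma_init: float = 1e-4
    seed: int = 0
    noise_mode: str = HETEROGENEOUS
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    g2_decay: float = 0.999  # running <g^2> window for diagnostics / Eq.-7 rates
    sigma_grad_floor: float = 1e-8  # floor inside the reliability gradient only
    per_example_sampling: bool = False
    eval_noise_samples: int = 10

    def __post_init__(self) -> None:
        if self.eta_base <= 0 or self.batch_size < 1 or self.sigma_init <= 0:
            raise ValueError("eta_base > 0, batch_size >= 1, sigma_init > 0 required")


@dataclass
class TrainHistory:
    """Per-epoch records plus per-synapse running gradient statistics."""

    records: list = field(default_factory=list)
    g2: list | None = None  # per layer, running mean square of dL/dw

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def final(self) -> dict:
        return self.records[-1]


class _Adam:
    """Per-array Adam state; handles scalars via 0-d arrays."""

    def __init__(self, shapes, lr, beta1, beta2, eps):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        out = []
        for i, g in enumerate(grads):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            out.append(self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps))
        return out


def _reliability_sigma_grad(sigma, spec: CostSpec, floor: float):
    """d(reliability cost)/d(sigma), with sigma floored to keep the
    power-law gradient finite near zero.  The floor never touches the
    reported sigma values."""
    s = np.maximum(sigma, floor)
    if spec.reliability_form == ENTROPIC:
        return -1.0 / s
    return -spec.c * spec.rho * s ** (-spec.rho - 1.0)


def _check_finite(breakdown: CostBreakdown, step: int) -> None:
    for name, value in breakdown.as_dict().items():
        if not np.isfinite(value):
            raise TrainingError(
                f"{name} cost became non-finite ({value}) at step {step}"
            )


def train(
    params: SynapseParams,
    dataset: Dataset | QuadraticToy,
    cost_spec: CostSpec,
    config: TrainConfig,
    net_config: NetworkConfig | None = None,
) -> tuple[SynapseParams, TrainHistory]:
    """Minibatch training of (mu, phi) under the overall cost.

    Dispatches to the quadratic-toy trainer when ``dataset`` is a
    :class:`QuadraticToy`.  Deterministic given ``config.seed``.
    """
    if isinstance(dataset, QuadraticToy):
        raise TypeError("use train_quadratic for QuadraticToy problems")
    if net_config is None:
        widths = [params.mu[0].shape[0]] + [m.shape[1] for m in params.mu]
        net_config = NetworkConfig(tuple(widths), config.per_example_sampling)

    params = params.copy()
    x_train, y_train = dataset.subset("train")
    x_val, y_val = dataset.subset("val")
    n_train = x_train.shape[0]
    if n_train == 0:
        raise ValueError("dataset has an empty train split")

    rng = np.random.default_rng(config.seed)
    homogeneous = params.noise_mode == HOMOGENEOUS

    shapes = [m.shape for m in params.mu]
    opt_mu = _Adam(shapes, config.eta_base, config.beta1, config.beta2, config.eps)
    opt_bias = _Adam([b.shape for b in params.bias], config.eta_base, config.beta1, config.beta2, config.eps)
    if homogeneous:
        opt_phi = _Adam([()], config.eta_base, config.beta1, config.beta2, config.eps)
    else:
        opt_phi = _Adam(shapes, config.eta_base, config.beta1, config.beta2, config.eps)

    g2 = [np.zeros(s) for s in shapes]
    steps_per_epoch = max(1, n_train // config.batch_size)
    history = TrainHistory()
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        perf_sum = 0.0
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            n_ex = xb.shape[0] if config.per_example_sampling else None
            sample = net.sample_weights(params, rng, n_examples=n_ex)
            scores, acts = net.forward(xb, sample, params, cache=True)

            perf = performance_cost(scores, yb)
            sigmas = params.sigmas()
            all_sigma = np.concatenate([s.ravel() for s in sigmas])
            if cost_spec.reliability_form == ENTROPIC:
                rel = cost_spec.c * entropic_cost(all_sigma)
            else:
                rel = reliability_cost(all_sigma, cost_spec.c, cost_spec.rho)
            mag = magnitude_cost(np.concatenate([m.ravel() for m in params.mu]), cost_spec.lam)
            breakdown = CostBreakdown(perf, mag, rel)
            _check_finite(breakdown, step)
            perf_sum += perf

            delta = performance_cost_grad(scores, yb)
            gW, gb, gSig = net.backprop(delta, acts, sample)

            g_mu, g_phi = [], []
            phi_shared_grad = 0.0
            for l in range(len(shapes)):
                g2[l] = config.g2_decay * g2[l] + (1 - config.g2_decay) * gW[l] ** 2
                g_mu.append(gW[l] + cost_spec.lam * np.sign(params.mu[l]))
                rel_grad = _reliability_sigma_grad(sigmas[l], cost_spec, config.sigma_grad_floor)
                if cost_spec.reliability_form == ENTROPIC:
                    rel_grad = cost_spec.c * rel_grad
                total_sig_grad = gSig[l] + rel_grad
                if homogeneous:
                    phi_shared_grad += float(np.sum(total_sig_grad))
                else:
                    g_phi.append(total_sig_grad * sigmoid(params.phi[l]))

            d_mu = opt_mu.step(g_mu)
            d_bias = opt_bias.step(gb)
            for l in range(len(shapes)):
                params.mu[l] -= d_mu[l]
                params.bias[l] -= d_bias[l]
            if homogeneous:
                grad = phi_shared_grad * sigmoid(params.phi_shared)
                (d_phi,) = opt_phi.step([np.asarray(grad)])
                params.phi_shared = float(params.phi_shared - d_phi)
                for l in range(len(shapes)):
                    params.phi[l].fill(params.phi_shared)
            else:
                d_phi = opt_phi.step(g_phi)
                for l in range(len(shapes)):
                    params.phi[l] -= d_phi[l]
            step += 1

        mean_sigma = float(params.all_sigma().mean())
        record = {
            "epoch": epoch,
            "train_perf": perf_sum / steps_per_epoch,
            "mean_sigma": mean_sigma,
            "performance": breakdown.performance,
            "magnitude": breakdown.magnitude,
            "reliability": breakdown.reliability,
            "total": breakdown.total,
        }
        if x_val.shape[0] > 0:
            val_scores = net.forward(x_val, net.mean_weight_sample(params), params)
            record["val_perf"] = performance_cost(val_scores, y_val)
            record["val_accuracy"] = float(np.mean(np.argmax(val_scores, axis=1) == y_val))
        history.records.append(record)

    history.g2 = g2
    return params, history


@dataclass
class ToyTrainResult:
    """Trained toy parameters; ``sigma`` is tail-averaged over the final
    quarter of steps to average out the stationary optimiser jitter."""

    mu: np.ndarray
    sigma: np.ndarray
    sigma_trace: np.ndarray  # (n_report, n_synapses)
    history: pd.DataFrame


def train_quadratic(
    toy: QuadraticToy,
    cost_spec: CostSpec,
    *,
    steps: int = 6000,
    lr: float = 0.01,
    n_draws: int = 8,
    sigma_init: float = 0.5,
    mu_init_sd: float = 0.1,
    seed: int = 0,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
    sigma_grad_floor: float = 1e-8,
    tail_fraction: float = 0.25,
) -> ToyTrainResult:
    """Train per-synapse (mu, phi) on a diagonal quadratic loss.

    Each step averages the reparameterised gradient over ``n_draws``
    weight realisations.  At the optimum mu = w*, the stationarity of
    E[loss] + c sigma^(-rho) = h sigma^2/2 + c sigma^(-rho) gives
    sigma* = (c rho / h)^(1/(rho+2)), the analytic recovery target.
    """
    rng = np.random.default_rng(seed)
    n = toy.n_synapses
    mu = toy.w_star + rng.normal(0.0, mu_init_sd, size=n)
    phi = np.full(n, float(net.phi_from_sigma(sigma_init)))
    opt = _Adam([(n,), (n,)], lr, beta1, beta2, eps)

    n_tail = max(1, int(tail_fraction * steps))
    trace = np.empty((n_tail, n))
    records = []
    for t in range(steps):
        sigma = sigma_from_phi(phi)
        xi = rng.standard_normal((n_draws, n))
        w = mu + sigma * xi
        g = toy.h * (w - toy.w_star)  # per-draw gradient of the loss wrt w
        g_mu = g.mean(axis=0) + cost_spec.lam * np.sign(mu)
        rel_grad = _reliability_sigma_grad(sigma, cost_spec, sigma_grad_floor)
        if cost_spec.reliability_form == ENTROPIC:
            rel_grad = cost_spec.c * rel_grad
        g_phi = ((g * xi).mean(axis=0) + rel_grad) * sigmoid(phi)
        d_mu, d_phi = opt.step([g_mu, g_phi])
        mu -= d_mu
        phi -= d_phi
        if t >= steps - n_tail:
            trace[t - (steps - n_tail)] = sigma_from_phi(phi)
        if t % max(1, steps // 50) == 0:
            loss = float(np.mean([toy.loss(wk) for wk in w]))
            records.append(
                {"step": t, "loss": loss, "mean_sigma": float(sigma.mean())}
            )

    sigma_final = trace.mean(axis=0)
    return ToyTrainResult(mu, sigma_final, trace, pd.DataFrame(records))


def evaluate_accuracy(
    params: SynapseParams,
    dataset: Dataset,
    n_noise_samples: int = 10,
    seed: int = 0,
    *,
    split: str = "test",
    use_mean_weights: bool = False,
) -> float:
    """Classification accuracy averaged over independent weight draws."""
    if n_noise_samples < 1:
        raise ValueError("n_noise_samples must be >= 1")
    x, y = dataset.subset(split)
    if x.shape[0] == 0:
        raise ValueError(f"dataset split {split!r} is empty")
    if use_mean_weights:
        scores = net.forward(x, net.mean_weight_sample(params), params)
        return float(np.mean(np.argmax(scores, axis=1) == y))
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_noise_samples):
        sample = net.sample_weights(params, rng)
        scores = net.forward(x, sample, params)
        accs.append(np.mean(np.argmax(scores, axis=1) == y))
    return float(np.mean(accs))


def sweep_c(
    c_grid,
    rho: float,
    dataset: Dataset,
    config: TrainConfig,
    net_config: NetworkConfig,
    *,
    lam: float = 1e-4,
    modes: tuple = (HETEROGENEOUS, HOMOGENEOUS),
    cache_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Train one network per (c, noise mode) and tabulate the tradeoff.

    Output columns: c, rho, mode, accuracy, mean_sigma, reliability_cost.
    The reliability-cost column uses the scale-matched convention
    c = s^rho/rho with s = 1, so curves for different rho are comparable.
    When ``cache_dir`` is given, finished rows are written to (and reused
    from) one CSV per (c, rho, mode), so an interrupted sweep resumes.
    """
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(c_grid < 0) or np.any(np.diff(c_grid) < 0):
        raise ValueError("c_grid must be non-negative and sorted")
    rows = []
    for i, c in enumerate(c_grid):
        for mode in modes:
            tag = f"c{c:g}_rho{rho:g}_{mode}"
            if cache_dir is not None:
                cache = Path(cache_dir) / f"row_{tag}.csv"
                if cache.exists():
                    rows.append(pd.read_csv(cache).iloc[0].to_dict())
                    continue
            run_seed = (config.seed + 1009 * i + (7 if mode == HOMOGENEOUS else 0)) % (2**31)
            cfg = replace(config, seed=run_seed, noise_mode=mode)
            params = net.init_params(
                net_config,
                seed=run_seed,
                mu_range=cfg.mu_range,
                sigma_init=cfg.sigma_init,
                noise_mode=mode,
            )
            spec = CostSpec(c=float(c), rho=rho, lam=lam)
            try:
                trained, _ = train(params, dataset, spec, cfg, net_config)
            except TrainingError as err:
                raise TrainingError(f"(c={c:g}, mode={mode}): {err}") from err
            sigma = trained.all_sigma()
            row = {
                "c": float(c),
                "rho": rho,
                "mode": mode,
                "accuracy": evaluate_accuracy(
                    trained, dataset, cfg.eval_noise_samples, seed=run_seed + 1
                ),
                "mean_sigma": float(sigma.mean()),
                "reliability_cost": reliability_cost(sigma, 1.0 / rho, rho),
            }
            if cache_dir is not None:
                Path(cache_dir).mkdir(parents=True, exist_ok=True)
                pd.DataFrame([row]).to_csv(Path(cache_dir) / f"row_{tag}.csv", index=False)
            rows.append(row)
    return pd.DataFrame(rows)
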