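"""Post-training synapse diagnostics: importance, learning rates, input rates.

Synapse importance is measured by the diagonal of the Hessian of the
performance cost, approximated by the empirical Fisher: the average
squared gradient g_i^2 taken at the noise-free weights w = mu.  The same
mean-squared gradients give each synapse's effective adaptive learning
rate eta_i = eta_base / (sqrt(<g_i^2>) + eps).  Input rates are the mean
absolute presynaptic activations.  Trained energy-efficient networks
show the characteristic monotone (log-log) relations: high-importance
and high-input-rate synapses have small optimised variance, and
fast-learning synapses have large variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import network as net
from .datasets import Dataset
from .network import SynapseParams
from .objective import performance_cost_grad

__all__ = [
    "DiagnosticsReport",
    "CorrelationResult",
    "empirical_fisher",
    "adaptive_learning_rates",
    "input_rates",
    "log_log_correlation",
    "diagnostics_report",
]


@dataclass
class DiagnosticsReport:
    """Per-synapse diagnostics for one layer's incoming weights.

    Arrays are flattened over the (n_in, n_out) synapse grid; ``rate`` is
    the presynaptic unit's rate broadcast across its outgoing synapses.
    """

    layer: int
    fisher: np.ndarray  # H_ii, empirical Fisher
    g2: np.ndarray  # mean squared gradient used for H and eta
    eta: np.ndarray  # adaptive learning rate per synapse
    rate: np.ndarray  # presynaptic mean |activation|
    sigma2: np.ndarray  # optimised PSP variance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "H": self.fisher,
                "eta": self.eta,
                "input_rate": self.rate,
                "sigma2": self.sigma2,
            }
        )

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation and log-log slope between two positive
    per-synapse quantities."""

    rank_correlation: float
    slope: float
    n: int
    n_dropped: int = 0

    def as_dict(self) -> dict:
        return {
            "rank_correlation": self.rank_correlation,
            "slope": self.slope,
            "n": self.n,
            "n_dropped": self.n_dropped,
        }


def empirical_fisher(
    params: SynapseParams,
    dataset: Dataset,
    n_epochs: int = 10,
    *,
    batch_size: int = 20,
    seed: int = 0,
    split: str = "train",
) -> list:
    """Diagonal Hessian estimate H_ii ~ <g_i^2> at w = mu.

    mu and phi are frozen; minibatch gradients of the performance cost
    are squared and averaged over ``n_epochs`` passes.  Returns one array
    per layer (shape of mu).  A presynaptic unit that never activates
    contributes exactly zero to all its outgoing synapses.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    for m in params.mu:
        if not np.all(np.isfinite(m)):
            raise ValueError("params contain non-finite means")
    x, y = dataset.subset(split)
    if x.shape[0] == 0:
        raise ValueError(f"dataset split {split!r} is empty")
    rng = np.random.default_rng(seed)
    sample = net.mean_weight_sample(params)
    sums = [np.zeros_like(m) for m in params.mu]
    count = 0
    n_batches = max(1, x.shape[0] // batch_size)
    for _ in range(n_epochs):
        order = rng.permutation(x.shape[0])
        for b in range(n_batches):
            idx = order[b * batch_size : (b + 1) * batch_size]
            scores, acts = net.forward(x[idx], sample, params, cache=True)
            delta = performance_cost_grad(scores, y[idx])
            gW, _, _ = net.backprop(delta, acts, sample)
            for l, g in enumerate(gW):
                sums[l] += g * g
            count += 1
    return [s / count for s in sums]


def adaptive_learning_rates(g2, eta_base: float = 5e-4, eps: float = 1e-8):
    """Eq.-style adaptive rate eta_i = eta_base / (sqrt(<g_i^2>) + eps)."""
    g2 = np.asarray(g2, dtype=float)
    if np.any(g2 < 0):
        raise ValueError("mean squared gradients must be non-negative")
    if eta_base <= 0 or eps < 0:
        raise ValueError("eta_base must be positive and eps non-negative")
    return eta_base / (np.sqrt(g2) + eps)


def input_rates(
    params: SynapseParams,
    dataset: Dataset,
    layer: int = 1,
    *,
    split: str = "train",
) -> np.ndarray:
    """Mean absolute activation of the units feeding ``layer``'s synapses.

    Layer 0's inputs are the dataset features themselves; deeper layers
    see ReLU outputs (so means of already non-negative rates).  Weights
    are fixed at mu.
    """
    if not 0 <= layer < len(params.mu):
        raise ValueError(f"layer {layer} out of range")
    x, _ = dataset.subset(split)
    sample = net.mean_weight_sample(params)
    _, acts = net.forward(x, sample, params, cache=True)
    return np.mean(np.abs(acts[layer]), axis=0)


def log_log_correlation(a, b) -> CorrelationResult:
    """Spearman correlation and least-squares slope of log b on log a.

    Pairs where either entry is non-positive are dropped (logarithms
    undefined); the dropped count is reported.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    keep = (a > 0) & (b > 0)
    n_dropped = int(np.sum(~keep))
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("fewer than 3 strictly positive pairs")
    rho = stats.spearmanr(a, b).statistic
    slope, _ = np.polyfit(np.log(a), np.log(b), 1)
    return CorrelationResult(float(rho), float(slope), int(a.size), n_dropped)


def diagnostics_report(
    params: SynapseParams,
    dataset: Dataset,
    *,
    layer: int = 1,
    n_epochs: int = 10,
    eta_base: float = 5e-4,
    eps: float = 1e-8,
    seed: int = 0,
) -> DiagnosticsReport:
    """Assemble the per-synapse report for one layer (default: the second
    hidden layer's incoming weights)."""
    fisher = empirical_fisher(params, dataset, n_epochs, seed=seed)[layer]
    g2 = fisher  # H ~ <g^2>: same statistic feeds importance and eta
    eta = adaptive_learning_rates(g2, eta_base, eps)
    rate = input_rates(params, dataset, layer)
    n_out = params.mu[layer].shape[1]
    rate_grid = np.repeat(rate[:, None], n_out, axis=1)
    sigma2 = params.sigmas()[layer] ** 2
    return DiagnosticsReport(
        layer=layer,
        fisher=fisher.ravel(),
        g2=g2.ravel(),
        eta=eta.ravel(),
        rate=rate_grid.ravel(),
        sigma2=sigma2.ravel(),
    )
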