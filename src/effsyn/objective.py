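"""The energy-aware training objective and its entropic (ELBO) counterpart.

Overall cost = performance cost + magnitude cost + reliability cost:

* performance — mean cross-entropy of the class scores (nats);
* magnitude   — lambda * sum_i |mu_i|, the L1 price of large mean PSPs;
* reliability — c * sum_i sigma_i^(-rho), the power-law price of precise
  transmission, with rho in {1/2, 2/3, 4/3, 2} for the four biophysical
  mechanisms.

The entropic cost sum_i(-log sigma_i) is the negative Gaussian entropy up
to an additive constant: it is the "ideal" reliability penalty appearing
in the evidence lower bound of variational inference.  The inequality

    (s^rho / rho) sigma^(-rho) - log s - 1/rho  >=  -log sigma

(equality iff sigma = s; a consequence of log x <= x - 1 applied to
(sigma/s)^(-rho)) shows that each biological power-law cost with
c = s^rho / rho upper-bounds the entropic cost up to known constants, so
minimising the overall cost tightens an ELBO-style bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "CostSpec",
    "CostBreakdown",
    "performance_cost",
    "magnitude_cost",
    "reliability_cost",
    "entropic_cost",
    "entropy_bound_gap",
    "c_for_scale",
]

POWER = "power"
ENTROPIC = "entropic"


@dataclass(frozen=True)
class CostSpec:
    """Hyperparameters of the overall cost."""

    c: float = 0.0  # reliability-cost multiplier
    rho: float = 2.0  # power-law exponent of the dominant mechanism
    lam: float = 1e-4  # magnitude (L1) multiplier
    s: float = 1.0  # scale at which the power-law cost touches the entropy bound
    reliability_form: str = POWER

    def __post_init__(self) -> None:
        if self.c < 0 or self.lam < 0:
            raise ValueError("c and lambda must be non-negative")
        if self.rho <= 0 or self.s <= 0:
            raise ValueError("rho and s must be positive")
        if self.reliability_form not in (POWER, ENTROPIC):
            raise ValueError("reliability_form must be 'power' or 'entropic'")


@dataclass(frozen=True)
class CostBreakdown:
    performance: float
    magnitude: float
    reliability: float

    @property
    def total(self) -> float:
        return self.performance + self.magnitude + self.reliability

    def as_dict(self) -> dict:
        return {
            "performance": self.performance,
            "magnitude": self.magnitude,
            "reliability": self.reliability,
            "total": self.total,
        }


def c_for_scale(s: float, rho: float) -> float:
    """The multiplier c = s^rho / rho at which the power-law reliability
    cost is tangent to the entropy bound at sigma = s."""
    if s <= 0 or rho <= 0:
        raise ValueError("s and rho must be positive")
    return s**rho / rho


def performance_cost(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy (nats) of raw class scores against integer labels."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.atleast_1d(np.asarray(labels))
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("non-finite class scores in performance cost")
    if labels.shape[0] != scores.shape[0]:
        raise ValueError("labels and scores disagree on batch size")
    lse = logsumexp(scores, axis=1)
    picked = scores[np.arange(scores.shape[0]), labels]
    return float(np.mean(lse - picked))


def performance_cost_grad(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of the mean cross-entropy with respect to the scores:
    (softmax - onehot) / batch."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.atleast_1d(np.asarray(labels))
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    p[np.arange(scores.shape[0]), labels] -= 1.0
    return p / scores.shape[0]


def magnitude_cost(mu, lam: float) -> float:
    """L1 cost on mean PSPs, lambda * sum |mu_i|."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    mu = np.asarray(mu, dtype=float)
    return float(lam * np.sum(np.abs(mu)))


def reliability_cost(sigma, c: float, rho: float) -> float:
    """Power-law reliability cost c * sum sigma_i^(-rho)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("all sigma must be strictly positive")
    if c < 0 or rho <= 0:
        raise ValueError("need c >= 0 and rho > 0")
    return float(c * np.sum(sigma**-rho))


def entropic_cost(sigma) -> float:
    """Negative Gaussian entropy up to a constant: sum_i(-log sigma_i)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("all sigma must be strictly positive")
    return float(-np.sum(np.log(sigma)))


def entropy_bound_gap(sigma, rho: float, s: float):
    """Slack of the power-law-bounds-entropy inequality, elementwise.

    gap = [(s^rho/rho) sigma^(-rho) - log s - 1/rho] - (-log sigma),
    which equals (u - 1 - log u)/rho with u = (sigma/s)^(-rho): always
    >= 0, zero exactly at sigma = s.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0) or rho <= 0 or s <= 0:
        raise ValueError("sigma, rho and s must be positive")
    bound = (s**rho / rho) * sigma**-rho - np.log(s) - 1.0 / rho
    gap = bound + np.log(sigma)
    return float(gap) if gap.ndim == 0 else gap
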