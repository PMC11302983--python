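"""Binomial quantal release model and biophysical reliability costs.

A synaptic connection holds ``n`` docked vesicles, each releasing
independently with probability ``p`` and contributing a quantal PSP of
size ``q`` (with quantal size scaling as vesicle volume, q = r^3 in
arbitrary units).  PSP mean and variance follow the binomial model

    mu = n p q,        sigma^2 = n p (1 - p) q^2.

Reliability (small sigma at fixed mu) can be bought through four
biophysical mechanisms, each with its own energetic price:

* ``calcium``     — raise release probability p via calcium influx
  (Hill relation p = Ca^m / (K^m + Ca^m)); pumping the calcium back out
  costs energy proportional to Ca.  Holding the mean fixed through the
  quantal size gives cost ∝ sigma^(-2/m), i.e. sigma^(-1/2) at the
  default cooperativity m = 4.
* ``surface``     — share a fixed transmitter volume among many small
  vesicles; membrane surface area n r^2 costs phospholipid metabolism;
  cost ∝ sigma^(-2/3).
* ``actin``       — structural filament of length ∝ n r supporting the
  vesicle pool; cost ∝ sigma^(-4/3).
* ``trafficking`` — motor-driven transport, cost per vesicle, cost = n;
  cost ∝ sigma^(-2).

All proportionality constants are 1; costs are in arbitrary units.  Each
constrained sweep below is an exact power law, so a log-log least-squares
fit recovers the exponent to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VesicleParams",
    "CostCurve",
    "MECHANISMS",
    "MECHANISM_EXPONENTS",
    "psp_moments",
    "hill_release_probability",
    "cost_curve",
    "fit_power_exponent",
    "default_sweep_grid",
]

MECHANISMS = ("calcium", "surface", "actin", "trafficking")

#: Printed power-law exponents rho for cost ∝ sigma^(-rho), at m = 4.
MECHANISM_EXPONENTS = {
    "calcium": 0.5,
    "surface": 2.0 / 3.0,
    "actin": 4.0 / 3.0,
    "trafficking": 2.0,
}


@dataclass(frozen=True)
class VesicleParams:
    """Presynaptic biophysical parameters of one connection."""

    n: float = 10.0  # docked vesicle count (real-valued for sweeps)
    p: float = 0.5  # release probability
    q: float = 1.0  # quantal PSP size (mV, arbitrary scale)
    r: float = 1.0  # vesicle radius, q = r**3 when radius is swept
    Ca: float = 1.0  # intracellular calcium concentration (a.u.)
    K: float = 1.0  # Hill half-saturation constant (same units as Ca)
    m: float = 4.0  # Hill coefficient (calcium cooperativity)

    def __post_init__(self) -> None:
        if self.n < 0 or self.q < 0:
            raise ValueError("n and q must be non-negative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("release probability p must lie in [0, 1]")
        if min(self.r, self.Ca, self.K, self.m) <= 0:
            raise ValueError("r, Ca, K and m must be positive")


@dataclass(frozen=True)
class CostCurve:
    """One mechanism's (sigma, cost) sweep at fixed PSP mean ``mu_fix``."""

    mechanism: str
    sigma: np.ndarray
    cost: np.ndarray
    mu_fix: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "mechanism": self.mechanism,
                "sigma": self.sigma,
                "cost": self.cost,
                "mu_fix": self.mu_fix,
            }
        )


def psp_moments(params: VesicleParams) -> tuple[float, float]:
    """PSP mean and variance of the binomial release model.

    Returns ``(mu, sigma2)`` with mu = n p q and sigma2 = n p (1-p) q^2.
    """
    mu = params.n * params.p * params.q
    sigma2 = params.n * params.p * (1.0 - params.p) * params.q**2
    return float(mu), float(sigma2)


def hill_release_probability(Ca: float, K: float, m: float):
    """Release probability from calcium concentration via the Hill equation."""
    Ca = np.asarray(Ca, dtype=float)
    if np.any(Ca < 0):
        raise ValueError("calcium concentration must be non-negative")
    if K <= 0 or m <= 0:
        raise ValueError("K and m must be positive")
    x = (Ca / K) ** m
    out = x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


def _hill_inverse(p, K: float, m: float):
    """Calcium concentration producing release probability ``p``."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("p must lie in [0, 1) to invert the Hill relation")
    return K * (p / (1.0 - p)) ** (1.0 / m)


def cost_curve(
    mechanism: str,
    mu_fix: float,
    sweep_grid: np.ndarray,
    params: VesicleParams = VesicleParams(),
) -> CostCurve:
    """Sweep one biophysical variable at fixed PSP mean, recording cost vs sigma.

    The swept variable and the mean-preserving constraint per mechanism:

    * ``calcium``: sweep p on the grid (must lie in (0, 1)); vesicle count
      n is fixed and the quantal size q = mu/(n p) absorbs the mean
      constraint.  Cost = Ca = Hill inverse of p.
    * ``surface`` / ``actin`` / ``trafficking``: sweep vesicle radius r at
      fixed p, with q = r^3 and n = mu/(p r^3) absorbing the constraint.
      Cost = n r^2, n r, n respectively.
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}; expected one of {MECHANISMS}")
    if mu_fix <= 0:
        raise ValueError("mu_fix must be positive")
    grid = np.asarray(sweep_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("sweep_grid must be a 1-D grid with >= 2 points")
    d = np.diff(grid)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("sweep_grid must be strictly monotone")

    if mechanism == "calcium":
        p = grid
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("calcium sweep requires release probabilities in (0, 1)")
        q = mu_fix / (params.n * p)
        sigma = np.sqrt(params.n * p * (1.0 - p) * q**2)
        cost = _hill_inverse(p, params.K, params.m)
    else:
        r = grid
        if np.any(r <= 0):
            raise ValueError("radius sweep must be positive")
        if not 0.0 < params.p < 1.0:
            raise ValueError("radius sweeps need a fixed p strictly inside (0, 1)")
        q = r**3
        n = mu_fix / (params.p * q)
        sigma = np.sqrt(n * params.p * (1.0 - params.p) * q**2)
        if mechanism == "surface":
            cost = n * r**2
        elif mechanism == "actin":
            cost = n * r
        else:  # trafficking
            cost = n

    # constraint check: the binomial mean must be held at mu_fix exactly
    if mechanism == "calcium":
        mu_check = params.n * p * q
    else:
        mu_check = n * params.p * q
    if np.any(np.abs(mu_check - mu_fix) > 1e-10 * mu_fix):
        raise AssertionError("mean-preserving constraint violated")

    return CostCurve(mechanism, sigma, cost, float(mu_fix))


def fit_power_exponent(curve: CostCurve) -> tuple[float, float]:
    """Least-squares slope of log(cost) on log(sigma).

    Returns ``(rho_hat, slope)`` where ``slope`` is signed and
    ``rho_hat = -slope`` is the power-law magnitude in cost ∝ sigma^(-rho).
    """
    if curve.sigma.size < 3:
        raise ValueError("need at least 3 points to fit a power law")
    if np.any(curve.sigma <= 0) or np.any(curve.cost <= 0):
        raise ValueError("sigma and cost must be strictly positive for a log-log fit")
    slope, _ = np.polyfit(np.log(curve.sigma), np.log(curve.cost), 1)
    return float(-slope), float(slope)


def default_sweep_grid(mechanism: str, n_points: int = 50) -> np.ndarray:
    """Default sweep for each mechanism: the asymptotic high-p segment for
    calcium, a radius decade for the rest."""
    if mechanism == "calcium":
        return np.linspace(0.9, 0.999, n_points)
    return np.geomspace(0.5, 5.0, n_points)
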