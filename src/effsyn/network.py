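"""Feedforward rate network with Gaussian stochastic synapses.

Each synapse transmits a postsynaptic potential drawn from
Normal(mu_i, sigma_i); the unit's firing rate is a rectified linear
function of the summed potentials minus a (deterministic) bias,
rate = relu(sum_i w_i x_i - w0).  Noise is reparameterised as
w_i = mu_i + sigma_i * xi_i with xi standard normal, so gradients flow
to both mu_i and the unconstrained noise parameter phi_i
(sigma_i = softplus(phi_i), keeping sigma positive structurally).

Gradients are computed by explicit reverse-mode passes written for this
architecture; there is no framework dependency, and every draw is a pure
function of its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkConfig",
    "SynapseParams",
    "WeightSample",
    "sigma_from_phi",
    "phi_from_sigma",
    "init_params",
    "sample_weights",
    "forward",
]

HETEROGENEOUS = "heterogeneous"
HOMOGENEOUS = "homogeneous"


def sigma_from_phi(phi):
    """Overflow-safe softplus, sigma = log(1 + exp(phi)).

    Strictly positive and monotone; linear for large phi, ~exp(phi) for
    very negative phi.
    """
    phi = np.asarray(phi, dtype=float)
    out = np.maximum(phi, 0.0) + np.log1p(np.exp(-np.abs(phi)))
    return float(out) if out.ndim == 0 else out


def sigmoid(x):
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return float(out) if out.ndim == 0 else out


def phi_from_sigma(sigma):
    """Inverse softplus, phi = log(expm1(sigma)); stable for small sigma."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    out = np.where(sigma > 30, sigma, np.log(np.expm1(np.minimum(sigma, 30.0))))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the fully connected rate network.

    Hidden layers use ReLU; the output layer emits raw class scores
    (softmax lives inside the performance cost).
    """

    layer_widths: tuple = (784, 100, 100, 10)
    per_example_sampling: bool = False

    def __post_init__(self) -> None:
        if len(self.layer_widths) < 3:
            raise ValueError("need at least one hidden layer")

    @property
    def n_layers(self) -> int:
        return len(self.layer_widths) - 1

    def layer_shapes(self):
        w = self.layer_widths
        return [(w[i], w[i + 1]) for i in range(self.n_layers)]


@dataclass
class SynapseParams:
    """Trainable per-synapse PSP means and noise parameters.

    In ``homogeneous`` mode a single scalar ``phi_shared`` replaces the
    per-synapse ``phi`` arrays: every synapse in the network then carries
    exactly the same PSP standard deviation.
    """

    mu: list  # per layer, (n_in, n_out)
    phi: list  # per layer, (n_in, n_out); mirrors phi_shared when homogeneous
    bias: list  # per layer, (n_out,)
    noise_mode: str = HETEROGENEOUS
    phi_shared: float | None = None

    def sigmas(self) -> list:
        if self.noise_mode == HOMOGENEOUS:
            s = sigma_from_phi(self.phi_shared)
            return [np.full_like(m, s) for m in self.mu]
        return [sigma_from_phi(p) for p in self.phi]

    def all_sigma(self) -> np.ndarray:
        return np.concatenate([s.ravel() for s in self.sigmas()])

    @property
    def n_synapses(self) -> int:
        return int(sum(m.size for m in self.mu))

    def copy(self) -> "SynapseParams":
        return SynapseParams(
            [m.copy() for m in self.mu],
            [p.copy() for p in self.phi],
            [b.copy() for b in self.bias],
            self.noise_mode,
            self.phi_shared,
        )

    def save_npz(self, path: str | Path, config: NetworkConfig | None = None) -> None:
        arrays = {}
        for i, (m, p, b) in enumerate(zip(self.mu, self.phi, self.bias)):
            arrays[f"mu_{i}"] = m
            arrays[f"phi_{i}"] = p
            arrays[f"bias_{i}"] = b
        header = {
            "noise_mode": self.noise_mode,
            "phi_shared": self.phi_shared,
            "n_layers": len(self.mu),
            "layer_widths": list(config.layer_widths) if config else None,
        }
        arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load_npz(cls, path: str | Path) -> "SynapseParams":
        with np.load(path) as f:
            header = json.loads(bytes(f["header"]).decode())
            n = header["n_layers"]
            return cls(
                [f[f"mu_{i}"] for i in range(n)],
                [f[f"phi_{i}"] for i in range(n)],
                [f[f"bias_{i}"] for i in range(n)],
                header["noise_mode"],
                header["phi_shared"],
            )


@dataclass
class WeightSample:
    """One realisation of all synaptic weights, w = mu + sigma * xi."""

    weights: list
    xi: list
    seed: int | None = None


def init_params(
    config: NetworkConfig,
    seed: int = 0,
    *,
    mu_range: float = 0.1,
    sigma_init: float = 1e-4,
    noise_mode: str = HETEROGENEOUS,
) -> SynapseParams:
    """Initialise mu ~ Uniform(-mu_range, mu_range), sigma homogeneous at
    ``sigma_init``, biases at zero."""
    if noise_mode not in (HETEROGENEOUS, HOMOGENEOUS):
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    rng = np.random.default_rng(seed)
    phi0 = float(phi_from_sigma(sigma_init))
    mu, phi, bias = [], [], []
    for shape in config.layer_shapes():
        mu.append(rng.uniform(-mu_range, mu_range, size=shape))
        phi.append(np.full(shape, phi0))
        bias.append(np.zeros(shape[1]))
    shared = phi0 if noise_mode == HOMOGENEOUS else None
    return SynapseParams(mu, phi, bias, noise_mode, shared)


def sample_weights(params: SynapseParams, seed=None, n_examples: int | None = None) -> WeightSample:
    """Draw w = mu + sigma * xi with xi iid standard normal.

    ``seed`` may be an int or a ``numpy.random.Generator``.  When
    ``n_examples`` is given, an independent weight realisation is drawn
    for each example (leading axis), otherwise one realisation is shared.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigmas = params.sigmas()
    xi, weights = [], []
    for m, s in zip(params.mu, sigmas):
        shape = (n_examples, *m.shape) if n_examples else m.shape
        x = rng.standard_normal(shape)
        xi.append(x)
        weights.append(m + s * x)
    return WeightSample(weights, xi, seed if isinstance(seed, int) else None)


def mean_weight_sample(params: SynapseParams) -> WeightSample:
    """The zero-noise realisation w = mu (xi = 0)."""
    return WeightSample([m.copy() for m in params.mu], [np.zeros_like(m) for m in params.mu])


def forward(x: np.ndarray, sample: WeightSample, params: SynapseParams, *, cache: bool = False):
    """Run the rate network: hidden rates relu(a W - w0), raw output scores.

    ``x`` is (batch, n_in) or (n_in,).  With ``cache=True`` also returns
    the list of layer activations [a0, a1, ..., scores] needed for
    reverse-mode gradients.
    """
    a = np.atleast_2d(np.asarray(x, dtype=float))
    n_layers = len(sample.weights)
    if a.shape[1] != sample.weights[0].shape[-2]:
        raise ValueError(
            f"input width {a.shape[1]} does not match first layer "
            f"({sample.weights[0].shape[-2]} inputs)"
        )
    activations = [a]
    for l, (W, b) in enumerate(zip(sample.weights, params.bias)):
        if W.ndim == 3:  # per-example weights
            z = np.einsum("bi,bij->bj", a, W) - b
        else:
            z = a @ W - b
        a = np.maximum(z, 0.0) if l < n_layers - 1 else z
        activations.append(a)
    if cache:
        return a, activations
    return a


def backprop(
    delta_out: np.ndarray,
    activations: list,
    sample: WeightSample,
) -> tuple[list, list, list]:
    """Reverse pass from an output-score gradient ``delta_out``.

    Returns per-layer gradients (summed over the batch, shape of mu) with
    respect to the realised weights (``gW``), the biases (``gb``), and
    the noise scales (``gSig``, the reparameterisation product g * xi).
    Handles both shared and per-example weight samples.
    """
    n_layers = len(sample.weights)
    gW = [None] * n_layers
    gb = [None] * n_layers
    gSig = [None] * n_layers
    delta = delta_out
    for l in range(n_layers - 1, -1, -1):
        a_prev = activations[l]
        W = sample.weights[l]
        if W.ndim == 3:  # per-example weights: resolve products per example
            gw_b = np.einsum("bi,bj->bij", a_prev, delta)
            gW[l] = gw_b.sum(axis=0)
            gSig[l] = np.einsum("bij,bij->ij", gw_b, sample.xi[l])
        else:
            gW[l] = np.einsum("bi,bj->ij", a_prev, delta)
            gSig[l] = gW[l] * sample.xi[l]
        gb[l] = -delta.sum(axis=0)
        if l > 0:
            if W.ndim == 3:
                back = np.einsum("bj,bij->bi", delta, W)
            else:
                back = delta @ W.T
            delta = back * (activations[l] > 0)
    return gW, gb, gSig
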