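"""Gaussian stochastic synapses: sampling, forward pass, gradients."""

import numpy as np
import pytest

from effsyn import network as net
from effsyn.network import (
    HOMOGENEOUS,
    NetworkConfig,
    SynapseParams,
    WeightSample,
    init_params,
    phi_from_sigma,
    sample_weights,
    sigma_from_phi,
)


class TestSoftplus:
    def test_at_zero(self):
        assert sigma_from_phi(0.0) == pytest.approx(np.log(2.0))

    def test_linear_asymptote(self):
        assert sigma_from_phi(50.0) == pytest.approx(50.0, rel=1e-12)

    def test_positive_in_the_far_tail(self):
        s = sigma_from_phi(-50.0)
        assert 0 < s == pytest.approx(np.exp(-50.0), rel=1e-10)

    def test_inverse_roundtrip(self):
        for sigma in (1e-6, 1e-4, 0.5, 3.0, 40.0):
            assert sigma_from_phi(phi_from_sigma(sigma)) == pytest.approx(sigma, rel=1e-9)

    def test_monotone(self):
        phi = np.linspace(-20, 20, 200)
        assert np.all(np.diff(sigma_from_phi(phi)) > 0)


class TestSampling:
    def test_same_seed_identical(self, micro_network):
        params = init_params(micro_network, seed=3)
        a = sample_weights(params, seed=11)
        b = sample_weights(params, seed=11)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_zero_noise_limit_returns_mu(self, micro_network):
        params = init_params(micro_network, seed=3, sigma_init=1e-30)
        s = sample_weights(params, seed=0)
        for w, m in zip(s.weights, params.mu):
            assert np.allclose(w, m, atol=1e-12)

    def test_reparameterisation_identity_holds(self, micro_network):
        params = init_params(micro_network, seed=0, sigma_init=0.3)
        s = sample_weights(params, seed=5)
        for w, m, x, sig in zip(s.weights, params.mu, s.xi, params.sigmas()):
            assert np.allclose(w, m + sig * x)

    def test_monte_carlo_moments(self):
        # single synapse, 1e5 draws: sample mean/variance within 4 SE
        config = NetworkConfig((1, 2, 1))  # smallest legal net; use layer 0 entry
        params = init_params(config, seed=2, sigma_init=0.7)
        mu = params.mu[0][0, 0]
        sigma = params.sigmas()[0][0, 0]
        rng = np.random.default_rng(9)
        draws = np.array(
            [sample_weights(params, rng).weights[0][0, 0] for _ in range(100_000)]
        )
        n = draws.size
        assert abs(draws.mean() - mu) < 4 * sigma / np.sqrt(n)
        var_se = sigma**2 * np.sqrt(2.0 / (n - 1))
        assert abs(draws.var() - sigma**2) < 4 * var_se


class TestForward:
    def test_zero_network_gives_zero_scores(self):
        config = NetworkConfig((3, 4, 2))
        params = init_params(config, seed=0, mu_range=0.0, sigma_init=1e-30)
        scores = net.forward(np.ones(3), net.mean_weight_sample(params), params)
        assert np.allclose(scores, 0.0)

    def test_rectification_of_negative_preactivation(self):
        # one hidden unit, weights [1, -1], input [0.5, 2] -> pre-act -1.5 -> 0
        params = SynapseParams(
            mu=[np.array([[1.0], [-1.0]]), np.array([[1.0]])],
            phi=[np.full((2, 1), -50.0), np.full((1, 1), -50.0)],
            bias=[np.zeros(1), np.zeros(1)],
        )
        out, acts = net.forward(
            np.array([0.5, 2.0]), net.mean_weight_sample(params), params, cache=True
        )
        assert acts[1][0, 0] == 0.0
        assert out[0, 0] == 0.0

    def test_hand_computed_chain(self):
        # x=2 -> hidden relu(2*3 - 1) = 5 -> output 5*(-2) - 0.5 = -10.5
        params = SynapseParams(
            mu=[np.array([[3.0]]), np.array([[-2.0]])],
            phi=[np.full((1, 1), -50.0)] * 2,
            bias=[np.array([1.0]), np.array([0.5])],
        )
        out = net.forward(np.array([2.0]), net.mean_weight_sample(params), params)
        assert out[0, 0] == pytest.approx(-10.5)

    def test_dimension_mismatch_raises(self, micro_network):
        params = init_params(micro_network, seed=0)
        with pytest.raises(ValueError):
            net.forward(np.ones(7), net.mean_weight_sample(params), params)

    def test_hidden_activations_nonnegative(self, micro_network):
        params = init_params(micro_network, seed=4, sigma_init=0.5)
        rng = np.random.default_rng(0)
        x = rng.uniform(-5, 5, size=(50, 20))
        _, acts = net.forward(x, sample_weights(params, rng), params, cache=True)
        for a in acts[1:-1]:
            assert np.all(a >= 0)

    def test_zero_noise_equals_plain_mlp(self, micro_network):
        # oracle: an independent plain-MLP forward
        params = init_params(micro_network, seed=8, sigma_init=1e-30)
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, size=(40, 20))
        got = net.forward(x, sample_weights(params, rng), params)

        a = x
        for i, (w, b) in enumerate(zip(params.mu, params.bias)):
            z = a @ w - b
            a = np.maximum(z, 0) if i < len(params.mu) - 1 else z
        assert np.allclose(got, a, atol=1e-10)


class TestBackprop:
    def test_matches_finite_differences(self, micro_network):
        from effsyn.objective import performance_cost, performance_cost_grad

        params = init_params(micro_network, seed=5, sigma_init=0.2)
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, size=(8, 20))
        y = rng.integers(0, 3, size=8)
        sample = sample_weights(params, seed=3)
        scores, acts = net.forward(x, sample, params, cache=True)
        gW, gb, gSig = net.backprop(performance_cost_grad(scores, y), acts, sample)

        eps = 1e-6
        check = [(0, 3, 2), (1, 5, 1), (2, 0, 2)]
        for l, i, j in check:
            w_up = [w.copy() for w in sample.weights]
            w_dn = [w.copy() for w in sample.weights]
            w_up[l][i % w_up[l].shape[0], j % w_up[l].shape[1]] += eps
            w_dn[l][i % w_dn[l].shape[0], j % w_dn[l].shape[1]] -= eps
            up = performance_cost(net.forward(x, WeightSample(w_up, sample.xi), params), y)
            dn = performance_cost(net.forward(x, WeightSample(w_dn, sample.xi), params), y)
            fd = (up - dn) / (2 * eps)
            assert gW[l][i % gW[l].shape[0], j % gW[l].shape[1]] == pytest.approx(fd, abs=1e-6)

    def test_per_example_sampling_shapes_and_grads(self, micro_network):
        from effsyn.objective import performance_cost_grad

        params = init_params(micro_network, seed=5, sigma_init=0.2)
        sample = sample_weights(params, seed=1, n_examples=6)
        assert sample.weights[0].shape == (6, 20, 8)
        x = np.random.default_rng(0).uniform(0, 1, size=(6, 20))
        scores, acts = net.forward(x, sample, params, cache=True)
        gW, gb, gSig = net.backprop(performance_cost_grad(scores, np.zeros(6, int)), acts, sample)
        for g, m in zip(gW, params.mu):
            assert g.shape == m.shape
            assert np.all(np.isfinite(g))


class TestHomogeneousMode:
    def test_shared_phi_means_equal_sigmas(self, micro_network):
        params = init_params(micro_network, seed=0, noise_mode=HOMOGENEOUS, sigma_init=0.1)
        sig = params.all_sigma()
        assert np.ptp(sig) == 0.0  # every synapse shares one sigma exactly
        assert sig[0] == pytest.approx(0.1, rel=1e-9)


def test_checkpoint_roundtrip(tmp_path, micro_network):
    params = init_params(micro_network, seed=6, sigma_init=0.05)
    path = tmp_path / "ckpt.npz"
    params.save_npz(path, micro_network)
    back = SynapseParams.load_npz(path)
    for a, b in zip(params.mu, back.mu):
        assert np.array_equal(a, b)
    for a, b in zip(params.phi, back.phi):
        assert np.array_equal(a, b)
    assert back.noise_mode == params.noise_mode
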