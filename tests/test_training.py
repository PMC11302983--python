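"""Trainer behaviour: toy recovery, determinism, noise modes, evaluation."""

import numpy as np
import pytest

from effsyn.datasets import make_quadratic_toy
from effsyn.network import HOMOGENEOUS, init_params
from effsyn.objective import CostBreakdown, CostSpec
from effsyn.training import (
    TrainConfig,
    TrainingError,
    _check_finite,
    evaluate_accuracy,
    sweep_c,
    train,
    train_quadratic,
)


class TestQuadraticToyTraining:
    def test_sigma_converges_to_analytic_optimum(self):
        # h=1, c=1, rho=2: sigma* = (c rho / h)^(1/(rho+2)) = 2^(1/4)
        toy = make_quadratic_toy([1.0], [0.0])
        res = train_quadratic(toy, CostSpec(c=1.0, rho=2.0, lam=0.0), seed=0)
        assert res.sigma[0] == pytest.approx(2 ** 0.25, rel=0.05)

    def test_noise_shrinks_without_reliability_pressure(self):
        # c = 0, lam = 0: noise only hurts performance, so sigma decreases
        toy = make_quadratic_toy([1.0, 4.0], [0.0, 1.0])
        res = train_quadratic(
            toy, CostSpec(c=0.0, rho=2.0, lam=0.0), sigma_init=0.1, steps=2000, seed=1
        )
        assert np.all(res.sigma < 0.1)

    def test_mu_converges_to_optimum(self):
        toy = make_quadratic_toy([2.0, 0.5], [1.5, -3.0])
        res = train_quadratic(toy, CostSpec(c=0.01, rho=2.0, lam=0.0), seed=2)
        assert np.allclose(res.mu, toy.w_star, atol=0.1)

    def test_deterministic_given_seed(self):
        toy = make_quadratic_toy([1.0, 2.0], [0.0, 0.0])
        spec = CostSpec(c=0.5, rho=0.5, lam=1e-4)
        a = train_quadratic(toy, spec, steps=500, seed=42)
        b = train_quadratic(toy, spec, steps=500, seed=42)
        assert np.array_equal(a.sigma, b.sigma)
        assert np.array_equal(a.mu, b.mu)


class TestNetworkTraining:
    def test_deterministic_given_seed(self, micro_dataset, micro_network):
        cfg = TrainConfig(eta_base=1e-3, epochs=2, seed=11)
        spec = CostSpec(c=1e-4, rho=2.0)
        outs = []
        for _ in range(2):
            p0 = init_params(micro_network, seed=11)
            p, _ = train(p0, micro_dataset, spec, cfg, micro_network)
            outs.append(p)
        for a, b in zip(outs[0].mu, outs[1].mu):
            assert np.array_equal(a, b)
        for a, b in zip(outs[0].phi, outs[1].phi):
            assert np.array_equal(a, b)

    def test_homogeneous_mode_keeps_sigma_uniform(self, micro_dataset, micro_network):
        cfg = TrainConfig(eta_base=1e-3, epochs=2, seed=0, noise_mode=HOMOGENEOUS)
        p0 = init_params(micro_network, seed=0, noise_mode=HOMOGENEOUS)
        p, _ = train(p0, micro_dataset, CostSpec(c=1e-3, rho=2.0), cfg, micro_network)
        sig = p.all_sigma()
        assert np.ptp(sig) == 0.0  # still exactly uniform after training
        assert sig[0] != pytest.approx(1e-4)  # it did move

    def test_learns_the_task(self, micro_dataset, micro_network):
        cfg = TrainConfig(eta_base=5e-3, epochs=8, seed=1)
        p0 = init_params(micro_network, seed=1)
        p, hist = train(p0, micro_dataset, CostSpec(c=0.0, rho=2.0), cfg, micro_network)
        assert hist.final["val_accuracy"] > 0.8  # chance = 1/3
        assert hist.to_frame().shape[0] == 8

    def test_history_tracks_positive_sigma(self, micro_dataset, micro_network):
        cfg = TrainConfig(eta_base=1e-3, epochs=3, seed=2)
        p0 = init_params(micro_network, seed=2)
        _, hist = train(p0, micro_dataset, CostSpec(c=1e-4, rho=2.0), cfg, micro_network)
        assert np.all(hist.to_frame()["mean_sigma"] > 0)

    def test_divergence_error_names_term(self):
        with pytest.raises(TrainingError, match="performance"):
            _check_finite(CostBreakdown(float("nan"), 0.0, 0.0), step=3)
        with pytest.raises(TrainingError, match="reliability"):
            _check_finite(CostBreakdown(0.0, 0.0, float("inf")), step=3)

    def test_toy_dispatch_rejected_in_network_trainer(self, micro_network):
        toy = make_quadratic_toy([1.0], [0.0])
        with pytest.raises(TypeError):
            train(init_params(micro_network, 0), toy, CostSpec(), TrainConfig())


@pytest.fixture(scope="module")
def trained(micro_dataset, micro_network):
    cfg = TrainConfig(eta_base=2e-3, epochs=5, seed=1)
    p0 = init_params(micro_network, seed=1)
    p, _ = train(p0, micro_dataset, CostSpec(c=0.0, rho=2.0), cfg, micro_network)
    return p


class TestEvaluateAccuracy:

    def test_shuffled_labels_give_chance(self, micro_dataset, trained):
        import copy

        shuffled = copy.copy(micro_dataset)
        rng = np.random.default_rng(0)
        shuffled.labels = rng.permutation(micro_dataset.labels)
        acc = evaluate_accuracy(trained, shuffled, 5, seed=0)
        n = micro_dataset.subset("test")[0].shape[0]
        assert abs(acc - 1 / 3) < 4 * np.sqrt((1 / 3) * (2 / 3) / n)

    def test_zero_noise_equals_mean_weight_accuracy(self, micro_dataset, trained):
        frozen = trained.copy()
        for p in frozen.phi:
            p.fill(-60.0)
        sampled = evaluate_accuracy(frozen, micro_dataset, 3, seed=1)
        mean_w = evaluate_accuracy(frozen, micro_dataset, 1, use_mean_weights=True)
        assert sampled == mean_w

    def test_averaging_more_samples_stabilises(self, micro_dataset, trained):
        noisy = trained.copy()
        for p in noisy.phi:
            p.fill(0.0)  # sigma = log 2 everywhere: very noisy
        few = [evaluate_accuracy(noisy, micro_dataset, 1, seed=s) for s in range(12)]
        many = [evaluate_accuracy(noisy, micro_dataset, 16, seed=s) for s in range(12)]
        assert np.var(many) < np.var(few)

    def test_empty_split_raises(self, micro_dataset, trained):
        import copy

        ds = copy.copy(micro_dataset)
        ds.split = np.full(ds.n_samples, "train")
        with pytest.raises(ValueError):
            evaluate_accuracy(trained, ds, 1, split="test")


class TestSweepC:
    def test_rejects_unsorted_grid(self, micro_dataset, micro_network):
        with pytest.raises(ValueError):
            sweep_c([0.1, 0.0], 2.0, micro_dataset, TrainConfig(), micro_network)

    def test_cache_resume(self, tmp_path, micro_dataset, micro_network):
        cfg = TrainConfig(eta_base=1e-3, epochs=1, seed=0)
        tbl1 = sweep_c([0.0], 2.0, micro_dataset, cfg, micro_network, cache_dir=tmp_path)
        assert any(tmp_path.glob("row_*.csv"))
        tbl2 = sweep_c([0.0], 2.0, micro_dataset, cfg, micro_network, cache_dir=tmp_path)
        assert np.allclose(tbl1.accuracy, tbl2.accuracy)  # CSV text roundtrip
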