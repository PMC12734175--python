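"""Objective, warm-up schedule, folds, samplers, and the training loop."""

import numpy as np
import pytest

from leafgate.branches import BranchConfig, ImageBatch
from leafgate.data.synthetic import SyntheticDatasetSpec, synth_generate
from leafgate.fusion import GateNetwork, GateWeights, HMCTAFModel
from leafgate.nn import Tensor
from leafgate.training import (
    TrainConfig,
    class_aware_batches,
    cross_entropy,
    cross_validate,
    evaluate_model,
    focal_loss,
    lambda_schedule,
    shuffled_batches,
    stratified_kfold,
    total_loss,
    train_single,
)
from leafgate.utils import substream


def make_gates(g: np.ndarray) -> GateWeights:
    t = Tensor(g)
    return GateWeights(z_d=t, z_g=t, z_t=t, u=t, s=t, g=t)


class TestLosses:
    def test_cross_entropy_matches_scipy_logsumexp_oracle(self):
        from scipy.special import log_softmax
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((16, 5))
        labels = rng.integers(0, 5, 16)
        expect = -log_softmax(logits, axis=-1)[np.arange(16), labels].mean()
        got = cross_entropy(Tensor(logits), labels).item()
        assert got == pytest.approx(expect, rel=1e-9)

    def test_cross_entropy_gradient_is_softmax_minus_onehot(self):
        rng = np.random.default_rng(1)
        logits = Tensor(rng.standard_normal((4, 3)), requires_grad=True)
        labels = np.array([0, 2, 1, 1])
        cross_entropy(logits, labels).backward()
        from scipy.special import softmax
        p = softmax(logits.data, axis=-1)
        p[np.arange(4), labels] -= 1
        np.testing.assert_allclose(logits.grad, p / 4, rtol=1e-7, atol=1e-12)

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            cross_entropy(Tensor(np.array([[np.inf, 0.0]])), [0])

    def test_focal_gamma_zero_reduces_to_cross_entropy(self):
        rng = np.random.default_rng(2)
        logits = rng.standard_normal((10, 4))
        labels = rng.integers(0, 4, 10)
        from scipy.special import softmax
        probs = softmax(logits, axis=-1)
        ce = cross_entropy(Tensor(logits), labels).item()
        assert focal_loss(probs, labels, gamma=0.0) == pytest.approx(ce,
                                                                     abs=1e-7)

    def test_focal_perfectly_confident_correct_is_zero(self):
        probs = np.array([[1.0, 0.0, 0.0]])
        assert focal_loss(probs, [0], gamma=2.0) == pytest.approx(0.0,
                                                                  abs=1e-9)

    def test_focal_half_probability_gamma_two(self):
        probs = np.array([[0.5, 0.5]])
        expect = 0.25 * np.log(2)
        assert focal_loss(probs, [0], gamma=2.0) == pytest.approx(expect,
                                                                  rel=1e-9)
        assert expect == pytest.approx(0.17329, abs=5e-6)

    def test_focal_tensor_path_matches_array_path(self):
        rng = np.random.default_rng(3)
        from scipy.special import softmax
        probs = softmax(rng.standard_normal((8, 3)), axis=-1)
        labels = rng.integers(0, 3, 8)
        t = focal_loss(Tensor(probs, requires_grad=True), labels, gamma=2.0)
        assert t.item() == pytest.approx(focal_loss(probs, labels, gamma=2.0),
                                         rel=1e-6)


class TestTotalLoss:
    def test_zero_lambda_equals_classification_loss_exactly(self):
        rng = np.random.default_rng(0)
        logits = Tensor(rng.standard_normal((6, 3)))
        labels = rng.integers(0, 3, 6)
        gates = make_gates(rng.dirichlet(np.ones(3), 6))
        l0 = total_loss(logits, labels, gates, 0.0).item()
        assert l0 == cross_entropy(logits, labels).item()

    def test_one_hot_gates_contribute_nothing(self):
        rng = np.random.default_rng(1)
        logits = Tensor(rng.standard_normal((4, 3)))
        labels = rng.integers(0, 3, 4)
        onehot = np.eye(3)[rng.integers(0, 3, 4)]
        l = total_loss(logits, labels, make_gates(onehot), 5.0).item()
        assert l == pytest.approx(cross_entropy(logits, labels).item(),
                                  abs=1e-9)

    def test_uniform_gates_add_lambda_ln3(self):
        rng = np.random.default_rng(2)
        logits = Tensor(rng.standard_normal((4, 3)))
        labels = rng.integers(0, 3, 4)
        uniform = np.full((4, 3), 1 / 3)
        l = total_loss(logits, labels, make_gates(uniform), 0.1).item()
        expect = cross_entropy(logits, labels).item() + 0.1 * np.log(3)
        assert l == pytest.approx(expect, rel=1e-6)

    def test_warmup_passes_no_gradient_to_gate(self):
        """During warm-up (lambda_eff = 0) the entropy term must
        contribute exactly zero gradient to the gate parameters."""
        rng = np.random.default_rng(3)
        net = GateNetwork(4, 3, rng)
        z = Tensor(rng.standard_normal((5, 4)))
        gw = net(z, z, z)
        # logits independent of the gate: only the entropy path reaches it
        logits = Tensor(rng.standard_normal((5, 3)), requires_grad=True)
        loss = total_loss(logits, rng.integers(0, 3, 5), gw, 0.0)
        loss.backward()
        assert net.fc1.weight.grad is None
        loss2 = total_loss(logits, rng.integers(0, 3, 5), gw, 0.5)
        loss2.backward()
        assert net.fc1.weight.grad is not None


class TestLambdaSchedule:
    def test_warmup_then_constant(self):
        cfg = TrainConfig(epochs=10, lambda_sparsity=0.1, warmup_epochs=5)
        assert [lambda_schedule(e, cfg) for e in range(7)] == \
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.1, 0.1]

    def test_zero_lambda_config_always_zero(self):
        cfg = TrainConfig(epochs=10, lambda_sparsity=0.0, warmup_epochs=5)
        assert all(lambda_schedule(e, cfg) == 0.0 for e in range(20))

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lambda_schedule(-1, TrainConfig(epochs=1))


class TestTrainConfig:
    def test_published_defaults(self):
        cfg = TrainConfig()
        assert (cfg.learning_rate, cfg.momentum, cfg.weight_decay,
                cfg.batch_size) == (0.001, 0.9, 0.0005, 32)
        assert (cfg.lambda_sparsity, cfg.tau, cfg.warmup_epochs) == \
            (0.10, 1.0, 5)
        assert cfg.optimizer == "sgd"

    @pytest.mark.parametrize("kw", [
        {"epochs": 0}, {"learning_rate": -1}, {"lambda_sparsity": -0.1},
        {"optimizer": "rmsprop"}, {"loss": "hinge"}, {"focal_gamma": -1},
    ])
    def test_invalid_fields_rejected(self, kw):
        with pytest.raises(ValueError):
            TrainConfig(**kw)


class TestStratifiedKFold:
    def test_single_class_splits_equally(self):
        fs = stratified_kfold(np.zeros(10, dtype=int), k=5, seed=0)
        counts = np.bincount(fs.fold_assignments, minlength=5)
        np.testing.assert_array_equal(counts, 2)

    def test_two_class_fold_composition(self):
        labels = np.array([0] * 6 + [1] * 4)
        fs = stratified_kfold(labels, k=2, seed=1)
        for fold in range(2):
            idx = fs.test_indices(fold)
            assert (labels[idx] == 0).sum() == 3
            assert (labels[idx] == 1).sum() == 2

    def test_folds_disjoint_and_exhaustive(self):
        labels = np.random.default_rng(0).integers(0, 3, 60)
        fs = stratified_kfold(labels, k=5, seed=0)
        all_idx = np.concatenate([fs.test_indices(f) for f in range(5)])
        np.testing.assert_array_equal(np.sort(all_idx), np.arange(60))

    def test_same_seed_reproducible(self):
        labels = np.random.default_rng(1).integers(0, 4, 80)
        a = stratified_kfold(labels, k=5, seed=3).fold_assignments
        b = stratified_kfold(labels, k=5, seed=3).fold_assignments
        np.testing.assert_array_equal(a, b)

    def test_small_class_rejected_naming_it(self):
        labels = np.array([0] * 10 + [1] * 3)
        with pytest.raises(ValueError, match="class 1"):
            stratified_kfold(labels, k=5, seed=0)


class TestSamplers:
    def test_shuffled_batches_cover_all_indices(self):
        batches = shuffled_batches(50, 8, substream(0, "s"))
        got = np.sort(np.concatenate(batches))
        np.testing.assert_array_equal(got, np.arange(50))

    def test_class_aware_batches_contain_every_class(self):
        labels = np.array([0] * 40 + [1] * 5 + [2] * 5)   # imbalanced
        batches = class_aware_batches(labels, 12, substream(0, "c"))
        for b in batches:
            assert set(labels[b]) == {0, 1, 2}

    def test_class_aware_epoch_size(self):
        labels = np.random.default_rng(0).integers(0, 4, 64)
        batches = class_aware_batches(labels, 16, substream(1, "c"))
        assert len(batches) == 4
        assert all(len(b) == 16 for b in batches)


@pytest.fixture(scope="module")
def micro_dataset():
    """Tiny 3-class synthetic set on a 32px grid for fast loop tests."""
    spec = SyntheticDatasetSpec(
        n_per_class=16, classes=("blotch", "healthy", "speckle"),
        image_size=32, seed=11)
    batch, names = synth_generate(spec)
    return batch, names


class TestTrainingLoop:
    def test_smoke_train_records_history_and_metrics(self, micro_dataset):
        batch, names = micro_dataset
        cfg = BranchConfig.tiny(input_size=32)
        tc = TrainConfig(epochs=2, learning_rate=0.02, warmup_epochs=1,
                         batch_size=16, seed=0)
        model = HMCTAFModel(cfg, 3, "gsaf", seed=0)
        history = train_single(model, batch, tc)
        assert len(history) == 2
        assert history[0]["lambda_eff"] == 0.0
        assert history[1]["lambda_eff"] == tc.lambda_sparsity
        assert all(np.isfinite(h["loss"]) for h in history)
        ev = evaluate_model(model, batch, 3)
        assert 0.0 <= ev["macro_f1"] <= 1.0
        assert ev["gates"].shape == (len(batch), 3)

    def test_training_is_reproducible_for_fixed_seed(self, micro_dataset):
        batch, _ = micro_dataset
        cfg = BranchConfig.tiny(input_size=32)
        tc = TrainConfig(epochs=1, learning_rate=0.02, batch_size=16, seed=4)

        def run():
            m = HMCTAFModel(cfg, 3, "gsaf", seed=4)
            train_single(m, batch, tc)
            return evaluate_model(m, batch, 3)

        a, b = run(), run()
        np.testing.assert_array_equal(a["predictions"], b["predictions"])
        np.testing.assert_array_equal(a["gates"], b["gates"])

    def test_empty_training_set_rejected(self):
        cfg = BranchConfig.tiny(input_size=32)
        model = HMCTAFModel(cfg, 2, "gsaf", seed=0)
        empty = ImageBatch(np.zeros((0, 32, 32, 3)), np.zeros(0, dtype=int))
        with pytest.raises(ValueError, match="empty"):
            train_single(model, empty, TrainConfig(epochs=1))

    def test_adam_option_changes_only_optimizer(self, micro_dataset):
        from leafgate.training import _make_optimizer
        from leafgate.nn import Adam, SGD
        cfg = BranchConfig.tiny(input_size=32)
        m = HMCTAFModel(cfg, 3, "gsaf", seed=0)
        assert isinstance(_make_optimizer(m, TrainConfig(epochs=1)), SGD)
        assert isinstance(
            _make_optimizer(m, TrainConfig(epochs=1, optimizer="adam")), Adam)

    def test_cross_validation_reuses_given_folds(self, micro_dataset):
        batch, names = micro_dataset
        cfg = BranchConfig.tiny(input_size=32)
        tc = TrainConfig(epochs=1, learning_rate=0.02, batch_size=16, seed=0)
        folds = stratified_kfold(batch.labels, k=2, seed=0)
        res = cross_validate(batch, 3, cfg, tc, strategy="static_average",
                             folds=folds)
        assert res.fold_split is folds
        assert len(res.folds) == 2
        true, pred = res.pooled_predictions()
        assert (true >= 0).all() and len(true) == len(batch)
        np.testing.assert_array_equal(true, batch.labels)
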