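"""Loss, schedule, optimizer and training-loop behaviour."""

import math

import numpy as np
import pytest

from ednet.architecture import EDNetConfig, assemble_ednet
from ednet.data import SyntheticSpec, generate_synthetic_dataset
from ednet.training import (
    EpochRecord,
    TrainConfig,
    cross_entropy,
    cross_entropy_grad,
    evaluate,
    export_history,
    load_checkpoint,
    lr_schedule,
    save_checkpoint,
    sgd_update,
    train,
)

TINY = dict(train_counts=(6,) * 7, test_counts=(3,) * 7, image_size=24)


def tiny_net(seed=0, **kw):
    return assemble_ednet(
        EDNetConfig(width_multiplier=0.06, input_size=24, bn_momentum=0.3,
                    weight_init_seed=seed, **kw)
    )


@pytest.fixture(scope="module")
def tiny_manifest(tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny")
    return generate_synthetic_dataset(
        SyntheticSpec(**TINY, noise=0.0, separability=1.0, seed=11), out
    )


class TestCrossEntropy:
    def test_uniform_logits_give_log_c(self):
        logits = np.zeros((5, 7))
        labels = np.arange(5) % 7
        assert cross_entropy(logits, labels) == pytest.approx(math.log(7), abs=1e-12)

    def test_confident_correct_prediction_is_near_zero(self):
        logits = np.zeros((1, 7))
        logits[0, 2] = 100.0
        assert cross_entropy(logits, np.array([2])) < 1e-10

    def test_monotone_in_true_class_logit(self):
        labels = np.array([0])
        losses = [
            cross_entropy(np.array([[z, 1.0, 0.5]]), labels) for z in (0.0, 1.0, 2.0)
        ]
        assert losses[0] > losses[1] > losses[2]

    def test_stable_for_extreme_logits(self):
        logits = np.array([[1e4, -1e4, 0.0]])
        assert np.isfinite(cross_entropy(logits, np.array([1])))

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            cross_entropy(np.zeros((2, 7)), np.array([0, 7]))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(4, 7))
        labels = rng.integers(0, 7, size=4)
        grad = cross_entropy_grad(logits, labels)
        eps = 1e-6
        for i, j in [(0, 0), (1, 3), (3, 6)]:
            up, dn = logits.copy(), logits.copy()
            up[i, j] += eps
            dn[i, j] -= eps
            fd = (cross_entropy(up, labels) - cross_entropy(dn, labels)) / (2 * eps)
            assert grad[i, j] == pytest.approx(fd, abs=1e-6)


class TestSchedule:
    def test_initial_and_decayed_values(self):
        cfg = TrainConfig()
        assert lr_schedule(cfg, 0) == 0.01
        assert lr_schedule(cfg, 1) == pytest.approx(0.0095)
        assert lr_schedule(cfg, 10) == pytest.approx(0.01 * 0.95**10)

    def test_strictly_decreasing(self):
        cfg = TrainConfig()
        rates = [lr_schedule(cfg, e) for e in range(50)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(TrainConfig(), -1)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_decay=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)


class TestSgdUpdate:
    def test_plain_gradient_step_without_momentum(self):
        w = np.array([1.0, 2.0])
        g = np.array([0.5, -0.5])
        new_w, _ = sgd_update(w, g, np.zeros(2), lr=0.1, momentum=0.0)
        np.testing.assert_allclose(new_w, [0.95, 2.05])

    def test_zero_gradient_zero_velocity_is_identity(self):
        w = np.array([3.0])
        new_w, new_v = sgd_update(w, np.zeros(1), np.zeros(1), lr=0.1,
                                  momentum=0.9, weight_decay=0.0)
        np.testing.assert_array_equal(new_w, w)
        np.testing.assert_array_equal(new_v, 0.0)

    def test_two_steps_on_quadratic_match_hand_recurrence(self):
        # f(w) = w^2/2, grad = w; lr=0.1, momentum=0.9, wd=0
        # v1 = 1.0 -> w1 = 1 - 0.1 = 0.9
        # v2 = 0.9*1.0 + 0.9 = 1.8 -> w2 = 0.9 - 0.18 = 0.72
        w, v = np.array([1.0]), np.array([0.0])
        w, v = sgd_update(w, w.copy(), v, lr=0.1, momentum=0.9)
        assert w[0] == pytest.approx(0.9)
        w, v = sgd_update(w, w.copy(), v, lr=0.1, momentum=0.9)
        assert w[0] == pytest.approx(0.72)

    def test_weight_decay_is_coupled_into_gradient(self):
        w = np.array([2.0])
        new_w, _ = sgd_update(w, np.zeros(1), np.zeros(1), lr=0.1,
                              momentum=0.0, weight_decay=0.1)
        assert new_w[0] == pytest.approx(2.0 - 0.1 * 0.2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sgd_update(np.zeros(2), np.zeros(3), np.zeros(2), lr=0.1)


class TestBackprop:
    def test_network_gradients_match_finite_differences(self):
        """End-to-end check: analytic parameter gradients of the full
        conv/BN/swish6/residual stack against central differences."""
        net = tiny_net(seed=3)
        net.set_training(True)
        rng = np.random.default_rng(5)
        x = rng.random((4, 3, 24, 24)).astype(np.float32)
        labels = rng.integers(0, 7, size=4)

        def loss_value():
            return cross_entropy(net.model.forward(x), labels)

        logits = net.model.forward(x)
        net.zero_grad()
        net.backward(cross_entropy_grad(logits, labels))
        params = net.parameters()
        check = [(0, 0), (len(params) // 2, 0), (len(params) - 2, 3)]
        eps = 1e-2
        for pi, flat_idx in check:
            p = params[pi]
            orig = p.value.ravel()[flat_idx]
            p.value.ravel()[flat_idx] = orig + eps
            up = loss_value()
            p.value.ravel()[flat_idx] = orig - eps
            dn = loss_value()
            p.value.ravel()[flat_idx] = orig
            fd = (up - dn) / (2 * eps)
            analytic = p.grad.ravel()[flat_idx]
            assert analytic == pytest.approx(fd, abs=max(2e-3, 0.05 * abs(fd)))


class TestTrainLoop:
    def test_history_length_and_lr_column(self, tiny_manifest):
        net = tiny_net()
        cfg = TrainConfig(batch_size=8, epochs=3, seed=0)
        history = train(net, tiny_manifest, cfg)
        assert len(history) == 3
        for rec in history:
            assert rec.lr == pytest.approx(lr_schedule(cfg, rec.epoch))
            assert 0.0 <= rec.train_acc <= 1.0 and rec.train_loss >= 0

    def test_identical_seed_reproduces_history_bitwise(self, tiny_manifest):
        def run():
            net = tiny_net(seed=4)
            hist = train(net, tiny_manifest,
                         TrainConfig(batch_size=8, epochs=2, seed=4))
            return hist, [p.value.copy() for p in net.parameters()]

        h1, w1 = run()
        h2, w2 = run()
        assert [(r.train_loss, r.train_acc, r.test_acc) for r in h1] == [
            (r.train_loss, r.train_acc, r.test_acc) for r in h2
        ]
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    def test_empty_train_split_rejected(self, tmp_path):
        manifest = generate_synthetic_dataset(
            SyntheticSpec(train_counts=(0,) * 7, test_counts=(1,) * 7,
                          image_size=24), tmp_path
        )
        with pytest.raises(ValueError, match="training split is empty"):
            train(tiny_net(), manifest, TrainConfig(epochs=1))

    def test_checkpoint_round_trip(self, tiny_manifest, tmp_path):
        net = tiny_net(seed=1)
        cfg = TrainConfig(batch_size=8, epochs=1, seed=1)
        history = train(net, tiny_manifest, cfg,
                        checkpoint_path=tmp_path / "ckpt.npz")
        restored = tiny_net(seed=99)
        meta = load_checkpoint(restored, tmp_path / "ckpt.npz")
        for a, b in zip(net.parameters(), restored.parameters()):
            np.testing.assert_array_equal(a.value, b.value)
        assert meta["train_config"]["seed"] == 1
        assert len(meta["history"]) == len(history)

    def test_smoothed_loss_trend_non_increasing_across_seeds(self, desk_runs):
        """Window-3 moving average of epoch losses must not increase for any
        of the pinned seeds on the fully-separable noise-free set."""
        for seed, (history, _) in desk_runs.items():
            losses = np.array([r.train_loss for r in history])
            smooth = np.convolve(losses, np.ones(3) / 3, mode="valid")
            assert np.all(np.diff(smooth) <= 1e-9), f"seed {seed}: {losses}"


class TestEvaluate:
    def test_constant_predictor_accuracy_equals_majority_share(self, tmp_path):
        """A predictor stuck on one class scores that class's share of the
        emulated test split: 275/1149 for the largest class."""
        manifest = generate_synthetic_dataset(
            SyntheticSpec(train_counts=(0,) * 7, image_size=16, noise=0.0),
            tmp_path,
        )
        net = assemble_ednet(
            EDNetConfig(width_multiplier=0.03, input_size=16, weight_init_seed=0)
        )
        head_w, head_b = net.parameters()[-2], net.parameters()[-1]
        head_w.value[...] = 0.0
        head_b.value[...] = 0.0
        head_b.value[3] = 10.0  # always predict Diabetic_retinopathy
        res = evaluate(net, manifest.split("test"), batch_size=128)
        assert res.accuracy == pytest.approx(275 / 1149, abs=1e-12)
        assert res.confusion.sum() == 1149
        np.testing.assert_array_equal(res.confusion.sum(axis=1),
                                      manifest.class_counts("test"))

    def test_perfect_predictions_give_diagonal_confusion(self, desk_runs):
        _, result = desk_runs[0]
        assert result.confusion.sum() == result.confusion.trace() or \
            result.accuracy < 1.0
        if result.accuracy == 1.0:
            assert np.all(result.per_class_recall == 1.0)

    def test_empty_split_rejected(self, tiny_manifest):
        from ednet.data import DatasetManifest

        with pytest.raises(ValueError, match="empty"):
            evaluate(tiny_net(), DatasetManifest([]))


class TestHistoryExport:
    def test_csv_round_trip_and_plot(self, tmp_path):
        import pandas as pd

        history = [
            EpochRecord(epoch=e, lr=0.01 * 0.95**e, train_loss=2.0 - 0.1 * e,
                        train_acc=0.1 * e, test_acc=0.05 * e)
            for e in range(5)
        ]
        csv_path = tmp_path / "history.csv"
        plot_path = tmp_path / "history.png"
        export_history(history, csv_path, plot_path)
        df = pd.read_csv(csv_path)
        assert list(df.columns) == ["epoch", "lr", "train_loss", "train_acc",
                                    "test_acc"]
        assert len(df) == 5
        assert plot_path.exists()

    def test_record_validation(self):
        with pytest.raises(ValueError):
            EpochRecord(epoch=0, lr=0.01, train_loss=-1.0, train_acc=0.5,
                        test_acc=0.5)
        with pytest.raises(ValueError):
            EpochRecord(epoch=0, lr=0.01, train_loss=1.0, train_acc=1.5,
                        test_acc=0.5)
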