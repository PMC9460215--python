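"""Loss arithmetic (closed forms), training-loop mechanics, baselines."""

import math

import numpy as np
import pytest

from bowelwarn import nn, train
from bowelwarn.model import build_classifier
from bowelwarn.train import (TrainConfig, cnn_baseline_train, generator_loss,
                             supervised_loss, unsupervised_loss)


def _rows(*rows):
    return np.array(rows, dtype=np.float64)


class TestSupervisedLoss:
    def test_perfect_prediction_is_zero(self):
        p = _rows([1.0, 0.0, 0.0])
        assert supervised_loss(p, [0]) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_probabilities_give_ln3(self):
        p = _rows([1 / 3, 1 / 3, 1 / 3])
        assert supervised_loss(p, [1]) == pytest.approx(math.log(3), rel=1e-9)

    def test_batch_mean_of_neg_log(self):
        p = _rows([0.5, 0.3, 0.2], [0.25, 0.55, 0.2])
        expected = (math.log(2) + math.log(4)) / 2
        assert supervised_loss(p, [0, 0]) == pytest.approx(expected, rel=1e-9)

    def test_fake_label_rejected(self):
        with pytest.raises(ValueError, match="fake"):
            supervised_loss(_rows([0.2, 0.3, 0.5]), [2])

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            supervised_loss(_rows([0.9, 0.9, 0.9]), [0])


class TestUnsupervisedLoss:
    def test_perfect_discrimination_is_zero(self):
        real = _rows([0.6, 0.4, 0.0])
        fake = _rows([0.0, 0.0, 1.0])
        assert unsupervised_loss(real, fake) == pytest.approx(0.0, abs=1e-5)

    def test_symmetric_half_gives_two_ln2(self):
        real = _rows([0.25, 0.25, 0.5])
        fake = _rows([0.25, 0.25, 0.5])
        assert unsupervised_loss(real, fake) == pytest.approx(
            2 * math.log(2), rel=1e-9)

    def test_divergence_clamped_to_ceiling(self):
        real = _rows([0.0, 0.0, 1.0])  # real data called fake
        fake = _rows([0.0, 0.0, 1.0])
        value = unsupervised_loss(real, fake)
        assert np.isfinite(value)
        assert value == pytest.approx(-math.log(train.CLAMP_EPS), rel=1e-3)

    def test_empty_real_batch_reduces_to_fake_term(self):
        fake = _rows([0.1, 0.1, 0.8])
        expected = -math.log(0.8)
        assert unsupervised_loss(np.empty((0, 3)), fake) == pytest.approx(
            expected, rel=1e-9)

    def test_empty_fake_batch_rejected(self):
        with pytest.raises(ValueError, match="fake"):
            unsupervised_loss(_rows([0.5, 0.3, 0.2]), np.empty((0, 3)))


class TestGeneratorLoss:
    def test_fooling_classifier_is_zero(self):
        assert generator_loss(_rows([0.7, 0.3, 0.0])) == pytest.approx(
            0.0, abs=1e-5)

    def test_half_gives_ln2(self):
        assert generator_loss(_rows([0.25, 0.25, 0.5])) == pytest.approx(
            math.log(2), rel=1e-9)

    def test_detected_fake_clamped(self):
        value = generator_loss(_rows([0.0, 0.0, 1.0]))
        assert np.isfinite(value)
        assert value == pytest.approx(-math.log(train.CLAMP_EPS), rel=1e-3)


class TestTrainingLoop:
    def test_seeded_run_is_reproducible(self, random_frames):
        frames, labels = random_frames
        config = TrainConfig(epochs=2, seed=7, noise_length=32)
        a = train.train(frames[:30], labels[:30], frames[30:], config)
        b = train.train(frames[:30], labels[:30], frames[30:], config)
        assert [r.loss for r in a.history] == [r.loss for r in b.history]
        for (pa, _), (pb, _) in zip(a.classifier.parameters(),
                                    b.classifier.parameters()):
            assert np.array_equal(pa, pb)

    def test_loss_decomposition_holds_at_every_step(self, tiny_train_result):
        result, _ = tiny_train_result
        assert len(result.step_records) > 0
        for l1, l2, loss in result.step_records:
            assert loss == pytest.approx(l1 + l2, rel=1e-12)
            assert l1 >= 0 and l2 >= 0

    def test_history_epochs_and_nonnegativity(self, tiny_train_result):
        result, config = tiny_train_result
        assert [r.epoch for r in result.history] == list(range(config.epochs))
        for rec in result.history:
            assert rec.L1 >= 0 and rec.L2 >= 0 and rec.generator_loss >= 0
            assert rec.loss == pytest.approx(rec.L1 + rec.L2, rel=1e-12)

    def test_empty_unlabeled_pool_uses_fake_term_only(self, random_frames):
        """Without an unlabeled pool the unsupervised loss reduces to the
        generated-data term; training still runs and records finite,
        non-negative losses."""
        frames, labels = random_frames
        result = train.train(frames[:20], labels[:20], frames[:0],
                             TrainConfig(epochs=1, seed=5, noise_length=16))
        assert all(np.isfinite(r.L2) and r.L2 >= 0 for r in result.history)

    def test_empty_labeled_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            train.train(np.empty((0, 10_000)), np.empty(0, int),
                        np.empty((0, 10_000)), TrainConfig(epochs=1))

    def test_missing_class_rejected(self, random_frames):
        frames, _ = random_frames
        labels = np.zeros(len(frames), dtype=np.int64)  # class 1 absent
        with pytest.raises(ValueError, match="classes"):
            train.train(frames, labels, frames[:0], TrainConfig(epochs=1))

    def test_single_small_step_does_not_increase_batch_loss(self,
                                                            random_frames):
        """One classifier update at a small learning rate (1e-4) on a fixed
        batch must not increase that batch's supervised loss."""
        frames, labels = random_frames
        xb, yb = frames[:10][:, :, None], labels[:10]
        clf = build_classifier(2, rng=np.random.default_rng(0))
        opt = nn.Adam(clf, lr=1e-4)

        def batch_loss():
            return supervised_loss(
                nn.softmax(clf.forward(xb).astype(np.float64)), yb)

        before = batch_loss()
        clf.zero_grad()
        p = nn.softmax(clf.forward(xb).astype(np.float64))
        clf.backward(train._grad_supervised(p, yb).astype(np.float32),
                     need_input_grad=False)
        opt.step()
        assert batch_loss() <= before + 1e-6


class TestCnnBaseline:
    def test_head_has_two_outputs(self, random_frames):
        frames, labels = random_frames
        model, losses = cnn_baseline_train(frames, labels,
                                           TrainConfig(epochs=1, seed=0))
        assert model.layers[-1].params["W"].shape[1] == 2
        assert len(losses) == 1

    def test_seeded_run_reproducible(self, random_frames):
        frames, labels = random_frames
        config = TrainConfig(epochs=1, seed=3)
        a, la = cnn_baseline_train(frames, labels, config)
        b, lb = cnn_baseline_train(frames, labels, config)
        assert la == lb
        for (pa, _), (pb, _) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)

    def test_learns_separable_data_above_chance(self, separable_config):
        """On well-separated synthetic frames a short supervised run must
        beat the 0.7 majority-class rate on held-out data."""
        from bowelwarn import synth
        from bowelwarn.model import forward_classifier

        frames, labels = synth.generate_fixture_set(separable_config,
                                                    120, 60, rng_seed=21)
        test_frames, test_labels = synth.generate_fixture_set(
            separable_config, 100, 30, rng_seed=22)
        model, _ = cnn_baseline_train(frames, labels,
                                      TrainConfig(epochs=8, seed=1))
        preds = np.argmax(forward_classifier(model, test_frames), axis=1)
        assert np.mean(preds == test_labels) > 0.7


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tiny_train_result,
                                              tmp_path):
        result, config = tiny_train_result
        path = tmp_path / "model.ckpt.npz"
        train.save_checkpoint(path, result, config)
        clf, gen, cfg = train.load_checkpoint(path)
        assert cfg == config
        rng = np.random.default_rng(0)
        frames = rng.uniform(-1, 1, (3, 10_000)).astype(np.float32)
        from bowelwarn.model import forward_classifier
        assert np.array_equal(forward_classifier(result.classifier, frames),
                              forward_classifier(clf, frames))
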