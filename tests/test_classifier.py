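"""Classifier contracts: loss, confusion accuracy, training loop, networks."""

import dataclasses
import math

import numpy as np
import pytest

from bestmcg import (
    ClassifierConfig,
    ConfusionMatrix,
    TrainingResult,
    accuracy_from_confusion,
    best_validation_accuracy,
    build_classifier,
    cross_entropy,
    split_dataset,
    train_classifier,
)
from bestmcg.classifier import EpochRecord
from bestmcg import _nn

from conftest import quick_classifier, synthetic_maps


def _dataset(n_per_class, offset, seed):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return split_dataset(synthetic_maps(n_per_class, offset, seed))


class TestCrossEntropy:
    @pytest.mark.parametrize(
        "p,y,expected",
        [
            (1.0, 1, 0.0),
            (0.5, 1, math.log(2)),
            (0.5, 0, math.log(2)),
            (0.2, 0, -math.log(0.8)),
        ],
    )
    def test_pointwise_values(self, p, y, expected):
        assert cross_entropy(p, y) == pytest.approx(expected, abs=1e-9)

    def test_batch_mean(self):
        # {(y=1, p=0.8), (y=0, p=0.2)} -> both contribute -ln 0.8
        assert cross_entropy([0.8, 0.2], [1, 0]) == pytest.approx(-math.log(0.8), abs=1e-12)

    def test_clamping_keeps_loss_finite(self):
        assert np.isfinite(cross_entropy(0.0, 1))
        assert np.isfinite(cross_entropy(1.0, 0))


class TestConfusionAccuracy:
    @pytest.mark.parametrize(
        "cm,expected",
        [
            (ConfusionMatrix(2000, 0, 0, 2000), 1.0),
            (ConfusionMatrix(0, 2000, 2000, 0), 0.0),
            (ConfusionMatrix(1700, 500, 300, 1500), 0.8),
        ],
    )
    def test_accuracy_formula(self, cm, expected):
        assert accuracy_from_confusion(cm) == pytest.approx(expected)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            accuracy_from_confusion(ConfusionMatrix(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 1)

    def test_accuracy_matches_direct_counting(self, rng):
        y = rng.integers(0, 2, size=500)
        pred = rng.integers(0, 2, size=500)
        cm = ConfusionMatrix(
            tp=int(np.sum((pred == 1) & (y == 1))),
            fp=int(np.sum((pred == 1) & (y == 0))),
            fn=int(np.sum((pred == 0) & (y == 1))),
            tn=int(np.sum((pred == 0) & (y == 0))),
        )
        assert accuracy_from_confusion(cm) == pytest.approx(float(np.mean(pred == y)))


class TestBestEpoch:
    def _result(self, accuracies):
        cm = ConfusionMatrix(1, 1, 1, 1)
        records = tuple(
            EpochRecord(epoch=i + 1, train_loss=1.0, val_loss=1.0, confusion=cm, accuracy=a)
            for i, a in enumerate(accuracies)
        )
        return TrainingResult(records=records, config=ClassifierConfig())

    def test_argmax_selection(self):
        assert best_validation_accuracy(self._result([0.6, 0.9, 0.7])) == (2, 0.9)

    def test_ties_break_to_the_earliest_epoch(self):
        assert best_validation_accuracy(self._result([0.7, 0.7, 0.7])) == (1, 0.7)

    def test_thirty_record_argmax_oracle(self, rng):
        accs = rng.uniform(0.4, 0.9, size=30).tolist()
        accs[17] = 0.95
        epoch, acc = best_validation_accuracy(self._result(accs))
        assert (epoch, acc) == (18, 0.95)


class TestNetworks:
    def test_cnn_forward_produces_probability_vectors(self):
        config = ClassifierConfig(
            architecture="dense_se_cnn", init_channels=8,
            block_layers=(2, 2), growth=4, epochs=1,
        )
        model = build_classifier(config, (16, 16))
        X = np.random.default_rng(0).normal(size=(3, 16, 16))
        probs = model.predict_proba(X)
        assert probs.shape == (3, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(probs > 0)

    def test_transition_layers_halve_the_channel_count(self):
        config = ClassifierConfig(
            architecture="dense_se_cnn", init_channels=8,
            block_layers=(2, 2, 2), growth=4, epochs=1,
        )
        model = build_classifier(config, (16, 16))
        blocks = [m for m in model.net.modules if isinstance(m, _nn.DenseBlock)]
        transitions = [m for m in model.net.modules if isinstance(m, _nn.Transition)]
        assert len(blocks) == 3 and len(transitions) == 2
        for block, transition in zip(blocks, transitions):
            assert transition.cout == block.cout // 2

    def test_logistic_probabilities_lie_in_the_open_interval(self):
        model = build_classifier(quick_classifier(), (6, 6))
        X = np.random.default_rng(0).normal(size=(5, 6, 6))
        probs = model.predict_proba(X)
        assert np.all((probs > 0) & (probs < 1))

    def test_cnn_gradients_match_finite_differences(self):
        """Backprop oracle: central finite differences through the full net."""
        rng = np.random.default_rng(42)
        config = ClassifierConfig(
            architecture="dense_se_cnn", init_channels=4,
            block_layers=(1,), growth=3, se_reduction=2, epochs=1, seed=1,
        )
        model = build_classifier(config, (8, 8))
        X = rng.normal(size=(4, 8, 8))
        y = np.array([0, 1, 1, 0])

        def loss_value():
            logits = model.forward_logits(X, training=True)
            loss, _, _ = _nn.softmax_cross_entropy(logits, y)
            return loss

        logits = model.forward_logits(X, training=True)
        _, dlogits, _ = _nn.softmax_cross_entropy(logits, y)
        for p in model.net.params():
            p.grad[...] = 0.0
        model.net.backward(dlogits)

        eps = 1e-6
        checked = 0
        for p in model.net.params():
            flat = p.value.reshape(-1)
            grad = p.grad.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 3)):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_value()
                flat[idx] = orig - eps
                down = loss_value()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)
                checked += 1
        assert checked > 10


class TestTraining:
    def test_thirty_epochs_emit_thirty_records(self):
        data = _dataset(60, offset=3.0, seed=0)
        result = train_classifier(data, quick_classifier(epochs=30))
        assert len(result.records) == 30
        assert [r.epoch for r in result.records] == list(range(1, 31))

    def test_separable_fixture_reaches_high_accuracy_and_loss_decreases(self):
        data = _dataset(200, offset=3.0, seed=1)
        result = train_classifier(data, quick_classifier(epochs=30))
        assert result.best_accuracy >= 0.99
        assert result.records[-1].train_loss < result.records[0].train_loss

    def test_null_fixture_stays_near_chance(self):
        data = _dataset(500, offset=0.0, seed=2)
        result = train_classifier(data, quick_classifier(epochs=10))
        n_val = len(data.validation)
        assert abs(result.best_accuracy - 0.5) <= 3 * 0.5 / np.sqrt(n_val)

    def test_training_is_reproducible_for_a_fixed_seed(self):
        data = _dataset(50, offset=1.0, seed=3)
        r1 = train_classifier(data, quick_classifier(epochs=3, seed=11))
        r2 = train_classifier(data, quick_classifier(epochs=3, seed=11))
        assert [r.accuracy for r in r1.records] == [r.accuracy for r in r2.records]
        assert [r.train_loss for r in r1.records] == [r.train_loss for r in r2.records]

    def test_single_class_split_rejected(self):
        data = _dataset(20, offset=1.0, seed=4)
        broken = dataclasses.replace(
            data, training=[m for m in data.training if m.label == 0]
        )
        with pytest.raises(ValueError):
            train_classifier(broken, quick_classifier())

    def test_small_cnn_trains_on_the_separable_fixture(self):
        data = _dataset(30, offset=3.0, seed=5)
        config = ClassifierConfig(
            architecture="dense_se_cnn", epochs=3, batch_size=16,
            init_channels=4, block_layers=(1,), growth=3, se_reduction=2, seed=0,
        )
        result = train_classifier(data, config)
        assert len(result.records) == 3
        assert result.records[-1].train_loss < result.records[0].train_loss

    def test_validation_loss_tracks_training_loss_on_sentinel_geometries(self):
        """Scaled-down convergence check on the three extreme geometries:
        no divergence, final validation loss within 2x final training loss."""
        import warnings

        from bestmcg import HeartModel, assemble_final_measurements, calibrate_sigma
        from bestmcg import generate_noise_bank, measure_models, sample_lesion_sets
        from bestmcg.sensors import ArrayConfig, SensorSpec

        sigma = calibrate_sigma()
        sets = sample_lesion_sets(150, np.random.default_rng(21))
        bank = generate_noise_bank(150, sigma, np.random.default_rng(22))
        for a, h, d in ((0.5, 0.5, 2.0), (4.0, 4.0, 5.0), (4.0, 0.5, 5.0)):
            normal, abnormal = measure_models(
                HeartModel(), sets, ArrayConfig(d=d), SensorSpec(a=a, h=h)
            )
            maps = assemble_final_measurements(normal, abnormal, bank)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                data = split_dataset(maps)
            result = train_classifier(data, quick_classifier(epochs=8, seed=6))
            final = result.records[-1]
            assert final.val_loss <= 2.0 * max(final.train_loss, 1e-6)
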