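"""Training-loop, metrics and harness contracts (desk-scale sizes only)."""

import numpy as np
import pandas as pd
import pytest

from leafmoe.backbone import NoiseConfig
from leafmoe.moe import MoEConfig, MoEHead
from leafmoe.objectives import LossWeights
from leafmoe.trainer import (MetricsReport, TrainConfig, TrainingHistory,
                             ablate_regularizers, evaluate,
                             mean_pairwise_similarity, predict, sweep_experts,
                             track_expert_usage, train)


@pytest.fixture(scope="module")
def toy_features():
    """Two Gaussian blobs per class in 8-D: trivially learnable."""
    rng = np.random.default_rng(3)
    centers = rng.normal(0, 2.0, size=(3, 8))
    x = np.concatenate([rng.normal(c, 0.3, size=(30, 8)) for c in centers])
    y = np.repeat(np.arange(3), 30)
    return x, y


def _head(seed=0, num_experts=4, top_k=2):
    return MoEHead(8, 3, MoEConfig(num_experts=num_experts, top_k=top_k,
                                   hidden_dim=16), NoiseConfig(sigma=0.0),
                   seed=seed)


class TestTrainLoop:
    def test_history_length_matches_epochs(self, toy_features):
        history = train(_head(), toy_features, toy_features,
                        TrainConfig(epochs=2, batch_size=16, seed=0))
        assert len(history) == 2
        assert history.usage.shape == (2, 4)

    def test_usage_rows_sum_to_one(self, toy_features):
        history = train(_head(), toy_features, toy_features,
                        TrainConfig(epochs=3, batch_size=16, seed=0))
        np.testing.assert_allclose(history.usage.sum(axis=1), 1.0, atol=1e-9)

    def test_same_seed_reproduces_history_bitwise(self, toy_features):
        cfg = TrainConfig(epochs=2, batch_size=16, seed=5)
        h1 = train(_head(seed=5), toy_features, toy_features, cfg)
        h2 = train(_head(seed=5), toy_features, toy_features, cfg)
        assert h1.val_accuracy[-1] == h2.val_accuracy[-1]
        pd.testing.assert_frame_equal(h1.losses, h2.losses)

    def test_learns_separable_blobs(self, toy_features):
        history = train(_head(), toy_features, toy_features,
                        TrainConfig(epochs=15, batch_size=16, seed=0))
        assert history.val_accuracy[-1] >= 0.95

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(_head(), (np.zeros((0, 8)), np.zeros(0, dtype=int)),
                  (np.zeros((0, 8)), np.zeros(0, dtype=int)), TrainConfig(epochs=1))


class TestMetrics:
    def test_perfect_predictions(self, toy_features):
        x, y = toy_features
        class Oracle:
            def eval(self):
                pass
            def __call__(self, xb):
                from leafmoe.autodiff import Tensor
                out = np.zeros((len(xb), 3))
                idx = [np.flatnonzero((x == row).all(axis=1))[0] for row in xb]
                out[np.arange(len(xb)), y[idx]] = 1.0
                return Tensor(out)
        report = evaluate(Oracle(), (x, y), n_classes=3)
        assert report.accuracy == 1.0
        assert report.macro_f1 == pytest.approx(1.0)
        assert report.confusion.sum() == len(y)

    def test_confusion_matrix_arithmetic(self):
        # predictions realizing the confusion matrix [[5, 5], [0, 10]]
        y = np.array([0] * 10 + [1] * 10)
        y_hat = np.array([0] * 5 + [1] * 5 + [1] * 10)

        class Fixed:
            def eval(self):
                pass
            def __call__(self, xb):
                from leafmoe.autodiff import Tensor
                out = np.zeros((len(xb), 2))
                out[np.arange(len(xb)), y_hat[xb[:, 0].astype(int)]] = 1.0
                return Tensor(out)

        x = np.arange(20, dtype=float)[:, None]
        report = evaluate(Fixed(), (x, y), n_classes=2)
        assert report.confusion.tolist() == [[5, 5], [0, 10]]
        assert report.accuracy == pytest.approx(0.75)
        recall_0 = report.confusion[0, 0] / report.confusion[0].sum()
        precision_0 = report.confusion[0, 0] / report.confusion[:, 0].sum()
        assert recall_0 == pytest.approx(0.5) and precision_0 == pytest.approx(1.0)

    def test_metrics_match_confusion_recomputation(self, rng):
        y = rng.integers(0, 4, size=1000)
        y_hat = rng.integers(0, 4, size=1000)

        class Fixed:
            def eval(self):
                pass
            def __call__(self, xb):
                from leafmoe.autodiff import Tensor
                out = np.zeros((len(xb), 4))
                out[np.arange(len(xb)), y_hat[xb[:, 0].astype(int)]] = 1.0
                return Tensor(out)

        report = evaluate(Fixed(), (np.arange(1000, dtype=float)[:, None], y),
                          n_classes=4)
        cm = np.zeros((4, 4), dtype=int)
        for t, p in zip(y, y_hat):
            cm[t, p] += 1
        assert report.confusion.tolist() == cm.tolist()
        assert report.accuracy == pytest.approx(np.trace(cm) / cm.sum())
        recalls = cm.diagonal() / cm.sum(axis=1)
        precisions = cm.diagonal() / np.maximum(cm.sum(axis=0), 1)
        f1 = 2 * precisions * recalls / np.maximum(precisions + recalls, 1e-12)
        assert report.macro_recall == pytest.approx(recalls.mean())
        assert report.macro_precision == pytest.approx(precisions.mean())
        assert report.macro_f1 == pytest.approx(f1.mean())

    def test_absent_class_warns(self, toy_features):
        x, y = toy_features
        model = _head()
        with pytest.warns(UserWarning, match="classes present"):
            evaluate(model, (x[:5], np.zeros(5, dtype=int)), n_classes=3)


class TestUsageTracking:
    def test_uniform_usage_not_collapsed(self):
        history = TrainingHistory(pd.DataFrame({"l_total": [0.0] * 3}),
                                  np.zeros(3), np.zeros(3),
                                  np.full((3, 4), 0.25))
        df = track_expert_usage(history)
        assert not df.attrs["collapsed"]
        assert df.min_usage.min() == pytest.approx(0.25)

    def test_expert_hitting_zero_flags_collapse(self):
        usage = np.full((5, 4), 0.25)
        usage[-1] = [0.5, 0.5, 0.0, 0.0]
        history = TrainingHistory(pd.DataFrame({"l_total": [0.0] * 5}),
                                  np.zeros(5), np.zeros(5), usage)
        assert track_expert_usage(history).attrs["collapsed"]

    def test_empty_history_rejected(self):
        history = TrainingHistory(pd.DataFrame(), np.zeros(0), np.zeros(0),
                                  np.zeros((0, 4)))
        with pytest.raises(ValueError):
            track_expert_usage(history)


class TestHarnesses:
    def test_sweep_grid_shape_and_best_k(self, toy_features):
        cfg = TrainConfig(epochs=2, batch_size=16)
        df = sweep_experts(lambda k, seed: _head(seed=seed, top_k=k),
                           toy_features, toy_features, cfg, [1, 2, 4], [0, 1])
        assert len(df) == 6
        assert set(df.K) == {1, 2, 4}
        assert df.attrs["best_k"] in {1, 2, 4}

    def test_ablation_grid_rows(self, toy_features):
        cfg = TrainConfig(epochs=2, batch_size=16)
        grid = [(0.0, 0.0, 0.0), (0.5, 0.01, 0.1)]
        df = ablate_regularizers(lambda seed: _head(seed=seed), toy_features,
                                 toy_features, cfg, grid, [0])
        assert len(df) == 2
        assert {"val_accuracy", "weight_similarity", "min_final_usage"} <= set(df.columns)

    def test_similarity_of_orthogonal_vs_identical(self):
        b = np.array([[1.0, 0.0]])
        c = np.array([[0.0, 1.0]])
        assert mean_pairwise_similarity([b, b]) == pytest.approx(1.0)
        assert mean_pairwise_similarity([b, c]) == pytest.approx(0.0)
        # identical orthonormal matrices of rank r score sqrt(r)/r
        a = np.eye(2)
        assert mean_pairwise_similarity([a, a]) == pytest.approx(np.sqrt(2) / 2)


def test_predict_batches_match_single_pass(toy_features):
    x, _ = toy_features
    model = _head()
    np.testing.assert_array_equal(predict(model, x, batch_size=7),
                                  predict(model, x, batch_size=1000))
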