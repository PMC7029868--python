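"""Classifier construction, training regime and probability semantics."""

import numpy as np
import pytest

from signkin import _nn
from signkin._nn import cross_entropy, softmax
from signkin.classifiers import (
    FlattenedBaseline,
    NeuralSequenceClassifier,
    TrainConfig,
    baseline_fit_predict,
    build_model,
    make_classifier,
    train,
)
from signkin.errors import ConfigError, LeakageError


def _separable_sequences(n_per_class=30, n_classes=2, T=20, F=6, seed=0):
    """Classes distinguished by a constant offset: trivially separable."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        base = np.zeros((T, F)) + 3.0 * c
        for _ in range(n_per_class):
            X.append(base + 0.1 * rng.standard_normal((T, F)))
            y.append(c)
    return np.asarray(X), np.asarray(y)


class TestBuildModel:
    def test_mlp_consumes_flattened_input(self):
        net = build_model("mlp", (100, 60), 60, rng=np.random.default_rng(0))
        dense = [l for l in net.layers if isinstance(l, _nn.Dense)]
        assert dense[0].params["W"].shape[0] == 6000

    def test_mlp_parameter_count_matches_hand_formula(self):
        net = build_model("mlp", (100, 60), 60, rng=np.random.default_rng(0))
        widths = [6000, 256, 512, 1024, 60]
        expected = sum(
            (w_in + 1) * w_out for w_in, w_out in zip(widths, widths[1:])
        )
        assert net.n_parameters() == expected

    def test_deepconvlstm_layer_sequence(self):
        net = build_model("deepconvlstm", (100, 60), 60,
                          rng=np.random.default_rng(0))
        kinds = [type(l).__name__ for l in net.layers
                 if type(l).__name__ != "Dropout"]
        assert kinds == [
            "ExpandChannel", "TimeConv", "TimeConv", "TimeConv", "TimeConv",
            "MergeChannels", "LSTM", "LSTM", "LastStep", "Dense",
        ]
        convs = [l for l in net.layers if isinstance(l, _nn.TimeConv)]
        assert [c.params["W"].shape[2] for c in convs] == [16, 16, 32, 64]
        assert [c.kernel for c in convs] == [20, 20, 10, 5]
        assert [c.stride for c in convs] == [1, 2, 2, 2]

    def test_conv_time_axis_shrinks_to_13_steps(self):
        t = 100
        for s in (1, 2, 2, 2):
            t = _nn.TimeConv.output_length(t, s)
        assert t == 13

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigError):
            build_model("transformer", (100, 60), 60)


class TestSoftmaxAndLoss:
    def test_probability_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        p = softmax(rng.standard_normal((50, 7)) * 10)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_equal_logits_give_uniform_probabilities(self):
        p = softmax(np.full((3, 5), 2.7))
        np.testing.assert_allclose(p, 1.0 / 5.0, atol=1e-12)

    def test_hand_computed_softmax(self):
        logits = np.array([[1.0, 2.0, 3.0]])
        e = np.exp([1.0, 2.0, 3.0])
        np.testing.assert_allclose(softmax(logits)[0], e / e.sum(), atol=1e-12)

    def test_loss_equals_negative_log_true_class_probability(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((20, 6))
        y = rng.integers(0, 6, 20)
        onehot = np.eye(6)[y]
        expected = -np.mean(np.log(softmax(logits)[np.arange(20), y]))
        assert cross_entropy(logits, onehot) == pytest.approx(expected, abs=1e-9)


class TestTraining:
    def test_mlp_reaches_full_training_accuracy_on_separable_data(self):
        X, y = _separable_sequences()
        model = NeuralSequenceClassifier(
            architecture="mlp", mlp_units=(32,), batch_size=16,
            max_epochs=60, keep_prob=1.0, random_state=0,
        )
        model.fit(X, y)
        assert max(model.history_["train_acc"]) == 1.0
        assert model.stopping_epoch_ <= 60

    def test_early_stop_on_decreasing_validation_accuracy(self):
        """If validation accuracy never improves after epoch 1, training
        stops after the patience window and keeps the epoch-1 parameters."""

        class Shrinking(_nn.Layer):
            pass

        X, y = _separable_sequences(n_per_class=8)
        # validation labels permuted adversarially: accuracy cannot improve
        Xv, yv = X[:8], (y[:8] + 1) % 2
        model = NeuralSequenceClassifier(
            architecture="mlp", mlp_units=(8,), batch_size=8,
            max_epochs=50, patience=5, keep_prob=1.0, random_state=1,
        )
        model.fit(X, y, X_val=Xv, y_val=yv)
        assert model.stopping_epoch_ <= 10

    def test_same_seed_identical_history(self):
        X, y = _separable_sequences(n_per_class=6)
        kwargs = dict(architecture="mlp", mlp_units=(8,), batch_size=8,
                      max_epochs=5, random_state=3)
        a = NeuralSequenceClassifier(**kwargs).fit(X, y)
        b = NeuralSequenceClassifier(**kwargs).fit(X, y)
        assert a.history_ == b.history_

    def test_overlapping_subject_tags_rejected(self):
        X, y = _separable_sequences(n_per_class=4)
        model = NeuralSequenceClassifier(architecture="mlp", mlp_units=(4,),
                                         max_epochs=1, random_state=0)
        with pytest.raises(LeakageError):
            model.fit(X, y, X_val=X, y_val=y,
                      train_subjects=["a", "b"], val_subjects=["b", "c"])

    def test_empty_training_set_rejected(self):
        net = build_model("mlp", (4, 2), 2, rng=np.random.default_rng(0),
                          mlp_units=(4,))
        with pytest.raises(ConfigError):
            train(net, np.empty((0, 4, 2)), np.empty(0, dtype=int))

    def test_learning_rate_staircase_decay(self):
        net = build_model("mlp", (4, 2), 2, rng=np.random.default_rng(0),
                          mlp_units=(4,))
        opt = _nn.Adam(net, learning_rate=1e-3, decay=0.9, decay_every=5)
        assert opt.learning_rate(0) == pytest.approx(1e-3)
        assert opt.learning_rate(4) == pytest.approx(1e-3)
        assert opt.learning_rate(5) == pytest.approx(9e-4)
        assert opt.learning_rate(12) == pytest.approx(1e-3 * 0.9**2)


class TestGradients:
    """Analytic gradients vs central finite differences on tiny networks."""

    @pytest.mark.parametrize(
        "name,layers_fn,x_shape,n_classes",
        [
            (
                "dense",
                lambda rng: [_nn.Flatten(), _nn.Dense(12, 8, "sigmoid", rng),
                             _nn.Dense(8, 3, None, rng)],
                (4, 3, 4),
                3,
            ),
            (
                "conv",
                lambda rng: [_nn.ExpandChannel(),
                             _nn.TimeConv(1, 3, 4, 2, rng=rng),
                             _nn.Flatten(), _nn.Dense(27, 3, None, rng)],
                (2, 5, 3),
                3,
            ),
            (
                "lstm",
                lambda rng: [_nn.LSTM(4, 6, rng=rng), _nn.LSTM(6, 5, rng=rng),
                             _nn.LastStep(), _nn.Dense(5, 3, None, rng)],
                (3, 7, 4),
                3,
            ),
            (
                "convlstm",
                lambda rng: [_nn.ExpandChannel(),
                             _nn.TimeConv(1, 2, 3, 2, rng=rng),
                             _nn.MergeChannels(), _nn.LSTM(6, 5, rng=rng),
                             _nn.LastStep(), _nn.Dense(5, 4, None, rng)],
                (2, 8, 3),
                4,
            ),
        ],
    )
    def test_analytic_matches_numeric(self, name, layers_fn, x_shape, n_classes):
        rng = np.random.default_rng(1)
        net = _nn.Network(layers_fn(rng))
        x = rng.standard_normal(x_shape)
        y = np.eye(n_classes)[rng.integers(0, n_classes, x_shape[0])]
        net.loss_and_grad(x, y)
        for layer in net.layers:
            for k, p in layer.params.items():
                analytic = layer.grads[k].copy()
                flat = p.ravel()
                for i in rng.choice(flat.size, size=min(6, flat.size),
                                    replace=False):
                    eps, orig = 1e-6, flat[i]
                    flat[i] = orig + eps
                    lp = cross_entropy(net.forward(x), y)
                    flat[i] = orig - eps
                    lm = cross_entropy(net.forward(x), y)
                    flat[i] = orig
                    numeric = (lp - lm) / (2 * eps)
                    denom = max(1e-8, abs(numeric) + abs(analytic.ravel()[i]))
                    assert abs(numeric - analytic.ravel()[i]) / denom < 1e-4


class TestBaselines:
    def test_knn_predicts_label_of_identical_training_vectors(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 5, 4))
        X_train = np.concatenate([np.repeat(x, 12, axis=0),
                                  rng.standard_normal((20, 5, 4)) + 10])
        y_train = np.array(["hit"] * 12 + ["other"] * 20)
        pred = baseline_fit_predict("knn", (X_train, y_train), x)
        assert pred[0] == "hit"

    def test_rf_on_single_class_always_predicts_it(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((15, 4, 3))
        pred = baseline_fit_predict(
            "rf", (X, np.array(["only"] * 15)), rng.standard_normal((6, 4, 3))
        )
        assert np.all(pred == "only")

    def test_svm_separates_linearly_separable_classes(self):
        X, y = _separable_sequences(n_per_class=20)
        X_test, y_test = _separable_sequences(n_per_class=5, seed=99)
        pred = baseline_fit_predict("svm", (X, y), X_test)
        assert np.mean(pred == y_test) == 1.0

    def test_unknown_baseline_rejected(self):
        with pytest.raises(ConfigError):
            FlattenedBaseline(model="gbm").fit(np.zeros((4, 2, 2)), [0, 1, 0, 1])

    def test_registry_covers_all_names(self):
        for name in ("knn", "rf", "svm", "constant", "mlp", "convnet", "rnn",
                     "deepconvlstm", "deepconvlstm-small"):
            estimator = make_classifier(name, random_state=0)
            assert hasattr(estimator, "fit")

    def test_predict_proba_rows_sum_to_one(self):
        X, y = _separable_sequences(n_per_class=10)
        model = FlattenedBaseline(model="svm", random_state=0).fit(X, y)
        p = model.predict_proba(X[:5])
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
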