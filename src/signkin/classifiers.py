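"""The seven sequence classifiers and their training regime.

Classical baselines (k-NN with k = 10, random forest with 1000 trees of
depth 5, linear-kernel SVM) consume the 100x60 matrices flattened to
6000-vectors.  The four neural architectures are:

========  ==================================================================
mlp       6000 -> 256 -> 512 -> 1024 (sigmoid) -> softmax
convnet   4 time-axis conv layers (16/16/32/64 channels, kernels
          20/20/10/5 x 1, strides 1/2/2/2, ReLU, "same" padding) ->
          dense 128 (tanh) -> softmax
rnn       4 stacked LSTM layers of 256 units -> last time step -> softmax
deepconvlstm
          the convnet's 4 conv layers -> 2 LSTM layers of 256 units ->
          last time step -> softmax
========  ==================================================================

Kernels slide along the time axis only (one-wide in the feature axis) and
no pooling is used.  Training minimises softmax cross-entropy with Adam
(lr 0.001, staircase decay x0.9 every 5 epochs), mini-batches of 500,
inverted dropout at keep probability 0.8 on every hidden layer, and early
stopping on validation accuracy (patience 5, best-epoch parameters
restored).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import _nn
from ._nn import Network, softmax
from .errors import ConfigError, LeakageError

NEURAL_MODELS = ("mlp", "convnet", "rnn", "deepconvlstm")
BASELINE_MODELS = ("knn", "rf", "svm")
MODEL_NAMES = BASELINE_MODELS + NEURAL_MODELS


@dataclass
class TrainConfig:
    """Optimisation hyperparameters shared by all neural models."""

    learning_rate: float = 1e-3
    decay: float = 0.9
    decay_every: int = 5
    batch_size: int = 500
    keep_prob: float = 0.8
    max_epochs: int = 200
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.decay, self.batch_size,
               self.keep_prob, self.max_epochs, self.patience) <= 0:
            raise ConfigError("all training parameters must be positive")


# ---------------------------------------------------------------------------
# architecture construction


def _conv_stack(rng, filters, kernels, strides, keep_prob):
    layers = [_nn.ExpandChannel()]
    c_in = 1
    for c_out, k, s in zip(filters, kernels, strides):
        layers.append(_nn.TimeConv(c_in, c_out, kernel=k, stride=s,
                                   activation="relu", rng=rng))
        layers.append(_nn.Dropout(keep_prob))
        c_in = c_out
    return layers, c_in


def build_model(
    name: str,
    input_shape: tuple[int, int],
    n_classes: int,
    rng: Optional[np.random.Generator] = None,
    conv_filters: Sequence[int] = (16, 16, 32, 64),
    conv_kernels: Sequence[int] = (20, 20, 10, 5),
    conv_strides: Sequence[int] = (1, 2, 2, 2),
    mlp_units: Sequence[int] = (256, 512, 1024),
    dense_units: int = 128,
    lstm_units: int = 256,
    n_lstm_layers: int = 2,
    keep_prob: float = 0.8,
) -> Network:
    """Build a network for ``input_shape`` = (frames, features)."""
    rng = rng or np.random.default_rng()
    T, F = input_shape
    if name == "mlp":
        layers = [_nn.Flatten()]
        width = T * F
        for units in mlp_units:
            layers.append(_nn.Dense(width, units, "sigmoid", rng=rng))
            layers.append(_nn.Dropout(keep_prob))
            width = units
        layers.append(_nn.Dense(width, n_classes, None, rng=rng))
        return Network(layers)
    if name == "convnet":
        layers, c = _conv_stack(rng, conv_filters, conv_kernels, conv_strides,
                                keep_prob)
        t_out = T
        for s in conv_strides:
            t_out = _nn.TimeConv.output_length(t_out, s)
        layers += [
            _nn.Flatten(),
            _nn.Dense(t_out * F * c, dense_units, "tanh", rng=rng),
            _nn.Dropout(keep_prob),
            _nn.Dense(dense_units, n_classes, None, rng=rng),
        ]
        return Network(layers)
    if name == "rnn":
        layers = []
        width = F
        for _ in range(4):
            layers.append(_nn.LSTM(width, lstm_units, rng=rng))
            layers.append(_nn.Dropout(keep_prob))
            width = lstm_units
        layers += [_nn.LastStep(), _nn.Dense(width, n_classes, None, rng=rng)]
        return Network(layers)
    if name == "deepconvlstm":
        layers, c = _conv_stack(rng, conv_filters, conv_kernels, conv_strides,
                                keep_prob)
        layers.append(_nn.MergeChannels())
        width = F * c
        for _ in range(n_lstm_layers):
            layers.append(_nn.LSTM(width, lstm_units, rng=rng))
            layers.append(_nn.Dropout(keep_prob))
            width = lstm_units
        layers += [_nn.LastStep(), _nn.Dense(width, n_classes, None, rng=rng)]
        return Network(layers)
    raise ConfigError(f"unknown neural model {name!r}")


# ---------------------------------------------------------------------------
# training


def _check_subject_disjoint(train_subjects, val_subjects) -> None:
    if train_subjects is None or val_subjects is None:
        return
    overlap = set(map(str, train_subjects)) & set(map(str, val_subjects))
    if overlap:
        raise LeakageError(
            f"subjects appear in both train and validation: {sorted(overlap)}"
        )


def train(
    network: Network,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
    config: Optional[TrainConfig] = None,
    train_subjects=None,
    val_subjects=None,
) -> dict:
    """Train a network in place; returns the history/manifest dict.

    ``y_*`` are integer class indices.  Early stopping monitors validation
    accuracy with the configured patience and restores the best-epoch
    parameters; without validation data, training runs to ``max_epochs``.
    """
    config = config or TrainConfig()
    if X_train.shape[0] == 0:
        raise ConfigError("empty training set")
    if X_val is not None and X_val.shape[0] == 0:
        raise ConfigError("empty validation set")
    _check_subject_disjoint(train_subjects, val_subjects)
    n_classes = int(max(y_train.max(), 0 if y_val is None else y_val.max())) + 1
    eye = np.eye(n_classes)
    rng = np.random.default_rng(config.seed)
    batch = min(config.batch_size, X_train.shape[0])

    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_state, best_val, best_epoch, since_best = None, -np.inf, 0, 0
    optimizer = _nn.Adam(network, config.learning_rate, config.decay,
                         config.decay_every)

    def evaluate(X, y):
        logits = network.predict_logits(X)
        loss = _nn.cross_entropy(logits, eye[y])
        acc = float(np.mean(np.argmax(logits, axis=1) == y))
        return loss, acc

    stopping_epoch = config.max_epochs
    for epoch in range(config.max_epochs):
        order = rng.permutation(X_train.shape[0])
        epoch_loss, n_correct = 0.0, 0
        for start in range(0, len(order), batch):
            idx = order[start : start + batch]
            loss, logits = network.loss_and_grad(
                X_train[idx], eye[y_train[idx]], rng=rng
            )
            optimizer.step(epoch)
            epoch_loss += loss * len(idx)
            n_correct += int(np.sum(np.argmax(logits, axis=1) == y_train[idx]))
        # training metrics accumulated from the minibatch passes (dropout on)
        history["train_loss"].append(epoch_loss / len(order))
        history["train_acc"].append(n_correct / len(order))
        if X_val is not None:
            val_loss, val_acc = evaluate(X_val, y_val)
            history["val_loss"].append(val_loss)
            history["val_acc"].append(val_acc)
            if val_acc > best_val:
                best_val, best_epoch = val_acc, epoch
                best_state = network.get_state()
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    stopping_epoch = epoch + 1
                    break
    else:
        stopping_epoch = len(history["train_loss"])

    if best_state is not None:
        network.set_state(best_state)
    return {
        "history": history,
        "stopping_epoch": stopping_epoch,
        "best_epoch": best_epoch + 1 if X_val is not None else stopping_epoch,
        "config": asdict(config),
        "n_parameters": network.n_parameters(),
    }


# ---------------------------------------------------------------------------
# estimators


class NeuralSequenceClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style wrapper around the numpy network engine.

    ``X`` is an ``(n_samples, frames, features)`` array.  Extra ``fit``
    keyword arguments accept validation data for early stopping and
    subject tags for leakage checking.
    """

    def __init__(
        self,
        architecture: str = "deepconvlstm",
        conv_filters: tuple = (16, 16, 32, 64),
        conv_kernels: tuple = (20, 20, 10, 5),
        conv_strides: tuple = (1, 2, 2, 2),
        mlp_units: tuple = (256, 512, 1024),
        dense_units: int = 128,
        lstm_units: int = 256,
        n_lstm_layers: int = 2,
        learning_rate: float = 1e-3,
        decay: float = 0.9,
        decay_every: int = 5,
        batch_size: int = 500,
        keep_prob: float = 0.8,
        max_epochs: int = 200,
        patience: int = 5,
        random_state: Optional[int] = None,
        dtype: str = "float32",
    ):
        self.architecture = architecture
        self.conv_filters = conv_filters
        self.conv_kernels = conv_kernels
        self.conv_strides = conv_strides
        self.mlp_units = mlp_units
        self.dense_units = dense_units
        self.lstm_units = lstm_units
        self.n_lstm_layers = n_lstm_layers
        self.learning_rate = learning_rate
        self.decay = decay
        self.decay_every = decay_every
        self.batch_size = batch_size
        self.keep_prob = keep_prob
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state
        self.dtype = dtype

    def _encode(self, y):
        return np.searchsorted(self.classes_, y)

    def fit(self, X, y, X_val=None, y_val=None, train_subjects=None,
            val_subjects=None):
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 3:
            raise ConfigError("X must have shape (n_samples, frames, features)")
        y = np.asarray(y)
        self.classes_ = np.unique(
            y if y_val is None else np.concatenate([y, np.asarray(y_val)])
        )
        rng = np.random.default_rng(self.random_state)
        self.network_ = build_model(
            self.architecture,
            input_shape=X.shape[1:],
            n_classes=len(self.classes_),
            rng=rng,
            conv_filters=self.conv_filters,
            conv_kernels=self.conv_kernels,
            conv_strides=self.conv_strides,
            mlp_units=self.mlp_units,
            dense_units=self.dense_units,
            lstm_units=self.lstm_units,
            n_lstm_layers=self.n_lstm_layers,
            keep_prob=self.keep_prob,
        )
        self.network_.astype(np.dtype(self.dtype))
        config = TrainConfig(
            learning_rate=self.learning_rate,
            decay=self.decay,
            decay_every=self.decay_every,
            batch_size=self.batch_size,
            keep_prob=self.keep_prob,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=0 if self.random_state is None else int(self.random_state),
        )
        manifest = train(
            self.network_,
            X,
            self._encode(y),
            X_val=None if X_val is None else np.asarray(X_val, dtype=self.dtype),
            y_val=None if y_val is None else self._encode(np.asarray(y_val)),
            config=config,
            train_subjects=train_subjects,
            val_subjects=val_subjects,
        )
        self.history_ = manifest["history"]
        self.stopping_epoch_ = manifest["stopping_epoch"]
        self.best_epoch_ = manifest["best_epoch"]
        self.manifest_ = manifest
        return self

    def decision_function(self, X):
        return self.network_.predict_logits(np.asarray(X, dtype=self.dtype))

    def predict_proba(self, X):
        return softmax(self.decision_function(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


class FlattenedBaseline(BaseEstimator, ClassifierMixin):
    """Classical baseline over flattened 6000-vectors.

    ``model`` is one of ``knn`` (k = 10), ``rf`` (1000 trees, depth 5),
    ``svm`` (linear kernel) or ``constant`` (chance-level prior stub).
    """

    def __init__(self, model: str = "knn", random_state: Optional[int] = None):
        self.model = model
        self.random_state = random_state

    def _make(self):
        if self.model == "knn":
            return KNeighborsClassifier(n_neighbors=10)
        if self.model == "rf":
            return RandomForestClassifier(
                n_estimators=1000, max_depth=5, random_state=self.random_state
            )
        if self.model == "svm":
            return SVC(kernel="linear", probability=False,
                       random_state=self.random_state)
        if self.model == "constant":
            return DummyClassifier(strategy="most_frequent")
        raise ConfigError(f"unknown baseline {self.model!r}")

    @staticmethod
    def _flatten(X):
        X = np.asarray(X, dtype=float)
        return X.reshape(X.shape[0], -1)

    def fit(self, X, y, **kwargs):
        _check_subject_disjoint(kwargs.get("train_subjects"),
                                kwargs.get("val_subjects"))
        estimator = self._make()
        n = np.asarray(X).shape[0]
        if isinstance(estimator, KNeighborsClassifier) and n < estimator.n_neighbors:
            estimator.set_params(n_neighbors=n)  # k capped at training size
        self.estimator_ = estimator.fit(self._flatten(X), y)
        self.classes_ = self.estimator_.classes_
        return self

    def predict(self, X):
        return self.estimator_.predict(self._flatten(X))

    def predict_proba(self, X):
        est = self.estimator_
        if hasattr(est, "predict_proba"):
            return est.predict_proba(self._flatten(X))
        # linear SVM without probability calibration: softmax over margins
        scores = est.decision_function(self._flatten(X))
        if scores.ndim == 1:
            scores = np.stack([-scores, scores], axis=1)
        return softmax(scores)


#: reduced DeepConvLSTM for desk-scale experiments: halved channel counts
#: and a 64-unit LSTM, trained for at most 30 epochs
SMALL_DEEPCONVLSTM = dict(
    architecture="deepconvlstm",
    conv_filters=(8, 8, 16, 32),
    lstm_units=64,
    n_lstm_layers=2,
    batch_size=64,
    learning_rate=2e-3,
    max_epochs=30,
)


def make_classifier(name: str, random_state: Optional[int] = None, **overrides):
    """Model registry: estimator by name.

    Names: ``knn``, ``rf``, ``svm``, ``constant``, ``mlp``, ``convnet``,
    ``rnn``, ``deepconvlstm``, ``deepconvlstm-small``.
    """
    if name in BASELINE_MODELS + ("constant",):
        return FlattenedBaseline(model=name, random_state=random_state)
    if name == "deepconvlstm-small":
        params = dict(SMALL_DEEPCONVLSTM)
        params.update(overrides)
        return NeuralSequenceClassifier(random_state=random_state, **params)
    if name in NEURAL_MODELS:
        return NeuralSequenceClassifier(
            architecture=name, random_state=random_state, **overrides
        )
    raise ConfigError(f"unknown model name {name!r}")


def baseline_fit_predict(name: str, train, test) -> np.ndarray:
    """Fit a classical baseline on (X, y) and predict labels for test X."""
    X_train, y_train = train
    model = FlattenedBaseline(model=name, random_state=0).fit(X_train, y_train)
    return model.predict(test)


def predict_proba(model, X) -> np.ndarray:
    """Per-class probability rows (non-negative, each summing to 1)."""
    return model.predict_proba(X)
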