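"""The A-line classifier: a sequential 1-D CNN.

Architecture (input = one downsampled A-line of 512 depth pixels):

    3 x [Conv1D(48 filters, kernel 21, stride 1, 'same', ReLU)
         -> MaxPool1D(2) -> Dropout(0.5)]
    Flatten                       (64 positions x 48 channels = 3072)
    Dense(16, ReLU, no bias) -> BatchNorm -> Dropout(0.5)
    Dense(8,  ReLU, no bias) -> BatchNorm -> Dropout(0.5)
    Dense(2, sigmoid, bias)       (unit 0: other, unit 1: lipid)

Trained with class-weighted binary cross-entropy on one-hot targets
under Adamax.  The two sigmoid outputs are independent scores (they
need not sum to 1); the hard decision is their argmax.

The public surface is a scikit-learn style estimator,
:class:`ALineCNNClassifier`, plus thin functional wrappers.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .preprocess import ALineBatch


class ModelConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Every architecture and training hyperparameter in one record."""

    input_len: int = 512
    conv_blocks: int = 3
    conv_filters: int = 48
    conv_kernel: int = 21
    conv_stride: int = 1
    pool_size: int = 2
    dropout_rate: float = 0.5
    dense_units: tuple[int, ...] = (16, 8)
    dense_use_bias: bool = False
    output_units: int = 2
    optimizer: str = "adamax"
    learning_rate: float | None = None  # None -> optimizer default
    max_epochs: int = 100
    batch_size: int = 256
    early_stop_patience: int = 10
    lr_plateau_factor: float = 0.5
    lr_plateau_patience: int = 5
    min_lr: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.input_len % (self.pool_size ** self.conv_blocks):
            raise ModelConfigError(
                f"input_len {self.input_len} must be divisible by "
                f"pool_size^conv_blocks = {self.pool_size ** self.conv_blocks}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ModelConfigError("dropout_rate must lie in [0, 1)")
        if self.dropout_rate > 0.5:
            warnings.warn("dropout rates above 0.5 destabilize training; "
                          "0.5 is the recommended ceiling")
        if self.output_units != 2:
            raise ModelConfigError("the binary head uses exactly 2 sigmoid units")

    @property
    def flatten_width(self) -> int:
        return (self.input_len // self.pool_size ** self.conv_blocks) * self.conv_filters

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dense_units"] = list(self.dense_units)
        return d


def _build_network(config: ModelConfig) -> _nn.Sequential:
    rng = np.random.default_rng(config.seed)
    layers: list = []
    channels = 1
    for block in range(config.conv_blocks):
        layers += [
            _nn.Conv1D(channels, config.conv_filters, config.conv_kernel,
                       input_layer=(block == 0), rng=rng),
            _nn.ReLU(),
            _nn.MaxPool1D(config.pool_size),
            _nn.Dropout(config.dropout_rate),
        ]
        channels = config.conv_filters
    layers.append(_nn.Flatten())
    width = config.flatten_width
    for units in config.dense_units:
        layers += [
            _nn.Dense(width, units, use_bias=config.dense_use_bias, rng=rng),
            _nn.ReLU(),
            _nn.BatchNorm(units),
            _nn.Dropout(config.dropout_rate),
        ]
        width = units
    layers += [
        _nn.Dense(width, config.output_units, use_bias=True, rng=rng),
        _nn.Sigmoid(),
    ]
    return _nn.Sequential(layers, seed=config.seed + 1)


class ALineCNNClassifier(BaseEstimator, ClassifierMixin):
    """Binary lipid-vs-other A-line classifier (scikit-learn API).

    Parameters mirror :class:`ModelConfig`.  ``fit`` accepts plain 0/1
    labels, applies balanced class weights by default, and honours a
    held-out validation set for early stopping and learning-rate
    scheduling.  Inference is deterministic (dropout off, batch-norm in
    running-statistics mode).
    """

    def __init__(self, input_len=512, conv_blocks=3, conv_filters=48, conv_kernel=21,
                 pool_size=2, dropout_rate=0.5, dense_units=(16, 8), dense_use_bias=False,
                 optimizer="adamax", learning_rate=None, max_epochs=100, batch_size=256,
                 early_stop_patience=10, lr_plateau_factor=0.5, lr_plateau_patience=5,
                 min_lr=1e-5, seed=0):
        self.input_len = input_len
        self.conv_blocks = conv_blocks
        self.conv_filters = conv_filters
        self.conv_kernel = conv_kernel
        self.pool_size = pool_size
        self.dropout_rate = dropout_rate
        self.dense_units = dense_units
        self.dense_use_bias = dense_use_bias
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.early_stop_patience = early_stop_patience
        self.lr_plateau_factor = lr_plateau_factor
        self.lr_plateau_patience = lr_plateau_patience
        self.min_lr = min_lr
        self.seed = seed

    # -- construction -------------------------------------------------

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            input_len=self.input_len, conv_blocks=self.conv_blocks,
            conv_filters=self.conv_filters, conv_kernel=self.conv_kernel,
            pool_size=self.pool_size, dropout_rate=self.dropout_rate,
            dense_units=tuple(self.dense_units), dense_use_bias=self.dense_use_bias,
            optimizer=self.optimizer, learning_rate=self.learning_rate,
            max_epochs=self.max_epochs, batch_size=self.batch_size,
            early_stop_patience=self.early_stop_patience,
            lr_plateau_factor=self.lr_plateau_factor,
            lr_plateau_patience=self.lr_plateau_patience,
            min_lr=self.min_lr, seed=self.seed,
        )

    def build(self) -> "ALineCNNClassifier":
        """Initialize the network without training (seeded weights)."""
        self.network_ = _build_network(self.model_config())
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.input_len
        return self

    def _ensure_network(self):
        if not hasattr(self, "network_"):
            self.build()

    # -- training ------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None, class_weight="balanced"):
        from .train import compute_class_weights  # local import, avoids cycle

        X = self._validate_batch(X)
        y = np.asarray(y).astype(int).ravel()
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.build()
        y_onehot = np.eye(2, dtype=np.float32)[y]
        if class_weight == "balanced":
            cw = compute_class_weights(y)
            weights = np.where(y == 1, cw.weight_lipid, cw.weight_other).astype(np.float32)
            self.class_weights_ = cw
        elif class_weight is None:
            weights = None
            self.class_weights_ = None
        else:
            weights = np.where(y == 1, class_weight[1], class_weight[0]).astype(np.float32)
            self.class_weights_ = class_weight
        yv = np.eye(2, dtype=np.float32)[np.asarray(y_val).astype(int).ravel()] \
            if y_val is not None else None
        Xv = self._validate_batch(X_val) if X_val is not None else None
        cfg = self.model_config()
        opt = _nn.make_optimizer(cfg.optimizer, cfg.learning_rate)
        self.history_ = _nn.fit_network(
            self.network_, opt, X[:, :, None], y_onehot, weights,
            Xv[:, :, None] if Xv is not None else None, yv,
            batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
            early_stop_patience=cfg.early_stop_patience if Xv is not None else 0,
            lr_plateau_factor=cfg.lr_plateau_factor,
            lr_plateau_patience=cfg.lr_plateau_patience,
            min_lr=cfg.min_lr, shuffle_seed=cfg.seed + 2,
        )
        return self

    # -- inference -----------------------------------------------------

    def _validate_batch(self, X) -> np.ndarray:
        if isinstance(X, ALineBatch):
            X = X.data
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.input_len:
            raise ValueError(f"expected (S, {self.input_len}) input, got {X.shape}")
        return X

    def predict_scores(self, X) -> np.ndarray:
        """Raw S x 2 sigmoid scores (not normalized to sum to 1)."""
        self._ensure_network()
        X = self._validate_batch(X)
        return _nn.forward_in_batches(self.network_, X[:, :, None], self.batch_size)

    def predict_proba(self, X) -> np.ndarray:
        scores = self.predict_scores(X)
        total = scores.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return scores / total

    def predict(self, X) -> np.ndarray:
        return self.predict_scores(X).argmax(axis=1)

    # -- bookkeeping ---------------------------------------------------

    def count_parameters(self) -> int:
        self._ensure_network()
        return self.network_.n_trainable()

    def layer_summary(self) -> list[dict]:
        """Human-readable per-layer manifest (type, trainable params)."""
        self._ensure_network()
        return [{"layer": type(l).__name__, "trainable_params": l.n_trainable()}
                for l in self.network_.layers]

    def save_weights(self, path) -> None:
        check_is_fitted(self, "network_")
        np.savez(path, **self.network_.state_dict())

    def load_weights(self, path) -> "ALineCNNClassifier":
        self.build()
        with np.load(path) as data:
            self.network_.load_state_dict(dict(data))
        return self


# -- functional wrappers ----------------------------------------------


def build_classifier(config: ModelConfig | None = None) -> ALineCNNClassifier:
    config = config or ModelConfig()
    clf = ALineCNNClassifier(**{k: v for k, v in config.to_dict().items()
                                if k not in ("conv_stride", "output_units")})
    clf.dense_units = tuple(config.dense_units)
    return clf.build()


def predict_alines(clf: ALineCNNClassifier, batch) -> tuple[np.ndarray, np.ndarray]:
    """Per-A-line sigmoid scores (S x 2) and hard argmax labels (S,)."""
    scores = clf.predict_scores(batch)
    return scores, scores.argmax(axis=1)


def count_parameters(clf: ALineCNNClassifier) -> int:
    return clf.count_parameters()
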