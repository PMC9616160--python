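"""Sequential container and the mini-batch training loop.

The loop reproduces the standard callback-controlled protocol: shuffled
mini-batches, per-sample loss weights, early stopping on validation
loss with best-weight restoration, learning-rate halving on plateau,
and a hard epoch cap.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .losses import WeightedBinaryCrossEntropy
from .optimizers import Optimizer


class Sequential:
    def __init__(self, layers: list, seed: int = 0):
        self.layers = layers
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, training, self.rng)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_trainable(self) -> int:
        return sum(layer.n_trainable() for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w

    def state_dict(self, copy: bool = False) -> dict:
        """All arrays (trainable and running statistics) for persistence.

        Snapshots taken for best-weight restoration must include the
        batch-norm running statistics, or restored weights would run
        against statistics from a later epoch.
        """
        out = {}
        for i, layer in enumerate(self.layers):
            for name in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(layer, name):
                    arr = getattr(layer, name)
                    out[f"layer{i}.{name}"] = arr.copy() if copy else arr
        return out

    def load_state_dict(self, state: dict) -> None:
        for key, value in state.items():
            idx, name = key.split(".", 1)
            getattr(self.layers[int(idx.removeprefix("layer"))], name)[...] = value


def forward_in_batches(net: Sequential, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Inference-mode forward pass in memory-bounded chunks."""
    outs = [net.forward(X[i:i + batch_size], training=False)
            for i in range(0, len(X), batch_size)]
    return np.concatenate(outs, axis=0)


@dataclass
class FitHistory:
    loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    epochs_run: int = 0
    stopping_reason: str = ""
    final_lr: float = 0.0


def fit_network(
    net: Sequential,
    optimizer: Optimizer,
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    *,
    batch_size: int = 256,
    max_epochs: int = 100,
    early_stop_patience: int = 10,
    lr_plateau_factor: float = 0.5,
    lr_plateau_patience: int = 5,
    min_lr: float = 1e-5,
    shuffle_seed: int = 0,
) -> FitHistory:
    loss_fn = WeightedBinaryCrossEntropy()
    rng = np.random.default_rng(shuffle_seed)
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    has_val = X_val is not None and len(X_val) > 0
    if early_stop_patience and not has_val:
        raise ValueError("early stopping requires a non-empty validation set")

    hist = FitHistory()
    best_val = np.inf
    best_weights = None
    es_wait = 0
    lr_wait = 0
    n = len(X)

    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = X[idx], y[idx]
            wb = sample_weight[idx] if sample_weight is not None else None
            probs = net.forward(xb, training=True)
            epoch_loss += loss_fn.value(probs, yb, wb) * len(idx)
            net.backward(loss_fn.grad(probs, yb, wb))
            optimizer.step(net.params(), net.grads())
        hist.loss.append(epoch_loss / n)
        hist.lr.append(optimizer.lr)
        hist.epochs_run = epoch + 1

        if has_val:
            val_probs = forward_in_batches(net, X_val, batch_size)
            val_loss = loss_fn.value(val_probs, np.asarray(y_val, dtype=np.float32))
            hist.val_loss.append(val_loss)
            if val_loss < best_val - 1e-7:
                best_val = val_loss
                best_weights = net.state_dict(copy=True)
                es_wait = 0
                lr_wait = 0
            else:
                es_wait += 1
                lr_wait += 1
                if early_stop_patience and es_wait >= early_stop_patience:
                    hist.stopping_reason = "early_stopping"
                    break
                if lr_wait >= lr_plateau_patience and optimizer.lr > min_lr:
                    optimizer.lr = max(optimizer.lr * lr_plateau_factor, min_lr)
                    lr_wait = 0

    if not hist.stopping_reason:
        hist.stopping_reason = "max_epochs"
    if best_weights is not None:
        net.load_state_dict(best_weights)
    hist.final_lr = optimizer.lr
    return hist
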