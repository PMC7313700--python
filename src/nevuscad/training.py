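"""Reference backpropagation trainer for the melanoma MLP.

Plain full-batch gradient descent on the mean squared error against
one-hot targets ([1, 0] melanoma, [0, 1] non-melanoma) with the exact
logistic sigmoid everywhere — the software training phase whose weights
the fixed-point network then replays.  Deliberately free of momentum,
adaptive rates or early-stopping heuristics: given a seed it is exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annm import MELANOMA, NON_MELANOMA, MlpModel, PAPER_LAYER_SIZES, sigmoid
from .fixed_point import WEIGHT_FMT

__all__ = [
    "TrainingConfig",
    "TrainingReport",
    "train_mlp",
    "quantize_model",
    "split_dataset",
    "labels_to_targets",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Trainer knobs; all are configuration defaults, not fidelity claims.

    ``target_mse`` is the convergence criterion (default 1e-6);
    ``validation_fraction`` defaults to 0.15, the 170/30 style hold-out.
    """

    learning_rate: float = 2.0
    max_epochs: int = 3000
    target_mse: float = 1e-6
    seed: int = 0
    validation_fraction: float = 0.15

    def __post_init__(self):
        if self.target_mse <= 0:
            raise ValueError("target_mse must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must lie in (0, 1)")


@dataclass
class TrainingReport:
    mse_curve: np.ndarray
    final_weights: MlpModel       # weights at the minimum recorded error
    epochs_run: int
    best_epoch: int = field(default=-1)


def labels_to_targets(labels) -> np.ndarray:
    """One-hot class coding: melanoma -> [1, 0], non-melanoma -> [0, 1]."""
    out = np.zeros((len(labels), 2), dtype=float)
    for i, lab in enumerate(labels):
        if lab == MELANOMA:
            out[i, 0] = 1.0
        elif lab == NON_MELANOMA:
            out[i, 1] = 1.0
        else:
            raise ValueError(f"unknown label: {lab!r}")
    return out


def _init_weights(layer_sizes, rng) -> list:
    """Uniform [-0.5, 0.5] initialization, bias column included."""
    ws = []
    for n_in, n_out in zip(layer_sizes, layer_sizes[1:]):
        ws.append(rng.uniform(-0.5, 0.5, size=(n_out, n_in + 1)))
    return ws


def _forward(weights, X):
    """Batch forward pass; returns the activations of every layer."""
    acts = [np.asarray(X, dtype=float)]
    for w in weights:
        acts.append(sigmoid(acts[-1] @ w[:, 1:].T - w[:, 0]))
    return acts


def _mse_and_grads(weights, X, T):
    """MSE over samples and outputs, and its gradient per weight array."""
    acts = _forward(weights, X)
    n, k = T.shape
    err = acts[-1] - T
    mse = float(np.mean(err * err))
    delta = err * acts[-1] * (1.0 - acts[-1]) * (2.0 / (n * k))
    grads = []
    for li in range(len(weights) - 1, -1, -1):
        g = np.empty_like(weights[li])
        g[:, 1:] = delta.T @ acts[li]
        g[:, 0] = -delta.sum(axis=0)          # bias input is the constant -1
        grads.append(g)
        if li > 0:
            delta = (delta @ weights[li][:, 1:]) * acts[li] * (1.0 - acts[li])
    grads.reverse()
    return mse, grads


def train_mlp(
    X,
    labels,
    cfg: TrainingConfig,
    layer_sizes=PAPER_LAYER_SIZES,
) -> TrainingReport:
    """Train by full-batch gradient descent until target MSE or the epoch
    budget; the reported weights are those at the lowest recorded error.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two training examples")
    if X.shape[1] != layer_sizes[0]:
        raise ValueError(
            f"descriptor width {X.shape[1]} != network input {layer_sizes[0]}"
        )
    T = labels_to_targets(labels)
    if len({tuple(t) for t in T}) < 2:
        raise ValueError("training set contains a single class")

    rng = np.random.default_rng(cfg.seed)
    weights = _init_weights(layer_sizes, rng)
    curve = []
    best_mse = np.inf
    best_weights = [w.copy() for w in weights]
    best_epoch = 0
    epochs = 0
    for epoch in range(cfg.max_epochs):
        mse, grads = _mse_and_grads(weights, X, T)
        curve.append(mse)
        epochs = epoch + 1
        if mse < best_mse:
            best_mse = mse
            best_weights = [w.copy() for w in weights]
            best_epoch = epoch
        if mse <= cfg.target_mse:
            break
        for w, g in zip(weights, grads):
            w -= cfg.learning_rate * g
    return TrainingReport(
        mse_curve=np.array(curve),
        final_weights=MlpModel(best_weights),
        epochs_run=epochs,
        best_epoch=best_epoch,
    )


def quantize_model(model: MlpModel) -> tuple[MlpModel, float]:
    """Quantize every weight to sQ5.10 (truncation + saturation).

    Returns the quantized model and the maximum per-weight quantization
    error (<= 2**-10 for weights inside the representable range).
    """
    step = WEIGHT_FMT.step
    qweights = []
    max_err = 0.0
    for w in model.weights:
        raw = np.floor(w / step)
        raw = np.clip(raw, WEIGHT_FMT.raw_min, WEIGHT_FMT.raw_max)
        qw = raw * step
        max_err = max(max_err, float(np.abs(qw - w).max()))
        qweights.append(qw)
    return MlpModel(qweights), max_err


def split_dataset(n: int, validation_fraction: float, seed: int):
    """Deterministic train/validation index split drawn from the seed."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    n_val = max(1, int(round(n * validation_fraction)))
    return idx[n_val:], idx[:n_val]
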