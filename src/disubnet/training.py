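"""Loss, activations, and the training protocol.

The loss is categorical cross-entropy between a one-hot label ``y`` and the
softmax probability vector ``s`` over ``C`` classes,

    E(y, s) = -sum_i y_i log(s_i),

with probabilities clipped to ``[1e-12, 1]`` for numerical stability.  The
activations are ReLU, ``f(x) = max(x, 0)``, and LeakyReLU with negative
slope 0.1, ``f(x) = max(0.1 x, x)``.

The reference protocol trains with Adam (batch size 32, 100 epochs) at
learning rates 1e-2, 1e-3 and 1e-4; desk-scale runs shrink widths, sample
count and epochs but keep the protocol shape.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .backend import Adam, NumpyModel
from .layer_graph import GraphError, LayerGraph, TensorShape, count_parameters
from .synthetic_thermal import CLASS_NAMES

__all__ = [
    "PredictionBatch",
    "TrainConfig",
    "TrainHistory",
    "categorical_cross_entropy",
    "relu",
    "leaky_relu",
    "one_hot",
    "preprocess_images",
    "train_model",
]


def preprocess_images(x: np.ndarray) -> np.ndarray:
    """Map [0, 1] grayscale images to the network input range [-1, 1].

    Centering the input is the package's preprocessing convention (the same
    one the separable-convolution model family uses): with strictly positive
    inputs the first-layer weight gradients are all positively correlated,
    which conditions early training badly on low-contrast thermal scenes.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.min() < 0 or x.max() > 1:
        raise ValueError("expected intensities in [0, 1]")
    return 2.0 * x - 1.0


def one_hot(labels: np.ndarray, n_classes: int = len(CLASS_NAMES)) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("label index out of range")
    return np.eye(n_classes, dtype=np.float32)[labels]


@dataclass(frozen=True)
class PredictionBatch:
    """One-hot labels ``y`` and softmax probabilities ``s``, both (N, C)."""

    y: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        y, s = np.asarray(self.y), np.asarray(self.s)
        if y.shape != s.shape or y.ndim != 2:
            raise ValueError(f"y and s must share a (N, C) shape, got {y.shape} vs {s.shape}")
        if not np.all((y == 0) | (y == 1)) or not np.all(y.sum(axis=1) == 1):
            raise ValueError("y must be one-hot")
        if s.min() < 0 or np.abs(s.sum(axis=1) - 1).max() > 1e-6:
            raise ValueError("s rows must be probability vectors")


def categorical_cross_entropy(batch: PredictionBatch) -> float:
    """Mean of ``-sum_i y_i log(s_i)`` with s clipped to [1e-12, 1]."""
    s = np.clip(batch.s, 1e-12, 1.0)
    return float(-(batch.y * np.log(s)).sum(axis=1).mean())


def relu(x):
    return np.maximum(x, 0)


def leaky_relu(x, negative_slope: float = 0.1):
    return np.maximum(negative_slope * np.asarray(x), x)


@dataclass(frozen=True)
class TrainConfig:
    """Reference protocol: Adam, batch 32, 100 epochs, lr in {1e-2, 1e-3, 1e-4}."""

    batch_size: int = 32
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0
    l2_lambda: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class TrainHistory:
    """Per-epoch training and validation accuracy/loss."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self) + 1),
            "train_acc": self.train_acc,
            "val_acc": self.val_acc,
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
        })


def _eval_on(model: NumpyModel, x: np.ndarray, y: np.ndarray,
             batch_size: int) -> tuple[float, float]:
    probs = model.predict_proba(x, batch_size)
    loss = categorical_cross_entropy(PredictionBatch(one_hot(y, probs.shape[1]), probs))
    acc = float((probs.argmax(axis=1) == y).mean())
    return loss, acc


def train_model(graph: LayerGraph,
                x_train: np.ndarray, y_train: np.ndarray,
                x_val: np.ndarray, y_val: np.ndarray,
                cfg: TrainConfig = TrainConfig()) -> tuple[NumpyModel, TrainHistory]:
    """Materialize ``graph`` and train it with mini-batch Adam.

    Before training, the backend's allocated parameter totals are checked
    against the analytic engine; a mismatch is a graph-translation bug and a
    hard error.  All randomness (init, shuffling, dropout) derives from
    ``cfg.seed``.
    """
    input_shape = TensorShape(*x_train.shape[1:])
    model = NumpyModel(graph, input_shape, seed=cfg.seed)

    report = count_parameters(graph, input_shape)
    if model.trainable_parameter_count() != report.total_trainable:
        raise GraphError(
            f"backend materialized {model.trainable_parameter_count()} trainable "
            f"parameters but the analytic engine counted {report.total_trainable}"
        )
    nt = report.total_with_non_trainable - report.total_trainable
    if model.non_trainable_parameter_count() != nt:
        raise GraphError("backend/analytic non-trainable parameter mismatch")

    n_classes = model.shapes[graph.output_node].channels
    yt = one_hot(y_train, n_classes)
    opt = Adam(model, learning_rate=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7124]))
    history = TrainHistory()
    n = x_train.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses, hits, seen = [], 0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, probs = model.loss_and_gradients(
                x_train[idx], yt[idx], rng=rng, l2_lambda=cfg.l2_lambda)
            opt.step()
            losses.append(loss * len(idx))
            hits += int((probs.argmax(axis=1) == y_train[idx]).sum())
            seen += len(idx)
        vl, va = _eval_on(model, x_val, y_val, cfg.batch_size)
        history.train_loss.append(float(np.sum(losses) / seen))
        history.train_acc.append(hits / seen)
        history.val_loss.append(vl)
        history.val_acc.append(va)
    return model, history
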