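"""Normal/abnormal field-map classifiers and the accuracy-as-score contract.

Two architectures share one training loop and one metric contract:

``dense_se_cnn``
    A compact DenseNet-style network with squeeze-and-excitation channel
    attention: a 3x3 convolutional stem with batch normalisation, ReLU and
    an SE gate; several dense blocks whose layers comprise two convolutions
    plus an SE unit; transition layers halving the channel count with 2x2
    average-pool downsampling; global average pooling into a two-class
    fully connected head.

``logistic_baseline``
    Softmax regression on the flattened, per-sensor-standardised map,
    augmented by default with its elementwise squares.  Lesion dipoles
    have zero-mean random orientation, so the two classes share the same
    mean readout and differ only in (co)variance; the likelihood-ratio
    detector for such an equal-mean variance shift is quadratic in the
    data, which a purely linear model cannot express.  The squared
    features make the baseline a genuine shallow detector while keeping
    it fast enough for desk-scale geometry sweeps.  It shares the exact
    same epoch-record/accuracy contract, which is architecture-agnostic
    by design.

The per-sample loss is the cross-entropy
``-[y log p + (1 - y) log(1 - p)]`` where ``p`` is the predicted
probability of the abnormal class (y = 1) and the decision threshold is
``p >= 0.5``.  The sensor-performance score is the best validation accuracy
over all trained epochs (earliest epoch wins ties).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from . import _nn
from .datasets import Dataset, dataset_arrays

__all__ = [
    "ClassifierConfig",
    "ConfusionMatrix",
    "EpochRecord",
    "TrainingResult",
    "build_classifier",
    "cross_entropy",
    "train_classifier",
    "accuracy_from_confusion",
    "best_validation_accuracy",
    "save_training_result",
]

ARCHITECTURES = ("dense_se_cnn", "logistic_baseline")


@dataclasses.dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and optimisation settings for one training run."""

    architecture: str = "logistic_baseline"
    epochs: int = 30
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 0
    # dense_se_cnn structure
    init_channels: int = 24
    block_layers: tuple[int, ...] = (4, 4, 4)
    growth: int = 12
    se_reduction: int = 4
    # logistic_baseline: append elementwise squares of the standardised map
    quadratic_features: bool = True

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if not self.block_layers or any(n < 1 for n in self.block_layers):
            raise ValueError(f"invalid block structure {self.block_layers}")


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 validation counts; the abnormal class (label 1) is positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclasses.dataclass(frozen=True)
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    confusion: ConfusionMatrix
    accuracy: float


@dataclasses.dataclass(frozen=True)
class TrainingResult:
    """Per-epoch records; the score is the best validation accuracy."""

    records: tuple[EpochRecord, ...]
    config: ClassifierConfig

    @property
    def best_epoch(self) -> int:
        return best_validation_accuracy(self)[0]

    @property
    def best_accuracy(self) -> float:
        return best_validation_accuracy(self)[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": [r.epoch for r in self.records],
                "train_loss": [r.train_loss for r in self.records],
                "val_loss": [r.val_loss for r in self.records],
                "TP": [r.confusion.tp for r in self.records],
                "FP": [r.confusion.fp for r in self.records],
                "FN": [r.confusion.fn for r in self.records],
                "TN": [r.confusion.tn for r in self.records],
                "accuracy": [r.accuracy for r in self.records],
            }
        )


def cross_entropy(p, y, eps: float = 1e-12):
    """Per-sample loss -[y log p + (1-y) log(1-p)]; arrays give the batch mean.

    ``p`` is the predicted probability of the abnormal class (y = 1),
    clamped to [eps, 1 - eps].
    """
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    y = np.asarray(y, dtype=float)
    losses = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(losses.mean()) if losses.ndim else float(losses)


def accuracy_from_confusion(cm: ConfusionMatrix) -> float:
    """A = (TP + TN) / (TP + FP + FN + TN)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def best_validation_accuracy(result: TrainingResult) -> tuple[int, float]:
    """(epoch, accuracy) of the best validation epoch; earliest wins ties."""
    if not result.records:
        raise ValueError("empty training result")
    best = max(result.records, key=lambda r: (r.accuracy, -r.epoch))
    return best.epoch, best.accuracy


class _Model:
    """A network plus its input standardisation; exposes a (N, 2) probability
    contract independent of architecture."""

    def __init__(self, net: _nn.Module, flatten_input: bool, quadratic: bool = False):
        self.net = net
        self.flatten_input = flatten_input
        self.quadratic = quadratic
        self.mean = 0.0
        self.std = 1.0

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        Xn = (np.asarray(X, dtype=float) - self.mean) / self.std
        if self.flatten_input:
            Z = Xn.reshape(Xn.shape[0], -1)
            return np.hstack([Z, Z * Z]) if self.quadratic else Z
        return Xn[:, None, :, :]  # single channel

    def fit_normalisation(self, X: np.ndarray) -> None:
        # Per-sensor (per-pixel) standardisation from the training split.
        self.mean = np.mean(X, axis=0)
        std = np.std(X, axis=0)
        self.std = np.where(std > 0, std, 1.0)

    def forward_logits(self, X: np.ndarray, training: bool) -> np.ndarray:
        return self.net.forward(self._prepare(X), training)

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for start in range(0, X.shape[0], batch_size):
            logits = self.forward_logits(X[start : start + batch_size], training=False)
            out.append(_nn.softmax(logits))
        return np.concatenate(out)


def build_classifier(config: ClassifierConfig, input_shape: tuple[int, int]) -> _Model:
    """Instantiate a model for maps of the given (H, W) shape."""
    rng = np.random.default_rng(config.seed)
    if config.architecture == "logistic_baseline":
        fin = int(np.prod(input_shape)) * (2 if config.quadratic_features else 1)
        return _Model(
            _nn.Sequential(_nn.Linear(fin, 2, rng)),
            flatten_input=True,
            quadratic=config.quadratic_features,
        )

    modules: list[_nn.Module] = [
        _nn.Conv2d(1, config.init_channels, 3, 1, rng),
        _nn.BatchNorm2d(config.init_channels),
        _nn.ReLU(),
        _nn.SELayer(config.init_channels, config.se_reduction, rng),
    ]
    channels = config.init_channels
    for b, n_layers in enumerate(config.block_layers):
        block = _nn.DenseBlock(channels, n_layers, config.growth, config.se_reduction, rng)
        modules.append(block)
        channels = block.cout
        if b < len(config.block_layers) - 1:
            transition = _nn.Transition(channels, rng)
            modules.append(transition)
            channels = transition.cout
    modules += [
        _nn.BatchNorm2d(channels),
        _nn.ReLU(),
        _nn.GlobalAvgPool(),
        _nn.Linear(channels, 2, rng),
    ]
    return _Model(_nn.Sequential(*modules), flatten_input=False)


def _evaluate(model: _Model, X: np.ndarray, y: np.ndarray) -> tuple[float, ConfusionMatrix]:
    probs = model.predict_proba(X)
    p_abnormal = probs[:, 1]
    loss = cross_entropy(p_abnormal, y)
    pred = (p_abnormal >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    return loss, ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def train_classifier(data: Dataset, config: ClassifierConfig) -> TrainingResult:
    """Train for ``config.epochs`` epochs and record one EpochRecord each.

    The training set is reshuffled every epoch from the seeded generator;
    the validation confusion matrix uses the 0.5 decision threshold.  The
    whole run is deterministic given the config seed.
    """
    interpolated = bool(data.attrs.get("interpolated", False))
    X_train, y_train = dataset_arrays(data.training, interpolated=interpolated)
    X_val, y_val = dataset_arrays(data.validation, interpolated=interpolated)
    if len(set(y_train.tolist())) < 2 or len(set(y_val.tolist())) < 2:
        raise ValueError("both classes must be present in both splits")

    model = build_classifier(config, X_train.shape[1:])
    model.fit_normalisation(X_train)
    optimiser = _nn.Adam(model.net.params(), lr=config.lr)
    shuffle_rng = np.random.default_rng(config.seed + 1)

    records = []
    n = X_train.shape[0]
    for epoch in range(1, config.epochs + 1):
        order = shuffle_rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward_logits(X_train[idx], training=True)
            loss, dlogits, _ = _nn.softmax_cross_entropy(logits, y_train[idx])
            optimiser.zero_grad()
            model.net.backward(dlogits)
            optimiser.step()
            batch_losses.append(loss)
        val_loss, confusion = _evaluate(model, X_val, y_val)
        records.append(
            EpochRecord(
                epoch=epoch,
                train_loss=float(np.mean(batch_losses)),
                val_loss=val_loss,
                confusion=confusion,
                accuracy=accuracy_from_confusion(confusion),
            )
        )
    return TrainingResult(records=tuple(records), config=config)


def save_training_result(result: TrainingResult, csv_path, sidecar_path=None) -> None:
    """CSV of per-epoch records plus an optional JSON provenance sidecar."""
    result.to_frame().to_csv(csv_path, index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as f:
            json.dump(
                {
                    "config": dataclasses.asdict(result.config),
                    "best_epoch": result.best_epoch,
                    "best_accuracy": result.best_accuracy,
                },
                f,
                indent=2,
            )
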