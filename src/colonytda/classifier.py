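"""Feedforward landscape classifier (TDANet-style) with early stopping.

The model maps a flattened persistence-landscape matrix through three dense
20-neuron ReLU hidden layers to a 5-way softmax, trained with categorical
cross-entropy and the Adam optimizer.  Training follows the study protocol:
a randomized 70/30 train/validation split, a cap of 200 epochs, stopping
after several consecutive decreases in validation accuracy, and returning
the checkpoint with the highest validation accuracy.

Usage follows the fitted-model idiom::

    model = TDANet(X, y, config=TrainingConfig(seed=3))
    result = model.fit()
    result.best_val_accuracy
    result.predict(X_new)
    print(result.summary())
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "TrainingConfig",
    "TrainingResult",
    "TDANet",
    "build_tdanet",
    "count_parameters",
    "count_head_parameters",
    "count_resnet18_parameters",
    "split_train_val",
    "randomize_labels",
    "train_model",
    "predict",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of a dense feedforward classifier."""

    layer_sizes: tuple[int, ...]
    hidden_activation: str = "relu"
    output_activation: str = "softmax"
    loss: str = "categorical_crossentropy"

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.layer_sizes)
        if len(sizes) < 2 or any(s < 1 for s in sizes):
            raise ValueError(f"need >= 2 positive layer sizes, got {self.layer_sizes}")
        object.__setattr__(self, "layer_sizes", sizes)

    @property
    def input_dim(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_classes(self) -> int:
        return self.layer_sizes[-1]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol: split, epoch cap, patience, optimizer, seed."""

    train_fraction: float = 0.70
    max_epochs: int = 200
    patience: int = 5
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    seed: int = 0
    stratify: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.max_epochs < 1 or self.patience < 1:
            raise ValueError("max_epochs and patience must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def build_tdanet(input_dim: int, n_classes: int = 5) -> ModelSpec:
    """Standard architecture: input -> 20 -> 20 -> 20 -> n_classes softmax."""
    if input_dim < 1 or n_classes < 2:
        raise ValueError("input_dim must be >= 1 and n_classes >= 2")
    return ModelSpec((input_dim, 20, 20, 20, n_classes))


def count_parameters(spec: ModelSpec) -> int:
    """Trainable parameter count: dense weights plus biases per layer pair."""
    sizes = spec.layer_sizes if isinstance(spec, ModelSpec) else tuple(spec)
    return int(sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:])))


def count_head_parameters(feature_dim: int, n_classes: int) -> int:
    """Parameters of a single dense output layer on a frozen feature backbone."""
    if feature_dim < 1 or n_classes < 1:
        raise ValueError("feature_dim and n_classes must be >= 1")
    return feature_dim * n_classes + n_classes


def count_resnet18_parameters(n_classes: int = 5) -> int:
    """Parameter count of the standard 18-layer residual image classifier.

    Counted layer by layer (convolutions, batch-norm scale/shift pairs, and
    the final dense head); used only to reproduce the printed parameter
    arithmetic — no image model is trained here.
    """

    def conv(c_in: int, c_out: int, k: int) -> int:
        return c_in * c_out * k * k  # no bias before batch norm

    def bn(c: int) -> int:
        return 2 * c

    total = conv(3, 64, 7) + bn(64)  # stem
    c_in = 64
    for c_out in (64, 128, 256, 512):
        for block in range(2):
            total += conv(c_in, c_out, 3) + bn(c_out)
            total += conv(c_out, c_out, 3) + bn(c_out)
            if c_in != c_out:  # projection shortcut on the first block of a stage
                total += conv(c_in, c_out, 1) + bn(c_out)
            c_in = c_out
    total += count_head_parameters(512, n_classes)
    return int(total)


def split_train_val(
    n_items: int, train_fraction: float, seed: int, labels: Sequence | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Randomized disjoint exhaustive split; train size = ceil(fraction * n).

    With ``labels`` given, the split is stratified per class (same ceiling
    rule within each class).  Returns (train_idx, val_idx).
    """
    if n_items < 1:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    if labels is not None:
        labels = np.asarray(labels)
        train, val = [], []
        for cls in sorted(set(labels.tolist())):
            idx = np.flatnonzero(labels == cls)
            idx = rng.permutation(idx)
            k = math.ceil(train_fraction * idx.size)
            train.append(idx[:k])
            val.append(idx[k:])
        train_idx = np.sort(np.concatenate(train))
        val_idx = np.sort(np.concatenate(val))
    else:
        perm = rng.permutation(n_items)
        k = math.ceil(train_fraction * n_items)
        train_idx, val_idx = np.sort(perm[:k]), np.sort(perm[k:])
    if train_idx.size == 0 or val_idx.size == 0:
        raise ValueError(
            f"split of {n_items} items at fraction {train_fraction} leaves one side empty"
        )
    return train_idx, val_idx


def randomize_labels(
    labels: Mapping[str, str] | Sequence[str], classes: Sequence[str], seed: int
):
    """Replace each colony's label by an i.i.d. uniform draw from the class set.

    A mapping input returns a new mapping (one draw per colony, so the
    relabelling is constant across that colony's timepoints); a sequence
    returns an array of the same length.  Original labels are left untouched
    for audit.
    """
    classes = list(classes)
    rng = np.random.default_rng(seed)
    if isinstance(labels, Mapping):
        keys = list(labels.keys())
        draws = rng.integers(0, len(classes), size=len(keys))
        return {k: classes[d] for k, d in zip(keys, draws)}
    labels = list(labels)
    draws = rng.integers(0, len(classes), size=len(labels))
    return np.asarray([classes[d] for d in draws])


# ---------------------------------------------------------------------------
# network internals


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_params(spec: ModelSpec, rng: np.random.Generator):
    """He-normal weights (suits ReLU), zero biases."""
    params = []
    for a, b in zip(spec.layer_sizes[:-1], spec.layer_sizes[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b))
        params.append((W, np.zeros(b)))
    return params


def _forward(params, X: np.ndarray) -> np.ndarray:
    h = X
    for W, b in params[:-1]:
        h = np.maximum(0.0, h @ W + b)
    W, b = params[-1]
    return _softmax(h @ W + b)


def _forward_backward(params, X, Y):
    """Cross-entropy loss and gradients for one full batch (one-hot Y)."""
    acts = [X]
    h = X
    for W, b in params[:-1]:
        h = np.maximum(0.0, h @ W + b)
        acts.append(h)
    W, b = params[-1]
    probs = _softmax(h @ W + b)
    n = X.shape[0]
    loss = -np.sum(Y * np.log(np.clip(probs, 1e-12, None))) / n
    grads = [None] * len(params)
    delta = (probs - Y) / n
    for layer in range(len(params) - 1, -1, -1):
        grads[layer] = (acts[layer].T @ delta, delta.sum(axis=0))
        if layer > 0:
            delta = (delta @ params[layer][0].T) * (acts[layer] > 0)
    return loss, probs, grads


class _Adam:
    def __init__(self, params, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
        self.v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]

    def step(self, params, grads):
        self.t += 1
        out = []
        for i, ((W, b), (gW, gb)) in enumerate(zip(params, grads)):
            mW, mb = self.m[i]
            vW, vb = self.v[i]
            mW = self.b1 * mW + (1 - self.b1) * gW
            mb = self.b1 * mb + (1 - self.b1) * gb
            vW = self.b2 * vW + (1 - self.b2) * gW**2
            vb = self.b2 * vb + (1 - self.b2) * gb**2
            self.m[i], self.v[i] = (mW, mb), (vW, vb)
            c1 = 1 - self.b1**self.t
            c2 = 1 - self.b2**self.t
            W = W - self.lr * (mW / c1) / (np.sqrt(vW / c2) + self.eps)
            b = b - self.lr * (mb / c1) / (np.sqrt(vb / c2) + self.eps)
            out.append((W, b))
        return out


class _SGD:
    def __init__(self, params, lr: float):
        self.lr = lr

    def step(self, params, grads):
        return [(W - self.lr * gW, b - self.lr * gb) for (W, b), (gW, gb) in zip(params, grads)]


@dataclass
class TrainingResult:
    """Fitted classifier: best-epoch parameters, history, and split record."""

    spec: ModelSpec
    config: TrainingConfig
    classes: tuple[str, ...]
    params: list
    history: pd.DataFrame
    best_epoch: int
    best_val_accuracy: float
    train_idx: np.ndarray
    val_idx: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model input "
                f"{self.spec.input_dim}"
            )
        return _forward(self.params, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.asarray(self.classes)[probs.argmax(axis=1)]

    def summary(self) -> str:
        lines = [
            "Landscape feedforward classifier",
            "=" * 40,
            f"architecture     : {' -> '.join(map(str, self.spec.layer_sizes))}",
            f"parameters       : {count_parameters(self.spec):,}",
            f"classes          : {', '.join(self.classes)}",
            f"optimizer        : {self.config.optimizer} (lr={self.config.learning_rate})",
            f"train/val sizes  : {self.train_idx.size}/{self.val_idx.size}",
            f"epochs run       : {len(self.history)} (cap {self.config.max_epochs}, "
            f"patience {self.config.patience})",
            f"best epoch       : {self.best_epoch}",
            f"best val accuracy: {self.best_val_accuracy:.4f}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize spec, config, classes and parameters to one JSON file."""
        payload = {
            "spec": asdict(self.spec),
            "config": asdict(self.config),
            "classes": list(self.classes),
            "best_epoch": self.best_epoch,
            "best_val_accuracy": self.best_val_accuracy,
            "train_idx": self.train_idx.tolist(),
            "val_idx": self.val_idx.tolist(),
            "params": [[W.tolist(), b.tolist()] for W, b in self.params],
            "history": self.history.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainingResult":
        with open(path) as fh:
            payload = json.load(fh)
        spec = ModelSpec(tuple(payload["spec"]["layer_sizes"]),
                         payload["spec"]["hidden_activation"],
                         payload["spec"]["output_activation"],
                         payload["spec"]["loss"])
        return cls(
            spec=spec,
            config=TrainingConfig(**payload["config"]),
            classes=tuple(payload["classes"]),
            params=[(np.asarray(W), np.asarray(b)) for W, b in payload["params"]],
            history=pd.DataFrame(payload["history"]),
            best_epoch=payload["best_epoch"],
            best_val_accuracy=payload["best_val_accuracy"],
            train_idx=np.asarray(payload["train_idx"], dtype=int),
            val_idx=np.asarray(payload["val_idx"], dtype=int),
        )


class TDANet:
    """Feedforward classifier over flattened landscape matrices.

    Parameters
    ----------
    X : (n_samples, n_features) array
        Flattened landscape matrices, one row per colony.
    y : sequence of class names
        Treatment label per colony.
    classes : optional explicit class ordering (default: sorted unique labels).
    spec : optional architecture override (default: ``build_tdanet``).
    config : training protocol (split fraction, epochs, patience, seed, ...).
    """

    def __init__(self, X, y, classes=None, spec: ModelSpec | None = None,
                 config: TrainingConfig | None = None):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] < 2:
            raise ValueError("X must be (n_samples >= 2, n_features)")
        y = np.asarray(y)
        if y.shape[0] != self.X.shape[0]:
            raise ValueError("X and y lengths differ")
        self.classes = tuple(classes) if classes is not None else tuple(sorted(set(y.tolist())))
        unknown = set(y.tolist()) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside the class set: {sorted(unknown)}")
        self.y = np.asarray([self.classes.index(v) for v in y.tolist()])
        self.config = config or TrainingConfig()
        self.spec = spec or build_tdanet(self.X.shape[1], len(self.classes))
        if self.spec.input_dim != self.X.shape[1] or self.spec.n_classes != len(self.classes):
            raise ValueError("spec does not match data dimensions")

    def fit(self, seed: int | None = None) -> TrainingResult:
        """Train with early stopping; return the best-validation-accuracy checkpoint.

        ``seed`` overrides ``config.seed`` (convenient for repeat models on
        the same data).  Fully deterministic given (data, config, seed).
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        train_idx, val_idx = split_train_val(
            self.X.shape[0], cfg.train_fraction, seed,
            labels=self.y if cfg.stratify else None,
        )
        y_tr = self.y[train_idx]
        if len(set(y_tr.tolist())) < 2:
            raise ValueError("degenerate split: training set contains a single class")
        X_tr, X_va = self.X[train_idx], self.X[val_idx]
        y_va = self.y[val_idx]
        Y_tr = np.eye(len(self.classes))[y_tr]

        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7da]))
        params = _init_params(self.spec, rng)
        opt = (_Adam if cfg.optimizer == "adam" else _SGD)(params, cfg.learning_rate)

        hist = {"epoch": [], "train_loss": [], "train_accuracy": [], "val_accuracy": []}
        best_params, best_acc, best_epoch = params, -1.0, 0
        prev_acc, n_decreases = None, 0
        for epoch in range(1, cfg.max_epochs + 1):
            loss, probs_tr, grads = _forward_backward(params, X_tr, Y_tr)
            params = opt.step(params, grads)
            train_acc = float((_forward(params, X_tr).argmax(axis=1) == y_tr).mean())
            val_acc = float((_forward(params, X_va).argmax(axis=1) == y_va).mean())
            hist["epoch"].append(epoch)
            hist["train_loss"].append(float(loss))
            hist["train_accuracy"].append(train_acc)
            hist["val_accuracy"].append(val_acc)
            if val_acc > best_acc:
                best_params, best_acc, best_epoch = params, val_acc, epoch
            if prev_acc is not None and val_acc < prev_acc:
                n_decreases += 1
            else:
                n_decreases = 0
            prev_acc = val_acc
            if n_decreases >= cfg.patience:
                break
        return TrainingResult(
            spec=self.spec,
            config=cfg,
            classes=self.classes,
            params=best_params,
            history=pd.DataFrame(hist),
            best_epoch=best_epoch,
            best_val_accuracy=best_acc,
            train_idx=train_idx,
            val_idx=val_idx,
        )


def train_model(X, y, config: TrainingConfig | None = None, classes=None,
                spec: ModelSpec | None = None) -> TrainingResult:
    """Functional wrapper: construct a :class:`TDANet` and fit it."""
    return TDANet(X, y, classes=classes, spec=spec, config=config).fit()


def predict(result: TrainingResult, X) -> np.ndarray:
    """Per-class probability vectors (rows sum to 1) for new feature rows."""
    return result.predict_proba(X)
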