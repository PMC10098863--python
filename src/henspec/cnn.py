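"""Small scalogram CNN: build, train, evaluate.

The classifier is deliberately tiny — the scalogram already encodes
the discriminative spectral structure, so a shallow network suffices:

====  ==========================================================
conv1  8 filters, kernel (3, 1), stride (3, 1), ReLU
pool1  max pool (2, 2), stride (2, 2)
conv2  32 filters, kernel (1, 1), stride (1, 1), ReLU
pool2  max pool (3, 3), stride (2, 2)
head   flatten -> dense(2) -> softmax
====  ==========================================================

All convolutions and pools are valid (no padding), so the layer output
sizes follow floor((d - k) / s) + 1 exactly; for a 200 x 300 scalogram
the flattened feature vector has 16 * 74 * 32 = 37,888 entries.

The network is implemented directly on NumPy arrays (forward and
backward passes, Adam, softmax cross-entropy). At this size a
framework buys nothing, and a from-scratch implementation keeps
training bitwise reproducible from a single integer seed on one
platform: parameter initialization, batch shuffling, and every update
are pure, deterministically ordered array operations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from .dataset import FeatureDataset

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainingHistory",
    "ClassificationReport",
    "ShapeError",
    "build_model",
    "shape_trace",
    "train",
    "predict",
    "evaluate_report",
    "SmallScalogramCNN",
]


class ShapeError(ValueError):
    """An input is too small for a layer's kernel, or shapes mismatch."""


#: Network compute dtype. Single precision is ample for a 2-layer net and
#: halves memory traffic; all ops keep a fixed order, so runs with the same
#: seed remain bitwise identical.
DTYPE = np.float32


@dataclass(frozen=True)
class ModelConfig:
    """Fixed layer stack of the comb classifier (see module docstring)."""

    conv1_filters: int = 8
    conv1_kernel: tuple[int, int] = (3, 1)
    conv1_stride: tuple[int, int] = (3, 1)
    pool1_size: tuple[int, int] = (2, 2)
    pool1_stride: tuple[int, int] = (2, 2)
    conv2_filters: int = 32
    conv2_kernel: tuple[int, int] = (1, 1)
    conv2_stride: tuple[int, int] = (1, 1)
    pool2_size: tuple[int, int] = (3, 3)
    pool2_stride: tuple[int, int] = (2, 2)
    n_classes: int = 2
    input_shape: tuple[int, int, int] = (200, 300, 1)

    def layer_specs(self) -> list[tuple[str, str, tuple, tuple, int]]:
        """(name, kind, kernel, stride, channels) for the spatial layers."""
        return [
            ("conv1", "conv", self.conv1_kernel, self.conv1_stride, self.conv1_filters),
            ("pool1", "pool", self.pool1_size, self.pool1_stride, 0),
            ("conv2", "conv", self.conv2_kernel, self.conv2_stride, self.conv2_filters),
            ("pool2", "pool", self.pool2_size, self.pool2_stride, 0),
        ]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    optimizer: str = "adam"
    loss: str = "cross_entropy"

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size must be >= 1 and learning_rate > 0")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
            }
        )


def _out_dim(d: int, k: int, s: int) -> int:
    return (d - k) // s + 1


def trace_layers(
    layers: Sequence[tuple[str, str, tuple, tuple, int]],
    input_shape: tuple[int, int, int],
) -> list[tuple[str, tuple]]:
    """Valid-convolution shape arithmetic for a spatial layer list.

    Returns one (name, output_shape) pair per layer; an empty layer
    list returns an empty trace (the shape is the unchanged input).
    """
    h, w, c = input_shape
    out: list[tuple[str, tuple]] = []
    for name, kind, kernel, stride, channels in layers:
        kh, kw = kernel
        sh, sw = stride
        if h < kh or w < kw:
            raise ShapeError(
                f"layer {name}: input {h}x{w} smaller than kernel {kh}x{kw}"
            )
        h, w = _out_dim(h, kh, sh), _out_dim(w, kw, sw)
        if kind == "conv":
            c = channels
        out.append((name, (h, w, c)))
    return out


def shape_trace(
    cfg: ModelConfig, input_shape: Optional[tuple[int, int, int]] = None
) -> list[tuple[str, tuple]]:
    """Per-layer output shapes for the full stack, including the head."""
    if input_shape is None:
        input_shape = cfg.input_shape
    trace = trace_layers(cfg.layer_specs(), input_shape)
    h, w, c = trace[-1][1]
    trace.append(("flatten", (h * w * c,)))
    trace.append(("dense", (cfg.n_classes,)))
    return trace


# ---------------------------------------------------------------------------
# Layers


class _Conv2D:
    """Valid 2-D convolution with arbitrary kernel/stride."""

    def __init__(self, name, kernel, stride, c_in, c_out, rng):
        self.name = name
        self.kernel, self.stride = kernel, stride
        kh, kw = kernel
        fan_in = kh * kw * c_in
        self.W = (rng.standard_normal((kh, kw, c_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)

    def _windows(self, x):
        kh, kw = self.kernel
        sh, sw = self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
        return win[:, ::sh, ::sw]  # (B, Ho, Wo, C, kh, kw)

    def forward(self, x):
        self._x_shape = x.shape
        self._win = self._windows(x)
        return (
            np.tensordot(self._win, self.W, axes=([3, 4, 5], [2, 0, 1])) + self.b
        )

    def backward(self, dout):
        kh, kw = self.kernel
        sh, sw = self.stride
        self.dW = np.tensordot(self._win, dout, axes=([0, 1, 2], [0, 1, 2])).transpose(
            1, 2, 0, 3
        )  # (C, kh, kw, cout) -> (kh, kw, C, cout)
        self.db = dout.sum(axis=(0, 1, 2))
        dx = np.zeros(self._x_shape, dtype=DTYPE)
        _, ho, wo, _ = dout.shape
        for u in range(kh):
            for v in range(kw):
                # contribution of kernel tap (u, v) to each input position
                contrib = dout @ self.W[u, v].T  # (B, Ho, Wo, C_in)
                dx[:, u : u + ho * sh : sh, v : v + wo * sw : sw, :] += contrib
        self._win = None
        return dx

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


class _ReLU:
    name = "relu"

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out

    def params(self):
        return []

    def grads(self):
        return []


class _MaxPool2D:
    """Max pooling with arbitrary (possibly overlapping) windows."""

    def __init__(self, name, size, stride):
        self.name = name
        self.size, self.stride = size, stride
        self.training = True

    def _windows(self, x):
        ph, pw = self.size
        sh, sw = self.stride
        return np.lib.stride_tricks.sliding_window_view(x, (ph, pw), axis=(1, 2))[
            :, ::sh, ::sw
        ]  # (B, Ho, Wo, C, ph, pw)

    def forward(self, x):
        ph, pw = self.size
        win = self._windows(x)
        if not self.training:
            return win.max(axis=(4, 5))
        self._x_shape = x.shape
        b, ho, wo, c = win.shape[:4]
        flat = win.reshape(b, ho, wo, c, ph * pw)
        self._arg = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self._arg[..., np.newaxis], axis=-1)[..., 0]

    def backward(self, dout):
        ph, pw = self.size
        sh, sw = self.stride
        _, ho, wo, _ = dout.shape
        dx = np.zeros(self._x_shape, dtype=DTYPE)
        # Route each window's gradient to its argmax tap; one vectorized
        # pass per tap handles overlapping windows correctly.
        for u in range(ph):
            for v in range(pw):
                sel = dout * (self._arg == u * pw + v)
                dx[:, u : u + ho * sh : sh, v : v + wo * sw : sw, :] += sel
        self._arg = None
        return dx

    def params(self):
        return []

    def grads(self):
        return []


class _Dense:
    def __init__(self, name, n_in, n_out, rng):
        self.name = name
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


class _Flatten:
    name = "flatten"

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []

    def grads(self):
        return []


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallScalogramCNN:
    """The two-conv scalogram classifier with its optimizer state."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        # Validates the stack against the configured input shape.
        trace = shape_trace(cfg, cfg.input_shape)
        flat_len = trace[-2][1][0]
        rng = np.random.default_rng(seed)
        c_in = cfg.input_shape[2]
        self.layers = [
            _Conv2D("conv1", cfg.conv1_kernel, cfg.conv1_stride, c_in, cfg.conv1_filters, rng),
            _ReLU(),
            _MaxPool2D("pool1", cfg.pool1_size, cfg.pool1_stride),
            _Conv2D("conv2", cfg.conv2_kernel, cfg.conv2_stride, cfg.conv1_filters, cfg.conv2_filters, rng),
            _ReLU(),
            _MaxPool2D("pool2", cfg.pool2_size, cfg.pool2_stride),
            _Flatten(),
            _Dense("dense", flat_len, cfg.n_classes, rng),
        ]
        self.classes_: Optional[np.ndarray] = None
        self._adam_state = None

    # -- forward / backward -------------------------------------------------

    def _set_training(self, flag: bool) -> None:
        for layer in self.layers:
            if isinstance(layer, _MaxPool2D):
                layer.training = flag

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 3:  # (B, H, W) -> single channel
            x = x[..., np.newaxis]
        if x.ndim != 4 or x.shape[1:] != self.cfg.input_shape:
            raise ShapeError(
                f"input shape {x.shape[1:]} does not match model input {self.cfg.input_shape}"
            )
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = self._check_input(x)
        self._set_training(False)
        try:
            outs = [
                _softmax(self.forward(x[i : i + batch_size]))
                for i in range(0, x.shape[0], batch_size)
            ]
        finally:
            self._set_training(True)
        return np.concatenate(outs)

    # -- optimizer ----------------------------------------------------------

    def _adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        params = [p for layer in self.layers for _, p in layer.params()]
        grads = [g for layer in self.layers for g in layer.grads()]
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(p) for p in params],
                "v": [np.zeros_like(p) for p in params],
            }
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        for p, g, m, v in zip(params, grads, st["m"], st["v"]):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, layer in enumerate(self.layers):
            for pname, p in layer.params():
                arrays[f"{i}_{layer.name}_{pname}"] = p
        np.savez(directory / "weights.npz", **arrays)
        meta = {
            "config": asdict(self.cfg),
            "seed": self.seed,
            "classes": None if self.classes_ is None else self.classes_.tolist(),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        return directory

    @classmethod
    def load(cls, directory) -> "SmallScalogramCNN":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        cfg_dict = meta["config"]
        for key, val in cfg_dict.items():
            if isinstance(val, list):
                cfg_dict[key] = tuple(val)
        model = cls(ModelConfig(**cfg_dict), seed=meta["seed"])
        with np.load(directory / "weights.npz") as data:
            for i, layer in enumerate(model.layers):
                for pname, p in layer.params():
                    p[...] = data[f"{i}_{layer.name}_{pname}"]
        if meta["classes"] is not None:
            model.classes_ = np.array(meta["classes"])
        return model


def build_model(cfg: Optional[ModelConfig] = None, seed: int = 0) -> SmallScalogramCNN:
    """Instantiate the classifier with seeded (He-normal) initialization.

    Raises :class:`ShapeError` if the configured input is too small for
    the layer stack.
    """
    return SmallScalogramCNN(cfg or ModelConfig(), seed=seed)


# ---------------------------------------------------------------------------
# Training / inference


def _xy(ds: FeatureDataset, classes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = ds.features[..., np.newaxis].astype(DTYPE)
    lookup = {c: i for i, c in enumerate(classes)}
    y = np.array([lookup[l] for l in ds.labels.tolist()])
    return x, y


def _eval_loss_acc(model: SmallScalogramCNN, x, y, batch_size=64):
    probs = model.predict_proba(x, batch_size=batch_size)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(y.size), y] + eps)))
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return loss, acc


def train(
    model: SmallScalogramCNN,
    train_ds: FeatureDataset,
    val_ds: FeatureDataset,
    tcfg: Optional[TrainConfig] = None,
    out_dir=None,
) -> TrainingHistory:
    """Mini-batch Adam training with softmax cross-entropy.

    Records per-epoch train/validation loss and accuracy (training
    metrics are running averages over the epoch's batches, at the
    weights current when each batch was seen). With a fixed
    ``tcfg.seed`` the returned history is bitwise reproducible. When
    ``out_dir`` is given the final model, config and history are
    persisted there.
    """
    tcfg = tcfg or TrainConfig()
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("train and validation sets must be nonempty")
    classes = np.array(sorted(set(train_ds.labels) | set(val_ds.labels)))
    if classes.size != model.cfg.n_classes:
        raise ValueError(
            f"dataset has {classes.size} classes, model expects {model.cfg.n_classes}"
        )
    model.classes_ = classes
    x_tr, y_tr = _xy(train_ds, classes)
    x_va, y_va = _xy(val_ds, classes)
    if x_tr.shape[1:] != model.cfg.input_shape:
        raise ShapeError(
            f"feature maps {x_tr.shape[1:]} do not match model input {model.cfg.input_shape}"
        )

    rng = np.random.default_rng(tcfg.seed)
    history = TrainingHistory()
    n = x_tr.shape[0]
    for _ in range(tcfg.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, tcfg.batch_size):
            idx = perm[start : start + tcfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = model.forward(xb)
            probs = _softmax(logits)
            eps = 1e-12
            losses.append(
                -np.sum(np.log(probs[np.arange(yb.size), yb] + eps))
            )
            correct += int(np.sum(probs.argmax(axis=1) == yb))
            dlogits = probs.copy()
            dlogits[np.arange(yb.size), yb] -= 1.0
            model.backward(dlogits / yb.size)
            model._adam_step(tcfg.learning_rate)
        history.train_loss.append(float(np.sum(losses) / n))
        history.train_acc.append(correct / n)
        vl, va = _eval_loss_acc(model, x_va, y_va)
        history.val_loss.append(vl)
        history.val_acc.append(va)

    if out_dir is not None:
        out_dir = Path(out_dir)
        model.save(out_dir)
        history.to_frame().to_csv(out_dir / "history.tsv", sep="\t", index=False)
        (out_dir / "train_config.json").write_text(json.dumps(asdict(tcfg), indent=1))
    return history


def predict(
    model: SmallScalogramCNN, features: np.ndarray | FeatureDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (argmax of softmax) and per-sample probabilities."""
    x = features.features if isinstance(features, FeatureDataset) else features
    probs = model.predict_proba(np.asarray(x, float)[..., np.newaxis] if np.asarray(x).ndim == 3 else x)
    if model.classes_ is None:
        labels = probs.argmax(axis=1)
    else:
        labels = model.classes_[probs.argmax(axis=1)]
    return labels, probs


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class ClassificationReport:
    """Per-class precision/recall/F1/support plus accuracy and averages."""

    classes: list
    precision: dict
    recall: dict
    f1: dict
    support: dict
    accuracy: float
    macro_avg: dict
    weighted_avg: dict

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: metric rows, class + average columns."""
        cols = {c: [self.precision[c], self.recall[c], self.f1[c]] for c in self.classes}
        cols["macro avg"] = [self.macro_avg[k] for k in ("precision", "recall", "f1")]
        cols["weighted avg"] = [self.weighted_avg[k] for k in ("precision", "recall", "f1")]
        return pd.DataFrame(cols, index=["precision", "recall", "f1-score"])


def evaluate_report(
    y_true: Sequence, y_pred: Sequence, classes: Optional[Sequence] = None
) -> ClassificationReport:
    """Precision, recall, F1 per class plus macro/weighted averages.

    Per class: precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2*precision*recall/(precision+recall). Macro averages are
    unweighted means over classes, weighted averages use the true class
    supports. Zero-denominator metrics (e.g. a class never predicted)
    are defined as 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("label vectors must be nonempty and of equal length")
    if classes is None:
        classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    classes = list(classes)
    prec, rec, f1, supp = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    mp, mr, mf, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="macro", zero_division=0
    )
    wp, wr, wf, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="weighted", zero_division=0
    )
    return ClassificationReport(
        classes=classes,
        precision=dict(zip(classes, prec.tolist())),
        recall=dict(zip(classes, rec.tolist())),
        f1=dict(zip(classes, f1.tolist())),
        support=dict(zip(classes, supp.tolist())),
        accuracy=float(np.mean(y_true == y_pred)),
        macro_avg={"precision": float(mp), "recall": float(mr), "f1": float(mf)},
        weighted_avg={"precision": float(wp), "recall": float(wr), "f1": float(wf)},
    )
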