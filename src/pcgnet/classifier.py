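"""The CNN-GRU heart-sound classifier: architecture, training, prediction.

The default network takes a 1001-sample frame (0.5 s at 2000 Hz) and
stacks three blocks of valid-padding convolution (kernel 20, 9 filters,
stride 1, ReLU) and max pooling (pool 4, stride 4), shrinking the
temporal axis 1001 -> 982 -> 245 -> 226 -> 56 -> 37 -> 9.  The pooled
output is consumed as a 9-step sequence of 9-dimensional vectors by a GRU
with 128 units (dropout 0.5 on its output), whose final hidden state
feeds a 2-unit softmax dense head (survival vs sudden death; sudden death
is the positive class).

Training follows a fixed protocol: Adam at learning rate 0.001,
cross-entropy plus an L2 penalty (weight 0.001) on all weight matrices,
batch size 64, at most 50 epochs, early stopping when the validation loss
has not improved for 10 consecutive epochs (strict comparison to the
running best; the best-validation weights are restored).

Ablation variants - kernel in {10, 20, 30}, depth in {4, 6, 8} layers,
GRU units in {8 ... 256} - and CNN-only / GRU-only baselines are built
from the same declarative :class:`ModelSpec`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn

#: class coding: sudden death is the positive class
CLASS_NAMES = ("survival", "sudden_death")
POSITIVE_CLASS = "sudden_death"


class ShapeError(ValueError):
    """Raised when an architecture cannot propagate its input shape."""


@dataclass
class LayerSpec:
    """One layer of a declarative network description."""

    kind: str                      # conv1d | maxpool1d | gru | dense | flatten
    size: int | None = None        # kernel or pool size
    filters: int | None = None     # conv filters
    units: int | None = None       # gru or dense units
    stride: int = 1
    padding: str = "valid"
    activation: str | None = None  # relu | softmax | None
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {"conv1d", "maxpool1d", "gru", "dense", "flatten"}:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.padding != "valid":
            raise ValueError("only valid padding is supported")
        if self.activation not in {None, "relu", "softmax"}:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class ModelSpec:
    """Ordered layer list plus the input contract."""

    layers: list[LayerSpec]
    input_len: int = 1001
    n_classes: int = 2

    def to_json(self) -> str:
        return json.dumps({"input_len": self.input_len, "n_classes": self.n_classes,
                           "layers": [asdict(l) for l in self.layers]}, indent=2)

    @staticmethod
    def from_json(text: str) -> "ModelSpec":
        data = json.loads(text)
        return ModelSpec(layers=[LayerSpec(**l) for l in data["layers"]],
                         input_len=data["input_len"], n_classes=data["n_classes"])


@dataclass
class TrainConfig:
    """Hyperparameters of the training protocol."""

    lr: float = 0.001
    l2: float = 0.001
    dropout: float = 0.5
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lr <= 1 or not 0 <= self.dropout < 1:
            raise ValueError("rates out of range")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


# ---------------------------------------------------------------------------
# Architecture builders
# ---------------------------------------------------------------------------

def build_cnn_gru(input_len: int = 1001, kernel: int = 20, filters: int = 9,
                  pool: int = 4, gru_units: int = 128, n_classes: int = 2,
                  n_layers: int = 8, dropout: float = 0.5) -> ModelSpec:
    """The CNN-GRU stack: (n_layers - 2) / 2 conv/pool blocks + GRU + dense.

    ``n_layers = 8`` is the default network; 6 and 4 drop one and two
    conv/pool blocks respectively (the ablation depths).
    """
    if n_layers not in (4, 6, 8):
        raise ValueError("n_layers must be one of 4, 6, 8")
    if min(input_len, kernel, filters, pool, gru_units, n_classes) < 1:
        raise ValueError("all architecture parameters must be positive")
    layers: list[LayerSpec] = []
    for _ in range((n_layers - 2) // 2):
        layers.append(LayerSpec(kind="conv1d", size=kernel, filters=filters,
                                stride=1, activation="relu"))
        layers.append(LayerSpec(kind="maxpool1d", size=pool, stride=pool))
    layers.append(LayerSpec(kind="gru", units=gru_units, dropout=dropout))
    layers.append(LayerSpec(kind="dense", units=n_classes, activation="softmax"))
    spec = ModelSpec(layers=layers, input_len=input_len, n_classes=n_classes)
    output_shapes(spec)  # fail fast on impossible stacks
    return spec


def build_baseline(kind: str, input_len: int = 1001, kernel: int = 20,
                   filters: int = 9, pool: int = 4, units: int = 128,
                   n_classes: int = 2, dropout: float = 0.5) -> ModelSpec:
    """CNN-only (conv/pool stack + flatten + dense) or GRU-only baseline."""
    if kind == "cnn":
        layers = []
        for _ in range(3):
            layers.append(LayerSpec(kind="conv1d", size=kernel, filters=filters,
                                    stride=1, activation="relu"))
            layers.append(LayerSpec(kind="maxpool1d", size=pool, stride=pool))
        layers.append(LayerSpec(kind="flatten"))
        layers.append(LayerSpec(kind="dense", units=n_classes, activation="softmax"))
    elif kind == "gru":
        layers = [LayerSpec(kind="gru", units=units, dropout=dropout),
                  LayerSpec(kind="dense", units=n_classes, activation="softmax")]
    else:
        raise ValueError(f"baseline kind must be 'cnn' or 'gru', got {kind!r}")
    spec = ModelSpec(layers=layers, input_len=input_len, n_classes=n_classes)
    output_shapes(spec)
    return spec


def output_shapes(spec: ModelSpec) -> list[tuple[int, ...]]:
    """Propagate the input shape through the stack.

    Returns one shape tuple per layer: ``(temporal length, channels)``
    for conv/pool, ``(units,)`` for GRU and dense, ``(flattened,)`` for
    flatten.  Valid convolution gives ``out = in - kernel + 1``; pooling
    ``out = floor((in - pool) / stride) + 1``.
    """
    t, c = spec.input_len, 1
    shapes: list[tuple[int, ...]] = []
    flat: int | None = None
    for i, layer in enumerate(spec.layers):
        if layer.kind == "conv1d":
            t = t - layer.size + 1
            c = layer.filters
            if t < 1:
                raise ShapeError(f"layer {i}: conv output length {t} < 1")
            shapes.append((t, c))
        elif layer.kind == "maxpool1d":
            t = (t - layer.size) // layer.stride + 1
            if t < 1:
                raise ShapeError(f"layer {i}: pool output length {t} < 1")
            shapes.append((t, c))
        elif layer.kind == "gru":
            shapes.append((layer.units,))
            flat = layer.units
        elif layer.kind == "flatten":
            flat = t * c
            shapes.append((flat,))
        elif layer.kind == "dense":
            shapes.append((layer.units,))
            flat = layer.units
    return shapes


def compile_model(spec: ModelSpec, l2: float = 0.001, seed: int = 0,
                  dtype=np.float32) -> nn.Model:
    """Instantiate a trainable numpy model from a declarative spec."""
    rng = np.random.default_rng(seed)
    shapes = output_shapes(spec)
    layers: list[nn.Layer] = []
    t, c = spec.input_len, 1
    flat = None
    for layer, shape in zip(spec.layers, shapes):
        if layer.kind == "conv1d":
            layers.append(nn.Conv1D(c, layer.filters, layer.size,
                                    relu=layer.activation == "relu",
                                    rng=rng, dtype=dtype))
            t, c = shape
        elif layer.kind == "maxpool1d":
            layers.append(nn.MaxPool1D(layer.size))
            t = shape[0]
        elif layer.kind == "gru":
            layers.append(nn.GRU(c, layer.units, dropout=layer.dropout,
                                 rng=rng, dtype=dtype))
            flat = layer.units
        elif layer.kind == "flatten":
            layers.append(nn.Flatten())
            flat = shape[0]
        elif layer.kind == "dense":
            layers.append(nn.Dense(flat, layer.units, rng=rng, dtype=dtype))
            flat = layer.units
    return nn.Model(layers, l2=l2)


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

def encode_labels(labels) -> np.ndarray:
    """Map class-name strings to {0, 1} with sudden death as class 1."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        return labels.astype(np.int64)
    out = np.empty(labels.shape, dtype=np.int64)
    for i, name in enumerate(CLASS_NAMES):
        out[labels == name] = i
    unknown = ~np.isin(labels, CLASS_NAMES)
    if unknown.any():
        raise ValueError(f"unknown labels: {set(labels[unknown])}")
    return out


def _as_batch(frames: np.ndarray, input_len: int, dtype=np.float32) -> np.ndarray:
    frames = np.asarray(frames, dtype=dtype)
    if frames.ndim == 2:
        frames = frames[:, :, None]
    if frames.shape[1] != input_len:
        raise ValueError(f"frame length {frames.shape[1]} does not match "
                         f"model input length {input_len}")
    return frames


def train(spec: ModelSpec, frames_train: np.ndarray, y_train,
          frames_val: np.ndarray, y_val,
          cfg: TrainConfig | None = None) -> tuple[nn.Model, dict]:
    """Train a model under the fixed protocol.

    Returns the trained model (best-validation weights restored) and a
    history dict with per-epoch ``train_loss``, ``train_acc``,
    ``val_loss`` and ``val_acc`` lists whose length equals the number of
    epochs actually run.
    """
    cfg = cfg or TrainConfig()
    y_train = encode_labels(y_train)
    y_val = encode_labels(y_val)
    if len(y_train) == 0 or len(y_val) == 0:
        raise ValueError("empty training or validation split")
    if np.unique(y_train).size < 2:
        raise ValueError("training set contains a single class")
    X_train = _as_batch(frames_train, spec.input_len)
    X_val = _as_batch(frames_val, spec.input_len)

    model = compile_model(spec, l2=cfg.l2, seed=cfg.seed)
    opt = nn.Adam(model, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)

    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_loss = np.inf
    best_weights = model.get_weights()
    stall = 0
    n = X_train.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses, accs, sizes = [], [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, acc = model.loss_and_grad(X_train[idx], y_train[idx], train=True)
            opt.step()
            losses.append(loss)
            accs.append(acc)
            sizes.append(idx.size)
        w = np.asarray(sizes, dtype=float)
        history["train_loss"].append(float(np.average(losses, weights=w)))
        history["train_acc"].append(float(np.average(accs, weights=w)))
        val_loss, val_acc = evaluate_loss(model, X_val, y_val)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = model.get_weights()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    model.set_weights(best_weights)
    return model, history


def evaluate_loss(model: nn.Model, X: np.ndarray, y: np.ndarray,
                  batch_size: int = 256) -> tuple[float, float]:
    """Mean cross-entropy (without the L2 term) and accuracy on a set."""
    losses, accs, sizes = [], [], []
    for start in range(0, X.shape[0], batch_size):
        xb, yb = X[start:start + batch_size], y[start:start + batch_size]
        probs = model.predict_proba(xb)
        eps = np.finfo(probs.dtype).tiny
        losses.append(-float(np.mean(np.log(probs[np.arange(len(yb)), yb] + eps))))
        accs.append(float(np.mean(probs.argmax(axis=1) == yb)))
        sizes.append(len(yb))
    w = np.asarray(sizes, dtype=float)
    return float(np.average(losses, weights=w)), float(np.average(accs, weights=w))


def predict(model: nn.Model, frames: np.ndarray,
            input_len: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels for a batch of frames."""
    if input_len is None:
        first = model.layers[0]
        if isinstance(first, nn.Conv1D):
            input_len = None  # any length the stack accepts
    X = np.asarray(frames, dtype=np.float32)
    if X.ndim == 2:
        X = X[:, :, None]
    if input_len is not None and X.shape[1] != input_len:
        raise ValueError(f"frame length {X.shape[1]} does not match input "
                         f"length {input_len}")
    probs = model.predict_proba(X)
    return probs, probs.argmax(axis=1)
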