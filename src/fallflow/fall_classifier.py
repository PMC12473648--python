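"""Compact CNN over 6x150 motion windows, and a CNN+BiLSTM variant.

The CNN treats a window as a 6-row image and convolves along the time axis
only (width-only kernels and pools), so the six motion channels are never
mixed spatially — only through learned feature channels.  Two mandatory
conv blocks (conv + batch norm + ReLU + time max-pool) are followed by an
optional third refinement block, then flatten -> dense 64 -> dropout ->
dense 2 -> softmax.  The hybrid variant feeds the time-indexed feature maps
of the conv stack into a bidirectional LSTM whose final states feed the
same dense head.

Training: Adam (lr 0.001), mini-batches of 32, up to 16 epochs,
cross-entropy loss with L2 weight penalty (0.001), fully seeded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .synthetic_scenes import MotionWindow
from .windowing import ChannelStats

N_CHANNELS = 6
DEFAULT_WINDOW_LENGTH = 150


@dataclass
class ConvBlockSpec:
    filters: int
    kernel: int
    pool: int  # 0 disables pooling


@dataclass
class ClassifierConfig:
    architecture: str = "cnn"  # "cnn" | "cnn_bilstm"
    window_length: int = DEFAULT_WINDOW_LENGTH
    conv_blocks: list[ConvBlockSpec] = field(
        default_factory=lambda: [
            ConvBlockSpec(filters=16, kernel=7, pool=2),
            ConvBlockSpec(filters=32, kernel=5, pool=2),
            ConvBlockSpec(filters=64, kernel=3, pool=0),
        ]
    )
    use_third_block: bool = True
    dense_units: int = 64
    dropout_rate: float = 0.5
    lstm_units: int = 64
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 16
    l2_weight: float = 0.001
    seed: int = 0
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.architecture not in ("cnn", "cnn_bilstm"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        self.conv_blocks = [
            b if isinstance(b, ConvBlockSpec) else ConvBlockSpec(*b) for b in self.conv_blocks
        ]

    def active_blocks(self) -> list[ConvBlockSpec]:
        blocks = list(self.conv_blocks)
        if not self.use_third_block and len(blocks) >= 3:
            blocks = blocks[:2]
        return blocks

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierConfig":
        d = dict(d)
        d["conv_blocks"] = [ConvBlockSpec(**b) for b in d.get("conv_blocks", [])]
        return cls(**d)


class WindowClassifier:
    """An untrained or trained window model: layer stack + metadata."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        rng = np.random.default_rng([config.seed, 0x5EED])
        self._dropout_rng = np.random.default_rng([config.seed, 0xD0])
        layers: list[nn.Layer] = []
        manifest: list[str] = []
        t = config.window_length
        c_in = 1
        for i, block in enumerate(config.active_blocks()):
            layers.append(nn.ConvWidth(c_in, block.filters, block.kernel, rng, f"conv{i}"))
            layers.append(nn.BatchNorm(block.filters, f"bn{i}"))
            layers.append(nn.ReLU())
            manifest.append(f"conv_block{i}(filters={block.filters}, kernel=1x{block.kernel})")
            if block.pool > 1:
                layers.append(nn.MaxPoolTime(block.pool))
                t = t // block.pool
                if t < 1:
                    raise ValueError("pooling exhausts the time axis")
                manifest[-1] += f"+pool1x{block.pool}"
            c_in = block.filters

        if config.architecture == "cnn":
            layers.append(nn.Flatten())
            head_in = N_CHANNELS * t * c_in
            manifest.append("flatten")
        else:
            layers.append(nn.TimeCollapse())
            layers.append(nn.BiLSTM(N_CHANNELS * c_in, config.lstm_units, rng, "bilstm"))
            head_in = 2 * config.lstm_units
            manifest.append(f"bilstm(units={config.lstm_units})")

        layers.append(nn.Dense(head_in, config.dense_units, rng, "dense1"))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(config.dropout_rate, self._dropout_rng))
        layers.append(nn.Dense(config.dense_units, 2, rng, "dense2"))
        manifest.append(f"dense({config.dense_units})+dropout({config.dropout_rate})")
        manifest.append("dense(2)+softmax")

        self.net = nn.Sequential(layers)
        self.layer_manifest = manifest
        self.history: dict[str, list[float]] = {}
        self.class_order = ("no_fall", "fall")
        self.stats: Optional[ChannelStats] = None

    def num_parameters(self) -> int:
        return self.net.num_parameters()

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != N_CHANNELS or x.shape[2] != self.config.window_length:
            raise ValueError(
                f"expected windows of shape (B, {N_CHANNELS}, {self.config.window_length}), "
                f"got {x.shape}"
            )
        return x[:, :, :, np.newaxis]

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._check_input(windows))

    # --- serialization -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, p in enumerate(self.net.params()):
            out[f"p{i:03d}"] = p.value
        for i, layer in enumerate(self.net.layers):
            if isinstance(layer, nn.BatchNorm):
                out[f"rm{i:03d}"] = layer.running_mean
                out[f"rv{i:03d}"] = layer.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.net.params()):
            val = np.asarray(arrays[f"p{i:03d}"], dtype=np.float64)
            if val.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value = val
        for i, layer in enumerate(self.net.layers):
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = np.asarray(arrays[f"rm{i:03d}"], dtype=np.float64)
                layer.running_var = np.asarray(arrays[f"rv{i:03d}"], dtype=np.float64)


def build_model(config: ClassifierConfig) -> WindowClassifier:
    """Instantiate the selected architecture with seeded initialization."""
    return WindowClassifier(config)


def windows_to_array(windows: Sequence[MotionWindow]) -> np.ndarray:
    return np.stack([w.values for w in windows], axis=0)


def _stratified_split(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices for a seeded stratified holdout of the given fraction."""
    hold: list[np.ndarray] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        k = max(1, int(round(fraction * idx.size)))
        hold.append(idx[:k])
    hold_idx = np.sort(np.concatenate(hold))
    train_idx = np.setdiff1d(np.arange(y.size), hold_idx)
    return train_idx, hold_idx


def train(
    model: WindowClassifier,
    windows: np.ndarray | Sequence[MotionWindow],
    labels: Optional[np.ndarray] = None,
    config: Optional[ClassifierConfig] = None,
) -> WindowClassifier:
    """Fit in place with Adam + cross-entropy + L2; returns the model.

    ``windows`` may be an array (B, 6, N) with explicit ``labels`` or a list
    of labeled MotionWindow objects.  Raises on single-class input and on a
    NaN loss.
    """
    if labels is None:
        if not isinstance(windows, np.ndarray):
            labels = np.array([w.label for w in windows], dtype=np.int64)
            if any(l is None for l in (w.label for w in windows)):
                raise ValueError("unlabeled windows passed to train()")
        else:
            raise ValueError("labels required when windows is an array")
    if not isinstance(windows, np.ndarray):
        windows = windows_to_array(windows)
    cfg = config or model.config
    y = np.asarray(labels, dtype=np.int64)
    if set(np.unique(y).tolist()) != {0, 1}:
        raise ValueError("training data must contain both classes")
    x = model._check_input(windows)

    rng = np.random.default_rng([cfg.seed, 0x7A1])
    val_x = val_y = None
    if cfg.validation_fraction > 0:
        tr_idx, va_idx = _stratified_split(y, cfg.validation_fraction, rng)
        val_x, val_y = x[va_idx], y[va_idx]
        x, y = x[tr_idx], y[tr_idx]

    opt = nn.Adam(model.net.params(), lr=cfg.learning_rate, l2=cfg.l2_weight)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    if val_x is not None:
        history["val_loss"] = []
        history["val_accuracy"] = []

    n = x.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.net.forward(xb, train=True)
            probs = nn.softmax(logits)
            loss = nn.cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}: "
                    f"loss={loss}, logit range [{logits.min()}, {logits.max()}]"
                )
            model.net.backward(nn.softmax_xent_grad(probs, yb))
            opt.step()
            epoch_loss += loss * idx.size
            epoch_correct += int((probs.argmax(axis=1) == yb).sum())
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(epoch_correct / n)
        if val_x is not None:
            vp = model.net.predict_proba(val_x)
            history["val_loss"].append(nn.cross_entropy(vp, val_y))
            history["val_accuracy"].append(float((vp.argmax(axis=1) == val_y).mean()))

    model.history = history
    return model


def predict(
    model: WindowClassifier,
    windows: np.ndarray | Sequence[MotionWindow],
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window class probabilities (B, 2) and thresholded fall labels.

    The default threshold 0.5 reproduces argmax; extreme thresholds behave
    as sentinels (<= 0 labels everything fall, >= 1 labels nothing).
    """
    if not isinstance(windows, np.ndarray):
        windows = windows_to_array(windows)
    probs = model.predict_proba(windows)
    fall_p = probs[:, 1]
    if threshold <= 0.0:
        labels = np.ones(fall_p.shape, dtype=np.int64)
    elif threshold >= 1.0:
        labels = np.zeros(fall_p.shape, dtype=np.int64)
    else:
        labels = (fall_p >= threshold).astype(np.int64)
    return probs, labels


def save_model(model: WindowClassifier, path) -> None:
    """Single-file artifact: weights + config + normalization stats."""
    meta = {
        "config": model.config.to_dict(),
        "history": model.history,
        "class_order": list(model.class_order),
        "stats": None
        if model.stats is None
        else {"mean": model.stats.mean.tolist(), "std": model.stats.std.tolist()},
    }
    arrays = model.state_arrays()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> WindowClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    model = WindowClassifier(ClassifierConfig.from_dict(meta["config"]))
    model.load_state_arrays(arrays)
    model.history = meta.get("history", {})
    if meta.get("stats"):
        model.stats = ChannelStats(
            mean=np.asarray(meta["stats"]["mean"]), std=np.asarray(meta["stats"]["std"])
        )
    return model
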