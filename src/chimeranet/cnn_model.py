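"""The 1-D convolutional chimera classifier.

The network reads a one-hot encoded 110 x 4 chimera and emits the
probability that the miRNA (first ~21 nt) interacts with the appended
target-site sequence.  Architecture: four length-preserving Conv1D blocks
(16/32/64/128 filters, kernel sizes 2/3/4/5, ReLU) each followed by
max-pooling of size 2 (ceil length convention), then flatten, dropout,
a 128-unit ReLU dense layer with L2 weight decay, dropout, and a single
sigmoid output unit — 166,001 trainable parameters in total.

Everything is implemented directly on NumPy: forward pass, backpropagation,
binary cross-entropy on logits, Adam, and early stopping on validation loss
with best-weight restoration.  Given a seed, training is bit-reproducible
on a fixed platform.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from .chimera_builder import EncodedBatch
from .exceptions import ChimeranetError, ValidationError

INPUT_LENGTH = 110
INPUT_CHANNELS = 4


# ---------------------------------------------------------------------------
# declarative architecture


@dataclass
class LayerSpec:
    kind: str  # conv | maxpool | flatten | dropout | dense
    filters: int = 0
    kernel_size: int = 0
    pool_size: int = 0
    units: int = 0
    dropout_rate: float = 0.0
    l2_coefficient: float = 0.0
    activation: str = "none"  # relu | sigmoid | none

    def __post_init__(self):
        kinds = {"conv", "maxpool", "flatten", "dropout", "dense"}
        if self.kind not in kinds:
            raise ValidationError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv" and (self.filters <= 0 or self.kernel_size <= 0):
            raise ValidationError("conv layer needs positive filters and kernel_size")
        if self.kind == "maxpool" and self.pool_size <= 0:
            raise ValidationError("maxpool layer needs positive pool_size")
        if self.kind == "dense" and self.units <= 0:
            raise ValidationError("dense layer needs positive units")


@dataclass
class ArchitectureSpec:
    input_length: int = INPUT_LENGTH
    input_channels: int = INPUT_CHANNELS
    layers: list[LayerSpec] = field(default_factory=list)

    def __post_init__(self):
        if self.layers:
            last = self.layers[-1]
            if not (last.kind == "dense" and last.units == 1 and last.activation == "sigmoid"):
                raise ValidationError(
                    "final layer must be dense(1) with sigmoid activation"
                )

    def to_dict(self) -> dict:
        return {
            "input_length": self.input_length,
            "input_channels": self.input_channels,
            "layers": [asdict(l) for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            input_length=d["input_length"],
            input_channels=d["input_channels"],
            layers=[LayerSpec(**l) for l in d["layers"]],
        )


def build_architecture(
    dropout_rates: tuple[float, float] = (0.5, 0.3),
    l2_coefficient: float = 1e-3,
) -> ArchitectureSpec:
    """The default network: 4 conv/pool blocks, flatten, dropout, dense-128
    (ReLU, L2), dropout, dense-1 (sigmoid)."""
    layers = []
    for filters, k in ((16, 2), (32, 3), (64, 4), (128, 5)):
        layers.append(LayerSpec("conv", filters=filters, kernel_size=k, activation="relu"))
        layers.append(LayerSpec("maxpool", pool_size=2))
    layers.append(LayerSpec("flatten"))
    layers.append(LayerSpec("dropout", dropout_rate=dropout_rates[0]))
    layers.append(
        LayerSpec("dense", units=128, activation="relu", l2_coefficient=l2_coefficient)
    )
    layers.append(LayerSpec("dropout", dropout_rate=dropout_rates[1]))
    layers.append(LayerSpec("dense", units=1, activation="sigmoid"))
    return ArchitectureSpec(layers=layers)


def output_shapes(
    arch: ArchitectureSpec, input_length: int | None = None
) -> list[tuple[int, ...]]:
    """Per-layer output shapes, (length, channels) for spatial layers and
    (width,) after flattening.  Convolutions preserve length ("same"
    padding); pooling maps L -> ceil(L / pool)."""
    L = arch.input_length if input_length is None else input_length
    C = arch.input_channels
    flat: int | None = None
    shapes: list[tuple[int, ...]] = []
    for layer in arch.layers:
        if layer.kind == "conv":
            C = layer.filters
            shapes.append((L, C))
        elif layer.kind == "maxpool":
            L = math.ceil(L / layer.pool_size)
            shapes.append((L, C))
        elif layer.kind == "flatten":
            flat = L * C
            shapes.append((flat,))
        elif layer.kind == "dropout":
            shapes.append(shapes[-1] if shapes else (L, C))
        elif layer.kind == "dense":
            flat = layer.units
            shapes.append((flat,))
    return shapes


def count_parameters(arch: ArchitectureSpec) -> tuple[list[int], int]:
    """Per-layer trainable parameter counts (biases included) and total."""
    counts: list[int] = []
    C = arch.input_channels
    L = arch.input_length
    flat: int | None = None
    for layer in arch.layers:
        if layer.kind == "conv":
            counts.append(layer.filters * (layer.kernel_size * C + 1))
            C = layer.filters
        elif layer.kind == "maxpool":
            counts.append(0)
            L = math.ceil(L / layer.pool_size)
        elif layer.kind == "flatten":
            flat = L * C
            counts.append(0)
        elif layer.kind == "dropout":
            counts.append(0)
        elif layer.kind == "dense":
            in_dim = flat if flat is not None else L * C
            counts.append(layer.units * (in_dim + 1))
            flat = layer.units
    return counts, sum(counts)


# ---------------------------------------------------------------------------
# runtime layers (NumPy forward/backward)


class _Conv1D:
    """Length-preserving 1-D convolution with bias and optional ReLU.

    Asymmetric "same" padding for even kernels: (k-1)//2 on the left,
    the remainder on the right.
    """

    def __init__(self, k: int, c_in: int, c_out: int, activation: str, rng):
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.activation = activation
        limit = math.sqrt(6.0 / (k * c_in + k * c_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(k, c_in, c_out))
        self.b = np.zeros(c_out)
        self.l2 = 0.0

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self.x = x
        B, L, _ = x.shape
        pl = (self.k - 1) // 2
        pr = self.k - 1 - pl
        self.pl = pl
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # win: (B, L, c_in, k)
        self.win = win
        z = np.einsum("blck,kcf->blf", win, self.W, optimize=True) + self.b
        if self.activation == "relu":
            self.mask = z > 0
            return z * self.mask
        return z

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self.mask
        dW = np.einsum("blck,blf->kcf", self.win, dy, optimize=True)
        db = dy.sum(axis=(0, 1))
        B, L, _ = self.x.shape
        dxp = np.zeros((B, L + self.k - 1, self.c_in))
        for off in range(self.k):
            dxp[:, off : off + L, :] += dy @ self.W[off].T
        dx = dxp[:, self.pl : self.pl + L, :]
        self.grads = [dW, db]
        return dx


class _MaxPool1D:
    """Max pooling with ceil length convention (trailing partial window kept)."""

    def __init__(self, pool: int):
        self.pool = pool

    params: list = []
    grads: list = []

    def forward(self, x, train):
        B, L, C = x.shape
        self.L = L
        L_out = math.ceil(L / self.pool)
        pad = L_out * self.pool - L
        xp = np.pad(x, ((0, 0), (0, pad), (0, 0)), constant_values=-np.inf)
        xr = xp.reshape(B, L_out, self.pool, C)
        self.arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dy):
        B, L_out, C = dy.shape
        dxp = np.zeros((B, L_out, self.pool, C))
        np.put_along_axis(dxp, self.arg[:, :, None, :], dy[:, :, None, :], axis=2)
        return dxp.reshape(B, L_out * self.pool, C)[:, : self.L, :]


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x, train):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self.shape)


class _Dropout:
    """Inverted dropout; active only during training."""

    def __init__(self, rate: float, rng):
        self.rate = rate
        self.rng = rng

    params: list = []
    grads: list = []

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (self.rng.random(x.shape) < keep) / keep
        return x * self.mask

    def backward(self, dy):
        return dy if self.mask is None else dy * self.mask


class _Dense:
    def __init__(self, d_in: int, units: int, activation: str, l2: float, rng):
        limit = math.sqrt(6.0 / (d_in + units))
        self.W = rng.uniform(-limit, limit, size=(d_in, units))
        self.b = np.zeros(units)
        self.activation = activation
        self.l2 = l2

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self.x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self.mask = z > 0
            return z * self.mask
        # sigmoid outputs are produced outside (loss works on logits)
        return z

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self.mask
        dW = self.x.T @ dy
        if self.l2 > 0:
            dW = dW + 2.0 * self.l2 * self.W
        db = dy.sum(axis=0)
        self.grads = [dW, db]
        return dy @ self.W.T


def _build_runtime(arch: ArchitectureSpec, rng: np.random.Generator):
    layers = []
    C = arch.input_channels
    L = arch.input_length
    flat = None
    for spec in arch.layers:
        if spec.kind == "conv":
            layers.append(_Conv1D(spec.kernel_size, C, spec.filters, spec.activation, rng))
            C = spec.filters
        elif spec.kind == "maxpool":
            layers.append(_MaxPool1D(spec.pool_size))
            L = math.ceil(L / spec.pool_size)
        elif spec.kind == "flatten":
            layers.append(_Flatten())
            flat = L * C
        elif spec.kind == "dropout":
            layers.append(_Dropout(spec.dropout_rate, rng))
        elif spec.kind == "dense":
            d_in = flat if flat is not None else L * C
            layers.append(_Dense(d_in, spec.units, spec.activation, spec.l2_coefficient, rng))
            flat = spec.units
    return layers


def _forward_logits(layers, x, train):
    h = x
    for layer in layers:
        h = layer.forward(h, train)
    return h[:, 0]  # final dense has one unit; sigmoid applied by caller


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_with_logits(z, y):
    # log(1 + exp(-|z|)) + max(z, 0) - z*y, numerically stable
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingConfig:
    """Optimization settings: Adam with its published default moments,
    binary cross-entropy loss, early stopping on validation loss."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 128
    max_epochs: int = 100
    early_stop_patience: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.early_stop_patience < 1:
            raise ValidationError("batch_size and patience must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainedModel:
    architecture: ArchitectureSpec
    weights: list[np.ndarray]
    training_log: list[dict]  # epoch, train_loss, val_loss
    config: TrainingConfig

    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights))


class _Adam:
    def __init__(self, params: list[np.ndarray], cfg: TrainingConfig):
        self.cfg = cfg
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]):
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1**self.t
        bc2 = 1.0 - c.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * g * g
            p -= c.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + c.epsilon)


def _collect_params(layers):
    params, owners = [], []
    for layer in layers:
        for p in layer.params:
            params.append(p)
            owners.append(layer)
    return params


def _eval_loss(layers, batch: EncodedBatch, chunk: int = 1024) -> float:
    losses, n = 0.0, len(batch)
    for s in range(0, n, chunk):
        x = batch.data[s : s + chunk].astype(np.float64)
        y = batch.labels[s : s + chunk].astype(np.float64)
        z = _forward_logits(layers, x, train=False)
        losses += _bce_with_logits(z, y) * len(y)
    return losses / n


def train(
    arch: ArchitectureSpec,
    train_set: EncodedBatch,
    validation_set: EncodedBatch,
    config: TrainingConfig | None = None,
) -> TrainedModel:
    """Fit the network with Adam and early stopping.

    Stops when validation loss has not improved for
    ``config.early_stop_patience`` consecutive epochs (or at
    ``max_epochs``), then restores the best-validation weights.  Adds the
    L2 penalty of the regularized dense layer to the optimized loss.
    """
    if config is None:
        config = TrainingConfig()
    if len(train_set) == 0 or len(validation_set) == 0:
        raise ValidationError("train and validation sets must be non-empty")
    for batch in (train_set, validation_set):
        if not np.isin(batch.labels, (0, 1)).all():
            raise ValidationError("labels must be binary")

    rng = np.random.default_rng(config.seed)
    layers = _build_runtime(arch, rng)
    params = _collect_params(layers)
    opt = _Adam(params, config)

    x_all = train_set.data.astype(np.float64)
    y_all = train_set.labels.astype(np.float64)
    n = len(train_set)

    best_val = np.inf
    best_weights = [p.copy() for p in params]
    best_epoch = -1
    log: list[dict] = []
    since_improved = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            x, y = x_all[idx], y_all[idx]
            z = _forward_logits(layers, x, train=True)
            loss = _bce_with_logits(z, y)
            if not np.isfinite(loss):
                raise ChimeranetError(
                    f"non-finite training loss at epoch {epoch}; aborting"
                )
            epoch_loss += loss * len(y)
            dz = (_sigmoid(z) - y)[:, None] / len(y)
            grad = dz
            for layer in reversed(layers):
                grad = layer.backward(grad)
            grads = []
            for layer in layers:
                if layer.params:
                    grads.extend(layer.grads)
            opt.step(params, grads)
        train_loss = epoch_loss / n
        val_loss = _eval_loss(layers, validation_set)
        log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = [p.copy() for p in params]
            best_epoch = epoch
            since_improved = 0
        else:
            since_improved += 1
            if since_improved >= config.early_stop_patience:
                break

    for p, w in zip(params, best_weights):
        p[...] = w
    return TrainedModel(
        architecture=arch,
        weights=[w.copy() for w in best_weights],
        training_log=log,
        config=config,
    )


# ---------------------------------------------------------------------------
# inference and persistence


def _runtime_with_weights(model: TrainedModel):
    layers = _build_runtime(model.architecture, np.random.default_rng(0))
    params = _collect_params(layers)
    if len(params) != len(model.weights):
        raise ValidationError("weight list does not match architecture")
    for p, w in zip(params, model.weights):
        if p.shape != w.shape:
            raise ValidationError(f"weight shape {w.shape} != expected {p.shape}")
        p[...] = w
    return layers


def predict(model: TrainedModel, batch: EncodedBatch | np.ndarray) -> np.ndarray:
    """Per-chimera interaction probabilities, in input order."""
    data = batch.data if isinstance(batch, EncodedBatch) else np.asarray(batch)
    if data.ndim != 3 or data.shape[1:] != (
        model.architecture.input_length,
        model.architecture.input_channels,
    ):
        raise ValidationError(f"bad input shape {data.shape}")
    layers = _runtime_with_weights(model)
    out = []
    for s in range(0, len(data), 1024):
        z = _forward_logits(layers, data[s : s + 1024].astype(np.float64), train=False)
        out.append(_sigmoid(z))
    return np.concatenate(out) if out else np.empty(0)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a model artifact directory: architecture + config manifest
    (JSON), weights blob (NPZ), and the per-epoch training log (TSV)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "chimeranet-model-v1",
        "architecture": model.architecture.to_dict(),
        "config": model.config.to_dict(),
        "n_parameters": model.n_parameters(),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    np.savez(
        path / "weights.npz",
        **{f"w{i}": w for i, w in enumerate(model.weights)},
    )
    with open(path / "training_log.tsv", "w") as fh:
        fh.write("epoch\ttrain_loss\tval_loss\n")
        for row in model.training_log:
            fh.write(f"{row['epoch']}\t{row['train_loss']:.10g}\t{row['val_loss']:.10g}\n")


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
        arch = ArchitectureSpec.from_dict(manifest["architecture"])
        config = TrainingConfig(**manifest["config"])
        with np.load(path / "weights.npz") as npz:
            weights = [npz[f"w{i}"] for i in range(len(npz.files))]
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise ChimeranetError(f"cannot load model from {path}: {exc}") from exc
    log = []
    log_path = path / "training_log.tsv"
    if log_path.exists():
        for line in log_path.read_text().splitlines()[1:]:
            e, tl, vl = line.split("\t")
            log.append({"epoch": int(e), "train_loss": float(tl), "val_loss": float(vl)})
    model = TrainedModel(arch, weights, log, config)
    expected = count_parameters(arch)[1]
    if model.n_parameters() != expected:
        raise ChimeranetError(
            f"artifact has {model.n_parameters()} parameters, expected {expected}"
        )
    return model
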