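"""Declarative route architectures, symbolic tracing, and training harness.

The three routes are fixed convolutional architectures over the subband
features:

* ``conv1d_energy`` — 1D CNN on the per-subject energy vector,
* ``conv2d_fused`` — 2D CNN on the mean-fused CH subband image,
* ``conv3d_volume`` — 3D CNN on the CV subband volume.

Each is described as an ordered list of :class:`LayerSpec`; output shapes
and parameter counts are derived symbolically (valid convolutions, stride 1:
``out = in - k + 1``; pooling: ``out = floor(in / p)``) so the reference
tables can be checked without building or training anything.  At the
reference input sizes — (88, 1), (128, 128, 1) and (88, 128, 128, 1) — the
traces give flatten widths 1280 / 25088 / 193536 and totals 88,385 /
3,305,089 (448 non-trainable) / 24,957,985.

For smaller inputs (the scaled test profile) the same layer pattern is laid
down and, for the 3D route, trailing conv/pool blocks that would drive a
spatial dimension non-positive are dropped.

Hidden activations are ReLU; the single output unit is sigmoid (a softmax
over one logit is degenerate, so the binary head is a sigmoid throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "TrainConfig",
    "ParamCount",
    "MODEL_KINDS",
    "REFERENCE_INPUT_SHAPES",
    "model_spec",
    "shape_trace",
    "parameter_count",
    "build_network",
    "train",
    "classify",
    "kfold_evaluate",
    "architecture_report",
]

MODEL_KINDS = ("conv1d_energy", "conv2d_fused", "conv3d_volume")

#: Channels-last input shapes of the reference (full-size) architectures.
REFERENCE_INPUT_SHAPES = {
    "conv1d_energy": (88, 1),
    "conv2d_fused": (128, 128, 1),
    "conv3d_volume": (88, 128, 128, 1),
}


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv1d/2d/3d, maxpool1d/2d/3d, batchnorm, flatten, dense, dropout
    kernel: tuple[int, ...] | None = None
    filters: int | None = None
    units: int | None = None
    activation: str = "none"
    rate: float | None = None

    def __post_init__(self) -> None:
        if self.kernel is not None and any(k < 1 for k in self.kernel):
            raise ValueError("kernel entries must be positive")
        if self.rate is not None and not 0.0 <= self.rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    name: str
    input_shape: tuple[int, ...]
    layers: tuple[LayerSpec, ...]


@dataclass(frozen=True)
class TrainConfig:
    """Reference training protocol: Adam, lr 0.001, 20 epochs, batch 32,
    5-fold cross-validation, decision threshold 0.5."""

    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 32
    k_folds: int = 5
    seed: int = 0
    threshold: float = 0.5
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")


@dataclass(frozen=True)
class ParamCount:
    total: int
    trainable: int
    non_trainable: int

    def __post_init__(self) -> None:
        if self.total != self.trainable + self.non_trainable:
            raise ValueError("total must equal trainable + non_trainable")


def _conv_block_fits(spatial: tuple[int, ...], kernel: tuple[int, ...], pool: tuple[int, ...]) -> bool:
    after_conv = tuple(n - k + 1 for n, k in zip(spatial, kernel))
    if any(n < 1 for n in after_conv):
        return False
    after_pool = tuple(n // p for n, p in zip(after_conv, pool))
    return all(n >= 1 for n in after_pool)


def model_spec(kind: str, input_shape: tuple[int, ...] | None = None) -> ModelSpec:
    """Build the layer list of one route, at the reference input size by
    default or at a caller-supplied (scaled) input size."""
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    shape = tuple(input_shape) if input_shape is not None else REFERENCE_INPUT_SHAPES[kind]
    layers: list[LayerSpec] = []
    if kind == "conv1d_energy":
        if len(shape) != 2:
            raise ValueError(f"conv1d_energy expects (length, channels), got {shape}")
        layers += [
            LayerSpec("conv1d", kernel=(3,), filters=32, activation="relu"),
            LayerSpec("maxpool1d", kernel=(2,)),
            LayerSpec("conv1d", kernel=(3,), filters=64, activation="relu"),
            LayerSpec("maxpool1d", kernel=(2,)),
            LayerSpec("flatten"),
            LayerSpec("dense", units=64, activation="relu"),
            LayerSpec("dense", units=1, activation="sigmoid"),
        ]
    elif kind == "conv2d_fused":
        if len(shape) != 3:
            raise ValueError(f"conv2d_fused expects (H, W, channels), got {shape}")
        for f in (32, 64, 128):
            layers += [
                LayerSpec("conv2d", kernel=(3, 3), filters=f, activation="relu"),
                LayerSpec("batchnorm"),
                LayerSpec("maxpool2d", kernel=(2, 2)),
            ]
        layers += [
            LayerSpec("flatten"),
            LayerSpec("dense", units=128, activation="relu"),
            LayerSpec("dropout", rate=0.2),
            LayerSpec("dense", units=1, activation="sigmoid"),
        ]
    else:  # conv3d_volume
        if len(shape) != 4:
            raise ValueError(f"conv3d_volume expects (D, H, W, channels), got {shape}")
        spatial = shape[:-1]
        kernel, pool = (2, 3, 3), (1, 2, 2)
        for f in (32, 64, 64, 64):
            # Scaled inputs may not admit all four blocks; keep the prefix
            # that preserves positive spatial dimensions.
            if not _conv_block_fits(spatial, kernel, pool):
                break
            layers += [
                LayerSpec("conv3d", kernel=kernel, filters=f, activation="relu"),
                LayerSpec("maxpool3d", kernel=pool),
            ]
            spatial = tuple((n - k + 1) // p for n, k, p in zip(spatial, kernel, pool))
        layers += [
            LayerSpec("flatten"),
            LayerSpec("dense", units=128, activation="relu"),
            LayerSpec("dense", units=1, activation="sigmoid"),
        ]
    spec = ModelSpec(name=kind, input_shape=shape, layers=tuple(layers))
    shape_trace(spec)  # validate
    return spec


def shape_trace(spec: ModelSpec) -> list[tuple[int, ...]]:
    """Output shape after each layer (channels-last, batch axis omitted)."""
    shape = spec.input_shape
    trace: list[tuple[int, ...]] = []
    for layer in spec.layers:
        if layer.kind.startswith("conv"):
            spatial = tuple(n - k + 1 for n, k in zip(shape[:-1], layer.kernel))
            if any(n < 1 for n in spatial):
                raise ValueError(
                    f"{spec.name}: non-positive dimension after {layer.kind} on {shape}"
                )
            shape = spatial + (layer.filters,)
        elif layer.kind.startswith("maxpool"):
            spatial = tuple(n // p for n, p in zip(shape[:-1], layer.kernel))
            if any(n < 1 for n in spatial):
                raise ValueError(
                    f"{spec.name}: non-positive dimension after {layer.kind} on {shape}"
                )
            shape = spatial + (shape[-1],)
        elif layer.kind == "batchnorm" or layer.kind == "dropout":
            pass
        elif layer.kind == "flatten":
            shape = (int(np.prod(shape)),)
        elif layer.kind == "dense":
            shape = (layer.units,)
        else:
            raise ValueError(f"unknown layer kind {layer.kind!r}")
        trace.append(shape)
    return trace


def parameter_count(spec: ModelSpec) -> ParamCount:
    """Exact parameter bookkeeping of a spec.

    conv: prod(kernel) * c_in * c_out + c_out; dense: n_in * n_out + n_out;
    batchnorm: 4 per channel, half trainable (scale/shift) and half not
    (running moments); pooling/flatten/dropout: none.
    """
    shape = spec.input_shape
    trainable = 0
    non_trainable = 0
    for layer in spec.layers:
        if layer.kind.startswith("conv"):
            c_in = shape[-1]
            trainable += int(np.prod(layer.kernel)) * c_in * layer.filters + layer.filters
            shape = tuple(n - k + 1 for n, k in zip(shape[:-1], layer.kernel)) + (layer.filters,)
        elif layer.kind.startswith("maxpool"):
            shape = tuple(n // p for n, p in zip(shape[:-1], layer.kernel)) + (shape[-1],)
        elif layer.kind == "batchnorm":
            trainable += 2 * shape[-1]
            non_trainable += 2 * shape[-1]
        elif layer.kind == "flatten":
            shape = (int(np.prod(shape)),)
        elif layer.kind == "dense":
            trainable += shape[0] * layer.units + layer.units
            shape = (layer.units,)
    return ParamCount(
        total=trainable + non_trainable, trainable=trainable, non_trainable=non_trainable
    )


def build_network(spec: ModelSpec, seed: int = 0) -> nn.Network:
    """Instantiate a trainable network from a spec.

    The final sigmoid is fused with the loss inside the engine, so the last
    dense layer is built with a linear output.
    """
    shape = spec.input_shape
    layers: list[nn.Layer] = []
    for i, layer in enumerate(spec.layers):
        last = i == len(spec.layers) - 1
        if layer.kind.startswith("conv"):
            layers.append(nn.Conv(layer.kernel, shape[-1], layer.filters, activation="relu"))
            shape = tuple(n - k + 1 for n, k in zip(shape[:-1], layer.kernel)) + (layer.filters,)
        elif layer.kind.startswith("maxpool"):
            layers.append(nn.MaxPool(layer.kernel))
            shape = tuple(n // p for n, p in zip(shape[:-1], layer.kernel)) + (shape[-1],)
        elif layer.kind == "batchnorm":
            layers.append(nn.BatchNorm(shape[-1]))
        elif layer.kind == "dropout":
            layers.append(nn.Dropout(layer.rate))
        elif layer.kind == "flatten":
            layers.append(nn.Flatten())
            shape = (int(np.prod(shape)),)
        elif layer.kind == "dense":
            act = "none" if last else "relu"
            layers.append(nn.Dense(shape[0], layer.units, activation=act))
            shape = (layer.units,)
    return nn.Network(layers, seed=seed)


def _check_features(spec: ModelSpec, x: np.ndarray) -> None:
    if tuple(x.shape[1:]) != tuple(spec.input_shape):
        raise ValueError(
            f"feature shape {tuple(x.shape[1:])} does not match spec input {spec.input_shape}"
        )


def train(
    spec: ModelSpec,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    epochs: int | None = None,
) -> tuple[nn.Network, dict[str, list[float]]]:
    """Train one route deterministically under ``cfg.seed``.

    With ``validation_fraction > 0`` a stratified validation split is held
    out and the best-validation-loss epoch is checkpointed and restored.
    """
    x = np.asarray(x)
    y = np.asarray(y).ravel()
    _check_features(spec, x)
    net = build_network(spec, seed=cfg.seed)
    n_epochs = cfg.epochs if epochs is None else epochs
    x_val = y_val = None
    if cfg.validation_fraction > 0 and n_epochs > 0:
        x, x_val, y, y_val = train_test_split(
            x, y, test_size=cfg.validation_fraction, stratify=y, random_state=cfg.seed
        )
    history = net.fit(
        x,
        y,
        epochs=n_epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        x_val=x_val,
        y_val=y_val,
    )
    return net, history


def classify(
    model: nn.Network, x: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and probabilities; label 1 iff probability >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly in (0, 1)")
    probs = model.predict_proba(np.asarray(x))
    return (probs >= threshold).astype(int), probs


def kfold_evaluate(
    x: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    cfg: TrainConfig,
    seeds: list[int],
):
    """Stratified k-fold accuracy across seeds.

    Returns ``(folds, summary)`` pandas DataFrames: one row per (seed, fold)
    with its held-out accuracy, and per-seed mean/SD.  Fold assignment and
    training are fully determined by each seed.
    """
    import pandas as pd

    x = np.asarray(x)
    y = np.asarray(y).ravel()
    if not seeds:
        raise ValueError("seeds must be non-empty")
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < cfg.k_folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects, fewer than k_folds={cfg.k_folds}"
        )
    rows = []
    for seed in seeds:
        skf = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True, random_state=seed)
        for fold, (tr, te) in enumerate(skf.split(x, y)):
            fold_cfg = replace(cfg, seed=seed)
            net, _ = train(spec, x[tr], y[tr], fold_cfg)
            pred, _ = classify(net, x[te], threshold=cfg.threshold)
            rows.append(
                {"seed": seed, "fold": fold, "accuracy": float((pred == y[te]).mean())}
            )
    folds = pd.DataFrame(rows)
    summary = (
        folds.groupby("seed")["accuracy"].agg(mean_accuracy="mean", sd="std").reset_index()
    )
    return folds, summary


def architecture_report(input_shapes: dict[str, tuple[int, ...]] | None = None) -> dict:
    """Shape traces and parameter counts of all three routes, as plain data."""
    report = {}
    for kind in MODEL_KINDS:
        shape = None if input_shapes is None else input_shapes.get(kind)
        spec = model_spec(kind, input_shape=shape)
        counts = parameter_count(spec)
        report[kind] = {
            "input_shape": list(spec.input_shape),
            "layers": [layer.kind for layer in spec.layers],
            "shape_trace": [list(s) for s in shape_trace(spec)],
            "total_params": counts.total,
            "trainable_params": counts.trainable,
            "non_trainable_params": counts.non_trainable,
        }
    return report
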