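"""Age predictors: MLPs on feature tables, 3-D CNNs on volumes.

Two model families estimate chronological age:

* MLPs on hand-crafted features (223 T1 morphometry columns, or 24 artery
  features + total brain volume), with one to four hidden layers drawn from
  fixed candidate grids and z-scored inputs (scaler fitted on the training
  fold only).
* A compact fully-convolutional CNN on 3-D volumes: four blocks of
  [3x3x3 conv, batch-norm, 2x2x2 max-pool, ReLU] with 32/64/128/256 filters,
  a 1x1x1 conv block with 64 filters, then global average pooling, dropout
  0.5 and a linear output.

Training minimizes mean squared error with Adam, evaluates the validation
loss after every epoch and returns the parameters of the epoch with the
lowest validation loss (not the final epoch).  Volumetric training optionally
augments a random fraction of each batch with small rigid perturbations
(default +/- 5 degree rotations, +/- 10 voxel integer translations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn import (
    Adam, BatchNorm, Conv3D, Dense, Dropout, GlobalAvgPool, MaxPool3D,
    ReLU, Sequential, mse_loss,
)

__all__ = [
    "MLPSpec", "CNNSpec", "TrainConfig",
    "MLP_T1_GRID", "MLP_TOF_GRID",
    "mlp_train_config", "cnn_train_config",
    "build_mlp", "build_cnn", "augment_volume",
    "train", "predict", "select_mlp_architecture",
    "TabularPredictor", "VolumePredictor",
]

#: Candidate hidden-layer grids (one to four hidden layers).
MLP_T1_GRID = ((256,), (256, 128), (256, 128, 64), (256, 128, 64, 32))
MLP_TOF_GRID = ((32,), (16, 32), (8, 16, 32), (4, 8, 16, 32))


@dataclass(frozen=True)
class MLPSpec:
    """Hidden-layer sizes; output is always a single linear unit."""

    hidden: tuple[int, ...] = (256, 128)

    def __post_init__(self) -> None:
        if len(self.hidden) < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("MLP needs at least one hidden layer of positive width")


@dataclass(frozen=True)
class CNNSpec:
    """Four conv blocks with the given filter counts, a 1x1x1 conv head and
    a dropout + dense output block."""

    filters: tuple[int, int, int, int] = (32, 64, 128, 256)
    head_filters: int = 64
    dropout: float = 0.5


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol.  Defaults are set by the two factory functions:
    MLPs use lr 0.1, batch 200, 1000 epochs; CNNs use lr 0.001, batch 8,
    200 epochs with augmentation of half of each batch."""

    lr: float = 0.001
    batch_size: int = 8
    epochs: int = 200
    augment_fraction: float = 0.5
    rotation_deg: float = 5.0
    translate_vox: int = 10
    seed: int = 0
    optimizer: str = "adam"
    loss: str = "mse"
    #: train against mean-centered ages (offset restored at inference); with
    #: raw targets around 50 years Adam's fixed-magnitude steps cannot move
    #: the output head far enough at any usable learning rate
    center_target: bool = True

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("lr, batch_size and epochs must be positive")
        if not 0.0 <= self.augment_fraction <= 1.0:
            raise ValueError("augment_fraction must be in [0, 1]")


def mlp_train_config(**overrides) -> TrainConfig:
    cfg = TrainConfig(lr=0.1, batch_size=200, epochs=1000, augment_fraction=0.0)
    return replace(cfg, **overrides)


def cnn_train_config(**overrides) -> TrainConfig:
    return replace(TrainConfig(), **overrides)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_mlp(n_inputs: int, spec: MLPSpec = MLPSpec(), seed: int = 0,
              dtype=np.float32) -> Sequential:
    """Fully-connected regressor ``n_inputs -> hidden... -> 1`` (ReLU)."""
    rng = np.random.default_rng(seed)
    layers, width = [], n_inputs
    for h in spec.hidden:
        layers += [Dense(width, h, rng, dtype=dtype), ReLU()]
        width = h
    layers.append(Dense(width, 1, rng, dtype=dtype))
    return Sequential(layers)


def build_cnn(input_shape: tuple[int, int, int], spec: CNNSpec = CNNSpec(),
              seed: int = 0, dtype=np.float32) -> Sequential:
    """Volumetric age regressor; input must survive the four 2x pools."""
    if min(input_shape) // 16 < 1:
        raise ValueError(
            f"input shape {input_shape} too small: each axis must be >= 16 "
            "so that four 2x2x2 poolings keep a nonzero spatial extent"
        )
    rng = np.random.default_rng(seed)
    layers: list = []
    c_in = 1
    for f in spec.filters:
        layers += [Conv3D(c_in, f, 3, rng, dtype=dtype), BatchNorm(f, dtype=dtype),
                   MaxPool3D(), ReLU()]
        c_in = f
    layers += [Conv3D(c_in, spec.head_filters, 1, rng, dtype=dtype),
               BatchNorm(spec.head_filters, dtype=dtype), ReLU()]
    layers += [GlobalAvgPool(), Dropout(spec.dropout),
               Dense(spec.head_filters, 1, rng, dtype=dtype)]
    return Sequential(layers)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment_volume(vol: np.ndarray, rng: np.random.Generator,
                   rotation_deg: float = 5.0, translate_vox: int = 10) -> np.ndarray:
    """One random rigid perturbation: per-axis rotation angles drawn uniform
    in +/- ``rotation_deg`` and per-axis integer translations uniform in
    +/- ``translate_vox``, resampled with linear interpolation in a single
    affine pass.  Out-of-field voxels take the median corner intensity of the
    input (the phantom background)."""
    angles = np.deg2rad(rng.uniform(-rotation_deg, rotation_deg, size=3))
    t = rng.integers(-translate_vox, translate_vox + 1, size=3).astype(float)
    rots = []
    for ax, ang in enumerate(angles):
        c, s = np.cos(ang), np.sin(ang)
        r = np.eye(3)
        i, j = [k for k in range(3) if k != ax]
        r[i, i] = c; r[i, j] = -s; r[j, i] = s; r[j, j] = c
        rots.append(r)
    R = rots[2] @ rots[1] @ rots[0]
    center = (np.asarray(vol.shape) - 1) / 2.0
    # output[o] = input[R.T @ (o - t - center) + center]
    A = R.T
    offset = center - A @ (center + t)
    corners = vol[np.ix_((0, -1), (0, -1), (0, -1))]
    return ndimage.affine_transform(vol, A, offset=offset, order=1,
                                    cval=float(np.median(corners)))


# ---------------------------------------------------------------------------
# Training / inference
# ---------------------------------------------------------------------------

def predict(net: Sequential, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Deterministic inference (dropout off, batch-norm running stats)."""
    out = [net.predict(X[i:i + batch_size]) for i in range(0, len(X), batch_size)]
    return np.concatenate(out)


def train(
    net: Sequential,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    volumetric: bool = False,
) -> pd.DataFrame:
    """Minimize MSE with Adam; keep the epoch checkpoint with the lowest
    validation loss.

    The network is mutated in place and ends up holding the best-validation
    parameters.  Returns the per-epoch history (``epoch, train_loss,
    val_loss``).  Volumetric inputs are ``(n, D, H, W)`` and get a channel
    axis appended; a random ``augment_fraction`` of each batch is augmented.
    Raises ``RuntimeError`` if the loss turns non-finite.
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(net, lr=config.lr)
    n = len(X_train)
    offset = float(np.mean(y_train)) if config.center_target else 0.0
    net.output_offset = offset
    y_train = np.asarray(y_train, float) - offset
    best_val = np.inf
    best_state = None
    history = []
    Xv = X_val[..., None] if volumetric else X_val
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = X_train[idx]
            if volumetric:
                if config.augment_fraction > 0.0:
                    xb = xb.copy()
                    for i in range(len(xb)):
                        if rng.random() < config.augment_fraction:
                            xb[i] = augment_volume(
                                xb[i], rng, config.rotation_deg, config.translate_vox
                            )
                xb = xb[..., None]
            pred = net.forward(xb, training=True, rng=rng)
            loss, gout = mse_loss(pred, y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}; "
                    "reduce the learning rate or check the inputs"
                )
            net.backward(gout)
            opt.step()
            epoch_losses.append(loss)
        val_pred = predict(net, Xv)
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.append((epoch, float(np.mean(epoch_losses)), val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.get_state()
    net.set_state(best_state)
    return pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss"])


def select_mlp_architecture(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    grid=MLP_T1_GRID,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[MLPSpec, Sequential]:
    """Train one MLP per candidate architecture and keep the one with the
    lowest validation MAE."""
    config = config or mlp_train_config()
    best = (np.inf, None, None)
    for hidden in grid:
        spec = MLPSpec(tuple(hidden))
        net = build_mlp(X_train.shape[1], spec, seed=seed)
        train(net, X_train, y_train, X_val, y_val, config)
        mae = float(np.mean(np.abs(predict(net, X_val) - y_val)))
        if mae < best[0]:
            best = (mae, spec, net)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Wrappers binding nets to their input schema
# ---------------------------------------------------------------------------

@dataclass
class TabularPredictor:
    """An MLP plus the feature schema and the z-scoring fitted on its
    training fold.  Rejects tables that do not carry the full schema."""

    net: Sequential
    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit_scaler(cls, net: Sequential, table: pd.DataFrame,
                   feature_names: list[str]) -> "TabularPredictor":
        X = table[feature_names].to_numpy(float)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return cls(net, list(feature_names), X.mean(axis=0), sd)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")
        X = table[self.feature_names].to_numpy(float)
        return ((X - self.mean) / self.sd).astype(np.float32)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return predict(self.net, self.transform(table))


@dataclass
class VolumePredictor:
    """A CNN plus the deterministic input reduction applied before it
    (integer down-sampling by striding and per-volume z-scoring)."""

    net: Sequential
    downsample: int = 1

    def transform(self, volumes: np.ndarray) -> np.ndarray:
        v = volumes[:, ::self.downsample, ::self.downsample, ::self.downsample]
        v = np.asarray(v, np.float32)
        mu = v.mean(axis=(1, 2, 3), keepdims=True)
        sd = v.std(axis=(1, 2, 3), keepdims=True)
        sd[sd == 0] = 1.0
        return (v - mu) / sd

    def predict(self, volumes: np.ndarray) -> np.ndarray:
        return predict(self.net, self.transform(volumes)[..., None])
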