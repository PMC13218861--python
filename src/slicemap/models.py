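"""Classifier families and training.

Three architectures share one block vocabulary:

* slice-specific 2D CNN — three conv blocks (3x3 kernels, channels
  8/16/32, optional batch norm, ReLU, 2x2 max pool), flatten,
  FC-128 -> layer norm -> ReLU -> dropout(0.5) -> linear(1 logit);
* lightweight 3D patch CNN — the direct 3D analogue (3x3x3 kernels,
  2x2x2 pooling) for cubic patches;
* three-slice fusion model — three unshared 2D trunks whose flattened
  features are concatenated into a shared FC head.

Training uses AdamW on binary cross-entropy with logits, optional step
learning-rate decay, per-epoch checkpointing, and selection of the
checkpoint with the lowest validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import nn
from .exceptions import ParameterError
from .metrics import accuracy, confusion, mcc, precision

__all__ = [
    "Cnn2dSpec",
    "TrainConfig",
    "TrainResult",
    "PredictionSet",
    "NeuralClassifier",
    "FusionClassifier",
    "build_cnn2d",
    "build_cnn3d_patch",
    "build_fusion",
    "train_model",
    "run_hyperparameter_search",
]


@dataclass(frozen=True)
class Cnn2dSpec:
    conv_blocks: int = 3
    kernel: int = 3
    channels: tuple[int, ...] = (8, 16, 32)
    pool: int = 2
    use_batch_norm: bool = True
    fc_hidden: int = 128
    dropout_rate: float = 0.5

    def __post_init__(self):
        if len(self.channels) != self.conv_blocks:
            raise ParameterError("one channel width per conv block required")
        if any(b >= a for a, b in zip(self.channels[1:], self.channels)):
            raise ParameterError("channel widths must be strictly increasing")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 5e-5
    batch_size: int = 64
    max_epochs: int = 200
    weight_decay: float = 0.1
    scheduler_step: int | None = 10  # None = fixed learning rate
    scheduler_gamma: float = 0.5
    seed: int = 0
    n_repeats: int = 10

    def __post_init__(self):
        if self.lr <= 0:
            raise ParameterError("lr must be positive")
        if self.max_epochs < 1:
            raise ParameterError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")


@dataclass
class PredictionSet:
    """Per-sample logits/probabilities/labels of one evaluated split."""

    subject_ids: list[str]
    logits: np.ndarray
    probabilities: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.logits = np.asarray(self.logits, dtype=float)
        self.probabilities = np.clip(np.asarray(self.probabilities, dtype=float),
                                     1e-12, 1 - 1e-12)
        self.labels = np.asarray(self.labels)

    @property
    def predicted_labels(self) -> np.ndarray:
        return (self.logits > 0).astype(int)

    def metrics(self) -> dict[str, float]:
        c = confusion(self.predicted_labels, self.labels)
        return {"mcc": mcc(c), "accuracy": accuracy(c), "precision": precision(c)}


@dataclass
class TrainResult:
    best_epoch: int
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss, lr
    test_predictions: PredictionSet | None
    seed: int


def _pooled_extent(extent: int, pools: int, factor: int = 2) -> int:
    for _ in range(pools):
        extent //= factor
    return extent


class NeuralClassifier:
    """A single-input sequential network emitting one logit per sample.

    Input samples are channel-less spatial grids; a trailing channel axis
    is added internally.
    """

    def __init__(self, net: nn.Sequential, input_shape: tuple[int, ...]):
        self.net = net
        self.input_shape = tuple(input_shape)

    # -- training interface -------------------------------------------------
    def forward_train(self, x: np.ndarray) -> np.ndarray:
        out = self.net.forward(self._with_channel(x), training=True)
        return out[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        self.net.backward(dlogits[:, None].astype(np.float32))

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def zero_grad(self) -> None:
        self.net.zero_grad()

    def state_dict(self) -> dict:
        return self.net.state_dict()

    def load_state_dict(self, state: dict) -> None:
        self.net.load_state_dict(state)

    # -- inference ----------------------------------------------------------
    def predict_logits(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        images = np.asarray(images, dtype=np.float32)
        if images.shape[1:] != self.input_shape:
            raise ParameterError(
                f"expected samples of shape {self.input_shape}, got {images.shape[1:]}")
        out = np.empty(len(images), dtype=np.float64)
        for start in range(0, len(images), batch_size):
            batch = self._with_channel(images[start:start + batch_size])
            out[start:start + len(batch)] = self.net.forward(batch, training=False)[:, 0]
        return out

    @staticmethod
    def _with_channel(x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=np.float32)[..., None]


def _conv_trunk(spec: Cnn2dSpec, ndim: int, rng: np.random.Generator) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    in_ch = 1
    for ch in spec.channels:
        layers.append(nn.Conv(in_ch, ch, kernel=spec.kernel, ndim=ndim, rng=rng))
        if spec.use_batch_norm:
            layers.append(nn.BatchNorm(ch))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool(ndim=ndim, factor=spec.pool))
        in_ch = ch
    return layers


def _head(spec: Cnn2dSpec, flat_features: int, rng: np.random.Generator) -> list[nn.Layer]:
    return [
        nn.Linear(flat_features, spec.fc_hidden, rng=rng),
        nn.LayerNorm(spec.fc_hidden),
        nn.ReLU(),
        nn.Dropout(spec.dropout_rate, rng=rng),
        nn.Linear(spec.fc_hidden, 1, rng=rng),
    ]


def _flat_features(input_shape: Sequence[int], spec: Cnn2dSpec) -> int:
    sides = [_pooled_extent(s, spec.conv_blocks, spec.pool) for s in input_shape]
    if any(s < 1 for s in sides):
        raise ParameterError(
            f"input shape {tuple(input_shape)} collapses below 1 after "
            f"{spec.conv_blocks} {spec.pool}x poolings")
    return int(np.prod(sides)) * spec.channels[-1]


def build_cnn2d(spec: Cnn2dSpec | None = None, input_shape: tuple[int, int] = (64, 64),
                seed: int = 0) -> NeuralClassifier:
    """Slice-specific 2D CNN; identical seeds yield identical parameters."""
    spec = spec or Cnn2dSpec()
    if len(input_shape) != 2:
        raise ParameterError("input_shape must be 2D")
    rng = np.random.default_rng(seed)
    flat = _flat_features(input_shape, spec)
    layers = _conv_trunk(spec, 2, rng) + [nn.Flatten()] + _head(spec, flat, rng)
    return NeuralClassifier(nn.Sequential(layers), input_shape)


def build_cnn3d_patch(input_shape: tuple[int, int, int] = (24, 24, 24),
                      spec: Cnn2dSpec | None = None, seed: int = 0) -> NeuralClassifier:
    """Lightweight 3D patch CNN (3D analogue of the 2D architecture)."""
    spec = spec or Cnn2dSpec()
    if len(input_shape) != 3:
        raise ParameterError("input_shape must be 3D")
    if min(input_shape) < 16:
        raise ParameterError("patch sides must be >= 16 voxels")
    rng = np.random.default_rng(seed)
    flat = _flat_features(input_shape, spec)
    layers = _conv_trunk(spec, 3, rng) + [nn.Flatten()] + _head(spec, flat, rng)
    return NeuralClassifier(nn.Sequential(layers), input_shape)


class FusionClassifier:
    """Three unshared 2D conv trunks -> concatenated features -> shared head."""

    def __init__(self, trunks: list[nn.Sequential], head: nn.Sequential,
                 input_shapes: list[tuple[int, int]]):
        self.trunks = trunks
        self.head = head
        self.input_shapes = [tuple(s) for s in input_shapes]
        self._feat_sizes: list[int] | None = None

    def forward_train(self, xs: Sequence[np.ndarray]) -> np.ndarray:
        feats = [t.forward(NeuralClassifier._with_channel(x), training=True)
                 for t, x in zip(self.trunks, xs)]
        self._feat_sizes = [f.shape[1] for f in feats]
        return self.head.forward(np.concatenate(feats, axis=1), training=True)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        gcat = self.head.backward(dlogits[:, None].astype(np.float32))
        offset = 0
        for trunk, size in zip(self.trunks, self._feat_sizes):
            trunk.backward(gcat[:, offset:offset + size])
            offset += size

    def params(self) -> list[nn.Param]:
        out = []
        for t in self.trunks:
            out.extend(t.params())
        out.extend(self.head.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_dict(self) -> dict:
        return {"trunks": [t.state_dict() for t in self.trunks],
                "head": self.head.state_dict()}

    def load_state_dict(self, state: dict) -> None:
        for t, s in zip(self.trunks, state["trunks"]):
            t.load_state_dict(s)
        self.head.load_state_dict(state["head"])

    def predict_logits(self, xs: Sequence[np.ndarray], batch_size: int = 256) -> np.ndarray:
        n = len(xs[0])
        out = np.empty(n, dtype=np.float64)
        for start in range(0, n, batch_size):
            feats = [t.forward(NeuralClassifier._with_channel(x[start:start + batch_size]),
                               training=False) for t, x in zip(self.trunks, xs)]
            out[start:start + feats[0].shape[0]] = \
                self.head.forward(np.concatenate(feats, axis=1), training=False)[:, 0]
        return out


def build_fusion(input_shapes: Sequence[tuple[int, int]], spec: Cnn2dSpec | None = None,
                 seed: int = 0) -> FusionClassifier:
    """Joint classifier over the three best-performing slices."""
    spec = spec or Cnn2dSpec()
    if len(input_shapes) != 3:
        raise ParameterError("fusion model requires exactly three slice shapes")
    rng = np.random.default_rng(seed)
    trunks = []
    flat_sizes = []
    for shape in input_shapes:
        flat_sizes.append(_flat_features(shape, spec))
        trunks.append(nn.Sequential(_conv_trunk(spec, 2, rng) + [nn.Flatten()]))
    head = nn.Sequential(_head(spec, sum(flat_sizes), rng))
    return FusionClassifier(trunks, head, list(input_shapes))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _as_xy(data) -> tuple[np.ndarray | list[np.ndarray], np.ndarray, list[str]]:
    """Accept SliceDataset-likes, (X, y) or (X, y, ids) tuples."""
    if hasattr(data, "images"):
        return (np.asarray(data.images, dtype=np.float32),
                np.asarray(data.labels), list(data.subject_ids))
    x, y = data[0], data[1]
    ids = list(data[2]) if len(data) > 2 else [f"s{i}" for i in range(len(y))]
    if isinstance(x, (list, tuple)):
        x = [np.asarray(xi, dtype=np.float32) for xi in x]
    else:
        x = np.asarray(x, dtype=np.float32)
    return x, np.asarray(y), ids


def _take(x, idx):
    if isinstance(x, list):
        return [xi[idx] for xi in x]
    return x[idx]


def _n_samples(x) -> int:
    return len(x[0]) if isinstance(x, list) else len(x)


def _eval_loss(model, x, y, batch_size: int) -> float:
    logits = model.predict_logits(x, batch_size=batch_size)
    loss, _ = nn.bce_with_logits(logits, y)
    return loss


def train_model(model, train_data, val_data, test_data, cfg: TrainConfig) -> TrainResult:
    """Train with AdamW + BCE, keep the lowest-validation-loss checkpoint.

    The test split is only touched once, after training, with the best
    checkpoint restored.
    """
    x_tr, y_tr, _ = _as_xy(train_data)
    x_va, y_va, _ = _as_xy(val_data)
    n_tr = _n_samples(x_tr)
    if n_tr == 0 or _n_samples(x_va) == 0:
        raise ParameterError("train and validation sets must be nonempty")
    if len(np.unique(y_tr)) < 2:
        raise ParameterError("training set must contain both classes")

    opt = nn.AdamW(model.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = nn.StepLR(cfg.lr, cfg.scheduler_step, cfg.scheduler_gamma)
    rng = np.random.default_rng(cfg.seed)

    best_loss = np.inf
    best_epoch = -1
    best_state = None
    rows = []
    for epoch in range(cfg.max_epochs):
        opt.lr = sched.lr_at(epoch)
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model.zero_grad()
            logits = model.forward_train(_take(x_tr, idx))
            loss, dlogits = nn.bce_with_logits(logits, y_tr[idx])
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_loss = _eval_loss(model, x_va, y_va, cfg.batch_size)
        rows.append({"epoch": epoch, "train_loss": epoch_loss / n_batches,
                     "val_loss": val_loss, "lr": opt.lr})
        if val_loss < best_loss:
            best_loss = val_loss
            best_epoch = epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    test_predictions = None
    if test_data is not None:
        x_te, y_te, ids_te = _as_xy(test_data)
        if _n_samples(x_te):
            logits = model.predict_logits(x_te, batch_size=cfg.batch_size)
            test_predictions = PredictionSet(
                subject_ids=ids_te, logits=logits,
                probabilities=nn.sigmoid(logits), labels=y_te)
    return TrainResult(best_epoch=best_epoch, history=pd.DataFrame(rows),
                       test_predictions=test_predictions, seed=cfg.seed)


def run_hyperparameter_search(build_fn: Callable[[dict, int], object],
                              train_data, val_data, test_data,
                              grid: Sequence[dict], base_cfg: TrainConfig,
                              n_repeats: int = 10) -> tuple[pd.DataFrame, dict]:
    """Train every grid configuration ``n_repeats`` times on identical splits.

    ``build_fn(config, seed)`` must return a fresh model for the given
    configuration. Config dicts may override any :class:`TrainConfig`
    field; other keys are passed through to ``build_fn``. Returns the
    table ranked by mean test MCC and the best configuration.
    """
    if not grid:
        raise ParameterError("hyperparameter grid must be nonempty")
    cfg_fields = set(TrainConfig.__dataclass_fields__)
    rows = []
    for config in grid:
        overrides = {k: v for k, v in config.items() if k in cfg_fields and k != "seed"}
        mccs = []
        for r in range(n_repeats):
            seed = base_cfg.seed + 1000 * r
            cfg = replace(base_cfg, **overrides, seed=seed)
            model = build_fn(config, seed)
            result = train_model(model, train_data, val_data, test_data, cfg)
            mccs.append(result.test_predictions.metrics()["mcc"])
        rows.append({**config, "mcc_mean": float(np.mean(mccs)),
                     "mcc_sd": float(np.std(mccs, ddof=1)) if len(mccs) > 1 else 0.0,
                     "mccs": mccs})
    table = pd.DataFrame(rows).sort_values("mcc_mean", ascending=False,
                                           kind="stable").reset_index(drop=True)
    best = {k: table.iloc[0][k] for k in grid[0].keys()}
    return table, best
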