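"""The multitask CNN-BiLSTM blood-pressure network.

A 250-sample ECG-PPG difference sequence enters a shared feature extractor —
1-D convolution (56 filters, kernel 10, ReLU, L2 on the kernel), batch
normalization, a bidirectional LSTM (28 units per direction, concatenated)
followed by two unidirectional LSTMs (28 units, full sequences), and global
average pooling over time — whose 28 features feed two independent heads
(dense 28 -> ReLU -> dense 16 -> ReLU -> dense 1, linear) emitting SBP and
DBP in mmHg simultaneously. The default architecture has 38,370 parameters
(38,258 trainable; the 112 non-trainable are the batch-norm moving
statistics).

Training minimizes the sum of the per-head mean squared errors with Adam
(lr 0.01, per-update decay 2e-5, batch 28), early stopping on validation
loss with best-weight restoration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .preprocess import SequenceWindow

__all__ = [
    "ArchitectureConfig", "TrainConfig", "ParamCount", "TrainedModel",
    "build_model", "count_parameters", "split_dataset", "train", "predict",
    "windows_to_arrays",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Network hyperparameters (defaults are the published architecture)."""

    input_len: int = 250
    conv_filters: int = 56
    conv_kernel: int = 10
    lstm_units: int = 28
    dense_units: tuple[int, int] = (28, 16)
    l2_lambda: float = 1e-3

    def validate(self) -> None:
        for name in ("input_len", "conv_filters", "conv_kernel", "lstm_units"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.dense_units) != 2 or any(u <= 0 for u in self.dense_units):
            raise ValueError("dense_units must be two positive counts")
        if self.conv_kernel > self.input_len:
            raise ValueError("conv_kernel cannot exceed input_len")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol (defaults are the published one)."""

    lr: float = 0.01
    decay: float = 0.00002
    batch_size: int = 28
    max_epochs: int = 1000
    early_stop_patience: int = 50
    #: relative validation-loss improvement below which patience counts down
    min_rel_delta: float = 1e-3
    val_fraction: float = 0.1
    test_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError(f"val_fraction must be in (0, 1), got {self.val_fraction}")
        if not 0 < self.test_fraction < 1:
            raise ValueError(f"test_fraction must be in (0, 1), got {self.test_fraction}")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass(frozen=True)
class ParamCount:
    total: int
    trainable: int
    non_trainable: int


class TrainedModel:
    """Network plus its training history."""

    def __init__(self, architecture: ArchitectureConfig, seed: int = 0):
        architecture.validate()
        self.architecture = architecture
        rng = np.random.default_rng(seed)
        a = architecture
        u = a.lstm_units
        self.shared = [
            nn.Conv1D(1, a.conv_filters, a.conv_kernel, rng, l2=a.l2_lambda),
            nn.ReLU(),
            nn.BatchNorm(a.conv_filters),
            nn.Bidirectional(a.conv_filters, u, rng),
            nn.LSTM(2 * u, u, rng),
            nn.LSTM(u, u, rng),
            nn.GlobalAveragePooling1D(),
        ]
        d1, d2 = a.dense_units
        self.heads = {}
        for name in ("sbp", "dbp"):
            self.heads[name] = [
                nn.Dense(u, d1, rng), nn.ReLU(),
                nn.Dense(d1, d2, rng), nn.ReLU(),
                nn.Dense(d2, 1, rng),
            ]
        self.history: dict[str, list[float]] = {"loss": [], "val_loss": [],
                                                "loss_sbp": [], "loss_dbp": []}
        self.best_epoch: Optional[int] = None

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
        h = x
        for lay in self.shared:
            h = lay.forward(h, training)
        outs = {}
        for name, layers in self.heads.items():
            z = h
            for lay in layers:
                z = lay.forward(z, training)
            outs[name] = z[:, 0]
        return outs["sbp"], outs["dbp"]

    def backward(self, dy_sbp: np.ndarray, dy_dbp: np.ndarray) -> None:
        dh_total = 0.0
        for name, dy in (("sbp", dy_sbp), ("dbp", dy_dbp)):
            dz = dy[:, None]
            for lay in reversed(self.heads[name]):
                dz = lay.backward(dz)
            dh_total = dh_total + dz
        dh = dh_total
        for lay in reversed(self.shared):
            dh = lay.backward(dh)

    # -- parameter plumbing --------------------------------------------------
    def all_layers(self) -> list[nn.Layer]:
        layers = list(self.shared)
        for h in self.heads.values():
            layers.extend(h)
        return nn.iter_param_layers(layers)

    def l2_penalty(self) -> float:
        return sum(lay.l2_penalty() for lay in self.all_layers()
                   if isinstance(lay, nn.Conv1D))

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [
            {"params": {k: v.copy() for k, v in lay.params.items()},
             "buffers": {k: v.copy() for k, v in lay.buffers.items()}}
            for lay in self.all_layers()
        ]

    def set_weights(self, weights) -> None:
        for lay, w in zip(self.all_layers(), weights):
            for k, v in w["params"].items():
                lay.params[k] = v.copy()
            for k, v in w["buffers"].items():
                lay.buffers[k] = v.copy()

    def save_weights(self, path) -> None:
        flat = {}
        for i, lay in enumerate(self.all_layers()):
            for k, v in lay.params.items():
                flat[f"{i}:p:{k}"] = v
            for k, v in lay.buffers.items():
                flat[f"{i}:b:{k}"] = v
        np.savez(path, **flat)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            for i, lay in enumerate(self.all_layers()):
                for k in lay.params:
                    lay.params[k] = data[f"{i}:p:{k}"]
                for k in lay.buffers:
                    lay.buffers[k] = data[f"{i}:b:{k}"]


def build_model(arch: ArchitectureConfig = ArchitectureConfig(),
                seed: int = 0) -> TrainedModel:
    """Build the (untrained) multitask network for the given architecture."""
    return TrainedModel(arch, seed=seed)


def count_parameters(model: TrainedModel) -> ParamCount:
    trainable = sum(lay.n_trainable() for lay in model.all_layers())
    non_trainable = sum(lay.n_non_trainable() for lay in model.all_layers())
    return ParamCount(total=trainable + non_trainable,
                      trainable=trainable, non_trainable=non_trainable)


# ---------------------------------------------------------------------------
# Data handling
# ---------------------------------------------------------------------------

def windows_to_arrays(windows: Sequence[SequenceWindow]
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack windows into (X [N,250,1], y_sbp [N], y_dbp [N])."""
    X = np.stack([w.diff for w in windows])[:, :, None].astype(float)
    y_sbp = np.array([w.sbp_label for w in windows], dtype=float)
    y_dbp = np.array([w.dbp_label for w in windows], dtype=float)
    return X, y_sbp, y_dbp


def split_dataset(windows: Sequence[SequenceWindow], cfg: TrainConfig
                  ) -> tuple[list[SequenceWindow], list[SequenceWindow],
                             list[SequenceWindow]]:
    """Seeded disjoint exhaustive train/val/test split.

    |test| = round(test_fraction * N); the validation set is
    round(val_fraction * |rest|) windows of the remaining training pool.
    """
    cfg.validate()
    n = len(windows)
    if n < 10:
        raise ValueError(f"need at least 10 windows to split, got {n}")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    n_test = int(round(cfg.test_fraction * n))
    test_idx = order[:n_test]
    pool = order[n_test:]
    n_val = int(round(cfg.val_fraction * pool.size))
    val_idx = pool[:n_val]
    train_idx = pool[n_val:]
    pick = lambda idx: [windows[i] for i in idx]
    return pick(train_idx), pick(val_idx), pick(test_idx)


# ---------------------------------------------------------------------------
# Training / inference
# ---------------------------------------------------------------------------

class TrainingDiverged(RuntimeError):
    pass


def _loss_and_grads(model, X, ys, yd, training):
    ps, pd = model.forward(X, training=training)
    es, ed = ps - ys, pd - yd
    loss_s = float(np.mean(es ** 2))
    loss_d = float(np.mean(ed ** 2))
    return ps, pd, loss_s, loss_d, 2.0 * es / es.size, 2.0 * ed / ed.size


def evaluate_loss(model: TrainedModel, windows: Sequence[SequenceWindow],
                  batch: int = 256) -> tuple[float, float]:
    """Inference-mode per-head MSE over a window set."""
    X, ys, yd = windows_to_arrays(windows)
    se_s = se_d = 0.0
    for i in range(0, len(X), batch):
        ps, pd = model.forward(X[i:i + batch], training=False)
        se_s += float(np.sum((ps - ys[i:i + batch]) ** 2))
        se_d += float(np.sum((pd - yd[i:i + batch]) ** 2))
    return se_s / len(X), se_d / len(X)


def train(model: TrainedModel,
          train_windows: Sequence[SequenceWindow],
          val_windows: Sequence[SequenceWindow],
          cfg: TrainConfig,
          verbose: bool = False) -> TrainedModel:
    """Fit with summed per-head MSE, Adam, and early stopping.

    Stops when validation loss has not improved (relatively, by more than
    ``min_rel_delta``) for ``early_stop_patience`` epochs, or at
    ``max_epochs``, and restores the best-validation weights. Shuffles per
    epoch with the config seed; fully deterministic. The output-layer biases
    start at the respective training-label means so that epochs are spent on
    the waveform signal rather than on the mmHg offset.
    """
    cfg.validate()
    X, ys, yd = windows_to_arrays(train_windows)
    if not (np.isfinite(ys).all() and np.isfinite(yd).all()
            and np.isfinite(X).all()):
        raise ValueError("training data contain non-finite values")
    for name, labels in (("sbp", ys), ("dbp", yd)):
        model.heads[name][-1].params["b"][:] = labels.mean()
    opt = nn.Adam(model.shared + [l for h in model.heads.values() for l in h],
                  lr=cfg.lr, decay=cfg.decay)
    rng = np.random.default_rng((cfg.seed, 0x7A1))
    best_val = np.inf
    mark = np.inf        # last val loss that reset the patience counter
    best_weights = model.get_weights()
    best_epoch = 0
    wait = 0
    n = len(X)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        tot_s = tot_d = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            _, _, ls, ld, ds, dd = _loss_and_grads(
                model, X[idx], ys[idx], yd[idx], training=True)
            if not (np.isfinite(ls) and np.isfinite(ld)):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch} (sbp={ls}, dbp={ld})")
            model.backward(ds, dd)
            opt.step()
            tot_s += ls * idx.size
            tot_d += ld * idx.size
        loss_s, loss_d = tot_s / n, tot_d / n
        if val_windows:
            vs, vd = evaluate_loss(model, val_windows)
        else:
            vs, vd = loss_s, loss_d
        val = vs + vd
        model.history["loss"].append(loss_s + loss_d)
        model.history["loss_sbp"].append(loss_s)
        model.history["loss_dbp"].append(loss_d)
        model.history["val_loss"].append(val)
        if verbose:
            print(f"epoch {epoch:4d}  loss {loss_s + loss_d:10.3f}  "
                  f"val {val:10.3f}")
        if val < best_val:
            best_val = val
            best_weights = model.get_weights()
            best_epoch = epoch
        if val < mark * (1.0 - cfg.min_rel_delta):
            mark = val
            wait = 0
        else:
            wait += 1
            if wait >= cfg.early_stop_patience:
                break
    model.set_weights(best_weights)
    model.best_epoch = best_epoch
    return model


def predict(model: TrainedModel,
            windows: Sequence[SequenceWindow] | np.ndarray,
            batch: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Paired (sbp_hat, dbp_hat) in mmHg, order preserved, deterministic."""
    if isinstance(windows, np.ndarray):
        X = windows
    else:
        X, _, _ = windows_to_arrays(windows)
    if X.ndim != 3 or X.shape[1] != model.architecture.input_len or X.shape[2] != 1:
        raise ValueError(
            f"expected input shape (N, {model.architecture.input_len}, 1), "
            f"got {X.shape}")
    outs_s, outs_d = [], []
    for i in range(0, len(X), batch):
        ps, pd = model.forward(X[i:i + batch], training=False)
        outs_s.append(ps)
        outs_d.append(pd)
    return np.concatenate(outs_s), np.concatenate(outs_d)
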