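"""Dual-channel 1-D U-Net regressor with BiLSTM layers, and its training loop.

Architecture (4-level default): an encoder of Conv1d+ReLU blocks that halves
the temporal length per level while doubling the channel count; two
bidirectional LSTM layers at the bottleneck; a mirrored decoder with
nearest-neighbour upsampling, convolution and skip concatenation from the
matching encoder level; a bidirectional LSTM over the decoder output whose
final forward/backward states feed a single fully connected unit producing
the scalar CO estimate (on the [0, 1] label scale).

The four pooling stages of factor 2 require the input length to be divisible
by 16 for the default depth; this is validated at construction.

Training follows MSE loss / MAE metric with Adam at learning rate 0.001,
batch size 32, an 80/20 random train/test split, 10% of the training set held
out for validation, and the best-validation-loss epoch kept as the result.
The validation subset is fixed across epochs by default; per-epoch resampling
is available as ``val_mode="per_epoch_resample"``.
"""

from __future__ import annotations

import copy
import csv
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from cowave.errors import TrainingDivergedError, ValidationError
from cowave.nn import Adam, BiLSTM, Conv1d, Dense, Tensor, ops
from cowave.preprocessing import Segment, unscale_label

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    input_length: int = 2048
    channels: Tuple[str, ...] = ("ppg", "art")
    depth: int = 4
    base_filters: int = 16
    kernel_size: int = 3
    pool_factor: int = 2
    bottleneck_lstm_layers: int = 2
    bottleneck_lstm_units: int = 64
    head_lstm_units: int = 64
    activation: str = "relu"
    seed: int = 0

    @property
    def in_channels(self) -> int:
        return len(self.channels)

    def validate(self) -> None:
        stride = self.pool_factor**self.depth
        if self.input_length % stride:
            raise ValidationError(
                f"input_length ({self.input_length}) must be divisible by "
                f"pool_factor**depth = {stride} (a multiple of 16 for the "
                "default 4-level model) so every pooling stage halves evenly"
            )
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        for name in (
            "input_length",
            "base_filters",
            "kernel_size",
            "pool_factor",
            "bottleneck_lstm_layers",
            "bottleneck_lstm_units",
            "head_lstm_units",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.kernel_size % 2 != 1:
            raise ValidationError("kernel_size must be odd (same padding)")
        if self.activation != "relu":
            raise ValidationError(f"unsupported activation {self.activation!r}")
        if not self.channels or any(c not in ("ppg", "art") for c in self.channels):
            raise ValidationError(f"channels must be drawn from ('ppg','art'), got {self.channels}")


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "mse"
    metric: str = "mae"
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 500
    train_fraction: float = 0.8
    val_fraction_of_train: float = 0.1
    val_mode: str = "fixed"  # or "per_epoch_resample"
    split_level: str = "segment"  # or "case"
    seed: int = 0

    def validate(self) -> None:
        if self.loss != "mse" or self.metric != "mae":
            raise ValidationError("loss must be 'mse' and metric 'mae'")
        if not (0 < self.train_fraction < 1) or not (0 < self.val_fraction_of_train < 1):
            raise ValidationError("fractions must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.val_mode not in ("fixed", "per_epoch_resample"):
            raise ValidationError(f"unknown val_mode {self.val_mode!r}")
        if self.split_level not in ("segment", "case"):
            raise ValidationError(f"unknown split_level {self.split_level!r}")


class UNet1DRegressor:
    """The network: encoder -> BiLSTM bottleneck -> decoder -> BiLSTM head."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        f, d, k = config.base_filters, config.depth, config.kernel_size
        self.enc: List[Conv1d] = []
        ch = config.in_channels
        for level in range(d):
            out = f * 2**level
            self.enc.append(Conv1d(ch, out, k, rng))
            ch = out
        self.bottleneck_conv = Conv1d(ch, f * 2**d, k, rng)
        ch = f * 2**d
        self.bottleneck_lstms: List[BiLSTM] = []
        for _ in range(config.bottleneck_lstm_layers):
            self.bottleneck_lstms.append(BiLSTM(ch, config.bottleneck_lstm_units, rng))
            ch = 2 * config.bottleneck_lstm_units
        self.up: List[Conv1d] = []
        self.merge: List[Conv1d] = []
        for level in reversed(range(d)):
            out = f * 2**level
            self.up.append(Conv1d(ch, out, k, rng))
            self.merge.append(Conv1d(2 * out, out, k, rng))
            ch = out
        self.head_lstm = BiLSTM(ch, config.head_lstm_units, rng)
        self.head = Dense(2 * config.head_lstm_units, 1, rng)

    def parameters(self):
        params = []
        for layer in (
            self.enc
            + [self.bottleneck_conv]
            + self.bottleneck_lstms
            + self.up
            + self.merge
            + [self.head_lstm, self.head]
        ):
            params.extend(layer.parameters())
        return params

    def forward(self, x: np.ndarray) -> Tensor:
        """Batch (N, in_channels, input_length) -> scalar predictions (N,)."""
        if x.ndim != 3 or x.shape[1] != self.config.in_channels or x.shape[2] != self.config.input_length:
            raise ValidationError(
                f"expected input of shape (N, {self.config.in_channels}, "
                f"{self.config.input_length}), got {x.shape}"
            )
        p = self.config.pool_factor
        t = Tensor(x)
        skips: List[Tensor] = []
        for conv in self.enc:
            t = ops.relu(conv(t))
            skips.append(t)
            t = ops.maxpool1d(t, p)
        t = ops.relu(self.bottleneck_conv(t))
        # shape trace for structural tests: (channels, length) per stage
        self.last_trace = {
            "encoder": [s.shape[1:] for s in skips],
            "bottleneck": t.shape[1:],
            "decoder": [],
        }
        t = ops.transpose(t, (0, 2, 1))  # (N, T, C) for the recurrence
        for lstm in self.bottleneck_lstms:
            t, _ = lstm(t)
        t = ops.transpose(t, (0, 2, 1))
        for conv_up, conv_merge, skip in zip(self.up, self.merge, reversed(skips)):
            t = ops.relu(conv_up(ops.upsample1d(t, p)))
            t = ops.concat([t, skip], axis=1)
            t = ops.relu(conv_merge(t))
            self.last_trace["decoder"].append(t.shape[1:])
        t = ops.transpose(t, (0, 2, 1))
        _, last = self.head_lstm(t)  # final forward+backward states, (N, 2H)
        out = self.head(last)  # (N, 1)
        return ops.reshape(out, (x.shape[0],))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).data

    def get_weights(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValidationError(
                f"weight count mismatch: model has {len(params)} arrays, got {len(weights)}"
            )
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValidationError(
                    f"weight shape mismatch: expected {p.data.shape}, got {w.shape}"
                )
            p.data = np.asarray(w, dtype=np.float64).copy()


def build_model(config: ModelConfig) -> UNet1DRegressor:
    """Construct a seeded, untrained network from *config*."""
    return UNet1DRegressor(config)


@dataclass
class TrainedModel:
    model: UNet1DRegressor
    train_config: TrainConfig
    history: Dict[str, List[float]]
    best_epoch: int  # 1-based epoch with the smallest validation loss

    @property
    def config(self) -> ModelConfig:
        return self.model.config


def split_dataset(
    segments: Sequence[Segment],
    train_fraction: float = 0.8,
    seed: int = 0,
    split_level: str = "segment",
) -> Tuple[List[Segment], List[Segment]]:
    """Random disjoint train/test partition; reproducible under *seed*.

    At ``split_level="segment"`` the train size is exactly
    ``floor(train_fraction * n)`` (9,446 segments at 0.8 give 7,556/1,890).
    At ``split_level="case"`` whole cases are assigned to one side, so the
    achieved fraction is approximate.
    """
    n = len(segments)
    if n < 2:
        raise ValidationError(f"need at least 2 segments to split, got {n}")
    if not (0 < train_fraction < 1):
        raise ValidationError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if split_level == "segment":
        order = rng.permutation(n)
        n_train = int(np.floor(train_fraction * n))
        train_idx, test_idx = order[:n_train], order[n_train:]
        return [segments[i] for i in sorted(train_idx)], [segments[i] for i in sorted(test_idx)]
    if split_level == "case":
        cases = sorted({s.case_id for s in segments})
        rng.shuffle(cases)
        target = int(np.floor(train_fraction * n))
        train_cases, count = set(), 0
        per_case = {c: sum(1 for s in segments if s.case_id == c) for c in cases}
        for c in cases:
            if count >= target:
                break
            train_cases.add(c)
            count += per_case[c]
        train = [s for s in segments if s.case_id in train_cases]
        test = [s for s in segments if s.case_id not in train_cases]
        return train, test
    raise ValidationError(f"unknown split_level {split_level!r}")


def validation_size(n_train: int, val_fraction: float) -> int:
    """Number of training samples held out for validation (rounded: 7,556 -> 756)."""
    return int(round(val_fraction * n_train))


def _stack_inputs(segments: Sequence[Segment], channels: Tuple[str, ...]) -> np.ndarray:
    chans = {"ppg": [s.ppg_in for s in segments], "art": [s.art_in for s in segments]}
    return np.stack([np.stack(chans[c]) for c in channels], axis=1)


def _labels(segments: Sequence[Segment]) -> np.ndarray:
    return np.array([s.co_label_scaled for s in segments], dtype=float)


def train_model(
    model: UNet1DRegressor,
    train_segments: Sequence[Segment],
    config: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """MSE/Adam training with a validation hold-out and best-epoch checkpoint.

    Expects segments that passed screening and were normalized (inputs and
    labels on the [0, 1] scale). History has one entry per epoch; the
    returned parameters are those of the epoch with the smallest validation
    loss.
    """
    config.validate()
    if not train_segments:
        raise ValidationError("empty training set")
    for s in train_segments:
        if not s.normalized:
            raise ValidationError(
                f"segment at center {s.center_index} is not normalized; run "
                "normalize_segment after screening"
            )
    X = _stack_inputs(train_segments, model.config.channels)
    y = _labels(train_segments)
    n = len(train_segments)
    n_val = min(max(1, validation_size(n, config.val_fraction_of_train)), n - 1)
    rng = np.random.default_rng(config.seed)
    fixed_val = rng.permutation(n)[:n_val] if config.val_mode == "fixed" else None

    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history: Dict[str, List[float]] = {
        "train_loss": [],
        "train_mae": [],
        "val_loss": [],
        "val_mae": [],
    }
    best_loss, best_epoch, best_weights = np.inf, 0, model.get_weights()

    for epoch in range(1, config.epochs + 1):
        if fixed_val is None:
            val_idx = rng.permutation(n)[:n_val]
        else:
            val_idx = fixed_val
        val_mask = np.zeros(n, dtype=bool)
        val_mask[val_idx] = True
        fit_idx = rng.permutation(np.flatnonzero(~val_mask))

        losses, maes, weights = [], [], []
        for start in range(0, fit_idx.size, config.batch_size):
            batch = fit_idx[start : start + config.batch_size]
            pred = model.forward(X[batch])
            err = ops.sub(pred, Tensor(y[batch]))
            loss = ops.mean(ops.mul(err, err))
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}; lower the "
                    "learning rate or inspect the inputs"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
            maes.append(float(np.mean(np.abs(err.data))))
            weights.append(batch.size)
        train_loss = float(np.average(losses, weights=weights))
        train_mae = float(np.average(maes, weights=weights))

        val_pred = _predict_batched(model, X[val_idx])
        val_err = val_pred - y[val_idx]
        val_loss = float(np.mean(val_err**2))
        val_mae = float(np.mean(np.abs(val_err)))
        history["train_loss"].append(train_loss)
        history["train_mae"].append(train_mae)
        history["val_loss"].append(val_loss)
        history["val_mae"].append(val_mae)
        if val_loss < best_loss:
            best_loss, best_epoch = val_loss, epoch
            best_weights = model.get_weights()

    model.set_weights(best_weights)
    return TrainedModel(model=model, train_config=config, history=history, best_epoch=best_epoch)


def _predict_batched(model: UNet1DRegressor, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = np.empty(X.shape[0])
    for start in range(0, X.shape[0], batch_size):
        out[start : start + batch_size] = model.predict(X[start : start + batch_size])
    return out


def predict_co(trained: TrainedModel, segments: Sequence[Segment]) -> np.ndarray:
    """Predict CO in L/min for preprocessed segments (order preserved)."""
    if not segments:
        return np.empty(0)
    for s in segments:
        if s.length != trained.config.input_length:
            raise ValidationError(
                f"segment length {s.length} does not match the model input "
                f"length {trained.config.input_length}"
            )
    X = _stack_inputs(segments, trained.config.channels)
    scaled = _predict_batched(trained.model, X)
    return unscale_label(scaled)


def save_model(trained: TrainedModel, path) -> None:
    """Write config JSON, parameter arrays (.npz) and history CSV to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "model_config": asdict(trained.config),
        "train_config": asdict(trained.train_config),
        "best_epoch": trained.best_epoch,
        "n_weight_arrays": len(trained.model.parameters()),
    }
    (path / "config.json").write_text(json.dumps(meta, indent=2))
    np.savez(path / "weights.npz", *[p.data for p in trained.model.parameters()])
    with open(path / "history.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        keys = list(trained.history)
        writer.writerow(["epoch"] + keys)
        for i in range(len(trained.history["train_loss"])):
            writer.writerow([i + 1] + [trained.history[k][i] for k in keys])


def load_model(path) -> TrainedModel:
    """Inverse of :func:`save_model`; validates format version and shapes."""
    path = Path(path)
    try:
        meta = json.loads((path / "config.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValidationError(f"cannot read model config at {path}: {exc}") from exc
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"model format version {meta.get('format_version')} is not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    mc = dict(meta["model_config"])
    mc["channels"] = tuple(mc["channels"])
    model = build_model(ModelConfig(**mc))
    try:
        with np.load(path / "weights.npz") as npz:
            weights = [npz[k] for k in npz.files]
    except Exception as exc:
        raise ValidationError(f"cannot read model weights at {path}: {exc}") from exc
    if len(weights) != meta["n_weight_arrays"]:
        raise ValidationError(
            f"weight file holds {len(weights)} arrays, config expects "
            f"{meta['n_weight_arrays']} (truncated or mismatched save)"
        )
    model.set_weights(weights)
    history: Dict[str, List[float]] = {}
    with open(path / "history.csv", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            for key, value in row.items():
                if key == "epoch":
                    continue
                history.setdefault(key, []).append(float(value))
    return TrainedModel(
        model=model,
        train_config=TrainConfig(**meta["train_config"]),
        history=history,
        best_epoch=int(meta["best_epoch"]),
    )
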