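"""Range-error compensation with a small backpropagation-trained network.

UWB range estimates carry a systematic, distance-dependent error (crystal
frequency offsets, antenna delay, temperature).  A static sweep of
(measured, true) distance pairs — here 1-20 m with 10 samples per metre,
200 pairs — is used to fit a one-input / one-output feed-forward network
with a single tanh hidden layer, trained by full-batch gradient descent on
the mean squared error of min-max normalised data.  The trained network
maps a raw distance to a corrected one.

Hidden-layer width is chosen by sweeping a candidate set (default 4-9) and
picking the width with the lowest held-out RMSE; the sweep table is kept
for reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationDataset",
    "CalibrationModel",
    "TrainConfig",
    "RangeCalibrator",
    "split_dataset",
    "train",
    "predict",
    "rmse_1d",
    "select_hidden_size",
    "save_model",
    "load_model",
    "read_calibration_csv",
    "write_calibration_csv",
]


@dataclass
class CalibrationDataset:
    """Paired (measured, true) distances in metres."""

    measured: np.ndarray
    true: np.ndarray
    split_seed: int = 0

    def __post_init__(self) -> None:
        self.measured = np.asarray(self.measured, dtype=float)
        self.true = np.asarray(self.true, dtype=float)
        if self.measured.shape != self.true.shape or self.measured.ndim != 1:
            raise ValueError("measured and true must be 1-D arrays of equal length")
        if np.any(self.measured < 0) or np.any(self.true < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return self.measured.size


@dataclass
class TrainConfig:
    """Gradient-descent settings.

    Training stops at ``max_epochs`` or once the per-epoch improvement of
    the training MSE falls below ``tolerance``.
    """

    max_epochs: int = 5000
    learning_rate: float = 0.1
    momentum: float = 0.9
    lr_up: float = 1.05  # rate growth after an accepted step
    lr_down: float = 0.7  # rate shrink after a rejected step
    max_error_growth: float = 1.04  # reject steps that grow the loss beyond this
    tolerance: float = 1e-9
    patience: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


@dataclass
class CalibrationModel:
    """Trained 1-h-1 corrector with its normalisation constants.

    Normalisation maps a raw value ``x`` to ``(x - offset) / scale`` (so the
    training span lands in [-1, 1]); the output path inverts the target's
    normalisation.
    """

    hidden_size: int
    input_norm: tuple[float, float]  # (offset, scale)
    output_norm: tuple[float, float]
    hidden_weights: np.ndarray  # (h,)
    hidden_bias: np.ndarray  # (h,)
    output_weights: np.ndarray  # (h,)
    output_bias: float
    activation_name: str = "tanh"
    n_epochs_run: int = 0
    final_train_mse: float = float("nan")

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.input_norm[1] <= 0 or self.output_norm[1] <= 0:
            raise ValueError("normalisation scales must be strictly positive")
        for name in ("hidden_weights", "hidden_bias", "output_weights"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.hidden_size,):
                raise ValueError(f"{name} must have shape ({self.hidden_size},)")
            setattr(self, name, arr)


def split_dataset(
    dataset: CalibrationDataset, train_fraction: float
) -> tuple[CalibrationDataset, CalibrationDataset]:
    """Disjoint shuffled train/test split, reproducible from ``split_seed``.

    Train size is ``floor(n * train_fraction)``; the remainder is the test
    set.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 pairs to split")
    rng = np.random.default_rng(dataset.split_seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * train_fraction))
    tr, te = perm[:n_train], perm[n_train:]
    return (
        CalibrationDataset(dataset.measured[tr], dataset.true[tr], dataset.split_seed),
        CalibrationDataset(dataset.measured[te], dataset.true[te], dataset.split_seed),
    )


def _norm_params(x: np.ndarray) -> tuple[float, float]:
    # min-max to [-1, 1]; degenerate (constant) spans fall back to unit scale
    lo, hi = float(np.min(x)), float(np.max(x))
    offset = 0.5 * (lo + hi)
    scale = 0.5 * (hi - lo)
    if scale <= 0:
        scale = 1.0
    return offset, scale


def train(
    train_set: CalibrationDataset, hidden_size: int, config: TrainConfig | None = None
) -> CalibrationModel:
    """Fit the 1-h-1 tanh network by full-batch gradient descent.

    Uses the classic variable-learning-rate backpropagation heuristic:
    momentum plus an adaptive step size that grows by ``lr_up`` after each
    accepted epoch and is rejected (weights restored, rate shrunk by
    ``lr_down``, momentum reset) when the loss grows by more than
    ``max_error_growth``.  Deterministic given ``config.seed`` (which sets
    the weight initialisation).  Raises if the loss leaves the finite
    range.
    """
    if config is None:
        config = TrainConfig()
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    if hidden_size < 1:
        raise ValueError("hidden_size must be >= 1")

    in_off, in_scale = _norm_params(train_set.measured)
    out_off, out_scale = _norm_params(train_set.true)
    x = (train_set.measured - in_off) / in_scale  # (n,)
    y = (train_set.true - out_off) / out_scale

    rng = np.random.default_rng(config.seed)
    w1 = rng.normal(0.0, 1.0, hidden_size)
    b1 = rng.uniform(-1.0, 1.0, hidden_size)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(hidden_size), hidden_size)
    b2 = 0.0

    n = x.size
    lr = config.learning_rate
    mom = config.momentum
    vw1 = np.zeros_like(w1)
    vb1 = np.zeros_like(b1)
    vw2 = np.zeros_like(w2)
    vb2 = 0.0

    def forward():
        a = np.tanh(np.outer(x, w1) + b1)  # (n, h)
        err = a @ w2 + b2 - y
        with np.errstate(over="ignore"):  # overflow -> inf -> divergence error
            return a, err, float(np.mean(err**2))

    a, err, mse = forward()
    if not np.isfinite(mse):
        raise FloatingPointError(
            f"training diverged (non-finite loss) at initialisation "
            f"with learning_rate={lr}"
        )
    best_mse = mse
    stall = 0
    epochs_run = 0
    for epoch in range(config.max_epochs):
        g_yhat = 2.0 * err / n  # (n,)
        g_w2 = a.T @ g_yhat
        g_b2 = float(np.sum(g_yhat))
        g_a = np.outer(g_yhat, w2) * (1.0 - a**2)  # (n, h)
        g_w1 = g_a.T @ x
        g_b1 = g_a.sum(axis=0)
        vw1_new = mom * vw1 - lr * g_w1
        vb1_new = mom * vb1 - lr * g_b1
        vw2_new = mom * vw2 - lr * g_w2
        vb2_new = mom * vb2 - lr * g_b2

        w1 += vw1_new
        b1 += vb1_new
        w2 += vw2_new
        b2 += vb2_new
        a_new, err_new, mse_new = forward()
        if not np.isfinite(mse_new):
            raise FloatingPointError(
                f"training diverged (non-finite loss) at epoch {epoch} "
                f"with learning_rate={lr}"
            )
        epochs_run = epoch + 1
        if mse_new > mse * config.max_error_growth:
            # reject: restore weights, shrink the rate, drop momentum
            w1 -= vw1_new
            b1 -= vb1_new
            w2 -= vw2_new
            b2 -= vb2_new
            lr *= config.lr_down
            vw1 = np.zeros_like(w1)
            vb1 = np.zeros_like(b1)
            vw2 = np.zeros_like(w2)
            vb2 = 0.0
            if lr < 1e-12:
                break
            continue
        vw1, vb1, vw2, vb2 = vw1_new, vb1_new, vw2_new, vb2_new
        a, err, mse = a_new, err_new, mse_new
        lr *= config.lr_up
        # tolerance stop: no improvement beyond `tolerance` for `patience`
        # consecutive epochs (adaptive stepping makes single-epoch
        # improvement a noisy signal)
        if best_mse - mse > config.tolerance:
            best_mse = mse
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    return CalibrationModel(
        hidden_size=hidden_size,
        input_norm=(in_off, in_scale),
        output_norm=(out_off, out_scale),
        hidden_weights=w1,
        hidden_bias=b1,
        output_weights=w2,
        output_bias=float(b2),
        n_epochs_run=epochs_run,
        final_train_mse=mse,
    )


def predict(model: CalibrationModel, measured) -> np.ndarray | float:
    """Corrected distance(s) in metres; clamped at zero below."""
    arr = np.asarray(measured, dtype=float)
    x = (arr - model.input_norm[0]) / model.input_norm[1]
    a = np.tanh(np.multiply.outer(x, model.hidden_weights) + model.hidden_bias)
    y = a @ model.output_weights + model.output_bias
    out = np.maximum(y * model.output_norm[1] + model.output_norm[0], 0.0)
    return float(out) if np.isscalar(measured) else out


def rmse_1d(predicted: Sequence[float], actual: Sequence[float]) -> float:
    """Root mean squared difference of two equal-length scalar sequences."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size == 0:
        raise ValueError("predicted and actual must be non-empty and equal-length")
    return float(np.sqrt(np.mean((p - a) ** 2)))


def select_hidden_size(
    dataset: CalibrationDataset,
    candidates: Sequence[int] = range(4, 10),
    config: TrainConfig | None = None,
    train_fraction: float = 0.7,
) -> tuple[int, pd.DataFrame]:
    """Sweep hidden-layer widths; return (best width, sweep table).

    The best width minimises test RMSE; ties go to the smaller width.  The
    table has one row per candidate with train/test RMSE in metres.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    tr, te = split_dataset(dataset, train_fraction)
    rows = []
    for h in candidates:
        model = train(tr, h, config)
        rows.append(
            {
                "hidden_nodes": h,
                "train_rmse_m": rmse_1d(predict(model, tr.measured), tr.true),
                "test_rmse_m": rmse_1d(predict(model, te.measured), te.true),
            }
        )
    table = pd.DataFrame(rows)
    best_idx = table.sort_values(["test_rmse_m", "hidden_nodes"]).index[0]
    return int(table.loc[best_idx, "hidden_nodes"]), table


@dataclass
class RangeCalibrator:
    """Convenience fit/predict wrapper around the functional API."""

    hidden_size: int = 6
    config: TrainConfig = field(default_factory=TrainConfig)
    model_: CalibrationModel | None = None

    def fit(self, dataset: CalibrationDataset, train_fraction: float = 0.7) -> "RangeCalibrator":
        tr, _ = split_dataset(dataset, train_fraction)
        self.model_ = train(tr, self.hidden_size, self.config)
        return self

    def predict(self, measured):
        if self.model_ is None:
            raise RuntimeError("calibrator is not fitted")
        return predict(self.model_, measured)


# ---------------------------------------------------------------------------
# Persistence

def save_model(model: CalibrationModel, path) -> None:
    doc = {
        "format": "uwbid-calibration-model",
        "version": 1,
        "hidden_size": model.hidden_size,
        "activation": model.activation_name,
        "input_norm": list(model.input_norm),
        "output_norm": list(model.output_norm),
        "hidden_weights": model.hidden_weights.tolist(),
        "hidden_bias": model.hidden_bias.tolist(),
        "output_weights": model.output_weights.tolist(),
        "output_bias": model.output_bias,
        "n_epochs_run": model.n_epochs_run,
        "final_train_mse": model.final_train_mse,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> CalibrationModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "uwbid-calibration-model":
        raise ValueError(f"{path} is not a calibration-model document")
    return CalibrationModel(
        hidden_size=int(doc["hidden_size"]),
        input_norm=tuple(doc["input_norm"]),
        output_norm=tuple(doc["output_norm"]),
        hidden_weights=np.asarray(doc["hidden_weights"]),
        hidden_bias=np.asarray(doc["hidden_bias"]),
        output_weights=np.asarray(doc["output_weights"]),
        output_bias=float(doc["output_bias"]),
        activation_name=doc.get("activation", "tanh"),
        n_epochs_run=int(doc.get("n_epochs_run", 0)),
        final_train_mse=float(doc.get("final_train_mse", float("nan"))),
    )


def write_calibration_csv(dataset: CalibrationDataset, path) -> None:
    pd.DataFrame({"measured_m": dataset.measured, "true_m": dataset.true}).to_csv(
        path, index=False, float_format="%.9f"
    )


def read_calibration_csv(path, split_seed: int = 0) -> CalibrationDataset:
    df = pd.read_csv(path)
    if not {"measured_m", "true_m"} <= set(df.columns):
        raise ValueError("calibration CSV needs columns measured_m, true_m")
    return CalibrationDataset(df["measured_m"].to_numpy(), df["true_m"].to_numpy(), split_seed)
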