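"""The structure-function regression models: a small 1D convolutional
network mapping the 768-point peripapillary RNFL profile to the 52 SAP
sensitivity thresholds, and an ordinary-least-squares baseline on the same
inputs/outputs.

Architecture (fixed by design): conv(32 kernels, size 3) -> ReLU ->
conv(64, 3) -> ReLU -> flatten -> dense(54) -> ReLU -> dense(52, linear).
Convolutions use valid padding and stride 1, so the flattened width is
764*64.  Training is mini-batch gradient descent with Adam (initial lr
1e-3), mean-squared-error loss, for a fixed number of epochs; the weights
of the epoch with the lowest validation MSE are the returned model.

The network is implemented directly on numpy arrays (forward pass,
backpropagation, Adam) — at this scale (≈2.6M parameters, thousands of
exams) a BLAS-backed CPU implementation trains in minutes.  No spatial
priors are imposed: every output sees the full 768-point input through the
dense layers, so any structure-function topography is learned from data.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cohort import PairedExam, exam_arrays_right_eye
from .vf_geometry import N_RNFL, N_VF


@dataclass(frozen=True)
class CnnArchitecture:
    conv_channels: tuple[int, int] = (32, 64)
    kernel_size: int = 3
    fc_sizes: tuple[int, int] = (54, N_VF)
    input_length: int = N_RNFL
    input_scale: float = 100.0   # thickness um divided by this before the net
    padding: str = "valid"       # "valid" (default) or "circular"

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd")
        if self.fc_sizes[-1] != N_VF:
            raise ValueError(f"output dimension must be {N_VF}")
        if any(c <= 0 for c in self.conv_channels) or any(s <= 0 for s in self.fc_sizes):
            raise ValueError("layer sizes must be positive")
        if self.padding not in ("valid", "circular"):
            raise ValueError("padding must be 'valid' or 'circular'")

    @property
    def conv_out_length(self) -> int:
        if self.padding == "circular":
            return self.input_length
        return self.input_length - 2 * (self.kernel_size - 1)

    @property
    def flat_size(self) -> int:
        return self.conv_out_length * self.conv_channels[1]


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 128
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """(N, L, C) -> (N, L-k+1, C*k) sliding windows, (channel, tap) order."""
    w = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (N, Lout, C, k)
    n, lout = w.shape[0], w.shape[1]
    return np.ascontiguousarray(w).reshape(n, lout, -1)


def _conv_forward(x, w_flat, b, k, circular):
    if circular:
        x = np.concatenate([x, x[:, : k - 1, :]], axis=1)
    win = _windows(x, k)
    return win @ w_flat + b, win


def _conv_backward(d_out, win, w_flat, b_shape, k, n_ch_in, in_len, circular):
    n, lout, _ = d_out.shape
    dw = win.reshape(-1, win.shape[-1]).T @ d_out.reshape(-1, d_out.shape[-1])
    db = d_out.sum(axis=(0, 1))
    d_win = (d_out @ w_flat.T).reshape(n, lout, n_ch_in, k)
    pad_len = in_len + (k - 1 if circular else 0)
    dx = np.zeros((n, pad_len, n_ch_in), dtype=d_out.dtype)
    for j in range(k):
        dx[:, j : j + lout, :] += d_win[:, :, :, j]
    if circular:
        dx[:, : k - 1, :] += dx[:, in_len:, :]
        dx = dx[:, :in_len, :]
    return dx, dw, db


class Cnn1d:
    """The 768 -> 52 convolutional regressor (weights + forward/backward)."""

    PARAM_NAMES = ("w1", "b1", "w2", "b2", "w3", "b3", "w4", "b4")

    def __init__(self, arch: CnnArchitecture, seed: int = 0,
                 dtype=np.float32, params: dict | None = None):
        self.arch = arch
        self.dtype = np.dtype(dtype)
        k = arch.kernel_size
        c1, c2 = arch.conv_channels
        f1, f2 = arch.fc_sizes
        if params is not None:
            self.params = {n: np.asarray(p, dtype=self.dtype) for n, p in params.items()}
        else:
            rng = np.random.default_rng(seed)
            self.params = {
                "w1": _glorot(rng, 1 * k, c1 * k, (1 * k, c1), self.dtype),
                "b1": np.zeros(c1, self.dtype),
                "w2": _glorot(rng, c1 * k, c2 * k, (c1 * k, c2), self.dtype),
                "b2": np.zeros(c2, self.dtype),
                "w3": _glorot(rng, arch.flat_size, f1, (arch.flat_size, f1), self.dtype),
                "b3": np.zeros(f1, self.dtype),
                "w4": _glorot(rng, f1, f2, (f1, f2), self.dtype),
                "b4": np.zeros(f2, self.dtype),
            }

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def _forward(self, x_scaled: np.ndarray, need_cache: bool):
        """x_scaled: (N, L) already divided by input_scale."""
        a = self.arch
        p = self.params
        k = a.kernel_size
        circ = a.padding == "circular"
        x = x_scaled[:, :, None].astype(self.dtype, copy=False)
        z1, win1 = _conv_forward(x, p["w1"], p["b1"], k, circ)
        a1 = np.maximum(z1, 0)
        z2, win2 = _conv_forward(a1, p["w2"], p["b2"], k, circ)
        a2 = np.maximum(z2, 0)
        flat = a2.reshape(a2.shape[0], -1)
        z3 = flat @ p["w3"] + p["b3"]
        a3 = np.maximum(z3, 0)
        out = a3 @ p["w4"] + p["b4"]
        if not need_cache:
            return out, None
        return out, (win1, z1, win2, z2, a2.shape, flat, z3, a3)

    def forward(self, x_scaled: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(x_scaled), need_cache=False)[0]

    def loss_and_grads(self, x_scaled: np.ndarray, y: np.ndarray):
        """Mean-squared-error loss and gradients for one batch."""
        a = self.arch
        p = self.params
        k = a.kernel_size
        circ = a.padding == "circular"
        out, cache = self._forward(x_scaled, need_cache=True)
        win1, z1, win2, z2, a2_shape, flat, z3, a3 = cache
        n = out.shape[0]
        resid = (out - y.astype(self.dtype, copy=False))
        loss = float(np.mean(resid.astype(np.float64) ** 2))
        d_out = (2.0 / resid.size) * resid
        grads = {}
        grads["w4"] = a3.T @ d_out
        grads["b4"] = d_out.sum(axis=0)
        d_a3 = d_out @ p["w4"].T
        d_z3 = d_a3 * (z3 > 0)
        grads["w3"] = flat.T @ d_z3
        grads["b3"] = d_z3.sum(axis=0)
        d_flat = d_z3 @ p["w3"].T
        d_a2 = d_flat.reshape(a2_shape)
        d_z2 = d_a2 * (z2 > 0)
        c1 = a.conv_channels[0]
        l1 = z1.shape[1]
        d_a1, grads["w2"], grads["b2"] = _conv_backward(
            d_z2, win2, p["w2"], p["b2"].shape, k, c1, l1, circ
        )
        d_z1 = d_a1 * (z1 > 0)
        _, grads["w1"], grads["b1"] = _conv_backward(
            d_z1, win1, p["w1"], p["b1"].shape, k, 1, a.input_length, circ
        )
        return loss, grads

    def copy_params(self) -> dict:
        return {n: p.copy() for n, p in self.params.items()}


def build_cnn(arch: CnnArchitecture | None = None, seed: int = 0,
              dtype=np.float32) -> Cnn1d:
    """Seeded, untrained network with Glorot-uniform weights, zero biases."""
    return Cnn1d(arch or CnnArchitecture(), seed=seed, dtype=dtype)


# ---------------------------------------------------------------------------
# Trained model container + prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    arch: CnnArchitecture
    params: dict
    history: pd.DataFrame            # epoch, train_mse, val_mse
    selected_epoch: int              # 1-based epoch with lowest val MSE
    best_val_mse: float

    def network(self) -> Cnn1d:
        return Cnn1d(self.arch, params=self.params)

    def predict(self, profiles) -> np.ndarray:
        return predict(self, profiles)

    def save(self, model_dir) -> None:
        d = Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "architecture.json", "w") as fh:
            json.dump(
                {
                    "arch": dataclasses.asdict(self.arch),
                    "selected_epoch": self.selected_epoch,
                    "best_val_mse": self.best_val_mse,
                },
                fh,
                indent=2,
            )
        np.savez(d / "weights.npz", **self.params)
        self.history.to_csv(d / "history.csv", index=False)

    @classmethod
    def load(cls, model_dir) -> "TrainedModel":
        d = Path(model_dir)
        with open(d / "architecture.json") as fh:
            meta = json.load(fh)
        a = meta["arch"]
        arch = CnnArchitecture(
            conv_channels=tuple(a["conv_channels"]),
            kernel_size=a["kernel_size"],
            fc_sizes=tuple(a["fc_sizes"]),
            input_length=a["input_length"],
            input_scale=a["input_scale"],
            padding=a["padding"],
        )
        with np.load(d / "weights.npz") as z:
            params = {k: z[k] for k in z.files}
        return cls(
            arch=arch,
            params=params,
            history=pd.read_csv(d / "history.csv"),
            selected_epoch=meta["selected_epoch"],
            best_val_mse=meta["best_val_mse"],
        )


def predict(model: "TrainedModel | Cnn1d", profiles) -> np.ndarray:
    """Predicted thresholds (dB) for raw RNFL profiles in um.

    Scaling by the model's stored constant happens here; raw network outputs
    are returned unclamped (the report layer clamps for display only).
    """
    net = model.network() if isinstance(model, TrainedModel) else model
    x = np.asarray(profiles, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != net.arch.input_length:
        raise ValueError(f"profiles must have length {net.arch.input_length}")
    out = net.forward((x / net.arch.input_scale).astype(net.dtype))
    out = out.astype(float)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def exams_to_xy(exams: list[PairedExam]) -> tuple[np.ndarray, np.ndarray]:
    """Stack exams as (X um profiles, Y dB fields), right-eye convention."""
    arr = [exam_arrays_right_eye(e) for e in exams]
    return (
        np.array([a[0] for a in arr]),
        np.array([a[1] for a in arr]),
    )


class _Adam:
    def __init__(self, params: dict, cfg: TrainingConfig):
        self.cfg = cfg
        self.m = {n: np.zeros_like(p) for n, p in params.items()}
        self.v = {n: np.zeros_like(p) for n, p in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1**self.t
        bc2 = 1.0 - c.beta2**self.t
        for n, g in grads.items():
            g = g.astype(params[n].dtype, copy=False)
            self.m[n] = c.beta1 * self.m[n] + (1 - c.beta1) * g
            self.v[n] = c.beta2 * self.v[n] + (1 - c.beta2) * g * g
            params[n] -= (
                c.learning_rate * (self.m[n] / bc1)
                / (np.sqrt(self.v[n] / bc2) + c.adam_eps)
            )


def _full_mse(net: Cnn1d, x_scaled: np.ndarray, y: np.ndarray,
              batch: int = 512) -> float:
    se = 0.0
    for i in range(0, len(x_scaled), batch):
        out = net.forward(x_scaled[i : i + batch])
        se += float(np.sum((out.astype(np.float64) - y[i : i + batch]) ** 2))
    return se / y.size


def train_cnn(
    net: Cnn1d,
    train: "list[PairedExam] | tuple[np.ndarray, np.ndarray]",
    val: "list[PairedExam] | tuple[np.ndarray, np.ndarray]",
    cfg: TrainingConfig | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Train with Adam/MSE for ``cfg.epochs`` epochs; return the weights of
    the epoch with the lowest validation MSE.

    ``train``/``val`` are lists of exams (patient-level disjointness is then
    asserted) or pre-built ``(X, Y)`` arrays in um/dB.
    """
    cfg = cfg or TrainingConfig()
    if isinstance(train, list):
        overlap = {e.patient_id for e in train} & {e.patient_id for e in val}
        if overlap:
            raise ValueError(f"train/val share patients: {sorted(overlap)[:5]} ...")
        x_tr, y_tr = exams_to_xy(train)
        x_va, y_va = exams_to_xy(val)
    else:
        x_tr, y_tr = train
        x_va, y_va = val
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("train and validation sets must be non-empty")
    s = net.arch.input_scale
    x_tr = (np.asarray(x_tr) / s).astype(net.dtype)
    x_va = (np.asarray(x_va) / s).astype(net.dtype)
    y_tr = np.asarray(y_tr, dtype=net.dtype)
    y_va64 = np.asarray(y_va, dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(net.params, cfg)
    hist = []
    best = (np.inf, None, -1)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            loss, grads = net.loss_and_grads(x_tr[idx], y_tr[idx])
            opt.step(net.params, grads)
            losses.append(loss)
        val_mse = _full_mse(net, x_va, y_va64)
        hist.append((epoch, float(np.mean(losses)), val_mse))
        if val_mse < best[0]:
            best = (val_mse, net.copy_params(), epoch)
        if verbose:
            print(f"epoch {epoch:3d}  train_mse {hist[-1][1]:.3f}  val_mse {val_mse:.3f}")
    net.params = best[1]
    return TrainedModel(
        arch=net.arch,
        params=best[1],
        history=pd.DataFrame(hist, columns=["epoch", "train_mse", "val_mse"]),
        selected_epoch=best[2],
        best_val_mse=best[0],
    )


# ---------------------------------------------------------------------------
# OLS baseline
# ---------------------------------------------------------------------------

@dataclass
class LinearBaseline:
    """Per-output ordinary least squares on the same 768 inputs."""

    coef: np.ndarray        # (768, 52)
    intercept: np.ndarray   # (52,)

    def predict(self, profiles) -> np.ndarray:
        x = np.asarray(profiles, dtype=float)
        single = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[1] != self.coef.shape[0]:
            raise ValueError(f"profiles must have length {self.coef.shape[0]}")
        out = x @ self.coef + self.intercept
        return out[0] if single else out


def fit_linear_baseline(
    train: "list[PairedExam] | tuple[np.ndarray, np.ndarray]",
    ridge_alpha: float = 1e-3,
) -> LinearBaseline:
    """OLS fit of the 52 thresholds on the 768 thickness points.

    With fewer training rows than inputs the problem is rank deficient; a
    small ridge penalty is applied instead (with a warning).  Degenerate
    (constant) columns are handled by the pseudoinverse path of lstsq.
    """
    if isinstance(train, list):
        x, y = exams_to_xy(train)
    else:
        x, y = train
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    xa = np.column_stack([np.ones(n), x])
    if n <= p:
        warnings.warn(
            f"n_train={n} <= {p} inputs: rank deficient, using ridge "
            f"(alpha={ridge_alpha})",
            stacklevel=2,
        )
        reg = ridge_alpha * np.eye(p + 1)
        reg[0, 0] = 0.0
        beta = np.linalg.solve(xa.T @ xa + reg, xa.T @ y)
    else:
        beta, *_ = np.linalg.lstsq(xa, y, rcond=None)
    return LinearBaseline(coef=beta[1:], intercept=beta[0])
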