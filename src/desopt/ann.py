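"""Feed-forward surrogate (3-H-1 perceptron) trained by Levenberg-Marquardt.

The network maps the three extraction factors to yield through one hidden
layer of ``tansig`` units (hyperbolic-tangent sigmoid, ``2/(1+e^{-2x})-1``,
identical to ``tanh``) and a ``purelin`` (identity) output unit.  Inputs and
the response are min-max normalized to [-1, 1] before training and the
output is mapped back afterwards.

Training follows the damped Gauss-Newton scheme standard for small
regression networks: the update solves ``(J'J + mu I) d = J' e`` with the
Jacobian ``J`` of per-sample errors computed by backpropagation; the damping
``mu`` is divided by 10 after an accepted step and multiplied by 10 after a
rejected one.  Runs stop at the epoch cap, the MSE goal, the gradient floor,
damping overflow, or after ``max_fail`` consecutive epochs of rising
validation MSE; the parameters returned are those of the best-validation
epoch (early stopping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import DesignTable

__all__ = [
    "NormalizationSpec",
    "MLPParams",
    "TrainRecord",
    "TrainConfig",
    "TrainingDivergedError",
    "normalize",
    "denormalize",
    "forward",
    "split_data",
    "init_params",
    "train_lm",
    "train_multistart",
    "neuron_sweep",
]


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


@dataclass
class NormalizationSpec:
    """Per-variable observed bounds for the min-max map onto [-1, 1]."""

    n_min: np.ndarray
    n_max: np.ndarray
    m_min: float = -1.0
    m_max: float = 1.0

    def __post_init__(self) -> None:
        self.n_min = np.atleast_1d(np.asarray(self.n_min, dtype=float))
        self.n_max = np.atleast_1d(np.asarray(self.n_max, dtype=float))
        if np.any(self.n_max <= self.n_min):
            raise ValueError("degenerate variable: N_max must exceed N_min")

    @classmethod
    def from_data(cls, values: np.ndarray, axis: int = 0) -> "NormalizationSpec":
        v = np.asarray(values, dtype=float)
        return cls(v.min(axis=axis), v.max(axis=axis))


def normalize(values: np.ndarray, spec: NormalizationSpec) -> np.ndarray:
    """Linear map sending N_min to M_min (-1) and N_max to M_max (+1)."""
    v = np.asarray(values, dtype=float)
    scale = (spec.m_max - spec.m_min) / (spec.n_max - spec.n_min)
    return spec.m_min + (v - spec.n_min) * scale


def denormalize(values: np.ndarray, spec: NormalizationSpec) -> np.ndarray:
    """Exact inverse of :func:`normalize`."""
    v = np.asarray(values, dtype=float)
    scale = (spec.n_max - spec.n_min) / (spec.m_max - spec.m_min)
    return spec.n_min + (v - spec.m_min) * scale


def tansig(x: np.ndarray) -> np.ndarray:
    """Hyperbolic-tangent sigmoid, 2/(1+exp(-2x)) - 1."""
    return np.tanh(x)


@dataclass
class MLPParams:
    """Weights, biases and normalization bounds of the 3-H-1 network."""

    w1: np.ndarray  # (H, 3)
    b1: np.ndarray  # (H,)
    w2: np.ndarray  # (H,)
    b2: float
    norm_x: NormalizationSpec
    norm_y: NormalizationSpec

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float).reshape(-1)
        self.w2 = np.asarray(self.w2, dtype=float).reshape(-1)
        H = self.w1.shape[0]
        if self.w1.shape != (H, 3) or self.b1.shape != (H,) or self.w2.shape != (H,):
            raise ValueError("inconsistent parameter dimensions for a 3-H-1 network")

    @property
    def hidden(self) -> int:
        return self.w1.shape[0]

    # -- flat-vector view used by the trainer ------------------------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2, [self.b2]])

    def with_vector(self, theta: np.ndarray) -> "MLPParams":
        H = self.hidden
        w1 = theta[: 3 * H].reshape(H, 3)
        b1 = theta[3 * H : 4 * H]
        w2 = theta[4 * H : 5 * H]
        b2 = float(theta[5 * H])
        return MLPParams(w1, b1, w2, b2, self.norm_x, self.norm_y)

    def to_json(self, path: str | Path, record: "TrainRecord | None" = None) -> None:
        payload = {
            "hidden": self.hidden,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "norm_x": {"n_min": self.norm_x.n_min.tolist(),
                       "n_max": self.norm_x.n_max.tolist()},
            "norm_y": {"n_min": self.norm_y.n_min.tolist(),
                       "n_max": self.norm_y.n_max.tolist()},
        }
        if record is not None:
            payload["train_record"] = record.to_dict()
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MLPParams":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["w1"]), np.array(d["b1"]), np.array(d["w2"]), d["b2"],
            NormalizationSpec(np.array(d["norm_x"]["n_min"]),
                              np.array(d["norm_x"]["n_max"])),
            NormalizationSpec(np.array(d["norm_y"]["n_min"]),
                              np.array(d["norm_y"]["n_max"])),
        )


def _forward_norm(theta_params: MLPParams, xn: np.ndarray) -> np.ndarray:
    """Forward pass on already-normalized inputs; returns normalized output."""
    a = tansig(xn @ theta_params.w1.T + theta_params.b1)
    return a @ theta_params.w2 + theta_params.b2


def forward(params: MLPParams, x_actual: np.ndarray) -> float | np.ndarray:
    """Network prediction in actual units (percent yield).

    Normalizes the inputs, evaluates purelin(w2 . tansig(w1 x + b1) + b2),
    and denormalizes the output.
    """
    x = np.asarray(x_actual, dtype=float)
    single = x.ndim == 1
    xn = normalize(np.atleast_2d(x), params.norm_x)
    yn = _forward_norm(params, xn)
    y = denormalize(yn, params.norm_y)
    return float(y[0]) if single else y


@dataclass
class TrainRecord:
    """Split indices, per-epoch losses and stopping diagnostics of one run."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    mse_history: list[tuple[float, float, float]] = field(default_factory=list)
    stop_reason: str = ""
    final_epoch: int = 0
    best_epoch: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "train_idx": np.asarray(self.train_idx).tolist(),
            "val_idx": np.asarray(self.val_idx).tolist(),
            "test_idx": np.asarray(self.test_idx).tolist(),
            "mse_history": [list(t) for t in self.mse_history],
            "stop_reason": self.stop_reason,
            "final_epoch": self.final_epoch,
            "best_epoch": self.best_epoch,
            "seed": self.seed,
        }

    @property
    def best_val_mse(self) -> float:
        if not self.mse_history:
            return float("nan")
        return self.mse_history[self.best_epoch][1]


def split_data(
    n: int,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint train/validation/test partition of ``range(n)``.

    Subset sizes are ``round(n*f)`` repaired (the last subset absorbs the
    rounding remainder) so they sum to ``n``.  Reproducible when ``rng`` is
    a seed.
    """
    if n < 3:
        raise ValueError("need at least 3 samples to split three ways")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    sizes = [int(round(n * f)) for f in fractions]
    sizes[-1] += n - sum(sizes)  # test subset absorbs the rounding remainder
    if min(sizes) < 0:
        raise ValueError(f"fractions {fractions} give negative subset for n={n}")
    rng = np.random.default_rng(rng)
    perm = rng.permutation(n)
    cut1, cut2 = sizes[0], sizes[0] + sizes[1]
    return perm[:cut1], perm[cut1:cut2], perm[cut2:]


@dataclass
class TrainConfig:
    """Levenberg-Marquardt training settings.

    Defaults: 1000-epoch cap, MSE goal 1e-5 (normalized scale), gradient
    floor 1e-6, max_fail 6 consecutive validation increases, initial damping
    mu=1e-3 with x10 adaptation and overflow at 1e10.
    """

    epochs: int = 1000
    goal: float = 1e-5
    min_grad: float = 1e-6
    max_fail: int = 6
    mu_init: float = 1e-3
    mu_factor: float = 10.0
    mu_max: float = 1e10
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    init_scale: float = 0.5  # uniform(-scale, scale) weight initialization


def init_params(
    table: DesignTable, H: int, rng: np.random.Generator, scale: float = 0.5
) -> MLPParams:
    """Random uniform(-scale, scale) 3-H-1 network with data-driven bounds.

    Normalization bounds come from all runs of the table (inputs and
    response alike), so forward passes are independent of any train/val/test
    subsetting.
    """
    norm_x = NormalizationSpec.from_data(table.actual_levels())
    norm_y = NormalizationSpec.from_data(table.response)
    return MLPParams(
        w1=rng.uniform(-scale, scale, (H, 3)),
        b1=rng.uniform(-scale, scale, H),
        w2=rng.uniform(-scale, scale, H),
        b2=float(rng.uniform(-scale, scale)),
        norm_x=norm_x,
        norm_y=norm_y,
    )


def _jacobian(params: MLPParams, xn: np.ndarray) -> np.ndarray:
    """Jacobian of per-sample network outputs w.r.t. the flat parameters.

    Rows are samples, columns follow ``MLPParams.to_vector`` order
    (w1, b1, w2, b2).  For error e = yhat - y, dE/dtheta equals this
    Jacobian (backpropagation in closed form for one hidden layer).
    """
    n = xn.shape[0]
    H = params.hidden
    z = xn @ params.w1.T + params.b1          # (n, H)
    a = tansig(z)
    da = 1.0 - a**2                           # tansig'
    # d yhat / d w1[h, j] = w2[h] * da[:, h] * xn[:, j]
    g_hidden = params.w2 * da                 # (n, H)
    J_w1 = (g_hidden[:, :, None] * xn[:, None, :]).reshape(n, 3 * H)
    J_b1 = g_hidden
    J_w2 = a
    J_b2 = np.ones((n, 1))
    return np.hstack([J_w1, J_b1, J_w2, J_b2])


def _mse(params: MLPParams, xn: np.ndarray, yn: np.ndarray) -> float:
    e = _forward_norm(params, xn) - yn
    return float(np.mean(e**2))


def train_lm(
    table: DesignTable,
    H: int,
    config: TrainConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[MLPParams, TrainRecord]:
    """One Levenberg-Marquardt training run with validation early stopping.

    Returns the parameters of the best-validation epoch and the full
    training record (realized split, per-epoch train/val/test MSE on the
    normalized scale, stopping reason).
    """
    cfg = config or TrainConfig()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    params = init_params(table, H, rng, cfg.init_scale)

    xn_all = normalize(table.actual_levels(), params.norm_x)
    yn_all = normalize(table.response, params.norm_y)
    tr, va, te = split_data(table.n_runs, cfg.fractions, rng)
    record = TrainRecord(tr, va, te, seed=seed)

    xt, yt = xn_all[tr], yn_all[tr]

    theta = params.to_vector()
    mu = cfg.mu_init
    n_params = theta.size
    eye = np.eye(n_params)

    def losses(p: MLPParams) -> tuple[float, float, float]:
        return (
            _mse(p, xt, yt),
            _mse(p, xn_all[va], yn_all[va]) if len(va) else float("nan"),
            _mse(p, xn_all[te], yn_all[te]) if len(te) else float("nan"),
        )

    cur = params.with_vector(theta)
    record.mse_history.append(losses(cur))
    best_theta = theta.copy()
    best_val = record.mse_history[0][1]
    fails = 0
    stop = "epochs"
    epoch = 0

    for epoch in range(1, cfg.epochs + 1):
        e = _forward_norm(cur, xt) - yt
        sse = float(e @ e)
        if not np.isfinite(sse):
            raise TrainingDivergedError(epoch)
        J = _jacobian(cur, xt)
        grad = J.T @ e
        if np.max(np.abs(grad)) < cfg.min_grad:
            stop = "gradient"
            break
        JtJ = J.T @ J
        # inner damping loop: grow mu until a step reduces the training SSE
        accepted = False
        while mu <= cfg.mu_max:
            try:
                delta = np.linalg.solve(JtJ + mu * eye, grad)
            except np.linalg.LinAlgError:
                mu *= cfg.mu_factor
                continue
            trial = cur.with_vector(theta - delta)
            e_trial = _forward_norm(trial, xt) - yt
            sse_trial = float(e_trial @ e_trial)
            if np.isfinite(sse_trial) and sse_trial < sse:
                theta = theta - delta
                cur = trial
                mu = max(mu / cfg.mu_factor, 1e-20)
                accepted = True
                break
            mu *= cfg.mu_factor
        if not accepted:
            stop = "mu_overflow"
            break

        tr_mse, val_mse, te_mse = losses(cur)
        record.mse_history.append((tr_mse, val_mse, te_mse))
        if len(va) and np.isfinite(val_mse) and val_mse < best_val:
            best_val = val_mse
            best_theta = theta.copy()
            record.best_epoch = epoch
            fails = 0
        elif len(va):
            fails += 1
            if fails >= cfg.max_fail:
                stop = "validation"
                break
        else:
            best_theta = theta.copy()
            record.best_epoch = epoch
        if tr_mse <= cfg.goal:
            stop = "goal"
            break

    record.final_epoch = epoch
    record.stop_reason = stop
    return cur.with_vector(best_theta), record


def train_multistart(
    table: DesignTable,
    H: int,
    restarts: int,
    seed: int | None = None,
    config: TrainConfig | None = None,
) -> list[tuple[MLPParams, TrainRecord]]:
    """Independent LM runs from ``restarts`` random initializations.

    Child seeds are spawned deterministically from ``seed``; results are in
    restart order.  Callers pick the best run by validation MSE or by
    whole-data fit, depending on purpose.
    """
    root = np.random.default_rng(seed)
    out = []
    for _ in range(restarts):
        child = np.random.default_rng(root.integers(2**31))
        out.append(train_lm(table, H, config, child))
    return out


def best_by_validation(
    runs: Sequence[tuple[MLPParams, TrainRecord]],
) -> tuple[MLPParams, TrainRecord]:
    """The run with the lowest best-validation-epoch MSE."""
    return min(runs, key=lambda pr: pr[1].best_val_mse)


def neuron_sweep(
    table: DesignTable,
    H_range: Sequence[int],
    restarts: int = 20,
    seed: int | None = None,
    config: TrainConfig | None = None,
) -> list[tuple[int, float]]:
    """Best validation-epoch MSE per hidden-layer size.

    For each H in ``H_range``, trains ``restarts`` networks and records the
    lowest best-validation MSE; reproducible under ``seed``.
    """
    out = []
    for k, H in enumerate(H_range):
        runs = train_multistart(
            table, H, restarts,
            seed=None if seed is None else seed + 7919 * k,
            config=config,
        )
        out.append((H, best_by_validation(runs)[1].best_val_mse))
    return out
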