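"""Synthetic data with known ground truth for every pipeline stage.

Three generators cover the three kinds of raw input the pipeline consumes:

* noisy quadratic response surfaces evaluated on a Box-Behnken design
  (known coefficients, i.i.d. Gaussian error) -- exercises the fitting,
  ANOVA and optimization stages;
* fluorescence-decay plates whose net AUC is planted analytically from
  target Trolox-equivalent values -- exercises the ORAC chain end to end;
* linear calibration series with Gaussian noise.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .assay import LinearCalibration
from .design import DesignTable
from .rsm import QuadraticModel, design_matrix

__all__ = [
    "SurfaceTruth",
    "gen_surface",
    "gen_calibration",
    "gen_plate",
    "curve_with_auc",
    "TROLOX_STANDARDS_UM",
]

#: Trolox standard-curve concentrations (uM) spanning the usual assay range.
TROLOX_STANDARDS_UM = (6.25, 12.5, 25.0, 50.0)


@dataclass
class SurfaceTruth:
    """Ground-truth quadratic surface: 10 coefficients plus noise level."""

    b0: float
    b_lin: np.ndarray
    b_int: np.ndarray
    b_quad: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.b_lin = np.asarray(self.b_lin, dtype=float).reshape(3)
        self.b_int = np.asarray(self.b_int, dtype=float).reshape(3)
        self.b_quad = np.asarray(self.b_quad, dtype=float).reshape(3)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def from_model(cls, model: QuadraticModel, noise_sd: float = 0.0) -> "SurfaceTruth":
        return cls(model.b0, model.b_lin.copy(), model.b_int.copy(),
                   model.b_quad.copy(), noise_sd)

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate(([self.b0], self.b_lin, self.b_int, self.b_quad))


def gen_surface(
    truth: SurfaceTruth,
    design: DesignTable,
    rng: np.random.Generator | int | None = None,
) -> DesignTable:
    """Responses = quadratic(truth) + N(0, noise_sd) at the design's runs."""
    rng = np.random.default_rng(rng)
    mean = design_matrix(design.coded) @ truth.coefficients
    noise = rng.normal(0.0, truth.noise_sd, design.n_runs) if truth.noise_sd else 0.0
    return design.with_response(mean + noise)


def gen_calibration(
    slope: float,
    intercept: float,
    x_grid: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) series with y = slope*x + intercept + N(0, noise_sd)."""
    x = np.asarray(x_grid, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 grid points")
    rng = np.random.default_rng(rng)
    y = slope * x + intercept
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd, x.size)
    return x, y


def curve_with_auc(
    target_auc: float,
    n_readings: int = 60,
    interval_min: float = 2.0,
    f0: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A geometric fluorescence-decay curve with an exact ratio-sum AUC.

    Readings are ``f_i = f_0 * rho^i`` with ``rho`` solved so that
    ``1 + sum_{i=1..n} rho^i == target_auc``.  The ratio-sum AUC depends
    only on the ratios, so the decay shape is a free modelling choice.
    Requires ``1 < target_auc < 1 + n_readings``.
    """
    if not 1.0 < target_auc < 1.0 + n_readings:
        raise ValueError(
            f"target AUC {target_auc} not reachable with {n_readings} readings"
        )
    s = target_auc - 1.0

    def gap(rho: float) -> float:
        return rho * (1 - rho**n_readings) / (1 - rho) - s

    rho = brentq(gap, 1e-12, 1 - 1e-12, xtol=1e-15)
    times = np.arange(n_readings + 1) * interval_min
    f = f0 * rho ** np.arange(n_readings + 1)
    return times, f


def gen_plate(
    te_values: list[float],
    calibration: LinearCalibration,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    blank_auc: float = 12.0,
    n_readings: int = 60,
    interval_min: float = 2.0,
) -> pd.DataFrame:
    """A synthetic ORAC plate (long CSV layout: well, role, conc, t0, t2, ...).

    Sample wells are built so net AUC = slope*TE + intercept (+ Gaussian
    noise); blank (AAPH, no antioxidant) and Trolox-standard wells on the
    usual 6.25-50 uM grid are included, standards planted exactly on the
    calibration line.
    """
    if calibration.slope <= 0:
        raise ValueError("calibration slope must be positive")
    rng = np.random.default_rng(rng)
    rows: list[dict] = []
    times = np.arange(n_readings + 1) * interval_min

    def add_well(well: str, role: str, conc: float, auc: float) -> None:
        _, f = curve_with_auc(auc, n_readings, interval_min)
        row = {"well": well, "role": role, "conc": conc}
        row.update({f"t{int(t)}": v for t, v in zip(times, f)})
        rows.append(row)

    add_well("A1", "blank", 0.0, blank_auc)
    for k, conc in enumerate(TROLOX_STANDARDS_UM):
        net = calibration.slope * conc + calibration.intercept
        add_well(f"B{k + 1}", "trolox", conc, blank_auc + net)
    for k, te in enumerate(te_values):
        net = calibration.slope * te + calibration.intercept
        if noise_sd:
            net += rng.normal(0.0, noise_sd)
        add_well(f"C{k + 1}", "sample", np.nan, blank_auc + net)
    return pd.DataFrame(rows)
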