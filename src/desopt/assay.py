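"""Wet-assay calculators: Folin-Ciocalteu total phenolics and ORAC.

Total-phenolics yield converts a calibrated concentration reading into
percent of dry sample mass, ``Y = 100 * C * V * r / W`` (C in g/mL, V the
extract volume in mL, r the dilution ratio, W the dry mass in g).

The ORAC (oxygen radical absorbance capacity) assay tracks the decay of
fluorescein under AAPH-generated peroxyl radicals.  Each well's kinetic
trace is summarized by the ratio-sum area under the curve,
``AUC = 1 + sum_i f_i / f_0`` -- a plain sum of readings relative to the
initial one, no trapezoid correction.  Antioxidant capacity is the net AUC
(sample minus the radical-only blank) interpolated on a Trolox standard
curve of net AUC versus concentration, reported as Trolox equivalents
(umol TE); a single-point ratio against one Trolox standard is available
as a secondary path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AssayInput",
    "LinearCalibration",
    "FluorescenceCurve",
    "OracResult",
    "polyphenol_yield",
    "fit_calibration",
    "auc_curve",
    "orac_te",
    "read_plate",
    "orac_from_plate",
]


@dataclass(frozen=True)
class AssayInput:
    """Inputs of the total-phenolics yield computation (all > 0)."""

    concentration: float  # C, g/mL from the calibration line
    volume: float         # V, mL
    dilution: float       # r, dimensionless
    dry_mass: float       # W, g

    def __post_init__(self) -> None:
        for name in ("concentration", "volume", "dilution", "dry_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def polyphenol_yield(inp: AssayInput) -> float:
    """Total phenolics as percent of dry mass: 100 * C * V * r / W."""
    return 100.0 * inp.concentration * inp.volume * inp.dilution / inp.dry_mass


@dataclass(frozen=True)
class LinearCalibration:
    """A fitted calibration line y = slope*x + intercept with its r^2."""

    slope: float
    intercept: float
    r2: float = float("nan")
    x_units: str = ""
    y_units: str = ""

    def invert(self, y: float) -> float:
        """x at which the line predicts y."""
        return (y - self.intercept) / self.slope


def fit_calibration(
    x: Sequence[float], y: Sequence[float], x_units: str = "", y_units: str = ""
) -> LinearCalibration:
    """Ordinary-least-squares calibration line through (x, y) pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: constant x")
    res = stats.linregress(x, y)
    return LinearCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        x_units=x_units,
        y_units=y_units,
    )


@dataclass
class FluorescenceCurve:
    """One well's kinetic trace: readings f on a strictly increasing time grid."""

    times: np.ndarray  # minutes, first entry is the baseline reading time
    f: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.f.size == 0:
            raise ValueError("empty fluorescence curve")
        if self.times.shape != self.f.shape:
            raise ValueError("times and readings have different lengths")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.f[0] <= 0:
            raise ValueError("initial fluorescence f_0 must be positive")

    @property
    def f0(self) -> float:
        return float(self.f[0])


def auc_curve(curve: FluorescenceCurve) -> float:
    """Ratio-sum area under the curve: 1 + sum_{i>=1} f_i / f_0."""
    return 1.0 + float(np.sum(curve.f[1:] / curve.f0))


@dataclass
class OracResult:
    """Net AUC and its Trolox-equivalent conversion for one sample."""

    auc_sample: float
    auc_blank: float
    net_auc: float
    te: float            # umol Trolox equivalents (per g after mass scaling)
    auc_trolox: float = float("nan")   # single-point path only


def orac_te(
    sample: FluorescenceCurve,
    blank: FluorescenceCurve,
    calibration: LinearCalibration | None = None,
    trolox_curves: Sequence[tuple[float, FluorescenceCurve]] | None = None,
    mass_basis: float = 1.0,
) -> OracResult:
    """Trolox-equivalent antioxidant capacity of one sample well.

    ``blank`` is the radical-only (AAPH, no antioxidant) well.  The primary
    path interpolates net AUC on a ``calibration`` line of net AUC versus
    Trolox concentration (uM); alternatively ``trolox_curves`` gives
    (concentration, curve) standards for the single-point ratio path.
    ``mass_basis`` converts the concentration (uM) into umol TE per g dry
    weight for the plated sample amount.  Negative TE is clamped to zero.
    """
    auc_s = auc_curve(sample)
    auc_b = auc_curve(blank)
    net = auc_s - auc_b
    auc_t = float("nan")
    if calibration is not None:
        if calibration.slope <= 0:
            raise ValueError("invalid calibration: slope must be positive")
        te_conc = calibration.invert(net)
    elif trolox_curves:
        ratios = []
        for conc, tc in trolox_curves:
            auc_t = auc_curve(tc)
            net_t = auc_t - auc_b
            if net_t <= 0:
                raise ValueError("Trolox standard has nonpositive net AUC")
            ratios.append(net / net_t * conc)
        te_conc = float(np.mean(ratios))
    else:
        raise ValueError("provide either a calibration line or Trolox standards")
    if te_conc < 0:
        warnings.warn("negative Trolox equivalence clamped to 0", stacklevel=2)
        te_conc = 0.0
    return OracResult(
        auc_sample=auc_s,
        auc_blank=auc_b,
        net_auc=net,
        te=te_conc * mass_basis,
        auc_trolox=auc_t,
    )


def read_plate(path) -> "pd.DataFrame":
    """Read a plate CSV (``well,role,conc,t0,t2,...``) into a data frame."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"well", "role", "conc"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate CSV must have columns {sorted(required)} plus t* readings")
    tcols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    if not tcols:
        raise ValueError("plate CSV has no time-point columns (t0, t2, ...)")
    return df


def _well_curve(row, tcols) -> FluorescenceCurve:
    times = np.array([float(c[1:]) for c in tcols])
    return FluorescenceCurve(times, row[tcols].to_numpy(dtype=float))


def orac_from_plate(path, mass_basis: float = 1.0) -> tuple[LinearCalibration, list[OracResult]]:
    """Full ORAC workup of one plate CSV.

    Fits the net-AUC-versus-concentration calibration from the Trolox
    standard wells (net relative to the mean AAPH-blank AUC) and returns it
    with one :class:`OracResult` per sample well.
    """
    df = read_plate(path)
    tcols = sorted(
        (c for c in df.columns if c.startswith("t") and c[1:].isdigit()),
        key=lambda c: float(c[1:]),
    )
    blanks = df[df["role"] == "blank"]
    standards = df[df["role"] == "trolox"]
    samples = df[df["role"] == "sample"]
    if blanks.empty or standards.empty:
        raise ValueError("plate needs at least one blank and one trolox well")
    blank_curves = [_well_curve(r, tcols) for _, r in blanks.iterrows()]
    blank_auc = float(np.mean([auc_curve(c) for c in blank_curves]))
    concs = standards["conc"].to_numpy(dtype=float)
    nets = np.array(
        [auc_curve(_well_curve(r, tcols)) - blank_auc for _, r in standards.iterrows()]
    )
    cal = fit_calibration(concs, nets, x_units="uM Trolox", y_units="net AUC")
    results = [
        orac_te(_well_curve(r, tcols), blank_curves[0], calibration=cal,
                mass_basis=mass_basis)
        for _, r in samples.iterrows()
    ]
    return cal, results
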