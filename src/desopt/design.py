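"""Box-Behnken designs and coded/actual factor-level bookkeeping.

A three-level Box-Behnken design (BBD) for :math:`k` factors places runs at
the midpoints of the edges of the factor cube -- every pair of factors at
coded levels :math:`\\pm 1` with the remaining factor at 0 -- plus replicated
centre runs used to estimate pure error.  For three factors this gives
:math:`12 + n_c` runs.

Factor levels are handled in two unit systems: *actual* units (mL/g, W, min)
and *coded* units, where the low/centre/high levels map to -1/0/+1 via
half-range scaling.  All model fitting downstream happens in coded units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "DesignError",
    "build_bbd",
    "code_level",
    "decode_level",
    "load_design",
    "write_design",
    "load_table1",
    "table1_factors",
]


class DesignError(ValueError):
    """Invalid design construction or design-table validation failure."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its three BBD levels in actual units.

    ``low``, ``center`` and ``high`` are the actual values at coded levels
    -1, 0 and +1.  Levels must be equispaced (centre at the midpoint).
    """

    name: str
    units: str
    low: float
    center: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low < self.center < self.high):
            raise DesignError(
                f"factor {self.name!r}: levels must satisfy low < center < high, "
                f"got {self.low}, {self.center}, {self.high}"
            )
        mid = 0.5 * (self.low + self.high)
        scale = max(abs(self.low), abs(self.high), 1.0)
        if abs(self.center - mid) > 1e-9 * scale:
            raise DesignError(
                f"factor {self.name!r}: center {self.center} is not the midpoint "
                f"of ({self.low}, {self.high})"
            )

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


def code_level(actual: float, factor: FactorSpec) -> float:
    """Map an actual factor value to coded units ((actual - center)/half-range)."""
    if factor.high == factor.low:
        raise DesignError(f"factor {factor.name!r} is degenerate (high == low)")
    return (actual - factor.center) / factor.half_range


def decode_level(coded: float, factor: FactorSpec) -> float:
    """Inverse of :func:`code_level`: coded units back to actual units."""
    return factor.center + coded * factor.half_range


@dataclass
class DesignTable:
    """A design with coded run levels and (optionally) measured responses.

    ``coded`` is an (n_runs, n_factors) array; ``response`` is an (n_runs,)
    array with NaN for runs that have not been measured.  Responses are
    stored as percent yield (13.36 means 13.36%).
    """

    factors: list[FactorSpec]
    coded: np.ndarray
    response: np.ndarray
    run_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coded = np.atleast_2d(np.asarray(self.coded, dtype=float))
        n = self.coded.shape[0]
        if self.response is None:
            self.response = np.full(n, np.nan)
        self.response = np.asarray(self.response, dtype=float)
        if self.run_ids is None:
            self.run_ids = np.arange(1, n + 1)
        self.run_ids = np.asarray(self.run_ids)
        if self.coded.shape[1] != len(self.factors):
            raise DesignError(
                f"coded levels have {self.coded.shape[1]} columns for "
                f"{len(self.factors)} factors"
            )
        if len(self.response) != n or len(self.run_ids) != n:
            raise DesignError("run_ids, coded and response lengths disagree")

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def has_responses(self) -> bool:
        return bool(np.all(np.isfinite(self.response)))

    def actual_levels(self) -> np.ndarray:
        """Run levels in actual units, (n_runs, n_factors)."""
        half = np.array([f.half_range for f in self.factors])
        center = np.array([f.center for f in self.factors])
        return center + self.coded * half

    def center_mask(self) -> np.ndarray:
        """Boolean mask of all-zero (centre) runs."""
        return np.all(self.coded == 0.0, axis=1)

    def with_response(self, response: Sequence[float]) -> "DesignTable":
        resp = np.asarray(response, dtype=float)
        if resp.shape != (self.n_runs,):
            raise DesignError("response length does not match number of runs")
        return DesignTable(self.factors, self.coded.copy(), resp, self.run_ids.copy())

    def to_frame(self, coded: bool = False) -> pd.DataFrame:
        levels = self.coded if coded else self.actual_levels()
        df = pd.DataFrame(levels, columns=[f.name for f in self.factors])
        df.insert(0, "run", self.run_ids)
        df["response"] = self.response
        return df


def build_bbd(factors: Sequence[FactorSpec], n_center: int) -> DesignTable:
    """Construct a three-factor Box-Behnken design.

    Returns the 12 edge-midpoint runs (each factor pair at the four
    :math:`(\\pm 1, \\pm 1)` combinations, third factor at 0, pairs in
    lexicographic order with sign order (-,-), (+,-), (-,+), (+,+))
    followed by ``n_center`` centre runs.  Responses are absent (NaN).
    """
    factors = list(factors)
    if len(factors) != 3:
        raise DesignError(
            f"only the 3-factor Box-Behnken design is supported, got {len(factors)} factors"
        )
    if n_center < 1:
        raise DesignError("n_center must be >= 1")
    rows = []
    for i, j in itertools.combinations(range(3), 2):
        for signs in ((-1.0, -1.0), (1.0, -1.0), (-1.0, 1.0), (1.0, 1.0)):
            row = [0.0, 0.0, 0.0]
            row[i], row[j] = signs
            rows.append(row)
    rows.extend([[0.0, 0.0, 0.0]] * n_center)
    coded = np.array(rows)
    return DesignTable(factors, coded, np.full(len(rows), np.nan))


def table1_factors() -> list[FactorSpec]:
    """The three extraction factors at their published BBD levels."""
    return [
        FactorSpec("liquid_solid_ratio", "mL/g", 20.0, 30.0, 40.0),
        FactorSpec("ultrasonic_power", "W", 450.0, 600.0, 750.0),
        FactorSpec("extraction_time", "min", 30.0, 40.0, 50.0),
    ]


def _infer_factor_spec(name: str, values: np.ndarray) -> FactorSpec:
    levels = np.unique(values)
    if len(levels) != 3:
        raise DesignError(
            f"column {name!r}: expected 3 distinct levels for a BBD factor, "
            f"found {len(levels)}"
        )
    return FactorSpec(name, "", float(levels[0]), float(levels[1]), float(levels[2]))


def load_design(
    path: str | Path,
    factors: Sequence[FactorSpec] | None = None,
    coded: bool = False,
) -> DesignTable:
    """Read a design CSV (``run,<f1>,<f2>,<f3>,response``) into a DesignTable.

    Factor columns are in actual units unless ``coded=True``.  If ``factors``
    is omitted, each factor's three levels are inferred from the column's
    distinct values (valid only for complete BBD tables in actual units).
    Declared-BBD validation rejects coded levels outside [-1, 1].
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DesignError(f"{path}: empty design file") from None
    if df.shape[0] == 0:
        raise DesignError(f"{path}: design file has no runs")
    cols = list(df.columns)
    if cols[0] != "run" or cols[-1] != "response" or len(cols) < 3:
        raise DesignError(
            f"{path}: expected header 'run,<factors...>,response', got {cols}"
        )
    factor_names = cols[1:-1]
    for col in cols[1:]:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            raise DesignError(
                f"{path}: non-numeric value in column {col!r}, row {bad.index[0] + 2}"
            )
    values = df[factor_names].to_numpy(dtype=float)
    if factors is None:
        if coded:
            factors = [FactorSpec(n, "", -1.0, 0.0, 1.0) for n in factor_names]
        else:
            factors = [
                _infer_factor_spec(n, values[:, k]) for k, n in enumerate(factor_names)
            ]
    else:
        factors = list(factors)
        if [f.name for f in factors] != factor_names:
            raise DesignError(
                f"{path}: factor columns {factor_names} do not match specs "
                f"{[f.name for f in factors]}"
            )
    if coded:
        coded_levels = values
    else:
        coded_levels = np.column_stack(
            [ [code_level(v, f) for v in values[:, k]] for k, f in enumerate(factors) ]
        )
    out_of_range = np.abs(coded_levels) > 1 + 1e-9
    if out_of_range.any():
        r, c = np.argwhere(out_of_range)[0]
        raise DesignError(
            f"{path}: coded level outside [-1, 1] at row {r + 2}, "
            f"column {factor_names[c]!r}"
        )
    response = df["response"].to_numpy(dtype=float)
    return DesignTable(factors, coded_levels, response, df["run"].to_numpy())


def write_design(table: DesignTable, path: str | Path, coded: bool = False) -> None:
    """Write a design table as CSV; round-trips bit-exactly in decimal text."""
    df = table.to_frame(coded=coded)
    df.to_csv(path, index=False)


def load_table1() -> DesignTable:
    """The packaged 17-run extraction design with measured yields."""
    with resources.as_file(
        resources.files("desopt.fixtures").joinpath("table1.csv")
    ) as p:
        return load_design(p, factors=table1_factors())
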