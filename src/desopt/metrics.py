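"""Model-comparison statistics over paired predicted/observed responses.

Five statistics are reported for each model:

* ``r2``   — 1 - SS_err/SS_tot about the observed mean,
* ``mse``  — mean squared error with denominator n,
* ``rmse`` — square root of the MSE,
* ``aad_relative_percent`` — mean absolute deviation relative to each
  observation, times 100 (the textbook "absolute average deviation"),
* ``mad``  — plain mean absolute deviation in response units.

Both absolute-deviation flavours are kept because published comparison
tables in this domain frequently label the unnormalized ``mad`` as "AAD";
the two differ by the per-observation scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PredictionPairs", "MetricReport", "compare"]


@dataclass
class PredictionPairs:
    """Paired model predictions and observed values."""

    predicted: np.ndarray
    actual: np.ndarray

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float).ravel()
        self.actual = np.asarray(self.actual, dtype=float).ravel()
        if self.predicted.size != self.actual.size:
            raise ValueError("predicted and actual lengths differ")
        if self.predicted.size < 2:
            raise ValueError("need at least 2 pairs")

    @property
    def n(self) -> int:
        return self.predicted.size

    @property
    def actual_mean(self) -> float:
        return float(self.actual.mean())


@dataclass
class MetricReport:
    r2: float
    mse: float
    rmse: float
    aad_relative_percent: float
    mad: float


def compare(pairs: PredictionPairs) -> MetricReport:
    """Compute the five comparison statistics for one model's predictions."""
    err = pairs.predicted - pairs.actual
    mse = float(np.mean(err**2))
    ss_tot = float(np.sum((pairs.actual - pairs.actual_mean) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    mad = float(np.mean(np.abs(err)))
    if np.any(pairs.actual == 0.0):
        raise ZeroDivisionError(
            "zero observed value: relative AAD is undefined (use mad)"
        )
    aad = 100.0 * float(np.mean(np.abs(err) / np.abs(pairs.actual)))
    return MetricReport(
        r2=r2, mse=mse, rmse=float(np.sqrt(mse)),
        aad_relative_percent=aad, mad=mad,
    )
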