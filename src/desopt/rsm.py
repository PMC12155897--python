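"""Second-order response-surface fitting and ANOVA in coded units.

The response is modelled as the full 10-term quadratic

.. math::

    y = b_0 + \\sum_i b_i x_i + \\sum_{i<j} b_{ij} x_i x_j + \\sum_i b_{ii} x_i^2

with the :math:`x_i` in coded units.  Coefficients come from ordinary least
squares on the design runs.  The ANOVA partitions the corrected total sum of
squares into model and residual parts, splits the residual into lack-of-fit
and pure error using replicate centre runs, and reports per-term partial
(Type-III) sums of squares :math:`b_j^2 / c_{jj}`, where :math:`c_{jj}` is
the corresponding diagonal of the inverse normal matrix.  Partial SS is the
convention that handles the non-orthogonality of the pure-quadratic columns
with the intercept; sequential (Type-I) SS is available as an option.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignTable, FactorSpec

__all__ = [
    "QuadraticModel",
    "AnovaTable",
    "SingularDesignError",
    "fit_quadratic",
    "predict",
    "anova",
    "TERM_NAMES",
]

#: Column order of the quadratic design matrix (after the intercept).
TERM_NAMES = ("x1", "x2", "x3", "x1:x2", "x1:x3", "x2:x3", "x1^2", "x2^2", "x3^2")

_PAIRS = ((0, 1), (0, 2), (1, 2))


class SingularDesignError(ValueError):
    """The 10-term quadratic design matrix is rank deficient."""


@dataclass
class QuadraticModel:
    """Fitted quadratic response surface in coded units.

    ``b_int`` holds the interaction coefficients for the factor pairs
    (1,2), (1,3), (2,3); ``b_quad`` the pure-quadratic coefficients.
    """

    b0: float
    b_lin: np.ndarray
    b_int: np.ndarray
    b_quad: np.ndarray
    factors: list[FactorSpec]
    n_runs: int = 0

    def __post_init__(self) -> None:
        self.b_lin = np.asarray(self.b_lin, dtype=float).reshape(3)
        self.b_int = np.asarray(self.b_int, dtype=float).reshape(3)
        self.b_quad = np.asarray(self.b_quad, dtype=float).reshape(3)

    @property
    def coefficients(self) -> np.ndarray:
        """All 10 coefficients in design-matrix order."""
        return np.concatenate(([self.b0], self.b_lin, self.b_int, self.b_quad))

    def quadratic_form(self) -> np.ndarray:
        """Symmetric matrix B with b_quad on the diagonal and b_int/2 off it."""
        B = np.diag(self.b_quad)
        for k, (i, j) in enumerate(_PAIRS):
            B[i, j] = B[j, i] = 0.5 * self.b_int[k]
        return B

    def to_json(self, path: str | Path) -> None:
        payload = {
            "b0": self.b0,
            "b_lin": self.b_lin.tolist(),
            "b_int": self.b_int.tolist(),
            "b_quad": self.b_quad.tolist(),
            "n_runs": self.n_runs,
            "factors": [
                {"name": f.name, "units": f.units, "low": f.low,
                 "center": f.center, "high": f.high}
                for f in self.factors
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "QuadraticModel":
        d = json.loads(Path(path).read_text())
        factors = [FactorSpec(**f) for f in d["factors"]]
        return cls(d["b0"], np.array(d["b_lin"]), np.array(d["b_int"]),
                   np.array(d["b_quad"]), factors, d.get("n_runs", 0))


def design_matrix(coded: np.ndarray) -> np.ndarray:
    """10-column quadratic design matrix for coded run levels (n, 3)."""
    x = np.atleast_2d(np.asarray(coded, dtype=float))
    cols = [np.ones(x.shape[0])]
    cols.extend(x[:, i] for i in range(3))
    cols.extend(x[:, i] * x[:, j] for i, j in _PAIRS)
    cols.extend(x[:, i] ** 2 for i in range(3))
    return np.column_stack(cols)


def fit_quadratic(table: DesignTable) -> QuadraticModel:
    """Ordinary-least-squares fit of the full quadratic in coded units."""
    if not table.has_responses:
        raise ValueError("design table has missing responses")
    D = design_matrix(table.coded)
    if table.n_runs < 10:
        raise ValueError(f"need >= 10 runs with responses, got {table.n_runs}")
    rank = np.linalg.matrix_rank(D)
    if rank < 10:
        # name the collinear columns for the error message
        _, r = np.linalg.qr(D)
        dep = [("intercept",) + TERM_NAMES][0]
        bad = [dep[i] for i in range(10) if abs(r[i, i]) < 1e-10 * abs(r[0, 0])]
        raise SingularDesignError(
            f"quadratic design matrix is rank deficient (rank {rank}); "
            f"collinear columns: {bad}"
        )
    beta, *_ = np.linalg.lstsq(D, table.response, rcond=None)
    return QuadraticModel(
        b0=float(beta[0]),
        b_lin=beta[1:4],
        b_int=beta[4:7],
        b_quad=beta[7:10],
        factors=list(table.factors),
        n_runs=table.n_runs,
    )


def predict(model: QuadraticModel, point: np.ndarray) -> float | np.ndarray:
    """Evaluate the quadratic at one or more coded points."""
    pt = np.asarray(point, dtype=float)
    single = pt.ndim == 1
    vals = design_matrix(np.atleast_2d(pt)) @ model.coefficients
    return float(vals[0]) if single else vals


@dataclass
class AnovaTable:
    """ANOVA rows plus fit summary statistics.

    ``rows`` has columns ``source, SS, df, MS, F, p``; lack-of-fit and
    pure-error rows are present only when the design has replicate runs.
    """

    rows: pd.DataFrame
    r2: float
    adj_r2: float
    cv_percent: float
    response_mean: float

    def __getitem__(self, source: str) -> pd.Series:
        hit = self.rows[self.rows["source"] == source]
        if hit.empty:
            raise KeyError(source)
        return hit.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)


def _replicate_groups(coded: np.ndarray) -> list[np.ndarray]:
    """Indices of runs sharing an identical coded level vector (size >= 2)."""
    _, inverse, counts = np.unique(
        coded, axis=0, return_inverse=True, return_counts=True
    )
    return [np.flatnonzero(inverse == g) for g in np.flatnonzero(counts >= 2)]


def anova(
    model: QuadraticModel, table: DesignTable, sequential: bool = False
) -> AnovaTable:
    """ANOVA of a fitted quadratic with lack-of-fit/pure-error partition.

    Per-term SS are partial (Type-III) by default, sequential (Type-I)
    when ``sequential=True``.  F ratios use the residual mean square,
    except lack-of-fit which uses the pure-error mean square.
    """
    y = table.response
    n = table.n_runs
    D = design_matrix(table.coded)
    yhat = D @ model.coefficients
    ybar = float(y.mean())
    ss_total = float(np.sum((y - ybar) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_model = ss_total - ss_res
    df_model, df_res = 9, n - 10
    ms_res = ss_res / df_res
    ms_model = ss_model / df_model

    rows: list[dict] = []

    def frow(source, ss, df, denom=None):
        ms = ss / df
        if denom is None:
            rows.append({"source": source, "SS": ss, "df": df, "MS": ms,
                         "F": np.nan, "p": np.nan})
        else:
            ms_den, df_den = denom
            if ms_den > 0:
                F = ms / ms_den
            else:  # perfect fit: zero denominator mean square
                F = np.inf if ms > 0 else np.nan
            p = float(stats.f.sf(F, df, df_den)) if np.isfinite(F) else (
                0.0 if F == np.inf else np.nan
            )
            rows.append({"source": source, "SS": ss, "df": df, "MS": ms,
                         "F": F, "p": p})

    frow("Model", ss_model, df_model, (ms_res, df_res))

    if sequential:
        # Type-I: incremental SS as terms enter in design-matrix order
        q, r = np.linalg.qr(D)
        proj = q.T @ y
        term_ss = proj[1:] ** 2  # term j's increment, intercept excluded
    else:
        # Type-III partial SS: b_j^2 / c_jj with c = (D'D)^-1
        c = np.linalg.inv(D.T @ D)
        beta = model.coefficients
        term_ss = beta[1:] ** 2 / np.diag(c)[1:]
    for name, ss in zip(TERM_NAMES, term_ss):
        frow(name, float(ss), 1, (ms_res, df_res))

    frow("Residual", ss_res, df_res)

    groups = _replicate_groups(table.coded)
    if groups:
        ss_pe = float(sum(np.sum((y[g] - y[g].mean()) ** 2) for g in groups))
        df_pe = int(sum(len(g) - 1 for g in groups))
        df_lof = df_res - df_pe
        ss_lof = ss_res - ss_pe
        if df_lof > 0 and df_pe > 0:
            ms_pe = ss_pe / df_pe
            frow("Lack of Fit", ss_lof, df_lof, (ms_pe, df_pe))
            frow("Pure Error", ss_pe, df_pe)
        else:
            frow("Pure Error", ss_pe, df_pe)
    else:
        warnings.warn(
            "no replicate runs: lack-of-fit and pure-error rows omitted",
            stacklevel=2,
        )

    frow("Cor Total", ss_total, n - 1)

    r2 = ss_model / ss_total
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_res
    cv = 100.0 * np.sqrt(ms_res) / ybar
    return AnovaTable(
        rows=pd.DataFrame(rows),
        r2=float(r2),
        adj_r2=float(adj_r2),
        cv_percent=float(cv),
        response_mean=ybar,
    )
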