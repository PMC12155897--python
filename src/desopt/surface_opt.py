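"""Optimum location on a fitted quadratic response surface.

Two views of the optimum are provided: the unconstrained stationary point
(solution of :math:`2 B x = -b`, with :math:`B` the quadratic-form matrix
and :math:`b` the linear coefficients, classified by the eigenvalues of
:math:`B`) and the global maximum over a coded box, found by projected
gradient ascent started from a dense grid.  For the packaged extraction
surface the stationary point lies inside the experimental cube, so both
agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .design import decode_level
from .rsm import QuadraticModel, predict

__all__ = ["SurfaceOptimum", "RidgeSystemError", "stationary_point", "maximize_in_box"]

_EIG_TOL = 1e-10


class RidgeSystemError(ValueError):
    """Singular quadratic form: no unique stationary point (ridge system)."""


@dataclass
class SurfaceOptimum:
    """An optimum of the quadratic surface, in coded and actual units."""

    coded_point: np.ndarray
    actual_point: np.ndarray
    predicted_response: float
    nature: str  # "maximum" | "minimum" | "saddle"
    constrained: bool

    def __post_init__(self) -> None:
        self.coded_point = np.asarray(self.coded_point, dtype=float)
        self.actual_point = np.asarray(self.actual_point, dtype=float)


def _classify(B: np.ndarray) -> str:
    eig = np.linalg.eigvalsh(B)
    if np.any(np.abs(eig) <= _EIG_TOL):
        warnings.warn(
            "near-zero eigenvalue of the quadratic form: ridge/degenerate "
            "surface, classified as saddle",
            stacklevel=3,
        )
        return "saddle"
    if np.all(eig < 0):
        return "maximum"
    if np.all(eig > 0):
        return "minimum"
    return "saddle"


def _to_actual(model: QuadraticModel, coded: np.ndarray) -> np.ndarray:
    return np.array(
        [decode_level(c, f) for c, f in zip(coded, model.factors)]
    )


def stationary_point(model: QuadraticModel) -> SurfaceOptimum:
    """Unconstrained stationary point of the fitted surface.

    Solves the linear system from the zero-gradient condition and
    classifies the point by the eigenvalue signs of the quadratic form.
    """
    B = model.quadratic_form()
    if abs(np.linalg.det(B)) < 1e-12 * max(1.0, np.linalg.norm(B) ** 3):
        raise RidgeSystemError(
            "quadratic form is singular (ridge system); use maximize_in_box "
            "over the experimental region instead"
        )
    x = np.linalg.solve(2.0 * B, -model.b_lin)
    return SurfaceOptimum(
        coded_point=x,
        actual_point=_to_actual(model, x),
        predicted_response=predict(model, x),
        nature=_classify(B),
        constrained=False,
    )


def maximize_in_box(
    model: QuadraticModel,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    grid: int = 21,
    iters: int = 200,
) -> SurfaceOptimum:
    """Global maximum of the quadratic over a coded box.

    Multistart projected gradient ascent seeded on a ``grid``³ lattice
    (default 21³); the result is never below the best lattice value.  A
    perfectly flat surface returns the box centre.
    """
    if bounds is None:
        lo, hi = -np.ones(3), np.ones(3)
    else:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
    if np.any(hi < lo):
        raise ValueError("empty box: upper bound below lower bound")

    B = model.quadratic_form()
    b = model.b_lin
    if np.allclose(B, 0.0) and np.allclose(b, 0.0):
        center = 0.5 * (lo + hi)
        return SurfaceOptimum(center, _to_actual(model, center),
                              predict(model, center), "saddle", True)

    axes = [np.linspace(lo[k], hi[k], grid) for k in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    vals = predict(model, pts)
    order = np.argsort(vals)[::-1]
    grid_best_val = float(vals[order[0]])

    # Lipschitz-safe fixed step for ascent on the quadratic
    L = 2.0 * max(np.abs(np.linalg.eigvalsh(B)).max(), 1e-12)
    step = 1.0 / L
    best_x, best_v = pts[order[0]].copy(), grid_best_val
    for idx in order[:20]:  # refine the 20 best seeds
        x = pts[idx].astype(float).copy()
        for _ in range(iters):
            g = 2.0 * B @ x + b
            x_new = np.clip(x + step * g, lo, hi)
            if np.linalg.norm(x_new - x) < 1e-12:
                break
            x = x_new
        v = predict(model, x)
        if v > best_v:
            best_x, best_v = x, v

    return SurfaceOptimum(
        coded_point=best_x,
        actual_point=_to_actual(model, best_x),
        predicted_response=float(best_v),
        nature="maximum",
        constrained=True,
    )
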