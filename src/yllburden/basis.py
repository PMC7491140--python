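"""Spline basis construction for the exposure, lag, and covariate smooths.

Two basis families are used throughout:

* a quadratic B-spline for the temperature (exposure) dimension, with
  internal knots at location-specific temperature percentiles and clamped
  boundary knots at the observed minimum and maximum;
* a natural cubic spline (linear beyond the boundary knots, i.e. zero
  second derivative at and outside them) for the lag dimension, the
  seasonal/long-term time trend and relative humidity.

Both are thin wrappers over :class:`scipy.interpolate.BSpline`; the natural
constraint is imposed by projecting the cubic B-spline basis onto the null
space of its boundary second derivatives, which reproduces the column space
of the classical ``ns()`` construction.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "quadratic_bspline_basis",
    "natural_cubic_basis",
    "log_lag_knots",
]


def _full_knots(knots: np.ndarray, boundary: tuple[float, float], degree: int) -> np.ndarray:
    lo, hi = boundary
    return np.concatenate(
        [np.repeat(lo, degree + 1), np.asarray(knots, dtype=float), np.repeat(hi, degree + 1)]
    )


def quadratic_bspline_basis(
    x: np.ndarray,
    knots: np.ndarray,
    boundary: tuple[float, float],
) -> np.ndarray:
    """Quadratic B-spline design matrix without an intercept column.

    Parameters
    ----------
    x : array_like
        Evaluation points. Values outside ``boundary`` are permitted (for
        prediction grids) and are evaluated by polynomial continuation of
        the boundary spline pieces.
    knots : array_like
        Strictly increasing internal knots, strictly inside ``boundary``.
    boundary : (float, float)
        Clamped boundary knots, normally the observed min/max of the
        series the basis is built for.

    Returns
    -------
    ndarray of shape (len(x), len(knots) + 2)
        The full clamped quadratic B-spline basis has ``len(knots) + 3``
        columns and sums to one; the first column is dropped so the model
        intercept is not confounded (the ``bs()`` convention).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    knots = np.sort(np.asarray(knots, dtype=float))
    lo, hi = float(boundary[0]), float(boundary[1])
    if lo >= hi:
        raise ValueError("boundary must satisfy lo < hi")
    if knots.size and (knots[0] <= lo or knots[-1] >= hi):
        raise ValueError(f"internal knots {knots} must lie strictly inside boundary {boundary}")
    if knots.size > 1 and np.any(np.diff(knots) <= 0):
        raise ValueError("internal knots must be strictly increasing")
    t = _full_knots(knots, (lo, hi), degree=2)
    full = BSpline.design_matrix(x, t, 2, extrapolate=True).toarray()
    return full[:, 1:]


def _nat_constraint(t: np.ndarray, boundary: tuple[float, float], drop_first: bool) -> np.ndarray:
    """Null-space projector enforcing zero second derivative at the boundary."""
    ncoef = len(t) - 4
    ident = np.eye(ncoef)
    d2 = BSpline(t, ident, 3, extrapolate=True)(np.asarray(boundary, dtype=float), nu=2)
    cols = slice(1, None) if drop_first else slice(None)
    d2 = d2[:, cols]
    # Orthonormal basis of the null space of the 2-row constraint matrix.
    _, _, vt = np.linalg.svd(d2)
    return vt[2:].T


def natural_cubic_basis(
    x: np.ndarray,
    df: int | None = None,
    knots: np.ndarray | None = None,
    boundary: tuple[float, float] | None = None,
    intercept: bool = False,
) -> np.ndarray:
    """Natural cubic spline design matrix.

    Either ``df`` (internal knots placed at quantiles of ``x``) or explicit
    ``knots`` must be given.  The returned matrix has ``df`` columns, or
    ``len(knots) + 1 + intercept`` columns when knots are explicit.  Beyond
    the boundary knots the basis continues linearly, the defining property
    of the natural spline.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if (df is None) == (knots is None):
        raise ValueError("give exactly one of df or knots")
    if boundary is None:
        boundary = (float(np.min(x)), float(np.max(x)))
    lo, hi = boundary
    if df is not None:
        if df < 1:
            raise ValueError("df must be >= 1")
        n_interior = df - 1 - int(intercept)
        if n_interior < 0:
            raise ValueError("df too small for the intercept setting")
        if df >= np.unique(x).size:
            raise ValueError("df must be smaller than the number of distinct x values")
        if n_interior:
            probs = np.arange(1, n_interior + 1) / (n_interior + 1)
            knots = np.quantile(x, probs)  # type-7 quantiles
        else:
            knots = np.array([])
    knots = np.sort(np.asarray(knots, dtype=float))
    if knots.size and (knots[0] <= lo or knots[-1] >= hi):
        raise ValueError("internal knots must lie strictly inside the boundary")

    t = _full_knots(knots, (lo, hi), degree=3)
    proj = _nat_constraint(t, (lo, hi), drop_first=not intercept)
    cols = slice(1, None) if not intercept else slice(None)

    def eval_inside(pts: np.ndarray) -> np.ndarray:
        return BSpline.design_matrix(pts, t, 3, extrapolate=True).toarray()[:, cols] @ proj

    inside = (x >= lo) & (x <= hi)
    out = np.empty((x.size, proj.shape[1]))
    if inside.any():
        out[inside] = eval_inside(x[inside])
    if not inside.all():
        # linear continuation: f(x) = f(edge) + f'(edge) * (x - edge)
        ncoef = len(t) - 4
        deriv = BSpline(t, np.eye(ncoef), 3, extrapolate=True)(
            np.array([lo, hi]), nu=1
        )[:, cols] @ proj
        base = eval_inside(np.array([lo, hi]))
        for side, edge, row in ((x < lo, lo, 0), (x > hi, hi, 1)):
            if side.any():
                out[side] = base[row] + np.outer(x[side] - edge, deriv[row])
    return out


def log_lag_knots(lag_max: int, n_knots: int = 3) -> np.ndarray:
    """Lag knots at equally spaced points on the log scale.

    Positions are ``exp`` of ``n_knots`` points equally spaced strictly
    between ``log(1) = 0`` and ``log(lag_max)``; for ``lag_max=21,
    n_knots=3`` this gives approximately (2.14, 4.58, 9.81) days.
    """
    if lag_max < 2:
        raise ValueError("lag_max must be >= 2")
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    i = np.arange(1, n_knots + 1)
    return np.exp(np.log(lag_max) * i / (n_knots + 1))
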