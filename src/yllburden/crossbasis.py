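"""Cross-basis construction for distributed-lag non-linear exposure models.

The cross-basis is the tensor product of an exposure basis R (quadratic
B-spline of temperature, internal knots at the 10th/50th/90th percentiles,
clamped boundary knots at the observed range) and a lag basis C (natural
cubic spline with intercept over integer lags 0..lag_max, internal knots
equally spaced on the log-lag scale).  Row t, column (j, k) holds

    sum_{l=0..lag_max} R_j(T_{t-l}) * C_{l,k}

so a single regression coefficient vector captures a non-linear
exposure-response surface distributed over lag days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import log_lag_knots, natural_cubic_basis, quadratic_bspline_basis

__all__ = ["CrossBasisSpec", "CrossBasis"]


@dataclass(frozen=True)
class CrossBasisSpec:
    """Configuration of the bi-dimensional temperature/lag basis.

    ``var_knots``/``var_boundary`` are in degrees Celsius and are normally
    derived from the fitted location's own series via :meth:`from_temps`;
    ``lag_max`` defaults to 21 days, long enough to capture delayed cold
    effects.
    """

    var_knots: tuple[float, ...]
    var_boundary: tuple[float, float]
    lag_max: int = 21
    lag_knots: tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    var_degree: int = 2
    n_lag_knots: int = 3

    def __post_init__(self):
        if self.lag_knots is None:
            object.__setattr__(
                self, "lag_knots", tuple(log_lag_knots(self.lag_max, self.n_lag_knots))
            )
        if self.var_degree != 2:
            raise ValueError("only the quadratic exposure basis is supported")
        lo, hi = self.var_boundary
        ks = np.asarray(self.var_knots)
        if np.any(ks <= lo) or np.any(ks >= hi):
            raise ValueError("var_knots must lie strictly inside var_boundary")

    @classmethod
    def from_temps(
        cls,
        temps: np.ndarray,
        knot_percentiles: tuple[float, ...] = (10.0, 50.0, 90.0),
        lag_max: int = 21,
    ) -> "CrossBasisSpec":
        """Build the spec from a temperature series (type-7 percentiles)."""
        temps = np.asarray(temps, dtype=float)
        knots = tuple(np.percentile(temps, knot_percentiles))
        return cls(
            var_knots=knots,
            var_boundary=(float(temps.min()), float(temps.max())),
            lag_max=lag_max,
        )

    @property
    def vx(self) -> int:
        """Exposure-basis dimension (degree + number of internal knots)."""
        return self.var_degree + len(self.var_knots)

    @property
    def vl(self) -> int:
        """Lag-basis dimension (internal knots + 1 + intercept)."""
        return len(self.lag_knots) + 2


class CrossBasis:
    """Cross-basis design block for one location's temperature series.

    Attributes
    ----------
    values : ndarray (n_days, vx * vl)
        The design block; column index ``j * vl + k`` pairs exposure basis
        function j with lag basis function k.  The first ``lag_max`` rows
        use an incomplete exposure history and are excluded via
        ``complete``.
    lag_basis : ndarray (lag_max + 1, vl)
        The lag basis C evaluated at integer lags.
    complete : ndarray of bool (n_days,)
        False for the leading rows with missing lagged exposures.
    """

    def __init__(self, temps: np.ndarray, spec: CrossBasisSpec, check_range: bool = True):
        temps = np.asarray(temps, dtype=float)
        if temps.ndim != 1:
            raise ValueError("temps must be one-dimensional")
        if temps.size <= spec.lag_max:
            raise ValueError("series shorter than lag_max + 1")
        lo, hi = spec.var_boundary
        if check_range and (temps.min() < lo or temps.max() > hi):
            raise ValueError(
                "temperatures outside var_boundary; build the spec from the same series"
            )
        self.spec = spec
        self.temps = temps
        self.lag_basis = self._lag_basis(spec)
        exposure = self.exposure_basis(temps)  # (n, vx)

        n, L = temps.size, spec.lag_max
        lagged = np.zeros((L + 1, n, spec.vx))
        for l in range(L + 1):
            lagged[l, l:] = exposure[: n - l]
        # values[t, j*vl + k] = sum_l R_j(T_{t-l}) C_{l,k}
        self.values = np.einsum("lnj,lk->njk", lagged, self.lag_basis).reshape(n, -1)
        self.complete = np.arange(n) >= L

    @staticmethod
    def _lag_basis(spec: CrossBasisSpec) -> np.ndarray:
        lags = np.arange(spec.lag_max + 1, dtype=float)
        return natural_cubic_basis(
            lags,
            knots=np.asarray(spec.lag_knots),
            boundary=(0.0, float(spec.lag_max)),
            intercept=True,
        )

    def exposure_basis(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the quadratic exposure basis R at temperatures ``x``."""
        return quadratic_bspline_basis(
            x, np.asarray(self.spec.var_knots), self.spec.var_boundary
        )

    @property
    def n_columns(self) -> int:
        return self.spec.vx * self.spec.vl

    def reduction_matrix(self) -> np.ndarray:
        """M = I_vx kron (1' C): sums the lag dimension over integer lags.

        Applied to the cross-basis coefficient vector it yields the
        overall cumulative exposure-response coefficients.
        """
        ones_c = self.lag_basis.sum(axis=0)  # (vl,)
        return np.kron(np.eye(self.spec.vx), ones_c)
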