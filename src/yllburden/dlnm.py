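"""First-stage regression: YLL rate on a temperature cross-basis.

The model for one location is a Gaussian identity-link regression

    E(Y_t) = a + cb(T_t, lag) + ns(time_t, 7 df/year) + ns(RH_t, 3 df)
             + beta_1 DOW_t

where Y_t is the daily YLL rate (years of life lost per 1e5 population),
cb is the temperature cross-basis, the time spline absorbs seasonality and
long-term trend, and DOW is a categorical day-of-week term.  The fitted
cross-basis coefficients are reduced to the overall cumulative
exposure-response (the lag-summed association) for second-stage pooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import natural_cubic_basis
from .crossbasis import CrossBasis, CrossBasisSpec

__all__ = ["ModelConfig", "DLNMModel", "DLNMResults", "ReducedFit", "fit_location"]


@dataclass(frozen=True)
class ModelConfig:
    """Covariate configuration of the first-stage regression."""

    time_df_per_year: int = 7
    rh_df: int = 3

    def __post_init__(self):
        if self.time_df_per_year < 1 or self.rh_df < 1:
            raise ValueError("df values must be positive integers")


class DLNMModel:
    """Distributed-lag non-linear model of daily YLL rates on temperature.

    Parameters
    ----------
    endog : array_like
        Daily YLL rate series (the regression outcome).
    temps : array_like
        Daily mean temperature, same length.
    rh : array_like
        Daily relative humidity (%).
    dow : array_like of int
        Day of week per day, 0..6.
    spec : CrossBasisSpec, optional
        Cross-basis configuration; derived from ``temps`` by default.
    config : ModelConfig, optional

    Notes
    -----
    Days with a missing outcome are dropped from the fit together with
    their design rows; their temperatures still feed the exposure history
    of later days.  The leading ``lag_max`` days are always dropped.
    """

    def __init__(
        self,
        endog,
        temps,
        rh,
        dow,
        spec: CrossBasisSpec | None = None,
        config: ModelConfig | None = None,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.temps = np.asarray(temps, dtype=float)
        self.rh = np.asarray(rh, dtype=float)
        self.dow = np.asarray(dow, dtype=int)
        n = self.endog.size
        if not (self.temps.size == self.rh.size == self.dow.size == n):
            raise ValueError("all series must have equal length")
        self.config = config or ModelConfig()
        self.spec = spec or CrossBasisSpec.from_temps(self.temps)
        self.crossbasis = CrossBasis(self.temps, self.spec)
        if n < 2 * 365:
            warnings.warn("fewer than 2 years of data; estimates may be unstable")
        self._build_design()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        endog_col: str = "yll_rate",
        temp_col: str = "tmean",
        rh_col: str = "rh",
        dow_col: str = "dow",
        **kwargs,
    ) -> "DLNMModel":
        return cls(
            df[endog_col].to_numpy(),
            df[temp_col].to_numpy(),
            df[rh_col].to_numpy(),
            df[dow_col].to_numpy(),
            **kwargs,
        )

    def _build_design(self) -> None:
        n = self.endog.size
        years = n / 365.25
        time_df = max(2, round(self.config.time_df_per_year * years))
        t_index = np.arange(n, dtype=float)
        time_basis = natural_cubic_basis(t_index, df=time_df)
        rh_basis = natural_cubic_basis(self.rh, df=self.config.rh_df)
        dow_dummies = np.zeros((n, 6))
        for d in range(1, 7):
            dow_dummies[:, d - 1] = self.dow == d

        blocks = [
            np.ones((n, 1)),
            self.crossbasis.values,
            time_basis,
            rh_basis,
            dow_dummies,
        ]
        self.exog = np.column_stack(blocks)
        ncb = self.crossbasis.n_columns
        self.cb_slice = slice(1, 1 + ncb)
        self._block_names = {
            "intercept": slice(0, 1),
            "crossbasis": self.cb_slice,
            "time": slice(1 + ncb, 1 + ncb + time_basis.shape[1]),
            "rh": slice(1 + ncb + time_basis.shape[1], 1 + ncb + time_basis.shape[1] + rh_basis.shape[1]),
            "dow": slice(self.exog.shape[1] - 6, self.exog.shape[1]),
        }

    def fit(self) -> "DLNMResults":
        """Fit by ordinary least squares; classical coefficient covariance."""
        keep = self.crossbasis.complete & np.isfinite(self.endog)
        X = self.exog[keep]
        y = self.endog[keep]
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = self._diagnose_collinear(X)
            raise np.linalg.LinAlgError(
                f"design matrix rank {rank} < {X.shape[1]} columns; "
                f"collinearity involves block(s): {bad}"
            )
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = X.shape[0] - X.shape[1]
        sigma2 = float(resid @ resid / dof)
        xtx_inv = np.linalg.inv(X.T @ X)
        cov = sigma2 * xtx_inv
        return DLNMResults(self, beta, cov, sigma2, int(keep.sum()))

    def _diagnose_collinear(self, X: np.ndarray) -> list[str]:
        bad = []
        for name, sl in self._block_names.items():
            sub = np.delete(X, np.r_[sl], axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
                bad.append(name)
        return bad or ["unknown"]


class DLNMResults:
    """Fit results: coefficients, covariance, and the reduction to the
    overall cumulative exposure-response."""

    def __init__(self, model: DLNMModel, params, cov_params, sigma2, nobs):
        self.model = model
        self.params = np.asarray(params)
        self.cov_params = np.asarray(cov_params)
        self.sigma2 = sigma2
        self.nobs = nobs

    @property
    def cb_params(self) -> np.ndarray:
        return self.params[self.model.cb_slice]

    @property
    def cb_cov(self) -> np.ndarray:
        sl = self.model.cb_slice
        return self.cov_params[sl, sl]

    def rsquared(self) -> float:
        keep = self.model.crossbasis.complete & np.isfinite(self.model.endog)
        y = self.model.endog[keep]
        fitted = self.model.exog[keep] @ self.params
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - ss_res / ss_tot

    def reduce(self, center: float) -> "ReducedFit":
        """Sum the fitted surface over lags 0..lag_max.

        With M = I_vx kron (1'C), theta = M beta_cb and
        V = M Sigma_cb M'; the overall cumulative excess at temperature T
        relative to ``center`` is [R(T) - R(center)] theta.
        """
        lo, hi = self.model.spec.var_boundary
        if not (lo <= center <= hi):
            raise ValueError("center outside var_boundary")
        M = self.model.crossbasis.reduction_matrix()
        theta = M @ self.cb_params
        vcov = M @ self.cb_cov @ M.T
        return ReducedFit(
            theta=theta,
            vcov=vcov,
            center=float(center),
            spec=self.model.spec,
            temps=self.model.temps,
        )

    def summary(self) -> str:
        cfg = self.model.config
        spec = self.model.spec
        lines = [
            "Distributed-lag non-linear model (Gaussian, identity link)",
            "=" * 60,
            f"n obs (complete days):      {self.nobs}",
            f"design columns:             {self.model.exog.shape[1]}",
            f"cross-basis dims (vx x vl): {spec.vx} x {spec.vl}",
            f"lag window:                 0..{spec.lag_max} days",
            f"exposure knots (degC):      "
            + ", ".join(f"{k:.2f}" for k in spec.var_knots),
            f"time df/year:               {cfg.time_df_per_year}",
            f"RH df:                      {cfg.rh_df}",
            f"residual SD:                {np.sqrt(self.sigma2):.4f}",
            f"R-squared:                  {self.rsquared():.4f}",
        ]
        return "\n".join(lines)


class ReducedFit:
    """Overall cumulative exposure-response for one location.

    Carries the reduced coefficients ``theta`` (length vx), their
    covariance, the reference temperature, and the exposure basis needed
    to evaluate the curve at arbitrary temperatures.
    """

    def __init__(self, theta, vcov, center, spec: CrossBasisSpec, temps):
        self.theta = np.asarray(theta, dtype=float)
        self.vcov = np.asarray(vcov, dtype=float)
        if self.vcov.shape != (self.theta.size, self.theta.size):
            raise ValueError("vcov shape inconsistent with theta")
        self.center = float(center)
        self.spec = spec
        self.temps = np.asarray(temps, dtype=float)

    def _basis(self, x) -> np.ndarray:
        from .basis import quadratic_bspline_basis

        return quadratic_bspline_basis(
            x, np.asarray(self.spec.var_knots), self.spec.var_boundary
        )

    def basis_diff(self, x, center: float | None = None) -> np.ndarray:
        """R(x) - R(center): the re-centred exposure basis."""
        c = self.center if center is None else float(center)
        return self._basis(np.atleast_1d(x)) - self._basis([c])

    def excess(self, x, center: float | None = None) -> np.ndarray:
        """Cumulative excess YLL rate at temperature x relative to center."""
        return self.basis_diff(x, center) @ self.theta

    def excess_se(self, x, center: float | None = None) -> np.ndarray:
        B = self.basis_diff(x, center)
        return np.sqrt(np.einsum("ij,jk,ik->i", B, self.vcov, B))

    def with_coefficients(self, theta, vcov) -> "ReducedFit":
        """Same basis/temps, different coefficients (e.g. a BLUP)."""
        return ReducedFit(theta, vcov, self.center, self.spec, self.temps)

    def curve_frame(self, grid=None, center: float | None = None) -> pd.DataFrame:
        if grid is None:
            lo, hi = self.spec.var_boundary
            grid = np.linspace(lo, hi, 101)
        grid = np.asarray(grid, dtype=float)
        est = self.excess(grid, center)
        se = self.excess_se(grid, center)
        return pd.DataFrame(
            {
                "temp": grid,
                "excess": est,
                "se": se,
                "ci_low": est - 1.96 * se,
                "ci_high": est + 1.96 * se,
            }
        )

    def plot(self, ax=None, grid=None, **kwargs):
        import matplotlib.pyplot as plt

        frame = self.curve_frame(grid)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(frame["temp"], frame["excess"], **kwargs)
        ax.fill_between(frame["temp"], frame["ci_low"], frame["ci_high"], alpha=0.2)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("temperature (degC)")
        ax.set_ylabel("excess YLL rate (per 1e5)")
        return ax


def fit_location(
    df: pd.DataFrame,
    spec: CrossBasisSpec | None = None,
    config: ModelConfig | None = None,
    endog_col: str = "yll_rate",
    temp_col: str = "tmean",
) -> DLNMResults:
    """Convenience wrapper: fit one location's daily table."""
    model = DLNMModel.from_dataframe(
        df, endog_col=endog_col, temp_col=temp_col, spec=spec, config=config
    )
    return model.fit()
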