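"""Attribution of YLLs to non-optimal temperature.

From a location's overall cumulative exposure-response curve (normally the
BLUP from second-stage pooling) this module locates the minimum-YLL-rate
temperature (MYT) and its percentile (MYP), attributes each day's YLL rate
to the departure of that day's temperature from the MYT, and aggregates to
the attributable fraction (AF, % of total YLLs) and the temperature-related
life loss per death (attributable YLLs / total deaths, years).

Burdens are split into four components by partitioning days at the 2.5th
percentile, the MYT, and the 97.5th percentile of the location's
temperature distribution (extreme cold, moderate cold, moderate heat,
extreme heat).  Empirical confidence intervals come from Monte Carlo
resampling of the reduced coefficients under a multivariate normal
assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dlnm import ReducedFit

__all__ = [
    "AttributionResult",
    "find_myt",
    "attribute_daily",
    "summarize_burden",
    "monte_carlo_eci",
    "attribute_location",
    "pool_strata",
]

logger = logging.getLogger(__name__)

COMPONENTS = ("extreme_cold", "moderate_cold", "moderate_heat", "extreme_heat")
_CLAMP_TOL = 1e-9


@dataclass
class AttributionResult:
    """Attributable burden for one location (or pooled stratum) stratum."""

    myt: float
    myp: float
    af: dict[str, float]          # keys: total, cold, heat + COMPONENTS (%)
    lld: dict[str, float]         # same keys; years per death
    attributable_yll: float       # person-years
    total_yll: float
    total_deaths: float
    eci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_sim: int = 0
    seed: int | None = None
    draws: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (quantity, component)."""
        rows = []
        for qty, vals in (("af", self.af), ("lld", self.lld)):
            for comp, est in vals.items():
                lo, hi = self.eci.get(f"{qty}_{comp}", (np.nan, np.nan))
                rows.append(
                    {"quantity": qty, "component": comp, "estimate": est,
                     "eci_low": lo, "eci_high": hi}
                )
        return pd.DataFrame(rows)


def find_myt(rfit: ReducedFit, temps=None, grid_step: float = 0.1,
             search_range: tuple[float, float] | None = None) -> tuple[float, float]:
    """Minimum-YLL-rate temperature and its empirical percentile.

    The MYT is the argmin over a temperature grid of the overall
    cumulative curve (which is invariant to the centring reference); the
    MYP is the percentile of the MYT within the observed series.  Ties are
    broken toward the median observed temperature.
    """
    temps = rfit.temps if temps is None else np.asarray(temps, dtype=float)
    lo, hi = (float(temps.min()), float(temps.max())) if search_range is None else search_range
    if hi <= lo:
        raise ValueError("empty search grid")
    grid = np.minimum(np.arange(lo, hi + grid_step / 2, grid_step), hi)
    curve = rfit.excess(grid)
    minval = curve.min()
    candidates = grid[np.isclose(curve, minval, rtol=0, atol=1e-12)]
    med = float(np.median(temps))
    myt = float(candidates[np.argmin(np.abs(candidates - med))])
    myp = float(np.mean(temps <= myt) * 100.0)
    return myt, myp


def attribute_daily(temps, rfit: ReducedFit, myt: float, population: float = 1e5,
                    clamp_negative: bool = True) -> pd.DataFrame:
    """Per-day attributable YLL rate and YLL.

    The day's attributable rate is the overall cumulative curve evaluated
    at that day's temperature, re-centred at the MYT:
    a_t = [R(T_t) - R(MYT)] theta.  When the MYT is the global argmin over
    the observed range, a_t >= 0 up to grid discretisation; small negative
    values are clamped to zero with a logged count.
    """
    temps = np.asarray(temps, dtype=float)
    lo, hi = rfit.spec.var_boundary
    if not (lo <= myt <= hi):
        raise ValueError("myt outside the exposure basis boundary")
    a = rfit.excess(temps, center=myt)
    if clamp_negative:
        neg = a < 0
        n_clamped = int(np.sum(neg & (a > -_CLAMP_TOL)))
        if n_clamped:
            logger.info("clamped %d tiny negative attributable rates", n_clamped)
        a = np.where(neg & (a > -_CLAMP_TOL), 0.0, a)
    out_of_range = (temps < lo) | (temps > hi)
    return pd.DataFrame(
        {
            "tmean": temps,
            "attr_rate": a,
            "attr_yll": a * population / 1e5,
            "out_of_range": out_of_range,
        }
    )


def _component_masks(temps: np.ndarray, myt: float,
                     cut_percentiles=(2.5, 97.5)) -> dict[str, np.ndarray]:
    """Partition days at {low percentile, MYT, high percentile}.

    Cold/heat are defined relative to the MYT so that the component split
    is an exact partition of the day set regardless of where the MYT falls
    relative to the percentile cuts.
    """
    p_lo, p_hi = np.percentile(temps, cut_percentiles)
    cold = temps <= myt
    heat = ~cold
    return {
        "cold": cold,
        "heat": heat,
        "extreme_cold": cold & (temps <= p_lo),
        "moderate_cold": cold & (temps > p_lo),
        "moderate_heat": heat & (temps < p_hi),
        "extreme_heat": heat & (temps >= p_hi),
    }


def _burden_sums(attr_yll: np.ndarray, masks: dict[str, np.ndarray]) -> dict[str, float]:
    sums = {"total": float(attr_yll.sum())}
    for key, mask in masks.items():
        sums[key] = float(attr_yll[mask].sum())
    return sums


def summarize_burden(daily: pd.DataFrame, total_yll: float, total_deaths: float,
                     temps, myt: float, myp: float,
                     cut_percentiles=(2.5, 97.5)) -> AttributionResult:
    """Point estimates of AF (%) and life loss per death (years).

    AF = sum of attributable YLLs / sum of YLLs x 100; life loss per death
    divides by total deaths instead.  Components restrict the day-sum to
    the four temperature ranges cut at {2.5th pct, MYT, 97.5th pct}.
    """
    if total_yll <= 0:
        raise ValueError("total YLL must be positive")
    if total_deaths <= 0:
        raise ValueError("life loss per death undefined: zero deaths")
    temps = np.asarray(temps, dtype=float)
    masks = _component_masks(temps, myt, cut_percentiles)
    sums = _burden_sums(daily["attr_yll"].to_numpy(), masks)
    af = {k: v / total_yll * 100.0 for k, v in sums.items()}
    lld = {k: v / total_deaths for k, v in sums.items()}
    return AttributionResult(
        myt=myt, myp=myp, af=af, lld=lld,
        attributable_yll=sums["total"], total_yll=total_yll,
        total_deaths=total_deaths,
    )


def monte_carlo_eci(rfit: ReducedFit, temps, myt: float, total_yll: float,
                    total_deaths: float, population: float = 1e5,
                    n_sim: int = 1000, seed: int = 0,
                    cut_percentiles=(2.5, 97.5),
                    refit_myt: bool = False,
                    grid_step: float = 0.1) -> tuple[dict, dict]:
    """Empirical 95% CIs by resampling the reduced coefficients.

    Draws theta* ~ MVN(theta, vcov) ``n_sim`` times and recomputes every
    attributable quantity per draw.  By default the MYT stays fixed at its
    point estimate; ``refit_myt`` re-locates the argmin per draw.

    Returns ``(eci, draws)`` where ``draws`` maps each quantity to its
    simulated vector (needed to pool strata with a shared draw index).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be positive")
    temps = np.asarray(temps, dtype=float)
    rng = np.random.default_rng(seed)
    w = np.linalg.eigvalsh((rfit.vcov + rfit.vcov.T) / 2)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ValueError("vcov is not positive semidefinite")
    thetas = rng.multivariate_normal(rfit.theta, rfit.vcov, size=n_sim,
                                     method="svd")  # (n_sim, vx)

    draws: dict[str, np.ndarray] = {}
    keys = ("total", "cold", "heat") + COMPONENTS
    for k in keys:
        draws[f"af_{k}"] = np.empty(n_sim)
        draws[f"lld_{k}"] = np.empty(n_sim)
        draws[f"ayll_{k}"] = np.empty(n_sim)

    if not refit_myt:
        B = rfit.basis_diff(temps, center=myt)     # (n_days, vx)
        A = B @ thetas.T                           # (n_days, n_sim)
        A[(A < 0) & (A > -_CLAMP_TOL)] = 0.0
        masks = _component_masks(temps, myt, cut_percentiles)
        sums = {"total": A.sum(axis=0)}
        for key, mask in masks.items():
            sums[key] = A[mask].sum(axis=0)
        for k in keys:
            draws[f"ayll_{k}"] = sums[k] * population / 1e5
            draws[f"af_{k}"] = sums[k] / total_yll * 100.0
            draws[f"lld_{k}"] = sums[k] * population / 1e5 / total_deaths
    else:
        for s in range(n_sim):
            rf_s = rfit.with_coefficients(thetas[s], rfit.vcov)
            myt_s, _ = find_myt(rf_s, temps, grid_step=grid_step)
            daily = attribute_daily(temps, rf_s, myt_s, population)
            masks = _component_masks(temps, myt_s, cut_percentiles)
            sums = _burden_sums(daily["attr_yll"].to_numpy(), masks)
            for k in keys:
                draws[f"ayll_{k}"][s] = sums[k]
                draws[f"af_{k}"][s] = sums[k] / (population / 1e5) / total_yll * 100.0
                draws[f"lld_{k}"][s] = sums[k] / total_deaths

    eci = {k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
           for k, v in draws.items()}
    return eci, draws


def attribute_location(rfit: ReducedFit, temps=None, total_yll: float = None,
                       total_deaths: float = None, population: float = 1e5,
                       n_sim: int = 1000, seed: int = 0, grid_step: float = 0.1,
                       cut_percentiles=(2.5, 97.5),
                       myt: float | None = None,
                       myt_percentile_range: tuple[float, float] = (2.0, 98.0),
                       ) -> AttributionResult:
    """Full attribution for one location: MYT, burdens, components, eCIs.

    The MYT search is restricted to an inner percentile window of the
    observed temperatures (default 2nd-98th): the fitted curve's variance
    explodes at the observed extremes, and an argmin there is an artifact
    of sparsity rather than an optimal temperature.
    """
    temps = rfit.temps if temps is None else np.asarray(temps, dtype=float)
    if myt is None:
        lo, hi = np.percentile(temps, myt_percentile_range)
        myt, myp = find_myt(rfit, temps, grid_step=grid_step,
                            search_range=(float(lo), float(hi)))
    else:
        myp = float(np.mean(temps <= myt) * 100.0)
    daily = attribute_daily(temps, rfit, myt, population)
    res = summarize_burden(daily, total_yll, total_deaths, temps, myt, myp,
                           cut_percentiles)
    eci, draws = monte_carlo_eci(
        rfit, temps, myt, total_yll, total_deaths, population,
        n_sim=n_sim, seed=seed, cut_percentiles=cut_percentiles,
    )
    res.eci = eci
    res.draws = draws
    res.n_sim = n_sim
    res.seed = seed
    return res


def pool_strata(results: list[AttributionResult]) -> AttributionResult:
    """Aggregate locations into a stratum-level result.

    Stratum AF = sum of attributable YLLs over locations / sum of YLLs;
    life loss per death analogous with deaths.  eCIs are obtained by
    summing per-draw attributable YLLs across locations at a shared draw
    index, so between-location sampling error combines coherently.
    """
    if not results:
        raise ValueError("empty stratum")
    total_yll = sum(r.total_yll for r in results)
    total_deaths = sum(r.total_deaths for r in results)
    keys = ("total", "cold", "heat") + COMPONENTS
    pop_factor = {k: sum(r.af[k] / 100.0 * r.total_yll for r in results) for k in keys}
    af = {k: pop_factor[k] / total_yll * 100.0 for k in keys}
    lld = {k: pop_factor[k] / total_deaths for k in keys}

    eci: dict[str, tuple[float, float]] = {}
    draws: dict[str, np.ndarray] = {}
    if all(r.draws for r in results):
        n_sim = min(r.n_sim for r in results)
        for k in keys:
            ayll = np.sum([r.draws[f"ayll_{k}"][:n_sim] for r in results], axis=0)
            draws[f"ayll_{k}"] = ayll
            draws[f"af_{k}"] = ayll / total_yll * 100.0
            draws[f"lld_{k}"] = ayll / total_deaths
        eci = {k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
               for k, v in draws.items()}

    myts = np.array([r.myt for r in results])
    return AttributionResult(
        myt=float(np.median(myts)), myp=float(np.median([r.myp for r in results])),
        af=af, lld=lld,
        attributable_yll=pop_factor["total"], total_yll=total_yll,
        total_deaths=total_deaths, eci=eci,
        n_sim=min((r.n_sim for r in results), default=0),
        seed=results[0].seed, draws=draws,
    )
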