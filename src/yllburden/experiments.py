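"""Canned validation experiments on synthetic data.

These are the package's standard self-checks: parameter recovery of the
planted exposure-response at panel scale, a null control for attribution,
empirical-CI calibration, and clustering recovery.  They are used by the
test suite and by ``scripts/acceptance.py``; each takes an integer seed
and returns a plain dict of computed quantities.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .attribution import attribute_daily, attribute_location, find_myt, pool_strata
from .clustering import classify_development, kmeans, select_k, standardize_features
from .dlnm import DLNMModel
from .meta import MVMeta
from .simulate import SimConfig, TrueSurface, expected_af, gen_outcomes, gen_weather

__all__ = [
    "fit_panel",
    "recovery_experiment",
    "null_control",
    "eci_coverage",
    "clustering_recovery",
]


def _fit_one(daily):
    model = DLNMModel(
        daily["yll_rate"].to_numpy(),
        daily["tmean"].to_numpy(),
        daily["rh"].to_numpy(),
        daily["dow"].to_numpy(),
    )
    res = model.fit()
    return res.reduce(center=float(np.median(daily["tmean"])))


def fit_panel(cfg: SimConfig, surface: TrueSurface):
    """Simulate and stage-1-fit every location; returns (dailies, reduced)."""
    dailies, reduced = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(cfg.n_locations):
            weather = gen_weather(cfg, i)
            daily, _ = gen_outcomes(cfg, weather, surface, i, with_records=False)
            dailies.append(daily)
            reduced.append(_fit_one(daily))
    return dailies, reduced


def recovery_experiment(
    seed: int,
    n_locations: int = 20,
    years: int = 10,
    n_sim: int = 300,
    grid_points: int = 50,
) -> dict:
    """Panel-scale recovery of the planted surface.

    Fits the full two-stage pipeline on ``n_locations`` x ``years`` of
    synthetic data and reports (a) the pointwise 95% CI coverage of the
    pooled overall curve against the planted truth over the central
    (2.5th-97.5th percentile) temperature range, (b) the pooled-curve MYT
    error, and (c) per-development-stratum AF estimates with their
    analytic expectations and Monte Carlo SDs.
    """
    surface = TrueSurface()
    cfg = SimConfig(seed=seed, n_locations=n_locations, n_days=years * 365)
    dailies, reduced = fit_panel(cfg, surface)

    # pooled curve over all locations
    meta_all = MVMeta([(rf.theta, rf.vcov) for rf in reduced]).fit()
    temps_all = np.concatenate(
        [d["tmean"].to_numpy()[surface.max_lag:] for d in dailies]
    )
    rf_pool = reduced[0].with_coefficients(meta_all.mu, meta_all.vcov_mu)
    lo, hi = np.percentile(temps_all, [2.5, 97.5])
    grid = np.linspace(lo, hi, grid_points)
    est = rf_pool.excess(grid, center=surface.myt_true)
    se = rf_pool.excess_se(grid, center=surface.myt_true)
    truth = surface.g(grid)
    coverage = float(np.mean((truth >= est - 1.96 * se) & (truth <= est + 1.96 * se)))
    myt_pool, myp_pool = find_myt(rf_pool, temps_all)

    # stratified attribution from per-stratum pooling and BLUPs
    from .simulate import gen_socio

    socio = classify_development(gen_socio(cfg), seed=seed)
    strata = {}
    for name in sorted(socio["development_level"].unique()):
        idx = list(socio.index[socio["development_level"] == name])
        meta = MVMeta([(reduced[i].theta, reduced[i].vcov) for i in idx]).fit()
        blups = meta.blups()
        locs = []
        for j, i in enumerate(idx):
            daily = dailies[i]
            sub = daily[~daily["burn_in"].to_numpy()]
            rf = reduced[i].with_coefficients(*blups[j])
            locs.append(
                attribute_location(
                    rf,
                    temps=sub["tmean"].to_numpy(),
                    total_yll=float(sub["yll_total"].sum()),
                    total_deaths=float(sub["deaths"].sum()),
                    population=cfg.population,
                    n_sim=n_sim,
                    seed=seed,  # shared draw stream within the stratum
                )
            )
        pooled = pool_strata(locs)
        temps_s = np.concatenate(
            [dailies[i]["tmean"].to_numpy()[surface.max_lag:] for i in idx]
        )
        strata[name] = {
            "af": pooled.af["total"],
            "af_analytic": expected_af(
                surface, temps_s, cfg.baseline_yll_rate, cfg.dow_effects
            ),
            "af_mc_sd": float(np.std(pooled.draws["af_total"])),
            "af_eci": pooled.eci["af_total"],
            "lld": pooled.lld["total"],
            "myt_median": float(
                np.median([loc.myt for loc in locs])
            ),
            "af_components": {k: pooled.af[k] for k in pooled.af},
            "n_locations": len(idx),
        }
    return {
        "coverage": coverage,
        "myt_pooled": myt_pool,
        "myp_pooled": myp_pool,
        "myt_true": surface.myt_true,
        "strata": strata,
    }


def null_control(seed: int, n_reps: int = 20, years: int = 3) -> dict:
    """Attribution null control: zero planted effect.

    Under a flat truth any temperature is optimal, so each replicate's AF
    is evaluated at the generator's reference temperature; the mean AF
    over replicates should be within its standard error of zero.  (The
    argmin-estimated MYT is deliberately not used here: referencing the
    minimum of a pure-noise curve makes every daily attribution
    non-negative and the estimate structurally positive.)
    """
    surface = TrueSurface(cold_slope=0.0, heat_slope=0.0)
    afs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            cfg = SimConfig(seed=seed + 1000 * rep, n_locations=1, n_days=years * 365)
            weather = gen_weather(cfg, 0)
            daily, _ = gen_outcomes(cfg, weather, surface, 0, with_records=False)
            rf = _fit_one(daily)
            sub = daily[~daily["burn_in"].to_numpy()]
            t = sub["tmean"].to_numpy()
            attr = attribute_daily(t, rf, surface.myt_true, clamp_negative=False)
            afs.append(float(attr["attr_rate"].sum() / sub["yll_rate"].sum() * 100))
    afs = np.asarray(afs)
    return {
        "mean_af": float(afs.mean()),
        "sd_af": float(afs.std(ddof=1)),
        "se_af": float(afs.std(ddof=1) / np.sqrt(n_reps)),
        "n_reps": n_reps,
    }


def eci_coverage(
    seed: int, n_reps: int = 200, years: int = 3, n_sim: int = 200
) -> dict:
    """Calibration of the Monte Carlo 95% eCI for the total AF.

    Each replicate simulates one location, estimates its AF with eCI, and
    checks whether the interval contains the analytic AF implied by the
    planted surface and that replicate's temperatures.
    """
    surface = TrueSurface()
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            cfg = SimConfig(seed=seed + 1000 * rep, n_locations=1, n_days=years * 365)
            weather = gen_weather(cfg, 0)
            daily, _ = gen_outcomes(cfg, weather, surface, 0, with_records=False)
            rf = _fit_one(daily)
            sub = daily[~daily["burn_in"].to_numpy()]
            t = sub["tmean"].to_numpy()
            res = attribute_location(
                rf,
                temps=t,
                total_yll=float(sub["yll_rate"].sum()),
                total_deaths=1000.0,
                n_sim=n_sim,
                seed=seed + rep,
            )
            af_true = expected_af(surface, t, cfg.baseline_yll_rate, cfg.dow_effects)
            lo, hi = res.eci["af_total"]
            hits += lo <= af_true <= hi
    return {"coverage": hits / n_reps, "n_reps": n_reps}


def clustering_recovery(seed: int, n_locations: int = 24) -> dict:
    """Development-cluster recovery at realistic centers, small spread."""
    from .simulate import gen_socio

    cfg = SimConfig(
        seed=seed, n_locations=n_locations, cluster_spread=(5.0, 0.5, 5.0)
    )
    socio = gen_socio(cfg)
    z, *_ = standardize_features(
        socio[["pct_urban", "edu_years", "gdp_per_capita"]].to_numpy()
    )
    best_k, _ = select_k(z, k_range=range(2, 8), seed=seed)
    labels = kmeans(z, k=2, seed=seed).labels
    ari = float(adjusted_rand_score(socio["true_cluster"], labels))
    return {"selected_k": best_k, "ari": ari}
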