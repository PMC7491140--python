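import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from yllburden.simulate import (
    SimConfig,
    TrueSurface,
    default_life_tables,
    gen_outcomes,
    gen_socio,
    gen_weather,
)


class TestTrueSurface:
    def test_lag_weights_sum_to_one(self):
        for decay in (0.3, 0.7, 0.95):
            s = TrueSurface(lag_decay=decay, max_lag=21)
            assert s.lag_weights().sum() == pytest.approx(1.0)
            assert np.all(np.diff(s.lag_weights()) < 0)

    def test_curve_zero_at_minimum_and_linear_in_tails(self):
        s = TrueSurface()
        assert s.g(s.myt_true) == 0.0
        # beyond the smoothing window the arms are exactly linear
        t = s.myt_true - s.smooth_delta - np.array([1.0, 5.0])
        np.testing.assert_allclose(np.diff(s.g(t)), -4.0 * -s.cold_slope, atol=1e-12)

    def test_invalid_decay_rejected(self):
        with pytest.raises(ValueError):
            TrueSurface(lag_decay=1.0)


class TestGenWeather:
    def test_degenerate_config_gives_constant_series(self):
        cfg = SimConfig(temp_seasonal_amplitude=0.0, temp_noise_sd=0.0)
        t = gen_weather(cfg, 0)["tmean"]
        np.testing.assert_allclose(t, cfg.temp_mean_annual)

    def test_bit_reproducible_under_fixed_seed(self):
        cfg = SimConfig()
        a = gen_weather(cfg, 1)
        b = gen_weather(cfg, 1)
        assert a.equals(b)
        assert not a["tmean"].equals(gen_weather(cfg, 0)["tmean"])

    def test_long_run_median_near_annual_mean(self):
        cfg = SimConfig(n_days=10 * 365, temp_mean_annual=15.0,
                        temp_seasonal_amplitude=10.0)
        t = gen_weather(cfg, 0)["tmean"]
        assert abs(np.median(t) - 15.0) < 1.0

    def test_tail_percentiles_approach_stationary_quantiles(self):
        """Empirical 2.5/97.5th percentiles converge to the quantiles of
        the sinusoid-plus-AR(1) stationary mixture distribution."""
        cfg = SimConfig(n_days=40 * 365, temp_mean_annual=15.0,
                        temp_seasonal_amplitude=10.0, temp_ar1=0.8,
                        temp_noise_sd=2.0)
        t = gen_weather(cfg, 0)["tmean"].to_numpy()
        sd = cfg.temp_noise_sd / np.sqrt(1 - cfg.temp_ar1**2)
        doy = np.arange(1, 366)
        seasonal = cfg.temp_seasonal_amplitude * np.sin(2 * np.pi * (doy - 105.0) / 365.25)

        def cdf(x):
            return norm.cdf((x - 15.0 - seasonal) / sd).mean()

        for q in (0.025, 0.975):
            closed_form = brentq(lambda x: cdf(x) - q, -40, 70)
            assert abs(np.percentile(t, 100 * q) - closed_form) < 0.7

    def test_humidity_anticorrelated_with_temperature_anomaly(self):
        cfg = SimConfig(n_days=5 * 365)
        w = gen_weather(cfg, 0)
        anomaly = w["tmean"] - cfg.temp_mean_annual
        assert np.corrcoef(anomaly, w["rh"])[0, 1] < -0.2

    def test_nonstationary_ar_rejected(self):
        with pytest.raises(ValueError, match="stationarity"):
            SimConfig(temp_ar1=1.0)


class TestGenOutcomes:
    def test_null_surface_noiseless_is_flat_baseline(self):
        cfg = SimConfig(noise_sd=0.0, dow_effects=(0.0,) * 7)
        surface = TrueSurface(cold_slope=0.0, heat_slope=0.0)
        daily, _ = gen_outcomes(cfg, gen_weather(cfg, 0), surface, 0, with_records=False)
        rate = daily.loc[~daily["burn_in"], "yll_rate"]
        np.testing.assert_allclose(rate, cfg.baseline_yll_rate)

    def test_constant_temperature_at_minimum_is_flat_baseline(self):
        cfg = SimConfig(noise_sd=0.0, dow_effects=(0.0,) * 7,
                        temp_seasonal_amplitude=0.0, temp_noise_sd=0.0,
                        temp_mean_annual=24.0)
        surface = TrueSurface(myt_true=24.0)
        daily, _ = gen_outcomes(cfg, gen_weather(cfg, 0), surface, 0, with_records=False)
        np.testing.assert_allclose(daily["yll_rate"], cfg.baseline_yll_rate)

    def test_records_reproduce_daily_yll_within_one_death(self):
        cfg = SimConfig(n_days=750)
        daily, records = gen_outcomes(cfg, gen_weather(cfg, 0), TrueSurface(), 0)
        tables = default_life_tables()
        max_ex = max(t.ex.max() for t in tables.values())
        target = daily["yll_rate"] * cfg.population / 1e5
        assert np.abs(daily["yll_total"] - target).max() < max_ex

    def test_subgroup_yll_columns_partition_total(self):
        cfg = SimConfig(n_days=750)
        daily, _ = gen_outcomes(cfg, gen_weather(cfg, 0), TrueSurface(), 0)
        np.testing.assert_allclose(
            daily["yll_male"] + daily["yll_female"], daily["yll_total"], atol=1e-9
        )
        np.testing.assert_allclose(
            daily["yll_age0_64"] + daily["yll_age65p"], daily["yll_total"], atol=1e-9
        )

    def test_series_shorter_than_lag_window_rejected(self):
        cfg = SimConfig(n_days=750)
        w = gen_weather(cfg, 0).iloc[:10]
        with pytest.raises(ValueError, match="max_lag"):
            gen_outcomes(cfg, w, TrueSurface(), 0)


class TestGenSocio:
    def test_zero_spread_limit_returns_exact_centers(self):
        cfg = SimConfig(cluster_spread=(1e-12, 1e-12, 1e-12))
        socio = gen_socio(cfg)
        centers = np.asarray(cfg.cluster_centers)
        feats = socio[["pct_urban", "edu_years", "gdp_per_capita"]].to_numpy()
        np.testing.assert_allclose(feats, centers[socio["true_cluster"]], atol=1e-9)

    def test_non_positive_spread_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            gen_socio(SimConfig(cluster_spread=(0.0, 1.0, 1.0)))

    def test_coincident_centers_rejected(self):
        c = ((50.0, 9.0, 30.0), (50.0, 9.0, 30.0))
        with pytest.raises(ValueError, match="distinct"):
            gen_socio(SimConfig(cluster_centers=c))

    def test_reproducible_and_labels_stored(self):
        cfg = SimConfig()
        a, b = gen_socio(cfg), gen_socio(cfg)
        assert a.equals(b)
        assert set(a["true_cluster"]) == {0, 1}


def test_short_study_period_rejected():
    with pytest.raises(ValueError, match="2 years"):
        SimConfig(n_days=400)
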