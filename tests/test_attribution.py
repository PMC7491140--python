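import numpy as np
import pytest

from yllburden.attribution import (
    attribute_daily,
    attribute_location,
    find_myt,
    monte_carlo_eci,
    pool_strata,
    summarize_burden,
)
from yllburden.crossbasis import CrossBasisSpec
from yllburden.dlnm import ReducedFit


def toy_reduced(theta=None, vcov=None, temps=None, center=15.0):
    """Small hand-set overall curve on a fixed basis."""
    rng = np.random.default_rng(0)
    temps = rng.uniform(-5, 35, 600) if temps is None else np.asarray(temps, float)
    spec = CrossBasisSpec(var_knots=(5.0, 15.0, 25.0), var_boundary=(-6.0, 36.0))
    theta = np.array([1.2, -0.8, 0.4, 1.5, 2.0]) if theta is None else theta
    vcov = 0.01 * np.eye(5) if vcov is None else vcov
    return ReducedFit(theta, vcov, center, spec, temps)


class TestFindMyt:
    def test_minimum_invariant_to_recentring(self):
        rf = toy_reduced()
        myt1, _ = find_myt(rf)
        myt2, _ = find_myt(rf.with_coefficients(rf.theta, rf.vcov))
        rf_shift = ReducedFit(rf.theta, rf.vcov, 25.0, rf.spec, rf.temps)
        myt3, _ = find_myt(rf_shift)
        assert myt1 == myt2 == myt3

    def test_monotone_curve_puts_minimum_at_boundary(self):
        temps = np.linspace(0, 30, 500)
        spec = CrossBasisSpec(var_knots=(5.0, 15.0, 25.0), var_boundary=(0.0, 30.0))
        # monotone decreasing curve: minimum at the observed maximum
        x = np.linspace(0, 30, 200)
        from yllburden.basis import quadratic_bspline_basis

        B = quadratic_bspline_basis(x, np.array(spec.var_knots), spec.var_boundary)
        theta, *_ = np.linalg.lstsq(B, -x, rcond=None)
        rf = ReducedFit(theta, 0.01 * np.eye(5), 15.0, spec, temps)
        myt, myp = find_myt(rf)
        assert myt == pytest.approx(30.0)
        assert myp == pytest.approx(100.0)

    def test_percentile_consistent_with_series(self):
        rf = toy_reduced()
        myt, myp = find_myt(rf)
        assert myp == pytest.approx(float(np.mean(rf.temps <= myt) * 100))


class TestAttributeDaily:
    def test_all_days_at_reference_give_zero(self):
        rf = toy_reduced()
        myt, _ = find_myt(rf)
        out = attribute_daily(np.full(50, myt), rf, myt)
        np.testing.assert_allclose(out["attr_yll"], 0.0, atol=1e-12)

    def test_population_1e5_identity(self):
        rf = toy_reduced()
        myt, _ = find_myt(rf)
        out = attribute_daily(rf.temps, rf, myt, population=1e5)
        np.testing.assert_allclose(out["attr_yll"], out["attr_rate"])

    def test_five_day_hand_oracle(self):
        """[R(T) - R(myt)] theta computed by hand for a printed theta."""
        from yllburden.basis import quadratic_bspline_basis

        theta = np.array([0.5, -0.25, 1.0, 0.75, -0.5])
        rf = toy_reduced(theta=theta)
        days = np.array([-2.0, 8.0, 15.0, 22.0, 33.0])
        myt = 14.0
        knots = np.array(rf.spec.var_knots)
        expected = (
            quadratic_bspline_basis(days, knots, rf.spec.var_boundary)
            - quadratic_bspline_basis([myt], knots, rf.spec.var_boundary)
        ) @ theta
        out = attribute_daily(days, rf, myt, clamp_negative=False)
        np.testing.assert_allclose(out["attr_rate"], expected, atol=1e-12)

    def test_reference_outside_boundary_rejected(self):
        rf = toy_reduced()
        with pytest.raises(ValueError, match="boundary"):
            attribute_daily(rf.temps, rf, myt=99.0)


class TestSummarizeBurden:
    def _result(self, rf=None):
        rf = rf or toy_reduced()
        myt, myp = find_myt(rf)
        daily = attribute_daily(rf.temps, rf, myt)
        return summarize_burden(
            daily, total_yll=5e4, total_deaths=3000.0, temps=rf.temps,
            myt=myt, myp=myp,
        )

    def test_component_additivity_is_exact(self):
        res = self._result()
        assert res.af["extreme_cold"] + res.af["moderate_cold"] == pytest.approx(
            res.af["cold"], abs=0
        )
        assert res.af["moderate_heat"] + res.af["extreme_heat"] == pytest.approx(
            res.af["heat"], abs=0
        )
        assert res.af["cold"] + res.af["heat"] == pytest.approx(res.af["total"], abs=1e-12)
        assert res.lld["cold"] + res.lld["heat"] == pytest.approx(res.lld["total"], abs=1e-12)

    def test_af_links_attributable_to_total_yll(self):
        res = self._result()
        assert res.attributable_yll / res.total_yll * 100 == pytest.approx(res.af["total"])

    def test_zero_deaths_rejected(self):
        rf = toy_reduced()
        myt, myp = find_myt(rf)
        daily = attribute_daily(rf.temps, rf, myt)
        with pytest.raises(ValueError, match="death"):
            summarize_burden(daily, 5e4, 0.0, rf.temps, myt, myp)


class TestMonteCarloEci:
    def test_zero_vcov_collapses_to_point_estimate(self):
        rf = toy_reduced(vcov=np.zeros((5, 5)))
        myt, _ = find_myt(rf)
        eci, draws = monte_carlo_eci(rf, rf.temps, myt, 5e4, 3000.0, n_sim=100, seed=0)
        point = attribute_daily(rf.temps, rf, myt)["attr_yll"].sum() / 5e4 * 100
        lo, hi = eci["af_total"]
        assert lo == pytest.approx(hi) == pytest.approx(point)

    def test_same_seed_identical_bounds(self):
        rf = toy_reduced()
        myt, _ = find_myt(rf)
        a, _ = monte_carlo_eci(rf, rf.temps, myt, 5e4, 3000.0, n_sim=200, seed=42)
        b, _ = monte_carlo_eci(rf, rf.temps, myt, 5e4, 3000.0, n_sim=200, seed=42)
        assert a == b

    def test_quadrupled_vcov_doubles_interval_width(self):
        """For a locally linear functional of theta, scaling the coefficient
        covariance by 4 should roughly double the eCI width."""
        rf1 = toy_reduced(vcov=0.0004 * np.eye(5))
        rf4 = toy_reduced(vcov=0.0016 * np.eye(5))
        myt, _ = find_myt(rf1)
        e1, _ = monte_carlo_eci(rf1, rf1.temps, myt, 5e4, 3000.0, n_sim=4000, seed=1)
        e4, _ = monte_carlo_eci(rf4, rf4.temps, myt, 5e4, 3000.0, n_sim=4000, seed=1)
        w1 = e1["af_total"][1] - e1["af_total"][0]
        w4 = e4["af_total"][1] - e4["af_total"][0]
        assert w4 / w1 == pytest.approx(2.0, rel=0.1)

    def test_non_psd_vcov_rejected(self):
        bad = np.diag([1.0, 1, 1, 1, -1.0])
        rf = toy_reduced(vcov=bad)
        myt = 15.0
        with pytest.raises(ValueError, match="positive semidefinite"):
            monte_carlo_eci(rf, rf.temps, myt, 5e4, 3000.0, n_sim=100, seed=0)


class TestPoolStrata:
    def _loc(self, seed, scale=1.0):
        rng = np.random.default_rng(seed)
        temps = rng.uniform(-5, 35, 400)
        rf = toy_reduced(temps=temps)
        return attribute_location(
            rf, total_yll=scale * 4e4, total_deaths=scale * 2500.0,
            n_sim=100, seed=seed,
        )

    def test_single_location_stratum_is_identity(self):
        r = self._loc(1)
        pooled = pool_strata([r])
        assert pooled.af["total"] == pytest.approx(r.af["total"])
        assert pooled.lld["total"] == pytest.approx(r.lld["total"])
        assert pooled.eci["af_total"] == pytest.approx(r.eci["af_total"])

    def test_identical_locations_preserve_af(self):
        r = self._loc(2)
        pooled = pool_strata([r, r])
        assert pooled.af["total"] == pytest.approx(r.af["total"])

    def test_three_location_hand_sum(self):
        locs = [self._loc(s, scale) for s, scale in ((1, 1.0), (2, 2.0), (3, 0.5))]
        pooled = pool_strata(locs)
        num = sum(r.attributable_yll for r in locs)
        den_yll = sum(r.total_yll for r in locs)
        den_d = sum(r.total_deaths for r in locs)
        assert pooled.af["total"] == pytest.approx(num / den_yll * 100)
        assert pooled.lld["total"] == pytest.approx(num / den_d)

    def test_af_invariant_to_uniform_population_rescaling(self):
        rng = np.random.default_rng(7)
        temps = rng.uniform(-5, 35, 400)
        rf = toy_reduced(temps=temps)
        a = attribute_location(rf, total_yll=4e4, total_deaths=2500.0,
                               population=1e5, n_sim=50, seed=0)
        b = attribute_location(rf, total_yll=8e4, total_deaths=5000.0,
                               population=2e5, n_sim=50, seed=0)
        assert a.af["total"] == pytest.approx(b.af["total"])

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pool_strata([])
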