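"""MMT search, attributable numbers/fractions, component splits, Monte Carlo eCIs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tempmort as tm
from tempmort.attribution import (
    RangeCutoffs,
    attributable_forward,
    component_masks,
    cumulative_logrr_series,
    find_mmt,
    forward_death_window,
    monte_carlo_eci,
    split_components,
)
from tempmort.basis import ExposureBasisSpec, predict_curve
from tempmort.data import LocationSeries
from tempmort.first_stage import ReducedCurve

ESPEC = ExposureBasisSpec((8.0, 18.0, 22.0), (-5.0, 30.0))


def make_curve(eta, vcov=None, espec=ESPEC):
    if vcov is None:
        vcov = np.zeros((len(eta), len(eta)))
    return ReducedCurve(location="x", eta=np.asarray(eta, float),
                        vcov=np.asarray(vcov, float), espec=espec)


def curve_through_function(f, espec=ESPEC):
    """Least-squares projection of a target log-RR shape onto the basis
    (with a free intercept: only contrasts of the curve are identified)."""
    grid = np.linspace(*espec.boundary, 400)
    B = np.column_stack([np.ones(grid.size), espec.evaluate(grid)])
    sol, *_ = np.linalg.lstsq(B, f(grid), rcond=None)
    return make_curve(sol[1:], espec=espec)


@pytest.fixture
def temps(rng):
    return rng.normal(15.0, 6.0, 2000).clip(-4.9, 29.9)


class TestFindMmt:
    def test_increasing_curve_hits_lower_bound(self, temps):
        curve = curve_through_function(lambda x: 0.05 * x)
        assert find_mmt(curve, temps).mmt_percentile == 1

    def test_symmetric_u_hits_median(self, temps):
        med = np.median(temps)
        curve = curve_through_function(lambda x: 0.002 * (x - med) ** 2)
        res = find_mmt(curve, temps)
        assert abs(res.mmt_percentile - 50) <= 2

    def test_matches_exhaustive_grid_oracle(self, rng, temps):
        for _ in range(20):
            curve = make_curve(rng.normal(size=5))
            res = find_mmt(curve, temps)
            grid = np.percentile(temps, np.arange(1, 100))
            vals = curve.espec.evaluate(grid) @ curve.eta
            assert res.grid_logrr.min() == pytest.approx(0.0, abs=1e-14)
            assert vals[res.mmt_percentile - 1] == pytest.approx(vals.min(), abs=1e-12)

    def test_degenerate_temperatures_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            find_mmt(make_curve(np.zeros(5)), np.full(200, 10.0))


class TestCumulativeLogrr:
    def test_zero_at_mmt_and_for_null_curve(self, temps):
        curve = make_curve(np.zeros(5))
        assert np.allclose(cumulative_logrr_series(temps, curve, 15.0), 0.0)
        curve2 = curve_through_function(lambda x: 0.03 * np.abs(x - 18))
        b = cumulative_logrr_series(np.full(10, 18.37), curve2, 18.37)
        assert np.allclose(b, 0.0, atol=1e-12)

    def test_consistent_with_predict_curve(self, rng, temps):
        curve = make_curve(rng.normal(size=5), np.eye(5) * 0.01)
        b = cumulative_logrr_series(temps[:50], curve, 16.0)
        ref = predict_curve(curve.eta, curve.vcov, curve.espec, at=temps[:50],
                            ref=16.0)["logrr"].to_numpy()
        assert np.max(np.abs(b - ref)) < 1e-12


class TestAttributableForward:
    def test_all_days_at_mmt_give_zero(self, rng):
        deaths = rng.poisson(20, 300).astype(float)
        curve = curve_through_function(lambda x: 0.03 * np.abs(x - 18.0))
        an_day, an, af = attributable_forward(deaths, np.full(300, 18.0), curve, 18.0)
        assert an == pytest.approx(0.0, abs=1e-9)

    def test_constant_rr2_converges_to_half(self):
        """b = log 2 every day: AF -> 1 - 1/RR = 0.5 as the series grows."""
        curve = make_curve(np.zeros(5))

        class ShiftCurve(ReducedCurve):
            def __init__(self):
                super().__init__("s", np.zeros(5), np.zeros((5, 5)), ESPEC)

        curve = ShiftCurve()
        # constant log-RR via a linear curve and a shifted reference
        lin = curve_through_function(lambda x: (np.log(2) / 5.0) * x)
        for n, tol in ((200, 0.06), (2000, 0.006), (20000, 0.0006)):
            deaths = np.full(n, 10.0)
            temps = np.full(n, 20.0)
            # reference 5 degC below -> b = log2 everywhere
            _, _, af = attributable_forward(deaths, temps, lin, 15.0)
            assert af == pytest.approx(0.5, abs=tol)

    def test_matches_scalar_loop_oracle(self, rng):
        n = 200
        deaths = rng.poisson(15, n).astype(float)
        temps = rng.uniform(-4, 29, n)
        curve = make_curve(rng.normal(scale=0.05, size=5))
        mmt = 17.3
        an_day, an_total, af_total = attributable_forward(deaths, temps, curve, mmt)
        # independent day-by-day scalar loop
        contrast_ref = curve.espec.evaluate(np.array([mmt]))[0]
        oracle = np.zeros(n)
        for t in range(n):
            bt = (curve.espec.evaluate(temps[t:t + 1])[0] - contrast_ref) @ curve.eta
            window = deaths[t:min(t + 22, n)]
            oracle[t] = (1.0 - np.exp(-bt)) * window.mean()
        assert np.max(np.abs(an_day - oracle)) < 1e-12
        assert an_total == pytest.approx(oracle.sum(), abs=1e-10)

    def test_af_invariant_to_death_scaling(self, rng):
        n = 400
        deaths = rng.poisson(15, n).astype(float) + 1
        temps = rng.uniform(-4, 29, n)
        curve = make_curve(rng.normal(scale=0.05, size=5))
        _, an1, af1 = attributable_forward(deaths, temps, curve, 15.0)
        _, an7, af7 = attributable_forward(7 * deaths, temps, curve, 15.0)
        assert af7 == pytest.approx(af1, rel=1e-12)
        assert an7 == pytest.approx(7 * an1, rel=1e-12)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError, match="empty"):
            attributable_forward(np.array([]), np.array([]), make_curve(np.zeros(5)), 15.0)

    def test_forward_window_mean(self):
        deaths = np.arange(30, dtype=float)
        w = forward_death_window(deaths, max_lag=21)
        assert w[0] == pytest.approx(np.arange(22).mean())
        assert w[-1] == 29.0  # only itself remains at the series end


class TestSplitComponents:
    def test_all_below_mmt_is_pure_cold(self, rng):
        temps = rng.uniform(-4, 10, 500)
        an_day = rng.uniform(0, 1, 500)
        cut = RangeCutoffs.from_temps(temps)
        comps = split_components(an_day, temps, mmt=25.0, cutoffs=cut)
        assert comps["heat"] == 0.0
        assert comps["cold"] == pytest.approx(comps["total"], abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(5.0, 25.0))
    def test_exact_partition(self, seed, mmt):
        rng = np.random.default_rng(seed)
        temps = rng.uniform(-4, 29, 300)
        an_day = rng.normal(size=300)
        cut = RangeCutoffs.from_temps(temps)
        comps = split_components(an_day, temps, mmt, cut)
        assert comps["cold"] + comps["heat"] == pytest.approx(comps["total"], abs=1e-12)
        assert comps["extreme_cold"] + comps["moderate_cold"] == pytest.approx(
            comps["cold"], abs=1e-12)
        assert comps["extreme_heat"] + comps["moderate_heat"] == pytest.approx(
            comps["heat"], abs=1e-12)
        assert comps["total"] == pytest.approx(an_day.sum(), abs=1e-12)

    def test_heavy_cold_tail_extreme_share_matches_filter_oracle(self, rng):
        temps = np.r_[rng.normal(-2, 2, 200), rng.normal(18, 4, 800)]
        an_day = rng.uniform(0, 1, 1000)
        cut = RangeCutoffs.from_temps(temps)
        comps = split_components(an_day, temps, mmt=20.0, cutoffs=cut)
        t25 = np.percentile(temps, 2.5)
        oracle = an_day[(temps < 20.0) & (temps < t25)].sum()
        assert comps["extreme_cold"] == pytest.approx(oracle, abs=1e-12)

    def test_masks_cover_each_day_once(self, rng):
        temps = rng.uniform(-4, 29, 400)
        masks = component_masks(temps, 15.0, RangeCutoffs.from_temps(temps))
        fine = (masks["extreme_cold"].astype(int) + masks["moderate_cold"]
                + masks["moderate_heat"] + masks["extreme_heat"])
        assert np.all(fine == 1)

    def test_cutoffs_validation(self):
        with pytest.raises(ValueError, match="2.5"):
            RangeCutoffs(percentiles=(10.0, 90.0), temperatures=(1.0, 2.0))
        with pytest.raises(ValueError, match="increasing"):
            RangeCutoffs(percentiles=(2.5, 2.5, 97.5), temperatures=(1.0, 1.0, 2.0))


def _mc_inputs(rng, n=400, vcov_scale=0.01):
    temps = rng.uniform(-4, 29, n)
    deaths = rng.poisson(20, n)
    series = LocationSeries("loc0", __import__("pandas").date_range("2000-01-03", periods=n),
                            deaths, temps)
    curve = make_curve(rng.normal(scale=0.05, size=5), np.eye(5) * vcov_scale)
    mmt = find_mmt(curve, temps)
    cut = RangeCutoffs.from_temps(temps)
    return [series], [curve], [mmt], [cut]


class TestMonteCarloEci:
    def test_zero_covariance_collapses_bounds(self, rng):
        series, curves, mmts, cuts = _mc_inputs(rng, vcov_scale=0.0)
        res = monte_carlo_eci(series, curves, mmts, cuts, n_sim=200, seed=3)
        total = res.query("level == 'total'")
        assert np.allclose(total["af_low"], total["af"], atol=1e-12)
        assert np.allclose(total["af_high"], total["af"], atol=1e-12)

    def test_seed_determinism(self, rng):
        series, curves, mmts, cuts = _mc_inputs(rng)
        a = monte_carlo_eci(series, curves, mmts, cuts, n_sim=300, seed=11)
        b = monte_carlo_eci(series, curves, mmts, cuts, n_sim=300, seed=11)
        assert a.equals(b)
        c = monte_carlo_eci(series, curves, mmts, cuts, n_sim=300, seed=12)
        assert not np.allclose(a["af_low"], c["af_low"])

    def test_additivity_of_point_estimates(self, rng):
        series, curves, mmts, cuts = _mc_inputs(rng)
        res = monte_carlo_eci(series, curves, mmts, cuts, n_sim=150, seed=1)
        wide = res.query("level == 'total'").set_index("component")["af"]
        assert wide["cold"] + wide["heat"] == pytest.approx(wide["total"], abs=1e-12)

    def test_small_nsim_rejected(self, rng):
        series, curves, mmts, cuts = _mc_inputs(rng)
        with pytest.raises(ValueError, match="n_sim"):
            monte_carlo_eci(series, curves, mmts, cuts, n_sim=10, seed=1)
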