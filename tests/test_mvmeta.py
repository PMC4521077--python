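"""Multivariate meta-regression: REML, heterogeneity, Wald tests, BLUPs."""

import numpy as np
import pandas as pd
import pytest

from tempmort.basis import ExposureBasisSpec
from tempmort.first_stage import ReducedCurve
from tempmort.mvmeta import (
    MetaDesign,
    MetaFit,
    _gls,
    build_meta_design,
    cochran_q_i2,
    compute_blups,
    fit_mvmeta,
    wald_test,
)

ESPEC = ExposureBasisSpec((8.0, 18.0, 22.0), (0.0, 30.0))


def make_curves(y, S):
    """Wrap arrays of estimates/covariances into ReducedCurve records."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    out = []
    for i in range(y.shape[0]):
        Si = np.atleast_2d(np.asarray(S[i], dtype=float))
        out.append(ReducedCurve(location=f"s{i}", eta=y[i], vcov=Si, espec=ESPEC))
    return out


def simulate_meta(rng, m=40, q=2, beta=None, psi=None, design=None):
    if beta is None:
        beta = np.array([[0.5, -0.2], [0.3, 0.1]])  # p x q
    if psi is None:
        psi = np.array([[0.04, 0.01], [0.01, 0.02]])
    if design is None:
        design = np.column_stack([np.ones(m), rng.normal(size=m)])
    S = []
    y = []
    for i in range(m):
        A = rng.normal(size=(q, q)) * 0.15
        Si = A @ A.T + 0.02 * np.eye(q)
        mean = design[i] @ beta
        yi = rng.multivariate_normal(mean, Si + psi)
        S.append(Si)
        y.append(yi)
    return np.array(y), S, design, beta, psi


def reml_grid_oracle(y, s2, psi_grid):
    """Dense grid search of the univariate intercept-only REML objective."""
    best, best_ll = None, np.inf
    for psi in psi_grid:
        w = 1.0 / (s2 + psi)
        mu = np.sum(w * y) / np.sum(w)
        n2ll = np.sum(np.log(s2 + psi)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
        if n2ll < best_ll:
            best, best_ll = psi, n2ll
    return best


class TestFitMvmeta:
    def test_fixed_effects_gls_is_inverse_variance_mean(self, rng):
        """With Psi = 0, equal S_i and an intercept-only design, GLS is the
        inverse-variance weighted mean."""
        y = rng.normal(size=(10, 1)) + 2.0
        s2 = rng.uniform(0.5, 2.0, size=10)
        S = [np.array([[v]]) for v in s2]
        X = np.ones((10, 1))
        b, *_ = _gls(y, np.array(S), X, np.zeros((1, 1)))
        expected = np.sum(y[:, 0] / s2) / np.sum(1 / s2)
        assert b[0] == pytest.approx(expected, rel=1e-12)

    def test_univariate_reml_matches_grid_oracle(self, rng):
        m = 25
        psi_true = 0.3
        s2 = rng.uniform(0.1, 0.5, size=m)
        y = rng.normal(1.0, np.sqrt(s2 + psi_true))
        curves = make_curves(y[:, None], [np.array([[v]]) for v in s2])
        design = MetaDesign(X=np.ones((m, 1)), names=["intercept"])
        fit = fit_mvmeta(curves, design, method="reml")
        grid = np.linspace(0, 10 * y.var(), 4001)
        psi_oracle = reml_grid_oracle(y, s2, grid)
        assert fit.Psi[0, 0] == pytest.approx(psi_oracle, abs=grid[1] - grid[0])

    def test_parameter_recovery(self, rng):
        """Mean bias of the fixed effects across replicates is within Monte
        Carlo error of zero, and Psi is recovered to the right scale."""
        n_rep = 30
        biases, psis = [], []
        for _ in range(n_rep):
            y, S, X, beta, psi = simulate_meta(rng)
            curves = make_curves(y, S)
            design = MetaDesign(X=X, names=["intercept", "x"])
            fit = fit_mvmeta(curves, design)
            biases.append(fit.beta - beta)
            psis.append(np.diag(fit.Psi))
        biases = np.array(biases)
        mc_se = biases.std(axis=0) / np.sqrt(n_rep)
        assert np.all(np.abs(biases.mean(axis=0)) < 4 * mc_se + 1e-6)
        med = np.median(psis, axis=0)
        assert np.all(np.abs(med - np.array([0.04, 0.02])) < 0.5 * np.array([0.04, 0.02]))

    def test_too_few_locations_raise(self, rng):
        y, S, X, *_ = simulate_meta(rng, m=2)
        with pytest.raises(ValueError, match="locations"):
            fit_mvmeta(make_curves(y, S), MetaDesign(X=X, names=["intercept", "x"]))

    def test_reml_invariant_to_indicator_recoding(self, rng):
        """Reparameterising the country indicators (changing the reference
        level) leaves the REML loglik, Psi, and BLUPs unchanged."""
        m = 16
        countries = np.repeat(["A", "B"], m // 2)
        meta = pd.DataFrame({
            "location": [f"s{i}" for i in range(m)],
            "country": countries,
            "avg_tmean": rng.uniform(5, 25, m),
            "range_tmean": rng.uniform(15, 35, m),
        })
        y, S, _, _, _ = simulate_meta(rng, m=m)
        y[countries == "B"] += 0.3
        curves = make_curves(y, S)
        d1 = build_meta_design(meta, use_temp_range=False)
        X2 = d1.X.copy()
        X2[:, 1] = 1.0 - X2[:, 1]  # swap the indicator's reference level
        d2 = MetaDesign(X=X2, names=d1.names)
        f1 = fit_mvmeta(curves, d1)
        f2 = fit_mvmeta(curves, d2)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
        assert np.max(np.abs(f1.Psi - f2.Psi)) < 1e-6
        b1 = compute_blups(f1, curves, d1)
        b2 = compute_blups(f2, curves, d2)
        for u, v in zip(b1, b2):
            assert np.max(np.abs(u.eta - v.eta)) < 1e-6


class TestWald:
    def _fit(self, b, V):
        q = 1
        return MetaFit(beta=b.reshape(-1, q), b=b, V_beta=V, Psi=np.zeros((q, q)),
                       loglik=0.0, method="reml", Q=0.0, Q_df=1, Q_pvalue=1.0, I2=0.0,
                       design_names=["intercept", "x"])

    def test_zero_coefficients_give_zero_statistic(self):
        fit = self._fit(np.array([0.0, 0.0]), np.eye(2))
        W, df, p = wald_test(fit, [1])
        assert W == 0.0 and p == 1.0

    def test_single_df_equals_squared_z(self):
        fit = self._fit(np.array([0.5, 1.2]), np.diag([0.04, 0.09]))
        W, df, p = wald_test(fit, [1])
        z = 1.2 / 0.3
        assert W == pytest.approx(z**2, abs=1e-12)
        assert df == 1

    def test_null_type_one_error_calibrated(self, rng):
        """Under a null meta-predictor the Wald test rejects at ~5%."""
        reject = 0
        n_rep = 300
        for _ in range(n_rep):
            m = 20
            s2 = rng.uniform(0.1, 0.3, m)
            y = rng.normal(1.0, np.sqrt(s2 + 0.1))
            x = rng.normal(size=m)  # unrelated
            curves = make_curves(y[:, None], [np.array([[v]]) for v in s2])
            design = MetaDesign(X=np.column_stack([np.ones(m), x]),
                                names=["intercept", "x"])
            fit = fit_mvmeta(curves, design)
            _, _, p = wald_test(fit, "x")
            reject += p < 0.05
        assert 0.02 <= reject / n_rep <= 0.08

    def test_invalid_subsets_raise(self):
        fit = self._fit(np.array([0.5, 1.2]), np.eye(2))
        with pytest.raises(ValueError):
            wald_test(fit, [])
        with pytest.raises(ValueError):
            wald_test(fit, [5])


class TestCochranQ:
    def test_identical_estimates_give_zero_q(self):
        curves = make_curves(np.full((6, 1), 1.5), [np.array([[0.2]])] * 6)
        design = MetaDesign(X=np.ones((6, 1)), names=["intercept"])
        Q, df, p, I2 = cochran_q_i2(curves, design)
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert I2 == 0.0
        assert df == 5

    def test_univariate_matches_textbook_formula(self, rng):
        m = 12
        s2 = rng.uniform(0.1, 0.4, m)
        y = rng.normal(2.0, 0.8, m)
        curves = make_curves(y[:, None], [np.array([[v]]) for v in s2])
        design = MetaDesign(X=np.ones((m, 1)), names=["intercept"])
        Q, df, _, I2 = cochran_q_i2(curves, design)
        w = 1 / s2
        mu = np.sum(w * y) / np.sum(w)
        Q_text = np.sum(w * (y - mu) ** 2)
        assert Q == pytest.approx(Q_text, rel=1e-10)
        assert df == m - 1
        assert I2 == pytest.approx(max(0, (Q_text - df) / Q_text) * 100, rel=1e-10)


class TestBlups:
    def test_zero_psi_gives_fixed_effect_prediction(self, rng):
        y, S, X, *_ = simulate_meta(rng, m=10)
        curves = make_curves(y, S)
        design = MetaDesign(X=X, names=["intercept", "x"])
        fit = fit_mvmeta(curves, design)
        fit.Psi = np.zeros_like(fit.Psi)
        blups = compute_blups(fit, curves, design)
        for i, b in enumerate(blups):
            pred, _ = fit.predict(X[i])
            assert np.max(np.abs(b.eta - pred)) < 1e-12

    def test_zero_s_gives_location_estimate(self, rng):
        y, _, X, *_ = simulate_meta(rng, m=10)
        S = [np.zeros((2, 2))] * 10
        curves = make_curves(y, S)
        design = MetaDesign(X=X, names=["intercept", "x"])
        fit = fit_mvmeta(make_curves(y, [np.eye(2) * 0.1] * 10), design)
        fit.Psi = np.eye(2) * 0.05
        blups = compute_blups(fit, curves, design)
        for i, b in enumerate(blups):
            assert np.max(np.abs(b.eta - y[i])) < 1e-12

    def test_scalar_equal_variances_midpoint_shrinkage(self):
        """With S = Psi the BLUP is the midpoint of the location estimate and
        the pooled prediction (shrinkage weight 1/2)."""
        y = np.array([[1.0], [3.0], [2.0], [0.5], [3.5]])
        S = [np.array([[0.2]])] * 5
        curves = make_curves(y, S)
        design = MetaDesign(X=np.ones((5, 1)), names=["intercept"])
        fit = fit_mvmeta(curves, design)
        fit.Psi = np.array([[0.2]])
        blups = compute_blups(fit, curves, design)
        pred = fit.predict(np.array([1.0]))[0][0]
        for i, b in enumerate(blups):
            assert b.eta[0] == pytest.approx((y[i, 0] + pred) / 2, rel=1e-10)

    def test_shrinkage_monotone_in_s(self):
        """Larger within-location variance pulls the BLUP closer to the
        pooled prediction."""
        y = np.array([[2.0], [1.0], [1.2], [0.8], [1.1]])
        design = MetaDesign(X=np.ones((5, 1)), names=["intercept"])
        dists = []
        for s in (0.05, 0.2, 1.0, 5.0):
            S = [np.array([[s]])] * 5
            curves = make_curves(y, S)
            fit = fit_mvmeta(curves, design)
            fit.Psi = np.array([[0.1]])
            b0 = compute_blups(fit, curves, design)[0].eta[0]
            pred = fit.predict(np.array([1.0]))[0][0]
            dists.append(abs(b0 - pred))
        assert all(a > b for a, b in zip(dists, dists[1:]))

    def test_borrowing_information_reduces_mse(self, rng):
        """BLUPs for imprecise locations beat the raw estimates in MSE."""
        n_rep = 200
        err_raw, err_blup = [], []
        for _ in range(n_rep):
            m = 12
            theta = rng.normal(1.0, np.sqrt(0.02), m)  # true location effects
            s2 = np.full(m, 0.02)
            s2[0] = 0.8  # one small-count, very imprecise location
            y = rng.normal(theta, np.sqrt(s2))
            curves = make_curves(y[:, None], [np.array([[v]]) for v in s2])
            design = MetaDesign(X=np.ones((m, 1)), names=["intercept"])
            fit = fit_mvmeta(curves, design)
            blup = compute_blups(fit, curves, design)[0].eta[0]
            err_raw.append((y[0] - theta[0]) ** 2)
            err_blup.append((blup - theta[0]) ** 2)
        assert np.mean(err_blup) < np.mean(err_raw)
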