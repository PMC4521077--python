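"""Multivariate random-effects meta-regression for pooling reduced curves.

Each location i contributes a q-vector estimate theta_i (the overall cumulative
exposure-response coefficients, q = vx) with within-location covariance S_i.
The model is

    theta_i ~ N( (x_i kron I_q) b,  S_i + Psi )

where x_i is the row of location-level meta-predictors (intercept, country
indicators, average temperature, temperature range), b the vectorised fixed
effects, and Psi the q x q between-location covariance.  Psi is estimated by
restricted (or full) maximum likelihood, profiling out b by generalised least
squares and optimising over the Cholesky factor of Psi (log-diagonal), which
enforces positive semidefiniteness without constraints.

Heterogeneity is summarised by the multivariate Cochran Q statistic (residual
weighted sum of squares about the fixed-effects fit) and I^2 = (Q - df)/Q.
Best linear unbiased predictions shrink each location's estimate towards its
meta-regression prediction in proportion to the relative sizes of S_i and Psi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .first_stage import ReducedCurve

__all__ = [
    "MetaDesign",
    "MetaFit",
    "BlupCurve",
    "build_meta_design",
    "fit_mvmeta",
    "wald_test",
    "cochran_q_i2",
    "compute_blups",
]


@dataclass
class MetaDesign:
    """Per-location meta-predictor rows (one row per location)."""

    X: np.ndarray  # m x p
    names: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("meta-design is rank deficient")

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class BlupCurve(ReducedCurve):
    """Per-location best linear unbiased prediction (same contract as
    ReducedCurve, marked as a BLUP).

    Also carries the decomposition of its covariance into the shared
    fixed-effect component and the location-specific residual component:
    V = F V_b F' + G with F = (I - A) X~_i and G = A S_i A'.  Cross-location
    covariance of BLUPs is F_i V_b F_j', which joint Monte Carlo resampling
    uses; marginals are unchanged.
    """

    fe_loading: np.ndarray | None = None  # F_i, q x pq
    resid_cov: np.ndarray | None = None   # G_i, q x q
    V_fixed: np.ndarray | None = None     # V_b, pq x pq (shared across locations)


@dataclass
class MetaFit:
    """Pooled meta-regression fit."""

    beta: np.ndarray            # p x q fixed-effect matrix
    b: np.ndarray               # vectorised (predictor-major) fixed effects, pq
    V_beta: np.ndarray          # pq x pq covariance of b
    Psi: np.ndarray             # q x q between-location covariance
    loglik: float
    method: str
    Q: float
    Q_df: int
    Q_pvalue: float
    I2: float
    design_names: list[str] = field(default_factory=list)
    converged: bool = True
    n_restarts_used: int = 0

    @property
    def q(self) -> int:
        return self.Psi.shape[0]

    def predict(self, x_row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fixed-effect prediction X~ b and its covariance for one design row."""
        Xt = np.kron(np.atleast_1d(x_row), np.eye(self.q))
        return Xt @ self.b, Xt @ self.V_beta @ Xt.T


def build_meta_design(
    metadata: pd.DataFrame,
    use_country: bool = True,
    use_avg_temp: bool = True,
    use_temp_range: bool = True,
) -> MetaDesign:
    """Design: intercept + reference-coded country indicators (reference =
    first country alphabetically) + average temperature + temperature range."""
    m = len(metadata)
    cols = [np.ones(m)]
    names = ["intercept"]
    if use_country and "country" in metadata and metadata["country"].nunique() > 1:
        countries = sorted(metadata["country"].unique())
        for c in countries[1:]:
            cols.append((metadata["country"] == c).to_numpy(dtype=float))
            names.append(f"country[{c}]")
    if use_avg_temp:
        cols.append(metadata["avg_tmean"].to_numpy(dtype=float))
        names.append("avg_tmean")
    if use_temp_range:
        cols.append(metadata["range_tmean"].to_numpy(dtype=float))
        names.append("range_tmean")
    return MetaDesign(X=np.column_stack(cols), names=names)


# ---------------------------------------------------------------------------
# (RE)ML machinery


def _chol_to_psi(par: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.diag_indices(q)] = np.exp(par[:q])
    if q > 1:
        L[np.tril_indices(q, -1)] = par[q:]
    return L @ L.T


def _psi_to_chol_par(Psi: np.ndarray) -> np.ndarray:
    q = Psi.shape[0]
    w, v = np.linalg.eigh((Psi + Psi.T) / 2)
    w = np.clip(w, 1e-10 * max(w.max(), 1e-10), None)
    L = np.linalg.cholesky(v @ np.diag(w) @ v.T)
    par = np.concatenate([np.log(np.diag(L)), L[np.tril_indices(q, -1)]])
    return par


def _gls(y: np.ndarray, S: np.ndarray, X: np.ndarray, Psi: np.ndarray):
    """GLS at fixed Psi.  Returns b, U (information), residuals, logdet terms,
    and the per-location inverses of Sigma_i = S_i + Psi."""
    m, q = y.shape
    p = X.shape[1]
    U = np.zeros((p * q, p * q))
    v = np.zeros(p * q)
    logdet_sigma = 0.0
    Sinv = np.empty((m, q, q))
    eye = np.eye(q)
    for i in range(m):
        c, low = cho_factor(S[i] + Psi, lower=True)
        logdet_sigma += 2.0 * np.sum(np.log(np.diag(c)))
        Sinv[i] = cho_solve((c, low), eye)
        xi = X[i]
        U += np.kron(np.outer(xi, xi), Sinv[i])
        v += np.kron(xi, Sinv[i] @ y[i])
    b = np.linalg.solve(U, v)
    resid = y - (X @ b.reshape(X.shape[1], q))
    return b, U, resid, logdet_sigma, Sinv


def _neg2_loglik(par, y, S, X, method: str) -> float:
    m, q = y.shape
    Psi = _chol_to_psi(par, q)
    try:
        b, U, resid, logdet_sigma, Sinv = _gls(y, S, X, Psi)
    except np.linalg.LinAlgError:
        return 1e12
    quad = float(np.einsum("iq,iqr,ir->", resid, Sinv, resid))
    n2ll = logdet_sigma + quad
    if method == "reml":
        sign, logdet_u = np.linalg.slogdet(U)
        if sign <= 0:
            return 1e12
        n2ll += logdet_u
    return n2ll


def _neg2_loglik_grad(par, y, S, X, method: str):
    """Objective and its analytic gradient in the Cholesky parameterisation.

    Profiling b out is exact for the gradient (the quadratic form is
    stationary in b at the GLS solution), so

        d(-2ll) = sum_i tr[(Sinv_i - u_i u_i' - Q_i) dPsi],
        u_i = Sinv_i r_i,   Q_i = Sinv_i B_i Sinv_i  (REML only),

    with B_i the x_i-weighted block contraction of U^{-1}; the chain rule
    through Psi = L L' gives dF/dL = 2 M L (log-scaled on the diagonal).
    """
    m, q = y.shape
    Psi = _chol_to_psi(par, q)
    try:
        b, U, resid, logdet_sigma, Sinv = _gls(y, S, X, Psi)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(par)
    quad = float(np.einsum("iq,iqr,ir->", resid, Sinv, resid))
    n2ll = logdet_sigma + quad
    M = Sinv.sum(axis=0)
    u = np.einsum("iqr,ir->iq", Sinv, resid)
    M -= np.einsum("iq,ir->qr", u, u)
    if method == "reml":
        sign, logdet_u = np.linalg.slogdet(U)
        if sign <= 0:
            return 1e12, np.zeros_like(par)
        n2ll += logdet_u
        Uinv = np.linalg.inv(U)
        p = X.shape[1]
        blocks = Uinv.reshape(p, q, p, q)
        # B_i = sum_{jk} x_ij x_ik Uinv[j,k] ; Q_i = Sinv_i B_i Sinv_i
        B = np.einsum("ij,jqkr,ik->iqr", X, blocks, X)
        M -= np.einsum("iqa,iab,ibr->qr", Sinv, B, Sinv)
    M = (M + M.T) / 2
    L = np.zeros((q, q))
    L[np.diag_indices(q)] = np.exp(par[:q])
    if q > 1:
        L[np.tril_indices(q, -1)] = par[q:]
    dL = 2.0 * M @ L
    grad = np.concatenate([np.diag(dL) * np.diag(L), dL[np.tril_indices(q, -1)]])
    return n2ll, grad


def _standardise(X: np.ndarray, names: list[str]):
    """Centre/scale continuous columns; returns X_s and the matrix T with
    X = X_s @ T (used to undo the transform on output)."""
    p = X.shape[1]
    T = np.eye(p)
    Xs = X.copy()
    has_intercept = np.allclose(X[:, 0], 1.0)
    for j in range(p):
        col = X[:, j]
        uniq = np.unique(col)
        binary = uniq.size <= 2 and set(np.round(uniq, 12)).issubset({0.0, 1.0})
        if j == 0 and has_intercept:
            continue
        if binary:
            continue
        mu, sd = col.mean(), col.std()
        if sd == 0:
            raise ValueError(f"constant meta-predictor {names[j]!r}")
        if has_intercept:
            Xs[:, j] = (col - mu) / sd
            T[0, j] = mu
        else:
            Xs[:, j] = col / sd
        T[j, j] = sd
    return Xs, T


def fit_mvmeta(
    curves: list[ReducedCurve],
    design: MetaDesign,
    method: str = "reml",
    n_restarts: int = 5,
    seed: int = 0,
) -> MetaFit:
    """Fit the multivariate meta-regression by (RE)ML.

    The profile likelihood over the Cholesky parameterisation of Psi is
    optimised by L-BFGS-B with numerical gradients; jittered restarts are used
    when the optimiser fails to converge.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    m = len(curves)
    if m < design.p + 1:
        raise ValueError(f"{m} locations cannot identify {design.p} meta-predictors")
    q = curves[0].eta.size
    y = np.stack([c.eta for c in curves])
    S = np.stack([c.vcov for c in curves])
    for i, c in enumerate(curves):
        eig = np.linalg.eigvalsh((S[i] + S[i].T) / 2)
        if eig.min() < -1e-8 * max(1.0, abs(eig).max()):
            raise ValueError(f"within-location covariance of {c.location!r} is not PSD")
        S[i] = (S[i] + S[i].T) / 2

    Xs, T = _standardise(design.X, design.names)

    # Moment-based start: residual covariance about the FE fit minus mean S.
    _, _, resid_fe, _, _ = _gls(y, S, Xs, np.zeros((q, q)))
    Psi0 = np.atleast_2d(np.cov(resid_fe.T)) - S.mean(axis=0) if m > 1 else np.eye(q)
    par0 = _psi_to_chol_par(np.atleast_2d(Psi0))

    bounds = [(-15.0, 12.0)] * q + [(None, None)] * (q * (q - 1) // 2)
    rng = np.random.default_rng(seed)
    best = None
    restarts = 0
    start = par0
    for attempt in range(n_restarts + 1):
        res = optimize.minimize(
            _neg2_loglik_grad, start, args=(y, S, Xs, method),
            method="L-BFGS-B", bounds=bounds, jac=True,
            options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if res.success and np.isfinite(res.fun):
            break
        restarts += 1
        start = par0 + rng.normal(scale=0.5, size=par0.size)
    assert best is not None

    Psi = _chol_to_psi(best.x, q)
    Psi = (Psi + Psi.T) / 2
    b_s, U, _, _, _ = _gls(y, S, Xs, Psi)
    V_bs = np.linalg.inv(U)

    # Undo the internal standardisation: X = X_s T  =>  beta = T^-1 beta_s.
    Tinv = np.linalg.inv(T)
    G = np.kron(Tinv, np.eye(q))
    b = G @ b_s
    V_b = G @ V_bs @ G.T

    Q, Q_df, Q_p, I2 = cochran_q_i2(curves, design)
    return MetaFit(
        beta=b.reshape(design.p, q),
        b=b,
        V_beta=(V_b + V_b.T) / 2,
        Psi=Psi,
        loglik=-0.5 * float(best.fun),
        method=method,
        Q=Q,
        Q_df=Q_df,
        Q_pvalue=Q_p,
        I2=I2,
        design_names=list(design.names),
        converged=bool(best.success),
        n_restarts_used=restarts,
    )


def wald_test(fit: MetaFit, subset) -> tuple[float, int, float]:
    """Multivariate Wald test of H0: b[subset] = 0.

    ``subset`` is either an index set into the vectorised fixed effects or a
    meta-predictor name (testing all q of its coefficients jointly).
    """
    if isinstance(subset, str):
        if subset not in fit.design_names:
            raise ValueError(f"unknown meta-predictor {subset!r}")
        j = fit.design_names.index(subset)
        idx = np.arange(j * fit.q, (j + 1) * fit.q)
    else:
        idx = np.asarray(list(subset), dtype=int)
    if idx.size == 0:
        raise ValueError("empty coefficient subset")
    if idx.min() < 0 or idx.max() >= fit.b.size:
        raise ValueError("coefficient subset out of range")
    bs = fit.b[idx]
    Vs = fit.V_beta[np.ix_(idx, idx)]
    if np.linalg.cond(Vs) > 1e12:
        raise ValueError("singular covariance block in Wald test")
    W = float(bs @ np.linalg.solve(Vs, bs))
    df = idx.size
    p = float(stats.chi2.sf(W, df))
    return W, df, p


def cochran_q_i2(curves: list[ReducedCurve], design: MetaDesign):
    """Multivariate Cochran Q about the fixed-effects (Psi = 0) GLS fit, and
    I^2 = max(0, (Q - df)/Q) * 100."""
    y = np.stack([c.eta for c in curves])
    S = np.stack([(c.vcov + c.vcov.T) / 2 for c in curves])
    m, q = y.shape
    Xs, _ = _standardise(design.X, design.names)
    try:
        _, _, resid, _, Sinv = _gls(y, S, Xs, np.zeros((q, q)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular within-location covariance in Q computation") from exc
    Q = float(np.einsum("iq,iqr,ir->", resid, Sinv, resid))
    df = m * q - design.p * q
    pval = float(stats.chi2.sf(Q, df)) if df > 0 else np.nan
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return Q, df, pval, I2


def compute_blups(
    fit: MetaFit,
    curves: list[ReducedCurve],
    design: MetaDesign,
) -> list[BlupCurve]:
    """Best linear unbiased predictions.

    theta~_i = X~_i b + Psi (S_i + Psi)^-1 (theta_i - X~_i b); the covariance
    combines the conditional variance of the random effect with the fixed-
    effect uncertainty:  A S_i A' + (I - A) X~ V_b X~' (I - A)',
    A = Psi (S_i + Psi)^-1.  Limits: S_i -> 0 gives the location estimate,
    Psi -> 0 gives the fixed-effect prediction.
    """
    q = fit.q
    eye = np.eye(q)
    out: list[BlupCurve] = []
    for i, c in enumerate(curves):
        S = (c.vcov + c.vcov.T) / 2
        pred, V_pred = fit.predict(design.X[i])
        M = S + fit.Psi
        if np.linalg.cond(M) > 1e14:
            raise ValueError(f"singular S_i + Psi for location {c.location!r}")
        A = fit.Psi @ np.linalg.inv(M)
        eta = pred + A @ (c.eta - pred)
        IA = eye - A
        Xt = np.kron(design.X[i], eye)
        F = IA @ Xt
        G = A @ S @ A.T
        G = (G + G.T) / 2
        V = G + F @ fit.V_beta @ F.T
        V = (V + V.T) / 2
        out.append(BlupCurve(location=c.location, eta=eta, vcov=V, espec=c.espec,
                             fe_loading=F, resid_cov=G, V_fixed=fit.V_beta))
    return out
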