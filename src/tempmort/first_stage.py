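"""Location-specific quasi-Poisson DLNM fit and reduction to the overall curve.

The first-stage model for one location regresses daily all-cause death counts
on a natural cubic spline of calendar time (8 df per year, absorbing seasonal
and long-term trends), reference-coded day-of-week indicators, and the
cross-basis of temperature (``basis.build_crossbasis``), under a log link with
the variance inflated by a Pearson-estimated dispersion.

The fit is then *reduced*: summing the lag basis over the integer lag grid
l = 0..21 gives the vector c, and eta = (I_vx kron c') theta_cb is the
coefficient vector of the overall cumulative exposure-response curve, with
covariance propagated through the same linear map.  Only (eta, V_eta) is
carried into the second stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .basis import CrossBasisMatrix, ExposureBasisSpec, LagBasisSpec, build_crossbasis

__all__ = [
    "FirstStageFit",
    "ReducedCurve",
    "build_time_spline",
    "build_dow",
    "fit_quasipoisson",
    "reduce_to_overall",
    "fit_location",
    "curves_to_frame",
    "curves_from_frame",
]

DAYS_PER_YEAR = 365.25


@dataclass
class FirstStageFit:
    """Full quasi-Poisson fit: coefficients, scaled covariance, dispersion,
    and a map from design-block names to column slices."""

    coefficients: np.ndarray
    vcov: np.ndarray
    dispersion: float
    df_resid: int
    column_map: dict[str, slice]
    deviance: float
    n_iter: int

    def block(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        s = self.column_map[name]
        return self.coefficients[s], self.vcov[s, s]


@dataclass
class ReducedCurve:
    """Overall cumulative exposure-response summary for one location."""

    location: str
    eta: np.ndarray
    vcov: np.ndarray
    espec: ExposureBasisSpec

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        self.vcov = np.asarray(self.vcov, dtype=float)
        if not np.all(np.isfinite(self.eta)):
            raise ValueError(f"{self.location}: non-finite reduced coefficients")


def build_time_spline(dates: pd.DatetimeIndex, df_per_year: float = 8.0) -> np.ndarray:
    """Natural cubic spline of the day index with round(df_per_year * n_years)
    total degrees of freedom; knots at equally spaced quantiles of the index."""
    from .basis import natural_cubic_basis

    dates = pd.DatetimeIndex(dates)
    if not dates.is_monotonic_increasing:
        raise ValueError("dates must be sorted")
    n = len(dates)
    df = int(round(df_per_year * n / DAYS_PER_YEAR))
    if df < 2:
        raise ValueError(f"time spline df = {df} < 2; series too short for {df_per_year} df/year")
    idx = np.arange(n, dtype=float)
    # df columns without intercept -> df - 1 internal knots.
    probs = np.linspace(0, 100, df + 1)[1:-1]
    knots = np.percentile(idx, probs)
    return natural_cubic_basis(idx, internal_knots=knots, boundary=(idx[0], idx[-1]),
                               with_intercept=False)


def build_dow(dates: pd.DatetimeIndex) -> np.ndarray:
    """Reference-coded weekday indicators (Monday is the reference): 6 columns
    Tue..Sun."""
    dow = pd.DatetimeIndex(dates).dayofweek.to_numpy()  # Monday = 0
    cols = [(dow == d).astype(float) for d in range(1, 7)]
    return np.column_stack(cols)


def _check_full_rank(X: np.ndarray) -> None:
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = np.flatnonzero(diag < tol)
    if bad.size:
        raise ValueError(f"design matrix is rank deficient; collinear columns {bad.tolist()}")


def fit_quasipoisson(
    y: np.ndarray,
    X: np.ndarray,
    column_map: dict[str, slice] | None = None,
    tol: float = 1e-9,
    maxiter: int = 50,
) -> FirstStageFit:
    """Log-link quasi-Poisson fit by IRLS.

    Dispersion phi is the Pearson chi-square over the residual degrees of
    freedom; the covariance is phi * (X'WX)^-1.  Raises on rank deficiency or
    non-convergence.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(y < 0):
        raise ValueError("negative counts in y")
    _check_full_rank(X)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter, tol=tol, scale="X2")
    if not getattr(res, "converged", True):
        raise RuntimeError(
            f"IRLS did not converge within {maxiter} iterations "
            f"(deviance trace tail: {res.fit_history['deviance'][-3:]})"
        )
    if column_map is None:
        column_map = {"all": slice(0, X.shape[1])}
    return FirstStageFit(
        coefficients=np.asarray(res.params, dtype=float),
        vcov=np.asarray(res.cov_params(), dtype=float),
        dispersion=float(res.scale),
        df_resid=int(res.df_resid),
        column_map=column_map,
        deviance=float(res.deviance),
        n_iter=len(res.fit_history["deviance"]),
    )


def reduce_to_overall(
    fit: FirstStageFit,
    lspec: LagBasisSpec,
    espec: ExposureBasisSpec,
    location: str = "",
    block: str = "crossbasis",
) -> ReducedCurve:
    """Cumulate the fitted surface over the integer lag grid.

    With c_k = sum_{l=0..L} C_k(l), the overall cumulative coefficients are
    eta = (I_vx kron c') theta_cb and V_eta = M V_cb M' for the same M.
    """
    theta, V = fit.block(block)
    vx, vl = espec.dimension, lspec.dimension
    if theta.size != vx * vl:
        raise ValueError(
            f"cross-basis block has {theta.size} coefficients; expected vx*vl = {vx * vl}"
        )
    c = lspec.evaluate().sum(axis=0)  # (vl,)
    M = np.kron(np.eye(vx), c[None, :])  # vx x (vx*vl)
    eta = M @ theta
    V_eta = M @ V @ M.T
    V_eta = (V_eta + V_eta.T) / 2
    return ReducedCurve(location=location, eta=eta, vcov=V_eta, espec=espec)


def fit_location(
    dates: pd.DatetimeIndex,
    deaths: np.ndarray,
    temps: np.ndarray,
    espec: ExposureBasisSpec,
    lspec: LagBasisSpec,
    df_per_year: float = 8.0,
    location: str = "",
) -> tuple[FirstStageFit, ReducedCurve, CrossBasisMatrix]:
    """Convenience wrapper: assemble the full design for one location, fit,
    and reduce.  Days with missing deaths or temperature are dropped from the
    likelihood (never imputed)."""
    deaths = np.asarray(deaths, dtype=float)
    temps = np.asarray(temps, dtype=float)
    cb = build_crossbasis(temps, espec, lspec)
    time_spline = build_time_spline(dates, df_per_year)
    dow = build_dow(dates)
    n = len(dates)
    blocks = [
        ("intercept", np.ones((n, 1))),
        ("time", time_spline),
        ("dow", dow),
        ("crossbasis", cb.values),
    ]
    column_map: dict[str, slice] = {}
    start = 0
    mats = []
    for name, mat in blocks:
        column_map[name] = slice(start, start + mat.shape[1])
        start += mat.shape[1]
        mats.append(mat)
    X = np.hstack(mats)
    keep = np.isfinite(deaths)
    if not np.all(keep):
        import warnings

        warnings.warn(f"{location}: dropping {int((~keep).sum())} days with missing deaths")
    fit = fit_quasipoisson(deaths[keep], X[keep], column_map)
    curve = reduce_to_overall(fit, lspec, espec, location=location)
    return fit, curve, cb


def curves_to_frame(curves: list[ReducedCurve]) -> pd.DataFrame:
    """Flat serialisation: one row per location with eta_1..eta_vx, the
    lower-triangle of V_eta, and the exposure-spec knots/boundary."""
    rows = []
    for c in curves:
        vx = c.eta.size
        row: dict[str, object] = {"location": c.location}
        for j in range(vx):
            row[f"eta_{j + 1}"] = c.eta[j]
        il, jl = np.tril_indices(vx)
        for i, j in zip(il, jl):
            row[f"v_{i + 1}_{j + 1}"] = c.vcov[i, j]
        for k, kn in enumerate(c.espec.internal_knots):
            row[f"knot_{k + 1}"] = kn
        row["boundary_low"], row["boundary_high"] = c.espec.boundary
        rows.append(row)
    return pd.DataFrame(rows)


def curves_from_frame(frame: pd.DataFrame) -> list[ReducedCurve]:
    eta_cols = sorted([c for c in frame.columns if c.startswith("eta_")],
                      key=lambda s: int(s.split("_")[1]))
    vx = len(eta_cols)
    knot_cols = sorted([c for c in frame.columns if c.startswith("knot_")],
                       key=lambda s: int(s.split("_")[1]))
    curves = []
    for _, row in frame.iterrows():
        eta = row[eta_cols].to_numpy(dtype=float)
        V = np.zeros((vx, vx))
        for i in range(vx):
            for j in range(i + 1):
                V[i, j] = V[j, i] = row[f"v_{i + 1}_{j + 1}"]
        espec = ExposureBasisSpec(
            internal_knots=tuple(row[knot_cols].to_numpy(dtype=float)),
            boundary=(float(row["boundary_low"]), float(row["boundary_high"])),
        )
        curves.append(ReducedCurve(location=str(row["location"]), eta=eta, vcov=V, espec=espec))
    return curves
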