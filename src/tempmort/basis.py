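"""Spline bases and the exposure x lag cross-basis of a distributed lag non-linear model.

A distributed lag non-linear model (DLNM) represents the risk surface over
exposure intensity and time-since-exposure as a tensor product of two marginal
bases: an exposure-response basis R (here a quadratic B-spline over temperature)
and a lag-response basis C (here a natural cubic spline over lag 0..21 days,
with intercept and knots equally spaced on the log-lag scale).  The cross-basis
column (j, k) evaluated on day t is

    W[t, j*vl + k] = sum_{l=0..L} R_j(x_{t-l}) * C_k(l)

so a quasi-Poisson regression on W estimates the full exposure-lag-response
surface.  Columns are ordered exposure-major, which makes the reduction to the
overall cumulative curve a Kronecker contraction (see ``first_stage``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "ExposureBasisSpec",
    "LagBasisSpec",
    "CrossBasisMatrix",
    "bspline_basis",
    "natural_cubic_basis",
    "log_lag_knots",
    "build_crossbasis",
    "predict_curve",
    "exposure_spec_from_temps",
]

# Default knot percentiles of the exposure spline, and the lag window.
DEFAULT_EXPOSURE_PERCENTILES = (10.0, 75.0, 90.0)
DEFAULT_MAX_LAG = 21
DEFAULT_LAG_KNOTS = 3


@dataclass(frozen=True)
class ExposureBasisSpec:
    """Quadratic B-spline over temperature, no intercept (dimension vx = 5).

    ``internal_knots`` sit at location-specific temperature percentiles
    (default 10th/75th/90th, type-7 empirical quantiles); boundary knots at the
    location min/max temperature.
    """

    internal_knots: tuple[float, ...]
    boundary: tuple[float, float]
    degree: int = 2

    def __post_init__(self) -> None:
        kn = np.asarray(self.internal_knots, dtype=float)
        lo, hi = self.boundary
        if not np.all(np.diff(kn) > 0):
            raise ValueError("exposure knots must be strictly increasing")
        if kn.size and (kn[0] <= lo or kn[-1] >= hi):
            raise ValueError("exposure knots must lie strictly inside the boundary")

    @property
    def dimension(self) -> int:
        # degree + n_internal: the intercept column is dropped.
        return self.degree + len(self.internal_knots)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Basis matrix R(x), len(x) x vx, extrapolating outside the boundary."""
        return bspline_basis(
            x,
            degree=self.degree,
            internal_knots=self.internal_knots,
            boundary=self.boundary,
            include_intercept=False,
        )


@dataclass(frozen=True)
class LagBasisSpec:
    """Natural cubic spline over the lag dimension, with intercept (vl = 5).

    Internal knots are equally spaced on the log-lag scale between lag 1 and
    the maximum lag L (default 21 days).
    """

    max_lag: int = DEFAULT_MAX_LAG
    n_knots: int = DEFAULT_LAG_KNOTS

    @property
    def knots(self) -> np.ndarray:
        return log_lag_knots(self.max_lag, self.n_knots)

    @property
    def dimension(self) -> int:
        return self.n_knots + 2  # n_knots + 1, plus the intercept column

    def evaluate(self, lags: np.ndarray | None = None) -> np.ndarray:
        if lags is None:
            lags = np.arange(self.max_lag + 1, dtype=float)
        return natural_cubic_basis(
            np.asarray(lags, dtype=float),
            internal_knots=self.knots,
            boundary=(0.0, float(self.max_lag)),
            with_intercept=True,
        )


@dataclass
class CrossBasisMatrix:
    """Tensor-product DLNM design with its construction metadata."""

    values: np.ndarray
    espec: ExposureBasisSpec
    lspec: LagBasisSpec
    edge_rows: np.ndarray = field(repr=False)  # bool: t < max_lag (truncated history)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def bspline_basis(
    x: np.ndarray,
    degree: int,
    internal_knots,
    boundary,
    include_intercept: bool = True,
) -> np.ndarray:
    """B-spline basis (Cox-de Boor) with repeated boundary knots.

    The full basis has ``degree + n_internal + 1`` columns and its rows sum to
    one for x inside the boundary; dropping the intercept removes the first
    column.  Points outside the boundary are evaluated by polynomial extension
    of the boundary pieces.
    """
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("bspline_basis: non-finite values in x")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    lo, hi = float(boundary[0]), float(boundary[1])
    kn = np.sort(np.asarray(internal_knots, dtype=float))
    if kn.size and (kn[0] <= lo or kn[-1] >= hi):
        raise ValueError("internal knots must lie strictly inside the boundary")
    t = np.r_[[lo] * (degree + 1), kn, [hi] * (degree + 1)]
    mat = BSpline.design_matrix(x, t, degree, extrapolate=True).toarray()
    if not include_intercept:
        mat = mat[:, 1:]
    return mat


def natural_cubic_basis(
    x: np.ndarray,
    internal_knots,
    boundary,
    with_intercept: bool = False,
) -> np.ndarray:
    """Natural cubic spline basis: cubic inside, linear beyond the boundary knots.

    Built by projecting the full cubic B-spline basis onto the null space of
    the second-derivative constraints at the two boundary knots; outside the
    boundary the basis is extended linearly (value + first derivative at the
    boundary), enforcing zero curvature there.  Dimension is
    ``n_internal + 2`` with the intercept column, one fewer without.
    """
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("natural_cubic_basis: non-finite values in x")
    kn = np.sort(np.asarray(internal_knots, dtype=float))
    if kn.size != np.unique(kn).size:
        raise ValueError("duplicate internal knots")
    lo, hi = float(boundary[0]), float(boundary[1])
    if kn.size and (kn[0] <= lo or kn[-1] >= hi):
        raise ValueError("internal knots must lie strictly inside the boundary")

    t = np.r_[[lo] * 4, kn, [hi] * 4]
    n_full = kn.size + 4
    spl = BSpline(t, np.eye(n_full), 3, extrapolate=True)
    d2 = spl.derivative(2)
    # Null space of the 2 x n_full constraint "second derivative zero at lo, hi".
    constraint = d2(np.array([lo, hi]))
    q, _ = np.linalg.qr(constraint.T, mode="complete")
    h = q[:, 2:]  # n_full x (n_internal + 2)

    out = np.empty((x.size, n_full - 2))
    inside = (x >= lo) & (x <= hi)
    if np.any(inside):
        out[inside] = spl(x[inside]) @ h
    for bound, mask in ((lo, x < lo), (hi, x > hi)):
        if np.any(mask):
            val = (spl(np.array([bound])) @ h)[0]
            der = (spl.derivative(1)(np.array([bound])) @ h)[0]
            out[mask] = val + np.outer(x[mask] - bound, der)
    if not with_intercept:
        out = out[:, 1:]
    return out


def log_lag_knots(max_lag: int, n_knots: int) -> np.ndarray:
    """Knots equally spaced on the log scale over (1, max_lag).

    The grid from log(1) to log(max_lag) has ``n_knots + 2`` points; the
    interior points, exponentiated, are the knots.
    """
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2")
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    if n_knots >= max_lag:
        raise ValueError("n_knots must be < max_lag")
    grid = np.linspace(np.log(1.0), np.log(float(max_lag)), n_knots + 2)
    return np.exp(grid[1:-1])


def exposure_spec_from_temps(
    temps: np.ndarray,
    percentiles=DEFAULT_EXPOSURE_PERCENTILES,
) -> ExposureBasisSpec:
    """Location-specific exposure spec: knots at temperature percentiles,
    boundary at the observed min/max (type-7 linear-interpolation quantiles)."""
    temps = np.asarray(temps, dtype=float)
    knots = tuple(np.percentile(temps, percentiles))
    return ExposureBasisSpec(internal_knots=knots, boundary=(temps.min(), temps.max()))


def build_crossbasis(
    temps: np.ndarray,
    espec: ExposureBasisSpec,
    lspec: LagBasisSpec,
) -> CrossBasisMatrix:
    """Cross-basis W[t, j*vl+k] = sum_l R_j(x_{t-l}) C_k(l), lags 0..L.

    The first L rows only see the available history (truncated sums) and are
    flagged as edge rows.
    """
    temps = np.asarray(temps, dtype=float)
    if np.any(~np.isfinite(temps)):
        bad = np.flatnonzero(~np.isfinite(temps))
        raise ValueError(f"missing/non-finite temperatures at positions {bad[:10].tolist()}")
    n = temps.size
    L = lspec.max_lag
    if n <= L:
        raise ValueError(f"series length {n} must exceed the maximum lag {L}")
    R = espec.evaluate(temps)  # n x vx
    C = lspec.evaluate()  # (L+1) x vl
    vx, vl = R.shape[1], C.shape[1]
    W = np.zeros((n, vx * vl))
    for lag in range(L + 1):
        Rl = np.zeros_like(R)
        Rl[lag:] = R[: n - lag]
        W += (Rl[:, :, None] * C[lag][None, None, :]).reshape(n, vx * vl)
    edge = np.zeros(n, dtype=bool)
    edge[:L] = True
    return CrossBasisMatrix(values=W, espec=espec, lspec=lspec, edge_rows=edge)


def predict_curve(
    coefs: np.ndarray,
    vcov: np.ndarray,
    espec: ExposureBasisSpec,
    at: np.ndarray,
    ref: float,
    ci_level: float = 0.95,
):
    """Overall cumulative exposure-response curve re-centred at ``ref``.

    log-RR(x) = [R(x) - R(ref)]' coefs, with pointwise variance from the same
    contrast applied to ``vcov``; RR(ref) = 1 exactly.  Returns a DataFrame
    with columns temperature, logrr, se, rr, rr_low, rr_high.
    """
    import pandas as pd
    from scipy.stats import norm

    coefs = np.asarray(coefs, dtype=float)
    vcov = np.asarray(vcov, dtype=float)
    if coefs.size != espec.dimension:
        raise ValueError("coefficient length does not match the exposure basis dimension")
    eig = np.linalg.eigvalsh((vcov + vcov.T) / 2)
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise ValueError("vcov is not positive semidefinite")
    at = np.atleast_1d(np.asarray(at, dtype=float))
    contrast = espec.evaluate(at) - espec.evaluate(np.array([ref]))
    logrr = contrast @ coefs
    var = np.einsum("ij,jk,ik->i", contrast, vcov, contrast)
    se = np.sqrt(np.clip(var, 0.0, None))
    z = norm.ppf(0.5 + ci_level / 2)
    return pd.DataFrame(
        {
            "temperature": at,
            "logrr": logrr,
            "se": se,
            "rr": np.exp(logrr),
            "rr_low": np.exp(logrr - z * se),
            "rr_high": np.exp(logrr + z * se),
        }
    )
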