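"""Spatial autocorrelation (Moran's I) and trend-surface analysis.

Ordinary kriging presumes the variable is a spatially autocorrelated
regionalised variable; Moran's I checks that assumption.  A deterministic
large-scale drift violates the stationarity the variogram needs, so a
second-degree polynomial trend surface is fitted by least squares on the
working scale and removed before variography; predictions add the trend
back.

Moran's I with row-standardised weights ``w_ij``:

    I = (n / S0) * sum_ij w_ij (z_i - zbar)(z_j - zbar) / sum_i (z_i - zbar)^2

Values above the null expectation ``E[I] = -1/(n-1)`` indicate clustering of
similar values.  The weight matrix is not part of the statistic's definition;
the default here is inverse distance over the 8 nearest neighbours,
row-standardised — a robust choice for irregular plot networks.  The p-value
comes from a seeded permutation null (one-sided, positive autocorrelation);
a normal-approximation p under the randomisation variance is reported
alongside for reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.spatial import cKDTree

DEFAULT_KNN = 8
DEFAULT_PERMUTATIONS = 999


@dataclass(frozen=True)
class MoranResult:
    i_value: float
    p_value: float          # permutation, one-sided (positive)
    p_normal: float         # randomisation normal approximation
    expected_i: float       # -1/(n-1)
    weight_scheme: str


@dataclass(frozen=True)
class TrendSurface:
    """A polynomial surface in centred, scaled coordinates.

    ``coeffs`` are on the internal scaled coordinates; ``coeffs_raw`` maps
    them back to raw (x, y) metres for reporting.  Degree 2 keeps the six
    terms (1, x, y, x^2, xy, y^2); degree 1 the first three.
    """

    coeffs: np.ndarray
    center: tuple[float, float]
    scale: tuple[float, float]
    degree: int
    r2: float
    p_value: float          # overall-F p

    def _design(self, coords: np.ndarray) -> np.ndarray:
        u = (coords[:, 0] - self.center[0]) / self.scale[0]
        v = (coords[:, 1] - self.center[1]) / self.scale[1]
        cols = [np.ones_like(u), u, v]
        if self.degree == 2:
            cols += [u ** 2, u * v, v ** 2]
        return np.column_stack(cols)

    def predict(self, coords) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return self._design(coords) @ self.coeffs

    @property
    def coeffs_raw(self) -> np.ndarray:
        """Coefficients re-expressed in raw coordinates.

        Order (1, x, y) for degree 1 and (1, x, y, x^2, xy, y^2) for
        degree 2, obtained by expanding u = (x - x0)/sx, v = (y - y0)/sy.
        """
        x0, y0 = self.center
        sx, sy = self.scale
        b = self.coeffs
        if self.degree == 1:
            b0, b1, b2 = b
            return np.array([b0 - b1 * x0 / sx - b2 * y0 / sy,
                             b1 / sx, b2 / sy])
        b0, b1, b2, b3, b4, b5 = b
        cxx = b3 / sx ** 2
        cyy = b5 / sy ** 2
        cxy = b4 / (sx * sy)
        cx = b1 / sx - 2 * b3 * x0 / sx ** 2 - b4 * y0 / (sx * sy)
        cy = b2 / sy - 2 * b5 * y0 / sy ** 2 - b4 * x0 / (sx * sy)
        c0 = (b0 - b1 * x0 / sx - b2 * y0 / sy + b3 * x0 ** 2 / sx ** 2
              + b4 * x0 * y0 / (sx * sy) + b5 * y0 ** 2 / sy ** 2)
        return np.array([c0, cx, cy, cxx, cxy, cyy])


def knn_inverse_distance_weights(coords, k: int = DEFAULT_KNN) -> np.ndarray:
    """Row-standardised inverse-distance weights over the k nearest plots."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 locations")
    k = min(k, n - 1)
    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=k + 1)
    w = np.zeros((n, n))
    for i in range(n):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):
            if d <= 0:
                raise ValueError("coincident locations in Moran weights")
            w[i, j] = 1.0 / d
    rs = w.sum(axis=1, keepdims=True)
    return w / rs


def morans_i(values, coords, k: int = DEFAULT_KNN,
             n_permutations: int = DEFAULT_PERMUTATIONS,
             seed: int | None = 0,
             weights: np.ndarray | None = None) -> MoranResult:
    """Global Moran's I with a permutation p-value.

    ``weights`` may be a precomputed (n, n) matrix (rows need not be
    standardised; S0 is handled explicitly); otherwise k-NN inverse-distance
    row-standardised weights are built from ``coords``.
    """
    z = np.asarray(values, dtype=float)
    n = z.size
    if n < 5:
        raise ValueError("need at least 5 observations for Moran's I")
    if np.ptp(z) == 0:
        raise ValueError("Moran's I is undefined for constant values")
    if weights is None:
        w = knn_inverse_distance_weights(coords, k=k)
        scheme = f"knn{min(k, n - 1)}_inverse_distance_row_standardised"
    else:
        w = np.asarray(weights, dtype=float)
        scheme = "user_supplied"
    s0 = w.sum()
    zc = z - z.mean()
    denom = np.sum(zc ** 2)

    def stat(v):
        return (n / s0) * (v @ w @ v) / np.sum(v ** 2)

    i_obs = float((n / s0) * (zc @ w @ zc) / denom)
    # permutation null (one-sided, positive autocorrelation)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        vp = rng.permutation(zc)
        if stat(vp) >= i_obs:
            exceed += 1
    p_perm = (1.0 + exceed) / (n_permutations + 1.0)
    # randomisation-variance normal approximation
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    m2 = np.mean(zc ** 2)
    m4 = np.mean(zc ** 4)
    b2 = m4 / m2 ** 2
    num = (n * ((n ** 2 - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2)
           - b2 * ((n ** 2 - n) * s1 - 2 * n * s2 + 6 * s0 ** 2))
    var_i = num / ((n - 1) * (n - 2) * (n - 3) * s0 ** 2) - e_i ** 2
    if var_i > 0:
        from scipy.stats import norm
        p_norm = float(norm.sf((i_obs - e_i) / np.sqrt(var_i)))
    else:
        p_norm = float("nan")
    return MoranResult(i_value=i_obs, p_value=float(p_perm), p_normal=p_norm,
                       expected_i=e_i, weight_scheme=scheme)


def fit_trend_surface(coords, values, degree: int = 2) -> TrendSurface:
    """Least-squares polynomial trend surface in centred, scaled coordinates.

    Coordinates are centred on their mean and scaled by their standard
    deviation before building the design matrix, avoiding the severe
    ill-conditioning of raw metre-scale quadratics; fitted coefficients are
    reported back on the raw scale via :attr:`TrendSurface.coeffs_raw`.
    """
    coords = np.asarray(coords, dtype=float)
    z = np.asarray(values, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n = z.size
    if n < 7:
        raise ValueError("need at least 7 observations for a quadratic trend")
    x0, y0 = coords[:, 0].mean(), coords[:, 1].mean()
    sx = coords[:, 0].std() or 1.0
    sy = coords[:, 1].std() or 1.0
    ts = TrendSurface(coeffs=np.zeros(3 if degree == 1 else 6),
                      center=(x0, y0), scale=(sx, sy), degree=degree,
                      r2=0.0, p_value=1.0)
    X = ts._design(coords)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate coordinates: singular trend design")
    if np.ptp(z) == 0:  # constant surface: intercept-only, R^2 undefined -> 0
        coeffs = np.zeros(X.shape[1])
        coeffs[0] = z[0]
        return TrendSurface(coeffs=coeffs, center=(x0, y0), scale=(sx, sy),
                            degree=degree, r2=0.0, p_value=1.0)
    res = sm.OLS(z, X).fit()
    return TrendSurface(coeffs=np.asarray(res.params), center=(x0, y0),
                        scale=(sx, sy), degree=degree,
                        r2=float(res.rsquared), p_value=float(res.f_pvalue))


def detrend(values, trend: TrendSurface, coords) -> np.ndarray:
    """Residuals after removing the fitted surface: ``values - trend(coords)``."""
    return np.asarray(values, dtype=float) - trend.predict(coords)


def retrend(residuals, trend: TrendSurface, coords) -> np.ndarray:
    """Exact inverse of :func:`detrend` on the same coordinates."""
    return np.asarray(residuals, dtype=float) + trend.predict(coords)
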