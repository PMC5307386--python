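"""Ordinary kriging and inverse-distance weighting over points and grids.

Ordinary kriging (OK) predicts the value at an unsampled location as the
weighted mean of its ``m`` nearest observations, with weights solving

    | Gamma  1 | | w  |   | gamma_0 |
    | 1^T    0 | | mu | = |    1    |

where ``Gamma`` holds model semivariances between the neighbours, ``gamma_0``
between each neighbour and the target, and the Lagrange multiplier ``mu``
enforces the unbiasedness constraint ``sum w = 1``.  The kriging variance is
``w . gamma_0 + mu``.  With the gamma(0) = 0 convention the predictor honours
the data exactly (a target coinciding with a sample returns that sample and
zero variance), even for a positive nugget.

IDW predicts ``sum(z_i / d_i^p) / sum(1 / d_i^p)`` over the ``m`` nearest
samples; the survey convention emulated here uses 16 neighbours and power 1.

Both interpolators run inside the standard pipeline order: log-transform
(when the normality gate demands it) -> remove the trend surface ->
interpolate the residuals -> add the trend back -> back-transform.  The
default log back-transform applies the lognormal bias correction
``exp(yhat + sigma_OK^2 / 2)`` for kriging and the plain exponential for IDW.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .spatial import TrendSurface
from .variogram import VariogramFit

DEFAULT_NEIGHBOURS = 16
DEFAULT_IDW_POWER = 1.0
NODATA = -9999.0


def deduplicate(coords, values):
    """Average values at duplicate coordinates (guarantees a nonsingular
    kriging system)."""
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    uniq, inv = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return coords, values
    sums = np.bincount(inv, weights=values)
    cnts = np.bincount(inv)
    return uniq, sums / cnts


def ok_predict(target, coords, values, fit: VariogramFit,
               m: int | None = DEFAULT_NEIGHBOURS
               ) -> tuple[float, float, np.ndarray]:
    """Ordinary-kriging estimate, variance and weights at one target.

    ``m`` is the neighbourhood size (``None`` for global kriging with every
    sample).  Duplicate sample coordinates are averaged before solving; a
    system that is still singular raises ``np.linalg.LinAlgError``.
    Kriging variance is clipped at zero (with a warning) if round-off makes
    it marginally negative.
    """
    target = np.asarray(target, dtype=float)
    coords, values = deduplicate(coords, values)
    n = len(values)
    if n < 2:
        raise ValueError("ordinary kriging needs at least 2 usable samples")
    if m is None or m >= n:
        nb = np.arange(n)
    else:
        d_all = np.hypot(*(coords - target).T)
        nb = np.argsort(d_all, kind="stable")[:m]
    nc = coords[nb]
    nv = values[nb]
    k = len(nb)
    dmat = np.hypot(nc[:, None, 0] - nc[None, :, 0],
                    nc[:, None, 1] - nc[None, :, 1])
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = fit.gamma(dmat)
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    d0 = np.hypot(nc[:, 0] - target[0], nc[:, 1] - target[1])
    b = np.empty(k + 1)
    b[:k] = fit.gamma(d0)
    b[k] = 1.0
    sol = np.linalg.solve(A, b)
    w, mu = sol[:k], sol[k]
    est = float(w @ nv)
    var = float(w @ b[:k] + mu)
    if var < 0:
        if var < -1e-8 * max(fit.sill, 1.0):
            warnings.warn(f"negative kriging variance {var:.3e} clipped to 0")
        var = 0.0
    return est, var, w


def idw_predict(target, coords, values, power: float = DEFAULT_IDW_POWER,
                m: int = DEFAULT_NEIGHBOURS) -> float:
    """Inverse-distance-weighted estimate at one target.

    A target coinciding with a sample returns that sample's value exactly.
    """
    if not power > 0:
        raise ValueError("power must be > 0")
    target = np.asarray(target, dtype=float)
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty sample set")
    d = np.hypot(coords[:, 0] - target[0], coords[:, 1] - target[1])
    order = np.argsort(d, kind="stable")[:max(1, min(m, len(values)))]
    dn, vn = d[order], values[order]
    if dn[0] == 0.0:
        return float(vn[0])
    w = 1.0 / dn ** power
    return float(w @ vn / w.sum())


def back_transform(log_estimate, kriging_variance=0.0,
                   mode: str = "lognormal"):
    """Return predictions from the natural-log working scale to Mg ha^-1.

    ``lognormal`` applies the standard lognormal-kriging bias correction
    ``exp(yhat + sigma^2/2)``; ``plain`` is ``exp(yhat)`` (the only option
    when no prediction variance exists, as for IDW).
    """
    y = np.asarray(log_estimate, dtype=float)
    if mode == "plain":
        out = np.exp(y)
    elif mode == "lognormal":
        out = np.exp(y + 0.5 * np.asarray(kriging_variance, dtype=float))
    else:
        raise ValueError(f"unknown back-transform mode {mode!r}")
    return float(out) if out.ndim == 0 else out


@dataclass
class GridSpec:
    """Geometry of a prediction raster: lower-left origin, square cells."""

    origin: tuple[float, float]
    cell_size: float
    nx: int
    ny: int
    mask: np.ndarray | None = None  # (ny, nx) bool, row 0 = southmost

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.ny, self.nx):
                raise ValueError("mask shape must be (ny, nx)")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + (np.arange(self.nx) + 0.5) * self.cell_size
        y = self.origin[1] + (np.arange(self.ny) + 0.5) * self.cell_size
        return x, y

    @classmethod
    def from_domain(cls, domain, cell_size: float,
                    mask: np.ndarray | None = None) -> "GridSpec":
        x0, y0, x1, y1 = domain
        nx = max(1, int(np.ceil((x1 - x0) / cell_size)))
        ny = max(1, int(np.ceil((y1 - y0) / cell_size)))
        return cls(origin=(x0, y0), cell_size=cell_size, nx=nx, ny=ny,
                   mask=mask)


@dataclass
class PredictionGrid:
    """Interpolated stock surface (Mg ha^-1) on a masked raster.

    ``prediction`` is NaN outside the mask; ``kriging_variance`` (working-
    scale units squared) is populated for OK only.  Arrays are (ny, nx) with
    row 0 the southmost row.
    """

    spec: GridSpec
    prediction: np.ndarray
    method: str
    kriging_variance: np.ndarray | None = None

    @property
    def mask(self) -> np.ndarray:
        if self.spec.mask is None:
            return np.ones((self.spec.ny, self.spec.nx), dtype=bool)
        return self.spec.mask


def predict_grid(coords, stocks, spec: GridSpec, method: str = "OK",
                 fit: VariogramFit | None = None,
                 m: int = DEFAULT_NEIGHBOURS,
                 power: float = DEFAULT_IDW_POWER,
                 log_transform: bool = False,
                 trend: TrendSurface | None = None,
                 back_mode: str = "lognormal") -> PredictionGrid:
    """Interpolate plot stocks onto the masked cells of a raster.

    Implements the full working-scale pipeline.  ``fit`` must describe the
    variogram of the *working residuals* when method is OK.  ``trend`` (if
    given) must have been fitted on the same working scale.
    """
    method = method.upper()
    if method not in ("OK", "IDW"):
        raise ValueError("method must be 'OK' or 'IDW'")
    if method == "OK" and fit is None:
        raise ValueError("OK prediction requires a fitted variogram")
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(stocks, dtype=float)
    work = np.log(values) if log_transform else values.copy()
    if trend is not None:
        work = work - trend.predict(coords)
    coords, work = deduplicate(coords, work)
    xs, ys = spec.cell_centers()
    mask = (np.ones((spec.ny, spec.nx), dtype=bool)
            if spec.mask is None else spec.mask)
    pred = np.full((spec.ny, spec.nx), np.nan)
    var = np.full((spec.ny, spec.nx), np.nan) if method == "OK" else None
    for i in range(spec.ny):
        for j in range(spec.nx):
            if not mask[i, j]:
                continue
            tgt = (xs[j], ys[i])
            if method == "OK":
                est, v, _ = ok_predict(tgt, coords, work, fit, m=m)
                var[i, j] = v
            else:
                est = idw_predict(tgt, coords, work, power=power, m=m)
                v = 0.0
            if trend is not None:
                est = est + float(trend.predict(tgt)[0])
            if log_transform:
                if method == "OK":
                    est = back_transform(est, v, mode=back_mode)
                else:
                    est = back_transform(est, mode="plain")
            pred[i, j] = est
    return PredictionGrid(spec=spec, prediction=pred, method=method,
                          kriging_variance=var)
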