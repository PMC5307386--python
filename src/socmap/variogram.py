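"""Empirical semivariogram estimation and variogram model fitting.

The semivariogram describes how dissimilarity between a spatial variable at
two locations grows with their separation ``h``:

    gamma_hat(h) = 1 / (2 N(h)) * sum_{pairs at lag h} (z(x_i) - z(x_i + h))^2

where ``N(h)`` is the number of point pairs whose separation falls in the lag
bin around ``h``.  Four permissible model families (spherical, exponential,
Gaussian, linear) are fitted to the binned estimates by weighted least
squares; the fitted nugget ``C0``, sill ``C0 + C`` and range ``A0`` feed the
ordinary-kriging system and the nugget-to-sill spatial-dependence
classification (< 25 % strong, 25–75 % moderate, > 75 % weak).

Conventions
-----------
* ``gamma(0) == 0`` exactly (exact-interpolation convention); the nugget is
  the limit of ``gamma(h)`` as ``h -> 0+``.
* For the exponential and Gaussian families the reported range is the
  *effective* (95 %) range: ``A0 = 3 a`` (exponential) and ``A0 = sqrt(3) a``
  (Gaussian) in terms of the internal scale parameter ``a``.  This matches
  the convention of the GS+ geostatistics package and is the scale on which
  ranges are usually reported for soil-survey variograms.
* The linear family is linear-to-sill: ``gamma`` rises with constant slope
  until the fitted extent (reported as the range) and is flat beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

FAMILIES = ("spherical", "exponential", "gaussian", "linear")

#: nugget-to-sill classification bounds, in percent
DEPENDENCE_BOUNDS = (25.0, 75.0)


class VariogramError(ValueError):
    """Raised for invalid variogram parameters or failed estimation/fits."""


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned semivariogram estimates.

    Attributes
    ----------
    lag_centers : mean pair separation per non-empty bin (m), increasing.
    gamma : semivariance estimate per bin (working-scale units squared).
    pair_counts : number of point pairs per bin.
    max_lag : upper distance cutoff used for binning (m).
    n_lags : number of bins requested (before dropping empty ones).
    """

    lag_centers: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray
    max_lag: float
    n_lags: int

    def __post_init__(self) -> None:
        lc = np.asarray(self.lag_centers, dtype=float)
        g = np.asarray(self.gamma, dtype=float)
        c = np.asarray(self.pair_counts)
        if np.any(g < 0):
            raise VariogramError("semivariance estimates must be >= 0")
        if np.any(np.diff(lc) <= 0):
            raise VariogramError("lag centers must be strictly increasing")
        object.__setattr__(self, "lag_centers", lc)
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "pair_counts", np.asarray(c, dtype=float))


@dataclass(frozen=True)
class VariogramFit:
    """A fitted (or prescribed) variogram model.

    ``sill`` is the total sill ``C0 + C``; the partial sill ``C`` is
    ``sill - nugget``.  ``range_`` is the (effective) range ``A0`` in metres.
    ``r2``/``rss`` are the weighted fit diagnostics; ``r2_unweighted`` is the
    plain coefficient of determination, reported for reference.
    """

    family: str
    nugget: float
    sill: float
    range_: float
    r2: float = float("nan")
    rss: float = float("nan")
    r2_unweighted: float = float("nan")

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise VariogramError(f"unknown model family {self.family!r}")
        if self.nugget < 0:
            raise VariogramError("nugget must be >= 0")
        if self.sill < self.nugget:
            raise VariogramError("sill must be >= nugget")
        if not self.range_ > 0:
            raise VariogramError("range must be > 0")

    @property
    def partial_sill(self) -> float:
        return self.sill - self.nugget

    @property
    def nugget_to_sill(self) -> float:
        """Nugget-to-sill ratio in percent (nan for an all-zero model)."""
        if self.sill == 0:
            return float("nan")
        return 100.0 * self.nugget / self.sill

    @property
    def dependence_class(self) -> str:
        """Spatial-dependence class: strong (<25 %), moderate, weak (>75 %)."""
        ratio = self.nugget_to_sill
        if np.isnan(ratio):
            return "undefined"
        lo, hi = DEPENDENCE_BOUNDS
        if ratio < lo:
            return "strong"
        if ratio > hi:
            return "weak"
        return "moderate"

    def gamma(self, h) -> np.ndarray | float:
        """Model semivariance at lag(s) ``h`` (``gamma(0) == 0``)."""
        return model_gamma(self.family, self.nugget, self.partial_sill,
                           self.range_, h)

    def covariance(self, h) -> np.ndarray | float:
        """Implied stationary covariance ``C(h) = sill - gamma(h)``.

        At ``h == 0`` this is the full sill (point variance); between
        distinct points it decays to 0 as ``gamma`` reaches the sill.
        """
        h = np.asarray(h, dtype=float)
        c = self.sill - self.gamma(h)
        return np.where(h == 0.0, self.sill, c)


def model_gamma(family: str, nugget: float, partial_sill: float,
                range_: float, h) -> np.ndarray | float:
    """Theoretical semivariance of one model family at lag(s) ``h``.

    ``gamma(0)`` is 0 by convention; for any ``h > 0`` the nugget is included.
    """
    if nugget < 0 or partial_sill < 0:
        raise VariogramError("nugget and partial sill must be >= 0")
    if not range_ > 0:
        raise VariogramError("range must be > 0")
    if family not in FAMILIES:
        raise VariogramError(f"unknown model family {family!r}")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise VariogramError("lag distances must be >= 0")
    hr = h / range_
    if family == "spherical":
        struct = np.where(hr < 1.0, 1.5 * hr - 0.5 * hr ** 3, 1.0)
    elif family == "exponential":
        # effective range A0 = 3a  =>  gamma = C (1 - exp(-3 h / A0))
        struct = 1.0 - np.exp(-3.0 * hr)
    elif family == "gaussian":
        # effective range A0 = sqrt(3) a  =>  gamma = C (1 - exp(-3 (h/A0)^2))
        struct = 1.0 - np.exp(-3.0 * hr ** 2)
    else:  # linear-to-sill
        struct = np.minimum(hr, 1.0)
    g = np.where(h > 0.0, nugget + partial_sill * struct, 0.0)
    return g if g.ndim else float(g)


def empirical_semivariogram(coords, values, n_lags: int = 12,
                            max_lag: float | None = None) -> EmpiricalVariogram:
    """Method-of-moments semivariogram on uniform lag bins.

    ``max_lag`` defaults to half the maximum pairwise distance, a common
    cutoff beyond which pair counts thin out and the estimate is unreliable.
    Empty bins are dropped; each kept bin reports the mean pair separation
    as its lag centre.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise VariogramError("need at least 2 samples for a semivariogram")
    if coords.shape != (n, 2):
        raise VariogramError("coords must be (n, 2) and match values")
    d = pdist(coords)
    if max_lag is None:
        max_lag = 0.5 * float(d.max())
    if not max_lag > 0:
        raise VariogramError("max_lag must be > 0")
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    keep = d <= max_lag
    if not keep.any():
        raise VariogramError("no point pairs within max_lag")
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    idx = np.clip(np.digitize(d[keep], edges) - 1, 0, n_lags - 1)
    counts = np.bincount(idx, minlength=n_lags).astype(float)
    gsum = np.bincount(idx, weights=sq[keep], minlength=n_lags)
    dsum = np.bincount(idx, weights=d[keep], minlength=n_lags)
    nz = counts > 0
    if not nz.any():
        raise VariogramError("all lag bins are empty")
    return EmpiricalVariogram(
        lag_centers=dsum[nz] / counts[nz],
        gamma=gsum[nz] / counts[nz],
        pair_counts=counts[nz],
        max_lag=float(max_lag),
        n_lags=int(n_lags),
    )


def _fit_weights(ev: EmpiricalVariogram, scheme: str,
                 gamma_model: np.ndarray | None = None) -> np.ndarray:
    if scheme == "uniform":
        return np.ones_like(ev.gamma)
    if scheme == "pair_counts":
        return ev.pair_counts.astype(float)
    if scheme == "cressie":
        g = ev.gamma if gamma_model is None else gamma_model
        return ev.pair_counts / np.maximum(g, 1e-12) ** 2
    raise VariogramError(f"unknown weight scheme {scheme!r}")


def fit_model(ev: EmpiricalVariogram, family: str,
              weights: str = "pair_counts") -> VariogramFit:
    """Weighted least-squares fit of one model family to binned estimates.

    The objective is non-convex in the range, so eight starts are taken from
    moment heuristics (nugget = 0 or first-bin gamma; sill = mean of the
    upper-third bins; range spanning 1/3 to 1 of ``max_lag``) and the best
    converged solution wins.  Weights default to pair counts N(h); the
    ``uniform`` and Cressie-style ``N(h)/gamma^2`` schemes are selectable.

    Diagnostics: weighted R^2 against the weighted mean of the estimates
    (primary, reported as ``r2``), the unweighted R^2 for reference, and
    ``rss`` the residual sum of squares under weights normalised to mean 1
    (so uniform weighting reproduces the plain RSS).
    """
    if family not in FAMILIES:
        raise VariogramError(f"unknown model family {family!r}")
    lags, gam = ev.lag_centers, ev.gamma
    if len(lags) < 4:
        raise VariogramError("need at least 4 non-empty lag bins to fit")
    w = _fit_weights(ev, weights)
    sw = np.sqrt(w)

    def resid(theta):
        nug, psill, rng = theta
        return sw * (model_gamma(family, nug, psill, rng, lags) - gam)

    ml = ev.max_lag
    sill0 = max(float(np.mean(gam[-max(1, len(gam) // 3):])), 1e-12)
    nug_starts = (0.0, float(gam[0]))
    rng_starts = (ml / 3.0, 0.55 * ml, 0.8 * ml, ml)
    lower = np.array([0.0, 0.0, 1e-9 * ml])
    upper = np.array([np.inf, np.inf, 10.0 * ml])
    best = None
    failures = []
    for nug0 in nug_starts:
        for rng0 in rng_starts:
            x0 = np.clip([nug0, max(sill0 - nug0, 1e-12), rng0], lower, upper)
            try:
                sol = least_squares(resid, x0, bounds=(lower, upper),
                                    method="trf")
            except Exception as exc:  # pragma: no cover - scipy internal
                failures.append(str(exc))
                continue
            if not sol.success and not np.isfinite(sol.cost):
                failures.append(sol.message)
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise VariogramError(
            f"{family} fit failed from all starts: {failures[:3]}")
    nug, psill, rng = best.x
    r = model_gamma(family, nug, psill, rng, lags) - gam
    wbar = np.sum(w * gam) / np.sum(w)
    tss_w = np.sum(w * (gam - wbar) ** 2)
    r2_w = 1.0 - np.sum(w * r ** 2) / tss_w if tss_w > 0 else float("nan")
    tss_u = np.sum((gam - gam.mean()) ** 2)
    r2_u = 1.0 - np.sum(r ** 2) / tss_u if tss_u > 0 else float("nan")
    rss = float(np.sum((w / w.mean()) * r ** 2))
    return VariogramFit(family=family, nugget=float(nug),
                        sill=float(nug + psill), range_=float(rng),
                        r2=float(r2_w), rss=rss, r2_unweighted=float(r2_u))


def fit_all_models(ev: EmpiricalVariogram,
                   families: Sequence[str] = FAMILIES,
                   weights: str = "pair_counts") -> list[VariogramFit]:
    """Fit every requested family, silently dropping families that fail."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_model(ev, fam, weights=weights))
        except VariogramError:
            continue
    return fits


def select_model(fits: Sequence[VariogramFit]) -> VariogramFit:
    """Pick the best fit: highest R^2, then smallest residuals.

    Ties after both criteria are broken by family order (spherical,
    exponential, gaussian, linear).
    """
    fits = list(fits)
    if not fits:
        raise VariogramError("no successful variogram fits to select from")

    def key(f: VariogramFit):
        r2 = f.r2 if np.isfinite(f.r2) else -np.inf
        rss = f.rss if np.isfinite(f.rss) else np.inf
        return (-r2, rss, FAMILIES.index(f.family))

    return min(fits, key=key)
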