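"""Per-plot SOC stock computation, descriptive statistics and the
topographic regression.

The stock of a soil layer follows from its organic-carbon concentration,
bulk density and thickness:

    stock [Mg ha^-1] = SOC [g kg^-1] * BD [g cm^-3] * D [cm] * 0.1

The 0.1 is the unit-conversion constant forced by dimensional analysis
(g kg^-1 x g cm^-3 x cm -> 100 Mg ha^-1 per unit product).

Descriptive summaries use the bias-adjusted sample skewness and *excess*
kurtosis.  Geostatistical interpolation assumes (near-)normal working data,
so a Shapiro-Wilk gate decides whether the pipeline proceeds on the natural
log of the stocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

STOCK_UNIT_CONSTANT = 0.1
SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class DescriptiveSummary:
    """Moments, quartiles and the normality p-value of one stock vector."""

    mean: float
    min: float
    max: float
    median: float
    sd: float
    cv: float           # percent; nan when the mean is 0
    q1: float
    q3: float
    skewness: float     # bias-adjusted; nan for a constant vector
    kurtosis: float     # excess, bias-adjusted; nan for a constant vector
    shapiro_p: float
    n: int


def compute_stock(soc_conc, bulk_density, depth):
    """SOC stock (Mg ha^-1) from concentration, bulk density and depth.

    Accepts scalars or arrays; linear in each argument.
    """
    soc_conc = np.asarray(soc_conc, dtype=float)
    bulk_density = np.asarray(bulk_density, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(soc_conc < 0) or np.any(bulk_density < 0) or np.any(depth < 0):
        raise ValueError("concentration, bulk density and depth must be >= 0")
    out = soc_conc * bulk_density * depth * STOCK_UNIT_CONSTANT
    return float(out) if out.ndim == 0 else out


def summarize(stocks) -> DescriptiveSummary:
    """Descriptive summary of a stock vector (CV reported in percent)."""
    x = np.asarray(stocks, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty vector")
    if x.size < 4:
        raise ValueError("need at least 4 values for moment estimates")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean > 0:
        cv = 100.0 * sd / mean
    elif sd == 0.0 and mean == 0.0:
        cv = float("nan")
    else:
        cv = float("nan")
    if sd == 0.0:
        skew = kurt = float("nan")
        cv = 0.0 if mean != 0 else cv
        shapiro_p = float("nan")
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, bias=False, fisher=True))
        shapiro_p = float(stats.shapiro(x).pvalue) if x.size <= 5000 else float("nan")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return DescriptiveSummary(
        mean=mean, min=float(x.min()), max=float(x.max()), median=float(med),
        sd=sd, cv=cv, q1=float(q1), q3=float(q3),
        skewness=skew, kurtosis=kurt, shapiro_p=shapiro_p, n=int(x.size))


def normality_gate(stocks, alpha: float = SHAPIRO_ALPHA) -> tuple[float, str]:
    """Shapiro-Wilk gate deciding the working scale of the pipeline.

    Returns ``(p_value, transform)`` with ``transform`` either ``"none"`` or
    ``"natural_log"``; downstream stages operate on ``ln(stock)`` whenever
    the test rejects normality at ``alpha`` and back-transform predictions
    at the end.
    """
    x = np.asarray(stocks, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    p = float(stats.shapiro(x).pvalue)
    return p, ("natural_log" if p < alpha else "none")


_PREDICTORS = ("elevation", "slope", "aspect",
               "elevation:slope", "elevation:aspect", "slope:aspect")


def topographic_regression(stocks, elevation, slope, aspect) -> pd.DataFrame:
    """OLS of stock on topography: main effects and pairwise interactions.

    Returns a coefficient table indexed by term with columns ``coef``,
    ``p_value``, ``sig_05`` and ``sig_01``.  Aspect enters as raw degrees
    (a known limitation for a circular variable, documented in the methods
    note).  A rank-deficient design raises ``ValueError``.
    """
    y = np.asarray(stocks, dtype=float)
    ele = np.asarray(elevation, dtype=float)
    slo = np.asarray(slope, dtype=float)
    asp = np.asarray(aspect, dtype=float)
    n = y.size
    if not (ele.size == slo.size == asp.size == n):
        raise ValueError("all vectors must have equal length")
    if n <= 7:
        raise ValueError("need n > 7 for six predictors plus intercept")
    X = np.column_stack([ele, slo, asp, ele * slo, ele * asp, slo * asp])
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("singular design: collinear topographic predictors")
    res = sm.OLS(y, Xc).fit()
    coefs = res.params[1:]
    pvals = res.pvalues[1:]
    return pd.DataFrame({
        "coef": coefs,
        "p_value": pvals,
        "sig_05": pvals < 0.05,
        "sig_01": pvals < 0.01,
    }, index=list(_PREDICTORS))
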