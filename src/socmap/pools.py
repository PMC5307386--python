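"""Regional SOC pool estimation and three-way method comparison.

A regional pool in teragrams (1 Tg = 10^6 Mg = 10^12 g) is obtained either
by integrating an interpolated stock surface over the masked grid cells

    total_Tg = sum_cells stock[Mg ha^-1] * cell_area_ha / 10^6

or by the conventional approach (CA): mean plot stock times total area.
CA ignores the spatial distribution entirely, so grid-based estimates
usually differ from it; the comparison reports the relative differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interpolation import PredictionGrid

MG_PER_TG = 1e6


@dataclass(frozen=True)
class RegionalPool:
    method: str       # "OK", "IDW" or "CA"
    layer: str
    total_tg: float
    area_ha: float
    cell_count: int = 0


def pool_from_grid(grid: PredictionGrid, layer: str = "") -> RegionalPool:
    """Integrate a masked prediction surface into a Tg pool."""
    mask = grid.mask & np.isfinite(grid.prediction)
    if not mask.any():
        raise ValueError("prediction grid has no masked-in cells")
    cell_area_ha = grid.spec.cell_size ** 2 / 1e4
    total = float(np.nansum(grid.prediction[mask]) * cell_area_ha / MG_PER_TG)
    return RegionalPool(method=grid.method, layer=layer, total_tg=total,
                        area_ha=float(mask.sum() * cell_area_ha),
                        cell_count=int(mask.sum()))


def pool_conventional(mean_stock: float, area_ha: float,
                      layer: str = "") -> RegionalPool:
    """Conventional-approach pool: mean stock (Mg ha^-1) x area (ha)."""
    if not (mean_stock > 0 and area_ha > 0):
        raise ValueError("mean stock and area must both be positive")
    return RegionalPool(method="CA", layer=layer,
                        total_tg=mean_stock * area_ha / MG_PER_TG,
                        area_ha=float(area_ha))


def compare_pools(pools) -> dict:
    """Pairwise relative differences between pool estimates for one layer.

    Differences versus CA use CA as denominator, ``(CA - X)/CA * 100``,
    rounded to whole percent; the OK-vs-IDW difference uses the mean of the
    two as denominator and one decimal.  A zero denominator yields NaN.
    """
    pools = list(pools)
    if len(pools) < 2:
        raise ValueError("need at least 2 pools to compare")
    layers = {p.layer for p in pools}
    if len(layers) > 1:
        raise ValueError(f"pools span multiple layers: {sorted(layers)}")
    by = {p.method: p for p in pools}
    out: dict[str, object] = {"layer": pools[0].layer}
    ca = by.get("CA")
    for name in ("OK", "IDW"):
        if ca is not None and name in by:
            if ca.total_tg == 0:
                out[f"{name.lower()}_vs_ca_pct"] = float("nan")
            else:
                out[f"{name.lower()}_vs_ca_pct"] = float(round(
                    (ca.total_tg - by[name].total_tg) / ca.total_tg * 100.0))
    if "OK" in by and "IDW" in by:
        mean = 0.5 * (by["OK"].total_tg + by["IDW"].total_tg)
        if mean == 0:
            out["ok_vs_idw_pct"] = float("nan")
        else:
            out["ok_vs_idw_pct"] = round(
                abs(by["OK"].total_tg - by["IDW"].total_tg) / mean * 100.0, 1)
    out["totals_tg"] = {p.method: round(p.total_tg, 2) for p in pools}
    return out
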