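"""Inventory-based biomass carbon: BEF conversion and provincial-to-grid mapping.

National forest inventories report, per province x forest type x five-year
period, the forest area and growing-stock timber volume. Timber volume per
hectare ``x`` is converted to whole-tree above-ground biomass with a
volume-dependent biomass expansion factor

    BEF(x) = a + b / x        (Mg biomass per m^3-equivalent)

whose constants (a, b) are specific to each forest type; biomass becomes
carbon with a factor of 0.5. Provincial carbon densities are then painted
onto the forest-type raster: each forest cell receives the area-weighted
provincial density of its (province, inventory type), which conserves
provincial stocks by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from domcarbon.grids import ForestTypeRaster

__all__ = [
    "PERIODS",
    "PERIOD_MIDPOINTS",
    "BEFParams",
    "bef",
    "inventory_biomass_c",
    "provincial_carbon_table",
    "grid_agb_map",
]

logger = logging.getLogger(__name__)

#: the five national inventory windows and their midpoint years
PERIODS = ("1984-1988", "1989-1993", "1994-1998", "1999-2003", "2004-2008")
PERIOD_MIDPOINTS = {
    "1984-1988": 1986,
    "1989-1993": 1991,
    "1994-1998": 1996,
    "1999-2003": 2001,
    "2004-2008": 2006,
}

#: hectares per Mha; Mg per Tg
_HA_PER_MHA = 1.0e6
_MG_PER_TG = 1.0e6


@dataclass(frozen=True)
class BEFParams:
    """Per-forest-type (a, b) constants of the expansion factor a + b/x.

    ``a`` is the asymptotic biomass per unit volume (Mg m^-3 equivalent) at
    high stocking; ``b`` (Mg ha^-1) inflates sparse stands, whose crown and
    bark fractions are relatively larger.
    """

    by_type: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for t, (a, b) in self.by_type.items():
            if a <= 0 or b < 0:
                raise ValueError(f"BEF constants for {t!r} must have a>0, b>=0")

    def get(self, forest_type: str) -> tuple[float, float]:
        try:
            return self.by_type[forest_type]
        except KeyError:
            raise KeyError(f"no BEF constants for forest type {forest_type!r}") from None


def bef(a: float, b: float, x: float) -> float:
    """Biomass expansion factor ``a + b/x`` for volume density ``x`` (m^3 ha^-1).

    Decreasing in ``x`` for ``b > 0`` and approaching ``a`` as ``x`` grows.
    """
    if x <= 0:
        raise ValueError("timber volume per unit area must be positive")
    return a + b / x


def inventory_biomass_c(
    area_mha: float,
    volume_per_area: float,
    a: float,
    b: float,
    c_fraction: float = 0.5,
) -> tuple[float, float]:
    """Carbon stock (Tg C) and density (Mg C ha^-1) of one inventory cell.

    Biomass density = volume density x BEF(volume density); carbon density
    applies ``c_fraction``; the stock integrates density over ``area_mha``
    (1 Mg C ha^-1 over 1 Mha = 1 Tg C).
    """
    if area_mha < 0:
        raise ValueError("area must be non-negative")
    if area_mha == 0:
        return 0.0, 0.0
    density = volume_per_area * bef(a, b, volume_per_area) * c_fraction
    stock_tg = density * area_mha * _HA_PER_MHA / _MG_PER_TG
    return stock_tg, density


def provincial_carbon_table(
    inventory: pd.DataFrame,
    params: BEFParams,
    c_fraction: float = 0.5,
) -> pd.DataFrame:
    """Provincial AGB carbon per (province, forest_type, period).

    ``inventory`` columns: province, forest_type, period, area_mha and either
    ``volume_per_area`` (m^3 ha^-1) or total ``volume_m3``. Returns the input
    keys plus ``agb_c_density`` (Mg C ha^-1) and ``agb_c_stock_tg``.
    """
    req = {"province", "forest_type", "period", "area_mha"}
    if not req.issubset(inventory.columns):
        raise ValueError(f"inventory table needs columns {sorted(req)}")
    df = inventory.copy()
    if "volume_per_area" not in df.columns:
        if "volume_m3" not in df.columns:
            raise ValueError("inventory needs volume_per_area or volume_m3")
        df["volume_per_area"] = df["volume_m3"] / (df["area_mha"] * _HA_PER_MHA)
    stocks, densities = [], []
    for row in df.itertuples(index=False):
        a, b = params.get(row.forest_type)
        stock, dens = inventory_biomass_c(
            row.area_mha, row.volume_per_area, a, b, c_fraction
        )
        stocks.append(stock)
        densities.append(dens)
    df["agb_c_density"] = densities
    df["agb_c_stock_tg"] = stocks
    return df


def grid_agb_map(
    provincial: pd.DataFrame,
    raster: ForestTypeRaster,
    period: str,
    fallback_province_mean: bool = True,
) -> xr.DataArray:
    """Paint provincial AGB carbon densities onto the forest-type raster.

    Every forest cell receives the ``agb_c_density`` of its (province,
    inventory type) for ``period``. Combinations present on the raster but
    absent from the table fall back, when enabled, to the province's
    area-weighted all-type mean density (logged); otherwise a coverage error
    lists the gaps.
    """
    sub = provincial[provincial["period"] == period]
    if sub.empty:
        raise ValueError(f"no provincial rows for period {period!r}")
    dens = {
        (int(r.province), str(r.forest_type)): float(r.agb_c_density)
        for r in sub.itertuples(index=False)
    }
    w = sub.groupby("province").apply(
        lambda g: float(np.average(g["agb_c_density"], weights=g["area_mha"]))
        if g["area_mha"].sum() > 0
        else float(g["agb_c_density"].mean()),
        include_groups=False,
    )
    prov_mean = {int(k): v for k, v in w.items()}

    ftype = raster.inventory_type().values
    prov = raster.data["province"].values
    mask = raster.forest_mask.values
    out = np.full(ftype.shape, np.nan)
    gaps = set()
    it = np.nditer(mask, flags=["multi_index"])
    for m in it:
        if not m:
            continue
        idx = it.multi_index
        key = (int(prov[idx]), str(ftype[idx]))
        if key in dens:
            out[idx] = dens[key]
        elif fallback_province_mean and key[0] in prov_mean:
            out[idx] = prov_mean[key[0]]
            gaps.add(key)
        else:
            gaps.add(key)
    if gaps and not fallback_province_mean:
        raise ValueError(
            f"no provincial AGB density for raster combinations: {sorted(gaps)}"
        )
    if gaps:
        logger.info(
            "grid_agb_map: %d (province, type) combinations fell back to the "
            "province mean: %s",
            len(gaps),
            sorted(gaps),
        )
    return xr.DataArray(out, coords=raster.data["fine_type"].coords, name="agb_c")
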