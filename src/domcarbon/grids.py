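"""Gridded data structures: the forest-type raster and per-period predictor grids.

Grids are regular lon/lat rasters (default 0.083 deg, the working resolution
of the national maps) held as :class:`xarray.Dataset` with cell-center
coordinates. Cell areas are computed on a spherical Earth (authalic radius)
per cell latitude, so zonal sums are in real hectares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["DEFAULT_RESOLUTION", "ForestTypeRaster", "PredictorGrid", "cell_area_ha"]

DEFAULT_RESOLUTION = 0.083

#: authalic Earth radius, m
_EARTH_RADIUS_M = 6371007.2
_M2_PER_HA = 1.0e4

#: sentinel for non-forest cells in integer class rasters
NONFOREST = -1


def cell_area_ha(lat: np.ndarray, resolution: float = DEFAULT_RESOLUTION) -> np.ndarray:
    """Area (ha) of grid cells centered at latitudes ``lat`` (degrees)."""
    lat = np.asarray(lat, dtype=float)
    half = resolution / 2.0
    band = np.sin(np.radians(lat + half)) - np.sin(np.radians(lat - half))
    area_m2 = _EARTH_RADIUS_M**2 * np.radians(resolution) * band
    return area_m2 / _M2_PER_HA


@dataclass
class ForestTypeRaster:
    """Fine forest-type classes plus province ids on a regular grid.

    ``data`` holds integer variables ``fine_type`` (fine vegetation-map
    class, ``-1`` outside forest) and ``province`` on ``(lat, lon)``;
    ``crosswalk`` maps each fine class to one of the (typically 18) inventory
    forest types.
    """

    data: xr.Dataset
    crosswalk: Mapping[int, str]
    resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        for var in ("fine_type", "province"):
            if var not in self.data:
                raise ValueError(f"raster dataset must contain {var!r}")
        fine = self.data["fine_type"].values
        forest_classes = np.unique(fine[fine != NONFOREST])
        missing = [int(c) for c in forest_classes if int(c) not in self.crosswalk]
        if missing:
            raise ValueError(f"fine classes missing from crosswalk: {missing}")
        for coord in ("lat", "lon"):
            vals = self.data[coord].values
            if len(vals) > 1:
                steps = np.diff(vals)
                if not np.allclose(steps, self.resolution, atol=1e-6):
                    raise ValueError(
                        f"{coord} spacing must equal the {self.resolution} deg resolution"
                    )

    @property
    def forest_mask(self) -> xr.DataArray:
        return self.data["fine_type"] != NONFOREST

    def inventory_type(self) -> xr.DataArray:
        """Map each forest cell through the crosswalk to its inventory type."""
        fine = self.data["fine_type"].values
        out = np.full(fine.shape, "", dtype=object)
        for cls, t18 in self.crosswalk.items():
            out[fine == cls] = t18
        return xr.DataArray(out, coords=self.data["fine_type"].coords)

    def cell_areas(self) -> xr.DataArray:
        """Per-cell area in hectares, broadcast over the grid."""
        per_lat = cell_area_ha(self.data["lat"].values, self.resolution)
        grid = np.broadcast_to(
            per_lat[:, None], (self.data.sizes["lat"], self.data.sizes["lon"])
        )
        return xr.DataArray(grid.copy(), coords=self.data["fine_type"].coords)


@dataclass
class PredictorGrid:
    """Per-period predictor surfaces on the forest cells of one raster.

    ``data`` carries ``mat`` (deg C), ``map`` (mm), ``agb_c`` (Mg C ha^-1)
    on dims ``(period, lat, lon)`` plus the static ``forest_type`` labels;
    ``region`` assigns each province to a reporting region.
    """

    data: xr.Dataset
    raster: ForestTypeRaster
    region_of_province: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var in ("mat", "map", "agb_c"):
            if var not in self.data:
                raise ValueError(f"predictor grid must contain {var!r}")
        agb = self.data["agb_c"].values
        mask = self.raster.forest_mask.values
        if np.any(agb[..., mask] < 0):
            raise ValueError("agb_c must be non-negative on forest cells")

    @property
    def periods(self) -> list[str]:
        return [str(p) for p in self.data["period"].values]

    def frame(self, period: str) -> pd.DataFrame:
        """Flat per-forest-cell predictor table for one period.

        Columns: cell (flat index), lat, lon, mat, map, agb_c, forest_type,
        province, region, area_ha.
        """
        mask = self.raster.forest_mask.values
        ftype = self.raster.inventory_type().values[mask]
        prov = self.raster.data["province"].values[mask]
        areas = self.raster.cell_areas().values[mask]
        sel = self.data.sel(period=period)
        lat2d, lon2d = xr.broadcast(self.data["lat"], self.data["lon"])
        df = pd.DataFrame(
            {
                "cell": np.flatnonzero(mask.ravel()),
                "lat": lat2d.values[mask],
                "lon": lon2d.values[mask],
                "mat": sel["mat"].values[mask],
                "map": sel["map"].values[mask],
                "agb_c": sel["agb_c"].values[mask],
                "forest_type": ftype,
                "province": prov,
                "area_ha": areas,
            }
        )
        df["region"] = df["province"].map(
            lambda p: self.region_of_province.get(int(p), f"province-{int(p)}")
        )
        return df
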