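"""Stage-2 surfaces: BEF conversion, provincial gridding, climate interpolation."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from domcarbon.climate import extract_at_sites, interpolate_climate
from domcarbon.grids import ForestTypeRaster, cell_area_ha
from domcarbon.inventory import (
    BEFParams,
    bef,
    grid_agb_map,
    inventory_biomass_c,
    provincial_carbon_table,
)


def _toy_raster(nx=10, ny=10, n_provinces=2):
    lat = 30.0 + 0.083 * (np.arange(ny) + 0.5)
    lon = 100.0 + 0.083 * (np.arange(nx) + 0.5)
    fine = np.zeros((ny, nx), dtype=int)
    fine[:, nx // 2:] = 1
    province = np.zeros((ny, nx), dtype=int)
    province[ny // 2:, :] = n_provinces - 1
    ds = xr.Dataset(
        {"fine_type": (("lat", "lon"), fine), "province": (("lat", "lon"), province)},
        coords={"lat": lat, "lon": lon},
    )
    return ForestTypeRaster(ds, crosswalk={0: "conifer", 1: "broadleaf"})


class TestBEF:
    def test_zero_b_returns_a(self):
        assert bef(0.7, 0.0, 3.0) == 0.7

    def test_hand_evaluation(self):
        assert bef(0.5, 50.0, 100.0) == pytest.approx(1.0)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            bef(0.5, 50.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(0.1, 2.0),
        b=st.floats(0.0, 100.0),
        x1=st.floats(1.0, 500.0),
        x2=st.floats(1.0, 500.0),
    )
    def test_monotone_decreasing_towards_a(self, a, b, x1, x2):
        lo, hi = sorted((x1, x2))
        assert bef(a, b, lo) >= bef(a, b, hi) >= a


class TestInventoryBiomassC:
    def test_chained_formula(self):
        # x=100, BEF=1.0 -> biomass 100 Mg/ha, C 50 Mg/ha, 50 Tg over 1 Mha
        stock, density = inventory_biomass_c(1.0, 100.0, 0.5, 50.0)
        assert density == pytest.approx(50.0)
        assert stock == pytest.approx(50.0)

    def test_zero_area_zero_stock(self):
        assert inventory_biomass_c(0.0, 100.0, 0.5, 50.0) == (0.0, 0.0)

    def test_c_fraction_linearity(self):
        s1, d1 = inventory_biomass_c(2.0, 80.0, 0.6, 20.0, c_fraction=0.5)
        s2, d2 = inventory_biomass_c(2.0, 80.0, 0.6, 20.0, c_fraction=0.25)
        assert s1 == pytest.approx(2 * s2)
        assert d1 == pytest.approx(2 * d2)


class TestGridAgbMap:
    def test_single_stratum_constant_map(self):
        raster = _toy_raster(n_provinces=1)
        prov = pd.DataFrame(
            {
                "province": [0, 0],
                "forest_type": ["conifer", "broadleaf"],
                "period": ["2004-2008"] * 2,
                "area_mha": [1.0, 1.0],
                "agb_c_density": [50.0, 50.0],
            }
        )
        out = grid_agb_map(prov, raster, "2004-2008")
        assert np.allclose(out.values, 50.0)

    def test_weighted_mean_and_conservation(self):
        raster = _toy_raster(n_provinces=1)
        prov = pd.DataFrame(
            {
                "province": [0, 0],
                "forest_type": ["conifer", "broadleaf"],
                "period": ["2004-2008"] * 2,
                "area_mha": [1.0, 1.0],
                "agb_c_density": [40.0, 60.0],
            }
        )
        out = grid_agb_map(prov, raster, "2004-2008")
        areas = raster.cell_areas().values
        # equal cell counts per type -> area-weighted provincial mean ~ 50
        mean = float((out.values * areas).sum() / areas.sum())
        assert mean == pytest.approx(50.0, rel=1e-3)
        # conservation against an independently summed stock at cell areas
        stock = float((out.values * areas).sum()) / 1e6
        expected = sum(
            d * (areas[raster.inventory_type().values == t].sum() / 1e6)
            for d, t in zip([40.0, 60.0], ["conifer", "broadleaf"])
        )
        assert stock == pytest.approx(expected, rel=1e-6)

    def test_unmatched_without_fallback_raises(self):
        raster = _toy_raster(n_provinces=2)
        prov = pd.DataFrame(
            {
                "province": [0, 0],
                "forest_type": ["conifer", "broadleaf"],
                "period": ["2004-2008"] * 2,
                "area_mha": [1.0, 1.0],
                "agb_c_density": [40.0, 60.0],
            }
        )
        with pytest.raises(ValueError, match="combinations"):
            grid_agb_map(prov, raster, "2004-2008", fallback_province_mean=False)

    def test_provincial_table_requires_bef_entry(self):
        inv = pd.DataFrame(
            {
                "province": [0], "forest_type": ["mystery"],
                "period": ["2004-2008"], "area_mha": [1.0],
                "volume_per_area": [80.0],
            }
        )
        with pytest.raises(KeyError, match="mystery"):
            provincial_carbon_table(inv, BEFParams({"conifer": (0.5, 20.0)}))


class TestClimate:
    def test_constant_station_values_give_constant_surface(self):
        raster = _toy_raster()
        st_df = pd.DataFrame(
            {"lon": [100.1, 100.4, 100.7], "lat": [30.1, 30.5, 30.7],
             "mat": [8.0] * 3, "map": [900.0] * 3}
        )
        clim = interpolate_climate(st_df, raster)
        assert np.allclose(clim["mat"].values, 8.0)
        assert np.allclose(clim["map"].values, 900.0)

    def test_needs_three_stations(self):
        raster = _toy_raster()
        st_df = pd.DataFrame({"lon": [100.1], "lat": [30.1], "mat": [8.0], "map": [900.0]})
        with pytest.raises(ValueError):
            interpolate_climate(st_df, raster)

    def test_planar_field_recovered_within_one_percent(self):
        raster = _toy_raster(nx=20, ny=20)
        rng = np.random.default_rng(5)
        lat = raster.data["lat"].values
        lon = raster.data["lon"].values
        slon = rng.uniform(lon[0], lon[-1], 150)
        slat = rng.uniform(lat[0], lat[-1], 150)
        st_df = pd.DataFrame(
            {"lon": slon, "lat": slat, "mat": 5.0 * slat - 100.0, "map": 2.0 * slon}
        )
        clim = interpolate_climate(st_df, raster, seed=0)
        glat = np.broadcast_to(lat[:, None], clim["mat"].shape)
        truth = 5.0 * glat - 100.0
        rmse = float(np.sqrt(((clim["mat"].values - truth) ** 2).mean()))
        assert rmse / np.ptp(truth) < 0.01

    def test_idw_bounded_by_station_extremes(self):
        raster = _toy_raster()
        st_df = pd.DataFrame(
            {"lon": [100.1, 100.5, 100.8], "lat": [30.1, 30.4, 30.8],
             "mat": [2.0, 10.0, 6.0], "map": [400.0, 1200.0, 800.0]}
        )
        clim = interpolate_climate(st_df, raster, method="idw")
        assert clim["mat"].values.min() >= 2.0 - 1e-9
        assert clim["mat"].values.max() <= 10.0 + 1e-9


class TestExtraction:
    def test_cell_center_and_constant_surface(self):
        raster = _toy_raster()
        surf = xr.DataArray(
            np.arange(100, dtype=float).reshape(10, 10),
            coords={"lat": raster.data["lat"], "lon": raster.data["lon"]},
            dims=("lat", "lon"),
        )
        lat0 = float(raster.data["lat"][2])
        lon0 = float(raster.data["lon"][3])
        got = extract_at_sites(surf, [lon0, lon0 + 0.01], [lat0, lat0 + 0.01])
        assert got[0] == surf.values[2, 3]
        assert got[1] == got[0]  # same containing cell

    def test_outside_extent_is_nan_not_crash(self):
        raster = _toy_raster()
        surf = xr.DataArray(
            np.ones((10, 10)),
            coords={"lat": raster.data["lat"], "lon": raster.data["lon"]},
            dims=("lat", "lon"),
        )
        got = extract_at_sites(surf, [500.0], [0.0])
        assert np.isnan(got[0])


def test_cell_area_decreases_towards_pole():
    a = cell_area_ha(np.array([0.0, 45.0, 60.0]))
    assert a[0] > a[1] > a[2] > 0
    # 0.083 deg cell at the equator is ~85 km^2 = 8500 ha
    assert a[0] == pytest.approx(8520, rel=0.02)
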