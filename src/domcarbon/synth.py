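"""A self-contained synthetic world with known truth for every pipeline stage.

The generator emulates the structure of a national DOM carbon study: a
lon/lat working grid with provinces and forest types, smooth climate fields
sampled by a station network, a five-period inventory whose BEF-derived
provincial AGB carbon densities are known exactly, and field sites whose raw
plot measurements (dead-wood pieces, litter subplots, tree lists, soil
profiles) decompose known target densities *exactly* — so stage-1
recomputation is a strict round-trip check.

True DOM response surfaces are linear-plus-interaction in (AGB, MAT, MAP)
with additive forest-type offsets. Their signs follow the observed pattern:
woody-debris pools (FWD, snags, logs) increase with AGB, MAT and MAP, while
litter decreases with MAT and MAP (cool, dry conifer stands accumulate deep
litter; warm, wet broadleaf stands turn over litter fast but carry more
large dead wood). Site observations add mean-one multiplicative lognormal
noise, keeping densities non-negative.

The default scale (200 sites, a 40 x 40 grid at 0.083 deg, 5 provinces,
4 forest types) runs the full pipeline in minutes while leaving enough
signal for ensemble recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import xarray as xr

from domcarbon import fieldplots as fp
from domcarbon.fieldplots import (
    CarbonConcentrationTable,
    DeadWoodPiece,
    LitterSample,
    PlotSurvey,
    SoilLayer,
    TreeRecord,
    WoodDensityTable,
)
from domcarbon.grids import NONFOREST, ForestTypeRaster, PredictorGrid
from domcarbon.inventory import PERIOD_MIDPOINTS, PERIODS, BEFParams

__all__ = ["WorldConfig", "World", "make_world", "roundtrip_check", "write_world"]

DEFAULT_FOREST_TYPES = (
    "evergreen_broadleaf",
    "deciduous_broadleaf",
    "mixed",
    "conifer",
)

#: true response surfaces: component -> coefficients on AGB (Mg C/ha),
#: MAT (deg C), MAP (mm), an AGB x MAT interaction, and type offsets
DEFAULT_SURFACES: dict[str, dict] = {
    "fwd": {
        "intercept": 0.04, "agb": 0.0012, "mat": 0.003, "map": 0.00004,
        "agb_mat": 0.0,
        "type_offsets": {"evergreen_broadleaf": 0.03, "conifer": -0.02},
    },
    "snags": {
        "intercept": 0.15, "agb": 0.010, "mat": 0.020, "map": 0.0002,
        "agb_mat": 0.0002,
        "type_offsets": {"evergreen_broadleaf": 0.35, "conifer": -0.20},
    },
    "logs": {
        "intercept": 0.15, "agb": 0.011, "mat": 0.022, "map": 0.0002,
        "agb_mat": 0.0002,
        "type_offsets": {"evergreen_broadleaf": 0.40, "conifer": -0.20},
    },
    "litter": {
        "intercept": 5.0, "agb": -0.004, "mat": -0.060, "map": -0.0009,
        "agb_mat": 0.0,
        "type_offsets": {"conifer": 0.45, "evergreen_broadleaf": -0.80},
    },
}

DEFAULT_WOOD_DENSITY = WoodDensityTable(
    {
        ("default", "I"): 450.0,
        ("default", "II"): 400.0,
        ("default", "III"): 350.0,
        ("default", "IV"): 300.0,
    }
)

DEFAULT_ALLOMETRY: dict[str, list[tuple[float, float]]] = {"default": [(0.06, 1.0)]}

_SOIL_BREAKS = ((0, 10), (10, 20), (20, 30), (30, 50), (50, 70), (70, 100))


@dataclass
class WorldConfig:
    """Everything that defines a synthetic study region.

    ``area_growth_rate`` is the linear national forest-area expansion per
    year (default 0.9 %/yr, the reforestation-era rate); ``agb_growth_rate``
    grows stand biomass between inventory periods. ``noise_sd`` is the
    lognormal sigma of site observation noise on component densities.
    """

    seed: int = 0
    n_sites: int = 200
    n_stations: int = 50
    grid_nx: int = 40
    grid_ny: int = 40
    resolution: float = 0.083
    lon0: float = 100.0
    lat0: float = 28.0
    n_provinces: int = 5
    forest_types: tuple[str, ...] = DEFAULT_FOREST_TYPES
    base_area_mha: float = 131.7
    area_growth_rate: float = 0.009
    agb_growth_rate: float = 0.010
    surfaces: Mapping[str, dict] = dc_field(default_factory=lambda: DEFAULT_SURFACES)
    noise_sd: float = 0.20
    nonforest_fraction: float = 0.08
    bef_a: float = 0.5
    bef_b: float = 15.0
    c_fraction: float = 0.5
    n_plots_per_site: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for comp, coef in self.surfaces.items():
            for key in ("intercept", "agb", "mat", "map"):
                if key not in coef:
                    raise ValueError(f"surface for {comp!r} missing {key!r}")


@dataclass
class World:
    """All pipeline inputs plus the truth record of one synthetic world."""

    config: WorldConfig
    raster: ForestTypeRaster
    predictor_grid: PredictorGrid
    stations: pd.DataFrame
    inventory: pd.DataFrame
    bef_params: BEFParams
    region_of_province: dict[int, str]
    sites: pd.DataFrame
    surveys: dict[str, list[PlotSurvey]]
    wood_density: WoodDensityTable
    concentrations: CarbonConcentrationTable
    allometry: dict[str, list[tuple[float, float]]]
    truth: dict


def _surface_value(coef: Mapping, agb: np.ndarray, mat: np.ndarray,
                   map_: np.ndarray, ftype: np.ndarray) -> np.ndarray:
    val = (
        coef["intercept"]
        + coef["agb"] * agb
        + coef["mat"] * mat
        + coef["map"] * map_
        + coef.get("agb_mat", 0.0) * agb * mat
    )
    offsets = coef.get("type_offsets", {})
    if offsets:
        off = np.vectorize(lambda t: offsets.get(t, 0.0))(ftype)
        val = val + off
    return np.maximum(val, 0.01)


def _mat_field(lon: np.ndarray, lat: np.ndarray, cfg: WorldConfig) -> np.ndarray:
    ext = cfg.grid_nx * cfg.resolution
    return (
        19.0
        - 5.0 * (lat - cfg.lat0)
        + 1.2 * np.sin(2 * np.pi * (lon - cfg.lon0) / ext)
    )


def _map_field(lon: np.ndarray, lat: np.ndarray, cfg: WorldConfig) -> np.ndarray:
    ext = cfg.grid_nx * cfg.resolution
    return (
        450.0
        + 320.0 * (lon - cfg.lon0)
        + 60.0 * np.cos(2 * np.pi * (lat - cfg.lat0) / ext)
    )


def _decompose_plot(
    targets: Mapping[str, float],
    stand_age_years: float,
    rng: np.random.Generator,
    cfg: WorldConfig,
) -> PlotSurvey:
    """Raw measurements whose stage-1 densities equal ``targets`` exactly.

    Masses are solved backwards through the same volume and density rules
    the accounting stage applies, so recomputation is a strict round trip.
    """
    area = 400.0
    conc = 0.5
    pieces: list[DeadWoodPiece] = []

    def wood_mass(rho: float) -> float:
        # Mg C ha^-1 -> total oven-dry kg on the plot
        return rho * area / 10.0 / conc

    # logs: one directly weighed piece + one estimated from volume (class II)
    m_logs = wood_mass(targets["logs"])
    if m_logs > 1e-9:
        frac = rng.uniform(0.3, 0.7)
        pieces.append(
            DeadWoodPiece(
                kind="log", diameter_mid=0.30, diameter_ends=(0.30, 0.30),
                length=rng.uniform(4, 10), decay_class="I",
                measured_dry_mass=m_logs * frac,
            )
        )
        vol = m_logs * (1 - frac) / DEFAULT_WOOD_DENSITY.entries[("default", fp.DecayClass.II)]
        d = 0.30
        pieces.append(
            DeadWoodPiece(
                kind="log", diameter_mid=d, diameter_ends=(d, d),
                length=4 * vol / (math.pi * d * d), decay_class="II",
            )
        )
    # snags: estimated from DBH-cylinder volume, decay class III
    m_snags = wood_mass(targets["snags"])
    if m_snags > 1e-9:
        d = 0.25
        vol = m_snags / DEFAULT_WOOD_DENSITY.entries[("default", fp.DecayClass.III)]
        pieces.append(
            DeadWoodPiece(
                kind="snag", diameter_mid=d,
                length=4 * vol / (math.pi * d * d), decay_class="III",
            )
        )
    # fine woody debris: weighed directly
    m_fwd = wood_mass(targets["fwd"])
    if m_fwd > 1e-9:
        pieces.append(
            DeadWoodPiece(
                kind="fwd", diameter_mid=0.06, length=0.5, decay_class="I",
                measured_dry_mass=m_fwd,
            )
        )

    # litter: five 4 m^2 subplots, masses summing exactly to the target
    m_litter = targets["litter"] * 20.0 / 10.0 / conc  # kg over 20 m^2
    shares = rng.dirichlet(np.full(5, 8.0))
    masses = m_litter * shares
    masses[-1] = m_litter - masses[:-1].sum()
    litter = [LitterSample(dry_mass=float(m)) for m in masses]

    # trees: heights scaled so allometric AGB hits the target exactly
    n_trees = int(rng.integers(12, 20))
    dbh = rng.uniform(6, 40, n_trees)
    height = 2.0 + 0.5 * dbh ** 0.8 * rng.uniform(0.8, 1.2, n_trees)
    a_allo = DEFAULT_ALLOMETRY["default"][0][0]
    target_biomass = targets["agb"] * area / 10.0 / cfg.c_fraction
    raw = float(np.sum(a_allo * dbh**2 * height))
    height *= target_biomass / raw
    order = np.argsort(-dbh)
    ages = np.full(n_trees, np.nan)
    top = order[:10]
    ages[top] = np.maximum(5.0, stand_age_years + rng.normal(0, 4, len(top)))
    # DBH ranks 1..4 older, 6..10 younger, rank 5 exactly the stand age
    for r, idx in enumerate(top):
        ages[idx] = stand_age_years + (4 - r) * rng.uniform(0.5, 2.0)
    ages[top[4]] = stand_age_years
    trees = [
        TreeRecord(dbh=float(d), height=float(h),
                   age=None if np.isnan(a) else float(a))
        for d, h, a in zip(dbh, height, ages)
    ]

    # soil: six standard layers, concentrations scaled to the target
    profiles = []
    for _ in range(3):
        bd = rng.uniform(0.9, 1.4, len(_SOIL_BREAKS))
        w = np.array([1.0, 0.8, 0.6, 0.45, 0.3, 0.2]) * rng.uniform(0.9, 1.1, 6)
        denom = sum(
            (b - t) * bdi * wi * 100.0
            for (t, b), bdi, wi in zip(_SOIL_BREAKS, bd, w)
        )
        k = targets["soil"] / denom
        profiles.append(
            [
                SoilLayer(t, b, float(bdi), float(k * wi))
                for (t, b), bdi, wi in zip(_SOIL_BREAKS, bd, w)
            ]
        )

    return PlotSurvey(pieces=pieces, litter=litter, trees=trees,
                      soil_profiles=profiles, plot_area=area)


def make_world(config: WorldConfig | None = None) -> World:
    """Generate every pipeline input plus the truth record.

    Deterministic under ``config.seed``. See the module docstring for what
    the world contains and which features of real data it does and does not
    emulate.
    """
    cfg = config or WorldConfig()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.seed)))
    types = list(cfg.forest_types)

    lat = cfg.lat0 + cfg.resolution * (np.arange(cfg.grid_ny) + 0.5)
    lon = cfg.lon0 + cfg.resolution * (np.arange(cfg.grid_nx) + 0.5)
    glat, glon = np.meshgrid(lat, lon, indexing="ij")
    mat_grid = _mat_field(glon, glat, cfg)
    map_grid = _map_field(glon, glat, cfg)

    # provinces: vertical strips; forest types: 5x5-cell blocks of one type
    prov = np.minimum(
        (np.arange(cfg.grid_nx) * cfg.n_provinces) // cfg.grid_nx,
        cfg.n_provinces - 1,
    )
    province = np.broadcast_to(prov, (cfg.grid_ny, cfg.grid_nx)).copy()
    block = 5
    nby, nbx = -(-cfg.grid_ny // block), -(-cfg.grid_nx // block)
    block_type = rng.integers(0, len(types), (nby, nbx))
    type_idx = np.repeat(np.repeat(block_type, block, 0), block, 1)[
        : cfg.grid_ny, : cfg.grid_nx
    ]
    # three fine vegetation-map classes per inventory type
    variant = rng.integers(0, 3, type_idx.shape)
    fine = type_idx * 3 + variant
    nonforest = rng.random(fine.shape) < cfg.nonforest_fraction
    fine[nonforest] = NONFOREST
    crosswalk = {int(t * 3 + v): types[t] for t in range(len(types)) for v in range(3)}

    raster = ForestTypeRaster(
        xr.Dataset(
            {
                "fine_type": (("lat", "lon"), fine.astype(int)),
                "province": (("lat", "lon"), province.astype(int)),
            },
            coords={"lat": lat, "lon": lon},
        ),
        crosswalk=crosswalk,
        resolution=cfg.resolution,
    )
    region_of_province = {p: f"region-{p + 1}" for p in range(cfg.n_provinces)}

    # stations sample the analytic climate fields; monthly series preserve
    # the annual statistics exactly (zero-mean seasonal cycle, flat precip)
    slon = rng.uniform(lon[0], lon[-1], cfg.n_stations)
    slat = rng.uniform(lat[0], lat[-1], cfg.n_stations)
    smat = _mat_field(slon, slat, cfg)
    smap = _map_field(slon, slat, cfg)
    months = np.arange(1, 13)
    seasonal = 9.0 * np.cos(2 * np.pi * (months - 7) / 12)
    stations = pd.DataFrame({"station": np.arange(cfg.n_stations), "lon": slon, "lat": slat})
    for m, s in zip(months, seasonal):
        stations[f"t{m:02d}"] = smat + s
    for m in months:
        stations[f"p{m:02d}"] = smap / 12.0

    # inventory: per (province, type) base AGB C density, growing over periods;
    # volumes are the exact BEF inversion so the pipeline recovers densities
    mask = ~nonforest
    areas_ha = raster.cell_areas().values
    strata: list[tuple[int, str]] = sorted(
        {(int(province[i, j]), types[type_idx[i, j]])
         for i, j in zip(*np.nonzero(mask))}
    )
    base_density = {
        s: 30.0 + 12.0 * types.index(s[1]) + 4.0 * s[0] + rng.uniform(-5, 5)
        for s in strata
    }
    stratum_cell_area = {
        s: float(
            areas_ha[
                mask
                & (province == s[0])
                & (np.vectorize(lambda t: types[t])(type_idx) == s[1])
            ].sum()
        )
        for s in strata
    }
    total_cell_area = sum(stratum_cell_area.values())

    bef_params = BEFParams({t: (cfg.bef_a, cfg.bef_b) for t in types})
    inv_rows = []
    for period in PERIODS:
        year = PERIOD_MIDPOINTS[period]
        national_area = cfg.base_area_mha * (1 + cfg.area_growth_rate * (year - 1986))
        growth = 1 + cfg.agb_growth_rate * (year - 1986)
        for s in strata:
            dens = base_density[s] * growth
            biomass = dens / cfg.c_fraction
            vol = (biomass - cfg.bef_b) / cfg.bef_a
            if vol <= 0:
                raise ValueError("BEF inversion infeasible; raise base densities")
            area_mha = national_area * stratum_cell_area[s] / total_cell_area
            inv_rows.append(
                {
                    "province": s[0], "forest_type": s[1], "period": period,
                    "area_mha": area_mha, "volume_per_area": vol,
                }
            )
    inventory = pd.DataFrame(inv_rows)

    # per-period AGB carbon grid: the stratum density painted on its cells
    type_name = np.vectorize(lambda t: types[t])(type_idx)
    agb_stack = np.full((len(PERIODS), cfg.grid_ny, cfg.grid_nx), np.nan)
    for k, period in enumerate(PERIODS):
        growth = 1 + cfg.agb_growth_rate * (PERIOD_MIDPOINTS[period] - 1986)
        for s in strata:
            cells = mask & (province == s[0]) & (type_name == s[1])
            agb_stack[k][cells] = base_density[s] * growth
    predictor_grid = PredictorGrid(
        xr.Dataset(
            {
                "mat": (("period", "lat", "lon"),
                        np.broadcast_to(mat_grid, agb_stack.shape).copy()),
                "map": (("period", "lat", "lon"),
                        np.broadcast_to(map_grid, agb_stack.shape).copy()),
                "agb_c": (("period", "lat", "lon"), agb_stack),
            },
            coords={"period": list(PERIODS), "lat": lat, "lon": lon},
        ),
        raster=raster,
        region_of_province=region_of_province,
    )

    # truth: noise-free component densities on the grid, per period
    components = list(cfg.surfaces)
    truth_density = {
        comp: np.stack(
            [
                np.where(
                    mask,
                    _surface_value(cfg.surfaces[comp], agb_stack[k], mat_grid,
                                   map_grid, type_name),
                    np.nan,
                )
                for k in range(len(PERIODS))
            ]
        )
        for comp in components
    }
    # national truth stocks: stratum-mean truth density x inventory area
    inv_area = {
        (r.province, r.forest_type, r.period): r.area_mha
        for r in inventory.itertuples(index=False)
    }
    national_stock = {comp: [] for comp in components + ["woody_debris", "dom"]}
    for k, period in enumerate(PERIODS):
        stocks = {comp: 0.0 for comp in components}
        for s in strata:
            cells = mask & (province == s[0]) & (type_name == s[1])
            w = areas_ha[cells]
            w = w / w.sum()
            for comp in components:
                d = float((truth_density[comp][k][cells] * w).sum())
                stocks[comp] += d * inv_area[(s[0], s[1], period)]
        for comp in components:
            national_stock[comp].append(stocks[comp])
        wd = stocks["fwd"] + stocks["snags"] + stocks["logs"]
        national_stock["woody_debris"].append(wd)
        national_stock["dom"].append(wd + stocks["litter"])

    from domcarbon.trends import ols_trend

    truth = {
        "components": components,
        "national_stock_tg": {k: list(map(float, v)) for k, v in national_stock.items()},
        "national_area_mha": [
            float(inventory[inventory["period"] == p]["area_mha"].sum())
            for p in PERIODS
        ],
        "dom_stock_trend_slope": float(ols_trend(national_stock["dom"]).slope),
        "surface_signs": {
            comp: {k: float(np.sign(cfg.surfaces[comp][k])) for k in ("agb", "mat", "map")}
            for comp in components
        },
        "cell_density": truth_density,
    }

    # sites: random forest cells; covariates from the true fields, AGB with
    # site-level spread around the stratum mean of the latest period
    forest_cells = np.argwhere(mask)
    chosen = forest_cells[
        rng.choice(len(forest_cells), size=cfg.n_sites,
                   replace=cfg.n_sites > len(forest_cells))
    ]
    site_rows = []
    surveys: dict[str, list[PlotSurvey]] = {}
    last = len(PERIODS) - 1
    for n, (i, j) in enumerate(chosen):
        sid = f"S{n:03d}"
        ftype = type_name[i, j]
        agb_site = max(5.0, agb_stack[last, i, j] * rng.lognormal(0, 0.15))
        mat_site = mat_grid[i, j]
        map_site = map_grid[i, j]
        target = {
            comp: float(
                _surface_value(cfg.surfaces[comp], np.array(agb_site),
                               np.array(mat_site), np.array(map_site),
                               np.array(ftype))
                * rng.lognormal(-cfg.noise_sd**2 / 2, cfg.noise_sd)
            )
            for comp in components
        }
        age = float(np.clip(rng.normal(15 + agb_site * 0.9, 10), 8, 200))
        target["agb"] = agb_site
        target["soil"] = float(np.clip(rng.normal(68, 20), 20, 140))
        origin = rng.choice(["primary", "secondary", "plantation"])
        surveys[sid] = [
            _decompose_plot(target, age, rng, cfg)
            for _ in range(cfg.n_plots_per_site)
        ]
        site_rows.append(
            {
                "site": sid, "lon": float(lon[j]), "lat": float(lat[i]),
                "elevation": float(rng.uniform(100, 2500)),
                "forest_type": ftype, "origin": origin, "stand_age": age,
                "mat": float(mat_site), "map": float(map_site),
                **{f"true_{c}": v for c, v in target.items()},
            }
        )
    sites = pd.DataFrame(site_rows)

    return World(
        config=cfg,
        raster=raster,
        predictor_grid=predictor_grid,
        stations=stations,
        inventory=inventory,
        bef_params=bef_params,
        region_of_province=region_of_province,
        sites=sites,
        surveys=surveys,
        wood_density=DEFAULT_WOOD_DENSITY,
        concentrations=CarbonConcentrationTable(),
        allometry=DEFAULT_ALLOMETRY,
        truth=truth,
    )


def roundtrip_check(world: World, rtol: float = 1e-6) -> pd.DataFrame:
    """Recompute stage-1 densities from raw measurements and compare to targets.

    The decomposition is exact by construction, so the maximum relative
    error should sit at floating-point level. Returns a per-site, per-
    component table with the relative errors; raises if any exceeds
    ``rtol``.
    """
    comps = ["fwd", "snags", "logs", "litter", "agb", "soil"]
    rows = []
    for r in world.sites.itertuples(index=False):
        plots = [
            fp.plot_carbon(
                p, world.wood_density, world.concentrations, world.allometry,
                live_c_fraction=world.config.c_fraction,
            )
            for p in world.surveys[r.site]
        ]
        sc = fp.site_aggregate(plots, site=r.site)
        for comp in comps:
            target = getattr(r, f"true_{comp}")
            got = getattr(sc, comp)
            err = abs(got - target) / max(abs(target), 1e-9)
            rows.append({"site": r.site, "component": comp,
                         "target": target, "recomputed": got, "rel_err": err})
    out = pd.DataFrame(rows)
    worst = out["rel_err"].max()
    if worst > rtol:
        bad = out.loc[out["rel_err"].idxmax()]
        raise AssertionError(
            f"round-trip failed: {bad['component']} at {bad['site']} "
            f"rel_err={worst:.2e}"
        )
    return out


def write_world(world: World, outdir: str | Path) -> None:
    """Write every pipeline input file plus ``truth.json`` to ``outdir``.

    Schemas match what the pipeline readers accept: CSV tables for sites,
    surveys, stations, inventory and BEF constants; NetCDF for the raster
    and predictor grids.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    world.sites.to_csv(out / "sites.csv", index=False)
    world.stations.to_csv(out / "stations.csv", index=False)
    world.inventory.to_csv(out / "inventory.csv", index=False)
    pd.DataFrame(
        [
            {"forest_type": t, "a": a, "b": b}
            for t, (a, b) in world.bef_params.by_type.items()
        ]
    ).to_csv(out / "bef.csv", index=False)
    pd.DataFrame(
        [{"fine_type": k, "forest_type": v} for k, v in world.raster.crosswalk.items()]
    ).to_csv(out / "crosswalk.csv", index=False)
    pd.DataFrame(
        [
            {"province": p, "region": r}
            for p, r in world.region_of_province.items()
        ]
    ).to_csv(out / "regions.csv", index=False)
    world.raster.data.to_netcdf(out / "raster.nc")
    world.predictor_grid.data.to_netcdf(out / "predictors.nc")

    pieces, litter, trees, soil = [], [], [], []
    for sid, plots in world.surveys.items():
        for pi, plot in enumerate(plots):
            key = {"site": sid, "plot": pi, "plot_area": plot.plot_area}
            for p in plot.pieces:
                pieces.append(
                    {
                        **key, "kind": p.kind.value, "diameter_mid": p.diameter_mid,
                        "diameter_end1": p.diameter_ends[0] if p.diameter_ends else "",
                        "diameter_end2": p.diameter_ends[1] if p.diameter_ends else "",
                        "length": p.length,
                        "decay_class": p.decay_class.value if p.decay_class else "",
                        "species": p.species,
                        "measured_dry_mass": (
                            "" if p.measured_dry_mass is None else p.measured_dry_mass
                        ),
                    }
                )
            for s in plot.litter:
                litter.append({**key, "subplot_area": s.subplot_area, "dry_mass": s.dry_mass})
            for t in plot.trees:
                trees.append(
                    {**key, "dbh": t.dbh, "height": t.height, "species": t.species,
                     "age": "" if t.age is None else t.age}
                )
            for prof_i, prof in enumerate(plot.soil_profiles):
                for layer in prof:
                    soil.append(
                        {
                            **key, "profile": prof_i,
                            "depth_top": layer.depth_top,
                            "depth_bottom": layer.depth_bottom,
                            "bulk_density": layer.bulk_density,
                            "c_concentration": layer.c_concentration,
                        }
                    )
    pd.DataFrame(pieces).to_csv(out / "deadwood.csv", index=False)
    pd.DataFrame(litter).to_csv(out / "litter.csv", index=False)
    pd.DataFrame(trees).to_csv(out / "trees.csv", index=False)
    pd.DataFrame(soil).to_csv(out / "soil.csv", index=False)

    truth = {
        k: v for k, v in world.truth.items() if k != "cell_density"
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
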