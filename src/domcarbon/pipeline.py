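"""End-to-end orchestration: synthetic world -> site table -> grids -> ensemble -> trends.

``run_pipeline`` executes the five stages in order on a synthetic world (or
on pre-built inputs following the same schemas) and returns every
intermediate product. All randomness flows from one root seed via named
substreams, so a fixed configuration reproduces its outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from domcarbon import fieldplots as fp
from domcarbon.climate import extract_at_sites, interpolate_climate
from domcarbon.inventory import PERIODS, PERIOD_MIDPOINTS, provincial_carbon_table, grid_agb_map
from domcarbon.reporting import component_by_group_table, period_stock_table
from domcarbon.synth import World, WorldConfig, make_world
from domcarbon.trends import ols_trend, change_partition
from domcarbon.upscaling import aggregate, fit_ensemble, predict_components

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stage1_site_table"]

logger = logging.getLogger(__name__)

#: components fitted by the ensemble (derived pools are sums per member)
FITTED_COMPONENTS = ("fwd", "snags", "logs", "litter")


@dataclass
class PipelineConfig:
    """Knobs of one pipeline run.

    ``n_members`` is the number of ensemble resamplings (the full analysis
    uses 500; the default 50 keeps a synthetic run in minutes).
    ``climate_source`` selects station interpolation (``stations``, the
    field-faithful route) or the world's noise-free fields (``truth``).
    """

    seed: int = 0
    n_members: int = 50
    n_trees: int = 100
    train_frac: float = 0.70
    climate_source: str = "stations"
    interpolation: str = "kriging"
    world: WorldConfig = field(default_factory=WorldConfig)

    def substream(self, name: str) -> int:
        """Derived seed for one named stage, stable across runs."""
        digest = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PipelineResult:
    config: PipelineConfig
    world: World
    site_table: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    period_table: pd.DataFrame
    group_table: pd.DataFrame
    trends: pd.DataFrame
    partition: dict[str, float]
    models: dict


def stage1_site_table(world: World) -> pd.DataFrame:
    """Recompute per-site carbon densities from the raw plot measurements."""
    records = []
    for r in world.sites.itertuples(index=False):
        plots = [
            fp.plot_carbon(
                p, world.wood_density, world.concentrations, world.allometry,
                live_c_fraction=world.config.c_fraction,
            )
            for p in world.surveys[r.site]
        ]
        sc = fp.site_aggregate(
            plots, site=r.site, lon=r.lon, lat=r.lat, elevation=r.elevation,
            forest_type=r.forest_type, origin=r.origin, stand_age=r.stand_age,
            mat=r.mat, map=r.map,
        )
        records.append(sc)
    return fp.sites_to_frame(records)


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run stages 1-5 on a synthetic world and return all products.

    1. Site carbon densities from raw measurements.
    2. Per-period predictor grids: inventory AGB via BEF, climate surfaces
       from stations (or truth fields).
    3. Per-component Random-Forest ensembles on the site table.
    4. Per-period pixel prediction and regional/national aggregation.
    5. OLS change rates of national density and stock, with the component
       partition of the DOM stock trend.
    """
    cfg = config or PipelineConfig()
    world_cfg = cfg.world
    if world_cfg.seed == 0 and cfg.seed != 0:
        from dataclasses import replace

        world_cfg = replace(world_cfg, seed=cfg.substream("world"))
    world = make_world(world_cfg)
    logger.info("stage 0: world with %d sites, %d strata",
                len(world.sites), len(world.inventory) // len(PERIODS))

    site_table = stage1_site_table(world)
    logger.info("stage 1: site table %d rows", len(site_table))

    provincial = provincial_carbon_table(
        world.inventory, world.bef_params, world.config.c_fraction
    )
    if cfg.climate_source == "stations":
        clim = interpolate_climate(
            world.stations, world.raster, method=cfg.interpolation,
            seed=cfg.substream("climate"),
        )
        mat_surface, map_surface = clim["mat"], clim["map"]
    else:
        first = world.predictor_grid.data.isel(period=0)
        mat_surface, map_surface = first["mat"], first["map"]

    # training covariates: site-measured AGB and age, grid-extracted climate
    train = site_table.copy()
    train["mat"] = extract_at_sites(mat_surface, train["lon"], train["lat"])
    train["map"] = extract_at_sites(map_surface, train["lon"], train["lat"])
    train["agb_c"] = train["agb"]
    logger.info("stage 2: predictor grids for %d periods", len(PERIODS))

    models = {
        comp: fit_ensemble(
            train[["mat", "map", "agb_c", "forest_type"]],
            train[comp],
            n_members=cfg.n_members,
            train_frac=cfg.train_frac,
            seed=cfg.substream(f"ensemble:{comp}"),
            n_trees=cfg.n_trees,
            component=comp,
        )
        for comp in FITTED_COMPONENTS
    }
    logger.info(
        "stage 3: ensembles fitted, mean R2 = %s",
        {c: round(m.mean_r2, 3) for c, m in models.items()},
    )

    # one prediction pass over all periods at once (members are applied
    # identically everywhere; splitting afterwards is exact)
    period_cells = []
    for period in PERIODS:
        cells = world.predictor_grid.frame(period)
        agb_map = grid_agb_map(provincial, world.raster, period)
        cells["agb_c"] = agb_map.values[world.raster.forest_mask.values]
        if cfg.climate_source == "stations":
            cells["mat"] = extract_at_sites(mat_surface, cells["lon"], cells["lat"])
            cells["map"] = extract_at_sites(map_surface, cells["lon"], cells["lat"])
        cells["period"] = period
        period_cells.append(cells)
    all_cells = pd.concat(period_cells, ignore_index=True)
    all_preds = predict_components(models, all_cells)

    summaries: dict[str, pd.DataFrame] = {}
    offset = 0
    for period, cells in zip(PERIODS, period_cells):
        n = len(cells)
        preds = {c: arr[:, offset:offset + n] for c, arr in all_preds.items()}
        offset += n
        inv_areas = world.inventory[world.inventory["period"] == period]
        summaries[period] = aggregate(preds, cells, inv_areas)
    logger.info("stage 4: regional summaries for %d periods", len(summaries))

    period_table = period_stock_table(summaries)
    group_table = component_by_group_table(site_table)

    trend_rows = []
    slopes: dict[str, float] = {}
    for comp in sorted(period_table["component"].unique()):
        sub = period_table[period_table["component"] == comp].set_index("period")
        sub = sub.loc[list(PERIODS)]
        for kind in ("density", "stock"):
            t = ols_trend(sub[f"{kind}_mean"].to_numpy())
            trend_rows.append(
                {
                    "component": comp, "quantity": kind, "slope": t.slope,
                    "slope_sd": t.slope_sd, "r_squared": t.r_squared,
                    "p_value": t.p_value,
                    "percent_per_year": t.percent_per_year,
                }
            )
            if kind == "stock":
                slopes[comp] = t.slope
    trends = pd.DataFrame(trend_rows)
    partition = change_partition(
        {k: slopes[k] for k in ("woody_debris", "litter") if k in slopes},
        slopes.get("dom", 0.0),
    )
    logger.info("stage 5: DOM stock trend %.3f Tg C/yr", slopes.get("dom", float("nan")))

    return PipelineResult(
        config=cfg, world=world, site_table=site_table, summaries=summaries,
        period_table=period_table, group_table=group_table, trends=trends,
        partition=partition, models=models,
    )


def write_result(result: PipelineResult, outdir: str | Path) -> None:
    """Write the per-stage artifact directory (CSV tables + provenance)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.site_table.to_csv(out / "site_carbon.csv", index=False)
    for period, summary in result.summaries.items():
        summary.to_csv(out / f"summary_{period}.csv", index=False)
    result.period_table.to_csv(out / "period_stocks.csv", index=False)
    result.group_table.to_csv(out / "group_comparison.csv", index=False)
    result.trends.to_csv(out / "trends.csv", index=False)
    provenance = {
        "seed": result.config.seed,
        "n_members": result.config.n_members,
        "n_trees": result.config.n_trees,
        "climate_source": result.config.climate_source,
        "n_sites": int(len(result.site_table)),
        "partition_pct": result.partition,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
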