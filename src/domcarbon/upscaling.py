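"""Ensemble upscaling of DOM carbon: resampled Random Forests with Monte-Carlo spread.

Each DOM component (FWD, snags, logs, litter) is modelled separately from
four predictors — mean annual temperature, mean annual precipitation, AGB
carbon density, and forest type. The ensemble repeats, ``n_members`` times
(500 in the full analysis): draw a random 70% of sites, fit one Random
Forest, score R^2 and RMSE on the held-out 30%. Applying every member to the
predictor grid yields a per-pixel distribution of predictions whose mean is
the estimate and whose between-member SD is the Monte-Carlo uncertainty;
aggregating each member to regions and the nation before summarizing
propagates that uncertainty to stocks.

Derived pools are combined per member before summarizing (CWD = snags +
logs, woody debris = FWD + CWD, DOM = woody debris + litter), which keeps
component additivity of the reported means exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "PREDICTORS",
    "DERIVED",
    "EnsembleMember",
    "EnsembleModel",
    "fit_ensemble",
    "variable_importance",
    "predict_grid",
    "predict_components",
    "aggregate",
    "partial_dependence_sign",
]

logger = logging.getLogger(__name__)

#: the four input variables of the upscaling models
PREDICTORS = ("mat", "map", "agb_c", "forest_type")
NUMERIC_PREDICTORS = ("mat", "map", "agb_c")
#: derived pools and their constituents, in dependency order
DERIVED = {
    "cwd": ("snags", "logs"),
    "woody_debris": ("fwd", "cwd"),
    "dom": ("woody_debris", "litter"),
}


@dataclass
class EnsembleMember:
    """One resampling: a fitted forest, its split, and holdout skill."""

    regressor: RandomForestRegressor
    train_index: np.ndarray
    r2: float
    rmse: float


@dataclass
class EnsembleModel:
    """A per-component ensemble of independently resampled Random Forests."""

    component: str
    members: list[EnsembleMember]
    feature_columns: list[str]
    forest_type_categories: list[str]
    train_frac: float = 0.70

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def mean_r2(self) -> float:
        vals = [m.r2 for m in self.members if math.isfinite(m.r2)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_rmse(self) -> float:
        return float(np.mean([m.rmse for m in self.members]))


def _encode(X: pd.DataFrame, categories: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix: MAT, MAP, AGB plus one-hot forest type."""
    out = X[list(NUMERIC_PREDICTORS)].astype(float).copy()
    ftype = X["forest_type"].astype(str)
    unseen = sorted(set(ftype) - set(categories))
    if unseen:
        logger.info("forest types unseen in training: %s (all-zero encoding)", unseen)
    for cat in categories:
        out[f"forest_type={cat}"] = (ftype == cat).astype(float)
    return out


def fit_ensemble(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_members: int = 500,
    train_frac: float = 0.70,
    seed: int = 0,
    n_trees: int = 100,
    component: str = "",
) -> EnsembleModel:
    """Fit the resampled Random-Forest ensemble for one DOM component.

    ``X`` must carry the columns in :data:`PREDICTORS`; ``y`` is the
    component's site carbon density (Mg C ha^-1, non-negative). Each member
    is one forest of ``n_trees`` trees with mtry = ceil(p/3) candidate
    features per split, trained on an independent random ``train_frac``
    subset and scored on its complement. Fully deterministic under ``seed``.
    """
    X = X.reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    if len(X) < 20:
        raise ValueError("ensemble fitting needs at least 20 sites")
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if np.any(y < 0):
        raise ValueError("component densities must be non-negative")
    missing = [c for c in PREDICTORS if c not in X.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    if X[list(NUMERIC_PREDICTORS)].isna().any().any():
        raise ValueError("predictors contain missing values")

    categories = sorted(X["forest_type"].astype(str).unique())
    design = _encode(X, categories)
    mtry = math.ceil(design.shape[1] / 3)
    n = len(X)
    n_train = max(1, round(train_frac * n))

    root = np.random.SeedSequence(seed)
    members = []
    for child in root.spawn(n_members):
        rng = np.random.Generator(np.random.PCG64(child))
        perm = rng.permutation(n)
        train_idx, val_idx = perm[:n_train], perm[n_train:]
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=mtry,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(design.iloc[train_idx], y[train_idx])
        if len(val_idx):
            pred = rf.predict(design.iloc[val_idx])
            resid = y[val_idx] - pred
            rmse = float(np.sqrt(np.mean(resid**2)))
            ss_tot = float(np.sum((y[val_idx] - y[val_idx].mean()) ** 2))
            # constant holdout response leaves R^2 undefined (flagged NaN)
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
        else:
            rmse, r2 = float("nan"), float("nan")
        members.append(EnsembleMember(rf, train_idx, r2, rmse))
    return EnsembleModel(
        component=component,
        members=members,
        feature_columns=list(design.columns),
        forest_type_categories=categories,
        train_frac=train_frac,
    )


def variable_importance(
    model: EnsembleModel,
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_repeats: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance (%IncMSE) per predictor, mean +/- SD over members.

    For each member the holdout MSE is compared with the MSE after permuting
    one predictor (the forest-type one-hot block is permuted as a unit);
    %IncMSE = 100 x (permuted - original) / original. Returns a DataFrame
    indexed by predictor with ``mean`` and ``sd`` columns, sorted descending.
    """
    X = X.reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    design = _encode(X, model.forest_type_categories)
    groups = {p: [p] for p in NUMERIC_PREDICTORS}
    groups["forest_type"] = [
        c for c in model.feature_columns if c.startswith("forest_type=")
    ]
    rng = np.random.Generator(np.random.PCG64(seed))
    per_member: dict[str, list[float]] = {p: [] for p in groups}
    n = len(X)
    for member in model.members:
        val_idx = np.setdiff1d(np.arange(n), member.train_index)
        if len(val_idx) == 0:
            continue
        Xv = design.iloc[val_idx].reset_index(drop=True)
        yv = y[val_idx]
        base_mse = float(np.mean((member.regressor.predict(Xv) - yv) ** 2))
        if base_mse <= 0:
            continue
        for name, cols in groups.items():
            incs = []
            for _ in range(n_repeats):
                Xp = Xv.copy()
                perm = rng.permutation(len(Xv))
                Xp[cols] = Xv[cols].to_numpy()[perm]
                mse = float(np.mean((member.regressor.predict(Xp) - yv) ** 2))
                incs.append(100.0 * (mse - base_mse) / base_mse)
            per_member[name].append(float(np.mean(incs)))
    rows = {
        name: {
            "mean": float(np.mean(v)) if v else float("nan"),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        }
        for name, v in per_member.items()
    }
    return pd.DataFrame(rows).T.sort_values("mean", ascending=False)


def predict_grid(model: EnsembleModel, predictors: pd.DataFrame) -> np.ndarray:
    """Per-member predictions on a predictor table.

    Returns an ``(n_members, n_cells)`` array, clipped at zero (tree
    averaging of non-negative responses cannot go negative, but the contract
    is enforced). Members are applied identically to every period's table, so
    temporal differences reflect predictor change only.
    """
    design = _encode(predictors, model.forest_type_categories)
    out = np.empty((model.n_members, len(design)))
    for i, member in enumerate(model.members):
        out[i] = member.regressor.predict(design)
    return np.clip(out, 0.0, None)


def predict_components(
    models: Mapping[str, EnsembleModel], predictors: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Per-member grids for the fitted components plus the derived pools."""
    preds = {comp: predict_grid(m, predictors) for comp, m in models.items()}
    for pool, parts in DERIVED.items():
        if all(p in preds for p in parts):
            preds[pool] = sum(preds[p] for p in parts)
    return preds


def _pixel_summary(member_preds: Mapping[str, np.ndarray], cells: pd.DataFrame) -> pd.DataFrame:
    out = cells[["cell", "lat", "lon"]].copy()
    for comp, arr in member_preds.items():
        out[f"{comp}_mean"] = arr.mean(axis=0)
        out[f"{comp}_sd"] = arr.std(axis=0, ddof=0)
    return out


def aggregate(
    member_preds: Mapping[str, np.ndarray],
    cells: pd.DataFrame,
    inventory_areas: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Regional and national density and stock summaries with Monte-Carlo SDs.

    ``cells`` is a per-forest-cell table (from :meth:`PredictorGrid.frame`)
    with province, forest_type, region and ``area_ha`` columns; every cell
    must carry a region. For each ensemble member, the (province, type) mean
    cell density (cell-area weighted) is integrated over the inventory area
    of that stratum — the raster supplies the spatial pattern, the inventory
    the areas — then summed to regions and the nation; means and SDs are
    taken over members afterwards.

    ``inventory_areas`` columns: province, forest_type, area_mha. When
    omitted, raster cell areas serve as the areas.

    Returns one row per (region + "national") x component with columns
    density_mean/density_sd (Mg C ha^-1), stock_mean/stock_sd (Tg C), and
    area_mha.
    """
    if cells["region"].isna().any():
        raise ValueError("every forest cell must be assigned a region")
    cells = cells.reset_index(drop=True)
    strata = cells.groupby(["province", "forest_type"], sort=True)

    stratum_rows = []
    for (prov, ftype), idx in strata.indices.items():
        w = cells["area_ha"].to_numpy()[idx]
        stratum_rows.append(
            {
                "province": prov,
                "forest_type": ftype,
                "region": cells["region"].iloc[idx[0]],
                "indices": idx,
                "weights": w / w.sum(),
                "cell_area_mha": w.sum() / 1e6,
            }
        )
    if inventory_areas is not None:
        amap = {
            (r.province, str(r.forest_type)): float(r.area_mha)
            for r in inventory_areas.itertuples(index=False)
        }
        for s in stratum_rows:
            s["area_mha"] = amap.get((s["province"], str(s["forest_type"])), 0.0)
    else:
        for s in stratum_rows:
            s["area_mha"] = s["cell_area_mha"]

    regions = sorted({s["region"] for s in stratum_rows})
    records = []
    for comp, arr in member_preds.items():
        # stratum density per member: cell-area-weighted mean, (n_members, n_strata)
        dens = np.column_stack([arr[:, s["indices"]] @ s["weights"] for s in stratum_rows])
        areas = np.array([s["area_mha"] for s in stratum_rows])
        stocks = dens * areas  # Tg C: Mg/ha x Mha = 1e6 Mg = 1 Tg
        region_of = np.array([s["region"] for s in stratum_rows])
        for region in regions + ["national"]:
            sel = slice(None) if region == "national" else region_of == region
            st = stocks[:, sel].sum(axis=1)
            area = areas[sel].sum()
            d = st / area if area > 0 else np.zeros_like(st)
            records.append(
                {
                    "region": region,
                    "component": comp,
                    "density_mean": float(d.mean()),
                    "density_sd": float(d.std(ddof=0)),
                    "stock_mean": float(st.mean()),
                    "stock_sd": float(st.std(ddof=0)),
                    "area_mha": float(area),
                }
            )
    return pd.DataFrame(records)


def partial_dependence_sign(
    model: EnsembleModel,
    X: pd.DataFrame,
    predictor: str,
    quantile_range: tuple[float, float] = (0.10, 0.90),
    n_points: int = 9,
) -> float:
    """Sign of the ensemble's partial dependence on one numeric predictor.

    The predictor is swept over the central ``quantile_range`` of its
    observed values while the other columns stay at their observed rows
    (the standard partial-dependence average); returns the sign of the
    least-squares slope of the mean curve (+1, -1, or 0).
    """
    if predictor not in NUMERIC_PREDICTORS:
        raise ValueError(f"partial dependence defined for {NUMERIC_PREDICTORS}")
    lo, hi = np.quantile(X[predictor].astype(float), quantile_range)
    grid_vals = np.linspace(lo, hi, n_points)
    curve = np.empty(n_points)
    for i, v in enumerate(grid_vals):
        Xv = X.copy()
        Xv[predictor] = v
        curve[i] = predict_grid(model, Xv).mean()
    slope = np.polyfit(grid_vals, curve, 1)[0] if hi > lo else 0.0
    return float(np.sign(slope))
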