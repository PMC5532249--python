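"""Paper-style summary tables from pipeline outputs.

Two layouts dominate DOM carbon reporting: a site-level table of component
carbon densities by forest type with ANOVA letters (what a "Table 1" looks
like), and a period table of national density and stock per component (a
"Table 2"). Both are emitted as tidy CSV-ready frames.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from domcarbon.trends import group_compare

__all__ = ["site_table_summary", "component_by_group_table", "period_stock_table"]

#: additive pools reported site-level, in display order
_SITE_COMPONENTS = (
    "dom", "woody_debris", "fwd", "cwd", "snags", "logs", "litter",
    "agb", "soil", "ecosystem",
)


def site_table_summary(sites: pd.DataFrame) -> dict[str, float]:
    """Headline site-table statistics.

    Returns the across-site mean and SD of DOM carbon density (Mg C ha^-1)
    and the mean percentage share of DOM in total ecosystem carbon. The
    input needs the per-site density columns (``dom``, ``ecosystem``; the
    derived columns are rebuilt from the bases when absent).
    """
    df = sites.copy()
    if "dom" not in df.columns:
        df["dom"] = df[["fwd", "snags", "logs", "litter"]].sum(axis=1)
    if "ecosystem" not in df.columns:
        df["ecosystem"] = df["dom"] + df["agb"] + df["soil"]
    share = 100.0 * df["dom"] / df["ecosystem"]
    return {
        "n_sites": int(len(df)),
        "dom_density_mean": float(df["dom"].mean()),
        "dom_density_sd": float(df["dom"].std(ddof=1)),
        "dom_share_of_ecosystem_pct": float(share.mean()),
        "dom_share_of_ecosystem_pct_sd": float(share.std(ddof=1)),
    }


def component_by_group_table(
    sites: pd.DataFrame,
    group_col: str = "forest_type",
    components: Sequence[str] = _SITE_COMPONENTS,
) -> pd.DataFrame:
    """Component x group means +/- SD with ANOVA significance letters.

    One row per component, one column block per group: ``mean``, ``sd`` and
    the Tukey-HSD compact letters (groups sharing no letter differ at
    p < 0.05). Components missing from the table are rebuilt from the base
    pools where possible.
    """
    df = sites.copy()
    derived = {
        "cwd": ("snags", "logs"),
        "woody_debris": ("fwd", "snags", "logs"),
        "dom": ("fwd", "snags", "logs", "litter"),
    }
    for pool, parts in derived.items():
        if pool not in df.columns and all(p in df.columns for p in parts):
            df[pool] = df[list(parts)].sum(axis=1)
    if "ecosystem" not in df.columns and {"dom", "agb", "soil"} <= set(df.columns):
        df["ecosystem"] = df["dom"] + df["agb"] + df["soil"]

    rows = []
    for comp in components:
        if comp not in df.columns:
            continue
        cmp_table = group_compare(df[comp], df[group_col])
        row: dict[str, object] = {"component": comp,
                                  "F": cmp_table.attrs["F"], "p": cmp_table.attrs["p"]}
        for grp, r in cmp_table.iterrows():
            row[f"{grp}_mean"] = r["mean"]
            row[f"{grp}_sd"] = r["sd"]
            row[f"{grp}_letters"] = r["letters"]
        rows.append(row)
    return pd.DataFrame(rows)


def period_stock_table(summaries: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """National density and stock per component across inventory periods.

    ``summaries`` maps period -> the regional summary frame from
    :func:`domcarbon.upscaling.aggregate`; only the ``national`` rows are
    used. Output: one row per (component, period) with density and stock
    means and SDs plus the forest area.
    """
    rows = []
    for period, summary in summaries.items():
        nat = summary[summary["region"] == "national"]
        for r in nat.itertuples(index=False):
            rows.append(
                {
                    "component": r.component,
                    "period": period,
                    "density_mean": r.density_mean,
                    "density_sd": r.density_sd,
                    "stock_mean": r.stock_mean,
                    "stock_sd": r.stock_sd,
                    "area_mha": r.area_mha,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["component", "period"]).reset_index(drop=True)
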