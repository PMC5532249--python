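"""Change rates, sink partitioning, and reporting statistics.

The five inventory windows are represented by their midpoint years (1986,
1991, 1996, 2001, 2006). The change rate of a density or stock series is the
slope of an ordinary-least-squares fit against those years; its uncertainty
is the standard error of the slope. Component shares of a total change and
the combined ecosystem sink are simple arithmetic on those slopes with
root-sum-square propagation of independent SDs.

Group comparisons (carbon density across forest types or stand origins) use
one-way ANOVA with Tukey-HSD pairwise tests compressed into the usual
compact letter display.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PERIOD_MIDPOINT_YEARS",
    "TrendEstimate",
    "ols_trend",
    "change_partition",
    "sink_summary",
    "group_compare",
    "bivariate_relations",
]

PERIOD_MIDPOINT_YEARS = (1986, 1991, 1996, 2001, 2006)


@dataclass(frozen=True)
class TrendEstimate:
    """Slope (units per year) with its standard error, plus fit diagnostics.

    ``r_squared`` and ``p_value`` are NaN-flagged for a constant series,
    where the fit is exact but the correlation is undefined.
    """

    slope: float
    slope_sd: float
    intercept: float
    r_squared: float
    p_value: float

    @property
    def percent_per_year(self) -> float:
        """Rate relative to the series mean implied by the fit, % per year."""
        return float("nan") if self._mean == 0 else 100.0 * self.slope / self._mean

    _mean: float = float("nan")


def ols_trend(values: Sequence[float], years: Sequence[float] | None = None) -> TrendEstimate:
    """OLS change rate of a period series.

    ``years`` defaults to the five inventory midpoints. The slope standard
    error is the classical OLS one; a constant series returns slope 0 with
    undefined (NaN) R^2 and p.
    """
    values = np.asarray(values, dtype=float)
    if years is None:
        if len(values) != len(PERIOD_MIDPOINT_YEARS):
            raise ValueError(
                "years must be given when the series is not the five inventory periods"
            )
        years = np.asarray(PERIOD_MIDPOINT_YEARS, dtype=float)
    else:
        years = np.asarray(years, dtype=float)
    if len(values) < 3:
        raise ValueError("a trend needs at least 3 points")
    if len(values) != len(years):
        raise ValueError("values and years lengths differ")
    if np.ptp(values) == 0:
        return TrendEstimate(0.0, 0.0, float(values[0]), float("nan"),
                             float("nan"), _mean=float(values.mean()))
    res = stats.linregress(years, values)
    return TrendEstimate(
        slope=float(res.slope),
        slope_sd=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        _mean=float(values.mean()),
    )


def change_partition(component_slopes: Mapping[str, float], total_slope: float) -> dict[str, float]:
    """Percent share of each component's slope in the total change rate.

    Shares of an exhaustive partition sum to 100 within rounding; a zero
    total leaves every share NaN-flagged.
    """
    if total_slope == 0:
        return {k: float("nan") for k in component_slopes}
    return {k: 100.0 * v / total_slope for k, v in component_slopes.items()}


def sink_summary(
    rates: Sequence[float], sds: Sequence[float] | None = None
) -> tuple[float, float]:
    """Combined carbon sink: sum of component rates, root-sum-square SD.

    The components (e.g. biomass, soil, and DOM sinks, Tg C per year) are
    treated as independent.
    """
    rates = np.asarray(rates, dtype=float)
    total = float(rates.sum())
    if sds is None:
        return total, 0.0
    sds = np.asarray(sds, dtype=float)
    return total, float(np.sqrt(np.sum(sds**2)))


def _compact_letters(order: list[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display over groups sorted by descending mean.

    Each maximal run of consecutive groups with no significant internal pair
    shares a letter; letters are assigned 'a', 'b', ... down the ranking.
    """
    n = len(order)

    def compatible(i: int, j: int) -> bool:
        return not any(
            tuple(sorted((order[a], order[b]))) in distinct
            for a, b in itertools.combinations(range(i, j + 1), 2)
        )

    runs = []
    for i in range(n):
        j = i
        while j + 1 < n and compatible(i, j + 1):
            j += 1
        runs.append((i, j))
    maximal = [
        r for r in runs
        if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)
    ]
    letters: dict[str, str] = {g: "" for g in order}
    for letter, (a, b) in zip("abcdefghijklmnopqrstuvwxyz", maximal):
        for k in range(a, b + 1):
            letters[order[k]] += letter
    return letters


def group_compare(values: Sequence[float], groups: Sequence[str], alpha: float = 0.05) -> pd.DataFrame:
    """Group means +/- SD with one-way ANOVA and Tukey-HSD letters.

    Groups sharing no letter differ at ``p < alpha``. Letters are assigned
    deterministically, 'a' starting at the largest mean. The returned frame
    (indexed by group, descending mean) carries the overall F and p in
    ``attrs['F']`` / ``attrs['p']``.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    counts = df.groupby("group").size()
    if len(counts) < 2:
        raise ValueError("group comparison needs at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 values")
    samples = [g["value"].to_numpy() for _, g in df.groupby("group")]
    F, p = stats.f_oneway(*samples)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tukey = pairwise_tukeyhsd(df["value"], df["group"], alpha=alpha)
    pairs = list(itertools.combinations(tukey.groupsunique, 2))
    distinct = {
        tuple(sorted((str(a), str(b))))
        for (a, b), rej in zip(pairs, tukey.reject)
        if rej
    }
    means = df.groupby("group")["value"].agg(["mean", "std", "count"])
    order = list(means.sort_values("mean", ascending=False).index)
    letters = _compact_letters(order, distinct)
    out = means.loc[order].rename(columns={"mean": "mean", "std": "sd", "count": "n"})
    out["letters"] = [letters[g] for g in order]
    out.attrs["F"] = float(F)
    out.attrs["p"] = float(p)
    return out


def bivariate_relations(
    sites: pd.DataFrame,
    components: Sequence[str],
    factors: Sequence[str],
) -> pd.DataFrame:
    """Simple linear regressions of each component on each site factor.

    Returns one row per (component, factor) with slope, r, p, n and the
    slope's sign — the sign table summarizing how woody-debris pools rise
    and litter falls along biomass, age and climate gradients. Pairs with
    fewer than 3 complete observations are flagged missing (NaN row).
    """
    rows = []
    for comp in components:
        for fac in factors:
            sub = sites[[fac, comp]].dropna()
            if len(sub) < 3:
                rows.append(
                    {"component": comp, "factor": fac, "slope": np.nan, "r": np.nan,
                     "p": np.nan, "n": len(sub), "sign": 0}
                )
                continue
            res = stats.linregress(sub[fac], sub[comp])
            rows.append(
                {
                    "component": comp,
                    "factor": fac,
                    "slope": float(res.slope),
                    "r": float(res.rvalue),
                    "p": float(res.pvalue),
                    "n": len(sub),
                    "sign": int(np.sign(res.slope)),
                }
            )
    return pd.DataFrame(rows)
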