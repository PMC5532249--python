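"""Change rates, partitioning, group comparisons, bivariate relations."""

import numpy as np
import pandas as pd
import pytest

from domcarbon.trends import (
    PERIOD_MIDPOINT_YEARS,
    bivariate_relations,
    change_partition,
    group_compare,
    ols_trend,
    sink_summary,
)


def _normal_equations(years, values):
    """Independent OLS oracle: solve X'X beta = X'y and the slope SE."""
    X = np.column_stack([np.ones(len(years)), years])
    beta = np.linalg.solve(X.T @ X, X.T @ values)
    resid = values - X @ beta
    dof = len(years) - 2
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta[1], np.sqrt(cov[1, 1]), beta[0]


class TestOlsTrend:
    def test_exact_line(self):
        years = np.asarray(PERIOD_MIDPOINT_YEARS, dtype=float)
        values = 5 + 2 * (years - 1986)
        t = ols_trend(values)
        assert t.slope == pytest.approx(2.0)
        assert t.r_squared == pytest.approx(1.0)
        assert t.p_value < 1e-8

    def test_constant_series_flagged(self):
        t = ols_trend([3.0] * 5)
        assert t.slope == 0.0
        assert np.isnan(t.r_squared) and np.isnan(t.p_value)

    def test_matches_normal_equations_to_1e10(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            values = rng.normal(10, 2, 5)
            t = ols_trend(values)
            slope, se, intercept = _normal_equations(
                np.asarray(PERIOD_MIDPOINT_YEARS, float), values
            )
            assert t.slope == pytest.approx(slope, abs=1e-10)
            assert t.slope_sd == pytest.approx(se, abs=1e-10)
            assert t.intercept == pytest.approx(intercept, abs=1e-8)

    def test_linearity_of_slopes(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(5, 1, 5), rng.normal(3, 1, 5)
        assert ols_trend(a + b).slope == pytest.approx(
            ols_trend(a).slope + ols_trend(b).slope, abs=1e-10
        )

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ols_trend([1.0, 2.0], years=[2000, 2001])


class TestChangePartition:
    def test_documented_split(self):
        shares = change_partition({"woody_debris": 3.9, "litter": 2.8}, 6.7)
        assert shares["woody_debris"] == pytest.approx(58.2, abs=0.05)
        assert shares["litter"] == pytest.approx(41.8, abs=0.05)

    def test_equal_components(self):
        shares = change_partition({"a": 1.0, "b": 1.0}, 2.0)
        assert shares == {"a": 50.0, "b": 50.0}

    def test_three_component_arithmetic(self):
        shares = change_partition({"a": 1.0, "b": 2.0, "c": 3.0}, 6.0)
        assert shares["a"] == pytest.approx(100 / 6)
        assert shares["b"] == pytest.approx(100 / 3)
        assert shares["c"] == pytest.approx(50.0)
        assert sum(shares.values()) == pytest.approx(100.0, abs=0.1)

    def test_zero_total_flagged(self):
        shares = change_partition({"a": 1.0}, 0.0)
        assert np.isnan(shares["a"])


class TestSinkSummary:
    def test_component_sum(self):
        total, sd = sink_summary([70.9, 67.2, 6.7], [0.0, 0.0, 2.2])
        assert total == pytest.approx(144.8)
        assert sd == pytest.approx(2.2)

    def test_zero_and_pythagorean_sd(self):
        assert sink_summary([0.0, 0.0]) == (0.0, 0.0)
        _, sd = sink_summary([1.0, 1.0], [3.0, 4.0])
        assert sd == pytest.approx(5.0)


class TestGroupCompare:
    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 1, 60)
        groups = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
        out = group_compare(vals, groups)
        assert len(set(out["letters"])) == 1

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(10, 0.1, 30), rng.normal(1, 0.1, 30)])
        out = group_compare(vals, ["hi"] * 30 + ["lo"] * 30)
        assert out.loc["hi", "letters"] == "a"
        assert out.loc["lo", "letters"] == "b"
        assert out.attrs["p"] < 1e-3

    def test_f_statistic_matches_mean_square_ratio(self):
        rng = np.random.default_rng(2)
        samples = [rng.normal(m, 1, 15) for m in (3.0, 4.0, 5.5)]
        vals = np.concatenate(samples)
        groups = sum([[g] * 15 for g in "ABC"], [])
        out = group_compare(vals, groups)
        # brute-force one-way ANOVA
        grand = vals.mean()
        ss_between = sum(15 * (s.mean() - grand) ** 2 for s in samples)
        ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
        F = (ss_between / 2) / (ss_within / (45 - 3))
        assert out.attrs["F"] == pytest.approx(F, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], ["A", "A"])


class TestBivariateRelations:
    def test_exact_proportionality(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2 * df["x"]
        out = bivariate_relations(df, ["y"], ["x"]).iloc[0]
        assert out["slope"] == pytest.approx(2.0)
        assert out["r"] == pytest.approx(1.0)
        assert out["sign"] == 1

    def test_world_sign_structure_recovered(self):
        # woody-debris pools rise with AGB; litter falls with temperature.
        # The full-size world is needed: a truncated climate gradient hides
        # the litter signal behind covariate confounding.
        from domcarbon.synth import WorldConfig, make_world

        sites = make_world(WorldConfig(seed=7)).sites
        df = sites.rename(
            columns={f"true_{c}": c for c in ("fwd", "snags", "logs", "litter")}
        )
        df["woody_debris"] = df[["fwd", "snags", "logs"]].sum(axis=1)
        out = bivariate_relations(
            df, ["woody_debris", "litter"], ["true_agb", "mat", "map"]
        ).set_index(["component", "factor"])
        assert out.loc[("woody_debris", "true_agb"), "sign"] == 1
        assert out.loc[("woody_debris", "mat"), "sign"] == 1
        assert out.loc[("litter", "mat"), "sign"] == -1
        assert out.loc[("litter", "map"), "sign"] == -1

    def test_permuted_response_mostly_insignificant(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, 40)
        y = 3 * x + rng.normal(0, 0.1, 40)
        insignificant = 0
        for _ in range(20):
            df = pd.DataFrame({"x": x, "y": rng.permutation(y)})
            out = bivariate_relations(df, ["y"], ["x"]).iloc[0]
            insignificant += out["p"] > 0.05
        assert insignificant >= 18

    def test_insufficient_pairs_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, np.nan]})
        out = bivariate_relations(df, ["y"], ["x"]).iloc[0]
        assert np.isnan(out["slope"]) and out["n"] < 3
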