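"""Stage-1 accounting: volumes, masses, densities, ages, aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domcarbon.fieldplots import (
    CarbonConcentrationTable,
    DeadWoodPiece,
    LitterSample,
    PlotSurvey,
    SoilLayer,
    TreeRecord,
    WoodDensityTable,
    cylinder_volume,
    log_volume,
    piece_dry_mass,
    plot_component_density,
    site_aggregate,
    soil_profile_carbon,
    stand_age,
    tree_agb,
)

DENSITIES = WoodDensityTable(
    {("default", "I"): 450.0, ("default", "II"): 400.0}
)


@pytest.mark.parametrize(
    "d, length, expected",
    [
        (0.0, 7.0, 0.0),
        (2.0 / math.sqrt(math.pi), 1.0, 1.0),
        (0.2, 10.0, 0.31416),
    ],
)
def test_cylinder_volume_matches_hand_evaluation(d, length, expected):
    assert cylinder_volume(d, length) == pytest.approx(expected, abs=5e-6)


def test_cylinder_volume_rejects_negative_inputs():
    with pytest.raises(ValueError):
        cylinder_volume(-0.1, 1.0)
    with pytest.raises(ValueError):
        cylinder_volume(0.1, -1.0)


@pytest.mark.parametrize(
    "d_mid, d_ends, length, expected",
    [
        (0.3, (0.3, 0.3), 8.0, 0.56549),   # equals cylinder_volume(0.3, 8)
        (0.4, (0.2, 0.3), 6.0, 0.42412),   # mean diameter 0.3
        (0.3, (0.3, 0.3), 0.0, 0.0),
    ],
)
def test_log_volume_uses_mean_of_three_diameters(d_mid, d_ends, length, expected):
    piece = DeadWoodPiece(
        kind="log", diameter_mid=d_mid, diameter_ends=d_ends,
        length=length, decay_class="I",
    )
    assert log_volume(piece) == pytest.approx(expected, abs=5e-6)


def test_log_volume_requires_end_diameters():
    piece = DeadWoodPiece(kind="snag", diameter_mid=0.3, length=8, decay_class="I")
    with pytest.raises(ValueError):
        log_volume(piece)


class TestPieceDryMass:
    def test_measured_mass_passes_through(self):
        piece = DeadWoodPiece(
            kind="log", diameter_mid=0.3, diameter_ends=(0.3, 0.3), length=8,
            measured_dry_mass=12.5,
        )
        assert piece_dry_mass(piece, DENSITIES) == 12.5

    def test_volume_times_density(self):
        # volume 0.5 m^3 log: choose length so the mean-diameter cylinder is 0.5
        d = 0.3
        length = 0.5 * 4 / (math.pi * d * d)
        piece = DeadWoodPiece(
            kind="log", diameter_mid=d, diameter_ends=(d, d), length=length,
            decay_class="II",
        )
        assert piece_dry_mass(piece, DENSITIES) == pytest.approx(0.5 * 400.0)

    def test_snag_falls_back_to_sound_wood_classes(self):
        table = WoodDensityTable({("oak", "I"): 450.0})
        snag = DeadWoodPiece(
            kind="snag", diameter_mid=0.2, length=10, decay_class="III",
            species="oak",
        )
        vol = cylinder_volume(0.2, 10)
        assert piece_dry_mass(snag, table) == pytest.approx(vol * 450.0)

    def test_missing_entry_names_species_and_class(self):
        log = DeadWoodPiece(
            kind="log", diameter_mid=0.3, diameter_ends=(0.3, 0.3), length=8,
            decay_class="IV", species="yew",
        )
        with pytest.raises(KeyError, match="yew.*IV"):
            piece_dry_mass(log, DENSITIES)


class TestPlotComponentDensity:
    def test_empty_wood_component_is_zero(self):
        assert plot_component_density(PlotSurvey(), "snags", DENSITIES) == 0.0

    def test_single_log_example(self):
        # 0.56549 m^3 x 400 kg/m^3 x 0.5 C = 113.1 kg C on 400 m^2
        piece = DeadWoodPiece(
            kind="log", diameter_mid=0.3, diameter_ends=(0.3, 0.3), length=8,
            decay_class="II",
        )
        plot = PlotSurvey(pieces=[piece])
        got = plot_component_density(plot, "logs", DENSITIES)
        assert got == pytest.approx(2.827, abs=1e-3)

    def test_litter_subplot_scaling(self):
        # 6 kg dry mass x 0.5 over 20 m^2 -> 1.5 Mg C ha^-1
        plot = PlotSurvey(litter=[LitterSample(dry_mass=1.2) for _ in range(5)])
        assert plot_component_density(plot, "litter") == pytest.approx(1.5)

    def test_empty_litter_is_an_error(self):
        with pytest.raises(ValueError):
            plot_component_density(PlotSurvey(), "litter")

    def test_matches_piece_by_piece_hand_summation(self):
        rng = np.random.default_rng(11)
        pieces = []
        for _ in range(8):
            d = rng.uniform(0.12, 0.5)
            pieces.append(
                DeadWoodPiece(
                    kind="snag", diameter_mid=d, length=rng.uniform(2, 15),
                    decay_class=rng.choice(["I", "II"]),
                )
            )
        plot = PlotSurvey(pieces=pieces, plot_area=400.0)
        # independent oracle: explicit loop over the definitions
        total_kg_c = 0.0
        for p in pieces:
            vol = math.pi * p.diameter_mid**2 * p.length / 4
            rho = {"I": 450.0, "II": 400.0}[p.decay_class.value]
            total_kg_c += vol * rho * 0.5
        expected = total_kg_c / 1000 / 400 * 1e4
        got = plot_component_density(plot, "snags", DENSITIES)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_halving_plot_area_doubles_density(self):
        piece = DeadWoodPiece(
            kind="snag", diameter_mid=0.2, length=10, decay_class="I",
        )
        full = plot_component_density(
            PlotSurvey(pieces=[piece], plot_area=400), "snags", DENSITIES
        )
        half = plot_component_density(
            PlotSurvey(pieces=[piece], plot_area=200), "snags", DENSITIES
        )
        assert half == pytest.approx(2 * full)


def test_tree_agb_power_law():
    allometry = {"default": [(0.05, 1.0)]}
    tree = TreeRecord(dbh=20, height=15)
    assert tree_agb(tree, allometry) == pytest.approx(0.05 * 20**2 * 15)
    doubled = {"default": [(0.10, 1.0)]}
    assert tree_agb(tree, doubled) == pytest.approx(2 * tree_agb(tree, allometry))
    with pytest.raises(KeyError):
        tree_agb(TreeRecord(dbh=20, height=15, species="x"), {"y": [(1, 1)]})


class TestSoilProfile:
    def test_unit_conversion(self):
        # 10 cm x 1.0 g/cm^3 x 2% C -> 20 Mg C ha^-1
        with pytest.warns(UserWarning):
            got = soil_profile_carbon([SoilLayer(0, 10, 1.0, 0.02)])
        assert got == pytest.approx(20.0)

    def test_additivity_of_layers(self):
        layers = [SoilLayer(0, 10, 1.1, 0.03), SoilLayer(10, 20, 1.1, 0.03)]
        with pytest.warns(UserWarning):
            two = soil_profile_carbon(layers)
        with pytest.warns(UserWarning):
            one = soil_profile_carbon(layers[:1])
        assert two == pytest.approx(2 * one)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            soil_profile_carbon(
                [SoilLayer(0, 15, 1.0, 0.02), SoilLayer(10, 20, 1.0, 0.02)]
            )

    def test_zero_concentration_gives_zero(self):
        layers = [
            SoilLayer(t, b, 1.2, 0.0)
            for t, b in ((0, 10), (10, 20), (20, 30), (30, 50), (50, 70), (70, 100))
        ]
        assert soil_profile_carbon(layers) == 0.0


class TestStandAge:
    def test_fifth_largest_by_dbh(self):
        ages = [120, 100, 90, 80, 75, 60, 50]
        trees = [
            TreeRecord(dbh=50 - i, height=20, age=a) for i, a in enumerate(ages)
        ]
        assert stand_age(trees) == 75

    def test_exactly_five_trees(self):
        trees = [TreeRecord(dbh=10 + i, height=15, age=40) for i in range(5)]
        assert stand_age(trees) == 40

    def test_fewer_than_five_uses_smallest_aged(self):
        trees = [
            TreeRecord(dbh=30, height=20, age=60),
            TreeRecord(dbh=25, height=18, age=55),
            TreeRecord(dbh=20, height=15, age=50),
        ]
        assert stand_age(trees) == 50

    def test_no_aged_trees_is_an_error(self):
        with pytest.raises(ValueError):
            stand_age([TreeRecord(dbh=20, height=15)])


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.tuples(
            *[st.floats(0, 20) for _ in range(6)]  # fwd,snags,logs,litter,agb,soil
        ),
        min_size=1,
        max_size=4,
    )
)
def test_site_aggregate_additivity_and_mean(plot_values):
    keys = ("fwd", "snags", "logs", "litter", "agb", "soil")
    plots = [dict(zip(keys, vals)) for vals in plot_values]
    site = site_aggregate(plots, site="s")
    for key in keys:
        expected = sum(p[key] for p in plots) / len(plots)
        assert getattr(site, key) == pytest.approx(expected, rel=1e-12, abs=1e-12)
    assert site.cwd == pytest.approx(site.snags + site.logs, rel=1e-9, abs=1e-12)
    assert site.woody_debris == pytest.approx(site.fwd + site.cwd, rel=1e-9, abs=1e-12)
    assert site.dom == pytest.approx(site.woody_debris + site.litter, rel=1e-9, abs=1e-12)
    assert site.ecosystem == pytest.approx(
        site.agb + site.soil + site.dom, rel=1e-9, abs=1e-12
    )


def test_piece_diameter_class_boundaries_enforced():
    with pytest.raises(ValueError):
        DeadWoodPiece(kind="fwd", diameter_mid=0.15, length=1, decay_class="I")
    with pytest.raises(ValueError):
        DeadWoodPiece(kind="log", diameter_mid=0.05, diameter_ends=(0.05, 0.05),
                      length=1, decay_class="I")
    with pytest.raises(ValueError):  # no decay class and no measured mass
        DeadWoodPiece(kind="log", diameter_mid=0.3, diameter_ends=(0.3, 0.3), length=1)
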