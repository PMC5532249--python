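"""Plot-scale carbon accounting: from raw field measurements to site carbon densities.

Dead organic matter (DOM) on the forest floor is split into three pools by
piece diameter at the widest section: coarse woody debris (CWD, >= 10 cm;
standing *snags* plus fallen *logs*), fine woody debris (FWD, 2-10 cm), and
litter (< 2 cm woody material plus leaf litter and other dead plant
material). Pieces too large to weigh in the field are measured (length and
diameters), converted to volume with the cylinder formula, and to oven-dry
mass with species- and decay-class-specific density ratios. Litter is
collected on small subplots and weighed after drying. Dry mass becomes
carbon through component/decay-class carbon concentrations (default 0.5).

All masses are kilograms, lengths and diameters metres, areas square metres;
carbon densities are reported in Mg C ha^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PieceKind",
    "DecayClass",
    "DeadWoodPiece",
    "WoodDensityTable",
    "CarbonConcentrationTable",
    "LitterSample",
    "SoilLayer",
    "TreeRecord",
    "PlotSurvey",
    "SiteCarbon",
    "WOOD_COMPONENTS",
    "COMPONENT_COLUMNS",
    "cylinder_volume",
    "log_volume",
    "snag_volume",
    "piece_volume",
    "piece_dry_mass",
    "plot_component_density",
    "tree_agb",
    "soil_profile_carbon",
    "stand_age",
    "plot_carbon",
    "site_aggregate",
    "sites_to_frame",
]

#: diameter bounds (m) separating litter / FWD / CWD
FWD_MIN_DIAMETER = 0.02
CWD_MIN_DIAMETER = 0.10

#: square metres per hectare, kilograms per megagram
_M2_PER_HA = 1.0e4
_KG_PER_MG = 1.0e3

WOOD_COMPONENTS = ("fwd", "snags", "logs")
#: densities carried by a SiteCarbon record, in additive order
COMPONENT_COLUMNS = (
    "fwd", "snags", "logs", "cwd", "woody_debris", "litter", "dom",
    "agb", "soil", "ecosystem",
)


class PieceKind(str, Enum):
    """What a piece of dead wood is: standing snag, fallen log, or fine debris."""

    SNAG = "snag"
    LOG = "log"
    FWD = "fwd"


class DecayClass(str, Enum):
    """Ordinal decay stage of dead wood, intact (I) to rotten heartwood (IV)."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


@dataclass(frozen=True)
class DeadWoodPiece:
    """One measured piece of dead wood.

    Parameters
    ----------
    kind
        ``snag`` (standing), ``log`` (fallen) or ``fwd`` (fine woody debris).
    diameter_mid
        Middle diameter for logs, DBH for snags, widest diameter for FWD (m).
    length
        Log length, snag height, or FWD piece length (m).
    diameter_ends
        Both end diameters (m), logs only.
    decay_class
        Required whenever ``measured_dry_mass`` is absent.
    measured_dry_mass
        Oven-dry mass (kg) for pieces weighed directly; when present it
        always bypasses volume-based estimation.
    """

    kind: PieceKind
    diameter_mid: float
    length: float
    diameter_ends: tuple[float, float] | None = None
    decay_class: DecayClass | None = None
    species: str = "unknown"
    measured_dry_mass: float | None = None

    def __post_init__(self) -> None:
        kind = PieceKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.decay_class is not None:
            object.__setattr__(self, "decay_class", DecayClass(self.decay_class))
        if self.diameter_mid < 0 or self.length < 0:
            raise ValueError("diameters and lengths must be non-negative")
        if self.diameter_ends is not None:
            if len(self.diameter_ends) != 2 or any(d < 0 for d in self.diameter_ends):
                raise ValueError("diameter_ends must be two non-negative values")
        if self.measured_dry_mass is not None and self.measured_dry_mass < 0:
            raise ValueError("measured_dry_mass must be non-negative")
        if self.measured_dry_mass is None and self.decay_class is None:
            raise ValueError(
                "decay_class is required when measured_dry_mass is absent"
            )
        dmax = self.max_diameter
        if kind is PieceKind.FWD and not (FWD_MIN_DIAMETER <= dmax < CWD_MIN_DIAMETER):
            raise ValueError(
                f"FWD pieces must have max diameter in [{FWD_MIN_DIAMETER}, "
                f"{CWD_MIN_DIAMETER}) m, got {dmax}"
            )
        if kind in (PieceKind.SNAG, PieceKind.LOG) and dmax < CWD_MIN_DIAMETER:
            raise ValueError(
                f"snags/logs must have max diameter >= {CWD_MIN_DIAMETER} m, got {dmax}"
            )

    @property
    def max_diameter(self) -> float:
        ds = [self.diameter_mid]
        if self.diameter_ends is not None:
            ds.extend(self.diameter_ends)
        return max(ds)


@dataclass(frozen=True)
class WoodDensityTable:
    """Oven-dry mass / green volume ratios (kg m^-3) by (species, decay class).

    ``snag_fallback_classes`` lists the decay classes tried, in order, when a
    snag's own class has no entry for its species: by default class II then I
    (field practice extrapolates large-snag mass from the density of barely
    decayed fallen logs of the same species). A ``"default"`` species entry,
    if present, backs any species without its own entries.
    """

    entries: Mapping[tuple[str, DecayClass], float]
    snag_fallback_classes: tuple[DecayClass, ...] = (DecayClass.II, DecayClass.I)

    def __post_init__(self) -> None:
        norm = {
            (sp, DecayClass(dc)): float(v) for (sp, dc), v in self.entries.items()
        }
        if any(v <= 0 for v in norm.values()):
            raise ValueError("wood density ratios must be positive")
        object.__setattr__(self, "entries", norm)

    def lookup(self, species: str, decay_class: DecayClass, kind: PieceKind) -> float:
        decay_class = DecayClass(decay_class)
        for sp in (species, "default"):
            key = (sp, decay_class)
            if key in self.entries:
                return self.entries[key]
            if kind is PieceKind.SNAG:
                for fb in self.snag_fallback_classes:
                    if (sp, fb) in self.entries:
                        return self.entries[(sp, fb)]
        raise KeyError(
            f"no wood density entry for species={species!r}, "
            f"decay_class={decay_class.value}"
        )


@dataclass(frozen=True)
class CarbonConcentrationTable:
    """Carbon mass fraction per DOM component and decay class.

    Falls back to ``default`` (0.5) when a (component, class) pair is not
    tabulated; litter has no decay class and uses the ``litter`` entry.
    """

    by_component_class: Mapping[tuple[str, DecayClass], float] = field(
        default_factory=dict
    )
    litter: float = 0.5
    default: float = 0.5

    def __post_init__(self) -> None:
        norm = {
            (comp, DecayClass(dc)): float(v)
            for (comp, dc), v in self.by_component_class.items()
        }
        for v in list(norm.values()) + [self.litter, self.default]:
            if not (0.0 < v < 1.0):
                raise ValueError("carbon concentrations must lie in (0, 1)")
        object.__setattr__(self, "by_component_class", norm)

    def wood(self, component: str, decay_class: DecayClass | None) -> float:
        if decay_class is not None:
            key = (component, DecayClass(decay_class))
            if key in self.by_component_class:
                return self.by_component_class[key]
        return self.default


@dataclass(frozen=True)
class LitterSample:
    """One litter subplot: collected dry mass (kg) over ``subplot_area`` (m^2)."""

    dry_mass: float
    subplot_area: float = 4.0

    def __post_init__(self) -> None:
        if self.subplot_area <= 0:
            raise ValueError("subplot_area must be positive")
        if self.dry_mass < 0:
            raise ValueError("dry_mass must be non-negative")


@dataclass(frozen=True)
class SoilLayer:
    """One sampled soil depth increment.

    depth_top/depth_bottom in cm (standard breaks 0-10, 10-20, 20-30, 30-50,
    50-70, 70-100), bulk density in g cm^-3, carbon concentration as a mass
    fraction.
    """

    depth_top: float
    depth_bottom: float
    bulk_density: float
    c_concentration: float

    def __post_init__(self) -> None:
        if not (0 <= self.depth_top < self.depth_bottom <= 100):
            raise ValueError("soil layer must satisfy 0 <= top < bottom <= 100 cm")
        if self.bulk_density <= 0:
            raise ValueError("bulk_density must be positive")
        if self.c_concentration < 0:
            raise ValueError("c_concentration must be non-negative")


@dataclass(frozen=True)
class TreeRecord:
    """A live tree >= 5 cm DBH: dbh (cm), height (m), optional ring-count age."""

    dbh: float
    height: float
    species: str = "unknown"
    age: float | None = None

    def __post_init__(self) -> None:
        if self.dbh < 5:
            raise ValueError("trees below 5 cm DBH are not tallied")
        if self.height <= 0:
            raise ValueError("height must be positive")


@dataclass
class PlotSurvey:
    """All raw measurements of one plot (default 20 x 20 m = 400 m^2)."""

    pieces: list[DeadWoodPiece] = field(default_factory=list)
    litter: list[LitterSample] = field(default_factory=list)
    trees: list[TreeRecord] = field(default_factory=list)
    soil_profiles: list[list[SoilLayer]] = field(default_factory=list)
    plot_area: float = 400.0

    def __post_init__(self) -> None:
        if self.plot_area <= 0:
            raise ValueError("plot_area must be positive")


@dataclass
class SiteCarbon:
    """Per-site carbon densities (Mg C ha^-1) plus location and covariates.

    The derived pools satisfy, by construction:
    ``cwd = snags + logs``, ``woody_debris = fwd + cwd``,
    ``dom = woody_debris + litter``, ``ecosystem = agb + soil + dom``.
    """

    site: str
    lon: float = float("nan")
    lat: float = float("nan")
    elevation: float = float("nan")
    forest_type: str = ""
    origin: str = ""
    stand_age: float = float("nan")
    fwd: float = 0.0
    snags: float = 0.0
    logs: float = 0.0
    litter: float = 0.0
    agb: float = 0.0
    soil: float = 0.0
    mat: float = float("nan")
    map: float = float("nan")

    @property
    def cwd(self) -> float:
        return self.snags + self.logs

    @property
    def woody_debris(self) -> float:
        return self.fwd + self.cwd

    @property
    def dom(self) -> float:
        return self.woody_debris + self.litter

    @property
    def ecosystem(self) -> float:
        return self.agb + self.soil + self.dom


def cylinder_volume(d: float, length: float) -> float:
    """Volume (m^3) of a cylinder of diameter ``d`` and length ``length`` (m).

    ``V = pi * d^2 * L / 4`` — the standard approximation for snag and log
    volume from a single representative diameter.
    """
    if d < 0 or length < 0:
        raise ValueError("diameter and length must be non-negative")
    return math.pi * d * d * length / 4.0


def log_volume(piece: DeadWoodPiece) -> float:
    """Volume of a fallen log from its middle and both end diameters.

    The representative diameter is the arithmetic mean of the middle and the
    two end diameters; the volume is the cylinder of that diameter over the
    log's length.
    """
    if PieceKind(piece.kind) is not PieceKind.LOG:
        raise ValueError("log_volume applies to pieces of kind 'log'")
    if piece.diameter_ends is None:
        raise ValueError("log pieces need middle and both end diameters")
    d = (piece.diameter_mid + piece.diameter_ends[0] + piece.diameter_ends[1]) / 3.0
    return cylinder_volume(d, piece.length)


def snag_volume(piece: DeadWoodPiece) -> float:
    """Volume of a standing snag: cylinder of its DBH over its height."""
    if PieceKind(piece.kind) is not PieceKind.SNAG:
        raise ValueError("snag_volume applies to pieces of kind 'snag'")
    return cylinder_volume(piece.diameter_mid, piece.length)


def piece_volume(piece: DeadWoodPiece) -> float:
    """Volume of any dead-wood piece using the rule for its kind."""
    kind = PieceKind(piece.kind)
    if kind is PieceKind.LOG:
        return log_volume(piece)
    if kind is PieceKind.SNAG:
        return snag_volume(piece)
    return cylinder_volume(piece.diameter_mid, piece.length)


def piece_dry_mass(piece: DeadWoodPiece, densities: WoodDensityTable | None) -> float:
    """Oven-dry mass (kg) of a piece.

    Directly weighed pieces return their measured mass unchanged. Otherwise
    mass = volume x density ratio for the piece's (species, decay class),
    with the table's snag fallback when a snag's class is untabulated.
    """
    if piece.measured_dry_mass is not None:
        return piece.measured_dry_mass
    if densities is None:
        raise KeyError(
            "a WoodDensityTable is required to estimate unweighed pieces"
        )
    ratio = densities.lookup(piece.species, piece.decay_class, PieceKind(piece.kind))
    return piece_volume(piece) * ratio


def _component_pieces(plot: PlotSurvey, component: str) -> list[DeadWoodPiece]:
    kind = {"fwd": PieceKind.FWD, "snags": PieceKind.SNAG, "logs": PieceKind.LOG}[
        component
    ]
    return [p for p in plot.pieces if PieceKind(p.kind) is kind]


def plot_component_density(
    plot: PlotSurvey,
    component: str,
    densities: WoodDensityTable | None = None,
    concentrations: CarbonConcentrationTable | None = None,
) -> float:
    """Carbon density (Mg C ha^-1) of one DOM component on one plot.

    Wood components (``fwd``, ``snags``, ``logs``) sum piece carbon over the
    full plot area; ``litter`` sums subplot carbon over the summed subplot
    area. An empty wood component is simply 0; an empty litter subplot list
    is an error because litter was never censused.
    """
    if concentrations is None:
        concentrations = CarbonConcentrationTable()
    if component == "litter":
        if not plot.litter:
            raise ValueError("litter density requires at least one subplot")
        area = sum(s.subplot_area for s in plot.litter)
        carbon_kg = sum(s.dry_mass for s in plot.litter) * concentrations.litter
        return carbon_kg / _KG_PER_MG / area * _M2_PER_HA
    if component not in WOOD_COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    carbon_kg = 0.0
    for piece in _component_pieces(plot, component):
        conc = concentrations.wood(component, piece.decay_class)
        carbon_kg += piece_dry_mass(piece, densities) * conc
    return carbon_kg / _KG_PER_MG / plot.plot_area * _M2_PER_HA


def tree_agb(
    tree: TreeRecord,
    allometry: Mapping[str, Sequence[tuple[float, float]]],
) -> float:
    """Above-ground biomass (kg) of one tree from power-law allometry.

    ``allometry`` maps species (with an optional ``"default"`` set) to a list
    of per-component ``(a, b)`` pairs; each component (stem, branch, bark,
    leaf...) contributes ``a * (D^2 H)^b`` with D in cm and H in m, and the
    tree total is their sum.
    """
    params = allometry.get(tree.species) or allometry.get("default")
    if params is None:
        raise KeyError(f"no allometric parameters for species {tree.species!r}")
    x = tree.dbh * tree.dbh * tree.height
    return float(sum(a * x**b for a, b in params))


def soil_profile_carbon(layers: Iterable[SoilLayer]) -> float:
    """Soil organic carbon (Mg C ha^-1) of one profile, 0-100 cm.

    Each layer contributes thickness(cm) x bulk density(g cm^-3) x carbon
    fraction x 100 (the factor converting g cm^-2 to Mg ha^-1). Depth ranges
    not covered by any layer contribute zero and trigger a warning.
    """
    layers = sorted(layers, key=lambda l: l.depth_top)
    prev_bottom = 0.0
    covered = 0.0
    total = 0.0
    for layer in layers:
        if layer.depth_top < prev_bottom:
            raise ValueError(
                f"overlapping soil layers at {layer.depth_top}-{layer.depth_bottom} cm"
            )
        thickness = layer.depth_bottom - layer.depth_top
        covered += thickness
        total += thickness * layer.bulk_density * layer.c_concentration * 100.0
        prev_bottom = layer.depth_bottom
    if covered < 100.0 - 1e-9:
        warnings.warn(
            f"soil profile covers {covered:g} of 100 cm; missing depth "
            "contributes zero carbon",
            stacklevel=2,
        )
    return total


def stand_age(trees: Iterable[TreeRecord]) -> float:
    """Stand age (years) as the age of the fifth-largest tree by DBH.

    Tree ages are determined by ring counts on the ten largest-DBH trees of a
    site; the fifth-largest represents the stand. If fewer than five aged
    trees exist, the smallest-DBH aged tree is used.
    """
    aged = sorted(
        (t for t in trees if t.age is not None), key=lambda t: -t.dbh
    )
    if not aged:
        raise ValueError("stand age requires at least one aged tree")
    idx = 4 if len(aged) >= 5 else len(aged) - 1
    return float(aged[idx].age)


def plot_carbon(
    plot: PlotSurvey,
    densities: WoodDensityTable | None = None,
    concentrations: CarbonConcentrationTable | None = None,
    allometry: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    live_c_fraction: float = 0.5,
) -> dict[str, float]:
    """All component carbon densities (Mg C ha^-1) for one plot.

    Returns fwd/snags/logs/litter plus AGB (tree allometry x live-biomass
    carbon fraction, default 0.5) and soil (mean over the plot's profiles).
    """
    out = {
        comp: plot_component_density(plot, comp, densities, concentrations)
        for comp in WOOD_COMPONENTS
    }
    out["litter"] = (
        plot_component_density(plot, "litter", densities, concentrations)
        if plot.litter
        else 0.0
    )
    if allometry is not None and plot.trees:
        agb_kg = sum(tree_agb(t, allometry) for t in plot.trees)
        out["agb"] = agb_kg * live_c_fraction / _KG_PER_MG / plot.plot_area * _M2_PER_HA
    else:
        out["agb"] = 0.0
    if plot.soil_profiles:
        vals = [soil_profile_carbon(p) for p in plot.soil_profiles]
        out["soil"] = float(sum(vals) / len(vals))
    else:
        out["soil"] = 0.0
    return out


def site_aggregate(
    plot_densities: Sequence[Mapping[str, float]],
    site: str = "",
    **metadata: object,
) -> SiteCarbon:
    """Site carbon record as the arithmetic mean of its plots' densities.

    ``plot_densities`` are the dicts from :func:`plot_carbon` (typically
    three replicate plots). The derived pools (cwd, woody debris, dom,
    ecosystem) are recomputed from the averaged bases, so additivity holds
    exactly.
    """
    if not plot_densities:
        raise ValueError("site_aggregate needs at least one plot")
    n = len(plot_densities)
    means = {
        key: sum(p.get(key, 0.0) for p in plot_densities) / n
        for key in ("fwd", "snags", "logs", "litter", "agb", "soil")
    }
    return SiteCarbon(site=site, **means, **metadata)  # type: ignore[arg-type]


def sites_to_frame(sites: Iterable[SiteCarbon]):
    """Tidy per-site table (one row per site, ten density columns)."""
    import pandas as pd

    rows = []
    for s in sites:
        row = {
            "site": s.site,
            "lon": s.lon,
            "lat": s.lat,
            "elevation": s.elevation,
            "forest_type": s.forest_type,
            "origin": s.origin,
            "stand_age": s.stand_age,
            "mat": s.mat,
            "map": s.map,
        }
        for col in COMPONENT_COLUMNS:
            row[col] = getattr(s, col)
        rows.append(row)
    return pd.DataFrame(rows)
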