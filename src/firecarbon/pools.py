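"""Carbon pool estimation: one plot inventory -> MgC/ha by pool.

Pools follow the standard stock-change partition for a mixed-conifer
inventory: aboveground live tree, snag, understory (shrub + herb),
fine woody debris by timelag class (1-h, 10-h, 100-h), coarse woody
debris (1000-h and larger), litter, duff, and mineral soil carbon in
the 0-15 cm layer.  Downed wood comes from Brown's planar-intercept
method with basal-area-weighted composite species coefficients; litter
and duff from depth-to-biomass regressions; everything is converted to
carbon with the fixed fractions in
:class:`~firecarbon.allometry.ConversionConstants`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .allometry import (
    TIMELAG_CLASSES,
    AllometryTable,
    ConversionConstants,
    FuelCoefficients,
)
from .records import (
    FuelTransect,
    PlotInventory,
    TreeRecord,
    UnderstoryRecord,
    expansion_factor,
    tree_basal_area_m2,
)

__all__ = [
    "CarbonPools",
    "tree_biomass",
    "tree_carbon",
    "snag_carbon",
    "shrub_carbon",
    "herb_carbon",
    "composite_fuel_coefficients",
    "fwd_load",
    "cwd_load",
    "plot_fuel_carbon",
    "soil_carbon",
    "plot_pools",
    "PLANAR_INTERCEPT_G",
]

#: unit-conversion constant of the planar-intercept load formula:
#: load [Mg/ha] = G * sum(d_i^2)[cm^2] * secant * specific gravity
#: [g/cm^3] * slope correction / sampled length [m];  G = pi^2 / 8.
PLANAR_INTERCEPT_G = math.pi**2 / 8.0


@dataclass
class CarbonPools:
    """Per-plot carbon density by pool, MgC/ha."""

    live_tree: float = 0.0
    snag: float = 0.0
    understory: float = 0.0
    fwd_1h: float = 0.0
    fwd_10h: float = 0.0
    fwd_100h: float = 0.0
    cwd: float = 0.0
    litter: float = 0.0
    duff: float = 0.0
    soil_0_15: float = 0.0

    POOL_NAMES = (
        "live_tree", "snag", "understory", "fwd_1h", "fwd_10h",
        "fwd_100h", "cwd", "litter", "duff", "soil_0_15",
    )

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"pool {f.name} is negative")

    @property
    def total(self) -> float:
        """Total measured carbon: the sum of all pools, MgC/ha."""
        return sum(getattr(self, n) for n in self.POOL_NAMES)

    def as_dict(self) -> dict[str, float]:
        d = {n: getattr(self, n) for n in self.POOL_NAMES}
        d["total"] = self.total
        return d


# -- trees ----------------------------------------------------------------

def tree_biomass(
    species: str, dbh: float, height: float, table: AllometryTable
) -> float:
    """Aboveground biomass of one live tree, Mg (stem+bark+branch+foliage)."""
    if dbh <= 0:
        raise ValueError(f"dbh must be > 0, got {dbh}")
    if height <= 0:
        raise ValueError(f"height must be > 0, got {height}")
    a, b, c = table.require_species(species, table.wood, "wood-biomass")
    wood_kg = a * dbh**b * height**c
    ratio = table.require_species(species, table.foliage_ratio, "foliage-ratio")
    return wood_kg * (1.0 + ratio) / 1000.0


def tree_carbon(biomass: float, constants: ConversionConstants | None = None) -> float:
    """Live-tree carbon from biomass via the 0.48 carbon:biomass ratio."""
    if biomass < 0:
        raise ValueError("biomass must be >= 0")
    c = constants.c_tree if constants is not None else 0.48
    return c * biomass


def snag_carbon(
    species: str,
    dbh: float,
    height: float,
    table: AllometryTable,
    constants: ConversionConstants,
) -> float:
    """Snag carbon, Mg: live-equivalent wood biomass x 0.88 x 0.51.

    The live-equivalent excludes foliage.  The decay-class-2 ratios are
    applied to snags of every decay class.
    """
    if dbh <= 0:
        raise ValueError(f"dbh must be > 0, got {dbh}")
    a, b, c = table.require_species(species, table.wood, "wood-biomass")
    wood_mg = a * dbh**b * height**c / 1000.0
    return wood_mg * constants.snag_dead_ratio * constants.c_snag


# -- understory -----------------------------------------------------------

def shrub_carbon(
    record: UnderstoryRecord,
    plot_area_ha: float,
    table: AllometryTable,
    constants: ConversionConstants,
) -> float:
    """Shrub carbon density from a cover-class record, MgC/ha.

    Cover midpoint -> covered area -> individual count via mean crown
    area -> per-individual allometric biomass -> carbon at 0.49.
    """
    crown_area_m2, indiv_kg = table.shrub_coefficients(record.species)
    covered_m2 = record.cover_fraction * plot_area_ha * 1e4
    n_individuals = covered_m2 / crown_area_m2
    biomass_mg_per_ha = n_individuals * indiv_kg / 1000.0 / plot_area_ha
    return biomass_mg_per_ha * constants.c_shrub


def herb_carbon(
    records: list[UnderstoryRecord], table: AllometryTable
) -> float:
    """Herb carbon density, MgC/ha: linear in summed cover midpoints."""
    cover = sum(r.cover_fraction for r in records if r.growth_form == "herb")
    return table.herb_coefficient * cover


# -- downed woody fuels ---------------------------------------------------

def composite_fuel_coefficients(
    trees: list[TreeRecord], table: AllometryTable
) -> FuelCoefficients:
    """Basal-area-weighted composite of the species fuel coefficients.

    Weights are the relative basal area of the live trees present; a
    treeless plot falls back to an equal-weight mean over the table.
    """
    weights: dict[str, float] = {}
    for t in trees:
        if t.status == "live" and t.species in table.fuel:
            weights[t.species] = weights.get(t.species, 0.0) + tree_basal_area_m2(t.dbh)
    if not weights:
        weights = {sp: 1.0 for sp in table.fuel}
    total = sum(weights.values())

    def blend(attr: str) -> dict[str, float]:
        return {
            cls: sum(
                w / total * getattr(table.fuel[sp], attr)[cls]
                for sp, w in weights.items()
            )
            for cls in TIMELAG_CLASSES
        }

    return FuelCoefficients(
        squared_mean_diameter=blend("squared_mean_diameter"),
        secant_of_lean=blend("secant_of_lean"),
        specific_gravity=blend("specific_gravity"),
    )


def fwd_load(
    transect: FuelTransect,
    comp: FuelCoefficients,
    cls: str,
    constants: ConversionConstants | None = None,
) -> float:
    """Fine woody debris load for one timelag class on one transect, Mg/ha.

    load = G * n * qmd * sec * sg * slope / L with the class-specific
    sampled length L (2 m for 1-h and 10-h, 3 m for 100-h).
    """
    if cls not in ("1h", "10h", "100h"):
        raise ValueError(f"not a fine woody debris class: {cls!r}")
    length = FuelTransect.SAMPLED_LENGTH_M[cls]
    if length <= 0:
        raise ValueError("sampled length must be > 0")
    n = getattr(transect, f"counts_{cls}")
    slope = constants.slope_correction if constants is not None else 1.0
    return (
        PLANAR_INTERCEPT_G
        * n
        * comp.squared_mean_diameter[cls]
        * comp.secant_of_lean[cls]
        * comp.specific_gravity[cls]
        * slope
        / length
    )


def cwd_load(
    transect: FuelTransect,
    comp: FuelCoefficients,
    constants: ConversionConstants | None = None,
) -> float:
    """Coarse woody debris (1000-h and larger) load on one transect, Mg/ha.

    Piece diameters are measured individually over the full 11.3 m.
    """
    length = FuelTransect.SAMPLED_LENGTH_M["cwd"]
    sum_d2 = sum(d * d for d in transect.cwd_diameters)
    slope = constants.slope_correction if constants is not None else 1.0
    return (
        PLANAR_INTERCEPT_G
        * sum_d2
        * comp.secant_of_lean["cwd"]
        * comp.specific_gravity["cwd"]
        * slope
        / length
    )


def plot_fuel_carbon(
    plot: PlotInventory,
    table: AllometryTable,
    constants: ConversionConstants,
) -> dict[str, float]:
    """Downed-wood, litter, and duff carbon for one plot, MgC/ha.

    Transect-level loads are averaged over the plot's two transects;
    litter/duff biomass come from mean depth times the depth-to-biomass
    coefficient; woody carbon at 0.5, litter at 0.463, duff at 0.362.
    """
    out = {"fwd_1h": 0.0, "fwd_10h": 0.0, "fwd_100h": 0.0,
           "cwd": 0.0, "litter": 0.0, "duff": 0.0}
    if not plot.transects:
        return out
    comp = composite_fuel_coefficients(plot.trees, table)
    ntr = len(plot.transects)
    for cls in ("1h", "10h", "100h"):
        mean_load = sum(
            fwd_load(tr, comp, cls, constants) for tr in plot.transects
        ) / ntr
        out[f"fwd_{cls}"] = mean_load * constants.c_wd
    out["cwd"] = (
        sum(cwd_load(tr, comp, constants) for tr in plot.transects) / ntr
    ) * constants.c_wd

    litter_depths = [d for tr in plot.transects for d in tr.litter_depths]
    duff_depths = [d for tr in plot.transects for d in tr.duff_depths]
    mean_litter = sum(litter_depths) / len(litter_depths)
    mean_duff = sum(duff_depths) / len(duff_depths)
    out["litter"] = mean_litter * constants.litter_depth_to_biomass * constants.c_litter
    out["duff"] = mean_duff * constants.duff_depth_to_biomass * constants.c_duff
    return out


# -- soil -----------------------------------------------------------------

def soil_carbon(samples) -> float:
    """Mineral soil carbon 0-15 cm, MgC/ha, averaged over plot samples.

    Per sample: bulk density [g/cm^3] x thickness [cm] x %C/100 x 100.
    """
    if not samples:
        return 0.0
    per_sample = [
        s.bulk_density * (s.depth_bottom - s.depth_top) * s.carbon_pct / 100.0 * 100.0
        for s in samples
    ]
    return sum(per_sample) / len(per_sample)


# -- assembly -------------------------------------------------------------

def live_tree_carbon_per_ha(
    trees: list[TreeRecord],
    inventory: PlotInventory,
    table: AllometryTable,
    constants: ConversionConstants,
) -> float:
    """Aboveground live-tree carbon density with expansion factors, MgC/ha."""
    total = 0.0
    for t in trees:
        if t.status != "live":
            continue
        height = t.height if t.height is not None else default_height(t.dbh)
        b = tree_biomass(t.species, t.dbh, height, table)
        total += tree_carbon(b, constants) * expansion_factor(t, inventory)
    return total


def default_height(dbh: float) -> float:
    """Fallback height (m) from dbh via a saturating curve."""
    return 1.37 + 46.0 * (1.0 - math.exp(-0.025 * dbh))


def plot_pools(
    plot: PlotInventory,
    table: AllometryTable,
    constants: ConversionConstants,
) -> CarbonPools:
    """Assemble the full per-plot carbon pool vector, MgC/ha."""
    live = live_tree_carbon_per_ha(plot.live_trees, plot, table, constants)

    snag = 0.0
    for t in plot.snags:
        height = t.height if t.height is not None else default_height(t.dbh)
        snag += (
            snag_carbon(t.species, t.dbh, height, table, constants)
            * expansion_factor(t, plot)
        )

    from .records import MAIN_PLOT_HA

    shrubs = sum(
        shrub_carbon(r, MAIN_PLOT_HA, table, constants)
        for r in plot.understory
        if r.growth_form == "shrub"
    )
    herbs = herb_carbon(plot.understory, table)

    fuels = plot_fuel_carbon(plot, table, constants)
    soil = soil_carbon(plot.soil)

    return CarbonPools(
        live_tree=live,
        snag=snag,
        understory=shrubs + herbs,
        soil_0_15=soil,
        **fuels,
    )
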