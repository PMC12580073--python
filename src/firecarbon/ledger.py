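"""Stock-change flux accounting: NECB, NEP, wood products, carbon cost.

The ledger follows a sign convention in which carbon *leaving* the
ecosystem (prescribed-fire emissions, harvest removals) is recorded as
a negative entry, so that

    NEP = NECB - fire_emission - wood_removals

recovers gross ecosystem production net of respiration: what the stand
fixed, whether it stayed on site or was exported.  NECB itself is the
plain stock change, total measured carbon at the end of the record
minus the start.

The harvested-wood chain routes sawlog carbon through a mill-efficiency
split: 67.6% of sawlog volume becomes long-lived products (LLP), less a
5% fossil-fuel deduction for harvest and transport; 22.4% (kerf and
trimmings) is burned as energy feedstock and counted as an emission;
hardwood fuelwood is an immediate emission; sub-merchantable stems stay
in the field as residue.

The carbon cost of a treatment is the discounted cumulative shortfall
of its annual flux against the untreated baseline, with LLP credited
back as sequestration, discounted at 4%/yr to start-year equivalents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .allometry import AllometryTable, ConversionConstants
from .pools import CarbonPools, tree_biomass
from .records import HARDWOOD_SPECIES, TreeRecord, tree_basal_area_m2

__all__ = [
    "FluxLedger",
    "WoodProductAccount",
    "CostSeries",
    "necb",
    "nep",
    "annualize",
    "wood_product_chain",
    "fire_emission_entry",
    "interpolate_annual_flux",
    "carbon_cost",
    "LLP_MILL_FRACTION",
    "LLP_FOSSIL_DEDUCTION",
    "KERF_FRACTION",
    "SAWLOG_MIN_DBH_CM",
    "FUELWOOD_MIN_DBH_CM",
]

#: mill efficiency: fraction of sawlog volume entering long-lived products
LLP_MILL_FRACTION = 0.676
#: fossil-fuel deduction applied to LLP for harvest + transport
LLP_FOSSIL_DEDUCTION = 0.05
#: kerf and trimmings, used as energy feedstock -> emission
KERF_FRACTION = 0.224
#: conifer sawlog eligibility (0.3-m stump to a 15.2-cm top)
SAWLOG_MIN_DBH_CM = 22.9
#: hardwood fuelwood eligibility (0.3-m stump to a 20.3-cm top)
FUELWOOD_MIN_DBH_CM = 27.9


@dataclass
class FluxLedger:
    """Per-unit flux summary over one record interval, MgC/ha.

    ``fire_emission`` and ``wood_removals`` are <= 0 by convention;
    ``nep`` is derived and the identity is enforced at construction.
    """

    unit_id: str
    interval: tuple[int, int]
    necb: float
    fire_emission: float = 0.0
    wood_removals: float = 0.0

    def __post_init__(self):
        if self.fire_emission > 0 or self.wood_removals > 0:
            raise ValueError(
                "fire_emission and wood_removals must be <= 0 (ledger convention)"
            )
        if self.years <= 0:
            raise ValueError("interval must span at least one year")

    @property
    def years(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def nep(self) -> float:
        return nep(self.necb, self.fire_emission, self.wood_removals)

    @property
    def annual_nep(self) -> float:
        return annualize(self.nep, self.years)


def necb(pools_start: CarbonPools, pools_end: CarbonPools) -> float:
    """Net ecosystem carbon balance: stock change in total measured carbon."""
    return pools_end.total - pools_start.total


def nep(necb_value: float, fire_emission: float, wood_removals: float) -> float:
    """Net ecosystem productivity from the ledger identity.

    NEP = NECB - fire emission - wood removals; with emissions and
    removals stored as negative entries, exported carbon adds back in.
    """
    if fire_emission > 0 or wood_removals > 0:
        raise ValueError("emissions and removals must be <= 0 under the sign convention")
    return necb_value - fire_emission - wood_removals


def llp_adjusted_balance(necb_value: float, llp: float) -> float:
    """Net balance counting long-lived wood products as stored carbon.

    A unit with negative NECB can still be a net sink once the carbon
    banked in durable wood products is added back.
    """
    if llp < 0:
        raise ValueError("LLP stock must be >= 0")
    return necb_value + llp


def annualize(total_flux: float, years: float) -> float:
    """Average annual flux, MgC/ha/yr (19 years for a 2001-2020 record)."""
    if years <= 0:
        raise ValueError("years must be > 0")
    return total_flux / years


# -- harvested wood products ---------------------------------------------

@dataclass
class WoodProductAccount:
    """Fate of harvested carbon, MgC/ha."""

    sawlog_carbon: float = 0.0
    llp: float = 0.0
    kerf_emission: float = 0.0
    fuelwood_emission: float = 0.0
    residue_field: float = 0.0
    residue_other: float = 0.0

    @property
    def removed_offsite(self) -> float:
        """Carbon exported from the forest (sawlogs + fuelwood + hauled residue)."""
        return self.sawlog_carbon + self.fuelwood_emission + self.residue_other


def sawlog_volume_m3(dbh: float, height: float, table: AllometryTable) -> float:
    """Merchantable stem volume via the table's form factor, m^3."""
    return table.stem_form_factor * tree_basal_area_m2(dbh) * height


def wood_product_chain(
    harvested: list[TreeRecord],
    table: AllometryTable,
    constants: ConversionConstants,
    expansion: float = 25.0,
    tops_fate: str = "field",
) -> WoodProductAccount:
    """Route a harvested tree list through the wood-product carbon chain.

    Parameters
    ----------
    harvested
        trees removed by the operation (live at harvest).
    expansion
        per-hectare multiplier for the records (25 for 0.04-ha plots).
    tops_fate
        ``"field"`` leaves tops and limbs as on-site residue (first-entry
        practice); ``"emission"`` hauls them to the landing and burns them
        (second-entry practice), moving that carbon to ``residue_other``.
    """
    if tops_fate not in ("field", "emission"):
        raise ValueError(f"tops_fate must be field|emission, got {tops_fate!r}")
    acct = WoodProductAccount()
    from .pools import default_height

    for t in harvested:
        height = t.height if t.height is not None else default_height(t.dbh)
        total_c = tree_biomass(t.species, t.dbh, height, table) * constants.c_tree
        total_c *= expansion
        is_hardwood = t.species in HARDWOOD_SPECIES
        if not is_hardwood and t.dbh > SAWLOG_MIN_DBH_CM:
            density = table.require_species(t.species, table.wood_density, "wood-density")
            vol = sawlog_volume_m3(t.dbh, height, table)
            sawlog_c = min(vol * density * constants.c_tree * expansion, total_c)
            acct.sawlog_carbon += sawlog_c
            tops = total_c - sawlog_c
            if tops_fate == "field":
                acct.residue_field += tops
            else:
                acct.residue_other += tops
        elif is_hardwood and t.dbh > FUELWOOD_MIN_DBH_CM:
            density = table.require_species(t.species, table.wood_density, "wood-density")
            vol = sawlog_volume_m3(t.dbh, height, table)
            fuel_c = min(vol * density * constants.c_tree * expansion, total_c)
            acct.fuelwood_emission += fuel_c
            acct.residue_field += total_c - fuel_c
        else:
            acct.residue_field += total_c

    acct.llp = acct.sawlog_carbon * LLP_MILL_FRACTION * (1.0 - LLP_FOSSIL_DEDUCTION)
    acct.kerf_emission = acct.sawlog_carbon * KERF_FRACTION
    # remainder of sawlog volume (mill residue + the fossil deduction)
    acct.residue_other += acct.sawlog_carbon - acct.llp - acct.kerf_emission
    return acct


# -- fire emissions -------------------------------------------------------

#: pools that can burn, plus the foliage share of the live-tree pool
COMBUSTIBLE_POOLS = (
    "litter", "duff", "fwd_1h", "fwd_10h", "fwd_100h", "cwd", "understory",
    "live_tree",
)


def fire_emission_entry(
    prefire_pools: CarbonPools, consumption: dict[str, float]
) -> float:
    """Emission ledger entry (<= 0) from per-pool consumption fractions.

    A simplified consumption stand-in: externally modeled emissions (for
    example first-order fire-effects model output) may be supplied to
    the ledger directly instead.  The ``live_tree`` fraction is the
    foliage/crown share consumed.
    """
    emission = 0.0
    for pool, frac in consumption.items():
        if pool not in COMBUSTIBLE_POOLS:
            raise KeyError(f"{pool!r} is not a combustible pool")
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"consumption fraction for {pool} outside [0, 1]")
        emission += getattr(prefire_pools, pool) * frac
    return -emission


# -- annual interpolation & carbon cost -----------------------------------

def interpolate_annual_flux(series: list[tuple[int, float]]) -> dict[int, float]:
    """Linear interpolation of stock change into constant annual fluxes.

    For each inventory interval (y0, y1) with stock change dC, every
    year y0+1..y1 receives dC/(y1-y0), so the fluxes telescope back to
    the endpoint difference.
    """
    series = sorted(series)
    if len(series) < 2:
        raise ValueError("need at least two inventories to interpolate")
    out: dict[int, float] = {}
    for (y0, c0), (y1, c1) in zip(series, series[1:]):
        if y1 <= y0:
            raise ValueError("inventory years must be strictly increasing")
        rate = (c1 - c0) / (y1 - y0)
        for y in range(y0 + 1, y1 + 1):
            out[y] = rate
    return out


@dataclass
class CostSeries:
    """Annual treatment-minus-control shortfall and its discounted sum.

    ``delta_flux[t]`` is control flux minus treatment flux (including
    the LLP credit) in year t; positive deltas are emissions charged to
    the treatment, negative are sequestration credits.  Discounting uses
    (1+r)^-(t - base_year), so a year-after-base delta is divided by
    (1+r) ("start-year equivalent" costs).
    """

    years: list[int]
    delta_flux: list[float]
    discount_rate: float = 0.04
    base_year: int = 2001
    discount_factors: list[float] = field(default_factory=list)

    def __post_init__(self):
        if len(self.years) != len(self.delta_flux):
            raise ValueError("years and delta_flux must align")
        if not self.discount_factors:
            self.discount_factors = [
                (1.0 + self.discount_rate) ** -(t - self.base_year) for t in self.years
            ]

    @property
    def undiscounted_cost(self) -> float:
        return math.fsum(self.delta_flux)

    @property
    def discounted_cost(self) -> float:
        return math.fsum(
            d * f for d, f in zip(self.delta_flux, self.discount_factors)
        )


def carbon_cost(
    control_flux: dict[int, float],
    treatment_flux: dict[int, float],
    llp_by_year: dict[int, float] | None = None,
    discount_rate: float = 0.04,
    base_year: int = 2001,
) -> CostSeries:
    """Discounted carbon cost of a treatment against the control baseline.

    delta_t = control_t - (treatment_t + llp_credit_t).  Any reduction
    in annual flux relative to control is an emission; any increase (or
    LLP stored) is a sequestration.  Lower cost is better for the
    treatment.
    """
    if set(control_flux) != set(treatment_flux):
        raise ValueError("control and treatment year ranges are misaligned")
    llp_by_year = llp_by_year or {}
    if not set(llp_by_year) <= set(control_flux):
        raise ValueError("LLP credit years outside the flux record")
    years = sorted(control_flux)
    deltas = [
        control_flux[t] - (treatment_flux[t] + llp_by_year.get(t, 0.0))
        for t in years
    ]
    return CostSeries(
        years=years,
        delta_flux=deltas,
        discount_rate=discount_rate,
        base_year=base_year,
    )
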