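"""Seeded generator of a synthetic BACI wildfire-mitigation experiment.

The generator emulates the structure of a replicated fire-and-fire-
surrogate experiment: 12 experimental units (3 replicates x 4
treatments: untreated control, prescribed fire only, mechanical only,
mechanical + fire), 20 permanent 0.04-ha plots per unit, a six-species
mixed-conifer composition, and inventories in 2001, 2003, 2009, 2010,
2016, 2017 and 2020 with the era-specific protocols (nested 0.004-ha
sapling subplots, the 2020 whole-plot small-tree census, the 2016 snag
dbh floor).  Treatment calendars follow the study design: burns in
2002/2009/2017 (fire-only) and 2002/2018 (mech+fire), thinning to a
28-34 m2/ha residual basal area in 2001 and 2019, mastication of 90%
of stems up to 25 cm dbh, and a 2019 salvage of fire-killed trees.

It is a statistical emulator, not a physiological model: diameter
growth is a clipped-normal annual increment, mortality is Bernoulli,
surface-fuel dynamics are first-order input/decay budgets, and
prescribed-fire effects are fractional pool consumption plus a
size-dependent logistic kill.  Carbon is conserved through every
discrete management event except the explicit emissions and removals,
which are returned as ledger entries.

Randomness contract: one root seed; each unit draws from its own
deterministic substream, so adding a unit never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .allometry import AllometryTable, ConversionConstants, default_constants, default_table
from .ledger import WoodProductAccount, wood_product_chain
from .pools import tree_biomass
from .records import (
    MAIN_PLOT_HA,
    SMALL_TREE_DBH,
    SPECIES,
    SUBPLOT_HA,
    TRANSECT_LENGTH_M,
    TREATMENT_CALENDAR,
    Event,
    EventSchedule,
    FuelTransect,
    PlotInventory,
    ProtocolFlags,
    SoilSample,
    TreeRecord,
    UnderstoryRecord,
    protocol_for_year,
    tree_basal_area_m2,
)

__all__ = ["SimConfig", "SimTree", "PlotState", "UnitState", "ExperimentResult",
           "generate_stand", "advance", "apply_thin", "apply_mastication",
           "apply_rx_fire", "apply_salvage", "generate_experiment"]

_COMPREHENSIVE_YEARS = (2001, 2003, 2009, 2016, 2020)
_UPDATE_YEARS = (2010, 2017)

_FWD_CLASSES = ("1h", "10h", "100h")


@dataclass(frozen=True)
class SimConfig:
    """Study-design and stochastic-process parameters of the generator."""

    seed: int = 0
    n_units: int = 12
    n_plots: int = 20
    inventory_years: tuple[int, ...] = (2001, 2003, 2009, 2010, 2016, 2017, 2020)
    #: unit -> treatment; 3 replicates x 4 treatments by default
    treatments: dict[str, str] = field(default_factory=dict)

    # stand structure (pre-treatment, per hectare)
    stems_per_ha: float = 1100.0
    #: comparability guard: unit-mean live basal area band, m2/ha
    ba_band: tuple[float, float] = (35.0, 62.0)
    species_probs: tuple[float, ...] = (0.30, 0.20, 0.15, 0.15, 0.12, 0.08)
    dbh_weibull_shape: float = 1.4
    dbh_weibull_scale: float = 20.0  # cm
    min_dbh: float = 1.0
    height_asymptote: float = 48.0   # m
    height_rate: float = 0.022       # per cm
    height_sigma: float = 0.08       # lognormal sd of the tree height multiplier

    # annual dynamics
    growth_mean: float = 0.35        # cm/yr dbh increment
    growth_sd: float = 0.15
    background_mortality: float = 0.012  # /yr, live stem -> snag
    snag_fall_rate: float = 0.08     # /yr, snag -> coarse woody debris
    litterfall: float = 1.4          # MgC/ha/yr into litter
    fwd_input: float = 0.35          # MgC/ha/yr into fine woody debris
    decay_litter: float = 0.12       # /yr (40% routed to duff, 60% respired)
    litter_to_duff: float = 0.4
    decay_duff: float = 0.03
    decay_fwd: float = 0.06
    decay_cwd: float = 0.025
    understory_growth: float = 0.08  # MgC/ha/yr
    understory_cap: float = 3.0      # MgC/ha

    # initial surface pools, MgC/ha (means; plot-level draws are jittered)
    init_litter: float = 5.0
    init_duff: float = 9.0
    init_fwd: tuple[float, float, float] = (0.3, 1.2, 2.0)
    init_cwd: float = 8.0
    init_understory: float = 1.2

    # thinning: residual basal-area band and target, m2/ha
    thin_band: tuple[float, float] = (28.0, 34.0)
    thin_target_ba: float = 31.0
    crown_thin_share: float = 0.3
    large_tree_dbh: float = 76.2

    # mastication
    mastication_dbh_max: float = 25.0
    mastication_fraction: float = 0.9
    mastication_understory_fraction: float = 0.9

    # prescribed fire: per-pool consumption fractions and kill curve
    rx_consumption: dict = field(default_factory=lambda: {
        "litter": 0.85, "duff": 0.75, "fwd_1h": 0.90, "fwd_10h": 0.75,
        "fwd_100h": 0.50, "cwd": 0.25, "understory": 0.80,
    })
    rx_severity: float = 0.9
    rx_dbh50: float = 14.0           # cm at which kill probability halves
    rx_scale: float = 7.0

    salvage_fraction: float = 0.7

    # soil
    soil_bd_mean: float = 0.9        # g/cm^3
    soil_bd_sd: float = 0.08
    soil_cpct_mean: float = 5.1      # %C
    soil_cpct_sd: float = 0.6

    # optional 2012-2015 drought mortality pulse (additional /yr), off by default
    drought_mortality: float = 0.0
    drought_years: tuple[int, ...] = (2012, 2013, 2014, 2015)

    def __post_init__(self):
        if not self.treatments:
            kinds = ("Control", "Fire", "Mech", "MechFire")
            mapping = {
                f"U{i + 1:02d}": kinds[i // 3] for i in range(self.n_units)
            }
            object.__setattr__(self, "treatments", mapping)
        if not (self.thin_band[0] <= self.thin_target_ba <= self.thin_band[1]):
            raise ValueError("thin target outside the residual basal-area band")
        if abs(sum(self.species_probs) - 1.0) > 1e-9:
            raise ValueError("species_probs must sum to 1")
        for frac in self.rx_consumption.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("rx consumption fractions must be in [0, 1]")


@dataclass
class SimTree:
    tag: str
    species: str
    dbh: float
    height_mult: float
    status: str = "live"   # live | snag


def _height(tree: SimTree, cfg: SimConfig) -> float:
    base = 1.37 + cfg.height_asymptote * (1.0 - math.exp(-cfg.height_rate * tree.dbh))
    return base * tree.height_mult


@dataclass
class PlotState:
    plot_id: str
    trees: list[SimTree]
    litter_c: float
    duff_c: float
    fwd_c: dict[str, float]
    cwd_c: float
    understory_c: float
    soil_bd: float
    soil_cpct: float

    def tree_carbon(self, cfg: "SimConfig", table: AllometryTable,
                    constants: ConversionConstants, status: str = "live") -> float:
        """Per-hectare carbon of live trees or snags, MgC/ha."""
        total = 0.0
        for t in self.trees:
            if t.status != status:
                continue
            h = _height(t, cfg)
            if status == "live":
                total += tree_biomass(t.species, t.dbh, h, table) * constants.c_tree
            else:
                # live-equivalent wood reduced by the snag ratios
                a, e1, e2 = table.wood[t.species]
                wood = a * t.dbh**e1 * h**e2 / 1000.0
                total += wood * constants.snag_dead_ratio * constants.c_snag
        return total / MAIN_PLOT_HA

    def total_carbon(self, cfg: "SimConfig", table: AllometryTable,
                     constants: ConversionConstants,
                     include_soil: bool = False) -> float:
        """Internal-state total measured carbon, MgC/ha."""
        t = (
            self.tree_carbon(cfg, table, constants, "live")
            + self.tree_carbon(cfg, table, constants, "snag")
            + self.litter_c + self.duff_c + self.cwd_c + self.understory_c
            + sum(self.fwd_c.values())
        )
        if include_soil:
            t += self.soil_bd * 15.0 * self.soil_cpct  # BD*depth*%C/100*100
        return t

    def live_basal_area(self) -> float:
        """Live basal area, m^2/ha."""
        return sum(
            tree_basal_area_m2(t.dbh) for t in self.trees if t.status == "live"
        ) / MAIN_PLOT_HA


@dataclass
class UnitState:
    unit_id: str
    treatment: str
    plots: list[PlotState]
    rng: np.random.Generator
    year: int = 2001


@dataclass
class ExperimentResult:
    """Full synthetic dataset plus the event-level ledger entries."""

    inventories: list[PlotInventory]
    schedules: list[EventSchedule]
    #: unit -> year -> prescribed-fire emission entry (MgC/ha, <= 0)
    fire_emissions: dict[str, dict[int, float]]
    #: unit -> year -> wood-product account for that harvest
    wood_accounts: dict[str, dict[int, WoodProductAccount]]
    #: unit -> year -> additional off-site removals (salvage), MgC/ha >= 0
    salvage_removals: dict[str, dict[int, float]]
    #: unit -> year -> internal-state mean total carbon across plots
    unit_totals: dict[str, dict[int, float]]
    config: SimConfig = None

    def unit_fire_emission(self, unit_id: str) -> float:
        return sum(self.fire_emissions.get(unit_id, {}).values())

    def unit_wood_removals(self, unit_id: str) -> float:
        accounts = self.wood_accounts.get(unit_id, {})
        removed = sum(a.removed_offsite for a in accounts.values())
        removed += sum(self.salvage_removals.get(unit_id, {}).values())
        return -removed

    def unit_llp_by_year(self, unit_id: str) -> dict[int, float]:
        return {
            y: a.llp for y, a in self.wood_accounts.get(unit_id, {}).items()
        }


# -- stand generation -----------------------------------------------------

def _unit_rng(cfg: SimConfig, unit_index: int) -> np.random.Generator:
    child = np.random.SeedSequence(cfg.seed).spawn(unit_index + 1)[unit_index]
    return np.random.default_rng(child)


def generate_stand(cfg: SimConfig, unit_id: str,
                   rng: np.random.Generator | None = None) -> list[PlotState]:
    """Pre-treatment (2001) plots for one experimental unit."""
    if rng is None:
        idx = list(cfg.treatments).index(unit_id)
        rng = _unit_rng(cfg, idx)
    plots = []
    for p in range(cfg.n_plots):
        n = rng.poisson(cfg.stems_per_ha * MAIN_PLOT_HA)
        species = rng.choice(SPECIES, size=n, p=cfg.species_probs)
        dbh = cfg.min_dbh + cfg.dbh_weibull_scale * rng.weibull(
            cfg.dbh_weibull_shape, size=n
        )
        mults = rng.lognormal(0.0, cfg.height_sigma, size=n)
        trees = [
            SimTree(
                tag=f"{unit_id}-P{p + 1:02d}-T{i + 1:03d}",
                species=str(species[i]),
                dbh=float(dbh[i]),
                height_mult=float(mults[i]),
            )
            for i in range(n)
        ]
        jit = lambda mu, frac=0.25: float(max(0.0, rng.normal(mu, frac * mu)))
        plots.append(
            PlotState(
                plot_id=f"{unit_id}-P{p + 1:02d}",
                trees=trees,
                litter_c=jit(cfg.init_litter),
                duff_c=jit(cfg.init_duff),
                fwd_c={cls: jit(v) for cls, v in zip(_FWD_CLASSES, cfg.init_fwd)},
                cwd_c=jit(cfg.init_cwd),
                understory_c=float(rng.uniform(0.4, 2.0 * cfg.init_understory)),
                soil_bd=float(max(0.3, rng.normal(cfg.soil_bd_mean, cfg.soil_bd_sd))),
                soil_cpct=float(max(0.5, rng.normal(cfg.soil_cpct_mean, cfg.soil_cpct_sd))),
            )
        )
    return plots


# -- annual dynamics ------------------------------------------------------

def advance(plots: list[PlotState], years: int, cfg: SimConfig,
            rng: np.random.Generator,
            table: AllometryTable, constants: ConversionConstants,
            calendar_years: tuple[int, ...] = ()) -> None:
    """Advance all plots by ``years`` annual steps, in place.

    Growth is a clipped-normal dbh increment; background mortality
    converts live stems to snags; fallen snags feed coarse woody
    debris; litterfall and decay run the surface-fuel budget.
    ``calendar_years`` (one entry per step) activates the optional
    drought mortality pulse in its configured years.
    """
    for step in range(years):
        year = calendar_years[step] if calendar_years else None
        mort = cfg.background_mortality
        if year is not None and year in cfg.drought_years:
            mort += cfg.drought_mortality
        for plot in plots:
            live = [t for t in plot.trees if t.status == "live"]
            if live:
                inc = rng.normal(cfg.growth_mean, cfg.growth_sd, size=len(live))
                inc = np.clip(inc, 0.0, None)
                dead = rng.random(len(live)) < mort
                for t, d, died in zip(live, inc, dead):
                    t.dbh += float(d)
                    if died:
                        t.status = "snag"
            # snag fall -> coarse woody debris (carbon moves, none lost)
            standing = []
            for t in plot.trees:
                if t.status == "snag" and rng.random() < cfg.snag_fall_rate:
                    h = _height(t, cfg)
                    a, e1, e2 = table.wood[t.species]
                    wood = a * t.dbh**e1 * h**e2 / 1000.0
                    plot.cwd_c += (
                        wood * constants.snag_dead_ratio * constants.c_snag
                        / MAIN_PLOT_HA
                    )
                else:
                    standing.append(t)
            plot.trees = standing
            # surface-fuel budget
            litter_out = plot.litter_c * cfg.decay_litter
            plot.litter_c += cfg.litterfall - litter_out
            plot.duff_c += cfg.litter_to_duff * litter_out - plot.duff_c * cfg.decay_duff
            for i, cls in enumerate(_FWD_CLASSES):
                share = (0.2, 0.35, 0.45)[i]
                plot.fwd_c[cls] += cfg.fwd_input * share - plot.fwd_c[cls] * cfg.decay_fwd
            plot.cwd_c *= 1.0 - cfg.decay_cwd
            plot.understory_c = min(
                cfg.understory_cap, plot.understory_c + cfg.understory_growth
            )


# -- management events ----------------------------------------------------

def apply_thin(plot: PlotState, cfg: SimConfig,
               rng: np.random.Generator) -> list[SimTree]:
    """Crown thin then thin from below to the residual basal-area band.

    Returns the harvested trees; the plot keeps the survivors.  A plot
    already below the band's lower edge is left untouched.
    """
    ba = plot.live_basal_area()
    if ba <= cfg.thin_band[0]:
        return []
    need = max(0.0, ba - cfg.thin_target_ba)
    if need <= 0.0:
        return []
    live = sorted(
        (t for t in plot.trees if t.status == "live"), key=lambda t: t.dbh
    )
    harvested: list[SimTree] = []
    removed_ba = 0.0
    # crown thin: largest non-"large" trees first, up to the crown share
    crown_budget = cfg.crown_thin_share * need
    for t in sorted(live, key=lambda t: -t.dbh):
        if removed_ba >= crown_budget:
            break
        if t.dbh >= cfg.large_tree_dbh:
            continue
        harvested.append(t)
        removed_ba += tree_basal_area_m2(t.dbh) / MAIN_PLOT_HA
    # thin from below
    taken = set(id(t) for t in harvested)
    for t in live:
        if removed_ba >= need:
            break
        if id(t) in taken:
            continue
        harvested.append(t)
        removed_ba += tree_basal_area_m2(t.dbh) / MAIN_PLOT_HA
    taken = set(id(t) for t in harvested)
    plot.trees = [t for t in plot.trees if id(t) not in taken]
    return harvested


def apply_mastication(plot: PlotState, cfg: SimConfig,
                      rng: np.random.Generator,
                      table: AllometryTable | None = None,
                      constants: ConversionConstants | None = None) -> float:
    """Masticate small stems and shrubs into the downed-fuel pools.

    90% of live stems below 25 cm dbh (and the same share of the
    understory) are shredded in place; their carbon moves to the fine
    and coarse woody debris pools.  Returns the carbon moved, MgC/ha.
    """
    if table is None or constants is None:
        table, constants = _default_tc()
    moved = 0.0
    kept = []
    for t in plot.trees:
        if (
            t.status == "live"
            and t.dbh < cfg.mastication_dbh_max
            and rng.random() < cfg.mastication_fraction
        ):
            c = (
                tree_biomass(t.species, t.dbh, _height(t, cfg), table)
                * constants.c_tree / MAIN_PLOT_HA
            )
            moved += c
        else:
            kept.append(t)
    plot.trees = kept
    shrub_moved = plot.understory_c * cfg.mastication_understory_fraction
    plot.understory_c -= shrub_moved
    moved += shrub_moved
    plot.fwd_c["10h"] += 0.2 * moved
    plot.fwd_c["100h"] += 0.4 * moved
    plot.cwd_c += 0.4 * moved
    return moved


def apply_rx_fire(plot: PlotState, cfg: SimConfig,
                  rng: np.random.Generator) -> float:
    """Prescribed burn: consume surface pools, kill small trees.

    Returns the emission ledger entry (MgC/ha, <= 0).  Killed trees
    become snags; survival probability increases monotonically with dbh
    by construction of the logistic kill curve.
    """
    consumed = 0.0
    for pool, frac in cfg.rx_consumption.items():
        if pool == "understory":
            consumed += plot.understory_c * frac
            plot.understory_c *= 1.0 - frac
        elif pool == "litter":
            consumed += plot.litter_c * frac
            plot.litter_c *= 1.0 - frac
        elif pool == "duff":
            consumed += plot.duff_c * frac
            plot.duff_c *= 1.0 - frac
        elif pool == "cwd":
            consumed += plot.cwd_c * frac
            plot.cwd_c *= 1.0 - frac
        elif pool.startswith("fwd_"):
            cls = pool[4:]
            consumed += plot.fwd_c[cls] * frac
            plot.fwd_c[cls] *= 1.0 - frac
    for t in plot.trees:
        if t.status != "live":
            continue
        if rng.random() < rx_kill_probability(t.dbh, cfg):
            t.status = "snag"
    return -consumed


def rx_kill_probability(dbh: float, cfg: SimConfig) -> float:
    """Prescribed-fire kill probability: logistic, declining with dbh."""
    return cfg.rx_severity / (1.0 + math.exp((dbh - cfg.rx_dbh50) / cfg.rx_scale))


def apply_salvage(plot: PlotState, cfg: SimConfig,
                  rng: np.random.Generator,
                  table: AllometryTable,
                  constants: ConversionConstants) -> float:
    """Salvage-harvest fire-killed snags; returns carbon removed, MgC/ha."""
    removed = 0.0
    kept = []
    for t in plot.trees:
        if t.status == "snag" and rng.random() < cfg.salvage_fraction:
            h = _height(t, cfg)
            a, e1, e2 = table.wood[t.species]
            wood = a * t.dbh**e1 * h**e2 / 1000.0
            removed += wood * constants.snag_dead_ratio * constants.c_snag / MAIN_PLOT_HA
        else:
            kept.append(t)
    plot.trees = kept
    return removed


def _default_tc() -> tuple[AllometryTable, ConversionConstants]:
    global _TC_CACHE
    try:
        return _TC_CACHE
    except NameError:
        _TC_CACHE = (default_table(), default_constants())
        return _TC_CACHE


# -- inventory emission ---------------------------------------------------

def _emit_transects(plot: PlotState, cfg: SimConfig, rng: np.random.Generator,
                    table: AllometryTable,
                    constants: ConversionConstants) -> list[FuelTransect]:
    """Synthesize two planar-intercept transects consistent with the
    plot's internal fuel state (counts Poisson around the expectation
    implied by inverting the load formula with composite coefficients)."""
    from .pools import PLANAR_INTERCEPT_G, composite_fuel_coefficients

    live_records = [
        TreeRecord(plot_id=plot.plot_id, tag=t.tag, species=t.species,
                   dbh=t.dbh, height=None, status="live")
        for t in plot.trees if t.status == "live"
    ]
    comp = composite_fuel_coefficients(live_records, table)
    litter_depth = plot.litter_c / (constants.c_litter * constants.litter_depth_to_biomass)
    duff_depth = plot.duff_c / (constants.c_duff * constants.duff_depth_to_biomass)
    transects = []
    for _ in range(2):
        counts = {}
        for cls in _FWD_CLASSES:
            load = plot.fwd_c[cls] / constants.c_wd  # biomass Mg/ha
            per_piece = (
                PLANAR_INTERCEPT_G
                * comp.squared_mean_diameter[cls]
                * comp.secant_of_lean[cls]
                * comp.specific_gravity[cls]
                / FuelTransect.SAMPLED_LENGTH_M[cls]
            )
            counts[cls] = int(rng.poisson(load / per_piece)) if per_piece > 0 else 0
        cwd_load_bio = plot.cwd_c / constants.c_wd
        diam_draw = lambda: float(rng.uniform(8.0, 30.0))
        diams: list[float] = []
        acc = 0.0
        per_d2 = (
            PLANAR_INTERCEPT_G * comp.secant_of_lean["cwd"]
            * comp.specific_gravity["cwd"] / TRANSECT_LENGTH_M
        )
        # add pieces until the expected load reaches the state (on average)
        while acc < cwd_load_bio - rng.uniform(0.0, 8.0):
            d = diam_draw()
            diams.append(d)
            acc += per_d2 * d * d
        jitter = lambda x: float(max(0.0, x * rng.lognormal(0.0, 0.15)))
        transects.append(
            FuelTransect(
                plot_id=plot.plot_id,
                azimuth=float(rng.uniform(0, 360)),
                counts_1h=counts["1h"],
                counts_10h=counts["10h"],
                counts_100h=counts["100h"],
                cwd_diameters=diams,
                litter_depths=(jitter(litter_depth), jitter(litter_depth)),
                duff_depths=(jitter(duff_depth), jitter(duff_depth)),
            )
        )
    return transects


_COVER_CLASSES = (("lt5", 0.025), ("5to25", 0.15), ("25to100", 0.63))


def _emit_understory(plot: PlotState, rng: np.random.Generator) -> list[UnderstoryRecord]:
    """Map internal understory carbon to cover-class records."""
    recs = []
    # one shrub + one herb record; class chosen by nearest midpoint of a
    # nominal carbon-per-cover scale
    shrub_c = 0.8 * plot.understory_c
    herb_c = 0.2 * plot.understory_c
    shrub_cover = min(0.99, shrub_c / 8.0)   # ~8 MgC/ha at full cover
    herb_cover = min(0.99, herb_c / 0.8)
    for cover, form, sp in ((shrub_cover, "shrub", "CEIN"), (herb_cover, "herb", "HERB")):
        if cover < 0.005:
            continue
        label = min(_COVER_CLASSES, key=lambda cm: abs(cm[1] - cover))[0]
        recs.append(
            UnderstoryRecord(plot_id=plot.plot_id, species=sp, cover_class=label,
                             mean_height=float(rng.uniform(0.3, 2.0)),
                             growth_form=form)
        )
    return recs


def emit_inventory(unit: UnitState, plot: PlotState, year: int, cfg: SimConfig,
                   rng: np.random.Generator, table: AllometryTable,
                   constants: ConversionConstants) -> PlotInventory:
    """Build a PlotInventory for one plot under the year's protocol."""
    flags = protocol_for_year(year)
    trees: list[TreeRecord] = []
    for t in plot.trees:
        if t.status == "snag" and t.dbh < flags.snag_dbh_floor:
            continue
        if t.status == "live" and t.dbh < SMALL_TREE_DBH:
            if flags.small_tree_frame == "none":
                continue
            if flags.small_tree_frame == "subplot":
                # nested 0.004-ha subplot: sampled with probability = area ratio
                if rng.random() >= SUBPLOT_HA / MAIN_PLOT_HA:
                    continue
                frame = "subplot"
            else:
                frame = "main_plot"
        else:
            frame = "main_plot"
        trees.append(
            TreeRecord(
                plot_id=plot.plot_id,
                tag=t.tag,
                species=t.species,
                dbh=round(t.dbh, 2),
                height=round(_height(t, cfg), 2),
                status=t.status,
                decay_class=2 if t.status == "snag" and year >= 2016 else None,
                sample_frame=frame,
            )
        )
    soil = [
        SoilSample(plot_id=plot.plot_id,
                   bulk_density=round(plot.soil_bd, 3),
                   carbon_pct=round(plot.soil_cpct, 3))
    ] if year in (2001, 2003, 2016, 2020) else []
    return PlotInventory(
        plot_id=plot.plot_id,
        unit_id=unit.unit_id,
        treatment=unit.treatment,
        year=year,
        trees=trees,
        understory=_emit_understory(plot, rng),
        transects=_emit_transects(plot, cfg, rng, table, constants),
        soil=soil,
        protocol_flags=flags,
    )


# -- the full experiment --------------------------------------------------

def generate_experiment(cfg: SimConfig,
                        table: AllometryTable | None = None,
                        constants: ConversionConstants | None = None
                        ) -> ExperimentResult:
    """Run the whole synthetic experiment: all units, 2001-2020."""
    table = table or default_table()
    constants = constants or default_constants()
    inventories: list[PlotInventory] = []
    schedules: list[EventSchedule] = []
    fire_emissions: dict[str, dict[int, float]] = {}
    wood_accounts: dict[str, dict[int, WoodProductAccount]] = {}
    salvage_removals: dict[str, dict[int, float]] = {}
    unit_totals: dict[str, dict[int, float]] = {}

    for idx, (unit_id, treatment) in enumerate(cfg.treatments.items()):
        rng = _unit_rng(cfg, idx)
        plots = generate_stand(cfg, unit_id, rng=rng)
        unit = UnitState(unit_id=unit_id, treatment=treatment, plots=plots, rng=rng)
        calendar = {y: [] for y in range(2001, 2021)}
        for kind, year in TREATMENT_CALENDAR[treatment]:
            calendar[year].append(kind)
        schedules.append(
            EventSchedule(
                unit_id=unit_id, treatment=treatment,
                events=[Event(year=y, kind=k)
                        for y in calendar for k in calendar[y]],
            )
        )
        fire_emissions[unit_id] = {}
        wood_accounts[unit_id] = {}
        salvage_removals[unit_id] = {}
        unit_totals[unit_id] = {}
        order = {"thin": 0, "mastication": 1, "rx_fire": 2, "salvage": 3}

        for year in range(2001, 2021):
            if year > 2001:
                advance(plots, 1, cfg, rng, table, constants,
                        calendar_years=(year,))
            if year in _COMPREHENSIVE_YEARS:
                # comprehensive summer inventory precedes any fall treatment
                for plot in plots:
                    inventories.append(
                        emit_inventory(unit, plot, year, cfg, rng, table, constants)
                    )
                unit_totals[unit_id][year] = float(
                    np.mean([p.total_carbon(cfg, table, constants) for p in plots])
                )
            for kind in sorted(calendar[year], key=order.get):
                if kind == "thin":
                    harvested_records = []
                    for plot in plots:
                        cut = apply_thin(plot, cfg, rng)
                        harvested_records.extend(
                            TreeRecord(plot_id=plot.plot_id, tag=t.tag,
                                       species=t.species, dbh=t.dbh,
                                       height=_height(t, cfg), status="live")
                            for t in cut
                        )
                    tops_fate = "field" if year <= 2002 else "emission"
                    acct = wood_product_chain(
                        harvested_records, table, constants,
                        expansion=1.0 / MAIN_PLOT_HA / cfg.n_plots,
                        tops_fate=tops_fate,
                    )
                    if tops_fate == "field" and acct.residue_field > 0:
                        # residue stays on site: spread over the downed pools
                        per_plot = acct.residue_field
                        for plot in plots:
                            plot.fwd_c["100h"] += 0.4 * per_plot
                            plot.cwd_c += 0.6 * per_plot
                    wood_accounts[unit_id][year] = acct
                elif kind == "mastication":
                    for plot in plots:
                        apply_mastication(plot, cfg, rng, table, constants)
                elif kind == "rx_fire":
                    emission = 0.0
                    for plot in plots:
                        emission += apply_rx_fire(plot, cfg, rng)
                    fire_emissions[unit_id][year] = emission / cfg.n_plots
                elif kind == "salvage":
                    removed = 0.0
                    for plot in plots:
                        removed += apply_salvage(plot, cfg, rng, table, constants)
                    salvage_removals[unit_id][year] = removed / cfg.n_plots
            if year in _UPDATE_YEARS:
                # post-fire update inventory follows the events
                for plot in plots:
                    inventories.append(
                        emit_inventory(unit, plot, year, cfg, rng, table, constants)
                    )
                unit_totals[unit_id][year] = float(
                    np.mean([p.total_carbon(cfg, table, constants) for p in plots])
                )

    return ExperimentResult(
        inventories=inventories,
        schedules=schedules,
        fire_emissions=fire_emissions,
        wood_accounts=wood_accounts,
        salvage_removals=salvage_removals,
        unit_totals=unit_totals,
        config=cfg,
    )
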