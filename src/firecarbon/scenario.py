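"""Wildfire-resistant carbon metrics and the simulated-wildfire ledger.

Fire behavior and first-order fire effects are *not* modeled here:
emissions and species- and size-specific mortality schedules enter as
inputs (from external simulators, or from the documented logistic
stand-in for synthetic runs).  This module does the accounting around
them: which share of live-tree carbon sits in wildfire-resistant pools
(large trees, dbh >= 76.2 cm, and the fire-resistant pines), the
"stable" carbon expected to survive a wildfire (pines >= 72.6 cm), the
carbon killed by a simulated fire, and the post-fire pool transfers
under strict carbon conservation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .allometry import AllometryTable, ConversionConstants
from .pools import CarbonPools, default_height, tree_biomass
from .records import (
    RESISTANT_SPECIES,
    PlotInventory,
    TreeRecord,
    expansion_factor,
)

__all__ = [
    "LARGE_TREE_DBH_CM",
    "STABLE_TREE_DBH_CM",
    "MortalitySchedule",
    "MortalityOutcome",
    "ScenarioResult",
    "resistant_fractions",
    "stable_carbon",
    "apply_mortality",
    "scenario_ledger",
    "with_wildfire_flux",
]

#: dbh threshold for "large" (wildfire-resistant) trees
LARGE_TREE_DBH_CM = 76.2
#: dbh threshold anchoring the stable-carbon definition
STABLE_TREE_DBH_CM = 72.6


def _tree_carbon_per_ha(
    t: TreeRecord,
    inventory: PlotInventory,
    table: AllometryTable,
    constants: ConversionConstants,
) -> float:
    height = t.height if t.height is not None else default_height(t.dbh)
    return (
        tree_biomass(t.species, t.dbh, height, table)
        * constants.c_tree
        * expansion_factor(t, inventory)
    )


@dataclass(frozen=True)
class MortalitySchedule:
    """Fraction of basal area killed, by species and dbh class.

    ``fractions[species][i]`` applies to the dbh class between
    ``dbh_breaks[i-1]`` and ``dbh_breaks[i]`` (open-ended at both
    extremes), so each species list has ``len(dbh_breaks) + 1`` entries.
    An ``"OTHER"`` key is the fallback for unlisted species.
    """

    dbh_breaks: tuple[float, ...]
    fractions: dict[str, tuple[float, ...]]
    source: str = "external_sim"  # external_sim | stand_in

    def __post_init__(self):
        n = len(self.dbh_breaks) + 1
        for sp, fr in self.fractions.items():
            if len(fr) != n:
                raise ValueError(f"{sp}: need {n} fractions for {n} dbh classes")
            if any(not 0.0 <= f <= 1.0 for f in fr):
                raise ValueError(f"{sp}: mortality fractions outside [0, 1]")

    def fraction_for(self, species: str, dbh: float) -> float:
        fr = self.fractions.get(species) or self.fractions.get("OTHER")
        if fr is None:
            raise KeyError(f"no mortality fractions for species {species!r}")
        idx = sum(1 for b in self.dbh_breaks if dbh >= b)
        return fr[idx]

    @classmethod
    def uniform(cls, fraction: float, source: str = "stand_in") -> "MortalitySchedule":
        return cls(dbh_breaks=(), fractions={"OTHER": (fraction,)}, source=source)

    @classmethod
    def logistic_stand_in(
        cls,
        severity: float = 0.9,
        dbh50: float = 30.0,
        scale: float = 12.0,
        species: tuple[str, ...] = ("OTHER",),
        resistant_advantage: float = 0.5,
        breaks: tuple[float, ...] = (10, 20, 30, 45, 60, 76.2),
    ) -> "MortalitySchedule":
        """Size-dependent logistic stand-in for an external fire simulator.

        Mortality declines with dbh: ``severity / (1 + exp((d - dbh50)/scale))``
        evaluated at class midpoints; fire-resistant pines get their
        fractions multiplied by ``resistant_advantage``.
        """
        mids = [breaks[0] / 2.0]
        mids += [(a + b) / 2.0 for a, b in zip(breaks, breaks[1:])]
        mids.append(breaks[-1] * 1.3)
        fractions = {}
        for sp in set(species) | {"OTHER"}:
            adv = resistant_advantage if sp in RESISTANT_SPECIES else 1.0
            fractions[sp] = tuple(
                min(1.0, adv * severity / (1.0 + math.exp((m - dbh50) / scale)))
                for m in mids
            )
        return cls(dbh_breaks=tuple(breaks), fractions=fractions, source="stand_in")


@dataclass
class MortalityOutcome:
    """Deterministic-expectation outcome of applying a mortality schedule.

    Carbon is conserved exactly: ``killed_carbon + survivor_carbon``
    equals the pre-fire live-tree carbon.  Per-tree weights carry the
    fractional kill so no rounding to whole stems is needed.
    """

    killed_carbon: float       # MgC/ha, moves to the snag pool
    survivor_carbon: float     # MgC/ha
    survivors: list[tuple[TreeRecord, float]] = field(default_factory=list)
    new_snags: list[tuple[TreeRecord, float]] = field(default_factory=list)


def resistant_fractions(
    trees: list[TreeRecord],
    inventory: PlotInventory,
    table: AllometryTable,
    constants: ConversionConstants,
    large_dbh_threshold: float = LARGE_TREE_DBH_CM,
) -> tuple[float, float]:
    """(% of live-tree C in large trees, % in fire-resistant species).

    Returns ``(nan, nan)`` on a plot with no live trees, where the
    fractions are undefined.
    """
    live = [t for t in trees if t.status == "live"]
    if not live:
        return (math.nan, math.nan)
    total = large = resistant = 0.0
    for t in live:
        c = _tree_carbon_per_ha(t, inventory, table, constants)
        total += c
        if t.dbh >= large_dbh_threshold:
            large += c
        if t.species in RESISTANT_SPECIES:
            resistant += c
    return (100.0 * large / total, 100.0 * resistant / total)


def stable_carbon(
    trees: list[TreeRecord],
    inventory: PlotInventory,
    table: AllometryTable,
    constants: ConversionConstants,
    dbh_threshold: float = STABLE_TREE_DBH_CM,
) -> float:
    """Carbon in live fire-resistant pines with dbh >= 72.6 cm, MgC/ha."""
    return sum(
        _tree_carbon_per_ha(t, inventory, table, constants)
        for t in trees
        if t.status == "live"
        and t.species in RESISTANT_SPECIES
        and t.dbh >= dbh_threshold
    )


def apply_mortality(
    trees: list[TreeRecord],
    schedule: MortalitySchedule,
    inventory: PlotInventory,
    table: AllometryTable,
    constants: ConversionConstants,
) -> MortalityOutcome:
    """Apply a species- and size-specific mortality schedule to live trees.

    Uses the deterministic expectation: each tree contributes its
    carbon times its class kill fraction to the killed pool, which is
    transferred to snags.
    """
    outcome = MortalityOutcome(killed_carbon=0.0, survivor_carbon=0.0)
    for t in trees:
        if t.status != "live":
            continue
        c = _tree_carbon_per_ha(t, inventory, table, constants)
        f = schedule.fraction_for(t.species, t.dbh)
        outcome.killed_carbon += c * f
        outcome.survivor_carbon += c * (1.0 - f)
        if f < 1.0:
            outcome.survivors.append((t, 1.0 - f))
        if f > 0.0:
            outcome.new_snags.append((replace_status(t, "snag"), f))
    return outcome


def replace_status(t: TreeRecord, status: str) -> TreeRecord:
    from dataclasses import replace as _replace

    return _replace(t, status=status)


@dataclass
class ScenarioResult:
    """Immediate carbon impacts of one simulated wildfire."""

    wildfire_emission: float          # MgC/ha, magnitude of the emission
    killed_tree_carbon: float         # MgC/ha moved from live to snag
    postfire_pools: CarbonPools
    pmort: float | None = None        # % basal area killed (external index)
    pct_large_dead: float | None = None
    pct_resistant_dead: float | None = None
    stable_carbon: float | None = None

    def __post_init__(self):
        for name in ("pmort", "pct_large_dead", "pct_resistant_dead"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0 or math.isnan(v)):
                raise ValueError(f"{name} = {v} outside [0, 100]")


#: surface pools debited when allocating a wildfire emission
_SURFACE_POOLS = ("litter", "duff", "fwd_1h", "fwd_10h", "fwd_100h",
                  "cwd", "understory")


def scenario_ledger(
    prefire: CarbonPools,
    emission: float,
    killed: float,
    pmort: float | None = None,
    pct_large_dead: float | None = None,
    pct_resistant_dead: float | None = None,
    stable: float | None = None,
) -> ScenarioResult:
    """Post-fire pools from a pre-fire state, an emission, and killed carbon.

    ``emission`` may be given as a magnitude or a negative ledger entry;
    its magnitude is debited proportionally from the combustible surface
    pools.  ``killed`` moves live-tree carbon to the snag pool.  Carbon
    is conserved exactly: pre-fire total = post-fire total + |emission|.
    """
    emis = abs(emission)
    if killed < 0:
        raise ValueError("killed carbon must be >= 0")
    if killed > prefire.live_tree + 1e-9:
        raise ValueError("killed carbon exceeds pre-fire live tree carbon")
    surface_total = sum(getattr(prefire, p) for p in _SURFACE_POOLS)
    if emis > surface_total + 1e-9:
        raise ValueError(
            f"emission {emis:.2f} MgC/ha exceeds combustible surface pools "
            f"({surface_total:.2f} MgC/ha)"
        )
    scale = 0.0 if surface_total == 0 else emis / surface_total
    updates = {p: getattr(prefire, p) * (1.0 - scale) for p in _SURFACE_POOLS}
    post = replace(
        prefire,
        live_tree=prefire.live_tree - killed,
        snag=prefire.snag + killed,
        **updates,
    )
    return ScenarioResult(
        wildfire_emission=emis,
        killed_tree_carbon=killed,
        postfire_pools=post,
        pmort=pmort,
        pct_large_dead=pct_large_dead,
        pct_resistant_dead=pct_resistant_dead,
        stable_carbon=stable,
    )


def with_wildfire_flux(
    flux: dict[int, float], emission: float, year: int = 2020
) -> dict[int, float]:
    """Annual flux series with a wildfire emission charged to one year.

    The convention for folding a single simulated fire into the cost
    series: the emission magnitude is subtracted from that year's flux.
    Feed the result to :func:`firecarbon.ledger.carbon_cost` for the
    "with simulated wildfire" comparison.
    """
    out = dict(flux)
    if year not in out:
        raise KeyError(f"year {year} not in the flux record")
    out[year] = out[year] - abs(emission)
    return out
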