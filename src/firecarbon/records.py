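"""Data model for repeated forest-inventory plots.

The sampling design this package targets is a long-term
Before-After-Control-Impact (BACI) experiment in Sierra Nevada mixed
conifer forest: experimental units carry permanent 0.04-ha circular
plots, each revisited over two decades.  Trees >= 11.4 cm dbh are
censused on the full plot; smaller stems on a nested 0.004-ha subplot
(expanded to the whole plot in the final inventory); shrubs and herbs
by cover class; downed woody fuel along two 11.3-m planar-intercept
transects per plot; litter and duff by depth on those transects; and
mineral soil carbon by core to 15 cm.

Records are plain dataclasses.  Protocol drift across inventory years
(small-tree binning, snag dbh floors, the whole-plot small-tree census)
is carried as per-year :class:`ProtocolFlags` so that downstream
estimators — not the reader — decide comparability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "MAIN_PLOT_HA",
    "SUBPLOT_HA",
    "SMALL_TREE_DBH",
    "TRANSECT_LENGTH_M",
    "STUDY_YEARS",
    "SPECIES",
    "RESISTANT_SPECIES",
    "HARDWOOD_SPECIES",
    "TREATMENTS",
    "ProtocolFlags",
    "TreeRecord",
    "UnderstoryRecord",
    "FuelTransect",
    "SoilSample",
    "PlotInventory",
    "Event",
    "EventSchedule",
    "expansion_factor",
    "consistently_sampled_plots",
    "tree_basal_area_m2",
]

MAIN_PLOT_HA = 0.04
SUBPLOT_HA = 0.004
#: dbh threshold (cm) separating main-plot trees from subplot saplings
SMALL_TREE_DBH = 11.4
TRANSECT_LENGTH_M = 11.3

#: comprehensive + post-fire update inventories
STUDY_YEARS = (2001, 2003, 2009, 2010, 2016, 2017, 2020)

#: the six study species: white fir, incense-cedar, Douglas-fir,
#: ponderosa pine, sugar pine, California black oak
SPECIES = ("ABCO", "CADE", "PSME", "PIPO", "PILA", "QUKE")
#: fire-resistant species (the two pines)
RESISTANT_SPECIES = frozenset({"PIPO", "PILA"})
HARDWOOD_SPECIES = frozenset({"QUKE"})

TREATMENTS = ("Control", "Fire", "Mech", "MechFire")

#: cover-class labels -> midpoint percent cover
COVER_CLASS_MIDPOINT = {"lt5": 2.5, "5to25": 15.0, "25to100": 63.0}


@dataclass(frozen=True)
class ProtocolFlags:
    """Per-year sampling rules that changed over the study.

    small_tree_frame
        ``"subplot"`` (0.004 ha), ``"whole_plot"`` (expanded census),
        or ``"none"`` (update inventory, no small-tree remeasure).
    small_trees_binned
        small trees tallied into 2.54-cm dbh bins instead of measured.
    snag_dbh_floor
        minimum snag dbh recorded that year (cm).
    """

    small_tree_frame: str = "subplot"
    small_trees_binned: bool = False
    snag_dbh_floor: float = SMALL_TREE_DBH


DEFAULT_PROTOCOL = {
    2001: ProtocolFlags(),
    2003: ProtocolFlags(),
    2009: ProtocolFlags(),
    2010: ProtocolFlags(small_tree_frame="none"),
    2016: ProtocolFlags(small_trees_binned=True, snag_dbh_floor=20.5),
    2017: ProtocolFlags(small_tree_frame="none"),
    2020: ProtocolFlags(small_tree_frame="whole_plot"),
}


def protocol_for_year(year: int) -> ProtocolFlags:
    return DEFAULT_PROTOCOL.get(year, ProtocolFlags())


@dataclass
class TreeRecord:
    plot_id: str
    tag: str
    species: str
    dbh: float            # cm
    height: float | None  # m
    status: str = "live"  # live | snag
    crown_class: str = "unknown"
    decay_class: int | None = None
    sample_frame: str = "main_plot"  # main_plot | subplot

    def validate(self) -> list[str]:
        errs = []
        if not self.dbh > 0:
            errs.append(f"tree {self.tag}: dbh must be > 0, got {self.dbh}")
        if self.height is not None and not self.height > 0:
            errs.append(f"tree {self.tag}: height must be > 0, got {self.height}")
        if self.status not in ("live", "snag"):
            errs.append(f"tree {self.tag}: status {self.status!r} not live|snag")
        if self.sample_frame not in ("main_plot", "subplot"):
            errs.append(f"tree {self.tag}: unknown sample_frame {self.sample_frame!r}")
        if self.decay_class is not None and self.decay_class not in (1, 2, 3, 4, 5):
            errs.append(f"tree {self.tag}: decay_class {self.decay_class} not in 1-5")
        return errs


@dataclass
class UnderstoryRecord:
    plot_id: str
    species: str
    cover_class: str            # lt5 | 5to25 | 25to100
    mean_height: float | None = None  # m
    growth_form: str = "shrub"  # shrub | herb

    @property
    def cover_fraction(self) -> float:
        """Midpoint cover of the plot as a fraction (0.025, 0.15, 0.63)."""
        return COVER_CLASS_MIDPOINT[self.cover_class] / 100.0

    def validate(self) -> list[str]:
        errs = []
        if self.cover_class not in COVER_CLASS_MIDPOINT:
            errs.append(f"understory {self.species}: bad cover_class {self.cover_class!r}")
        if self.growth_form not in ("shrub", "herb"):
            errs.append(f"understory {self.species}: bad growth_form {self.growth_form!r}")
        return errs


@dataclass
class FuelTransect:
    """One 11.3-m planar-intercept fuel transect.

    Timelag tallies are intersections within the class-specific sampled
    length: 1-h and 10-h fuels over 0-2 m, 100-h over 0-3 m, and 1000-h
    and larger (pieces > 7.62 cm, diameters recorded individually) over
    the full 11.3 m.  Litter and duff depths are taken at 0.3 and 0.9 m.
    """

    plot_id: str
    azimuth: float
    counts_1h: int
    counts_10h: int
    counts_100h: int
    cwd_diameters: list[float] = field(default_factory=list)  # cm
    litter_depths: tuple[float, float] = (0.0, 0.0)           # cm
    duff_depths: tuple[float, float] = (0.0, 0.0)             # cm

    SAMPLED_LENGTH_M = {"1h": 2.0, "10h": 2.0, "100h": 3.0, "cwd": TRANSECT_LENGTH_M}

    def validate(self) -> list[str]:
        errs = []
        for name in ("counts_1h", "counts_10h", "counts_100h"):
            if getattr(self, name) < 0:
                errs.append(f"transect {self.plot_id}/{self.azimuth}: {name} < 0")
        if any(d <= 7.62 for d in self.cwd_diameters):
            errs.append(
                f"transect {self.plot_id}/{self.azimuth}: cwd piece <= 7.62 cm"
            )
        for d in (*self.litter_depths, *self.duff_depths):
            if d < 0:
                errs.append(f"transect {self.plot_id}/{self.azimuth}: negative depth")
        return errs


@dataclass
class SoilSample:
    plot_id: str
    bulk_density: float  # g/cm^3, fine-fraction basis
    carbon_pct: float    # % of dry mass
    depth_top: float = 0.0
    depth_bottom: float = 15.0

    def validate(self) -> list[str]:
        errs = []
        if not (0 < self.carbon_pct < 60):
            errs.append(f"soil {self.plot_id}: carbon_pct {self.carbon_pct} outside (0, 60)")
        if self.bulk_density <= 0:
            errs.append(f"soil {self.plot_id}: bulk_density must be > 0")
        if (self.depth_top, self.depth_bottom) != (0.0, 15.0):
            errs.append(
                f"soil {self.plot_id}: depth interval "
                f"[{self.depth_top}, {self.depth_bottom}] != [0, 15]"
            )
        return errs


@dataclass
class PlotInventory:
    """One plot at one inventory date."""

    plot_id: str
    unit_id: str
    treatment: str
    year: int
    trees: list[TreeRecord] = field(default_factory=list)
    understory: list[UnderstoryRecord] = field(default_factory=list)
    transects: list[FuelTransect] = field(default_factory=list)
    soil: list[SoilSample] = field(default_factory=list)
    protocol_flags: ProtocolFlags | None = None

    def __post_init__(self):
        if self.protocol_flags is None:
            self.protocol_flags = protocol_for_year(self.year)

    @property
    def live_trees(self) -> list[TreeRecord]:
        return [t for t in self.trees if t.status == "live"]

    @property
    def snags(self) -> list[TreeRecord]:
        return [t for t in self.trees if t.status == "snag"]

    def validate(self) -> list[str]:
        errs = []
        if self.treatment not in TREATMENTS:
            errs.append(f"plot {self.plot_id}: unknown treatment {self.treatment!r}")
        if len(self.transects) not in (0, 2):
            errs.append(
                f"plot {self.plot_id}: expected 2 fuel transects, got {len(self.transects)}"
            )
        frame = self.protocol_flags.small_tree_frame
        for t in self.trees:
            errs.extend(t.validate())
            if t.dbh <= 0:
                continue
            if t.sample_frame == "subplot" and t.dbh >= SMALL_TREE_DBH:
                errs.append(f"tree {t.tag}: subplot record with dbh >= {SMALL_TREE_DBH} cm")
            if (
                t.sample_frame == "main_plot"
                and t.dbh < SMALL_TREE_DBH
                and frame != "whole_plot"
            ):
                errs.append(
                    f"tree {t.tag}: main-plot record with dbh < {SMALL_TREE_DBH} cm "
                    "outside a whole-plot census year"
                )
        for rec in self.understory:
            errs.extend(rec.validate())
        for tr in self.transects:
            errs.extend(tr.validate())
        for s in self.soil:
            errs.extend(s.validate())
        return errs


@dataclass(frozen=True)
class Event:
    year: int
    kind: str  # rx_fire | thin | mastication | salvage | wildfire_sim
    parameters: dict = field(default_factory=dict)


KNOWN_EVENT_KINDS = {"rx_fire", "thin", "mastication", "salvage", "wildfire_sim"}

#: treatment calendars: Fire burned 2002/2009/2017; Mech thinned 2001 and
#: 2019 with mastication 2001/2017; Mech+Fire thinned/masticated 2001 then
#: burned 2002, masticated 2017, burned 2018, salvaged 2019
TREATMENT_CALENDAR = {
    "Control": (),
    "Fire": (("rx_fire", 2002), ("rx_fire", 2009), ("rx_fire", 2017)),
    "Mech": (
        ("thin", 2001),
        ("mastication", 2001),
        ("mastication", 2017),
        ("thin", 2019),
    ),
    "MechFire": (
        ("thin", 2001),
        ("mastication", 2001),
        ("rx_fire", 2002),
        ("mastication", 2017),
        ("rx_fire", 2018),
        ("salvage", 2019),
    ),
}


@dataclass
class EventSchedule:
    unit_id: str
    treatment: str
    events: list[Event] = field(default_factory=list)

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.year)

    def validate(self) -> list[str]:
        errs = []
        years = [e.year for e in self.events]
        if years != sorted(years):
            errs.append(f"unit {self.unit_id}: events not ordered by year")
        for e in self.events:
            if e.kind not in KNOWN_EVENT_KINDS:
                errs.append(f"unit {self.unit_id}: unknown event kind {e.kind!r}")
        expected = TREATMENT_CALENDAR.get(self.treatment)
        if expected is not None:
            got = sorted((e.kind, e.year) for e in self.events)
            if sorted(expected) != got:
                errs.append(
                    f"unit {self.unit_id}: events {got} inconsistent with "
                    f"{self.treatment} calendar {sorted(expected)}"
                )
        return errs


def expansion_factor(record: TreeRecord, inventory: PlotInventory) -> float:
    """Per-hectare expansion multiplier for one tree record.

    Main-plot records expand by 1/0.04 = 25 ha^-1, subplot saplings by
    1/0.004 = 250 ha^-1.  In the whole-plot small-tree census year the
    small trees are main-plot records and expand by 25.
    """
    if record.sample_frame == "main_plot":
        return 1.0 / MAIN_PLOT_HA
    if record.sample_frame == "subplot":
        return 1.0 / SUBPLOT_HA
    raise ValueError(f"unknown sample_frame {record.sample_frame!r}")


def consistently_sampled_plots(
    inventories: list[PlotInventory], years: set[int]
) -> set[str]:
    """Plots measured at every required year.

    Repeated-inventory stock change is only meaningful on a constant plot
    set; plots skipped or lost in any required inventory are dropped, and
    the returned set size is the analysis N.
    """
    years = set(years)
    by_plot: dict[str, set[int]] = {}
    for inv in inventories:
        by_plot.setdefault(inv.plot_id, set()).add(inv.year)
    keep = {pid for pid, ys in by_plot.items() if years <= ys}
    if not keep:
        import warnings

        warnings.warn("no plot was sampled in every required year", stacklevel=2)
    return keep


def tree_basal_area_m2(dbh_cm: float) -> float:
    """Cross-sectional area at breast height of one stem, m^2."""
    import math

    return math.pi * (dbh_cm / 200.0) ** 2
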