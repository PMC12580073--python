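"""CSV/YAML input and output for plot inventories and event schedules.

The on-disk layout is one UTF-8, comma-delimited file per record
family, keyed by ``plot_id`` + ``year``:

- ``plots.csv`` — the inventory index (plot_id, unit_id, treatment,
  year); a plot-year appears here even if it has no tree records.
- ``trees.csv`` — tree and snag records; a ``dbh_bin_low`` column may
  replace ``dbh`` for tally-binned small trees (2.54-cm bins), which
  are assigned a dbh at the bin midpoint by default, or uniformly at
  random within the bin when a seed is supplied.
- ``understory.csv``, ``transects.csv``, ``soil.csv``.

Rows that violate record invariants are collected into an error report
rather than silently dropped; a missing mandatory column is a hard
failure naming the column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import (
    SPECIES,
    Event,
    EventSchedule,
    FuelTransect,
    PlotInventory,
    SoilSample,
    TreeRecord,
    UnderstoryRecord,
)

__all__ = [
    "SchemaError",
    "RowError",
    "ReadResult",
    "read_inventory",
    "write_inventory",
    "assign_binned_dbh",
    "read_events",
    "write_events",
    "DBH_BIN_WIDTH_CM",
]

DBH_BIN_WIDTH_CM = 2.54

FILES = {
    "plots": ("plot_id", "unit_id", "treatment", "year"),
    "trees": ("plot_id", "year", "tag", "species", "dbh", "height", "status",
              "crown_class", "decay_class", "sample_frame"),
    "understory": ("plot_id", "year", "species", "cover_class", "mean_height",
                   "growth_form"),
    "transects": ("plot_id", "year", "azimuth", "counts_1h", "counts_10h",
                  "counts_100h", "cwd_diameters", "litter_depth_030",
                  "litter_depth_090", "duff_depth_030", "duff_depth_090"),
    "soil": ("plot_id", "year", "bulk_density", "carbon_pct", "depth_top",
             "depth_bottom"),
}

#: columns that may legitimately be absent
OPTIONAL_COLUMNS = {"trees": {"dbh_bin_low"}}


class SchemaError(ValueError):
    """A mandatory column is missing or a file cannot be parsed."""


@dataclass(frozen=True)
class RowError:
    file: str
    row: int
    message: str


@dataclass
class ReadResult:
    inventories: list[PlotInventory]
    errors: list[RowError] = field(default_factory=list)

    def __iter__(self):
        return iter(self.inventories)

    def __len__(self):
        return len(self.inventories)


def _load_csv(directory: Path, name: str, required: bool = True) -> pd.DataFrame | None:
    path = directory / f"{name}.csv"
    if not path.exists():
        if required:
            raise SchemaError(f"missing input file {path.name}")
        return None
    df = pd.read_csv(path)
    missing = set(FILES[name]) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s) {sorted(missing)}"
        )
    return df


def assign_binned_dbh(
    bin_low: float,
    width: float = DBH_BIN_WIDTH_CM,
    mode: str = "midpoint",
    rng: np.random.Generator | None = None,
) -> float:
    """dbh for a tally-binned small tree.

    ``midpoint`` is deterministic; ``uniform`` draws within the bin and
    requires a generator so the draw is seeded.
    """
    if mode == "midpoint":
        return bin_low + width / 2.0
    if mode == "uniform":
        if rng is None:
            raise ValueError("uniform bin assignment requires a seeded generator")
        return float(rng.uniform(bin_low, bin_low + width))
    raise ValueError(f"unknown bin-assignment mode {mode!r}")


def _opt(value, cast=float):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return cast(value)


def read_inventory(
    directory: str | Path,
    binned_dbh_mode: str = "midpoint",
    seed: int | None = None,
) -> ReadResult:
    """Read a plot-inventory directory into validated records."""
    directory = Path(directory)
    plots_df = _load_csv(directory, "plots")
    trees_df = _load_csv(directory, "trees", required=False)
    under_df = _load_csv(directory, "understory", required=False)
    trans_df = _load_csv(directory, "transects", required=False)
    soil_df = _load_csv(directory, "soil", required=False)

    rng = np.random.default_rng(seed) if binned_dbh_mode == "uniform" else None
    errors: list[RowError] = []
    unknown_species: set[str] = set()

    def species_code(raw) -> str:
        sp = str(raw).strip().upper()
        if sp in SPECIES or sp == "OTHER":
            return sp
        unknown_species.add(sp)
        return "OTHER"

    inventories: dict[tuple[str, int], PlotInventory] = {}
    for _, row in plots_df.iterrows():
        key = (str(row["plot_id"]), int(row["year"]))
        inventories[key] = PlotInventory(
            plot_id=key[0],
            unit_id=str(row["unit_id"]),
            treatment=str(row["treatment"]),
            year=key[1],
        )

    def target(row, file, idx) -> PlotInventory | None:
        key = (str(row["plot_id"]), int(row["year"]))
        inv = inventories.get(key)
        if inv is None:
            errors.append(RowError(file, idx, f"plot-year {key} not in plots.csv"))
        return inv

    if trees_df is not None:
        has_bins = "dbh_bin_low" in trees_df.columns
        for idx, row in trees_df.iterrows():
            inv = target(row, "trees.csv", idx)
            if inv is None:
                continue
            dbh = _opt(row["dbh"])
            if dbh is None and has_bins and _opt(row["dbh_bin_low"]) is not None:
                dbh = assign_binned_dbh(
                    float(row["dbh_bin_low"]), mode=binned_dbh_mode, rng=rng
                )
            rec = TreeRecord(
                plot_id=inv.plot_id,
                tag=str(row["tag"]),
                species=species_code(row["species"]),
                dbh=dbh if dbh is not None else -1.0,
                height=_opt(row["height"]),
                status=str(row["status"]),
                crown_class=str(row["crown_class"]),
                decay_class=_opt(row["decay_class"], int),
                sample_frame=str(row["sample_frame"]),
            )
            errs = rec.validate()
            if errs:
                errors.extend(RowError("trees.csv", idx, e) for e in errs)
            else:
                inv.trees.append(rec)

    if under_df is not None:
        for idx, row in under_df.iterrows():
            inv = target(row, "understory.csv", idx)
            if inv is None:
                continue
            rec = UnderstoryRecord(
                plot_id=inv.plot_id,
                species=str(row["species"]).strip().upper(),
                cover_class=str(row["cover_class"]),
                mean_height=_opt(row["mean_height"]),
                growth_form=str(row["growth_form"]),
            )
            errs = rec.validate()
            if errs:
                errors.extend(RowError("understory.csv", idx, e) for e in errs)
            else:
                inv.understory.append(rec)

    if trans_df is not None:
        for idx, row in trans_df.iterrows():
            inv = target(row, "transects.csv", idx)
            if inv is None:
                continue
            raw = row["cwd_diameters"]
            if isinstance(raw, float) and np.isnan(raw):
                diams: list[float] = []
            else:
                diams = [float(x) for x in str(raw).split(";") if x.strip()]
            rec = FuelTransect(
                plot_id=inv.plot_id,
                azimuth=float(row["azimuth"]),
                counts_1h=int(row["counts_1h"]),
                counts_10h=int(row["counts_10h"]),
                counts_100h=int(row["counts_100h"]),
                cwd_diameters=diams,
                litter_depths=(float(row["litter_depth_030"]),
                               float(row["litter_depth_090"])),
                duff_depths=(float(row["duff_depth_030"]),
                             float(row["duff_depth_090"])),
            )
            errs = rec.validate()
            if errs:
                errors.extend(RowError("transects.csv", idx, e) for e in errs)
            else:
                inv.transects.append(rec)

    if soil_df is not None:
        for idx, row in soil_df.iterrows():
            inv = target(row, "soil.csv", idx)
            if inv is None:
                continue
            rec = SoilSample(
                plot_id=inv.plot_id,
                bulk_density=float(row["bulk_density"]),
                carbon_pct=float(row["carbon_pct"]),
                depth_top=float(row["depth_top"]),
                depth_bottom=float(row["depth_bottom"]),
            )
            errs = rec.validate()
            if errs:
                errors.extend(RowError("soil.csv", idx, e) for e in errs)
            else:
                inv.soil.append(rec)

    if unknown_species:
        warnings.warn(
            f"unknown species code(s) {sorted(unknown_species)} assigned to 'OTHER'",
            stacklevel=2,
        )
    out = sorted(inventories.values(), key=lambda i: (i.plot_id, i.year))
    return ReadResult(inventories=out, errors=errors)


def write_inventory(inventories: list[PlotInventory], directory: str | Path) -> None:
    """Write inventories to the one-file-per-family CSV layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    plots, trees, under, trans, soil = [], [], [], [], []
    for inv in inventories:
        plots.append(
            dict(plot_id=inv.plot_id, unit_id=inv.unit_id,
                 treatment=inv.treatment, year=inv.year)
        )
        for t in inv.trees:
            trees.append(
                dict(plot_id=inv.plot_id, year=inv.year, tag=t.tag,
                     species=t.species, dbh=t.dbh, height=t.height,
                     status=t.status, crown_class=t.crown_class,
                     decay_class=t.decay_class, sample_frame=t.sample_frame)
            )
        for u in inv.understory:
            under.append(
                dict(plot_id=inv.plot_id, year=inv.year, species=u.species,
                     cover_class=u.cover_class, mean_height=u.mean_height,
                     growth_form=u.growth_form)
            )
        for tr in inv.transects:
            trans.append(
                dict(plot_id=inv.plot_id, year=inv.year, azimuth=tr.azimuth,
                     counts_1h=tr.counts_1h, counts_10h=tr.counts_10h,
                     counts_100h=tr.counts_100h,
                     cwd_diameters=";".join(repr(d) for d in tr.cwd_diameters),
                     litter_depth_030=tr.litter_depths[0],
                     litter_depth_090=tr.litter_depths[1],
                     duff_depth_030=tr.duff_depths[0],
                     duff_depth_090=tr.duff_depths[1])
            )
        for s in inv.soil:
            soil.append(
                dict(plot_id=inv.plot_id, year=inv.year,
                     bulk_density=s.bulk_density, carbon_pct=s.carbon_pct,
                     depth_top=s.depth_top, depth_bottom=s.depth_bottom)
            )

    for name, rows in (("plots", plots), ("trees", trees), ("understory", under),
                       ("transects", trans), ("soil", soil)):
        cols = list(FILES[name])
        pd.DataFrame(rows, columns=cols).to_csv(directory / f"{name}.csv", index=False)


def read_events(path: str | Path) -> list[EventSchedule]:
    """Load per-unit event schedules from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    schedules = []
    for unit_id, spec in data.items():
        events = [
            Event(year=int(e["year"]), kind=str(e["kind"]),
                  parameters=dict(e.get("parameters") or {}))
            for e in spec.get("events", [])
        ]
        schedules.append(
            EventSchedule(unit_id=str(unit_id), treatment=str(spec["treatment"]),
                          events=events)
        )
    return schedules


def write_events(schedules: list[EventSchedule], path: str | Path) -> None:
    data = {
        s.unit_id: {
            "treatment": s.treatment,
            "events": [
                {"year": e.year, "kind": e.kind, "parameters": dict(e.parameters)}
                for e in s.events
            ],
        }
        for s in schedules
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
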