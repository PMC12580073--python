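"""Coefficient tables for biomass, volume, and fuel-load estimation.

Regional tree biomass/volume equations and species-specific
planar-intercept fuel coefficients are published externally and differ
by region; this package keeps them *pluggable*.  :class:`AllometryTable`
holds everything species-specific, and :func:`default_table` ships a
documented, literature-plausible default set for the six Sierra Nevada
mixed-conifer study species (defaults, replaceable — swap in regional
coefficients for real analyses).  :class:`ConversionConstants` holds the
fixed biomass-to-carbon ratios of the accounting method itself.

Default wood biomass is a power law ``wood_kg = a * dbh^b * height^c``
(dbh in cm, height in m) for stem + bark + branches; foliage is a
species ratio of wood biomass.  Default merchantable stem volume uses a
constant form factor on the breast-height cylinder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .records import SPECIES

__all__ = [
    "FuelCoefficients",
    "AllometryTable",
    "ConversionConstants",
    "default_table",
    "default_constants",
    "TIMELAG_CLASSES",
]

#: downed woody fuel timelag classes handled by the planar-intercept method
TIMELAG_CLASSES = ("1h", "10h", "100h", "cwd")


@dataclass(frozen=True)
class FuelCoefficients:
    """Per-species planar-intercept coefficients.

    squared_mean_diameter
        mean of squared piece diameters by timelag class, cm^2 (the cwd
        entry is unused: coarse pieces are measured individually).
    secant_of_lean
        correction for non-horizontal pieces, >= 1.
    specific_gravity
        oven-dry wood density by class, g/cm^3.
    """

    squared_mean_diameter: dict[str, float]
    secant_of_lean: dict[str, float]
    specific_gravity: dict[str, float]

    def validate(self) -> None:
        for cls in TIMELAG_CLASSES:
            if self.secant_of_lean[cls] < 1.0:
                raise ValueError(f"secant of lean < 1 for class {cls}")
            if self.specific_gravity[cls] <= 0:
                raise ValueError(f"non-positive specific gravity for class {cls}")
        for cls in ("1h", "10h", "100h"):
            if self.squared_mean_diameter[cls] <= 0:
                raise ValueError(f"non-positive squared mean diameter for {cls}")


@dataclass
class AllometryTable:
    """Pluggable species-level coefficients.

    wood
        species -> (a, b, c) of ``wood_kg = a * dbh^b * height^c``.
    foliage_ratio
        species -> foliage biomass as a fraction of wood biomass.
    wood_density
        species -> oven-dry wood density, Mg/m^3.
    fuel
        species -> :class:`FuelCoefficients`.
    stem_form_factor
        merchantable stem volume = form factor x basal area x height.
    shrub
        species (or ``"DEFAULT"``) -> (mean crown area m^2,
        per-individual biomass kg).
    herb_coefficient
        herb carbon at 100% cover, MgC/ha (linear in cover).
    """

    wood: dict[str, tuple[float, float, float]]
    foliage_ratio: dict[str, float]
    wood_density: dict[str, float]
    fuel: dict[str, FuelCoefficients]
    stem_form_factor: float = 0.42
    shrub: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"DEFAULT": (1.5, 2.0), "CEIN": (1.5, 2.0)}
    )
    herb_coefficient: float = 0.8

    def require_species(self, species: str, mapping: dict, what: str):
        try:
            return mapping[species]
        except KeyError:
            raise KeyError(f"species {species!r} absent from {what} table") from None

    def shrub_coefficients(self, species: str) -> tuple[float, float]:
        """Species entry, falling back to the genus-level default."""
        if species in self.shrub:
            return self.shrub[species]
        import warnings

        warnings.warn(
            f"no shrub allometry for {species!r}; using genus-level default",
            stacklevel=2,
        )
        return self.shrub["DEFAULT"]

    def validate(self) -> None:
        for sp in SPECIES:
            for mapping, what in (
                (self.wood, "wood"),
                (self.foliage_ratio, "foliage"),
                (self.wood_density, "density"),
                (self.fuel, "fuel"),
            ):
                if sp not in mapping:
                    raise ValueError(f"study species {sp} missing from {what} table")
        for coeffs in self.wood.values():
            if any(c <= 0 for c in coeffs):
                raise ValueError("wood-biomass coefficients must be > 0")
        for fc in self.fuel.values():
            fc.validate()


@dataclass(frozen=True)
class ConversionConstants:
    """Fixed biomass-to-carbon conversions of the accounting method.

    Carbon fractions: live tree 0.48 (IPCC); snags reduced by a 0.88
    live-to-dead biomass ratio then a 0.51 carbon fraction (decay class
    2, applied to all snags); shrubs 0.49; downed wood 0.5; litter
    0.463; duff 0.362.  Depth-to-biomass coefficients convert mean
    forest-floor depth (cm) to biomass density (Mg/ha).
    """

    c_tree: float = 0.48
    snag_dead_ratio: float = 0.88
    c_snag: float = 0.51
    c_shrub: float = 0.49
    c_wd: float = 0.5
    c_litter: float = 0.463
    c_duff: float = 0.362
    litter_depth_to_biomass: float = 2.5  # Mg/ha per cm
    duff_depth_to_biomass: float = 8.0    # Mg/ha per cm
    #: transect slope correction (horizontal transects -> 1.0)
    slope_correction: float = 1.0

    def __post_init__(self):
        for name in ("c_tree", "snag_dead_ratio", "c_snag", "c_shrub",
                     "c_wd", "c_litter", "c_duff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} = {v} outside (0, 1)")
        for name in ("litter_depth_to_biomass", "duff_depth_to_biomass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# Default per-species coefficients (defaults, replaceable).  Wood power
# laws give ~1.2 Mg aboveground wood for a 50-cm, 30-m conifer; densities
# and fuel coefficients are in the range published for Sierra Nevada
# species, lighter/finer for pines, denser for the oak.
_WOOD = {
    "ABCO": (0.038, 1.80, 1.00),
    "CADE": (0.034, 1.80, 1.00),
    "PSME": (0.040, 1.82, 1.00),
    "PIPO": (0.036, 1.80, 1.00),
    "PILA": (0.037, 1.78, 1.00),
    "QUKE": (0.055, 1.85, 0.90),
}
_FOLIAGE = {"ABCO": 0.10, "CADE": 0.09, "PSME": 0.08,
            "PIPO": 0.06, "PILA": 0.07, "QUKE": 0.04}
_DENSITY = {"ABCO": 0.37, "CADE": 0.35, "PSME": 0.45,
            "PIPO": 0.38, "PILA": 0.34, "QUKE": 0.51}

_FUEL_QMD = {  # cm^2 by timelag class
    "ABCO": {"1h": 0.13, "10h": 1.44, "100h": 20.6, "cwd": 0.0},
    "CADE": {"1h": 0.11, "10h": 1.28, "100h": 18.8, "cwd": 0.0},
    "PSME": {"1h": 0.15, "10h": 1.56, "100h": 22.9, "cwd": 0.0},
    "PIPO": {"1h": 0.17, "10h": 1.69, "100h": 24.2, "cwd": 0.0},
    "PILA": {"1h": 0.16, "10h": 1.60, "100h": 23.0, "cwd": 0.0},
    "QUKE": {"1h": 0.12, "10h": 1.37, "100h": 19.7, "cwd": 0.0},
}
_FUEL_SEC = {sp: {"1h": 1.03, "10h": 1.02, "100h": 1.02, "cwd": 1.02}
             for sp in SPECIES}
_FUEL_SG = {
    "ABCO": {"1h": 0.53, "10h": 0.48, "100h": 0.43, "cwd": 0.36},
    "CADE": {"1h": 0.52, "10h": 0.46, "100h": 0.41, "cwd": 0.34},
    "PSME": {"1h": 0.57, "10h": 0.52, "100h": 0.47, "cwd": 0.40},
    "PIPO": {"1h": 0.55, "10h": 0.49, "100h": 0.44, "cwd": 0.37},
    "PILA": {"1h": 0.52, "10h": 0.47, "100h": 0.42, "cwd": 0.35},
    "QUKE": {"1h": 0.60, "10h": 0.56, "100h": 0.52, "cwd": 0.45},
}


def default_table() -> AllometryTable:
    """The shipped default coefficient set (replaceable).

    Includes an ``"OTHER"`` entry (all-species mean) so records with
    unrecognized species codes remain estimable after the reader's
    fallback assignment.
    """
    def _mean(d: dict[str, float]) -> float:
        return sum(d.values()) / len(d)

    wood = dict(_WOOD)
    wood["OTHER"] = tuple(
        sum(v[i] for v in _WOOD.values()) / len(_WOOD) for i in range(3)
    )
    fuel = {
        sp: FuelCoefficients(
            squared_mean_diameter=dict(_FUEL_QMD[sp]),
            secant_of_lean=dict(_FUEL_SEC[sp]),
            specific_gravity=dict(_FUEL_SG[sp]),
        )
        for sp in SPECIES
    }
    fuel["OTHER"] = FuelCoefficients(
        squared_mean_diameter={
            cls: _mean({sp: _FUEL_QMD[sp][cls] for sp in SPECIES})
            for cls in TIMELAG_CLASSES
        },
        secant_of_lean={
            cls: _mean({sp: _FUEL_SEC[sp][cls] for sp in SPECIES})
            for cls in TIMELAG_CLASSES
        },
        specific_gravity={
            cls: _mean({sp: _FUEL_SG[sp][cls] for sp in SPECIES})
            for cls in TIMELAG_CLASSES
        },
    )
    table = AllometryTable(
        wood=wood,
        foliage_ratio={**_FOLIAGE, "OTHER": _mean(_FOLIAGE)},
        wood_density={**_DENSITY, "OTHER": _mean(_DENSITY)},
        fuel=fuel,
    )
    table.validate()
    return table


def default_constants() -> ConversionConstants:
    return ConversionConstants()


def constants_from_yaml(path) -> ConversionConstants:
    """Load conversion-constant overrides from a YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return replace(ConversionConstants(), **data)
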