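"""Interval recovery rates, annual mortality, and BACI contrasts.

Recovery/accumulation rates are simple difference quotients of grouped
pool carbon over the inter-fire intervals (for burned units each
interval starts immediately after a fire and runs to the next one; the
untreated controls use the matching calendar intervals).  The
treatment-effect machinery is a transparent difference-in-differences
contrast with a seeded bootstrap percentile interval over plots — mixed
-model inference is deliberately out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PoolGroup",
    "LIVE_VEGETATION",
    "SURFACE_FUEL",
    "FIRE_INTERVALS",
    "CONTROL_INTERVALS",
    "IntervalRate",
    "interval_rate",
    "annual_mortality_rate",
    "BaciResult",
    "baci_contrast",
]


@dataclass(frozen=True)
class PoolGroup:
    name: str
    members: tuple[str, ...]

    def group_total(self, pools) -> float:
        return sum(getattr(pools, m) for m in self.members)


#: aboveground live vegetation: tree + shrub + herb (understory pool)
LIVE_VEGETATION = PoolGroup("live_vegetation", ("live_tree", "understory"))
#: fine surface fuel: litter plus the 1-, 10-, and 100-h classes
SURFACE_FUEL = PoolGroup("surface_fuel", ("litter", "fwd_1h", "fwd_10h", "fwd_100h"))

#: post-fire recovery periods for burned units (1st, 2nd, 3rd)
FIRE_INTERVALS = ((2003, 2009), (2010, 2016), (2017, 2020))
#: matching accumulation periods in the controls
CONTROL_INTERVALS = ((2003, 2009), (2009, 2016), (2016, 2020))


@dataclass(frozen=True)
class IntervalRate:
    plot_id: str
    group: str
    interval_label: str  # 1st | 2nd | 3rd
    rate: float          # MgC/ha/yr


def interval_rate(
    series: dict[int, float] | list[tuple[int, float]],
    interval: tuple[int, int],
) -> float:
    """Annual rate of change of group carbon over one interval, MgC/ha/yr."""
    if not isinstance(series, dict):
        series = dict(series)
    y0, y1 = interval
    if y1 <= y0:
        raise ValueError("interval must have y1 > y0")
    try:
        c0, c1 = series[y0], series[y1]
    except KeyError as err:
        raise KeyError(f"year {err} missing from the series") from None
    return (c1 - c0) / (y1 - y0)


def annual_mortality_rate(
    n_initial: int, n_survivors: int, years: float, convention: str = "compound"
) -> float:
    """Annual stem mortality rate, %/yr.

    ``compound`` (default): 1 - (survivors/initial)^(1/years); ``simple``
    divides the fractional loss by the number of years.
    """
    if n_initial <= 0:
        raise ValueError("need at least one initial stem")
    if not 0 <= n_survivors <= n_initial:
        raise ValueError("survivors must be between 0 and the initial count")
    if years <= 0:
        raise ValueError("years must be > 0")
    frac = n_survivors / n_initial
    if convention == "compound":
        return 100.0 * (1.0 - frac ** (1.0 / years))
    if convention == "simple":
        return 100.0 * (1.0 - frac) / years
    raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class BaciResult:
    """Difference-in-differences effect with a bootstrap percentile CI."""

    effect: float
    ci_low: float
    ci_high: float
    n_treated: int
    n_control: int
    n_boot: int

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def baci_contrast(
    treated: "np.ndarray | list[float]",
    control: "np.ndarray | list[float]",
    n_boot: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> BaciResult:
    """Before-after-control-impact contrast on plot-level deltas.

    ``treated`` and ``control`` are per-plot before-to-after changes;
    the effect is mean(treated) - mean(control), with a percentile
    bootstrap CI from resampling plots within each group.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("both groups need at least one plot")
    effect = float(treated.mean() - control.mean())
    rng = np.random.default_rng(seed)
    ti = rng.integers(0, treated.size, size=(n_boot, treated.size))
    ci_ = rng.integers(0, control.size, size=(n_boot, control.size))
    boots = treated[ti].mean(axis=1) - control[ci_].mean(axis=1)
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BaciResult(
        effect=effect,
        ci_low=float(lo),
        ci_high=float(hi),
        n_treated=int(treated.size),
        n_control=int(control.size),
        n_boot=n_boot,
    )
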