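# Methods

This note documents the accounting model, the estimator conventions,
the synthetic-data generator, and the design choices that were
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The accounting model

The package uses a stock-change framework over a repeated-inventory
record (2001–2020 by default, 19 years). *Total measured carbon* is
the sum of the field-measured pools: aboveground live tree, snag,
understory (shrub + herb), fine woody debris by timelag class (1-h,
10-h, 100-h), coarse woody debris (1000-h and larger), litter, duff,
and mineral soil carbon in the 0–15 cm layer. The ledger identities
are

- NECB = total measured carbon at the end − at the start;
- NEP = NECB − fire emission − wood removals,

with emissions and removals stored as **negative** entries so exported
carbon adds back into productivity. This sign convention reproduces
published ledger tables literally and is enforced at construction of
`FluxLedger`.

Analyses of a repeated design use only plots measured at every
required inventory (`consistently_sampled_plots`); the surviving set
size is the analysis N. Mixing plot sets across years would confound
treatment effects with sampling effects.

## Pool estimators

**Trees.** Default aboveground wood biomass (stem + bark + branch) is
a per-species power law `wood_kg = a·dbh^b·height^c` with foliage as a
species ratio of wood; carbon at 0.48. These default curves are
literature-plausible stand-ins for regional biomass equations, which
are published externally — `AllometryTable` is pluggable and real
analyses should substitute regional coefficients. No test or
acceptance value depends on the default numbers, only on the formula
structure (monotonicity, linearity, closed-form agreement).

**Snags.** Live-equivalent wood biomass reduced by the 0.88
live-to-dead ratio, carbon at 0.51. The decay-class-2 ratios are
applied to snags of *all* decay classes, matching the field protocol's
treatment of pre-2016 snags without recorded decay state; this likely
overestimates old snags, but snag carbon is a small pool.

**Understory.** Shrub cover classes (<5%, 5–25%, 25–100%) are read as
midpoints 2.5%, 15%, 63%; covered area is converted to a count of
average-sized individuals via mean crown area, times a per-individual
allometric biomass, carbon at 0.49. Herb carbon is linear in summed
cover with a configurable coefficient (default 0.8 MgC/ha at full
cover), since the underlying cover-to-carbon method is external.

**Downed wood.** Brown's planar-intercept method on two 11.3-m
transects per plot, with class-specific sampled lengths (2 m for 1-h
and 10-h, 3 m for 100-h, 11.3 m for coarse pieces, which are measured
individually):

    load [Mg/ha] = (π²/8) · Σd² [cm²] · sec(lean) · SG [g/cm³] · slope / L [m]

Per-plot coefficients (squared mean diameter, secant of lean, specific
gravity) are basal-area-weighted composites of the species
coefficients of the live trees present; a treeless plot falls back to
an equal-weight mean. Transects are assumed horizontal (slope
correction 1.0, configurable). The formula is verified in the test
suite against an independently derived SI-unit oracle on 1,000 seeded
random transects.

**Litter, duff, soil.** Mean transect depth × a depth-to-biomass
coefficient (defaults 2.5 and 8.0 Mg/ha per cm — the published
regression coefficients are not printed, so these are configurable
constants), carbon at 0.463 (litter) and 0.362 (duff). Soil:
BD [g/cm³] × 15 cm × %C/100 × 100 → MgC/ha, averaged over plot cores;
only the 0–15 cm layer is in scope.

**Expansion factors** are exact plot-area reciprocals: 25/ha for the
0.04-ha main plot, 250/ha for the 0.004-ha sapling subplot; the 2020
whole-plot small-tree census expands at 25/ha. Protocol drift (2016
small-tree binning with midpoint or seeded-uniform dbh assignment,
2016's 20.5-cm snag floor) travels as per-year protocol flags so the
estimation layer, not the reader, decides comparability. How the 2016
snag floor should be reconciled in stock change is not specified by
the source protocol; the flags plus the consistent-plot filter are the
hook for a user-chosen rule.

## Wood products

Conifers above 22.9 cm dbh yield sawlogs (0.3-m stump to 15.2-cm
top); hardwoods above 27.9 cm yield fuelwood (immediate emission).
Default merchantable volume is a form-factor 0.42 on the
breast-height cylinder — again a documented stand-in for regional
volume equations. Sawlog carbon splits: LLP = 0.676 × 0.95 of sawlog
carbon, kerf emission = 0.224, with the remainder (mill residue plus
the fossil-fuel deduction) as other residue. Tops and limbs stay in
the field as downed wood for a first-entry harvest and are hauled and
burned for a second-entry harvest (`tops_fate`).

## Carbon cost

Stock changes between inventories are linearly interpolated into
constant annual fluxes, which telescope exactly back to NECB. The
annual cost of a treatment is control flux minus treatment flux with
the LLP of each harvest credited in the harvest year (a harvest in the
base year is credited to the first cost year). Discounting is
`(1+r)^−(t−base_year)` at r = 0.04, base 2001, so a year-2002 delta is
divided by 1.04 — "start-year equivalent" costs. The exponent
convention is configurable; r = 0 reduces to the plain sum. Costs of a
single simulated wildfire can be folded in by charging the emission to
its year (`with_wildfire_flux`); that convention is a package choice
and is deliberately excluded from any quantitative check.

## Wildfire scenario

Fire behavior and first-order fire effects are out of scope: wildfire
emissions and species-by-size mortality schedules are *inputs* (from
external simulators, or from a documented logistic stand-in whose kill
probability declines with dbh). The scenario ledger moves killed
carbon from live tree to snag, debits the emission proportionally from
the combustible surface pools, and conserves carbon exactly:
pre-fire total = post-fire total + emission. Mortality is applied as a
deterministic expectation (each tree's carbon × its class kill
fraction), so killed + surviving carbon reproduces the pre-fire pool
with no rounding to whole stems. Thresholds: "large" trees at
76.2 cm dbh, "stable" carbon (large fire-resistant pines) at 72.6 cm —
both configurable, with the two defaults anchored to the definitions
they serve.

## Recovery and BACI

Recovery/accumulation rates are difference quotients of grouped pools
(live vegetation = live tree + understory; fine surface fuel = litter
+ 1-h + 10-h + 100-h) over inter-fire intervals: 2003–2009, 2010–2016,
2017–2020 for burned units, and 2003–2009, 2009–2016, 2016–2020 for
controls. Annual tree mortality uses the compound convention
`1 − (survivors/initial)^(1/years)` (simple division is exposed as an
option; the convention is not dictated by the source protocol).

The treatment-effect machinery is a transparent difference-in-
differences: effect = mean(treated Δ) − mean(control Δ), with a seeded
percentile bootstrap over plots. Mixed-model inference (random unit
effects, Beta GLMMs, zero-inflation selection) is deliberately out of
scope — it is routine statistical machinery, not the accounting this
package exists for, and effect directions remain checkable without it.

## The synthetic-data generator

`SimConfig`/`generate_experiment` emulate the study conditions: 12
units × 20 plots (0.04-ha, with 0.004-ha sapling subplots), 4
treatments × 3 replicates, inventories at 2001/2003/2009/2010/2016/
2017/2020, six-species composition, thinning to a 28–34 m²/ha residual
basal area (target 31), mastication of 90% of stems below 25 cm dbh,
prescribed-fire consumption fractions per pool, and burn/harvest
calendars per treatment (burns 2002/2009/2017 for fire-only; thin +
mastication 2001, mastication 2017, thin 2019 for mechanical-only;
thin/mastication/burn 2001–2002, mastication/burn 2017–2018 and 2019
salvage for the combination).

Process defaults (chosen once as field-plausible values, documented
here, not fitted): pre-treatment density 1100 stems/ha with Weibull
dbh (shape 1.4, scale 20 cm) giving unit-mean basal areas in a
35–62 m²/ha comparability band; saturating height curve (asymptote
48 m); annual dbh increment N(0.35, 0.15) cm clipped at zero;
background mortality 1.2%/yr; snag fall 8%/yr into coarse wood;
litterfall 1.4 MgC/ha/yr with first-order decay (litter 0.12/yr, 40%
routed to duff; duff 0.03; fine wood 0.06; coarse wood 0.025/yr);
prescribed-fire kill logistic (severity 0.9, midpoint 14 cm, scale
7 cm) and consumption fractions 0.85/0.75 for litter/duff, 0.9/0.75/
0.5 for the fine-wood classes, 0.25 coarse, 0.8 understory. The
parameterization keeps the simulated control NECB within ±50% of
110 MgC/ha over 19 years — a realism guard asserted in the tests, not
a fitted calibration. An optional 2012–2015 drought mortality pulse is
off by default.

Randomness: one root seed; each unit consumes its own `SeedSequence`
substream, so identical configurations are byte-identical and adding a
unit never perturbs existing units.

What the generator does *not* emulate — and hence what passing tests
do not show about real data: physiological growth and competition
(increments are size-independent), bark-beetle and spatial fire
dynamics, measurement error in dbh/height, observer effects in cover
classes, within-plot spatial structure of fuels, and soil carbon
dynamics (plot soil properties are constant through time). Emitted
transect tallies are Poisson draws around the inverse of the
planar-intercept formula, so re-estimated pools track the internal
carbon state with sampling noise rather than exactly; conservation
invariants are therefore asserted on the internal state, and the
pipeline agreement between the two is checked at a coarser tolerance.

## Numerical conventions

- Pool totals are exact sums; conservation checks run at 1e-9–1e-12
  relative tolerance; annual-flux telescoping uses compensated
  summation.
- Undefined fractions (e.g., percent large-tree carbon on a treeless
  plot) return NaN rather than zero.
- Thinning removes a crown-thin share (30% of the basal-area excess,
  never taking trees at or above the large-tree threshold) and then
  thins from below until the residual basal area reaches the target;
  plots already below the band are untouched.
- Degenerate inputs fail loudly: non-positive dbh/height, emissions
  exceeding combustible pools, kills exceeding live carbon, misaligned
  cost series, unknown sample frames or species tables.

## Known limitations

- Default allometry, volume, and fuel coefficients are stand-ins;
  absolute pool levels from the defaults are indicative only, and any
  real analysis must plug in regional tables.
- The simulated wildfire covers immediate impacts only: no post-fire
  snag decay trajectories, regeneration failure, or reburn dynamics.
- Economic costs, emission-species breakdowns (CO₂/CO/CH₄), deeper
  soil layers (15–90 cm), and belowground biomass are out of scope.
- The cost baseline is the mean control trajectory; with three control
  units the baseline itself carries sampling error that the bootstrap
  contrast, not the cost series, is designed to expose.
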