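"""Pool estimators against closed-form and brute-force oracles."""

import dataclasses
import math

import numpy as np
import pytest

from firecarbon import (
    CarbonPools,
    UnderstoryRecord,
    composite_fuel_coefficients,
    cwd_load,
    fwd_load,
    herb_carbon,
    plot_fuel_carbon,
    plot_pools,
    shrub_carbon,
    snag_carbon,
    soil_carbon,
    tree_biomass,
    tree_carbon,
)
from firecarbon.pools import live_tree_carbon_per_ha, soil_carbon
from firecarbon.records import SoilSample, tree_basal_area_m2

from conftest import make_plot, make_transect, make_tree


class TestTreeBiomass:
    def test_matches_hand_evaluated_power_law(self, table):
        # independent evaluation of the shipped default curve
        a, b, c = table.wood["PIPO"]
        expected_wood_kg = a * 50.0**b * 30.0**c
        expected = expected_wood_kg * (1.0 + table.foliage_ratio["PIPO"]) / 1000.0
        assert tree_biomass("PIPO", 50.0, 30.0, table) == pytest.approx(
            expected, rel=1e-12
        )

    def test_vanishes_in_small_dbh_limit(self, table):
        assert tree_biomass("ABCO", 1e-6, 10.0, table) < 1e-9

    def test_strictly_increasing_in_dbh_and_height(self, table):
        assert tree_biomass("CADE", 50.0, 25.0, table) > tree_biomass(
            "CADE", 40.0, 25.0, table
        )
        assert tree_biomass("CADE", 40.0, 30.0, table) > tree_biomass(
            "CADE", 40.0, 25.0, table
        )

    def test_unknown_species_is_hard_failure(self, table):
        with pytest.raises(KeyError, match="SEGI"):
            tree_biomass("SEGI", 50.0, 30.0, table)


class TestCarbonRatios:
    @pytest.mark.parametrize("biomass,expected", [(100.0, 48.0), (0.0, 0.0), (1.0, 0.48)])
    def test_live_tree_carbon_fraction(self, biomass, expected):
        assert tree_carbon(biomass) == pytest.approx(expected)

    def test_snag_is_live_equivalent_times_dead_ratios(self, table, constants):
        a, b, c = table.wood["PSME"]
        wood_mg = a * 40.0**b * 28.0**c / 1000.0
        expected = wood_mg * 0.88 * 0.51
        assert snag_carbon("PSME", 40.0, 28.0, table, constants) == pytest.approx(
            expected, rel=1e-12
        )

    def test_snag_carbon_below_live_for_identical_geometry(self, table, constants):
        live = tree_carbon(tree_biomass("ABCO", 40.0, 28.0, table), constants)
        snag = snag_carbon("ABCO", 40.0, 28.0, table, constants)
        assert snag < live  # 0.88 * 0.51 = 0.4488 < 0.48, and no foliage


class TestUnderstory:
    def test_cover_class_midpoints(self):
        covers = {"lt5": 0.025, "5to25": 0.15, "25to100": 0.63}
        for label, frac in covers.items():
            rec = UnderstoryRecord(plot_id="p", species="CEIN", cover_class=label)
            assert rec.cover_fraction == pytest.approx(frac)

    def test_shrub_linear_in_individual_biomass(self, table, constants):
        rec = UnderstoryRecord(plot_id="p", species="CEIN", cover_class="5to25")
        base = shrub_carbon(rec, 0.04, table, constants)
        doubled = dataclasses.replace(table)
        doubled.shrub = {k: (area, 2.0 * kg) for k, (area, kg) in table.shrub.items()}
        assert shrub_carbon(rec, 0.04, doubled, constants) == pytest.approx(2 * base)

    def test_shrub_carbon_brute_force(self, table, constants):
        rec = UnderstoryRecord(plot_id="p", species="CEIN", cover_class="lt5")
        crown, kg = table.shrub["CEIN"]
        covered_m2 = 0.025 * 0.04 * 1e4
        expected = covered_m2 / crown * kg / 1000.0 / 0.04 * 0.49
        assert shrub_carbon(rec, 0.04, table, constants) == pytest.approx(expected)

    def test_herb_additivity(self, table):
        recs = [
            UnderstoryRecord(plot_id="p", species="A", cover_class="lt5",
                             growth_form="herb"),
            UnderstoryRecord(plot_id="p", species="B", cover_class="5to25",
                             growth_form="herb"),
        ]
        k = table.herb_coefficient
        assert herb_carbon(recs, table) == pytest.approx(0.175 * k)
        assert herb_carbon([], table) == 0.0


class TestCompositeCoefficients:
    def test_single_species_plot_returns_that_species(self, table):
        trees = [make_tree(species="PIPO", dbh=d, tag=str(d)) for d in (20, 30, 40)]
        comp = composite_fuel_coefficients(trees, table)
        for cls in ("1h", "10h", "100h"):
            assert comp.squared_mean_diameter[cls] == pytest.approx(
                table.fuel["PIPO"].squared_mean_diameter[cls]
            )

    def test_equal_basal_area_gives_arithmetic_mean(self, table):
        trees = [
            make_tree(species="PIPO", dbh=30.0, tag="a"),
            make_tree(species="ABCO", dbh=30.0, tag="b"),
        ]
        comp = composite_fuel_coefficients(trees, table)
        for cls in ("1h", "10h"):
            mean = 0.5 * (
                table.fuel["PIPO"].squared_mean_diameter[cls]
                + table.fuel["ABCO"].squared_mean_diameter[cls]
            )
            assert comp.squared_mean_diameter[cls] == pytest.approx(mean)

    def test_three_species_mix_matches_weight_oracle(self, table):
        trees = [
            make_tree(species="PIPO", dbh=25.0, tag="a"),
            make_tree(species="ABCO", dbh=40.0, tag="b"),
            make_tree(species="QUKE", dbh=33.0, tag="c"),
        ]
        ba = {t.species: tree_basal_area_m2(t.dbh) for t in trees}
        tot = sum(ba.values())
        comp = composite_fuel_coefficients(trees, table)
        for cls in ("1h", "10h", "100h"):
            expected = sum(
                ba[sp] / tot * table.fuel[sp].squared_mean_diameter[cls]
                for sp in ba
            )
            assert comp.squared_mean_diameter[cls] == pytest.approx(expected, rel=1e-12)

    def test_treeless_plot_uses_equal_weights(self, table):
        comp = composite_fuel_coefficients([], table)
        sgs = [fc.specific_gravity["1h"] for fc in table.fuel.values()]
        assert min(sgs) <= comp.specific_gravity["1h"] <= max(sgs)


def brute_force_planar_intercept(diams_cm, secant, sg_g_cm3, length_m, slope=1.0):
    """Independent SI-unit derivation of the planar-intercept load.

    Each intersected piece of diameter d contributes a volume per unit
    area of (pi^2/8) d^2 / L (Brown's derivation); mass follows from
    wood density, converted to Mg/ha at the end.
    """
    vol_m3_per_m2 = sum(
        (math.pi**2 / 8.0) * (d / 100.0) ** 2 / length_m for d in diams_cm
    )
    kg_per_m2 = vol_m3_per_m2 * sg_g_cm3 * 1000.0 * secant * slope
    return kg_per_m2 * 10.0  # -> Mg/ha


class TestPlanarIntercept:
    def test_zero_count_zero_load(self, table, constants):
        tr = make_transect(c1=0, c10=0, c100=0)
        comp = composite_fuel_coefficients([], table)
        assert fwd_load(tr, comp, "10h", constants) == 0.0

    def test_load_linear_in_count(self, table, constants):
        comp = composite_fuel_coefficients([], table)
        one = fwd_load(make_transect(c10=6), comp, "10h", constants)
        two = fwd_load(make_transect(c10=12), comp, "10h", constants)
        assert two == pytest.approx(2 * one)

    def test_fixed_count_matches_closed_form_oracle(self, table, constants):
        comp = table.fuel["PIPO"]
        got = fwd_load(make_transect(c10=12), comp, "10h", constants)
        d_eq = math.sqrt(comp.squared_mean_diameter["10h"])
        expected = brute_force_planar_intercept(
            [d_eq] * 12, comp.secant_of_lean["10h"],
            comp.specific_gravity["10h"], 2.0,
        )
        assert got == pytest.approx(expected, rel=1e-9)

    def test_cwd_quadratic_in_diameter(self, table, constants):
        comp = table.fuel["ABCO"]
        small = cwd_load(make_transect(cwd=(10.0,)), comp, constants)
        big = cwd_load(make_transect(cwd=(20.0,)), comp, constants)
        assert big == pytest.approx(4 * small)

    def test_cwd_additive_over_pieces(self, table, constants):
        comp = table.fuel["CADE"]
        pieces = (9.0, 14.0, 23.0)
        total = cwd_load(make_transect(cwd=pieces), comp, constants)
        parts = sum(cwd_load(make_transect(cwd=(d,)), comp, constants) for d in pieces)
        assert total == pytest.approx(parts, rel=1e-12)

    def test_thousand_random_transects_match_brute_force(self, table, constants):
        """Implementation equals the independent oracle on seeded random data."""
        rng = np.random.default_rng(20250401)
        comp = composite_fuel_coefficients(
            [make_tree(species="PIPO", dbh=30, tag="a"),
             make_tree(species="ABCO", dbh=25, tag="b")],
            table,
        )
        for _ in range(1000):
            counts = rng.integers(0, 30, size=3)
            n_cwd = int(rng.integers(0, 5))
            cwd = tuple(rng.uniform(8.0, 40.0, size=n_cwd))
            tr = make_transect(c1=int(counts[0]), c10=int(counts[1]),
                               c100=int(counts[2]), cwd=cwd)
            for cls, length in (("1h", 2.0), ("10h", 2.0), ("100h", 3.0)):
                d_eq = math.sqrt(comp.squared_mean_diameter[cls])
                n = getattr(tr, f"counts_{cls}")
                expected = brute_force_planar_intercept(
                    [d_eq] * n, comp.secant_of_lean[cls],
                    comp.specific_gravity[cls], length,
                )
                assert fwd_load(tr, comp, cls, constants) == pytest.approx(
                    expected, rel=1e-9, abs=1e-12
                )
            expected_cwd = brute_force_planar_intercept(
                cwd, comp.secant_of_lean["cwd"], comp.specific_gravity["cwd"], 11.3
            )
            assert cwd_load(tr, comp, constants) == pytest.approx(
                expected_cwd, rel=1e-9, abs=1e-12
            )


class TestPlotFuelCarbon:
    def test_identical_transects_mean_equals_either(self, table, constants):
        tr = make_transect()
        plot = make_plot(transects=[tr, dataclasses.replace(tr, azimuth=90.0)])
        fuels = plot_fuel_carbon(plot, table, constants)
        single = make_plot(transects=[tr, tr])
        assert fuels == pytest.approx(plot_fuel_carbon(single, table, constants))

    def test_litter_depth_arithmetic(self, table, constants):
        # 2-cm litter everywhere at 5 Mg/ha/cm -> 10 Mg/ha -> x0.463 carbon
        consts = dataclasses.replace(constants, litter_depth_to_biomass=5.0)
        plot = make_plot(transects=[
            make_transect(litter=(2.0, 2.0)), make_transect(litter=(2.0, 2.0)),
        ])
        fuels = plot_fuel_carbon(plot, table, consts)
        assert fuels["litter"] == pytest.approx(10.0 * 0.463)

    def test_zero_depths_zero_carbon(self, table, constants):
        plot = make_plot(transects=[
            make_transect(litter=(0, 0), duff=(0, 0)),
            make_transect(litter=(0, 0), duff=(0, 0)),
        ])
        fuels = plot_fuel_carbon(plot, table, constants)
        assert fuels["litter"] == 0.0 and fuels["duff"] == 0.0


class TestSoil:
    def test_unit_conversion_closed_form(self):
        s = SoilSample(plot_id="p", bulk_density=1.0, carbon_pct=1.0)
        assert soil_carbon([s]) == pytest.approx(15.0)

    def test_zero_carbon_percent(self):
        s = SoilSample(plot_id="p", bulk_density=1.2, carbon_pct=1e-12)
        assert soil_carbon([s]) == pytest.approx(0.0, abs=1e-9)

    def test_two_samples_average(self):
        a = SoilSample(plot_id="p", bulk_density=1.0, carbon_pct=2.0)
        b = SoilSample(plot_id="p", bulk_density=1.0, carbon_pct=4.0)
        assert soil_carbon([a, b]) == pytest.approx(45.0)


class TestPlotPools:
    def test_empty_plot_all_zero(self, table, constants):
        plot = make_plot(trees=[], understory=[], transects=[], soil=[])
        pools = plot_pools(plot, table, constants)
        assert pools.total == 0.0

    def test_total_equals_independent_component_sum(self, simple_plot, table, constants):
        pools = plot_pools(simple_plot, table, constants)
        manual = sum(getattr(pools, n) for n in CarbonPools.POOL_NAMES)
        assert pools.total == pytest.approx(manual, rel=1e-12)
        assert pools.live_tree > 0 and pools.snag > 0 and pools.soil_0_15 > 0

    def test_removing_only_snag_changes_only_snag_pool(self, simple_plot, table, constants):
        before = plot_pools(simple_plot, table, constants)
        no_snag = dataclasses.replace(
            simple_plot, trees=[t for t in simple_plot.trees if t.status == "live"]
        )
        after = plot_pools(no_snag, table, constants)
        assert after.snag == 0.0
        for name in CarbonPools.POOL_NAMES:
            if name != "snag":
                assert getattr(after, name) == pytest.approx(getattr(before, name))

    def test_doubling_identical_records_doubles_density(self, table, constants):
        t = make_tree(dbh=35.0, tag="x")
        one = plot_pools(make_plot(trees=[t], transects=[]), table, constants)
        t2 = dataclasses.replace(t, tag="y")
        two = plot_pools(make_plot(trees=[t, t2], transects=[]), table, constants)
        assert two.live_tree == pytest.approx(2 * one.live_tree, rel=1e-12)

    def test_subplot_sapling_expands_at_250(self, table, constants):
        sap = make_tree(dbh=5.0, height=4.0, frame="subplot")
        pools = plot_pools(make_plot(trees=[sap], transects=[]), table, constants)
        per_tree = tree_carbon(tree_biomass("PIPO", 5.0, 4.0, table))
        assert pools.live_tree == pytest.approx(per_tree * 250.0)
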