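"""Consumption kernel, Monte-Carlo scheme, and the scenario grid."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import crabrisk as cr
from crabrisk import Level, SpeciesGroup
from crabrisk.consumption import sample_consumption

positive = st.floats(1e-3, 1e6)


def kernel_oracle(area, den, cal, diet, cal_kg):
    """Independently coded kernel: product evaluated in log space."""
    if 0.0 in (area, den, cal, diet):
        return 0.0
    return math.exp(
        math.log(area) + math.log(den) + math.log(cal) + math.log(diet) - math.log(cal_kg)
    )


def make_levels(calories_value, densities=None):
    levels = cr.ScenarioLevels() if densities is None else cr.ScenarioLevels(densities=densities)
    levels.calories = {
        (sp, lv): calories_value for sp in SpeciesGroup for lv in Level.ordered()
    }
    return levels


class TestConsumptionPoint:
    def test_hand_arithmetic_example(self):
        # 500 km2 x 10,000 crabs/km2 x 100,000 cal/crab/yr x 0.25 / 250,000 cal/kg
        assert cr.consumption_point(500, 10_000, 100_000, 0.25, 250_000) == pytest.approx(
            500_000.0
        )

    def test_no_crabs_no_consumption(self):
        assert cr.consumption_point(500.0, 0.0, 1e5, 0.3, 2e5) == 0.0

    @given(area=positive, den=positive, cal=positive, diet=st.floats(1e-3, 1.0), ck=positive)
    def test_matches_independent_oracle(self, area, den, cal, diet, ck):
        ours = cr.consumption_point(area, den, cal, diet, ck)
        assert ours == pytest.approx(kernel_oracle(area, den, cal, diet, ck), rel=1e-9)

    @given(area=positive, den=positive, cal=positive, diet=st.floats(1e-3, 1.0), ck=positive, s=st.floats(0.1, 10.0))
    def test_linearity_and_inverse_proportionality(self, area, den, cal, diet, ck, s):
        base = cr.consumption_point(area, den, cal, diet, ck)
        assert cr.consumption_point(area, s * den, cal, diet, ck) == pytest.approx(s * base, rel=1e-12)
        assert cr.consumption_point(s * area, den, cal, diet, ck) == pytest.approx(s * base, rel=1e-12)
        assert cr.consumption_point(area, den, cal, diet, s * ck) == pytest.approx(base / s, rel=1e-12)

    def test_doubling_density_doubles_output_exactly(self):
        one = cr.consumption_point(523.71, 50_000, 24_099.0, 0.275, 356_700.0)
        assert cr.consumption_point(523.71, 100_000, 24_099.0, 0.275, 356_700.0) == 2.0 * one

    def test_zero_cal_per_kg_is_domain_error(self):
        with pytest.raises(cr.ValidationError):
            cr.consumption_point(1.0, 1.0, 1.0, 1.0, 0.0)

    def test_negative_input_rejected(self):
        with pytest.raises(cr.ValidationError):
            cr.consumption_point(-1.0, 1.0, 1.0, 1.0, 1.0)


class TestRunScenario:
    def test_degenerate_ranges_equal_closed_form(self):
        u = cr.UncertainInputs(
            area_mid=500.0,
            area_halfwidth=0.0,
            diet_lo=0.25,
            diet_hi=0.25,
            cal_per_kg={sp: (250_000.0, 250_000.0) for sp in SpeciesGroup},
        )
        levels = make_levels(100_000.0)
        est = cr.run_scenario(
            SpeciesGroup.OYSTER, Level.LOW, Level.LOW, u, levels, cr.MCSettings(2_000, 7)
        )
        closed = cr.consumption_point(500.0, levels.density(Level.LOW), 1e5, 0.25, 2.5e5)
        assert est.mean_kg == pytest.approx(closed, rel=1e-12)
        assert est.ci_lo_kg == pytest.approx(closed, rel=1e-12)
        assert est.ci_hi_kg == pytest.approx(closed, rel=1e-12)

    def test_zero_calories_give_zero_estimate(self):
        est = cr.run_scenario(
            SpeciesGroup.MUSSEL, Level.LOW, Level.LOW, cr.UncertainInputs(),
            make_levels(0.0), cr.MCSettings(500, 1),
        )
        assert (est.mean_kg, est.ci_lo_kg, est.ci_hi_kg) == (0.0, 0.0, 0.0)

    def test_unpopulated_calorie_level_is_configuration_error(self):
        with pytest.raises(cr.ConfigurationError, match="calorie"):
            cr.run_scenario(
                SpeciesGroup.OYSTER, Level.LOW, Level.LOW,
                cr.UncertainInputs(), cr.ScenarioLevels(), cr.MCSettings(10, 1),
            )

    def test_same_seed_bit_identical(self):
        levels = make_levels(20_000.0)
        kwargs = dict(
            species=SpeciesGroup.HARDSHELL_CLAM,
            density_level=Level.HIGH,
            calorie_level=Level.MEDIUM,
            uncertain=cr.UncertainInputs(),
            levels=levels,
        )
        a = cr.run_scenario(mc=cr.MCSettings(5_000, 42), **kwargs)
        b = cr.run_scenario(mc=cr.MCSettings(5_000, 42), **kwargs)
        c = cr.run_scenario(mc=cr.MCSettings(5_000, 43), **kwargs)
        assert a == b
        assert a.mean_kg != c.mean_kg

    def test_interval_brackets_mean(self, calibrated):
        est = cr.run_scenario(
            SpeciesGroup.MUSSEL, Level.HIGH, Level.HIGH, cr.UncertainInputs(),
            calibrated, cr.MCSettings(5_000, 11),
        )
        assert 0.0 <= est.ci_lo_kg <= est.mean_kg <= est.ci_hi_kg
        assert est.ci_lo_kg < est.ci_hi_kg

    def test_mc_mean_matches_analytic_expectation(self, uncertain):
        # E[product of independent draws] = product of expectations, with
        # E[1/U(a,b)] = ln(b/a)/(b-a) for the calorie-density divisor
        levels = make_levels(25_000.0)
        species, den_level = SpeciesGroup.HARDSHELL_CLAM, Level.MEDIUM
        n = 10_000
        rng = np.random.default_rng(123)
        sample = sample_consumption(species, den_level, Level.LOW, uncertain, levels, n, rng)
        lo, hi = uncertain.cal_per_kg[species]
        analytic = (
            levels.density(den_level)
            * 25_000.0
            * uncertain.area_mid
            * uncertain.diet_mid
            * (math.log(hi / lo) / (hi - lo))
        )
        se = sample.std(ddof=1) / math.sqrt(n)
        assert abs(sample.mean() - analytic) < 3.0 * se

    def test_widening_a_range_never_narrows_the_interval(self):
        widths = [0.0, 0.025, 0.05, 0.075]
        ci_widths = []
        for w in widths:
            u = cr.UncertainInputs(diet_lo=0.275 - w, diet_hi=0.275 + w)
            est = cr.run_scenario(
                SpeciesGroup.OYSTER, Level.MEDIUM, Level.MEDIUM, u,
                make_levels(10_000.0), cr.MCSettings(4_000, 99),
            )
            ci_widths.append(est.ci_hi_kg - est.ci_lo_kg)
        assert all(b >= a for a, b in zip(ci_widths, ci_widths[1:]))


class TestApplyConsumption:
    def _estimate(self, mean, lo=None, hi=None):
        return cr.ConsumptionEstimate(
            SpeciesGroup.MUSSEL, Level.HIGH, Level.HIGH,
            mean, lo if lo is not None else mean, hi if hi is not None else mean,
        )

    def test_consumption_beyond_baseline_floors_harvest_at_zero(self):
        outcome = cr.apply_consumption(1.0e6, 4.8e6, self._estimate(2.0e6))
        assert outcome.harvest_after_kg == 0.0
        assert outcome.loss_fraction == 1.0
        assert outcome.revenue_after_usd == 0.0

    def test_zero_consumption_is_identity(self):
        outcome = cr.apply_consumption(1.0e6, 4.8e6, self._estimate(0.0))
        assert outcome.harvest_after_kg == 1.0e6
        assert outcome.revenue_after_usd == 4.8e6
        assert outcome.loss_fraction == 0.0

    def test_revenue_scales_with_biomass_loss(self):
        outcome = cr.apply_consumption(100.0, 500.0, self._estimate(25.0))
        assert outcome.harvest_after_kg == pytest.approx(75.0)
        assert outcome.revenue_after_usd == pytest.approx(375.0)
        assert outcome.loss_fraction == pytest.approx(0.25)


class TestScenarioGrid:
    def test_zero_calories_leave_every_cell_at_baseline(self, baseline_table):
        grid = cr.scenario_grid(
            baseline_table, make_levels(0.0), mc=cr.MCSettings(100, 1)
        )
        assert all(oc.loss_kg == 0.0 for oc in grid.outcomes)
        assert all(cell.loss_usd == 0.0 for cell in grid.cell_totals.values())

    def test_shape_and_invariants(self, baseline_table, calibrated):
        grid = cr.scenario_grid(baseline_table, calibrated, mc=cr.MCSettings(400, 5))
        assert len(grid.outcomes) == 27
        assert len(grid.cell_totals) == 9
        for oc in grid.outcomes:
            assert 0.0 <= oc.loss_fraction <= 1.0
            baseline_kg = oc.harvest_after_kg + oc.loss_kg
            baseline_usd = oc.revenue_after_usd + oc.loss_usd
            # revenue loss fraction equals biomass loss fraction per species
            if baseline_usd > 0:
                assert oc.loss_usd / baseline_usd == pytest.approx(
                    oc.loss_kg / baseline_kg, rel=1e-12
                )
        for cell in grid.cell_totals.values():
            assert 0.0 <= cell.revenue_loss_fraction <= 1.0

    def test_cell_totals_sum_species_losses(self, baseline_table, calibrated):
        grid = cr.scenario_grid(baseline_table, calibrated, mc=cr.MCSettings(300, 5))
        cell = grid.cell_totals[(Level.HIGH, Level.HIGH)]
        summed = sum(
            oc.loss_kg
            for oc in grid.outcomes
            if oc.density_level is Level.HIGH and oc.calorie_level is Level.HIGH
        )
        assert cell.loss_kg == pytest.approx(summed, rel=1e-12)

    def test_same_seed_gives_identical_grid(self, baseline_table, calibrated):
        g1 = cr.scenario_grid(baseline_table, calibrated, mc=cr.MCSettings(300, 17))
        g2 = cr.scenario_grid(baseline_table, calibrated, mc=cr.MCSettings(300, 17))
        assert g1.to_frame().equals(g2.to_frame())
        assert g1.totals_frame().equals(g2.totals_frame())


def test_scenario_levels_validation():
    with pytest.raises(cr.ConfigurationError):
        cr.ScenarioLevels(densities={Level.LOW: 5e4, Level.MEDIUM: 5e4, Level.HIGH: 1e5})
    levels = cr.ScenarioLevels()
    assert levels.density(Level.LOW) == 10_000.0
    assert levels.density(Level.HIGH) == 100_000.0


def test_uncertain_inputs_validation():
    with pytest.raises(cr.ValidationError):
        cr.UncertainInputs(area_mid=50.0, area_halfwidth=75.0)
    with pytest.raises(cr.ValidationError):
        cr.UncertainInputs(diet_lo=0.5, diet_hi=0.4)
    with pytest.raises(cr.ValidationError):
        cr.MCSettings(n_reps=0)
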