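"""Per-intervention benefit and cost arithmetic, scenario grid, delays."""

import itertools
import math
from dataclasses import replace

import pytest
from hypothesis import given, strategies as st

from hbpopt import (
    Channel,
    CoverageChange,
    DelayBin,
    DiseaseBurden,
    DiseaseTargetEffect,
    EconomyConfig,
    InterventionSpec,
    ScreeningCost,
    SecondaryLink,
    ValidationError,
    apply_delay,
    bundle_totals,
    calibrate,
    deaths_averted_fatality,
    deaths_averted_incidence,
    evaluate_all,
    evaluate_intervention,
    government_cost,
    primary_che_averted,
    secondary_che_averted,
    treated_population,
)

EXP_MODEL = calibrate(1000.0, 0.5, che_threshold=0.10)  # exponential, scale 1000


def make_spec(**kw) -> InterventionSpec:
    base = dict(
        intervention_id="I", name="x",
        targets=(DiseaseTargetEffect(disease_id="D", channel=Channel.FATALITY,
                                     effect=0.5, addressable_share=1.0),),
        baseline_coverage=0.2, unit_cost=10.0, oop_share=0.34)
    base.update(kw)
    return InterventionSpec(**base)


class TestCoverageChange:
    def test_increment_capped_at_full_coverage(self):
        change = CoverageChange.from_increment(0.98, 0.05)
        assert change.expanded == 1.0
        assert change.increment == pytest.approx(0.02)

    def test_saturated_coverage_has_zero_increment(self):
        assert CoverageChange.from_increment(1.0, 0.05).increment == 0.0


class TestDeathsAverted:
    BURDEN = DiseaseBurden(disease_id="D", incidence=100000.0, cfr=0.1,
                           deaths=20000.0, target_population=10000.0)

    def test_incidence_channel_hand_arithmetic(self):
        change = CoverageChange(0.20, 0.25)
        effect = DiseaseTargetEffect(disease_id="D", channel=Channel.INCIDENCE,
                                     effect=0.6, addressable_share=0.5)
        d_inc, d_deaths = deaths_averted_incidence(change, effect, self.BURDEN)
        assert d_inc == pytest.approx(1500.0)
        assert d_deaths == pytest.approx(150.0)

    def test_fatality_channel_hand_arithmetic(self):
        change = CoverageChange(0.20, 0.25)
        effect = DiseaseTargetEffect(disease_id="D", channel=Channel.FATALITY,
                                     effect=0.4, addressable_share=1.0)
        assert deaths_averted_fatality(change, effect, self.BURDEN) == \
            pytest.approx(400.0)

    @pytest.mark.parametrize("effect,increment,expected", [
        (0.0, 0.05, 0.0),      # null effect
        (0.6, 0.0, 0.0),       # saturated coverage
    ])
    def test_null_cases(self, effect, increment, expected):
        change = CoverageChange.from_increment(1.0 if increment == 0 else 0.2,
                                               increment)
        eff = DiseaseTargetEffect(disease_id="D", channel=Channel.INCIDENCE,
                                  effect=effect, addressable_share=0.5)
        assert deaths_averted_incidence(change, eff, self.BURDEN) == (0.0, 0.0)

    def test_channel_mismatch_raises(self):
        change = CoverageChange(0.2, 0.25)
        eff = DiseaseTargetEffect(disease_id="D", channel=Channel.INCIDENCE,
                                  effect=0.5, addressable_share=0.5)
        with pytest.raises(ValidationError):
            deaths_averted_fatality(change, eff, self.BURDEN)

    def test_targets_sum_to_intervention_total(self):
        burdens = {
            "A": DiseaseBurden(disease_id="A", incidence=1e5, cfr=0.1,
                               deaths=1e4, target_population=1e5),
            "B": DiseaseBurden(disease_id="B", incidence=5e4, cfr=0.2,
                               deaths=1e4, target_population=1e5),
        }
        spec = make_spec(targets=(
            DiseaseTargetEffect(disease_id="A", channel=Channel.INCIDENCE,
                                effect=0.5, addressable_share=0.6),
            DiseaseTargetEffect(disease_id="B", channel=Channel.FATALITY,
                                effect=0.3, addressable_share=0.8),
        ))
        economy = EconomyConfig(mean_consumption=1000.0, gini=0.5)
        out = evaluate_intervention(spec, burdens, economy)
        change = CoverageChange.from_increment(0.2, 0.05)
        expected = (deaths_averted_incidence(change, spec.targets[0],
                                             burdens["A"])[1]
                    + deaths_averted_fatality(change, spec.targets[1],
                                              burdens["B"]))
        assert out.deaths_averted == pytest.approx(expected)


class TestTreatedAndChe:
    def test_treated_population_hand_arithmetic(self):
        change = CoverageChange(0.20, 0.25)
        eff = DiseaseTargetEffect(disease_id="D", channel=Channel.FATALITY,
                                  effect=0.4, addressable_share=1.0)
        assert treated_population(change, eff, 10000.0) == pytest.approx(2500.0)
        assert treated_population(change, replace(eff, addressable_share=0.0),
                                  10000.0) == 0.0

    def test_primary_che_product(self):
        # treated 2500 at OOP 50 under the exponential model: p = 1-exp(-0.5)
        spec = make_spec(unit_cost=100.0, oop_share=0.5)
        expected_p = 1.0 - math.exp(-0.5)
        assert primary_che_averted(spec, 2500.0, EXP_MODEL) == \
            pytest.approx(2500.0 * expected_p, rel=1e-6)
        # printed-precision check: p rounds to 0.3935, product to ~983.7
        assert 2500.0 * expected_p == pytest.approx(983.75, abs=0.25)

    def test_zero_oop_gives_zero_che(self):
        spec = make_spec(oop_share=0.0)
        assert primary_che_averted(spec, 1e6, EXP_MODEL) == 0.0

    def test_screening_two_threshold_tests(self):
        scr = ScreeningCost(screen_unit_cost=4.0, treat_unit_cost=30.0,
                            positivity_fraction=0.2)
        spec = make_spec(unit_cost=10.0, oop_share=0.5, screening=scr)
        treated = 1000.0
        expected = (treated * (1 - math.exp(-0.5 * 4.0 / 100.0))
                    + treated * 0.2 * (1 - math.exp(-0.5 * 30.0 / 100.0)))
        assert primary_che_averted(spec, treated, EXP_MODEL) == \
            pytest.approx(expected, rel=1e-6)

    def test_doubling_threshold_never_increases(self):
        spec = make_spec()
        t25 = EXP_MODEL.with_threshold(0.20)
        assert primary_che_averted(spec, 1000.0, t25) <= \
            primary_che_averted(spec, 1000.0, EXP_MODEL)

    def test_secondary_link_hand_arithmetic(self):
        link = SecondaryLink(upstream_id="I", downstream_id="J",
                             disease_id="D", downstream_coverage=0.4,
                             downstream_addressable=0.5, downstream_oop=10.0)
        # averted downstream users: 1000 * 0.4 * 0.5 = 200
        result = secondary_che_averted([link], {"D": 1000.0}, EXP_MODEL)
        assert result == pytest.approx(200.0 * (1 - math.exp(-0.1)), rel=1e-6)

    def test_no_links_and_zero_downstream_oop(self):
        assert secondary_che_averted([], {}, EXP_MODEL) == 0.0
        link = SecondaryLink(upstream_id="I", downstream_id="J",
                             disease_id="D", downstream_coverage=0.4,
                             downstream_addressable=0.5, downstream_oop=0.0)
        assert secondary_che_averted([link], {"D": 1000.0}, EXP_MODEL) == 0.0

    def test_dangling_link_raises(self):
        link = SecondaryLink(upstream_id="I", downstream_id="J",
                             disease_id="MISSING", downstream_coverage=0.4,
                             downstream_addressable=0.5, downstream_oop=10.0)
        with pytest.raises(ValidationError):
            secondary_che_averted([link], {"D": 1.0}, EXP_MODEL)


class TestGovernmentCost:
    def test_detailed_rule_hand_arithmetic(self):
        spec = make_spec(unit_cost=10.0, oop_share=0.34)
        change = CoverageChange(0.20, 0.25)
        # 2000 baseline users x 3.4 OOP subsidy + 500 new users x 10 full cost
        assert government_cost(spec, change, {"D": 10000.0}) == \
            pytest.approx(11800.0)

    def test_zero_increment_zero_oop_costs_nothing(self):
        spec = make_spec(oop_share=0.0)
        change = CoverageChange(1.0, 1.0)
        assert government_cost(spec, change, {"D": 10000.0}) == 0.0

    def test_zero_increment_is_oop_subsidy_only(self):
        spec = make_spec(unit_cost=10.0, oop_share=0.34)
        change = CoverageChange(0.20, 0.20)
        assert government_cost(spec, change, {"D": 10000.0}) == \
            pytest.approx(0.20 * 10000.0 * 3.4)

    def test_simple_rule_is_unit_cost_times_covered(self):
        spec = make_spec(unit_cost=10.0)
        change = CoverageChange(0.20, 0.25)
        assert government_cost(spec, change, {"D": 10000.0},
                               cost_rule="simple") == pytest.approx(25000.0)


class TestScenarioGrid:
    @pytest.fixture
    def bounded_instance(self):
        burdens = {"D": DiseaseBurden(
            disease_id="D", incidence=1e5, cfr=0.1, deaths=1e4,
            target_population=2e5, incidence_bounds=(7e4, 1.4e5),
            deaths_bounds=(8e3, 1.3e4))}
        spec = make_spec(targets=(
            DiseaseTargetEffect(disease_id="D", channel=Channel.INCIDENCE,
                                effect=0.5, addressable_share=0.6,
                                effect_bounds=(0.3, 0.7)),))
        economy = EconomyConfig(mean_consumption=1000.0, gini=0.5)
        return spec, burdens, economy

    def test_all_zero_effects_give_zero_outcome(self):
        burdens = {"D": DiseaseBurden(disease_id="D", incidence=1e5, cfr=0.1,
                                      deaths=1e4, target_population=0.0)}
        spec = make_spec(oop_share=0.0, targets=(
            DiseaseTargetEffect(disease_id="D", channel=Channel.FATALITY,
                                effect=0.0, addressable_share=1.0),))
        economy = EconomyConfig(mean_consumption=1000.0, gini=0.5)
        out = evaluate_intervention(spec, burdens, economy)
        assert (out.deaths_averted, out.che_averted, out.treated) == (0, 0, 0)

    def test_central_within_bounds(self, bounded_instance):
        spec, burdens, economy = bounded_instance
        out = evaluate_intervention(spec, burdens, economy)
        lo, hi = out.deaths_averted_bounds
        assert lo <= out.deaths_averted <= hi
        lo, hi = out.che_averted_bounds
        assert lo <= out.che_averted <= hi

    def test_grid_equals_brute_force_over_nine_combinations(
            self, bounded_instance):
        spec, burdens, economy = bounded_instance
        out = evaluate_intervention(spec, burdens, economy)
        model = calibrate(1000.0, 0.5)
        change = CoverageChange.from_increment(0.2, 0.05)
        target = spec.targets[0]
        b = burdens["D"]
        deaths_grid, che_grid = [], []
        for (inc, dth), eff in itertools.product(
                [(7e4, 8e3), (1e5, 1e4), (1.4e5, 1.3e4)], [0.3, 0.5, 0.7]):
            d_inc = change.increment * eff * target.addressable_share * inc
            deaths_grid.append(b.cfr * d_inc)
            treated = change.expanded * target.addressable_share * 2e5
            che_grid.append(primary_che_averted(spec, treated, model))
        assert out.deaths_averted_bounds == pytest.approx(
            (min(deaths_grid), max(deaths_grid)))
        assert out.che_averted_bounds == pytest.approx(
            (min(che_grid), max(che_grid)))

    def test_scenario_ordering(self, bounded_instance):
        spec, burdens, economy = bounded_instance
        pes = evaluate_intervention(spec, burdens, economy, scenario="pessimistic")
        cen = evaluate_intervention(spec, burdens, economy)
        opt = evaluate_intervention(spec, burdens, economy, scenario="optimistic")
        assert pes.deaths_averted <= cen.deaths_averted <= opt.deaths_averted
        assert pes.che_averted <= cen.che_averted <= opt.che_averted

    def test_missing_bounds_fall_back_to_central_with_warning(self, caplog):
        burdens = {"D": DiseaseBurden(disease_id="D", incidence=1e5, cfr=0.1,
                                      deaths=1e4, target_population=1e5)}
        spec = make_spec()
        economy = EconomyConfig(mean_consumption=1000.0, gini=0.5)
        with caplog.at_level("WARNING", logger="hbpopt"):
            out = evaluate_intervention(spec, burdens, economy,
                                        scenario="optimistic")
        cen = evaluate_intervention(spec, burdens, economy)
        assert out.deaths_averted == pytest.approx(cen.deaths_averted)
        assert any("bounds missing" in r.message for r in caplog.records)

    def test_cost_bounds_are_half_and_one_and_a_half(self, bounded_instance):
        spec, burdens, economy = bounded_instance
        out = evaluate_intervention(spec, burdens, economy)
        assert out.cost_bounds == pytest.approx(
            (0.5 * out.total_cost, 1.5 * out.total_cost))

    @given(increment=st.floats(0.0, 0.2), effect=st.floats(0.0, 1.0),
           share=st.floats(0.0, 1.0))
    def test_monotone_in_increment_effect_share(self, increment, effect, share):
        burden = DiseaseBurden(disease_id="D", incidence=1e5, cfr=0.1,
                               deaths=1e4, target_population=1e5)
        change = CoverageChange.from_increment(0.2, increment)
        eff = DiseaseTargetEffect(disease_id="D", channel=Channel.INCIDENCE,
                                  effect=effect, addressable_share=share)
        base = deaths_averted_incidence(CoverageChange.from_increment(0.2, 0.0),
                                        eff, burden)[1]
        more = deaths_averted_incidence(change, eff, burden)[1]
        assert more >= base
        # increasing either factor never decreases deaths averted
        bigger = DiseaseTargetEffect(
            disease_id="D", channel=Channel.INCIDENCE,
            effect=min(effect + 0.1, 1.0),
            addressable_share=min(share + 0.1, 1.0))
        assert deaths_averted_incidence(change, bigger, burden)[1] >= more


class TestDelay:
    def test_steady_state_is_identity(self, micro):
        out = evaluate_all(micro.tables.interventions, micro.tables.burdens,
                           micro.tables.economy)
        for spec, o in zip(micro.tables.interventions, out):
            assert apply_delay(o, spec, "steady_state") is o

    def test_lagged_annotates_without_discounting(self, micro):
        spec = micro.tables.interventions[0]  # delay bin: short
        out = evaluate_all(micro.tables.interventions, micro.tables.burdens,
                           micro.tables.economy)[0]
        lagged = apply_delay(out, spec, "lagged")
        assert lagged.benefit_year == 5
        assert lagged.cost_year == 0
        assert lagged.deaths_averted == out.deaths_averted

    def test_long_delay_is_twenty_years(self):
        spec = make_spec(delay_bin=DelayBin.LONG)
        burdens = {"D": DiseaseBurden(disease_id="D", incidence=1e5, cfr=0.1,
                                      deaths=1e4, target_population=1e5)}
        out = evaluate_intervention(
            spec, burdens, EconomyConfig(mean_consumption=1000.0, gini=0.5))
        lagged = apply_delay(out, spec, "lagged")
        assert (lagged.benefit_year, lagged.cost_year) == (20, 0)
        none_spec = make_spec(delay_bin=DelayBin.NONE)
        assert apply_delay(out, none_spec, "lagged").benefit_year == 0

    def test_discount_hook_scales_benefits_only(self):
        spec = make_spec(delay_bin=DelayBin.SHORT)
        burdens = {"D": DiseaseBurden(disease_id="D", incidence=1e5, cfr=0.1,
                                      deaths=1e4, target_population=1e5)}
        out = evaluate_intervention(
            spec, burdens, EconomyConfig(mean_consumption=1000.0, gini=0.5))
        disc = apply_delay(out, spec, "lagged", discount_rate=0.03)
        assert disc.deaths_averted == pytest.approx(
            out.deaths_averted / 1.03**5)
        assert disc.total_cost == out.total_cost


class TestBundles:
    def test_bundle_totals_are_component_sums(self, micro):
        specs = [replace(s, bundle_id="L&D") for s in
                 micro.tables.interventions[:2]]
        specs.append(micro.tables.interventions[2])
        out = evaluate_all(specs, micro.tables.burdens, micro.tables.economy)
        totals = bundle_totals(out, specs)
        assert set(totals) == {"L&D"}
        agg = totals["L&D"]
        assert agg.deaths_averted == pytest.approx(
            out[0].deaths_averted + out[1].deaths_averted)
        assert agg.che_averted == pytest.approx(
            out[0].che_averted + out[1].che_averted)
        assert agg.total_cost == pytest.approx(
            out[0].total_cost + out[1].total_cost)


class TestMicroExampleRegression:
    """The stored hand-derived values survive a full pipeline run."""

    def test_all_stored_values(self, micro):
        out = evaluate_all(micro.tables.interventions, micro.tables.burdens,
                           micro.tables.economy)
        for o in out:
            iid = o.intervention_id
            assert o.deaths_averted == pytest.approx(
                micro.expected_deaths[iid], rel=1e-9)
            assert o.treated == pytest.approx(
                micro.expected_treated[iid], rel=1e-9)
            assert o.total_cost == pytest.approx(
                micro.expected_cost[iid], rel=1e-9)
            assert o.che_primary == pytest.approx(
                micro.expected_che_primary[iid], rel=1e-6)
            assert o.che_secondary == pytest.approx(
                micro.expected_che_secondary[iid], rel=1e-6)
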