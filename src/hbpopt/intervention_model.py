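"""Per-intervention health benefits, financial risk protection and cost.

Inclusion of intervention ``i`` in the benefits package (a) raises its
coverage from ``C_i`` by a small policy increment (capped at full coverage),
and (b) waives all out-of-pocket (OOP) payments for the service. Against the
counterfactual of exclusion this produces, per disease target ``x``:

incidence channel
    averted incident cases  dI = (C' - C) * E * A * I_x
    averted deaths          dD = CFR_x * dI
fatality channel
    averted deaths          dD = (C' - C) * E * A * D_x

treated population (all covered users at the expanded coverage)
    T = C' * A * POP,   dH_i = sum_x T

Financial risk protection is counted as expected catastrophic-health-
expenditure (CHE) cases averted. *Primary* FRP: every covered user whose
(now waived) baseline OOP payment would have exceeded the threshold share
of their consumption counts as an averted CHE case, so
``dCHE_primary = T * P(OOP_i catastrophic)``. *Secondary* FRP: prevented
incidence removes demand for downstream care j on the same disease,
``dH_ij = dI_x * C_j * A_jx``, averting the downstream OOP exposure.

Government cost of inclusion: the OOP subsidy for the baseline-coverage
population plus the full unit cost for newly covered users,
``TC = sum_x [C*A*POP * oop_share*u + (C'-C)*A*POP * u]``. The alternative
"simple" rule ``TC = u * dH`` prices the whole covered population at full
unit cost and is available as ``cost_rule="simple"`` for comparison.

Expected counts stay fractional throughout; rounding is a reporting concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Optional, Sequence

from .consumption import ConsumptionModel, che_probability, from_economy
from .core_data import (
    ATOL,
    Channel,
    DelayBin,
    DiseaseBurden,
    DiseaseTargetEffect,
    EconomyConfig,
    InterventionOutcome,
    InterventionSpec,
    ValidationError,
)

logger = logging.getLogger("hbpopt")

Scenario = Literal["central", "optimistic", "pessimistic"]
CostRule = Literal["detailed", "simple"]
DelayMode = Literal["steady_state", "lagged"]

_LEVELS = ("low", "mean", "high")


@dataclass(frozen=True)
class CoverageChange:
    """Coverage before and after inclusion; the increment is capped at 1."""

    baseline: float
    expanded: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.baseline <= self.expanded <= 1.0):
            raise ValidationError(
                f"coverage must satisfy 0 <= baseline <= expanded <= 1, "
                f"got {self.baseline}, {self.expanded}"
            )

    @property
    def increment(self) -> float:
        return self.expanded - self.baseline

    @classmethod
    def from_increment(cls, baseline: float, increment: float) -> "CoverageChange":
        return cls(baseline=baseline, expanded=min(baseline + increment, 1.0))


@dataclass(frozen=True)
class SecondaryLink:
    """Resolved downstream-care link i -> j on shared disease x."""

    upstream_id: str
    downstream_id: str
    disease_id: str
    downstream_coverage: float
    downstream_addressable: float
    downstream_oop: float  # absolute OOP amount per downstream user, USD

    def __post_init__(self) -> None:
        for name in ("downstream_coverage", "downstream_addressable"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.downstream_oop < 0:
            raise ValidationError("downstream_oop must be >= 0")


def _bounded(mean: float, bounds, level: str) -> tuple[float, bool]:
    """Value at a grid level; returns (value, had_bounds)."""
    if level == "mean" or bounds is None:
        return mean, bounds is not None
    return (bounds[0] if level == "low" else bounds[1]), True


def deaths_averted_incidence(
    change: CoverageChange,
    effect: DiseaseTargetEffect,
    burden: DiseaseBurden,
    effect_value: Optional[float] = None,
    incidence_value: Optional[float] = None,
) -> tuple[float, float]:
    """Averted incidence and deaths for an incidence-channel target.

    ``effect_value``/``incidence_value`` override the central estimates when
    evaluating a scenario-grid corner.
    """
    if effect.channel is not Channel.INCIDENCE:
        raise ValidationError(
            f"target {effect.disease_id!r} uses channel {effect.channel.value!r}, "
            f"expected 'incidence'"
        )
    e = effect.effect if effect_value is None else effect_value
    incidence = burden.incidence if incidence_value is None else incidence_value
    delta_incidence = change.increment * e * effect.addressable_share * incidence
    return delta_incidence, burden.cfr * delta_incidence


def deaths_averted_fatality(
    change: CoverageChange,
    effect: DiseaseTargetEffect,
    burden: DiseaseBurden,
    effect_value: Optional[float] = None,
    deaths_value: Optional[float] = None,
) -> float:
    """Averted deaths for a fatality-channel target (acts on D_x directly)."""
    if effect.channel is not Channel.FATALITY:
        raise ValidationError(
            f"target {effect.disease_id!r} uses channel {effect.channel.value!r}, "
            f"expected 'fatality'"
        )
    e = effect.effect if effect_value is None else effect_value
    deaths = burden.deaths if deaths_value is None else deaths_value
    return change.increment * e * effect.addressable_share * deaths


def resolve_target_population(effect: DiseaseTargetEffect,
                              burden: DiseaseBurden) -> float:
    """Per-target population: the override wins over the burden default."""
    if effect.target_population_override is not None:
        return effect.target_population_override
    return burden.target_population


def treated_population(change: CoverageChange, effect: DiseaseTargetEffect,
                       population: float) -> float:
    """Users covered at the expanded coverage: T = C' * A * POP."""
    if population < 0:
        raise ValidationError(f"target population must be >= 0, got {population}")
    return change.expanded * effect.addressable_share * population


def primary_che_averted(spec: InterventionSpec, treated: float,
                        model: ConsumptionModel) -> float:
    """Expected CHE cases averted by waiving the service's own OOP payments.

    For screening interventions everyone screened faces the screening-cost
    OOP threshold test, and the screen-positive fraction additionally faces
    the treatment-cost OOP test; the two expected counts are summed.
    """
    if treated < 0:
        raise ValidationError(f"treated must be >= 0, got {treated}")
    if spec.screening is not None:
        scr = spec.screening
        return treated * che_probability(spec.oop_share * scr.screen_unit_cost, model) \
            + treated * scr.positivity_fraction \
            * che_probability(spec.oop_share * scr.treat_unit_cost, model)
    return treated * che_probability(spec.oop_amount, model)


def secondary_che_averted(links: Sequence[SecondaryLink],
                          delta_incidence_by_disease: Mapping[str, float],
                          model: ConsumptionModel) -> float:
    """Expected CHE cases averted through reduced downstream-care demand.

    One step deep (i -> j), no transitive closure: each prevented incident
    case would have sought downstream care j with probability C_j * A_jx.
    """
    total = 0.0
    for link in links:
        if link.disease_id not in delta_incidence_by_disease:
            raise ValidationError(
                f"link {link.upstream_id!r}->{link.downstream_id!r}: no averted "
                f"incidence available for disease {link.disease_id!r}"
            )
        averted_users = (delta_incidence_by_disease[link.disease_id]
                         * link.downstream_coverage * link.downstream_addressable)
        total += averted_users * che_probability(link.downstream_oop, model)
    return total


def averted_downstream_users(links: Sequence[SecondaryLink],
                             delta_incidence_by_disease: Mapping[str, float]
                             ) -> float:
    """dH_ij summed over links (the user count behind secondary FRP)."""
    return sum(
        delta_incidence_by_disease.get(link.disease_id, 0.0)
        * link.downstream_coverage * link.downstream_addressable
        for link in links
    )


def government_cost(spec: InterventionSpec, change: CoverageChange,
                    populations: Mapping[str, float],
                    cost_rule: CostRule = "detailed") -> float:
    """Cost to government of funding the intervention free at point of care.

    detailed: subsidise the waived OOP for baseline users and pay full unit
    cost for newly covered users, summed over targets. simple: full unit
    cost for the whole covered population (u * dH).
    """
    total = 0.0
    for target in spec.targets:
        pop = populations[target.disease_id]
        a = target.addressable_share
        if cost_rule == "simple":
            total += spec.unit_cost * change.expanded * a * pop
        else:
            total += (change.baseline * a * pop * spec.oop_share * spec.unit_cost
                      + change.increment * a * pop * spec.unit_cost)
    return total


def resolve_links(spec: InterventionSpec,
                  registry: Mapping[str, InterventionSpec]) -> list[SecondaryLink]:
    """Materialise the spec's (downstream_id, disease_id) pairs."""
    links = []
    for down_id, disease_id in spec.downstream_links:
        if down_id not in registry:
            raise ValidationError(
                f"intervention {spec.intervention_id!r}: dangling downstream "
                f"link to {down_id!r}"
            )
        down = registry[down_id]
        match = [t for t in down.targets if t.disease_id == disease_id]
        if not match:
            raise ValidationError(
                f"intervention {spec.intervention_id!r}: downstream "
                f"{down_id!r} does not target disease {disease_id!r}"
            )
        links.append(SecondaryLink(
            upstream_id=spec.intervention_id,
            downstream_id=down_id,
            disease_id=disease_id,
            downstream_coverage=down.baseline_coverage,
            downstream_addressable=match[0].addressable_share,
            downstream_oop=down.oop_amount,
        ))
    return links


def _evaluate_at(spec: InterventionSpec,
                 burdens: Mapping[str, DiseaseBurden],
                 model: ConsumptionModel,
                 change: CoverageChange,
                 links: Sequence[SecondaryLink],
                 burden_level: str,
                 effect_level: str) -> tuple[float, float, float, float, bool]:
    """(deaths, che_primary, che_secondary, treated, all_bounds_present)
    at one corner of the {low, mean, high} burden x effect grid."""
    deaths = 0.0
    treated = 0.0
    delta_incidence: dict[str, float] = {}
    complete = True
    for target in spec.targets:
        burden = burdens[target.disease_id]
        e, has_e = _bounded(target.effect, target.effect_bounds, effect_level)
        if effect_level != "mean":
            complete &= has_e
        if target.channel is Channel.INCIDENCE:
            inc, has_i = _bounded(burden.incidence, burden.incidence_bounds,
                                  burden_level)
            if burden_level != "mean":
                complete &= has_i
            d_inc, d_deaths = deaths_averted_incidence(
                change, target, burden, effect_value=e, incidence_value=inc)
            delta_incidence[target.disease_id] = (
                delta_incidence.get(target.disease_id, 0.0) + d_inc)
        else:
            dx, has_d = _bounded(burden.deaths, burden.deaths_bounds, burden_level)
            if burden_level != "mean":
                complete &= has_d
            d_deaths = deaths_averted_fatality(
                change, target, burden, effect_value=e, deaths_value=dx)
        deaths += d_deaths
        pop, _ = _bounded(resolve_target_population(target, burden),
                          burden.target_population_bounds
                          if target.target_population_override is None else None,
                          burden_level)
        treated += treated_population(change, target, pop)
    che_primary = primary_che_averted(spec, treated, model)
    che_secondary = secondary_che_averted(links, delta_incidence, model)
    return deaths, che_primary, che_secondary, treated, complete


def evaluate_intervention(
    spec: InterventionSpec,
    burdens: Mapping[str, DiseaseBurden],
    economy: EconomyConfig,
    scenario: Scenario = "central",
    cost_rule: CostRule = "detailed",
    registry: Optional[Mapping[str, InterventionSpec]] = None,
    model: Optional[ConsumptionModel] = None,
) -> InterventionOutcome:
    """Full per-intervention evaluation over all disease targets.

    The central estimate uses mean burden and mean effect. Optimistic and
    pessimistic bounds take the max/min of deaths averted and CHE cases
    averted over the 3x3 grid of {low, mean, high} burden x {low, mean,
    high} effect (9 combinations); fields without stated bounds fall back
    to their central value (with a warning if a non-central scenario was
    explicitly requested). Cost bounds are +/-50% of the unit cost.
    """
    if model is None:
        model = from_economy(economy)
    change = CoverageChange.from_increment(spec.baseline_coverage,
                                           economy.coverage_increment)
    links = resolve_links(spec, registry) if registry else []

    grid: dict[tuple[str, str], tuple[float, float, float, float, bool]] = {}
    for bl in _LEVELS:
        for el in _LEVELS:
            grid[(bl, el)] = _evaluate_at(spec, burdens, model, change, links,
                                          bl, el)
    deaths_c, che_p_c, che_s_c, treated_c, _ = grid[("mean", "mean")]
    all_deaths = [v[0] for v in grid.values()]
    all_che = [v[1] + v[2] for v in grid.values()]
    complete = all(v[4] for v in grid.values())
    if scenario != "central" and not complete:
        logger.warning(
            "intervention %r: some low/high bounds missing; %s scenario "
            "falls back to central values for those fields",
            spec.intervention_id, scenario,
        )

    populations = {
        t.disease_id: resolve_target_population(t, burdens[t.disease_id])
        for t in spec.targets
    }
    cost = government_cost(spec, change, populations, cost_rule)

    deaths_bounds = (min(all_deaths), max(all_deaths))
    che_bounds = (min(all_che), max(all_che))
    if scenario == "central":
        deaths, che = deaths_c, che_p_c + che_s_c
        che_p, che_s = che_p_c, che_s_c
    elif scenario == "optimistic":
        deaths, che = deaths_bounds[1], che_bounds[1]
        idx = max(grid.values(), key=lambda v: v[1] + v[2])
        che_p, che_s = idx[1], idx[2]
    else:
        deaths, che = deaths_bounds[0], che_bounds[0]
        idx = min(grid.values(), key=lambda v: v[1] + v[2])
        che_p, che_s = idx[1], idx[2]

    return InterventionOutcome(
        intervention_id=spec.intervention_id,
        deaths_averted=deaths,
        che_averted=che,
        che_primary=che_p,
        che_secondary=che_s,
        total_cost=cost,
        treated=treated_c,
        deaths_averted_bounds=deaths_bounds,
        che_averted_bounds=che_bounds,
        cost_bounds=(0.5 * cost, 1.5 * cost),
    )


def evaluate_all(
    specs: Sequence[InterventionSpec],
    burdens: Mapping[str, DiseaseBurden],
    economy: EconomyConfig,
    scenario: Scenario = "central",
    cost_rule: CostRule = "detailed",
    delay_mode: DelayMode = "steady_state",
    discount_rate: float = 0.0,
) -> list[InterventionOutcome]:
    """Evaluate every intervention against the same consumption model."""
    model = from_economy(economy)
    registry = {s.intervention_id: s for s in specs}
    outcomes = []
    for spec in specs:
        out = evaluate_intervention(spec, burdens, economy, scenario=scenario,
                                    cost_rule=cost_rule, registry=registry,
                                    model=model)
        outcomes.append(apply_delay(out, spec, delay_mode, discount_rate))
    return outcomes


def apply_delay(outcome: InterventionOutcome, spec: InterventionSpec,
                mode: DelayMode = "steady_state",
                discount_rate: float = 0.0) -> InterventionOutcome:
    """Annotate benefit timing; costs are always immediate (year 0).

    ``steady_state`` is the identity. ``lagged`` stamps the benefit year
    from the delay bin (0/5/10/20) with cost year 0. Benefit magnitudes are
    not discounted by default; a nonzero ``discount_rate`` scales the
    benefit fields by 1/(1+r)^delay as an optional hook.
    """
    if mode == "steady_state":
        return outcome
    years = spec.delay_bin.years
    factor = 1.0 / (1.0 + discount_rate) ** years if discount_rate > 0 else 1.0

    def _scale_bounds(b):
        return None if b is None else (b[0] * factor, b[1] * factor)

    return replace(
        outcome,
        deaths_averted=outcome.deaths_averted * factor,
        che_averted=outcome.che_averted * factor,
        che_primary=outcome.che_primary * factor,
        che_secondary=outcome.che_secondary * factor,
        deaths_averted_bounds=_scale_bounds(outcome.deaths_averted_bounds),
        che_averted_bounds=_scale_bounds(outcome.che_averted_bounds),
        benefit_year=years,
        cost_year=0,
    )


def bundle_totals(outcomes: Sequence[InterventionOutcome],
                  specs: Sequence[InterventionSpec]) -> dict[str, InterventionOutcome]:
    """Aggregate outcomes of bundled interventions (component sums).

    Components of a bundle (e.g. labor-and-delivery signal functions) are
    evaluated individually — each component's OOP faces its own threshold
    test — and their totals summed to the cumulative bundle total.
    """
    by_id = {o.intervention_id: o for o in outcomes}
    totals: dict[str, InterventionOutcome] = {}
    for bundle_id in sorted({s.bundle_id for s in specs if s.bundle_id}):
        members = [by_id[s.intervention_id] for s in specs
                   if s.bundle_id == bundle_id and s.intervention_id in by_id]
        totals[bundle_id] = InterventionOutcome(
            intervention_id=bundle_id,
            deaths_averted=sum(m.deaths_averted for m in members),
            che_averted=sum(m.che_averted for m in members),
            che_primary=sum(m.che_primary for m in members),
            che_secondary=sum(m.che_secondary for m in members),
            total_cost=sum(m.total_cost for m in members),
            treated=sum(m.treated for m in members),
        )
    return totals
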