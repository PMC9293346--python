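"""Seeded generator of realistic fixture tables, plus a hand-computed micro example.

The generator emulates the statistical shape of a national benefits-package
exercise in a low-income setting — around 20 candidate interventions over
around 23 disease areas, heterogeneous intervention costs spanning roughly
1e5 to 1e7 USD, out-of-pocket shares centred on the 34% health-sector
average — without reproducing any country's actual parameter values. The
economy block uses round placeholder values (mean consumption 1000 USD,
Gini 0.40); they are deliberately NOT the values of any real economy.

Everything is driven by one integer seed through ``numpy.random.default_rng``;
the same seed yields byte-identical tables. One deliberately expensive
intervention is always included so that budget sweeps exhibit the
displacement "cliff" where a high-cost high-value package enters and
evicts others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core_data import (
    Channel,
    DelayBin,
    DiseaseBurden,
    DiseaseTargetEffect,
    EconomyConfig,
    InterventionSpec,
    ScreeningCost,
    write_burden_table,
    write_economy,
    write_intervention_table,
    write_links_table,
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_interventions: int = 20
    n_diseases: int = 23
    seed: int = 0
    coverage_range: tuple[float, float] = (0.05, 0.80)
    effect_range: tuple[float, float] = (0.10, 0.90)
    addressable_range: tuple[float, float] = (0.20, 1.00)
    log10_unit_cost_range: tuple[float, float] = (0.3, 2.5)  # ~2 to ~300 USD
    oop_share_center: float = 0.34
    oop_share_sd: float = 0.12
    log10_incidence_range: tuple[float, float] = (4.0, 5.7)
    cfr_range: tuple[float, float] = (0.01, 0.50)
    log10_population_range: tuple[float, float] = (4.7, 6.7)
    bound_halfwidth_range: tuple[float, float] = (0.10, 0.50)  # +/-(10-50)%
    link_probability: float = 0.15
    bundle_count: int = 2
    bundle_size: int = 2
    screening_fraction: float = 0.20
    mean_consumption: float = 1000.0  # placeholder economy, not any country's
    gini: float = 0.40

    def __post_init__(self) -> None:
        if self.n_interventions < 3 or self.n_diseases < 2:
            raise ValueError("need at least 3 interventions and 2 diseases")
        if self.bundle_count * self.bundle_size > self.n_interventions:
            raise ValueError("bundles would need more interventions than exist")
        for name in ("coverage_range", "effect_range", "addressable_range",
                     "cfr_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must be within [0, 1] with lo <= hi")


@dataclass(frozen=True)
class FixtureTables:
    """A complete, validated model input set."""

    interventions: tuple[InterventionSpec, ...]
    burdens: dict[str, DiseaseBurden]
    economy: EconomyConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write interventions.csv, burden.csv, links.csv, economy.yaml."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "interventions": out / "interventions.csv",
            "burden": out / "burden.csv",
            "links": out / "links.csv",
            "economy": out / "economy.yaml",
        }
        write_intervention_table(self.interventions, paths["interventions"])
        write_burden_table(self.burdens, paths["burden"])
        write_links_table(self.interventions, paths["links"])
        write_economy(self.economy, paths["economy"])
        return paths


def _bounds_around(rng: np.random.Generator, mean: float,
                   halfwidth: tuple[float, float],
                   cap: Optional[float] = None) -> tuple[float, float]:
    lo_w, hi_w = rng.uniform(*halfwidth), rng.uniform(*halfwidth)
    low = mean * (1.0 - lo_w)
    high = mean * (1.0 + hi_w)
    if cap is not None:
        high = min(high, cap)
    return (low, max(high, mean))


def generate(config: GeneratorConfig = GeneratorConfig()) -> FixtureTables:
    """Draw a full fixture instance from the seeded generator.

    Guarantees at least one incidence-channel, one fatality-channel, one
    screening, one bundled, one delayed and one downstream-linked
    intervention, and deaths = incidence x CFR for every disease.
    """
    rng = np.random.default_rng(config.seed)
    hw = config.bound_halfwidth_range

    burdens: dict[str, DiseaseBurden] = {}
    disease_ids = [f"D{k + 1:02d}" for k in range(config.n_diseases)]
    for did in disease_ids:
        incidence = float(10 ** rng.uniform(*config.log10_incidence_range))
        cfr = float(rng.uniform(*config.cfr_range))
        deaths = incidence * cfr
        burdens[did] = DiseaseBurden(
            disease_id=did,
            incidence=incidence,
            cfr=cfr,
            deaths=deaths,
            target_population=float(10 ** rng.uniform(*config.log10_population_range)),
            incidence_bounds=_bounds_around(rng, incidence, hw),
            deaths_bounds=_bounds_around(rng, deaths, hw),
        )

    n = config.n_interventions
    n_screening = max(1, math.ceil(config.screening_fraction * n))
    bundle_of: dict[int, str] = {}
    # bundles occupy the tail indices so they never collide with the forced
    # channel/screening assignments at the head
    pos = n - 1
    for b in range(config.bundle_count):
        for _ in range(config.bundle_size):
            bundle_of[pos] = f"B{b + 1}"
            pos -= 1

    specs: list[InterventionSpec] = []
    incidence_targets: dict[str, int] = {}  # disease -> intervention index
    for i in range(n):
        iid = f"I{i + 1:02d}"
        n_targets = int(rng.integers(1, 4))
        target_ids = [disease_ids[j] for j in
                      rng.choice(config.n_diseases, size=n_targets, replace=False)]
        targets = []
        for t_pos, did in enumerate(target_ids):
            if i == 0:
                channel = Channel.INCIDENCE
            elif i == 1:
                channel = Channel.FATALITY
            else:
                channel = Channel.INCIDENCE if rng.random() < 0.5 else Channel.FATALITY
            effect = float(rng.uniform(*config.effect_range))
            pop_override = None
            if rng.random() < 0.3:
                pop_override = float(10 ** rng.uniform(4.0, 6.0))
            targets.append(DiseaseTargetEffect(
                disease_id=did,
                channel=channel,
                effect=effect,
                addressable_share=float(rng.uniform(*config.addressable_range)),
                effect_bounds=_bounds_around(rng, effect, hw, cap=1.0),
                target_population_override=pop_override,
            ))
            if channel is Channel.INCIDENCE and did not in incidence_targets:
                incidence_targets[did] = i

        unit_cost = float(10 ** rng.uniform(*config.log10_unit_cost_range))
        if i == n - 1:
            # the deliberately expensive candidate (sweep "cliff" behaviour)
            unit_cost = float(10 ** rng.uniform(2.5, 3.0))
        oop_share = float(np.clip(
            rng.normal(config.oop_share_center, config.oop_share_sd), 0.05, 0.90))

        screening = None
        if i < n_screening:
            positivity = float(rng.uniform(0.05, 0.5))
            screen_cost = float(rng.uniform(0.3, 0.8)) * unit_cost
            screening = ScreeningCost(
                screen_unit_cost=screen_cost,
                treat_unit_cost=(unit_cost - screen_cost) / positivity,
                positivity_fraction=positivity,
            )

        delay_bin = DelayBin(
            str(rng.choice(["none", "short", "medium", "long"],
                           p=[0.55, 0.20, 0.15, 0.10])))
        if i == 2:
            delay_bin = DelayBin.SHORT  # guarantee a delayed intervention

        specs.append(InterventionSpec(
            intervention_id=iid,
            name=f"intervention-{iid}",
            targets=tuple(targets),
            baseline_coverage=float(rng.uniform(*config.coverage_range)),
            unit_cost=unit_cost,
            oop_share=oop_share,
            delay_bin=delay_bin,
            screening=screening,
            bundle_id=bundle_of.get(i),
        ))

    # downstream links: an incidence-channel upstream feeds any intervention
    # that targets the same disease
    links_by_i: dict[int, list[tuple[str, str]]] = {}
    for did, i in sorted(incidence_targets.items()):
        for j, spec in enumerate(specs):
            if j == i:
                continue
            if any(t.disease_id == did for t in spec.targets):
                if rng.random() < config.link_probability:
                    links_by_i.setdefault(i, []).append(
                        (spec.intervention_id, did))
    if not links_by_i and incidence_targets:
        # guarantee at least one link by pointing the first incidence
        # upstream at any other intervention on the same disease, retargeting
        # one if necessary
        did, i = sorted(incidence_targets.items())[0]
        j = (i + 1) % len(specs)
        down = specs[j]
        if not any(t.disease_id == did for t in down.targets):
            new_targets = down.targets + (DiseaseTargetEffect(
                disease_id=did, channel=Channel.FATALITY,
                effect=float(rng.uniform(*config.effect_range)),
                addressable_share=float(rng.uniform(*config.addressable_range)),
            ),)
            down = InterventionSpec(
                intervention_id=down.intervention_id, name=down.name,
                targets=new_targets, baseline_coverage=down.baseline_coverage,
                unit_cost=down.unit_cost, oop_share=down.oop_share,
                delay_bin=down.delay_bin, screening=down.screening,
                bundle_id=down.bundle_id)
            specs[j] = down
        links_by_i[i] = [(down.intervention_id, did)]

    specs = [
        spec if i not in links_by_i else InterventionSpec(
            intervention_id=spec.intervention_id, name=spec.name,
            targets=spec.targets, baseline_coverage=spec.baseline_coverage,
            unit_cost=spec.unit_cost, oop_share=spec.oop_share,
            delay_bin=spec.delay_bin, screening=spec.screening,
            downstream_links=tuple(links_by_i[i]), bundle_id=spec.bundle_id)
        for i, spec in enumerate(specs)
    ]

    economy = EconomyConfig(
        mean_consumption=config.mean_consumption,
        gini=config.gini,
        che_threshold=0.10,
        coverage_increment=0.05,
        population_year_label="synthetic",
    )
    return FixtureTables(interventions=tuple(specs), burdens=burdens,
                         economy=economy)


# ---------------------------------------------------------------------------
# Worked micro example (all expected values derived by hand; see docs)

_E_034 = 1.0 - math.exp(-0.034)   # CHE probability at OOP 3.4, exp(scale 1000), t 0.10
_E_010 = 1.0 - math.exp(-0.10)    # CHE probability at OOP 10


@dataclass(frozen=True)
class MicroExample:
    tables: FixtureTables
    budget: float
    expected_deaths: dict[str, float]
    expected_treated: dict[str, float]
    expected_cost: dict[str, float]
    expected_che_primary: dict[str, float]
    expected_che_secondary: dict[str, float]
    #: non-dominated (selection, deaths, che) at ``budget``, ascending deaths
    expected_frontier: tuple[tuple[tuple[str, ...], float, float], ...]
    expected_lambda_star: float


def worked_micro_example() -> MicroExample:
    """Fixed 3-intervention, 2-disease instance with hand-computed outputs.

    The economy has Gini 0.5, so consumption is exponential with scale 1000
    USD and every CHE probability has the closed form 1 - exp(-OOP/100).

    * I1, a preventive vaccine: coverage 0.20 -> 0.25, effect 0.6 on
      incidence of D1 (addressable 0.5, incidence 100000, CFR 0.1):
      averted incidence 1500, deaths 150. Treated 0.25*0.5*100000 = 12500
      at OOP 3.4; downstream link to I2 averts 1500*0.4*0.5 = 300
      treatment episodes at OOP 10. Cost 10000*3.4 + 2500*10 = 59000.
    * I2, curative treatment: effect 0.5 on fatality of D1 (addressable
      0.5, deaths 10000): averts 125 deaths; treated 11250 at OOP 10;
      cost 10000*10 + 1250*20 = 125000.
    * I3, a surgical package: effect 0.4 on fatality of D2 (addressable
      1.0, deaths 20000): averts 400 deaths; treated 2500 at OOP 3.4;
      cost 2000*3.4 + 500*10 = 11800.

    At budget 130000 the feasible packages are all subsets except those
    containing I2 with anything else; the frontier is {I2} then {I1, I3}.
    """
    d1 = DiseaseBurden(disease_id="D1", incidence=100000.0, cfr=0.1,
                       deaths=10000.0, target_population=200000.0)
    d2 = DiseaseBurden(disease_id="D2", incidence=50000.0, cfr=0.4,
                       deaths=20000.0, target_population=50000.0)
    i1 = InterventionSpec(
        intervention_id="I1", name="preventive vaccine",
        targets=(DiseaseTargetEffect(
            disease_id="D1", channel=Channel.INCIDENCE, effect=0.6,
            addressable_share=0.5, target_population_override=100000.0),),
        baseline_coverage=0.20, unit_cost=10.0, oop_share=0.34,
        delay_bin=DelayBin.SHORT, downstream_links=(("I2", "D1"),))
    i2 = InterventionSpec(
        intervention_id="I2", name="curative treatment",
        targets=(DiseaseTargetEffect(
            disease_id="D1", channel=Channel.FATALITY, effect=0.5,
            addressable_share=0.5, target_population_override=50000.0),),
        baseline_coverage=0.40, unit_cost=20.0, oop_share=0.5)
    i3 = InterventionSpec(
        intervention_id="I3", name="surgical package",
        targets=(DiseaseTargetEffect(
            disease_id="D2", channel=Channel.FATALITY, effect=0.4,
            addressable_share=1.0, target_population_override=10000.0),),
        baseline_coverage=0.20, unit_cost=10.0, oop_share=0.34)

    tables = FixtureTables(
        interventions=(i1, i2, i3),
        burdens={"D1": d1, "D2": d2},
        economy=EconomyConfig(mean_consumption=1000.0, gini=0.5,
                              che_threshold=0.10, coverage_increment=0.05,
                              population_year_label="micro"),
    )
    che_i1_primary = 12500.0 * _E_034
    che_i1_secondary = 300.0 * _E_010
    che_i2 = 11250.0 * _E_010
    che_i3 = 2500.0 * _E_034
    frontier = (
        (("I2",), 125.0, che_i2),
        (("I1", "I3"), 550.0, che_i1_primary + che_i1_secondary + che_i3),
    )
    lam = (frontier[0][2] - frontier[1][2]) / (frontier[1][1] - frontier[0][1])
    return MicroExample(
        tables=tables,
        budget=130000.0,
        expected_deaths={"I1": 150.0, "I2": 125.0, "I3": 400.0},
        expected_treated={"I1": 12500.0, "I2": 11250.0, "I3": 2500.0},
        expected_cost={"I1": 59000.0, "I2": 125000.0, "I3": 11800.0},
        expected_che_primary={"I1": che_i1_primary, "I2": che_i2,
                              "I3": che_i3},
        expected_che_secondary={"I1": che_i1_secondary, "I2": 0.0, "I3": 0.0},
        expected_frontier=frontier,
        expected_lambda_star=lam,
    )
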