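"""Domain types, table schemas, readers/writers and validation.

The model is driven by three plain-text tables plus one YAML config:

``interventions.csv``
    Long format, one row per intervention x disease target. Intervention-level
    columns (name, coverage, cost, ...) are repeated on every row of the same
    intervention and must agree.
``burden.csv``
    One row per disease: incidence, case-fatality ratio, deaths, default
    target population, optional low/high bounds.
``links.csv``
    Downstream-care links (upstream intervention, downstream intervention,
    shared disease) feeding the secondary financial-risk-protection channel.
``economy.yaml``
    Mean per-capita consumption, Gini coefficient, catastrophic-expenditure
    threshold and the coverage-increment policy parameter.

All identifiers are case-sensitive opaque strings; no ICD-10 parsing is
performed. Out-of-pocket spending is stored as a *share* of unit cost
(``oop_share``); the absolute OOP amount is always derived, never stored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger("hbpopt")

#: Out-of-pocket share applied when a row leaves the column blank
#: (health-sector average).
DEFAULT_OOP_SHARE = 0.34

#: Absolute tolerance for float comparisons on costs/objective values.
ATOL = 1e-6


class SchemaError(ValueError):
    """A table is missing a required column or has a malformed header."""


class ValidationError(ValueError):
    """A field value violates a domain invariant; message names row and field."""


class CrossReferenceError(ValueError):
    """A row references an intervention or disease that does not exist."""


class Channel(str, Enum):
    """Effect channel: acts on disease incidence or directly on fatality."""

    INCIDENCE = "incidence"
    FATALITY = "fatality"


class DelayBin(str, Enum):
    """Benefit-delay category; costs are always immediate."""

    NONE = "none"
    SHORT = "short"
    MEDIUM = "medium"
    LONG = "long"

    @property
    def years(self) -> int:
        return {"none": 0, "short": 5, "medium": 10, "long": 20}[self.value]


Bounds = tuple[float, float]  # (low, high)


def _check_bounds(name: str, mean: float, bounds: Optional[Bounds], where: str) -> None:
    if bounds is None:
        return
    low, high = bounds
    if not (low <= mean + ATOL and mean <= high + ATOL):
        raise ValidationError(
            f"{where}: bounds for {name!r} must satisfy low <= mean <= high, "
            f"got low={low}, mean={mean}, high={high}"
        )


def _check_fraction(name: str, value: float, where: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{where}: {name!r} must lie in [0, 1], got {value}")


def _check_nonneg(name: str, value: float, where: str) -> None:
    if value < 0:
        raise ValidationError(f"{where}: {name!r} must be >= 0, got {value}")


@dataclass(frozen=True)
class DiseaseBurden:
    """Annual burden of one disease category.

    ``target_population`` is the default population an intervention acts on
    when its target row does not override it (general, incident or prevalent
    population depending on the disease).
    """

    disease_id: str
    incidence: float
    cfr: float
    deaths: float
    target_population: float
    incidence_bounds: Optional[Bounds] = None
    deaths_bounds: Optional[Bounds] = None
    target_population_bounds: Optional[Bounds] = None

    def __post_init__(self) -> None:
        where = f"disease {self.disease_id!r}"
        _check_nonneg("incidence", self.incidence, where)
        _check_nonneg("deaths", self.deaths, where)
        _check_nonneg("target_population", self.target_population, where)
        _check_fraction("cfr", self.cfr, where)
        _check_bounds("incidence", self.incidence, self.incidence_bounds, where)
        _check_bounds("deaths", self.deaths, self.deaths_bounds, where)
        _check_bounds(
            "target_population", self.target_population,
            self.target_population_bounds, where,
        )


@dataclass(frozen=True)
class DiseaseTargetEffect:
    """Effect of one intervention on one disease target."""

    disease_id: str
    channel: Channel
    effect: float
    addressable_share: float
    effect_bounds: Optional[Bounds] = None
    target_population_override: Optional[float] = None

    def __post_init__(self) -> None:
        where = f"target {self.disease_id!r}"
        _check_fraction("effect", self.effect, where)
        _check_fraction("addressable_share", self.addressable_share, where)
        _check_bounds("effect", self.effect, self.effect_bounds, where)
        if self.target_population_override is not None:
            _check_nonneg(
                "target_population_override", self.target_population_override, where
            )


@dataclass(frozen=True)
class ScreeningCost:
    """Two-stage costing: everyone screened, positives additionally treated.

    The effective per-person unit cost is
    ``screen_unit_cost + positivity_fraction * treat_unit_cost``.
    """

    screen_unit_cost: float
    treat_unit_cost: float
    positivity_fraction: float

    def __post_init__(self) -> None:
        _check_nonneg("screen_unit_cost", self.screen_unit_cost, "screening")
        _check_nonneg("treat_unit_cost", self.treat_unit_cost, "screening")
        _check_fraction("positivity_fraction", self.positivity_fraction, "screening")

    @property
    def effective_unit_cost(self) -> float:
        return self.screen_unit_cost + self.positivity_fraction * self.treat_unit_cost


@dataclass(frozen=True)
class InterventionSpec:
    """One candidate intervention with its targets, cost and coverage."""

    intervention_id: str
    name: str
    targets: tuple[DiseaseTargetEffect, ...]
    baseline_coverage: float
    unit_cost: float
    oop_share: float
    delay_bin: DelayBin = DelayBin.NONE
    screening: Optional[ScreeningCost] = None
    downstream_links: tuple[tuple[str, str], ...] = ()  # (downstream_id, disease_id)
    bundle_id: Optional[str] = None

    def __post_init__(self) -> None:
        where = f"intervention {self.intervention_id!r}"
        _check_fraction("baseline_coverage", self.baseline_coverage, where)
        _check_nonneg("unit_cost", self.unit_cost, where)
        _check_fraction("oop_share", self.oop_share, where)
        if not self.targets:
            raise ValidationError(f"{where}: must have at least one disease target")
        if self.screening is not None:
            eff = self.screening.effective_unit_cost
            if not math.isclose(eff, self.unit_cost, rel_tol=1e-6, abs_tol=ATOL):
                raise ValidationError(
                    f"{where}: screening decomposition gives effective unit cost "
                    f"{eff}, but unit_cost is {self.unit_cost}"
                )

    @property
    def oop_amount(self) -> float:
        """Baseline per-person out-of-pocket payment (derived, never stored)."""
        return self.oop_share * self.unit_cost


@dataclass(frozen=True)
class EconomyConfig:
    """Economy-wide parameters and policy settings."""

    mean_consumption: float
    gini: float
    che_threshold: float = 0.10
    coverage_increment: float = 0.05
    population_year_label: str = ""

    def __post_init__(self) -> None:
        where = "economy"
        if self.mean_consumption <= 0:
            raise ValidationError(f"{where}: mean_consumption must be > 0")
        if not (0.0 < self.gini < 1.0):
            raise ValidationError(f"{where}: gini must lie in (0, 1), got {self.gini}")
        if not (0.0 < self.che_threshold < 1.0):
            raise ValidationError(
                f"{where}: che_threshold must lie in (0, 1), got {self.che_threshold}"
            )
        _check_fraction("coverage_increment", self.coverage_increment, where)


@dataclass(frozen=True)
class InterventionOutcome:
    """Per-intervention expected benefits and government cost.

    Expected counts are kept fractional; rounding happens only at report
    time. ``che_averted`` is the sum of the primary channel (waived OOP for
    the covered service) and the secondary channel (averted downstream-care
    OOP from prevented incidence).
    """

    intervention_id: str
    deaths_averted: float
    che_averted: float
    che_primary: float
    che_secondary: float
    total_cost: float
    treated: float
    deaths_averted_bounds: Optional[Bounds] = None  # (pessimistic, optimistic)
    che_averted_bounds: Optional[Bounds] = None
    cost_bounds: Optional[Bounds] = None
    benefit_year: Optional[int] = None
    cost_year: Optional[int] = None

    def __post_init__(self) -> None:
        where = f"outcome {self.intervention_id!r}"
        for name in ("deaths_averted", "che_averted", "che_primary",
                     "che_secondary", "total_cost", "treated"):
            _check_nonneg(name, getattr(self, name), where)
        _check_bounds("deaths_averted", self.deaths_averted,
                      self.deaths_averted_bounds, where)
        _check_bounds("che_averted", self.che_averted, self.che_averted_bounds, where)
        _check_bounds("total_cost", self.total_cost, self.cost_bounds, where)


@dataclass(frozen=True)
class FrontierPoint:
    """One package on (or off, if infeasible) the Pareto frontier."""

    selection: tuple[str, ...]  # selected intervention ids, input order
    deaths_averted: float
    che_averted: float
    cost: float
    budget: float
    k_constraint: Optional[float] = None
    feasible: bool = True

    def __post_init__(self) -> None:
        if self.feasible and self.cost > self.budget + ATOL:
            raise ValidationError(
                f"frontier point cost {self.cost} exceeds budget {self.budget}"
            )


# ---------------------------------------------------------------------------
# CSV schemas

INTERVENTION_COLUMNS = [
    "intervention_id", "name", "disease_id", "channel", "effect",
    "effect_low", "effect_high", "addressable_share",
    "target_population_override", "baseline_coverage", "unit_cost",
    "screen_unit_cost", "treat_unit_cost", "positivity_fraction",
    "oop_share", "delay_bin", "bundle_id",
]

BURDEN_COLUMNS = [
    "disease_id", "incidence", "incidence_low", "incidence_high", "cfr",
    "deaths", "deaths_low", "deaths_high", "target_population",
]

LINK_COLUMNS = ["intervention_id", "downstream_intervention_id", "disease_id"]

OUTCOME_COLUMNS = [
    "intervention_id", "deaths_averted", "che_averted", "che_primary",
    "che_secondary", "total_cost", "treated",
    "deaths_averted_pessimistic", "deaths_averted_optimistic",
    "che_averted_pessimistic", "che_averted_optimistic",
    "cost_pessimistic", "cost_optimistic", "benefit_year", "cost_year",
]

FRONTIER_COLUMNS = [
    "deaths_averted", "che_averted", "cost", "k_constraint", "selection",
]

FLOAT_PRECISION = 6  # decimal places in result files


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _opt(value) -> Optional[float]:
    """NaN/empty cell -> None."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _opt_bounds(low, high) -> Optional[Bounds]:
    lo, hi = _opt(low), _opt(high)
    if lo is None and hi is None:
        return None
    if lo is None or hi is None:
        raise ValidationError("bounds must give both low and high or neither")
    return (lo, hi)


def read_burden_table(path: str | Path) -> dict[str, DiseaseBurden]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, BURDEN_COLUMNS, str(path))
    burdens: dict[str, DiseaseBurden] = {}
    for idx, row in df.iterrows():
        disease_id = str(row["disease_id"])
        if disease_id in burdens:
            raise ValidationError(f"{path} row {idx}: duplicate disease_id {disease_id!r}")
        try:
            burdens[disease_id] = DiseaseBurden(
                disease_id=disease_id,
                incidence=float(row["incidence"]),
                cfr=float(row["cfr"]),
                deaths=float(row["deaths"]),
                target_population=float(row["target_population"]),
                incidence_bounds=_opt_bounds(row["incidence_low"], row["incidence_high"]),
                deaths_bounds=_opt_bounds(row["deaths_low"], row["deaths_high"]),
            )
        except ValidationError as err:
            raise ValidationError(f"{path} row {idx}: {err}") from None
    return burdens


def read_links_table(path: str | Path) -> list[tuple[str, str, str]]:
    """Returns (upstream_id, downstream_id, disease_id) triples."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, LINK_COLUMNS, str(path))
    return [
        (str(r["intervention_id"]), str(r["downstream_intervention_id"]),
         str(r["disease_id"]))
        for _, r in df.iterrows()
    ]


def read_intervention_table(
    path: str | Path,
    burden_path: str | Path,
    links_path: Optional[str | Path] = None,
    default_oop_share: float = DEFAULT_OOP_SHARE,
) -> tuple[list[InterventionSpec], dict[str, DiseaseBurden]]:
    """Read and cross-validate the intervention and burden tables.

    Rows sharing an ``intervention_id`` form one intervention with several
    disease targets; intervention-level columns must agree across the rows.
    A blank ``oop_share`` falls back to ``default_oop_share`` (the
    health-sector average) with a logged warning. Unknown disease ids and
    dangling downstream links raise :class:`CrossReferenceError`.
    """
    burdens = read_burden_table(burden_path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, INTERVENTION_COLUMNS, str(path))

    links_by_upstream: dict[str, list[tuple[str, str]]] = {}
    if links_path is not None:
        for up, down, dis in read_links_table(links_path):
            links_by_upstream.setdefault(up, []).append((down, dis))

    specs: list[InterventionSpec] = []
    order: list[str] = []
    grouped: dict[str, list[tuple[int, pd.Series]]] = {}
    for idx, row in df.iterrows():
        iid = str(row["intervention_id"])
        if iid not in grouped:
            order.append(iid)
        grouped.setdefault(iid, []).append((idx, row))

    for iid in order:
        rows = grouped[iid]
        first_idx, first = rows[0]
        where = f"{path} row {first_idx}"

        # intervention-level columns must be constant within the group
        for col in ("name", "baseline_coverage", "unit_cost", "oop_share",
                    "delay_bin", "bundle_id", "screen_unit_cost",
                    "treat_unit_cost", "positivity_fraction"):
            vals = {repr(r[col]) for _, r in rows}
            if len(vals) > 1:
                raise ValidationError(
                    f"{path}: intervention {iid!r} has inconsistent {col!r} "
                    f"across its target rows"
                )

        targets = []
        for idx, row in rows:
            disease_id = str(row["disease_id"])
            if disease_id not in burdens:
                raise CrossReferenceError(
                    f"{path} row {idx}: unknown disease_id {disease_id!r}"
                )
            try:
                channel = Channel(str(row["channel"]))
            except ValueError:
                raise ValidationError(
                    f"{path} row {idx}: 'channel' must be one of "
                    f"{[c.value for c in Channel]}, got {row['channel']!r}"
                ) from None
            try:
                targets.append(DiseaseTargetEffect(
                    disease_id=disease_id,
                    channel=channel,
                    effect=float(row["effect"]),
                    addressable_share=float(row["addressable_share"]),
                    effect_bounds=_opt_bounds(row["effect_low"], row["effect_high"]),
                    target_population_override=_opt(row["target_population_override"]),
                ))
            except ValidationError as err:
                raise ValidationError(f"{path} row {idx}: {err}") from None

        oop_share = _opt(first["oop_share"])
        if oop_share is None:
            logger.warning(
                "intervention %r: oop_share missing, using health-sector "
                "average %.2f", iid, default_oop_share,
            )
            oop_share = default_oop_share

        screening = None
        if _opt(first["screen_unit_cost"]) is not None:
            screening = ScreeningCost(
                screen_unit_cost=float(first["screen_unit_cost"]),
                treat_unit_cost=float(first["treat_unit_cost"]),
                positivity_fraction=float(first["positivity_fraction"]),
            )

        bundle = first["bundle_id"]
        bundle_id = None if _is_blank(bundle) else str(bundle)

        try:
            delay_bin = DelayBin(str(first["delay_bin"]))
        except ValueError:
            raise ValidationError(
                f"{where}: 'delay_bin' must be one of "
                f"{[d.value for d in DelayBin]}, got {first['delay_bin']!r}"
            ) from None

        try:
            specs.append(InterventionSpec(
                intervention_id=iid,
                name=str(first["name"]),
                targets=tuple(targets),
                baseline_coverage=float(first["baseline_coverage"]),
                unit_cost=float(first["unit_cost"]),
                oop_share=oop_share,
                delay_bin=delay_bin,
                screening=screening,
                downstream_links=tuple(links_by_upstream.get(iid, ())),
                bundle_id=bundle_id,
            ))
        except ValidationError as err:
            raise ValidationError(f"{where}: {err}") from None

    # cross-check downstream links against the loaded universe
    known = {s.intervention_id for s in specs}
    targets_of = {s.intervention_id: {t.disease_id for t in s.targets} for s in specs}
    for spec in specs:
        for down, dis in spec.downstream_links:
            if down not in known:
                raise CrossReferenceError(
                    f"intervention {spec.intervention_id!r}: downstream link to "
                    f"unknown intervention {down!r}"
                )
            if dis not in burdens:
                raise CrossReferenceError(
                    f"intervention {spec.intervention_id!r}: downstream link on "
                    f"unknown disease {dis!r}"
                )
            if dis not in targets_of[down]:
                raise CrossReferenceError(
                    f"intervention {spec.intervention_id!r}: downstream "
                    f"intervention {down!r} does not target disease {dis!r}"
                )
    return specs, burdens


def _is_blank(value) -> bool:
    return (
        value is None
        or (isinstance(value, float) and math.isnan(value))
        or (isinstance(value, str) and value.strip() == "")
    )


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest round-trip representation
    return str(value)


def _write_csv(path: str | Path, columns: Sequence[str],
               rows: Iterable[Sequence[object]]) -> None:
    lines = [",".join(columns)]
    for row in rows:
        lines.append(",".join(_cell(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_burden_table(burdens: Mapping[str, DiseaseBurden] | Iterable[DiseaseBurden],
                       path: str | Path) -> None:
    if isinstance(burdens, Mapping):
        burdens = burdens.values()
    rows = []
    for b in burdens:
        ib = b.incidence_bounds or (None, None)
        db = b.deaths_bounds or (None, None)
        rows.append([b.disease_id, b.incidence, ib[0], ib[1], b.cfr,
                     b.deaths, db[0], db[1], b.target_population])
    _write_csv(path, BURDEN_COLUMNS, rows)


def write_intervention_table(specs: Iterable[InterventionSpec],
                             path: str | Path) -> None:
    rows = []
    for s in specs:
        scr = s.screening
        for t in s.targets:
            eb = t.effect_bounds or (None, None)
            rows.append([
                s.intervention_id, s.name, t.disease_id, t.channel.value,
                t.effect, eb[0], eb[1], t.addressable_share,
                t.target_population_override, s.baseline_coverage, s.unit_cost,
                scr.screen_unit_cost if scr else None,
                scr.treat_unit_cost if scr else None,
                scr.positivity_fraction if scr else None,
                s.oop_share, s.delay_bin.value, s.bundle_id,
            ])
    _write_csv(path, INTERVENTION_COLUMNS, rows)


def write_links_table(specs: Iterable[InterventionSpec], path: str | Path) -> None:
    rows = []
    for s in specs:
        for down, dis in s.downstream_links:
            rows.append([s.intervention_id, down, dis])
    _write_csv(path, LINK_COLUMNS, rows)


def read_economy(path: str | Path) -> EconomyConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: economy config must be a mapping")
    for key in ("mean_consumption", "gini"):
        if key not in raw:
            raise SchemaError(f"{path}: missing key {key!r}")
    return EconomyConfig(
        mean_consumption=float(raw["mean_consumption"]),
        gini=float(raw["gini"]),
        che_threshold=float(raw.get("che_threshold", 0.10)),
        coverage_increment=float(raw.get("coverage_increment", 0.05)),
        population_year_label=str(raw.get("population_year_label", "")),
    )


def write_economy(economy: EconomyConfig, path: str | Path) -> None:
    import yaml

    data = {
        "mean_consumption": economy.mean_consumption,
        "gini": economy.gini,
        "che_threshold": economy.che_threshold,
        "coverage_increment": economy.coverage_increment,
        "population_year_label": economy.population_year_label,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _round(x: Optional[float]) -> Optional[float]:
    return None if x is None else round(float(x), FLOAT_PRECISION)


def write_results(results: Sequence[InterventionOutcome] | Sequence[FrontierPoint],
                  path: str | Path) -> None:
    """Write outcomes or frontier points to CSV.

    Frontier points are sorted ascending by deaths averted, with the
    selection serialized as semicolon-joined intervention ids; floats are
    written at fixed precision. An empty frontier produces a header-only
    file (outcome layout is the default for an empty sequence).
    """
    results = list(results)
    if results and isinstance(results[0], FrontierPoint):
        pts = sorted(results, key=lambda p: (p.deaths_averted, p.che_averted))
        rows = [
            [_round(p.deaths_averted), _round(p.che_averted), _round(p.cost),
             _round(p.k_constraint), ";".join(p.selection)]
            for p in pts
        ]
        _write_csv(path, FRONTIER_COLUMNS, rows)
        return
    rows = []
    for o in results:
        db = o.deaths_averted_bounds or (None, None)
        cb = o.che_averted_bounds or (None, None)
        tb = o.cost_bounds or (None, None)
        rows.append([
            o.intervention_id, _round(o.deaths_averted), _round(o.che_averted),
            _round(o.che_primary), _round(o.che_secondary), _round(o.total_cost),
            _round(o.treated), _round(db[0]), _round(db[1]), _round(cb[0]),
            _round(cb[1]), _round(tb[0]), _round(tb[1]),
            o.benefit_year, o.cost_year,
        ])
    _write_csv(path, OUTCOME_COLUMNS, rows)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV back as a DataFrame (round-trip of write_results)."""
    return pd.read_csv(path, float_precision="round_trip")
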