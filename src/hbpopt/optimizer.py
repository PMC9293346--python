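"""Exact bi-criterion 0/1 selection of interventions under a budget.

The decision problem is a two-objective knapsack: choose a subset Z of the
candidate interventions maximizing one objective (deaths averted or CHE
cases averted) subject to a budget on total government cost, optionally
with a floor K on the second objective (epsilon-constraint). Sweeping K
with the jump rule (next K = achieved second objective + step) and a
lexicographic second-stage maximization traces the complete Pareto
frontier, including unsupported points that no weighted-sum scan can find.

The backend enumerates all subsets of *units* (bundles are all-or-nothing
and collapse to a single unit) with vectorized subset sums, so every result
is a guaranteed global optimum — practical for the desk-scale instances
this method is designed for (N around 20 candidates). Ties are broken
deterministically: higher auxiliary objective, then lower cost, then
preference for selecting earlier-listed interventions.

The convergence ratio of a frontier answers the preference-elicitation
question: above what relative valuation of the two outcomes does the
bi-criterion optimum coincide with the single-objective optimum?
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

from .core_data import ATOL, FrontierPoint, InterventionOutcome, ValidationError

Objective = Literal["deaths", "che"]

#: Tolerance used for the epsilon-constraint floor; strictly tighter than
#: the jump step so the K loop always advances.
K_ATOL = 1e-9

#: Default jump step for frontier tracing: tolerance-scale, so no
#: non-dominated point can hide inside a jump. Pass k_step=1.0 for a
#: unit-increment sweep.
DEFAULT_K_STEP = 1e-6

_MAX_UNITS = 22  # 2^22 subsets; enumeration memory bound


def _objective_values(outcomes: Sequence[InterventionOutcome],
                      objective: Objective) -> np.ndarray:
    attr = "deaths_averted" if objective == "deaths" else "che_averted"
    return np.array([getattr(o, attr) for o in outcomes], dtype=float)


@dataclass(frozen=True)
class OptimizationProblem:
    """One solve: outcomes, budget, objective, optional epsilon floor."""

    outcomes: tuple[InterventionOutcome, ...]
    budget: float
    objective: Objective = "deaths"
    constraint_objective: Optional[Objective] = None
    k: float = 0.0
    bundles: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValidationError(f"budget must be >= 0, got {self.budget}")
        if self.k < 0:
            raise ValidationError(f"K must be >= 0, got {self.k}")
        if (self.constraint_objective is not None
                and self.constraint_objective == self.objective):
            raise ValidationError("objective and constraint_objective must differ")


class _Enumeration:
    """Vectorized subset sums over bundle-collapsed units."""

    def __init__(self, outcomes: Sequence[InterventionOutcome],
                 bundles: Mapping[str, Sequence[str]]):
        self.outcomes = list(outcomes)
        ids = [o.intervention_id for o in self.outcomes]
        index = {iid: i for i, iid in enumerate(ids)}
        member_of: dict[int, str] = {}
        for bid, members in bundles.items():
            for iid in members:
                if iid not in index:
                    raise ValidationError(
                        f"bundle {bid!r} references unknown intervention {iid!r}")
                member_of[index[iid]] = bid
        units: list[list[int]] = []
        seen_bundle: dict[str, int] = {}
        for i in range(len(ids)):
            bid = member_of.get(i)
            if bid is None:
                units.append([i])
            elif bid in seen_bundle:
                units[seen_bundle[bid]].append(i)
            else:
                seen_bundle[bid] = len(units)
                units.append([i])
        if len(units) > _MAX_UNITS:
            raise ValidationError(
                f"enumeration backend supports at most {_MAX_UNITS} "
                f"independent units, got {len(units)}")
        self.units = units
        self.ids = ids

        cost = np.array([o.total_cost for o in self.outcomes])
        deaths = _objective_values(self.outcomes, "deaths")
        che = _objective_values(self.outcomes, "che")
        unit_cost = np.array([cost[u].sum() for u in units])
        unit_deaths = np.array([deaths[u].sum() for u in units])
        unit_che = np.array([che[u].sum() for u in units])

        self.cost = self._subset_sums(unit_cost)
        self.deaths = self._subset_sums(unit_deaths)
        self.che = self._subset_sums(unit_che)
        # bit-reversed mask: larger value <=> earlier units selected first,
        # the deterministic last-resort tie-break
        m = len(units)
        masks = np.arange(self.cost.size, dtype=np.uint64)
        rev = np.zeros_like(masks)
        for b in range(m):
            rev |= ((masks >> np.uint64(b)) & np.uint64(1)) << np.uint64(m - 1 - b)
        self.rev = rev

    @staticmethod
    def _subset_sums(values: np.ndarray) -> np.ndarray:
        sums = np.zeros(1)
        for v in values:
            sums = np.concatenate([sums, sums + v])
        return sums

    def value(self, objective: Objective) -> np.ndarray:
        return self.deaths if objective == "deaths" else self.che

    def selection(self, mask: int) -> tuple[str, ...]:
        chosen = sorted(
            i for b, unit in enumerate(self.units) if mask >> b & 1 for i in unit
        )
        return tuple(self.ids[i] for i in chosen)

    def argbest(self, feasible: np.ndarray, obj1: np.ndarray,
                obj2: np.ndarray) -> Optional[int]:
        """Deterministic argmax with the tie-break cascade; None if infeasible."""
        idx = np.flatnonzero(feasible)
        if idx.size == 0:
            return None
        v = obj1[idx]
        idx = idx[v >= v.max() - ATOL]
        v = obj2[idx]
        idx = idx[v >= v.max() - ATOL]
        c = self.cost[idx]
        idx = idx[c <= c.min() + ATOL]
        return int(idx[np.argmax(self.rev[idx])])

    def point(self, mask: int, budget: float,
              k: Optional[float] = None) -> FrontierPoint:
        return FrontierPoint(
            selection=self.selection(mask),
            deaths_averted=float(self.deaths[mask]),
            che_averted=float(self.che[mask]),
            cost=float(self.cost[mask]),
            budget=budget,
            k_constraint=k,
        )


def solve_single(problem: OptimizationProblem) -> FrontierPoint:
    """Global optimum of the single objective under the budget.

    The auxiliary objective is reported but not optimized (beyond its role
    as the first tie-break). The empty package is always feasible, so a
    zero budget returns it.
    """
    enum = _Enumeration(problem.outcomes, problem.bundles)
    obj1 = enum.value(problem.objective)
    obj2 = enum.value("che" if problem.objective == "deaths" else "deaths")
    mask = enum.argbest(enum.cost <= problem.budget + ATOL, obj1, obj2)
    assert mask is not None  # empty subset is feasible
    return enum.point(mask, problem.budget)


def solve_epsilon(problem: OptimizationProblem) -> FrontierPoint:
    """Maximize the objective subject to budget and second objective >= K.

    Infeasibility (K above the achievable maximum) is reported as a
    FrontierPoint with ``feasible=False``, never raised.
    """
    if problem.constraint_objective is None:
        raise ValidationError("solve_epsilon requires constraint_objective")
    enum = _Enumeration(problem.outcomes, problem.bundles)
    obj1 = enum.value(problem.objective)
    obj2 = enum.value(problem.constraint_objective)
    feasible = (enum.cost <= problem.budget + ATOL) & (obj2 >= problem.k - K_ATOL)
    mask = enum.argbest(feasible, obj1, obj2)
    if mask is None:
        return FrontierPoint(selection=(), deaths_averted=0.0, che_averted=0.0,
                             cost=0.0, budget=problem.budget,
                             k_constraint=problem.k, feasible=False)
    return enum.point(mask, problem.budget, k=problem.k)


@dataclass(frozen=True)
class ParetoFrontier:
    """Non-dominated packages at one budget, ascending in deaths averted."""

    points: tuple[FrontierPoint, ...]
    budget: float

    def __post_init__(self) -> None:
        pts = self.points
        for a, b in zip(pts, pts[1:]):
            if not (a.deaths_averted < b.deaths_averted - K_ATOL
                    and a.che_averted > b.che_averted + K_ATOL):
                raise ValidationError(
                    "frontier points must be strictly increasing in deaths "
                    "averted and strictly decreasing in CHE cases averted")

    @property
    def deaths_max(self) -> FrontierPoint:
        return self.points[-1]

    @property
    def che_max(self) -> FrontierPoint:
        return self.points[0]


def pareto_frontier(outcomes: Sequence[InterventionOutcome], budget: float,
                    bundles: Optional[Mapping[str, Sequence[str]]] = None,
                    k_step: float = DEFAULT_K_STEP) -> ParetoFrontier:
    """Trace the complete Pareto frontier by the epsilon-constraint loop.

    Maximizes deaths averted subject to CHE cases averted >= K, jumping K
    to the achieved CHE value plus ``k_step`` after each solve. The
    built-in tie-break (max CHE among deaths-optimal packages) is the
    lexicographic second stage that makes every returned point
    Pareto-optimal. With the default tolerance-scale step the result is
    the complete non-dominated set; ``k_step=1.0`` reproduces a
    unit-increment sweep, which may skip points closer than one unit in
    CHE cases averted.
    """
    bundles = bundles or {}
    enum = _Enumeration(outcomes, bundles)
    within_budget = enum.cost <= budget + ATOL
    points: list[FrontierPoint] = []
    k = 0.0
    while True:
        feasible = within_budget & (enum.che >= k - K_ATOL)
        mask = enum.argbest(feasible, enum.deaths, enum.che)
        if mask is None:
            break
        pt = enum.point(mask, budget, k=k)
        # the new point always has strictly higher CHE; a predecessor with
        # no more deaths averted is dominated (tolerance-band ties)
        while points and pt.deaths_averted >= points[-1].deaths_averted - K_ATOL:
            points.pop()
        points.append(pt)
        k = pt.che_averted + k_step
    points.reverse()  # ascending deaths averted
    return ParetoFrontier(points=tuple(points), budget=budget)


def convergence_ratio(frontier: ParetoFrontier,
                      endpoint: Objective = "deaths") -> float:
    """Preference weight above which the bi-criterion optimum is one endpoint.

    For the deaths endpoint: the smallest lambda (CHE cases per death) such
    that for every weight lambda' >= lambda the maximizer of
    lambda' * deaths + CHE over the frontier is the deaths-max package:

        lambda* = max_{j != *} (CHE_j - CHE_*) / (deaths_* - deaths_j).

    The symmetric ratio for the CHE endpoint weighs deaths per CHE case.
    A single-point frontier needs no tradeoff and returns 0.
    """
    pts = frontier.points
    if len(pts) < 2:
        return 0.0
    if endpoint == "deaths":
        star = frontier.deaths_max
        return max(
            (p.che_averted - star.che_averted)
            / (star.deaths_averted - p.deaths_averted)
            for p in pts if p is not star
        )
    star = frontier.che_max
    return max(
        (p.deaths_averted - star.deaths_averted)
        / (star.che_averted - p.che_averted)
        for p in pts if p is not star
    )


@dataclass(frozen=True)
class SweepPoint:
    """Single-objective optimum at one budget of a sweep."""

    budget: float
    point: FrontierPoint
    objective_value: float
    auxiliary_value: float
    entered: tuple[str, ...]
    exited: tuple[str, ...]


def budget_sweep(outcomes: Sequence[InterventionOutcome],
                 budgets: Sequence[float], objective: Objective = "deaths",
                 bundles: Optional[Mapping[str, Sequence[str]]] = None
                 ) -> list[SweepPoint]:
    """Single-objective optimum per budget, with package turnover reported.

    The optimized objective is non-decreasing in the budget (the feasible
    set only grows) and this is asserted; the auxiliary outcome is
    unconstrained and may drop when an expensive high-value package enters
    and displaces others.
    """
    if len(budgets) == 0:
        raise ValidationError("budget list must be non-empty")
    if any(b2 < b1 for b1, b2 in zip(budgets, budgets[1:])):
        raise ValidationError("budgets must be sorted ascending")
    bundles = bundles or {}
    results: list[SweepPoint] = []
    prev_sel: frozenset[str] = frozenset()
    prev_obj = -np.inf
    for budget in budgets:
        pt = solve_single(OptimizationProblem(
            outcomes=tuple(outcomes), budget=budget, objective=objective,
            bundles=bundles))
        obj = pt.deaths_averted if objective == "deaths" else pt.che_averted
        aux = pt.che_averted if objective == "deaths" else pt.deaths_averted
        assert obj >= prev_obj - ATOL, "optimized objective decreased with budget"
        sel = frozenset(pt.selection)
        results.append(SweepPoint(
            budget=budget, point=pt, objective_value=obj, auxiliary_value=aux,
            entered=tuple(sorted(sel - prev_sel)),
            exited=tuple(sorted(prev_sel - sel)),
        ))
        prev_sel, prev_obj = sel, obj
    return results


def write_sweep(sweep: Sequence[SweepPoint], path: str | Path) -> None:
    from .core_data import FLOAT_PRECISION, _write_csv

    rows = [
        [round(s.budget, FLOAT_PRECISION), round(s.objective_value, FLOAT_PRECISION),
         round(s.auxiliary_value, FLOAT_PRECISION),
         ";".join(s.entered), ";".join(s.exited)]
        for s in sweep
    ]
    _write_csv(path, ["budget", "objective_value", "auxiliary_value",
                      "entered", "exited"], rows)
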