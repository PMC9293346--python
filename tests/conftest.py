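"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorized enumeration:
they are plain-Python subset loops, so solver results are checked against
an implementation that shares no code path with what it verifies.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hbpopt import InterventionOutcome, worked_micro_example

settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

TOL = 1e-6


@pytest.fixture(scope="session")
def micro():
    return worked_micro_example()


def random_outcomes(rng: np.random.Generator, n: int) -> list[InterventionOutcome]:
    """Random knapsack items with continuous objective values."""
    return [
        InterventionOutcome(
            intervention_id=f"X{i:02d}",
            deaths_averted=float(rng.uniform(0, 100)),
            che_averted=float(rng.uniform(0, 100)),
            che_primary=0.0, che_secondary=0.0,
            total_cost=float(rng.uniform(1, 10)),
            treated=0.0,
        )
        for i in range(n)
    ]


def _units(outcomes: Sequence[InterventionOutcome],
           bundles: Optional[Mapping[str, Sequence[str]]]) -> list[list[int]]:
    index = {o.intervention_id: i for i, o in enumerate(outcomes)}
    member_of = {}
    for bid, members in (bundles or {}).items():
        for iid in members:
            member_of[index[iid]] = bid
    units, seen = [], {}
    for i in range(len(outcomes)):
        bid = member_of.get(i)
        if bid is None:
            units.append([i])
        elif bid in seen:
            units[seen[bid]].append(i)
        else:
            seen[bid] = len(units)
            units.append([i])
    return units


def enumerate_feasible(outcomes: Sequence[InterventionOutcome], budget: float,
                       bundles: Optional[Mapping[str, Sequence[str]]] = None):
    """Yield (selected_flags, cost, deaths, che) for every feasible subset."""
    units = _units(outcomes, bundles)
    for bits in itertools.product([0, 1], repeat=len(units)):
        chosen = [i for b, unit in zip(bits, units) if b for i in unit]
        cost = sum(outcomes[i].total_cost for i in chosen)
        if cost > budget + TOL:
            continue
        deaths = sum(outcomes[i].deaths_averted for i in chosen)
        che = sum(outcomes[i].che_averted for i in chosen)
        sel = tuple(1 if i in chosen else 0 for i in range(len(outcomes)))
        yield sel, cost, deaths, che


def brute_solve(outcomes, budget, objective="deaths", k=None,
                constraint_objective=None, bundles=None):
    """Exhaustive single/epsilon solve with the documented tie-breaks.

    Returns (selection ids, obj1, obj2, cost) or None when infeasible.
    """
    best = None
    best_key = None
    for sel, cost, deaths, che in enumerate_feasible(outcomes, budget, bundles):
        obj1 = deaths if objective == "deaths" else che
        obj2 = che if objective == "deaths" else deaths
        if k is not None:
            c_val = deaths if constraint_objective == "deaths" else che
            if c_val < k - 1e-9:
                continue
        key = (obj1, obj2, -cost, sel)
        if best_key is None or key > best_key:
            best_key = key
            best = (sel, obj1, obj2, cost)
    if best is None:
        return None
    sel, obj1, obj2, cost = best
    ids = tuple(o.intervention_id for o, s in zip(outcomes, sel) if s)
    return ids, obj1, obj2, cost


def brute_nondominated(outcomes, budget, bundles=None,
                       ndigits: int = 9) -> list[tuple[float, float]]:
    """All non-dominated (deaths, che) pairs among feasible subsets."""
    pts = sorted(
        {(round(d, ndigits), round(c, ndigits))
         for _, _, d, c in enumerate_feasible(outcomes, budget, bundles)},
        key=lambda t: (-t[0], -t[1]),
    )
    front = []
    best_che = -math.inf
    for d, c in pts:
        if c > best_che + 1e-9:
            front.append((d, c))
            best_che = c
    front.reverse()  # ascending deaths
    return front
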