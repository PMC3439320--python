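"""Derive design parameters from planning choices and search them for cost.

Study planners think in terms of "how many workers, how many repeats, how
many can we measure at once, do we commute or stay over" — not directly in
the model's six design counts.  This module maps such planning choices onto
a consistent :class:`~ergocost.core_model.DesignParameters` and exhaustively
searches a grid of choices for the cheapest feasible design, subject to
per-method limits on how many workers one researcher can measure
concurrently (by default 4 for inclinometry, 10 for the daily questionnaire
and 2 — the researcher's own subject plus one more — for video observation).
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from typing import Annotated, Literal, Union

from pydantic import Field, NonNegativeInt, PositiveInt

from .core_model import (
    CostBreakdown,
    CostProfile,
    DesignParameters,
    InfeasibleDesignError,
    MethodId,
    UsageError,
    _Model,
    total_study_cost,
)

__all__ = [
    "CommuteDaily",
    "StayOver",
    "ExplicitTrips",
    "TripPolicy",
    "PlanningChoices",
    "CapacityLimits",
    "DEFAULT_CAPACITIES",
    "derive_design",
    "minimize_cost",
    "OptimizationResult",
]


class CommuteDaily(_Model):
    """Travel to the worksite and back on every researcher-day; no nights."""

    kind: Literal["commute_daily"] = "commute_daily"


class StayOver(_Model):
    """Trips of ``nights_per_trip`` nights, each covering consecutive
    researcher-days (a trip with *k* nights covers *k*+1 days)."""

    kind: Literal["stay_over"] = "stay_over"
    nights_per_trip: PositiveInt


class ExplicitTrips(_Model):
    """Directly specified trip and night counts, for encoding achieved
    (possibly messy) field logistics that no clean policy reproduces."""

    kind: Literal["explicit"] = "explicit"
    n_t: NonNegativeInt
    n_n: NonNegativeInt


TripPolicy = Annotated[
    Union[CommuteDaily, StayOver, ExplicitTrips], Field(discriminator="kind")
]


class PlanningChoices(_Model):
    """High-level planning inputs from which a design is derived.

    ``n_measurements`` overrides ``n_workers × shifts_per_worker`` when the
    achieved number of worker-days differs from the planned one (lost
    measurements, drop-outs).
    """

    n_workers: PositiveInt
    shifts_per_worker: PositiveInt
    workers_per_researcher_day: PositiveInt
    trip_policy: TripPolicy = Field(default_factory=CommuteDaily)
    n_measurements: NonNegativeInt | None = None


class CapacityLimits(_Model):
    """Per-method upper bounds on concurrently measured workers per
    researcher-day.  Inclinometers need only set-up/take-down attention, so
    several workers can wear them at once; video requires actively following
    each worker, capping concurrency near one extra subject."""

    limits: dict[MethodId, PositiveInt]

    def limit(self, method: MethodId) -> int:
        method = MethodId.parse(method)
        if method not in self.limits:
            raise UsageError(f"no capacity limit configured for {method.value}")
        return self.limits[method]


DEFAULT_CAPACITIES = CapacityLimits(
    limits={
        MethodId.INCLINOMETER: 4,
        MethodId.DAILY_QUESTIONNAIRE: 10,
        MethodId.VIDEO_OBSERVATION: 2,
    }
)


def derive_design(choices: PlanningChoices) -> DesignParameters:
    """Turn planning choices into an internally consistent design.

    ``n_m = n_workers × shifts_per_worker`` (or the explicit override),
    ``n_d = ceil(n_m / workers_per_researcher_day)``, ``n_c = n_m − n_d``,
    and trips/nights follow the trip policy.  Derived designs always satisfy
    ``n_m = n_d + n_c``.
    """
    n_m = (
        choices.n_measurements
        if choices.n_measurements is not None
        else choices.n_workers * choices.shifts_per_worker
    )
    n_d = math.ceil(n_m / choices.workers_per_researcher_day)
    n_c = n_m - n_d
    policy = choices.trip_policy
    if isinstance(policy, CommuteDaily):
        n_t, n_n = n_d, 0
    elif isinstance(policy, StayOver):
        # each trip of k nights covers k+1 on-site days; a shorter last trip
        # still has one night fewer than its days
        days_per_trip = policy.nights_per_trip + 1
        n_t = math.ceil(n_d / days_per_trip)
        n_n = n_d - n_t
    else:
        n_t, n_n = policy.n_t, policy.n_n
    return DesignParameters(n_t=n_t, n_n=n_n, n_w=choices.n_workers, n_d=n_d, n_m=n_m, n_c=n_c)


class OptimizationResult(_Model):
    choices: PlanningChoices
    design: DesignParameters
    breakdown: CostBreakdown
    n_grid: int
    n_evaluated: int
    n_infeasible: int


def minimize_cost(
    profile: CostProfile,
    choices_grid: Iterable[PlanningChoices],
    method: MethodId,
    capacities: CapacityLimits | Mapping[MethodId, int] | None = None,
) -> OptimizationResult:
    """Exhaustively search a grid of planning choices for the cheapest design.

    Grid points whose concurrency exceeds the method's capacity are skipped
    as infeasible (and counted).  All points must target the same number of
    worker-days, so the search compares logistics, not sample size.  Ties
    are broken deterministically: lower total cost, then fewer
    researcher-days, then fewer trips, then grid order.
    """
    method = MethodId.parse(method)
    if capacities is None:
        capacities = DEFAULT_CAPACITIES
    elif not isinstance(capacities, CapacityLimits):
        capacities = CapacityLimits(limits=dict(capacities))
    cap = capacities.limit(method)

    grid = list(choices_grid)
    if not grid:
        raise UsageError("minimize_cost requires a non-empty grid")

    target_n_m: int | None = None
    n_infeasible = 0
    n_evaluated = 0
    best_entry = None
    for index, choices in enumerate(grid):
        design = derive_design(choices)
        if target_n_m is None:
            target_n_m = design.n_m
        elif design.n_m != target_n_m:
            raise UsageError(
                f"grid point {index} targets {design.n_m} worker-days, but the "
                f"grid was fixed at {target_n_m}; compare equal-volume designs"
            )
        if choices.workers_per_researcher_day > cap:
            n_infeasible += 1
            continue
        n_evaluated += 1
        breakdown = total_study_cost(profile, design, method)
        key = (breakdown.total, design.n_d, design.n_t, index)
        if best_entry is None or key < best_entry[0]:
            best_entry = (key, choices, design, breakdown)
    if best_entry is None:
        raise InfeasibleDesignError(
            f"all {len(grid)} grid points exceed the concurrency capacity "
            f"{cap} for {method.value}"
        )
    _, choices, design, breakdown = best_entry
    return OptimizationResult(
        choices=choices,
        design=design,
        breakdown=breakdown,
        n_grid=len(grid),
        n_evaluated=n_evaluated,
        n_infeasible=n_infeasible,
    )


def grid_from_ranges(
    n_workers: int,
    shifts_per_worker: int,
    concurrency_options: Iterable[int],
    trip_policies: Iterable[TripPolicy | CommuteDaily | StayOver | ExplicitTrips],
    n_measurements: int | None = None,
) -> list[PlanningChoices]:
    """Cartesian product of concurrency options and trip policies."""
    policies = list(trip_policies)
    return [
        PlanningChoices(
            n_workers=n_workers,
            shifts_per_worker=shifts_per_worker,
            workers_per_researcher_day=c,
            trip_policy=p,
            n_measurements=n_measurements,
        )
        for c in concurrency_options
        for p in policies
    ]
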