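"""Synthetic prospective cost-tracking records, and unit-cost estimation.

In a prospectively cost-tracked field study every expense is logged as it
happens: each trip's travel cost, each hotel night, each worker recruited,
each researcher-day's first-worker set-up, each concurrent measurement, plus
office time (planning, administration, recruitment administration, training)
logged as hours per task.  This module generates such record streams with a
chosen statistical structure — per-category event counts from a design, per-
category (mean, sd) cost distributions — and provides the inverse step:
estimating unit-cost means and sds back from a record stream, and
aggregating records into a stakeholder attribution.  Together with the cost
model this makes the whole pipeline testable end to end without any real
tracking data.

Fixed-cost components are emitted as office-task hour records whose labour
valuation (hours × rate × (1 + overhead)) reproduces the component targets
exactly; this includes equipment capital, which is conceptually a purchase
rather than labour but round-trips exactly under the same valuation.
Workers' paid non-productive time (arriving early, staying late) is emitted
as one hour per measured worker-day, valued at a separate worker rate.
"""

from __future__ import annotations

import csv
import enum
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
from pydantic import Field, NonNegativeFloat, model_validator

from .core_model import (
    FIXED_COMPONENTS,
    DesignParameters,
    LabourRate,
    MethodId,
    MissingDataError,
    Stakeholder,
    StakeholderAttribution,
    UnitCost,
    UnitCosts,
    UsageError,
    _Model,
    labour_cost,
)
from .uncertainty import DRAW_ORDER, draw_unit_cost

__all__ = [
    "Category",
    "TrackingRecord",
    "GeneratorSpec",
    "generate_tracking_records",
    "estimate_unit_costs",
    "summarize_by_stakeholder",
    "attribution_to_records",
    "write_records_csv",
    "read_records_csv",
]


class Category(str, enum.Enum):
    TRIP = "trip"
    NIGHT = "night"
    RECRUIT = "recruit"
    SUPPLIES = "supplies"
    FIRST_WORKER = "first_worker"
    CONCURRENT_WORKER = "concurrent_worker"
    OFFICE_TASK = "office_task"


#: Amount-bearing categories, in the shared draw order (see uncertainty).
AMOUNT_CATEGORIES: tuple[Category, ...] = (
    Category.TRIP,
    Category.NIGHT,
    Category.RECRUIT,
    Category.SUPPLIES,
    Category.FIRST_WORKER,
    Category.CONCURRENT_WORKER,
)

#: category -> design-parameter attribute giving its event count
_COUNT_ATTR: dict[Category, str] = {
    Category.TRIP: "n_t",
    Category.NIGHT: "n_n",
    Category.RECRUIT: "n_w",
    Category.SUPPLIES: "n_m",
    Category.FIRST_WORKER: "n_d",
    Category.CONCURRENT_WORKER: "n_c",
}


class TrackingRecord(_Model):
    """One prospective cost-tracking entry.

    Exactly one of ``amount`` (euros) and ``hours`` is present: office-task
    records carry hours (labour is logged as time and valued later), all
    other categories carry euro amounts.  ``task`` sub-labels office tasks
    with the component they belong to; ``hourly_rate``, when set, values the
    record's hours at that flat rate instead of the researcher labour rate.
    """

    day_index: int = 0
    researcher_id: str = "R1"
    category: Category
    task: str | None = None
    method: MethodId | None = None
    amount: NonNegativeFloat | None = None
    hours: NonNegativeFloat | None = None
    stakeholder: Stakeholder = Stakeholder.RESEARCHER
    hourly_rate: float | None = None

    @model_validator(mode="after")
    def _one_of_amount_hours(self) -> "TrackingRecord":
        if self.category is Category.OFFICE_TASK:
            if self.hours is None or self.amount is not None:
                raise ValueError("office_task records carry hours, not amounts")
        else:
            if self.amount is None or self.hours is not None:
                raise ValueError(
                    f"{self.category.value} records carry an amount, not hours"
                )
        return self


class GeneratorSpec(_Model):
    """Everything needed to generate a reproducible tracking-record stream.

    Event counts come from ``design``; per-category cost distributions from
    ``unit_costs`` (a category whose sd is absent or zero generates its mean
    deterministically); fixed-cost component targets from ``fixed_costs``.
    ``stakeholder_fractions`` optionally splits a fixed component across
    stakeholders (default: all researcher-borne).  ``worker_hourly_rate``
    values workers' paid non-productive time; the default of 52 €/h is a
    calibration that puts 80 worker-days near the reference study's figure,
    not an observed wage.
    """

    design: DesignParameters
    unit_costs: UnitCosts
    fixed_costs: dict[str, NonNegativeFloat] = Field(default_factory=dict)
    labour_rate: LabourRate = Field(default_factory=LabourRate)
    stakeholder_fractions: dict[str, dict[Stakeholder, NonNegativeFloat]] = Field(
        default_factory=dict
    )
    worker_hours_per_worker_day: NonNegativeFloat = 1.0
    worker_hourly_rate: NonNegativeFloat = 52.0
    family: str = "lognormal"
    method: MethodId | None = None
    seed: int = 0
    n_researchers: int = Field(default=4, ge=1)

    @model_validator(mode="after")
    def _check_fixed_keys(self) -> "GeneratorSpec":
        for key in self.fixed_costs:
            if key not in FIXED_COMPONENTS:
                raise ValueError(
                    f"unknown fixed component {key!r}; valid: "
                    + ", ".join(FIXED_COMPONENTS)
                )
        for key, fracs in self.stakeholder_fractions.items():
            if key not in FIXED_COMPONENTS:
                raise ValueError(f"stakeholder fractions for unknown component {key!r}")
            if sum(fracs.values()) > 1.0 + 1e-9:
                raise ValueError(f"stakeholder fractions for {key!r} exceed 1")
        return self


def generate_tracking_records(spec: GeneratorSpec) -> list[TrackingRecord]:
    """Generate one synthetic tracking-record stream.

    Exactly one record is emitted per event — n_t trips, n_n nights, n_w
    recruitments, n_m supply sets, n_d first-worker set-ups, n_c concurrent
    measurements — with amounts drawn from the spec's family (deterministic
    where no sd is recorded), in the same category order and from the same
    generator stream as per-event Monte-Carlo sampling, so identical seeds
    yield identical money.  Fixed components become office-task hour records;
    worker production time becomes hour records at the worker rate.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[TrackingRecord] = []
    day = 0
    for (slot, _param), category in zip(DRAW_ORDER, AMOUNT_CATEGORIES):
        n = getattr(spec.design, _COUNT_ATTR[category])
        if n == 0:
            continue
        amounts = draw_unit_cost(rng, spec.unit_costs.slot(slot), n, spec.family)
        for i, amount in enumerate(amounts):
            records.append(
                TrackingRecord(
                    day_index=i % max(spec.design.n_d, 1),
                    researcher_id=f"R{i % spec.n_researchers + 1}",
                    category=category,
                    method=spec.method,
                    amount=float(amount),
                )
            )
        day += 1

    hourly_value = spec.labour_rate.hourly_rate * (1.0 + spec.labour_rate.overhead_fraction)
    for component in FIXED_COMPONENTS:
        target = spec.fixed_costs.get(component, 0.0)
        if target == 0.0:
            continue
        fractions = spec.stakeholder_fractions.get(
            component, {Stakeholder.RESEARCHER: 1.0}
        )
        for stakeholder, fraction in fractions.items():
            if fraction == 0.0:
                continue
            records.append(
                TrackingRecord(
                    category=Category.OFFICE_TASK,
                    task=component,
                    hours=target * fraction / hourly_value,
                    stakeholder=stakeholder,
                )
            )

    if spec.worker_hourly_rate > 0 and spec.worker_hours_per_worker_day > 0:
        for i in range(spec.design.n_m):
            records.append(
                TrackingRecord(
                    day_index=i % max(spec.design.n_d, 1),
                    category=Category.OFFICE_TASK,
                    task="worker_production_time",
                    hours=spec.worker_hours_per_worker_day,
                    stakeholder=Stakeholder.WORKER_PRODUCTION,
                    hourly_rate=spec.worker_hourly_rate,
                )
            )
    return records


def estimate_unit_costs(
    records: Iterable[TrackingRecord],
    categories: Sequence[Category | str] | None = None,
) -> tuple[UnitCosts, dict[str, int]]:
    """Per-category mean and sample sd of tracked amounts.

    With ``categories=None`` every amount-bearing category present in the
    records is estimated; explicitly requested categories must be present or
    a :class:`MissingDataError` names the absent one.  Categories with a
    single record report their sd as absent (a sample sd needs two points);
    categories with no records report mean 0 so the result slots directly
    into a cost profile.
    """
    by_cat: dict[Category, list[float]] = {c: [] for c in AMOUNT_CATEGORIES}
    for rec in records:
        if rec.category is not Category.OFFICE_TASK:
            by_cat[rec.category].append(rec.amount)

    if categories is not None:
        requested = [Category(c) for c in categories]
        for cat in requested:
            if not by_cat[cat]:
                raise MissingDataError(
                    f"no tracking records for category {cat.value!r}"
                )
    elif not any(by_cat.values()):
        raise MissingDataError("no amount-bearing tracking records to estimate from")

    slot_for = {cat: slot for (slot, _), cat in zip(DRAW_ORDER, AMOUNT_CATEGORIES)}
    estimates: dict[str, UnitCost] = {}
    counts: dict[str, int] = {}
    for cat in AMOUNT_CATEGORIES:
        values = np.asarray(by_cat[cat], dtype=float)
        counts[cat.value] = values.size
        if values.size == 0:
            estimates[slot_for[cat]] = UnitCost(mean=0.0)
        elif values.size == 1:
            estimates[slot_for[cat]] = UnitCost(mean=float(values[0]))
        else:
            estimates[slot_for[cat]] = UnitCost(
                mean=float(values.mean()), sd=float(values.std(ddof=1))
            )
    return UnitCosts(**estimates), counts


#: category -> canonical cost-component name used in attributions
_COMPONENT_FOR: dict[Category, str] = {
    Category.TRIP: "travel",
    Category.NIGHT: "accommodation",
    Category.RECRUIT: "recruitment",
    Category.SUPPLIES: "supplies",
    Category.FIRST_WORKER: "first_worker",
    Category.CONCURRENT_WORKER: "concurrent_workers",
}


def summarize_by_stakeholder(
    records: Iterable[TrackingRecord], rate: LabourRate | None = None
) -> StakeholderAttribution:
    """Aggregate record value by (component, stakeholder).

    Hours are converted to euros with the researcher labour rate (including
    overhead) unless a record carries its own flat ``hourly_rate``.  Office
    tasks aggregate under their ``task`` label; amount records under their
    category's component name.
    """
    records = list(records)
    if not records:
        raise UsageError("summarize_by_stakeholder requires at least one record")
    rate = rate or LabourRate()
    shares: dict[str, dict[Stakeholder, float]] = {}
    for rec in records:
        if rec.category is Category.OFFICE_TASK:
            component = rec.task or "office_task"
            if rec.hourly_rate is not None:
                value = rec.hours * rec.hourly_rate
            else:
                value = labour_cost(rec.hours, rate)
        else:
            component = _COMPONENT_FOR[rec.category]
            value = rec.amount
        cell = shares.setdefault(component, {})
        cell[rec.stakeholder] = cell.get(rec.stakeholder, 0.0) + value
    return StakeholderAttribution(shares=shares)


def attribution_to_records(
    attribution: StakeholderAttribution, rate: LabourRate | None = None
) -> list[TrackingRecord]:
    """Replay an attribution table as an equivalent record stream.

    Every (component, stakeholder) cell becomes one office-task hour record
    whose labour valuation equals the cell exactly, so summarising the
    replayed records reproduces the original attribution.
    """
    rate = rate or LabourRate()
    hourly_value = rate.hourly_rate * (1.0 + rate.overhead_fraction)
    records = []
    for component, cell in attribution.shares.items():
        for stakeholder, amount in cell.items():
            records.append(
                TrackingRecord(
                    category=Category.OFFICE_TASK,
                    task=component,
                    hours=amount / hourly_value,
                    stakeholder=stakeholder,
                )
            )
    return records


_CSV_HEADER = [
    "day_index", "researcher_id", "category", "task", "method",
    "amount", "hours", "stakeholder", "hourly_rate",
]


def write_records_csv(records: Iterable[TrackingRecord], path: str | Path) -> None:
    """Write records as UTF-8 CSV with the documented header."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for rec in records:
            writer.writerow(
                [
                    rec.day_index,
                    rec.researcher_id,
                    rec.category.value,
                    rec.task or "",
                    rec.method.value if rec.method else "",
                    "" if rec.amount is None else repr(rec.amount),
                    "" if rec.hours is None else repr(rec.hours),
                    rec.stakeholder.value,
                    "" if rec.hourly_rate is None else repr(rec.hourly_rate),
                ]
            )


def read_records_csv(path: str | Path) -> list[TrackingRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        records = []
        for row in reader:
            records.append(
                TrackingRecord(
                    day_index=int(row["day_index"]),
                    researcher_id=row["researcher_id"],
                    category=Category(row["category"]),
                    task=row["task"] or None,
                    method=MethodId(row["method"]) if row["method"] else None,
                    amount=float(row["amount"]) if row["amount"] else None,
                    hours=float(row["hours"]) if row["hours"] else None,
                    stakeholder=Stakeholder(row["stakeholder"]),
                    hourly_rate=float(row["hourly_rate"]) if row["hourly_rate"] else None,
                )
            )
        return records
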