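"""Deterministic cost model for occupational exposure-assessment field studies.

The model prices the data-collection stage of a field study in which workers'
biomechanical exposure (e.g. trunk/shoulder posture) is measured with one of
three method families: whole-shift inclinometry, video observation, or a daily
self-report questionnaire.  Total study cost for a method decomposes into

* fixed costs incurred once per study — planning meetings, research
  administration, recruitment administration, equipment capital, and training
  of data collectors — partly shared across methods and partly
  method-specific; and
* variable costs linear in the study-design parameters — per-trip travel,
  per-night accommodation, per-worker recruitment, per-worker-day supplies,
  a first-worker set-up cost per researcher-day, and a marginal cost per
  concurrently measured worker.

Writing fixed components as ``Č`` and unit costs as ``ċ``, the total for
method *m* is

    C_Tm = Č_M + Č_A + Č_R + Č_E + Č_T
           + ċ_V·n_t + ċ_H·n_n + ċ_R·n_w + ċ_S·n_m + ċ_F·n_d + ċ_C·n_c

where ``n_t`` trips, ``n_n`` nights, ``n_w`` workers recruited, ``n_d``
researcher-days, ``n_m`` worker-days measured and ``n_c`` concurrent
worker-days describe the design.  All arithmetic is exact over the inputs;
rounding happens only on display.
"""

from __future__ import annotations

import enum
import logging
import math
from collections.abc import Iterable, Mapping

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    NonNegativeFloat,
    NonNegativeInt,
    model_validator,
)

logger = logging.getLogger("ergocost")

__all__ = [
    "MethodId",
    "Stakeholder",
    "FixedCosts",
    "UnitCost",
    "UnitCosts",
    "CostProfile",
    "DesignParameters",
    "LabourRate",
    "CostBreakdown",
    "StakeholderAttribution",
    "FIXED_COMPONENTS",
    "VARIABLE_COMPONENTS",
    "variable_data_cost",
    "total_study_cost",
    "combined_methods_cost",
    "labour_cost",
    "stakeholder_totals",
    "CostModelError",
    "ConfigurationError",
    "UsageError",
    "MissingDataError",
    "UndefinedCVError",
    "InfeasibleDesignError",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class CostModelError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(CostModelError):
    """A configuration (profile, scenario, file) is malformed or incomplete."""


class UsageError(CostModelError):
    """An operation was called with arguments that make it meaningless."""


class MissingDataError(CostModelError):
    """Requested data (e.g. a record category) is absent."""


class UndefinedCVError(CostModelError):
    """A coefficient of variation is undefined (zero mean or missing sd)."""


class InfeasibleDesignError(CostModelError):
    """No design in a search space satisfies the stated constraints."""


# ---------------------------------------------------------------------------
# Identifiers and canonical component names
# ---------------------------------------------------------------------------

class MethodId(str, enum.Enum):
    """The three exposure-assessment method families the model prices."""

    INCLINOMETER = "inclinometer"
    VIDEO_OBSERVATION = "video_observation"
    DAILY_QUESTIONNAIRE = "daily_questionnaire"

    @classmethod
    def parse(cls, label: "str | MethodId") -> "MethodId":
        try:
            return cls(label)
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ConfigurationError(
                f"unknown method label {label!r}; expected one of: {valid}"
            ) from None


class Stakeholder(str, enum.Enum):
    """Who bears a cost: researchers, employer administration, or workers'
    paid non-productive time."""

    RESEARCHER = "researcher"
    EMPLOYER_ADMIN = "employer_admin"
    WORKER_PRODUCTION = "worker_production"


#: Canonical fixed-cost component names, in model order.
FIXED_COMPONENTS: tuple[str, ...] = (
    "meetings",
    "administration",
    "recruitment_admin",
    "equipment",
    "training",
)

#: Canonical variable-cost component names, in model order.  Each pairs a
#: unit-cost slot with the design parameter it multiplies.
VARIABLE_COMPONENTS: tuple[str, ...] = (
    "travel",
    "accommodation",
    "recruitment",
    "supplies",
    "first_worker",
    "concurrent_workers",
)

#: variable component -> (unit-cost slot, design-parameter attribute)
_VARIABLE_MAP: dict[str, tuple[str, str]] = {
    "travel": ("trip", "n_t"),
    "accommodation": ("night", "n_n"),
    "recruitment": ("recruit", "n_w"),
    "supplies": ("supplies", "n_m"),
    "first_worker": ("first_worker", "n_d"),
    "concurrent_workers": ("concurrent_worker", "n_c"),
}

#: Unit-cost slots priced once per study regardless of method.
SHARED_UNIT_SLOTS: tuple[str, ...] = ("trip", "night", "recruit")

#: Unit-cost slots priced per method.
METHOD_UNIT_SLOTS: tuple[str, ...] = ("supplies", "first_worker", "concurrent_worker")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class FixedCosts(_Model):
    """Per-study fixed cost components, in a single currency.

    Unspecified components default to zero, so a method-specific block can
    list only the components that actually differ from zero.
    """

    meetings: NonNegativeFloat = 0.0
    administration: NonNegativeFloat = 0.0
    recruitment_admin: NonNegativeFloat = 0.0
    equipment: NonNegativeFloat = 0.0
    training: NonNegativeFloat = 0.0

    def total(self) -> float:
        return sum(getattr(self, name) for name in FIXED_COMPONENTS)


class UnitCost(_Model):
    """A marginal cost per event: mean and, when tracked, its between-event
    standard deviation."""

    mean: NonNegativeFloat
    sd: NonNegativeFloat | None = None


class UnitCosts(_Model):
    """The six unit costs the variable part of the model multiplies."""

    trip: UnitCost
    night: UnitCost
    recruit: UnitCost
    supplies: UnitCost
    first_worker: UnitCost
    concurrent_worker: UnitCost

    def slot(self, name: str) -> UnitCost:
        if name not in SHARED_UNIT_SLOTS + METHOD_UNIT_SLOTS:
            raise ConfigurationError(f"unknown unit-cost slot {name!r}")
        return getattr(self, name)


class _SharedUnitCosts(_Model):
    trip: UnitCost
    night: UnitCost
    recruit: UnitCost


class _MethodUnitCosts(_Model):
    supplies: UnitCost = Field(default_factory=lambda: UnitCost(mean=0.0))
    first_worker: UnitCost = Field(default_factory=lambda: UnitCost(mean=0.0))
    concurrent_worker: UnitCost = Field(default_factory=lambda: UnitCost(mean=0.0))


class CostProfile(_Model):
    """A complete cost profile: shared components plus per-method components.

    ``shared_fixed`` and ``shared_unit`` hold the costs required no matter
    which method is used; ``per_method_fixed`` / ``per_method_unit`` hold the
    method-specific additions.  A method absent from a per-method map is
    treated as contributing zero, with a logged notice, so profiles derived
    from partially blank cost tables load cleanly.
    """

    shared_fixed: FixedCosts
    per_method_fixed: dict[MethodId, FixedCosts] = Field(default_factory=dict)
    shared_unit: _SharedUnitCosts
    per_method_unit: dict[MethodId, _MethodUnitCosts] = Field(default_factory=dict)
    currency_label: str = "EUR"
    notes: str = ""

    def fixed_costs_for(self, method: MethodId) -> FixedCosts:
        """Shared plus method-specific fixed components, summed per component."""
        method = MethodId.parse(method)
        extra = self.per_method_fixed.get(method)
        if extra is None:
            logger.info("no method-specific fixed costs for %s; using 0", method.value)
            extra = FixedCosts()
        return FixedCosts(
            **{
                name: getattr(self.shared_fixed, name) + getattr(extra, name)
                for name in FIXED_COMPONENTS
            }
        )

    def unit_costs_for(self, method: MethodId) -> UnitCosts:
        """The six unit costs that apply when running ``method``."""
        method = MethodId.parse(method)
        mu = self.per_method_unit.get(method)
        if mu is None:
            logger.info("no method-specific unit costs for %s; using 0", method.value)
            mu = _MethodUnitCosts()
        return UnitCosts(
            trip=self.shared_unit.trip,
            night=self.shared_unit.night,
            recruit=self.shared_unit.recruit,
            supplies=mu.supplies,
            first_worker=mu.first_worker,
            concurrent_worker=mu.concurrent_worker,
        )


class DesignParameters(_Model):
    """Counts describing a study design.

    A design is "researcher-day consistent" when every worker-day is either
    the first measurement of a researcher-day or a concurrent one, i.e.
    ``n_m == n_d + n_c``.  The model itself never requires this, so a
    violation is logged as a warning rather than rejected: achieved field
    designs are often messier than planned ones.
    """

    n_t: NonNegativeInt = 0
    n_n: NonNegativeInt = 0
    n_w: NonNegativeInt = 0
    n_d: NonNegativeInt = 0
    n_m: NonNegativeInt = 0
    n_c: NonNegativeInt = 0

    @property
    def researcher_day_consistent(self) -> bool:
        return self.n_m == self.n_d + self.n_c

    @model_validator(mode="after")
    def _warn_if_inconsistent(self) -> "DesignParameters":
        if not self.researcher_day_consistent:
            logger.warning(
                "design is not researcher-day consistent: n_m=%d != n_d+n_c=%d",
                self.n_m,
                self.n_d + self.n_c,
            )
        return self


class LabourRate(_Model):
    """Hourly valuation of researcher time including institutional overhead."""

    hourly_rate: float = Field(default=31.0, gt=0)
    overhead_fraction: NonNegativeFloat = 0.68


class CostBreakdown(_Model):
    """A fully itemised evaluation of the cost model for one method (or a
    combination of methods)."""

    method: str
    components: dict[str, float]
    fixed_subtotal: float
    variable_subtotal: float
    total: float
    currency_label: str = "EUR"

    @model_validator(mode="after")
    def _check_additivity(self) -> "CostBreakdown":
        if not math.isclose(
            self.fixed_subtotal + self.variable_subtotal, self.total, rel_tol=1e-9, abs_tol=1e-9
        ):
            raise ValueError("subtotals do not sum to the reported total")
        return self


class StakeholderAttribution(_Model):
    """Euro amounts per cost component split across the three stakeholders."""

    shares: dict[str, dict[Stakeholder, NonNegativeFloat]]
    currency_label: str = "EUR"

    def component_total(self, component: str) -> float:
        return sum(self.shares[component].values())

    def grand_total(self) -> float:
        return sum(self.component_total(c) for c in self.shares)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def variable_data_cost(unit: UnitCosts, design: DesignParameters) -> float:
    """On-site data-acquisition cost: ``ċ_S·n_m + ċ_F·n_d + ċ_C·n_c``.

    The first worker measured on a researcher-day carries a set-up cost
    (confirming with the supervisor, rigging equipment, waiting) that is paid
    once per researcher-day; each additional concurrently measured worker
    costs only the marginal time to administer another measurement.
    """
    return (
        unit.supplies.mean * design.n_m
        + unit.first_worker.mean * design.n_d
        + unit.concurrent_worker.mean * design.n_c
    )


def _breakdown(
    fixed: FixedCosts, unit: UnitCosts, design: DesignParameters, method_label: str,
    currency: str = "EUR",
) -> CostBreakdown:
    components: dict[str, float] = {
        name: getattr(fixed, name) for name in FIXED_COMPONENTS
    }
    for comp, (slot, param) in _VARIABLE_MAP.items():
        components[comp] = unit.slot(slot).mean * getattr(design, param)
    fixed_subtotal = sum(components[c] for c in FIXED_COMPONENTS)
    variable_subtotal = sum(components[c] for c in VARIABLE_COMPONENTS)
    return CostBreakdown(
        method=method_label,
        components=components,
        fixed_subtotal=fixed_subtotal,
        variable_subtotal=variable_subtotal,
        total=fixed_subtotal + variable_subtotal,
        currency_label=currency,
    )


def total_study_cost(
    profile: CostProfile, design: DesignParameters, method: MethodId
) -> CostBreakdown:
    """Evaluate the full cost model for one method.

    Every component is listed separately in the returned breakdown; the
    total is the exact sum of fixed and variable subtotals, with no rounding.
    """
    method = MethodId.parse(method)
    return _breakdown(
        profile.fixed_costs_for(method),
        profile.unit_costs_for(method),
        design,
        method.value,
        profile.currency_label,
    )


def combined_methods_cost(
    profile: CostProfile, design: DesignParameters, methods: Iterable[MethodId]
) -> CostBreakdown:
    """Cost of running several methods on the same design simultaneously.

    Shared fixed and shared variable components are counted exactly once;
    method-specific components are summed over the requested methods.  No
    multitasking savings are assumed: researcher time is priced for the full
    time spent on each method, which suits budgeting single-method studies
    and gives a conservative combined figure.
    """
    methods = sorted({MethodId.parse(m) for m in methods}, key=lambda m: m.value)
    if not methods:
        raise UsageError("combined_methods_cost requires at least one method")

    components: dict[str, float] = {
        name: getattr(profile.shared_fixed, name) for name in FIXED_COMPONENTS
    }
    for comp in ("travel", "accommodation", "recruitment"):
        slot, param = _VARIABLE_MAP[comp]
        components[comp] = getattr(profile.shared_unit, slot).mean * getattr(design, param)

    for method in methods:
        fixed = profile.per_method_fixed.get(method, FixedCosts())
        for name in FIXED_COMPONENTS:
            value = getattr(fixed, name)
            if value:
                components[f"{method.value}.{name}"] = value
        mu = profile.per_method_unit.get(method, _MethodUnitCosts())
        for comp in ("supplies", "first_worker", "concurrent_workers"):
            slot, param = _VARIABLE_MAP[comp]
            value = getattr(mu, slot).mean * getattr(design, param)
            if value:
                components[f"{method.value}.{comp}"] = value

    fixed_subtotal = sum(
        v for k, v in components.items()
        if k in FIXED_COMPONENTS or k.split(".")[-1] in FIXED_COMPONENTS
    )
    variable_subtotal = sum(components.values()) - fixed_subtotal
    return CostBreakdown(
        method="+".join(m.value for m in methods),
        components=components,
        fixed_subtotal=fixed_subtotal,
        variable_subtotal=variable_subtotal,
        total=fixed_subtotal + variable_subtotal,
        currency_label=profile.currency_label,
    )


def labour_cost(hours: float, rate: LabourRate | None = None) -> float:
    """Value researcher time in euros: ``hours × rate × (1 + overhead)``."""
    if hours < 0:
        raise ValueError(f"hours must be non-negative, got {hours}")
    rate = rate or LabourRate()
    return hours * rate.hourly_rate * (1.0 + rate.overhead_fraction)


def stakeholder_totals(
    attribution: StakeholderAttribution,
) -> tuple[dict[Stakeholder, float], dict[Stakeholder, float], dict[Stakeholder, int]]:
    """Column sums of a stakeholder attribution.

    Returns ``(totals, shares, shares_pct)``: euro totals per stakeholder,
    their full-precision fractional shares of the grand total, and the shares
    rounded half-up to the nearest integer percent.
    """
    if not attribution.shares:
        raise UsageError("stakeholder_totals requires a non-empty attribution")
    totals: dict[Stakeholder, float] = {s: 0.0 for s in Stakeholder}
    for component_shares in attribution.shares.values():
        for stakeholder, amount in component_shares.items():
            totals[stakeholder] += amount
    grand = sum(totals.values())
    if grand <= 0:
        raise UsageError("attribution grand total is zero; shares undefined")
    shares = {s: totals[s] / grand for s in Stakeholder}
    shares_pct = {s: int(math.floor(shares[s] * 100 + 0.5)) for s in Stakeholder}
    return totals, shares, shares_pct


def attribution_from_mapping(
    shares: Mapping[str, Mapping[str, float]], currency: str = "EUR"
) -> StakeholderAttribution:
    """Build a :class:`StakeholderAttribution` from plain nested mappings."""
    return StakeholderAttribution(
        shares={
            comp: {Stakeholder(s): float(v) for s, v in inner.items()}
            for comp, inner in shares.items()
        },
        currency_label=currency,
    )
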