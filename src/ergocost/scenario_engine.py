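"""Named what-if scenarios over a baseline cost configuration.

A scenario is a sparse set of overrides — design parameters, unit-cost means
or sds, fixed-cost components — applied on top of a baseline profile and
design.  Because the cost model is linear, each override has a transparent,
exactly attributable effect on the total, which makes batch evaluation of
scenarios a cheap and reliable sensitivity analysis during study planning.
"""

from __future__ import annotations

import copy
import logging
from collections.abc import Sequence

from pydantic import Field

from .core_model import (
    FIXED_COMPONENTS,
    METHOD_UNIT_SLOTS,
    SHARED_UNIT_SLOTS,
    ConfigurationError,
    CostProfile,
    DesignParameters,
    MethodId,
    UsageError,
    _Model,
    total_study_cost,
)

logger = logging.getLogger("ergocost")

__all__ = [
    "Scenario",
    "ScenarioResult",
    "Baseline",
    "apply_scenario",
    "chain_scenarios",
    "evaluate_scenarios",
    "compare_to_baseline",
]

_DESIGN_FIELDS = ("n_t", "n_n", "n_w", "n_d", "n_m", "n_c")
_UNIT_FIELDS = ("mean", "sd")
_SLOTS = ("shared",) + tuple(m.value for m in MethodId)


class Baseline(_Model):
    """The reference configuration a scenario perturbs."""

    profile: CostProfile
    design: DesignParameters


class Scenario(_Model):
    """Sparse overrides of a baseline configuration.

    ``unit_cost_overrides`` and ``fixed_cost_overrides`` are keyed first by
    slot — ``"shared"`` or a method label — then by component.  A unit-cost
    override is itself a mapping with ``mean`` and/or ``sd`` keys, so a
    scenario can change a cost's level without touching its variability.
    """

    name: str
    notes: str = ""
    design_overrides: dict[str, int] = Field(default_factory=dict)
    unit_cost_overrides: dict[str, dict[str, dict[str, float | None]]] = Field(
        default_factory=dict
    )
    fixed_cost_overrides: dict[str, dict[str, float]] = Field(default_factory=dict)

    def validate_keys(self) -> None:
        for key in self.design_overrides:
            if key not in _DESIGN_FIELDS:
                raise ConfigurationError(
                    f"scenario {self.name!r}: unknown design parameter {key!r}; "
                    f"valid keys: {', '.join(_DESIGN_FIELDS)}"
                )
        for slot, cats in self.unit_cost_overrides.items():
            if slot not in _SLOTS:
                raise ConfigurationError(
                    f"scenario {self.name!r}: unknown unit-cost slot {slot!r}; "
                    f"valid slots: {', '.join(_SLOTS)}"
                )
            valid = SHARED_UNIT_SLOTS if slot == "shared" else METHOD_UNIT_SLOTS
            for cat, fields in cats.items():
                if cat not in valid:
                    raise ConfigurationError(
                        f"scenario {self.name!r}: unknown unit-cost category "
                        f"{cat!r} under {slot!r}; valid: {', '.join(valid)}"
                    )
                for f in fields:
                    if f not in _UNIT_FIELDS:
                        raise ConfigurationError(
                            f"scenario {self.name!r}: unknown unit-cost field {f!r}; "
                            f"valid fields: mean, sd"
                        )
        for slot, comps in self.fixed_cost_overrides.items():
            if slot not in _SLOTS:
                raise ConfigurationError(
                    f"scenario {self.name!r}: unknown fixed-cost slot {slot!r}; "
                    f"valid slots: {', '.join(_SLOTS)}"
                )
            for comp in comps:
                if comp not in FIXED_COMPONENTS:
                    raise ConfigurationError(
                        f"scenario {self.name!r}: unknown fixed component {comp!r}; "
                        f"valid: {', '.join(FIXED_COMPONENTS)}"
                    )


class ScenarioResult(_Model):
    name: str
    per_method_total: dict[MethodId, float]
    delta_vs_baseline: dict[MethodId, float]
    ratio_vs_baseline: dict[MethodId, float]


def apply_scenario(baseline: Baseline, scenario: Scenario) -> Baseline:
    """Apply a scenario's overrides, returning a new configuration.

    The baseline is never modified; fields the scenario does not touch are
    carried over unchanged.  Overridden values are re-validated against the
    target types, so e.g. a negative count is rejected here rather than at
    evaluation time.
    """
    scenario.validate_keys()

    design_data = baseline.design.model_dump()
    design_data.update(scenario.design_overrides)
    design = DesignParameters.model_validate(design_data)

    profile_data = copy.deepcopy(baseline.profile.model_dump(mode="json"))
    for slot, cats in scenario.unit_cost_overrides.items():
        for cat, fields in cats.items():
            if slot == "shared":
                target = profile_data["shared_unit"].setdefault(cat, {"mean": 0.0})
            else:
                target = profile_data["per_method_unit"].setdefault(slot, {}).setdefault(
                    cat, {"mean": 0.0}
                )
            target.update(fields)
    for slot, comps in scenario.fixed_cost_overrides.items():
        if slot == "shared":
            profile_data["shared_fixed"].update(comps)
        else:
            profile_data["per_method_fixed"].setdefault(slot, {}).update(comps)
    profile = CostProfile.model_validate(profile_data)

    return Baseline(profile=profile, design=design)


def chain_scenarios(scenarios: Sequence[Scenario], name: str | None = None) -> Scenario:
    """Merge scenarios into one, later overrides winning on conflict.

    A conflict (the same field overridden twice with different values) is
    resolved last-writer-wins and logged as a warning.
    """
    if not scenarios:
        raise UsageError("chain_scenarios requires at least one scenario")
    merged = Scenario(name=name or "+".join(s.name for s in scenarios))
    for sc in scenarios:
        sc.validate_keys()
        for key, value in sc.design_overrides.items():
            if key in merged.design_overrides and merged.design_overrides[key] != value:
                logger.warning(
                    "scenario chain: %s overrides design %s=%s (was %s)",
                    sc.name, key, value, merged.design_overrides[key],
                )
            merged.design_overrides[key] = value
        for slot, cats in sc.unit_cost_overrides.items():
            for cat, fields in cats.items():
                tgt = merged.unit_cost_overrides.setdefault(slot, {}).setdefault(cat, {})
                for f, v in fields.items():
                    if f in tgt and tgt[f] != v:
                        logger.warning(
                            "scenario chain: %s overrides %s.%s.%s=%s (was %s)",
                            sc.name, slot, cat, f, v, tgt[f],
                        )
                    tgt[f] = v
        for slot, comps in sc.fixed_cost_overrides.items():
            tgt = merged.fixed_cost_overrides.setdefault(slot, {})
            for comp, v in comps.items():
                if comp in tgt and tgt[comp] != v:
                    logger.warning(
                        "scenario chain: %s overrides %s.%s=%s (was %s)",
                        sc.name, slot, comp, v, tgt[comp],
                    )
                tgt[comp] = v
    return merged


def evaluate_scenarios(
    baseline: Baseline,
    scenarios: Sequence[Scenario],
    methods: Sequence[MethodId] | None = None,
) -> list[ScenarioResult]:
    """Evaluate each scenario for each method against the recomputed baseline.

    Results preserve the input scenario order.  Any failure aborts the batch
    with the offending scenario's name in the message.
    """
    methods = [MethodId.parse(m) for m in (methods or list(MethodId))]
    baseline_totals = {
        m: total_study_cost(baseline.profile, baseline.design, m).total for m in methods
    }
    results: list[ScenarioResult] = []
    for scenario in scenarios:
        try:
            effective = apply_scenario(baseline, scenario)
            totals = {
                m: total_study_cost(effective.profile, effective.design, m).total
                for m in methods
            }
        except Exception as exc:
            raise ConfigurationError(
                f"scenario {scenario.name!r} failed: {exc}"
            ) from exc
        deltas, ratios = compare_to_baseline(totals, baseline_totals)
        results.append(
            ScenarioResult(
                name=scenario.name,
                per_method_total=totals,
                delta_vs_baseline=deltas,
                ratio_vs_baseline=ratios,
            )
        )
    return results


def compare_to_baseline(
    scenario_totals: dict[MethodId, float], baseline_totals: dict[MethodId, float]
) -> tuple[dict[MethodId, float], dict[MethodId, float]]:
    """Per-method deltas (€) and ratios (fractions) of scenario vs baseline."""
    deltas: dict[MethodId, float] = {}
    ratios: dict[MethodId, float] = {}
    for method, total in scenario_totals.items():
        base = baseline_totals[method]
        if base == 0:
            raise UsageError(
                f"baseline total for {method.value} is zero; ratio undefined"
            )
        deltas[method] = total - base
        ratios[method] = total / base
    return deltas, ratios
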