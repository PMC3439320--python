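"""Unit and property tests for the deterministic cost model."""

import math

import pydantic
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ergocost as ec
from ergocost.core_model import FIXED_COMPONENTS, VARIABLE_COMPONENTS

METHODS = list(ec.MethodId)

counts = st.integers(min_value=0, max_value=500)
money = st.floats(min_value=0, max_value=5000, allow_nan=False, allow_infinity=False)


def profile_from_values(m) -> ec.CostProfile:
    """Build a profile from eleven independent money values."""
    return ec.CostProfile(
        shared_fixed=ec.FixedCosts(
            meetings=m[0], administration=m[1], recruitment_admin=m[2],
            equipment=m[3], training=m[4],
        ),
        per_method_fixed={ec.MethodId.INCLINOMETER: ec.FixedCosts(equipment=m[5])},
        shared_unit={
            "trip": {"mean": m[6]}, "night": {"mean": m[7]}, "recruit": {"mean": m[8]},
        },
        per_method_unit={
            ec.MethodId.INCLINOMETER: {
                "supplies": {"mean": m[9]},
                "first_worker": {"mean": m[10]},
                "concurrent_worker": {"mean": m[0]},
            }
        },
    )


profiles = st.lists(money, min_size=11, max_size=11).map(profile_from_values)
designs = st.builds(
    ec.DesignParameters,
    n_t=counts, n_n=counts, n_w=counts, n_d=counts, n_m=counts, n_c=counts,
)


# ---------------------------------------------------------------------------
# variable_data_cost
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "supplies, first, concurrent, design_counts, expected",
    [
        # reference inclinometer units on the achieved design: 80·1 + 51·508 + 29·83
        (1, 508, 83, dict(n_m=80, n_d=51, n_c=29), 28_395),
        # questionnaire units: 80·4 + 51·135 + 29·9
        (4, 135, 9, dict(n_m=80, n_d=51, n_c=29), 7_466),
        (4, 135, 9, dict(n_m=0, n_d=0, n_c=0), 0),
    ],
)
def test_onsite_acquisition_cost(supplies, first, concurrent, design_counts, expected):
    unit = ec.UnitCosts(
        trip={"mean": 0}, night={"mean": 0}, recruit={"mean": 0},
        supplies={"mean": supplies},
        first_worker={"mean": first},
        concurrent_worker={"mean": concurrent},
    )
    design = ec.DesignParameters(**design_counts)
    assert ec.variable_data_cost(unit, design) == expected


def test_negative_counts_rejected_by_name():
    with pytest.raises(pydantic.ValidationError, match="n_d"):
        ec.DesignParameters(n_d=-1)
    with pytest.raises(pydantic.ValidationError, match="mean"):
        ec.UnitCost(mean=-3.0)


# ---------------------------------------------------------------------------
# total_study_cost
# ---------------------------------------------------------------------------

def test_zero_design_total_is_fixed_subtotal(profile):
    breakdown = ec.total_study_cost(
        profile, ec.DesignParameters(), ec.MethodId.INCLINOMETER
    )
    assert breakdown.variable_subtotal == 0
    assert breakdown.total == breakdown.fixed_subtotal == 22_228


def test_no_travel_scenario_totals_reproduce_published_values(profile, design):
    """With travel priced at zero and no accommodation, every rounding
    artefact in the profile cancels and the published totals come out
    exactly."""
    no_travel = design.model_copy(update={"n_n": 0})
    data = profile.model_dump()
    data["shared_unit"]["trip"] = {"mean": 0}
    zero_trip = ec.CostProfile.model_validate(data)
    totals = {
        m: ec.total_study_cost(zero_trip, no_travel, m).total for m in METHODS
    }
    assert totals[ec.MethodId.INCLINOMETER] == 51_217
    assert totals[ec.MethodId.DAILY_QUESTIONNAIRE] == 23_040


def test_unknown_method_rejected(profile, design):
    with pytest.raises(ec.ConfigurationError, match="unknown method"):
        ec.total_study_cost(profile, design, "diary")


@given(profile=profiles, design=designs)
def test_oracle_equivalence_term_by_term(profile, design):
    """The breakdown equals an independently coded naive sum of the eleven
    model terms."""
    fixed = profile.fixed_costs_for(ec.MethodId.INCLINOMETER)
    unit = profile.unit_costs_for(ec.MethodId.INCLINOMETER)
    naive = (
        fixed.meetings + fixed.administration + fixed.recruitment_admin
        + fixed.equipment + fixed.training
        + unit.trip.mean * design.n_t
        + unit.night.mean * design.n_n
        + unit.recruit.mean * design.n_w
        + unit.supplies.mean * design.n_m
        + unit.first_worker.mean * design.n_d
        + unit.concurrent_worker.mean * design.n_c
    )
    breakdown = ec.total_study_cost(profile, design, ec.MethodId.INCLINOMETER)
    assert breakdown.total == pytest.approx(naive, rel=1e-12)


@given(design=designs, param=st.sampled_from(["n_t", "n_n", "n_w", "n_m", "n_d", "n_c"]))
def test_linearity_in_each_design_parameter(profile, design, param):
    """Adding one event changes the total by exactly that event's unit cost."""
    slot = {
        "n_t": "trip", "n_n": "night", "n_w": "recruit",
        "n_m": "supplies", "n_d": "first_worker", "n_c": "concurrent_worker",
    }[param]
    method = ec.MethodId.VIDEO_OBSERVATION
    bumped = design.model_copy(update={param: getattr(design, param) + 1})
    delta = (
        ec.total_study_cost(profile, bumped, method).total
        - ec.total_study_cost(profile, design, method).total
    )
    assert delta == pytest.approx(
        profile.unit_costs_for(method).slot(slot).mean, abs=1e-9
    )


@given(design=designs)
def test_breakdown_components_sum_to_total(profile, design):
    for method in METHODS:
        b = ec.total_study_cost(profile, design, method)
        assert sum(b.components.values()) == pytest.approx(b.total, rel=1e-9)
        assert set(b.components) == set(FIXED_COMPONENTS) | set(VARIABLE_COMPONENTS)


# ---------------------------------------------------------------------------
# combined_methods_cost
# ---------------------------------------------------------------------------

def test_single_method_combination_identity(profile, design):
    single = ec.combined_methods_cost(profile, design, [ec.MethodId.INCLINOMETER])
    alone = ec.total_study_cost(profile, design, ec.MethodId.INCLINOMETER)
    assert single.total == pytest.approx(alone.total, rel=1e-12)


def test_all_methods_between_max_and_sum(profile, design):
    combined = ec.combined_methods_cost(profile, design, METHODS).total
    singles = [ec.total_study_cost(profile, design, m).total for m in METHODS]
    assert max(singles) < combined < sum(singles)


def test_combination_order_invariance(profile, design):
    a = ec.combined_methods_cost(profile, design, METHODS)
    b = ec.combined_methods_cost(profile, design, list(reversed(METHODS)))
    assert a == b


def test_zero_shared_combination_equals_sum_of_singles(profile, design):
    """With shared components zeroed there is nothing to deduplicate, so the
    combination equals the brute-force sum of single-method totals."""
    data = profile.model_dump()
    data["shared_fixed"] = {}
    for slot in ("trip", "night", "recruit"):
        data["shared_unit"][slot] = {"mean": 0}
    zero_shared = ec.CostProfile.model_validate(data)
    combined = ec.combined_methods_cost(zero_shared, design, METHODS).total
    singles = sum(ec.total_study_cost(zero_shared, design, m).total for m in METHODS)
    assert combined == pytest.approx(singles, rel=1e-12)


def test_empty_method_set_rejected(profile, design):
    with pytest.raises(ec.UsageError):
        ec.combined_methods_cost(profile, design, [])


# ---------------------------------------------------------------------------
# labour_cost
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("hours, expected", [(1, 52.08), (0, 0.0), (100, 5208.0)])
def test_labour_valuation_default_rate(hours, expected):
    assert ec.labour_cost(hours) == pytest.approx(expected)


def test_labour_negative_hours_rejected():
    with pytest.raises(ValueError, match="hours"):
        ec.labour_cost(-0.5)


# ---------------------------------------------------------------------------
# stakeholder_totals
# ---------------------------------------------------------------------------

def test_stakeholder_column_sums(attribution):
    totals, shares, pct = ec.stakeholder_totals(attribution)
    assert totals[ec.Stakeholder.RESEARCHER] == 64_094
    assert pct[ec.Stakeholder.RESEARCHER] == 90
    assert math.isclose(sum(shares.values()), 1.0)


def test_single_stakeholder_holds_everything():
    att = ec.StakeholderAttribution(
        shares={"equipment": {ec.Stakeholder.RESEARCHER: 123.0}}
    )
    totals, shares, pct = ec.stakeholder_totals(att)
    assert shares[ec.Stakeholder.RESEARCHER] == 1.0
    assert pct[ec.Stakeholder.RESEARCHER] == 100


def test_empty_attribution_rejected():
    with pytest.raises(ec.UsageError):
        ec.stakeholder_totals(ec.StakeholderAttribution(shares={}))
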