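"""Monte-Carlo propagation of unit-cost variability into total study cost.

Prospective cost tracking yields not just mean unit costs but their
between-event standard deviations, and for travel and recruitment these are
large (coefficients of variation above 50%).  This module turns those sds
into a distribution of projected total study cost: each uncertain unit cost
is drawn from a non-negative distribution moment-matched to its (mean, sd),
the linear cost model is evaluated per draw, and the resulting totals are
summarised as a mean, sd, CV, and percentile interval.

Only means and sds are available, so a distribution family must be assumed.
The default is a log-normal — costs are positive and right-skewed — with
gamma and zero-truncated normal selectable; the choice is recorded in the
output so it is never silent.  Unit costs are drawn independently (no
covariance information exists).

Two sampling levels are offered.  The default draws one value per unit cost
per replicate, matching the aggregation level of the model itself.  The
stricter ``per_event`` level redraws the cost of every individual trip,
night, recruitment and measurement, which shrinks the between-replicate
variance of category sums by the usual 1/√n factor.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

from .core_model import (
    ConfigurationError,
    CostProfile,
    DesignParameters,
    MethodId,
    UndefinedCVError,
    UnitCost,
    _Model,
    total_study_cost,
)

__all__ = [
    "UncertaintySummary",
    "coefficient_of_variation",
    "monte_carlo_total",
    "FAMILIES",
]

FAMILIES = ("lognormal", "gamma", "truncnorm")

#: (unit-cost slot, design-parameter attribute) in fixed draw order; the
#: synthetic tracking generator follows the same order so that per-event
#: draws from the same seed coincide record-for-record.
DRAW_ORDER: tuple[tuple[str, str], ...] = (
    ("trip", "n_t"),
    ("night", "n_n"),
    ("recruit", "n_w"),
    ("supplies", "n_m"),
    ("first_worker", "n_d"),
    ("concurrent_worker", "n_c"),
)


class UncertaintySummary(_Model):
    """Distributional summary of projected total study cost."""

    mean: float
    sd: float
    cv: float | None
    interval: tuple[float, float]
    coverage: float
    n_draws: int
    seed: int
    distribution_family: str
    method: str
    deterministic_total: float


def coefficient_of_variation(unit: UnitCost) -> float:
    """sd/mean of a unit cost; raises when the ratio is undefined."""
    if unit.sd is None:
        raise UndefinedCVError("unit cost has no recorded sd; CV undefined")
    if unit.mean == 0:
        raise UndefinedCVError("unit cost mean is zero; CV undefined")
    return unit.sd / unit.mean


def cv_percent(unit: UnitCost) -> str:
    """Render a CV as the field usually prints it, e.g. ``'58%'``."""
    return f"{round(coefficient_of_variation(unit) * 100):d}%"


def _truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a zero-truncated normal with the given moments.

    A normal truncated to [0, ∞) cannot have CV ≥ 1 (the limit is the
    exponential-like tail as the parent mean goes to −∞), so a larger sd is
    rejected as un-matchable for this family.
    """
    cv = sd / mean

    def cv_of(alpha: float) -> float:
        # alpha = (0 - mu)/sigma; hazard lambda = phi(alpha)/(1 - Phi(alpha))
        lam = np.exp(stats.norm.logpdf(alpha) - stats.norm.logsf(alpha))
        mean_z = lam - alpha  # E[(X-mu)/sigma | X>0] + alpha... = E_std of shifted
        var_z = 1.0 + alpha * lam - lam**2
        return float(np.sqrt(max(var_z, 0.0)) / mean_z)

    lo, hi = -40.0, 30.0
    if not (cv_of(lo) < cv < cv_of(hi)):
        raise ConfigurationError(
            f"sd {sd} is too large for a zero-truncated normal with mean {mean} "
            f"(CV {cv:.3f} not attainable); use the lognormal or gamma family"
        )
    alpha = optimize.brentq(lambda a: cv_of(a) - cv, lo, hi, xtol=1e-12)
    lam = float(np.exp(stats.norm.logpdf(alpha) - stats.norm.logsf(alpha)))
    sigma = mean / (lam - alpha)
    mu = -alpha * sigma
    return mu, sigma


def draw_unit_cost(
    rng: np.random.Generator, unit: UnitCost, size, family: str = "lognormal"
) -> np.ndarray:
    """Draw unit-cost realisations moment-matched to ``(mean, sd)``.

    A unit cost without a recorded sd (or with sd 0) is held fixed at its
    mean and consumes no random numbers, so draw streams stay aligned across
    configurations that differ only in which costs are uncertain.
    """
    mean = unit.mean
    sd = unit.sd or 0.0
    if sd == 0.0:
        return np.full(size, mean)
    if mean <= 0:
        raise ConfigurationError(
            "cannot moment-match a non-negative family to mean 0 with sd > 0"
        )
    if family == "lognormal":
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size)
    if family == "gamma":
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return rng.gamma(shape, scale, size)
    if family == "truncnorm":
        mu, sigma = _truncnorm_params(mean, sd)
        return stats.truncnorm.rvs(
            -mu / sigma, np.inf, loc=mu, scale=sigma, size=size, random_state=rng
        )
    raise ConfigurationError(
        f"unknown distribution family {family!r}; expected one of: "
        + ", ".join(FAMILIES)
    )


def monte_carlo_total(
    profile: CostProfile,
    design: DesignParameters,
    method: MethodId,
    n_draws: int = 10_000,
    seed: int = 0,
    family: str = "lognormal",
    coverage: float = 0.95,
    per_event: bool = False,
    return_draws: bool = False,
) -> UncertaintySummary | tuple[UncertaintySummary, np.ndarray]:
    """Distribution of total study cost under unit-cost variability.

    Per draw, each unit cost with a recorded sd is sampled from ``family``
    (independently of the others), costs without sds are held at their
    means, and the cost model is evaluated.  Identical arguments and seed
    give bit-identical output.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must lie strictly between 0 and 1")
    method = MethodId.parse(method)
    deterministic = total_study_cost(profile, design, method)
    unit = profile.unit_costs_for(method)
    rng = np.random.default_rng(seed)

    totals = np.full(n_draws, deterministic.fixed_subtotal, dtype=float)
    for slot, param in DRAW_ORDER:
        uc = unit.slot(slot)
        n_x = getattr(design, param)
        if uc.sd:
            if per_event:
                if n_x:
                    totals += draw_unit_cost(rng, uc, (n_draws, n_x), family).sum(axis=1)
            else:
                totals += draw_unit_cost(rng, uc, n_draws, family) * n_x
        else:
            totals += uc.mean * n_x

    mean = float(totals.mean())
    sd = float(totals.std(ddof=1)) if n_draws > 1 else 0.0
    tail = (1.0 - coverage) / 2.0
    lower, upper = np.quantile(totals, [tail, 1.0 - tail])
    summary = UncertaintySummary(
        mean=mean,
        sd=sd,
        cv=sd / mean if mean > 0 else None,
        interval=(float(lower), float(upper)),
        coverage=coverage,
        n_draws=n_draws,
        seed=seed,
        distribution_family=family,
        method=method.value,
        deterministic_total=deterministic.total,
    )
    if return_draws:
        return summary, totals
    return summary
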