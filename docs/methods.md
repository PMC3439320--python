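# Methods

## Cost model

`ergocost` prices the data-collection stage of an occupational
exposure-assessment field study: the project is taken to start with
equipment acquisition and pilot testing and to end when the last scheduled
measurement day's data are on the institution's servers. Grant writing,
preliminary stakeholder meetings, data post-processing and statistical
analysis are outside the model's boundary by construction.

The model is linear: five fixed components (planning meetings,
administration, recruitment administration, equipment capital, training and
piloting) plus six variable components, each a unit cost multiplied by a
design count (trips, accommodation nights, workers recruited, worker-days
of supplies, researcher-days carrying a first-worker set-up cost, and
concurrent worker-days at a marginal cost). Fixed and unit costs split into
a shared part, required whichever method is used, and a method-specific
part. All arithmetic is exact over the given inputs; euro values are
rounded (half-up, to whole euros) only for display, and JSON output always
carries full precision.

Key assumptions inherited from the model's framing:

* **No equipment depreciation.** Equipment capital is charged in full to
  the study ("starting from scratch"). Amortisation is expressed, if
  wanted, by editing the profile — there is no depreciation machinery.
* **No multitasking savings in method combinations.**
  `combined_methods_cost` de-duplicates shared components but charges
  researcher time fully per method, which is the right convention for
  deciding between single-method studies and a conservative bound for
  actual concurrent deployment.
* **Single currency.** Profiles carry a currency label but no exchange
  rates.
* **Soft researcher-day consistency.** `n_m = n_d + n_c` holds for any
  cleanly planned design and is produced by `derive_design` by
  construction, but the model itself never requires it; a violating design
  logs a warning and evaluates normally, because achieved field designs are
  messier than planned ones.

### Fidelity to the reference fixtures

The bundled profile carries a published cost table whose unit costs are
rounded to whole euros, while the published totals were computed from
unrounded values. Reconstructed totals therefore differ from published
ones by small residuals (a consistent ~273 €, about one mean trip, for most
scenarios; within 0.5% for the inclinometer and questionnaire baselines and
within 2% for all scenario totals). The zero-travel scenario is the clean
case — every rounded-away digit multiplies a zero count — and reconstructs
the published totals exactly, as does the tenfold-recruitment delta
((220−22)·27 = 5 346 €) and the equipment saving (8 431 €). The
video-observation baseline reconstructs to 0.63% rather than 0.5%: its
blank supplies cell is read as 0 (the reading under which the zero-travel
scenario is exact), which leaves a slightly larger residual against the
published baseline. Blank method-specific cells are generally read as 0
with a logged notice.

## Scenario engine

A scenario is a sparse override set (design counts, unit-cost mean/sd,
fixed components) applied functionally to a baseline; application is
idempotent, disjoint scenarios commute, and chains resolve last-writer-wins
with a logged warning. Ratios are reported against the *recomputed*
baseline, not the published one, so that deltas and ratios are internally
exact consequences of linearity; comparisons against published totals live
in the test suite, not in the engine.

## Uncertainty propagation

Only means and sds of unit costs are available, so a distribution family
must be assumed. The default is a log-normal moment-matched to (mean, sd)
— costs are positive and right-skewed; gamma and zero-truncated normal are
selectable and the choice is recorded in the output summary. For the
truncated normal the parent (μ, σ) are solved by root-finding so the
*truncated* moments match the target; since a normal truncated at zero
cannot reach CV ≥ 1, such a request is rejected explicitly. Unit costs are
sampled independently (no covariance information exists). Costs without a
recorded sd are held fixed and consume no random numbers, keeping draw
streams aligned across configurations.

Sampling is at the unit-cost level by default (one draw per unit cost per
replicate, matching the model's aggregation level); `per_event=True`
instead redraws every individual trip, night, recruitment and measurement,
a stricter reading under which category sums concentrate by 1/√n. The
default summary uses 10 000 draws and a central 95% percentile interval;
identical arguments and seed give bit-identical output.

## Design explorer

Planning choices (workers, shifts per worker, workers per researcher-day,
trip policy) map deterministically onto design counts: `n_m` is workers ×
shifts unless overridden directly (the override exists precisely to encode
achieved designs with lost measurements), `n_d = ceil(n_m / concurrency)`,
`n_c = n_m − n_d`. Commuting sets one trip per researcher-day and no
nights; a stay-over policy of *k* nights per trip covers *k*+1 days per
trip, so `n_t = ceil(n_d / (k+1))` and `n_n = n_d − n_t`; an `explicit`
policy passes trip and night counts through untouched, because some
achieved logistics (e.g. 30 trips and 38 nights over 51 researcher-days)
follow no clean rule.

Default concurrency capacities are 4 workers per researcher-day for
inclinometry (set-up/take-down plus occasional troubleshooting), 10 for the
questionnaire, and 2 for video (the actively followed subject plus one
more); all are configurable since workplaces differ. The grid search is
exhaustive, requires all grid points to target the same measurement volume
(so it compares logistics, not sample size), counts infeasible points, and
breaks ties deterministically by total cost, then fewer researcher-days,
then fewer trips, then grid order.

## Synthetic tracking generator

The generator emulates prospective cost tracking: exactly one record per
event per category, with amounts drawn from the same moment-matched
families as the uncertainty module (deterministic where no sd was
tracked), in a fixed category order from a seeded generator — so a
generated stream's total equals the corresponding per-event Monte-Carlo
replicate exactly. Fixed components are emitted as office-task hour records
whose labour valuation (hours × 31 €/h × 1.68) reproduces each component
target exactly; this includes equipment, which is conceptually capital
rather than labour but round-trips identically under this valuation.

Stakeholder structure is a fixture, not a claim about any real study:
employer administrators share the planning-meeting, administration and
recruitment-administration components in the proportions of the reference
attribution table; workers' paid non-productive time is one hour per
measured worker-day at a flat worker rate whose 52 €/h default is a
calibration chosen so that 80 worker-days land near the reference figure.
The estimator computes per-category sample means and sds (sd reported as
absent for singleton categories), and its output slots directly into a cost
profile, closing the generate → estimate → evaluate loop.

What the generator does *not* emulate, and what green tests therefore do
not show about real data: researcher-specific reporting biases, correlated
unit costs (e.g. long trips implying hotel nights), non-linear recruitment
dynamics near exhaustive sampling, measurement failures, and the
within-study drift of unit costs over a field season.

## Problem sizes and numerical choices

The test suite and the acceptance script use 10⁴–10⁵ Monte-Carlo draws
(standard error a fraction of a percent of the total), 10⁴ events per
category for estimator-recovery checks (3-standard-error bounds), and
optimizer grids up to 1 000 points checked against brute-force
enumeration — sizes at which the stochastic checks are stable across seeds
while the whole suite runs in seconds. Breakdown additivity is asserted to
1e-9 relative; percent shares round half-up to integers, matching the
display convention for euro amounts.
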