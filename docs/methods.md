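# Methods

## Setting and estimand

The package implements a trial-based cost-utility analysis of a group
patient-education strategy ("learning and coping", LC) added to cardiac
rehabilitation, against standard education, over a 5-month horizon
(2 months of programme plus 3 months of follow-up). The estimand is the
incremental cost ΔC (DKK, price year 2013) and incremental QALY ΔE of LC
versus standard, summarised as net monetary benefit NB(λ) = λ·ΔE − ΔC and
as the probability of NB(λ) > 0 across willingness-to-pay thresholds
λ ∈ [0, 500 000] DKK per QALY (the cost-effectiveness acceptability
curve, CEAC).

## Micro-costing of the intervention

One course is costed bottom-up from role hours and unit costs:

- Nurse and physiotherapist formal hours (training, education, interviews,
  weekly team evaluations) are multiplied by a **load factor** of 1.5 —
  productive time is taken to be 45 min/h, the rest covers breaks,
  movement between locations, vacation and sickness — and valued at gross
  hourly wages (nurse 197 DKK/h, physiotherapist 160 DKK/h).
- The **expert patient** (a former patient acting as lay educator, average
  age 65) contributes unloaded volunteer hours, valued at a flat pensioner
  net wage of 108 DKK/h, including the assumed 20 min/way transport time;
  the hospital pays their transport, carried as a per-course total of
  2 304 DKK. (That total is not exactly 48 ways × 49 DKK/way = 2 352; the
  fixture carries the per-course constant as published.)
- A hospital **overhead rate** of 21 % is applied to the sum of all role
  subtotals, and the total is divided by the 10 patients a course serves
  on average.

Amounts are kept at full precision internally and rounded to whole DKK
(half-up) only at reported lines, which reproduces the published worked
example bit-exactly (LC 48 072 DKK/course, standard 27 348; 4 807 vs
2 735 per patient; increment 2 072).

Implementation-phase (ramp-up) costs are excluded by construction: the
estimate is the long-run average cost of routine provision.

## Patient-level costs and perspectives

Registry-priced categories — primary care (GP, specialist,
physiotherapist, dentist, other), prescribed medicine, secondary care
(outpatient tariffs and admissions) — enter as pre-tariffed amounts per
patient. The package derives the remaining categories:

- **Informal (patient) time**: attended sessions × 1.5 h plus interviews
  × 1 h, plus transport time (2 × 20 min per contact), valued by the
  opportunity-cost method at the gender- and 5-year-age-band-matched wage:
  gross (productive time) below pension age 67, net (leisure) at or above
  it. The shipped salary table is synthetic except for the published
  60–64 example cells, which it reproduces exactly.
- **Patient transport**: 2 × 10 km per attended contact at the 2013
  private-car tariff of 3.82 DKK/km.
- **Productivity loss**: weeks of work inability (sick leave, disability
  pension, re-schooling) × 37 h/week × gross wage, zero at or above
  pension age. The 37-hour week is the Danish full-time standard; the
  source tables price weeks without stating weekly hours.

The **healthcare perspective** counts primary care, medicine, secondary
care and the formal-care share of the intervention (staff time,
hospital-paid expert transport, overhead). The **societal perspective**
adds the expert patient's time, the patient's own time, patient transport
and productivity loss. A CPI map supports inflating earlier-year amounts
to 2013; all shipped unit costs are already in 2013 prices and no time
discounting is applied over the 5-month horizon (a rate parameter exists
and defaults to zero).

## QALYs

Utilities are preference-weighted health-state values in [0, 1]
(six-dimension short-form classification, British weights; scoring is out
of scope — utilities arrive as numbers) measured at months 0, 2 and 5.
QALY = area under the piecewise-linear utility curve with months/12 as
the time unit. Values outside [0, 1] are rejected rather than clamped,
since the weighting never leaves [0.30, 1] and out-of-range values signal
corruption. QALYs are not baseline-adjusted; the published arm QALYs are
plain AUCs of the printed trajectories, which the implementation
reproduces (0.319/0.314 imputed, 0.327/0.322 complete case).

## Missing utilities

Cost data come from full-coverage administrative registries and are never
imputed. Utility nonresponse (~43 % of patients miss at least one
measurement, non-monotonically) is handled by:

- **Chained equations (main analysis)**: each utility column is modelled
  by Bayesian linear regression on the other utility columns plus
  arm, age, gender, attendance, secondary-care cost, medicine cost and
  weeks of work inability (the trial's significant nonresponse
  predictors). Missing cells are filled from the posterior predictive
  draw (σ²* = RSS/χ²_{n−p}, β* ~ N(β̂, σ²*(XᵀX)⁻¹)), cycling 10 times,
  for m = 20 independent imputations, clipped to the observed range of
  the column. The source analysis does not state m or the conditional
  family; m = 20 stabilises pooled estimates at this nonresponse rate,
  and the linear-Gaussian conditional is the standard default for
  near-continuous utilities. Determinism: one master seed spawns one
  stream per imputation chain.
- **LOCF (sensitivity)**: missing month-2 values take the baseline,
  missing month-5 values the (post-imputation) month-2 value; patients
  without a baseline cannot be carried and are dropped with a reported
  count.
- **Complete case (sensitivity)**: patients with all three utilities
  observed.

Missing attendance counts (unregistered early in the trial, missing
completely at random) are imputed by arm means. A nonresponse analysis
compares responders and non-responders (Welch's t test, α = 0.05) on the
candidate predictors.

## Uncertainty: bootstrap, MI pooling, CEAC

Costs and QALYs are skewed, so uncertainty is non-parametric: each of
B = 10 000 replicates resamples patients with replacement independently
within each arm (the arms are independent randomised groups), preserving
arm sizes and each patient's cost-QALY pairing. Point estimates come from
the un-resampled data. SEs are the SD of the draws; intervals are
percentile (2.5th/97.5th) — the published intervals are asymmetric-capable
and percentile is the standard companion to a non-parametric bootstrap.

With multiple imputation, the bootstrap runs within each completed
dataset (B/m replicates each) and draws are pooled, so the CEAC carries
both sampling and between-imputation uncertainty; point estimates are
means over imputations (Rubin's rule for means). Pooling draws (rather
than bootstrapping before imputing) keeps the per-imputation CEAC average
identity exact; the bootstrap-then-impute alternative is not implemented.
Net benefit exactly zero counts as *not* cost-effective (strict
inequality; conservative, measure-zero for continuous data). The λ grid
is 0–500 000 in steps of 1 000.

## Sensitivity scenarios

Scenarios are declarative YAML files validated before any computation:
perspective, unit-cost overrides (e.g. nurse 150 / physiotherapist
120 DKK/h — the override also rescales the load-hour valuation, as it
must mechanically), load factor 1.0, 12 patients per course (divisor
only; course content fixed), category exclusions (patient time;
admissions discharged after follow-up, modelled as a flagged cost share
since discharge dates are not reproduced), and imputation mode. The
shipped fixtures cover the published sensitivity analyses.

## Synthetic trial generator

The generator emulates the study's data structure so the pipeline is
testable without registry access. Defaults are calibrated to the
published tables: arm sizes 413/412; age discretised around mean 63
(SD 10, range 27–92); 76 % male, 79 % ischemic heart disease; attendance
as bounded beta counts matching the arm means (training 19.61/18.48 of
1–24; education 6.46/5.97 of 0–9; dispersion κ = 1.5 chosen to give the
wide attendance spread the patient-time SEs imply); utilities at months
0/2/5 from a Gaussian copula (within-patient correlation 0.6, a typical
test–retest value) over beta marginals on [0.30, 1] with means per arm
and SD = SE·√n ≈ 0.122; per-category costs as gamma draws matching mean
and SD (costs are right-skewed and non-negative; no family is stated in
the source, gamma is the conventional choice); weeks of work inability
drawn only below pension age with the conditional mean rescaled so the
marginal mean stays on target; and a latent-health coupling of
secondary-care costs to utilities (copula correlation −0.3) so that
non-responders are genuinely worse off under MAR.

Nonresponse: a patient-level propensity p_i (constant under MCAR;
logistic in z(secondary-care cost) and −z(attendance) under MAR,
intercept calibrated by bisection to the marginal rate, default 0.43);
each utility cell is deleted independently with
q_i = 1 − (1 − p_i)^{1/3}, so P(any missing) = p_i exactly and patterns
are non-monotone.

What the generator does **not** emulate: registry event histories
(admission dates, DRG codes — only their cost consequences and a
post-follow-up flag), utility scoring from questionnaire items, clustered
course membership, and any cost-utility dependence beyond the single
latent-health factor. Passing tests therefore demonstrate correctness of
the analysis machinery under the stated data-generating assumptions, not
properties of the original registry data.

## Numerical choices and problem sizes

- Rounding: half-up to whole DKK at reported lines only.
- Bootstrap memory is bounded by chunking replicates; CEAC evaluation
  chunks the λ grid.
- The MICE posterior draw uses a pseudoinverse of XᵀX and an
  eigendecomposition square root, so collinear predictors degrade
  gracefully; if a column has fewer observed rows than predictors the
  chain falls back to resampling observed values.
- Degenerate inputs: zero-variance generator parameters produce constant
  columns; empty arms, all-missing columns, empty λ grids and unknown
  perspective/override/exclusion labels raise typed errors before
  computation.
- Test problem sizes are scaled for a laptop-class run: imputation
  recovery uses 200 replicates at 150 patients/arm with m = 5,
  end-to-end recovery 400/arm with B = 2 000 against a 40 000/arm truth
  run, null calibration 50 replicate trials at 100/arm. The acceptance
  script runs the full study scale (413/412, B = 10 000, m = 20).

## Known limitations

- Registry inputs are emulated, not linked; headline trial results are
  reproducible only in distribution, not as point values.
- The healthcare/societal split of the intervention's overhead assigns
  overhead wholly to healthcare (hospital capital), a judgement call.
- No MNAR sensitivity models (pattern mixture, delta adjustment), no
  value-of-information analysis, no parametric CEACs, no baseline-adjusted
  QALY variant.
- The salary table outside the published example cells is synthetic; with
  a real national table the informal-time and productivity valuations
  would shift accordingly.
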