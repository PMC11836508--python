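# Methods

This note records the models, assumptions, defaults and numerical choices
behind each stage of the engine, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Synthetic multi-database generator

The generator produces a network of independent databases sharing a common
design but differing in covariate prevalences and exposure prevalence,
which is what drives the cross-database equipoise differences the
diagnostics are meant to catch.

**Time** is an integer day index from a common origin (day 0 = Jan 1,
2010). No calendar arithmetic exists anywhere in the package; ages are
computed as `origin_year + day/365.25 − birth_year`.

**Persons.** Observation windows start uniformly in the first year and
last 730–3650 days (both configurable). Ages at day 0 are uniform on
25–90 so the age ≥ 35 filter genuinely binds; 80% of persons are female,
matching the predominance of women among outpatients treated for urinary
tract infection. Age and sex are recorded but are not confounders in the
default scenarios; confounding is carried by the binary covariates.

**Covariates** are independent Bernoulli with per-database prevalences
drawn uniformly from `covariate_prevalence_range`. This independence is a
stated simplification: real claims covariates are correlated and an order
of magnitude more numerous (the design this emulates uses >10,000). The
stored table is long/sparse and holds only the 1-entries; absence of a row
means absence of the feature, mirroring how binary baseline covariates are
handled in practice.

**Treatment assignment** is logistic with centred covariates:
`logit P(target) = intercept_d + (X − p_d)·coef`, where `intercept_d ~
Uniform(treatment_intercept_range)` per database. Centring makes the
intercept the (approximate) logit of the database's target prevalence, so
one parameter range controls the exposure-prevalence heterogeneity
directly. At most one exposure episode exists per person (a new-user
design has no use for re-exposures); the index date is uniform within the
window that leaves 365 days of history and 60 days of potential follow-up.

**Outcomes.** Outcome 0 is the primary outcome; outcomes 1..K (default
K = 50) are negative controls whose true hazard ratio is exactly 1 by
construction. First-event times are exponential with person hazard
`base · exp((X − p_d)·gamma)`; after the index date the target arm's
hazard is multiplied by `exp(true_log_hr)` (primary outcome only) and by
the per-outcome ascertainment-bias factor `exp(b_k)`, with
`b_k ~ N(bias_mean, bias_sd²)` drawn **once per outcome for the whole
network** — systematic error, the quantity EASE estimates, is correlated
across databases, not a fresh draw per site. The hazard switch at index
uses the memoryless property (the post-index residual time is redrawn at
the treated hazard), so the generated process is exactly the
proportional-hazards model the estimator assumes. Only the first event per
person and outcome is kept; 90% of events carry the hospital/ED setting
(configurable), exercising the outcome-setting filter. An optional
unmeasured confounder (binary, affecting treatment and all outcome
hazards, restrictable to a subset of databases) creates residual bias that
no amount of measured-covariate adjustment can remove.

**Default rates.** `baseline_hazard = 1e-4` events/person-day
(≈ 36.5/1000 person-years). Real aortic-event incidence is an order of
magnitude lower (≈ 2.5–6.5/1000 PY), but at 10⁴-person desk-scale
databases that rate would leave ~3 events per arm in a 60-day window and
every fit would be dominated by small-sample noise; the elevated rate
keeps the per-database estimates informative while the network sizes stay
small enough to simulate in seconds. This is a deliberate, fixed
desk-scale condition, stated here once.

**Determinism.** All randomness flows from `ScenarioConfig.seed` through
named substreams: network-level draws (bias terms) depend on the seed
only, database-level draws on (seed, database index), so a database
regenerated standalone is byte-identical to its copy inside the network,
and the same config always yields byte-identical output files.

## Cohort construction

Filters apply in a fixed order with per-step attrition counts (candidacy
by first use of any study class; exclusion when two classes tie on the
same first day; age ≥ 35; ≥ 365 days prior observation; indication within
the closed interval [index−7, index]; no hospitalisation in
[index−7, index]; no event of the analysed outcome in
[index−365, index−1]). Follow-up is intent-to-treat from index to the
first qualifying (hospital/ED) outcome, the end of the time-at-risk
window, or the end of observation, whichever is first. An outcome on the
index day counts as an event at 0.5 days — partial likelihood needs
strictly positive times, and the constant is documented rather than
hidden. Subjects eligible for both arms on the same day are excluded (the
least arbitrary of the defensible options).

## Propensity scores, matching, balance

The PS model is L1-penalised logistic regression (scikit-learn, saga;
intercept unpenalised). `reg_strength` is the penalty on the summed
log-likelihood (the inverse of scikit-learn's `C`); `"cv"` selects it by
10-fold cross-validated deviance. Zero regularisation is allowed but
raises a descriptive error under complete separation. Matching is greedy
nearest-neighbour without replacement on logit(PS), processing targets in
descending PS order (ties to the lower person id) with caliper
`0.2 × SD(logit PS)` pooled; a zero multiplier disables the caliper.
Greedy matching is order-dependent and not total-distance optimal — the
test suite documents a 2×2 case where it differs from the optimum — but it
is the behaviour used in practice and is deterministic here. The exact
caliper and algorithm used by the original design are not published;
these are the conventional choices and both are exposed in the config.

SMD uses the (target − comparator) convention with `p(1−p)` variances for
binary covariates; table output rounds to 2 decimals, full precision is
kept internally. Preference scores use the prevalence of the
*pre-matching* eligible population — equipoise is a pre-matching design
diagnostic. The equipoise gate is the per-arm fraction with F in the
closed band [0.3, 0.7]; a distribution-overlap coefficient is also
emitted as an auxiliary statistic because the two summaries are sometimes
conflated.

## Estimation

For a single binary covariate the Breslow-ties partial likelihood reduces
to `Σ_j [s_j β − d_j log(n1_j e^β + n0_j)]` over distinct event times;
Newton–Raphson on the scalar score converges in a handful of iterations,
with SE from the observed information and Wald intervals/p-values (these
feed calibration, which models normal random error). An Efron tie
correction sits behind a flag; ties are sparse in continuous-time
simulation. Fits with zero events in an arm — and the rarer monotone
likelihood where every target event precedes every comparator event — are
flagged non-estimable; their one-sided profile is retained so the
database can still contribute to pooling. The default profile grid is 401
points on log HR ∈ [−3, 3] (HR 0.05–20, step 0.015); interpolation is
piecewise-linear with −∞ outside the grid. The Cox model is fitted
unconditionally on the matched set (no pair stratification), matching how
the design is described; pair-stratified estimation is out of scope.

Event counts below 5 are masked as "<5" in every emitted table (a privacy
convention for small cells); estimates, person-time and rates are
untouched.

## Empirical calibration and EASE

The empirical null `b_i ~ N(mu, sigma² + t_i²)` is fitted by L-BFGS-B with
an analytic gradient and `sigma ≥ 0` (Nelder-Mead fallback); controls with
non-finite estimates or SEs are excluded and counted. Calibrated p-values
and CIs are the standard shift-and-widen formulas; EASE is the folded
normal mean. Uncertainty in (mu, sigma) itself is **not** propagated into
calibrated intervals — the fit uses 50+ controls and the extra width is
second-order; the reporting path fits the null on all controls, while the
coverage experiment uses the leave-one-out convention so a control never
calibrates itself.

For pooling, calibration is applied at the profile level: the likelihood
profile is convolved with N(mu, sigma²) by 31-node Gauss–Hermite
quadrature. For a normal profile this reduces *exactly* to the
shift-and-widen CI formula; for small-count profiles the non-normal shape
survives into the meta-analysis.

## Diagnostics and gating

All three thresholds are strict inequalities (a value exactly at the bar
fails), reflecting their definitions as "less than" / "greater than". The
balance gate applies to **all** simulated covariates — with synthetic data
the full covariate set is the natural analogue of a pre-defined list. A
missing input marks the corresponding check not-evaluable and fails the
analysis. Gating is idempotent and order-independent; exclusions are
reported with the failed checks.

## Evidence synthesis

Model: `beta_d ~ N(theta, tau²)`, priors `theta ~ N(0, 2²)` (weakly
informative on the log-HR scale) and `tau ~ half-N(0, 0.5²)`. The
original analysis does not publish its priors or sampler settings; these
are this package's choices, exposed in `MetaConfig`. Sampling is
Metropolis-within-Gibbs: random-walk Metropolis per `beta_d` on its
interpolated profile, exact Gibbs for `theta`, random-walk Metropolis on
`log tau` (half-normal prior, Jacobian included), with proposal scales
adapted only during burn-in so the kept chain has a fixed kernel. Defaults:
2 chains × 4000 kept iterations after 1000 burn-in. When every profile
carries an exact normal summary the `beta_d` updates collapse to conjugate
Gibbs draws — the fast path used when pooling many calibrated
normal-likelihood summaries; both paths are cross-checked against each
other and against a dense (theta, tau) quadrature oracle in the tests.
`tau` is floored at 1e-3 inside likelihood evaluations to avoid a sticky
boundary; `fix_tau=0` (fixed-effect pooling) and single-profile inputs are
handled by a direct single-parameter sampler on the summed profiles plus
prior. The reported 95% interval is the equal-tailed credible interval.

## Study runner

PS fitting and matching are performed once per (database, comparison) on
the primary-outcome eligible cohort; each negative control reuses the
matched set with its own 365-day washout applied by dropping affected
persons (partners are retained — the information loss from breaking a
pair is smaller than from discarding it, and the Cox model is unmatched
anyway). Negative controls are estimated per time-at-risk window, so each
window is calibrated against its own null. Database-level diagnostics use
the primary window's EASE. Every per-database stage runs inside a
partial-failure contract: an error is recorded and the run continues, and
the CLI exits 2 when anything failed. Outputs are deterministic CSV/JSON
(fixed float format, sorted keys) — re-running a config reproduces the
files byte for byte.

## What the tests do and do not show

The generator draws independent covariates, exponential event times and
exactly proportional hazards — the estimator is evaluated under its own
model. Passing tests therefore demonstrate the *engine* (correct
likelihoods, calibration algebra, gating logic, coverage under the stated
data-generating process), not robustness to the correlated covariates,
informative censoring, coding error and outcome misclassification of real
claims data. Chart-review validation of outcome definitions, vocabulary
handling and real-database connectivity are explicitly out of scope.

## Known limitations

- **Non-collapsibility / frailty attenuation**: with heavy censoring-free
  event fractions (cumulative incidence ≫ 5%), the marginal HR on the
  matched cohort attenuates below the conditional `exp(true_log_hr)`
  because high-frailty subjects are depleted — a property of the Cox
  estimand, not a bug. At the rare-outcome rates the engine targets
  (≤ 2% in the window) the effect is negligible, which the
  parameter-recovery experiment confirms.
- Greedy matching is not globally optimal; at small matched sizes
  (≲ 2000 pairs) residual chance imbalance occasionally exceeds the 0.1
  SMD gate — which the diagnostics then correctly report as a failed
  analysis rather than silently pooling it.
- Negative-control estimates within a database share the matched cohort
  and are treated as independent when fitting the null; with rare
  outcomes their dependence is negligible.
- The calibrated interval assumes systematic error independent of true
  effect size (negative controls only; no positive-control synthesis).
- One observation-end censoring mechanism; death and disenrollment are
  not distinguished.
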