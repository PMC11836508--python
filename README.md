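# netcohort

An **active-comparator, new-user cohort study engine** for comparative
drug-safety questions, exercised end to end on a bundled synthetic
multi-database generator with known ground truth.

Large distributed network studies estimate the risk of a rare outcome (for
example, aortic aneurysm or dissection after an antibiotic course) by
running the same rigorous design in every participating database: new-user
cohorts with an active comparator, large-scale propensity-score (PS)
matching, Cox proportional-hazards estimation, empirical calibration from
negative-control outcomes, objective study diagnostics that decide which
database results are trustworthy, and Bayesian random-effects meta-analysis
of the survivors. Patient-level data from such networks are never shared,
so this package pairs the full analysis engine with a synthetic-data module
that emulates a heterogeneous database network — confounded treatment
assignment, database-specific exposure prevalence, proportional-hazards
outcomes with a configurable true hazard ratio, true-null negative
controls, and injectable systematic bias — making every stage testable
against a known truth.

It is aimed at pharmacoepidemiologists and methods researchers who want a
transparent, fully reproducible implementation of this design to study its
operating characteristics.

## The method

For each database *d* and comparison (target vs comparator drug class):

1. **Cohort entry** at the first-ever use of any study drug class, with
   age ≥ 35 at index, ≥ 365 days of prior observation, a recorded
   indication on or within 7 days before index, no hospitalisation on or
   within 7 days before index, and no outcome event in the prior 365 days.
2. **Propensity scores** from L1-regularised logistic regression on all
   baseline covariates; greedy 1:1 nearest-neighbour matching on
   logit(PS) with a 0.2-SD caliper.
3. **Estimation**: Cox partial likelihood (Breslow ties) for the single
   treatment term; the log partial likelihood is also tabulated on a
   log-HR grid (a *likelihood profile*) so that small- and zero-event
   databases contribute their genuinely non-normal evidence downstream.
4. **Empirical calibration**: each negative-control estimate b_i with
   standard error t_i is modelled as b_i ~ N(mu, sigma^2 + t_i^2); the
   MLE (mu, sigma) is the *empirical null*. Calibrated p-values and CIs
   shift by mu and widen by sigma. EASE — the expected absolute
   systematic error — is E|X| for X ~ N(mu, sigma^2).
5. **Diagnostics gating** (all strict): max |SMD| after matching < 0.1;
   > 20% of *both* arms with preference scores in [0.3, 0.7] (the
   preference score removes exposure-prevalence effects:
   logit F = logit S − logit P); EASE < 0.25. Only analyses passing all
   three are pooled.
6. **Evidence synthesis**: beta_d ~ N(theta, tau^2) with
   theta ~ N(0, 2^2) and tau ~ half-N(0, 0.5^2), the data entering
   through each database's calibrated likelihood profile; the posterior is
   sampled by Metropolis-within-Gibbs.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
import numpy as np
import netcohort as nc

scenario = nc.ScenarioConfig(
    n_databases=4, n_persons=8000, n_covariates=10,
    covariate_prevalence_range=(0.1, 0.4),
    treatment_intercept_range=(-0.6, 0.2),   # per-database prevalence spread
    treatment_coefs=0.3, covariate_hazard_coefs=0.3,   # measured confounding
    baseline_hazard=3e-4, nc_baseline_hazard=3e-4,
    true_log_hr=float(np.log(1.5)), n_negative_controls=20, seed=11)
config = nc.StudyConfig(scenario=scenario, tar_days=(60,), primary_tar=60,
                        meta=nc.MetaConfig(n_chains=2, n_iter=2000,
                                           n_burn=500, seed=11))
report = nc.run_study(config, out_dir="results/example")
for d in report.diagnostics:
    print(f"{d.database_id}: max|SMD|={d.max_abs_smd_after:.3f} "
          f"equipoise=({d.equipoise_t:.2f}, {d.equipoise_c:.2f}) "
          f"EASE={d.ease_value:.3f} pass_all={d.pass_all}")
print(report.metas[("target_vs_comparator", 60)].summary())
```

prints

```
db_00: max|SMD|=0.029 equipoise=(0.97, 0.99) EASE=0.022 pass_all=True
db_01: max|SMD|=0.061 equipoise=(0.93, 0.95) EASE=0.060 pass_all=True
db_02: max|SMD|=0.103 equipoise=(0.97, 0.99) EASE=0.184 pass_all=False
db_03: max|SMD|=0.056 equipoise=(0.92, 0.94) EASE=0.078 pass_all=True
Bayesian random-effects meta-analysis (3 databases)
  pooled HR (posterior median) = 1.983 (95% CrI 1.285-3.111)
  pooled log HR: mean=0.6909 median=0.6846
  between-database SD tau (median) = 0.1793
  ESS(theta) = 356
```

Three of the four databases pass all diagnostics (db_02 narrowly misses
the balance gate and is excluded from pooling); the pooled calibrated 95%
credible interval comfortably covers the simulated true hazard ratio of
1.5 — at ~40 events per arm per database the interval is wide, which is
exactly what the engine is supposed to report honestly. `run_study` also
writes `estimates.csv`, `diagnostics.csv`, `null.json`, `meta.json`,
`forest.csv` (per-database calibrated HRs with small event counts masked
as "<5") and a `run_log.json` with the per-step cohort attrition.

The same pipeline is available from a shell:

```bash
netcohort simulate --config cfg.yaml --out data/
netcohort run --config cfg.yaml --data data/ --out results/
netcohort report --results results/
```

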