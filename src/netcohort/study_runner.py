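"""End-to-end study orchestration and report tables.

Runs the full chain — simulate (or load) the network, build new-user
cohorts, fit and match propensity scores, estimate Cox hazard ratios with
likelihood profiles, fit the empirical null from negative controls,
calibrate, evaluate the three objective diagnostics, gate, and pool the
gated databases with the Bayesian random-effects model — for every
comparison and time-at-risk window, writing CSV/JSON report tables.

The propensity model and the 1:1 matching are fitted once per
(database, comparison) on the primary-outcome eligible cohort; each
negative-control outcome reuses the matched set with that outcome's 365-day
washout applied by dropping affected persons. Every analysis stage runs per
database inside a partial-failure contract: an error in one database is
recorded and the run continues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .synthetic_data import (ScenarioConfig, SyntheticDatabase,
                             UnmeasuredConfounder, generate_network,
                             read_network)
from .cohort_builder import build_cohorts, extract_survival, prior_event_ids
from .propensity import (fit_propensity, preference_score, match_1to1,
                         balance_table, equipoise_fraction, preference_overlap)
from .estimation import (EstimationResult, fit_cox, mask_small_counts)
from .calibration import (fit_null, calibrate, calibrated_profile, ease)
from .diagnostics import (DEFAULT_THRESHOLDS, evaluate_diagnostics,
                          gate_for_meta)
from .evidence_synthesis import MetaConfig, MetaResult, pool

__all__ = ["StudyConfig", "StudyReport", "run_study", "forest_table"]

PRIMARY = 0


@dataclass
class StudyConfig:
    """Full study specification: scenario, comparisons, windows, gates."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    comparisons: tuple[tuple[str, str], ...] = (("target", "comparator"),)
    tar_days: tuple[int, ...] = (30, 60, 90, 365)
    primary_tar: int = 60
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    meta: MetaConfig = field(default_factory=MetaConfig)
    reg_strength: float | str = 1.0
    caliper_sd_mult: float = 0.2
    min_cell_count: int = 5
    mask_counts: bool = True

    def validate(self) -> None:
        self.scenario.validate()
        self.meta.validate()
        if self.primary_tar not in tuple(self.tar_days):
            raise ValueError("primary_tar must be in tar_days")
        if len(self.comparisons) < 1:
            raise ValueError("at least one comparison is required")

    # -- YAML round trip --------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        kw = dict(raw)
        sc = dict(kw.pop("scenario", {}))
        uc = sc.pop("unmeasured_confounder", None)
        if uc is not None:
            uc = UnmeasuredConfounder(**{
                k: tuple(v) if k == "databases" and v is not None else v
                for k, v in uc.items()})
        for k in ("covariate_prevalence_range", "treatment_intercept_range",
                  "observation_length_range", "age_range"):
            if k in sc:
                sc[k] = tuple(sc[k])
        scenario = ScenarioConfig(unmeasured_confounder=uc, **sc)
        meta = MetaConfig(**kw.pop("meta", {}))
        if "comparisons" in kw:
            kw["comparisons"] = tuple(tuple(c) for c in kw["comparisons"])
        if "tar_days" in kw:
            kw["tar_days"] = tuple(kw["tar_days"])
        return cls(scenario=scenario, meta=meta, **kw)

    def to_yaml(self, path) -> None:
        def clean(obj):
            if is_dataclass(obj):
                return {k: clean(v) for k, v in asdict(obj).items()}
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            return obj
        Path(path).write_text(yaml.safe_dump(clean(self), sort_keys=True))


@dataclass
class StudyReport:
    estimates: pd.DataFrame
    diagnostics: list
    nulls: dict                     # (db, comparison, tar) -> NullDistribution
    metas: dict                     # (comparison, tar) -> MetaResult
    forest: pd.DataFrame
    exclusions: list
    cohort_logs: dict
    errors: list
    out_dir: Optional[Path] = None


def _comparison_label(comp: tuple[str, str]) -> str:
    return f"{comp[0]}_vs_{comp[1]}"


def _analyze(db: SyntheticDatabase, comp, config: StudyConfig):
    """All per-(database, comparison) stages; returns a result bundle."""
    label = _comparison_label(comp)
    tcoh, ccoh, log = build_cohorts(db, config.primary_tar, PRIMARY, comp)
    if len(tcoh) == 0 or len(ccoh) == 0:
        raise ValueError(f"{db.database_id}/{label}: an arm is empty after "
                         "eligibility filtering")
    ids = np.concatenate([tcoh["person_id"], ccoh["person_id"]])
    X = db.covariate_matrix(ids)
    model = fit_propensity(X, tcoh["person_id"], ccoh["person_id"],
                           config.reg_strength)
    ps = np.clip(model.predict(X), 1e-12, 1 - 1e-12)
    nt = len(tcoh)
    ps_t, ps_c = ps[:nt], ps[nt:]
    pref_t = preference_score(ps_t, model.prevalence)
    pref_c = preference_score(ps_c, model.prevalence)
    equipoise = equipoise_fraction(pref_t, pref_c)
    overlap = preference_overlap(pref_t, pref_c)

    matched = match_1to1(tcoh["person_id"], ps_t, ccoh["person_id"], ps_c,
                         config.caliper_sd_mult)
    if matched.n_pairs == 0:
        raise ValueError(f"{db.database_id}/{label}: no matched pairs")
    balance = balance_table(X, tcoh["person_id"], ccoh["person_id"], matched)

    both = pd.concat([tcoh, ccoh], ignore_index=True)
    keep = np.concatenate([matched.target_ids, matched.comparator_ids])
    mcoh = both[both["person_id"].isin(keep)].reset_index(drop=True)

    results = {}      # (outcome_id, tar) -> EstimationResult
    nulls = {}        # tar -> NullDistribution
    survivals = {}    # tar -> primary-outcome survival records
    n_outcomes = db.n_outcomes
    for tar in config.tar_days:
        for k in range(n_outcomes):
            washed = prior_event_ids(db, mcoh, k)
            sub = (mcoh[~mcoh["person_id"].isin(washed)]
                   if len(washed) else mcoh)
            surv = extract_survival(sub, db, k, tar)
            res = fit_cox(surv, compute_profile=(k == PRIMARY),
                          database_id=db.database_id, comparison=label,
                          outcome_id=k, tar_days=tar)
            results[(k, tar)] = res
            if k == PRIMARY:
                survivals[tar] = surv
        controls = [results[(k, tar)] for k in range(1, n_outcomes)]
        usable = [(c.log_hr, c.se_log_hr) for c in controls if c.estimable]
        null = fit_null(usable)
        nulls[tar] = null
        for k in range(n_outcomes):
            res = results[(k, tar)]
            if res.estimable:
                res.calibrated = calibrate(res.log_hr, res.se_log_hr, null)

    report = evaluate_diagnostics(
        balance=balance, equipoise=equipoise,
        null=nulls[config.primary_tar], thresholds=config.thresholds,
        database_id=db.database_id, comparison=label,
        preference_overlap=overlap)
    cohort = both.assign(
        ps=np.concatenate([ps_t, ps_c]),
        preference=np.concatenate([pref_t, pref_c]))
    return {
        "label": label, "log": log, "model": model, "matched": matched,
        "balance": balance, "equipoise": equipoise, "results": results,
        "nulls": nulls, "diagnostics": report, "n_outcomes": n_outcomes,
        "cohort": cohort, "survivals": survivals,
    }


def run_study(config: StudyConfig,
              databases: Optional[list[SyntheticDatabase]] = None,
              data_dir=None, out_dir=None) -> StudyReport:
    """Execute the full study and (optionally) write the report tables.

    Fully deterministic given the config: all simulation randomness flows
    from the scenario seed, all sampling randomness from the meta seed.
    """
    config.validate()
    if databases is None:
        databases = (read_network(data_dir) if data_dir is not None
                     else generate_network(config.scenario))

    bundles = {}
    errors = []
    cohort_logs = {}
    diag_reports = []
    for db in databases:
        for comp in config.comparisons:
            key = (db.database_id, _comparison_label(comp))
            try:
                b = _analyze(db, comp, config)
            except Exception as exc:   # partial-failure contract
                errors.append({"database_id": db.database_id,
                               "comparison": _comparison_label(comp),
                               "error": f"{type(exc).__name__}: {exc}"})
                continue
            bundles[key] = b
            cohort_logs[key] = b["log"]
            diag_reports.append(b["diagnostics"])

    # meta-analysis per (comparison, tar) on gated, calibrated profiles
    metas, exclusions, forest_frames = {}, [], []
    nulls_out = {}
    for comp in config.comparisons:
        label = _comparison_label(comp)
        for tar in config.tar_days:
            primaries = [b["results"][(PRIMARY, tar)]
                         for k, b in bundles.items() if k[1] == label]
            if not primaries:
                continue
            gated, excl = gate_for_meta(diag_reports, primaries)
            exclusions.extend(excl)
            cal_profiles = []
            for res in gated:
                null = bundles[(res.database_id, label)]["nulls"][tar]
                if res.profile is not None:
                    cal_profiles.append(calibrated_profile(res.profile, null))
            if cal_profiles:
                meta = pool(cal_profiles, config.meta)
                metas[(label, tar)] = meta
                forest_frames.append(
                    forest_table(meta, gated,
                                 min_cell=config.min_cell_count,
                                 masked=config.mask_counts)
                    .assign(comparison=label, tar_days=tar))
    for key, b in bundles.items():
        for tar, null in b["nulls"].items():
            nulls_out[(key[0], key[1], tar)] = null

    estimates = _estimates_frame(bundles, config)
    forest = (pd.concat(forest_frames, ignore_index=True)
              if forest_frames else pd.DataFrame())

    report = StudyReport(estimates=estimates, diagnostics=diag_reports,
                         nulls=nulls_out, metas=metas, forest=forest,
                         exclusions=exclusions, cohort_logs=cohort_logs,
                         errors=errors,
                         out_dir=Path(out_dir) if out_dir else None)
    if out_dir is not None:
        _write_report(report, config, Path(out_dir))
        _write_detail(bundles, config, Path(out_dir))
    return report


def _estimates_frame(bundles, config: StudyConfig) -> pd.DataFrame:
    rows = []
    for (db_id, label), b in bundles.items():
        for (k, tar), res in b["results"].items():
            out = mask_small_counts(res, config.min_cell_count) \
                if config.mask_counts else res
            row = {
                "database_id": db_id, "comparison": label,
                "outcome_id": k, "tar_days": tar,
                "log_hr": res.log_hr, "se_log_hr": res.se_log_hr,
                "hr": res.hr, "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
                "p": res.p,
                "events_t": out.events_t, "events_c": out.events_c,
                "person_years_t": res.person_years_t,
                "person_years_c": res.person_years_c,
                "rate_t": res.rate_t, "rate_c": res.rate_c,
                "ard_per_1000py": res.ard_per_1000py,
                "estimable": res.estimable,
            }
            if res.calibrated is not None:
                row.update(cal_log_hr=res.calibrated.log_hr,
                           cal_hr=res.calibrated.hr,
                           cal_ci_lo=res.calibrated.ci95[0],
                           cal_ci_hi=res.calibrated.ci95[1],
                           cal_p=res.calibrated.p)
            rows.append(row)
    return pd.DataFrame(rows)


def forest_table(meta: MetaResult, gated: list[EstimationResult],
                 min_cell: int = 5, masked: bool = True) -> pd.DataFrame:
    """Tabular forest plot: one row per gated database plus a pooled row."""
    if not gated:
        raise ValueError("empty gated set")
    rows = []
    for res in gated:
        r = mask_small_counts(res, min_cell) if masked else res
        cal = res.calibrated
        rows.append({
            "database_id": res.database_id,
            "events_t": r.events_t, "events_c": r.events_c,
            "rate_t": res.rate_t, "rate_c": res.rate_c,
            "calibrated_hr": cal.hr if cal else np.nan,
            "ci_lo": cal.ci95[0] if cal else np.nan,
            "ci_hi": cal.ci95[1] if cal else np.nan,
        })
    rows.append({
        "database_id": "pooled",
        "events_t": "", "events_c": "", "rate_t": np.nan, "rate_c": np.nan,
        "calibrated_hr": meta.hr_median,
        "ci_lo": meta.ci95_hr[0], "ci_hi": meta.ci95_hr[1],
    })
    cols = ["database_id", "events_t", "events_c", "rate_t", "rate_c",
            "calibrated_hr", "ci_lo", "ci_hi"]
    return pd.DataFrame(rows)[cols]


def _write_report(report: StudyReport, config: StudyConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.estimates.to_csv(out / "estimates.csv", index=False,
                            float_format="%.10g")
    diag = pd.DataFrame([{k: v for k, v in asdict(d).items()
                          if k != "thresholds"}
                         | {f"threshold_{k}": v for k, v in d.thresholds.items()}
                         for d in report.diagnostics])
    diag.to_csv(out / "diagnostics.csv", index=False, float_format="%.10g")
    if len(report.forest):
        report.forest.to_csv(out / "forest.csv", index=False,
                             float_format="%.10g")
    nulls = {f"{db}|{comp}|tar{tar}": {
                 "mu": n.mu, "sigma": n.sigma, "ease": ease(n),
                 "n_controls_used": n.n_controls_used}
             for (db, comp, tar), n in report.nulls.items()}
    (out / "null.json").write_text(json.dumps(nulls, sort_keys=True, indent=1))
    metas = {f"{comp}|tar{tar}": {
                 "hr_median": m.hr_median, "ci95_hr": list(m.ci95_hr),
                 "theta_mean": m.theta_mean, "theta_median": m.theta_median,
                 "tau_median": m.tau_median, "ess": m.ess,
                 "n_databases": m.n_databases,
                 "shrunken_log_hr": [float(v) for v in m.shrunken_log_hr]}
             for (comp, tar), m in report.metas.items()}
    (out / "meta.json").write_text(json.dumps(metas, sort_keys=True, indent=1))
    logdoc = {
        "package_version": _version,
        "scenario_seed": config.scenario.seed,
        "meta_seed": config.meta.seed,
        "cohort_filters": {f"{db}|{comp}": {
            "candidates": lg.candidates, "excluded": lg.excluded,
            "retained": lg.retained}
            for (db, comp), lg in report.cohort_logs.items()},
        "exclusions": report.exclusions,
        "errors": report.errors,
    }
    (out / "run_log.json").write_text(json.dumps(logdoc, sort_keys=True,
                                                 indent=1))


def _write_detail(bundles, config: StudyConfig, out: Path) -> None:
    """Per-(database, comparison) working tables: cohort with scores,
    matched pairs, balance, primary-outcome survival records, and the
    primary likelihood profiles."""
    profiles = {}
    for (db_id, label), b in bundles.items():
        d = out / "detail" / f"{db_id}__{label}"
        d.mkdir(parents=True, exist_ok=True)
        b["cohort"].to_csv(d / "cohort.csv", index=False,
                           float_format="%.10g")
        b["cohort"][["person_id", "arm", "ps", "preference"]].to_csv(
            d / "preference.csv", index=False, float_format="%.10g")
        b["matched"].pairs.to_csv(d / "matches.csv", index=False,
                                  float_format="%.10g")
        b["balance"].to_csv(d / "balance.csv", index=False,
                            float_format="%.10g")
        for tar, surv in b["survivals"].items():
            surv.to_csv(d / f"survival_tar{tar}.csv", index=False,
                        float_format="%.10g")
        for tar in config.tar_days:
            prof = b["results"][(PRIMARY, tar)].profile
            if prof is not None:
                profiles[f"{db_id}|{label}|tar{tar}|outcome{PRIMARY}"] = {
                    "grid": [round(float(v), 6) for v in prof.grid],
                    "loglik": [round(float(v), 6) for v in prof.loglik],
                }
    (out / "profiles.json").write_text(
        json.dumps(profiles, sort_keys=True, indent=0))
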