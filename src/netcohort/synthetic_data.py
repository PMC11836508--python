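"""Synthetic multi-database observational data with known ground truth.

Emulates a heterogeneous network of observational health databases for an
active-comparator new-user drug-safety study: per-database populations with
sparse binary baseline covariates, confounded treatment assignment with
database-specific exposure prevalence, proportional-hazards outcome
generation with a configurable true hazard ratio, a panel of true-null
negative-control outcomes, and two injectable sources of systematic error
(differential outcome ascertainment in the target arm, and an unmeasured
confounder). Every downstream stage of the study engine can therefore be
tested against a known truth without any external data.

Time is an integer day index from a common origin (day 0 = Jan 1 of
``ORIGIN_YEAR``); no calendar arithmetic is performed anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ORIGIN_YEAR",
    "PRIMARY_OUTCOME",
    "UnmeasuredConfounder",
    "ScenarioConfig",
    "SyntheticDatabase",
    "generate_database",
    "generate_network",
    "write_database",
    "read_database",
    "write_network",
    "read_network",
]

ORIGIN_YEAR = 2010
#: outcome_id of the primary outcome; 1..n_negative_controls are true nulls
PRIMARY_OUTCOME = 0

_TABLES = ("persons", "covariates", "exposures", "indications",
           "hospitalizations", "outcomes")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class UnmeasuredConfounder:
    """A binary covariate that affects treatment and all outcomes but is
    absent from the recorded covariate table.

    ``databases`` restricts the *effects* to the listed database indices
    (None = every database); the latent variable itself is always drawn so
    that random streams are structurally identical across configurations.
    """

    prevalence: float = 0.2
    treatment_log_odds: float = 1.0
    outcome_log_hazard: float = 1.0
    databases: tuple[int, ...] | None = None

    def active_in(self, database_index: int) -> bool:
        return self.databases is None or database_index in self.databases


@dataclass
class ScenarioConfig:
    """Design parameters of one simulated network scenario.

    The defaults describe the reference study conditions: a 14-database
    network, 50 true-null negative-control outcomes, confounded treatment
    assignment through independent binary covariates, and per-database
    exposure-prevalence heterogeneity driven by ``intercept_range``.

    Treatment assignment is logistic:
    ``logit P(target) = intercept_d + (X - p_d) @ treatment_coefs`` with
    ``intercept_d ~ Uniform(intercept_range)`` per database and covariates
    centred at their database prevalences ``p_d``, so the intercept directly
    controls the database's target-arm prevalence. Outcome event times are
    exponential with person hazard
    ``baseline_hazard * exp((X - p_d) @ covariate_hazard_coefs)``; after the
    index date the target arm's hazard is multiplied by
    ``exp(true_log_hr)`` (primary outcome only) and by the per-outcome
    ascertainment-bias term ``exp(b_k)``, ``b_k ~ N(bias_mean, bias_sd^2)``
    drawn once per outcome for the whole network (systematic, not random,
    error).
    """

    n_databases: int = 14
    n_persons: int = 10_000
    n_covariates: int = 50
    covariate_prevalence_range: tuple[float, float] = (0.01, 0.5)
    treatment_intercept_range: tuple[float, float] = (-1.0, 1.0)
    treatment_coefs: float | Sequence[float] = 0.2
    baseline_hazard: float = 1e-4        # events per person-day, primary
    nc_baseline_hazard: float = 1e-4     # events per person-day, controls
    covariate_hazard_coefs: float | Sequence[float] = 0.2
    true_log_hr: float = 0.0
    n_negative_controls: int = 50
    bias_mean: float = 0.0
    bias_sd: float = 0.0
    unmeasured_confounder: UnmeasuredConfounder | None = None
    observation_length_range: tuple[int, int] = (730, 3650)
    exposure_fraction: float = 0.9
    indication_fraction: float = 0.95
    hospitalization_rate: float = 0.1
    hospital_setting_fraction: float = 0.9
    age_range: tuple[float, float] = (25.0, 90.0)
    female_fraction: float = 0.8
    seed: int = 0

    # -- helpers -----------------------------------------------------------
    def coef_vector(self, value) -> np.ndarray:
        v = np.asarray(value, dtype=float)
        if v.ndim == 0:
            return np.full(self.n_covariates, float(v))
        if v.shape != (self.n_covariates,):
            raise ValueError(
                f"coefficient vector has length {v.shape}, expected "
                f"{self.n_covariates}")
        return v

    @property
    def n_outcomes(self) -> int:
        return 1 + self.n_negative_controls

    def validate(self) -> None:
        if self.n_databases <= 0 or self.n_persons <= 0 or self.n_covariates <= 0:
            raise ValueError("n_databases, n_persons and n_covariates must be positive")
        lo, hi = self.covariate_prevalence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("covariate_prevalence_range must lie in [0, 1]")
        for name in ("exposure_fraction", "indication_fraction",
                     "hospitalization_rate", "hospital_setting_fraction",
                     "female_fraction"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.baseline_hazard <= 0 or self.nc_baseline_hazard <= 0:
            raise ValueError("hazards must be positive")
        if self.n_negative_controls < 2:
            raise ValueError("n_negative_controls must be >= 2")
        if self.observation_length_range[0] <= 0:
            raise ValueError("observation lengths must be positive")
        if self.bias_sd < 0:
            raise ValueError("bias_sd must be non-negative")
        self.coef_vector(self.treatment_coefs)
        self.coef_vector(self.covariate_hazard_coefs)

    def replace(self, **changes) -> "ScenarioConfig":
        return replace(self, **changes)


@dataclass
class SyntheticDatabase:
    """One simulated data source.

    Tables are tidy pandas DataFrames in the on-disk schema; ``truth``
    records the per-outcome true log hazard ratios and injected bias terms.
    The covariate table is long/sparse and holds only the 1-entries
    (absence of a row means the covariate is absent).
    """

    database_id: str
    persons: pd.DataFrame         # person_id, birth_year, sex, observation_start, observation_end
    covariates: pd.DataFrame      # person_id, covariate_id, value (=1)
    exposures: pd.DataFrame       # person_id, drug_class, start_date
    indications: pd.DataFrame     # person_id, date
    hospitalizations: pd.DataFrame  # person_id, date
    outcomes: pd.DataFrame        # person_id, outcome_id, date, setting
    truth: dict
    n_covariates: int
    _outcome_groups: dict | None = field(default=None, repr=False, compare=False)

    @property
    def n_outcomes(self) -> int:
        return len(self.truth["true_log_hr"])

    def covariate_matrix(self, person_ids) -> pd.DataFrame:
        """Dense 0/1 matrix (rows = ``person_ids``, cols = covariate ids)."""
        ids = np.asarray(person_ids)
        X = np.zeros((len(ids), self.n_covariates), dtype=np.int8)
        if len(self.covariates):
            row = pd.Index(ids).get_indexer(self.covariates["person_id"].to_numpy())
            keep = row >= 0
            X[row[keep], self.covariates["covariate_id"].to_numpy()[keep]] = 1
        return pd.DataFrame(X, index=ids,
                            columns=[f"c{j}" for j in range(self.n_covariates)])

    def outcome_events(self, outcome_id: int) -> pd.DataFrame:
        """Event records for one outcome (cached split of the long table)."""
        if self._outcome_groups is None:
            self._outcome_groups = {
                int(k): g[["person_id", "date", "setting"]].reset_index(drop=True)
                for k, g in self.outcomes.groupby("outcome_id", sort=True)
            }
        if outcome_id not in self._outcome_groups:
            if outcome_id >= self.n_outcomes or outcome_id < 0:
                raise KeyError(f"unknown outcome_id {outcome_id}")
            return self.outcomes.iloc[0:0][["person_id", "date", "setting"]]
        return self._outcome_groups[outcome_id]


def generate_database(config: ScenarioConfig, database_index: int) -> SyntheticDatabase:
    """Simulate one database of the network.

    Deterministic under ``(config.seed, database_index)``: network-level
    quantities (per-outcome bias terms) come from a stream keyed by the seed
    alone, database-level quantities (intercept, covariate prevalences,
    person data) from streams keyed by seed and database index, so a single
    database regenerated standalone is identical to its copy inside
    :func:`generate_network`.
    """
    config.validate()
    if not (0 <= database_index < config.n_databases):
        raise ValueError(f"database_index {database_index} out of range")
    cfg = config
    n, m = cfg.n_persons, cfg.n_covariates
    tcoef = cfg.coef_vector(cfg.treatment_coefs)
    gcoef = cfg.coef_vector(cfg.covariate_hazard_coefs)
    uc = cfg.unmeasured_confounder

    # network-level: ascertainment bias, one draw per outcome
    rng_net = np.random.default_rng([cfg.seed, 11])
    bias = rng_net.normal(cfg.bias_mean, cfg.bias_sd, cfg.n_outcomes)

    # database-level design draws
    rng_db = np.random.default_rng([cfg.seed, 13, database_index])
    intercept = rng_db.uniform(*cfg.treatment_intercept_range)
    prev = rng_db.uniform(*cfg.covariate_prevalence_range, m)

    rng = np.random.default_rng([cfg.seed, 17, database_index])

    # persons ------------------------------------------------------------
    age0 = rng.uniform(*cfg.age_range, n)
    birth_year = ORIGIN_YEAR - np.floor(age0).astype(np.int64)
    sex = np.where(rng.random(n) < cfg.female_fraction, "F", "M")
    obs_start = rng.integers(0, 366, n)
    length = rng.integers(cfg.observation_length_range[0],
                          cfg.observation_length_range[1] + 1, n)
    obs_end = obs_start + length
    pid = np.arange(n, dtype=np.int64)

    # covariates and latent confounder -----------------------------------
    X = (rng.random((n, m)) < prev).astype(np.int8)
    Xc = X - prev  # centred
    if uc is not None:
        u = (rng.random(n) < uc.prevalence).astype(np.int8)
    else:
        u = np.zeros(n, dtype=np.int8)
    uc_active = uc is not None and uc.active_in(database_index)

    # exposure episode (at most one per person: new-user design) ---------
    exposed = rng.random(n) < cfg.exposure_fraction
    lo = obs_start + 365
    hi = obs_end - 60  # leave room for follow-up inside observation
    exposed &= hi >= lo
    span = np.maximum(hi - lo + 1, 1)
    index_date = lo + np.floor(rng.random(n) * span).astype(np.int64)

    eta = intercept + Xc @ tcoef
    if uc_active:
        eta = eta + (u - uc.prevalence) * uc.treatment_log_odds
    target = rng.random(n) < _expit(eta)

    exposures = pd.DataFrame({
        "person_id": pid[exposed],
        "drug_class": np.where(target[exposed], "target", "comparator"),
        "start_date": index_date[exposed],
    })

    # indication within 7 days before (or on) the exposure date ----------
    has_ind = exposed & (rng.random(n) < cfg.indication_fraction)
    ind_offset = rng.integers(0, 8, n)
    indications = pd.DataFrame({
        "person_id": pid[has_ind],
        "date": np.maximum(index_date[has_ind] - ind_offset[has_ind],
                           obs_start[has_ind]),
    })

    # hospitalizations ---------------------------------------------------
    has_hosp = rng.random(n) < cfg.hospitalization_rate
    hosp_date = obs_start + np.floor(
        rng.random(n) * (obs_end - obs_start + 1)).astype(np.int64)
    hospitalizations = pd.DataFrame({
        "person_id": pid[has_hosp],
        "date": np.minimum(hosp_date[has_hosp], obs_end[has_hosp]),
    })

    # outcomes: exponential first-event times, hazard switch at index ----
    log_base_mult = Xc @ gcoef
    if uc_active:
        log_base_mult = log_base_mult + (u - uc.prevalence) * uc.outcome_log_hazard
    base_mult = np.exp(log_base_mult)
    on_target = exposed & target
    true_lhr = np.zeros(cfg.n_outcomes)
    true_lhr[PRIMARY_OUTCOME] = cfg.true_log_hr

    out_pid, out_oid, out_day, out_setting = [], [], [], []
    for k in range(cfg.n_outcomes):
        base = cfg.baseline_hazard if k == PRIMARY_OUTCOME else cfg.nc_baseline_hazard
        lam0 = base * base_mult
        day = obs_start + rng.exponential(1.0, n) / lam0
        tmult = np.exp(true_lhr[k] + bias[k])
        if tmult != 1.0:
            # memoryless redraw of the post-index residual at the treated hazard
            redo = on_target & (day >= index_date)
            nredo = int(redo.sum())
            if nredo:
                day = day.astype(float)
                day[redo] = index_date[redo] + \
                    rng.exponential(1.0, nredo) / (lam0[redo] * tmult)
        day_i = np.floor(day).astype(np.int64)
        keep = day_i <= obs_end
        nk = int(keep.sum())
        out_pid.append(pid[keep])
        out_oid.append(np.full(nk, k, dtype=np.int64))
        out_day.append(day_i[keep])
        out_setting.append(np.where(rng.random(nk) < cfg.hospital_setting_fraction,
                                    "hospital_or_ed", "other"))

    outcomes = pd.DataFrame({
        "person_id": np.concatenate(out_pid),
        "outcome_id": np.concatenate(out_oid),
        "date": np.concatenate(out_day),
        "setting": np.concatenate(out_setting),
    })

    cov_person, cov_id = np.nonzero(X)
    covariates = pd.DataFrame({
        "person_id": pid[cov_person],
        "covariate_id": cov_id.astype(np.int64),
        "value": np.ones(len(cov_id), dtype=np.int64),
    })

    persons = pd.DataFrame({
        "person_id": pid,
        "birth_year": birth_year,
        "sex": sex,
        "observation_start": obs_start,
        "observation_end": obs_end,
    })

    truth = {
        "true_log_hr": [float(v) for v in true_lhr],
        "bias": [float(b) for b in bias],
        "treatment_intercept": float(intercept),
    }
    return SyntheticDatabase(
        database_id=f"db_{database_index:02d}",
        persons=persons, covariates=covariates, exposures=exposures,
        indications=indications, hospitalizations=hospitalizations,
        outcomes=outcomes, truth=truth, n_covariates=m,
    )


def generate_network(config: ScenarioConfig) -> list[SyntheticDatabase]:
    """Simulate the full network; bias terms are shared across databases."""
    return [generate_database(config, i) for i in range(config.n_databases)]


# -- on-disk layout --------------------------------------------------------

def write_database(db: SyntheticDatabase, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(db, name).to_csv(out / f"{name}.csv", index=False)
    meta = dict(db.truth, database_id=db.database_id, n_covariates=db.n_covariates)
    (out / "truth.json").write_text(json.dumps(meta, sort_keys=True, indent=1))
    return out


def read_database(in_dir) -> SyntheticDatabase:
    p = Path(in_dir)
    meta = json.loads((p / "truth.json").read_text())
    tables = {name: pd.read_csv(p / f"{name}.csv") for name in _TABLES}
    truth = {k: meta[k] for k in ("true_log_hr", "bias", "treatment_intercept")}
    return SyntheticDatabase(database_id=meta["database_id"], truth=truth,
                             n_covariates=int(meta["n_covariates"]), **tables)


def write_network(dbs: list[SyntheticDatabase], out_dir) -> Path:
    out = Path(out_dir)
    for db in dbs:
        write_database(db, out / db.database_id)
    return out


def read_network(in_dir) -> list[SyntheticDatabase]:
    p = Path(in_dir)
    dirs = sorted(d for d in p.iterdir() if (d / "truth.json").exists())
    return [read_database(d) for d in dirs]
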