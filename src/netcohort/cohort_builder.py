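"""New-user cohort construction: eligibility, washout and time-at-risk.

Implements the study's entry rules for an active-comparator new-user design:
cohort entry at the first-ever exposure to any study drug class, age >= 35 at
index, >= 365 days of prior observation, a recorded indication on or within 7
days before index, no hospitalization on or within 7 days before index, and
no event of the analysed outcome in the 365 days before index. Follow-up is
intent-to-treat from the index date to the earliest of the first qualifying
outcome, the end of the time-at-risk window, or the end of observation.

"On or within 7 days prior" is the closed 8-day interval [index-7, index].
An outcome on the index date itself counts as an event at time 0.5 days (the
partial-likelihood machinery requires strictly positive times).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import ORIGIN_YEAR, SyntheticDatabase

__all__ = ["CohortLog", "build_cohorts", "extract_survival", "prior_event_ids",
           "DAY_ZERO_EVENT_TIME"]

#: time assigned to events occurring on the index date itself
DAY_ZERO_EVENT_TIME = 0.5

_COHORT_COLS = ["person_id", "arm", "index_date", "age_at_index",
                "observation_start", "observation_end"]


@dataclass
class CohortLog:
    """Per-step exclusion counts; candidates = sum(excluded) + retained."""

    candidates: int = 0
    excluded: dict = field(default_factory=dict)
    retained: int = 0

    def record(self, step: str, n: int) -> None:
        self.excluded[step] = int(n)

    def check(self) -> bool:
        return self.candidates == sum(self.excluded.values()) + self.retained


def build_cohorts(db: SyntheticDatabase, tar_days: int = 60,
                  outcome_id: int = 0,
                  comparison: tuple[str, str] = ("target", "comparator"),
                  ) -> tuple[pd.DataFrame, pd.DataFrame, CohortLog]:
    """Apply the eligibility and washout filters for one outcome.

    Returns ``(target, comparator, log)`` where the cohort frames carry
    person_id, arm, index_date, age_at_index and the observation bounds.
    Persons qualifying for both arms on the same day are excluded.
    """
    if not (0 <= outcome_id < db.n_outcomes):
        raise KeyError(f"unknown outcome_id {outcome_id}")
    target_class, comparator_class = comparison
    log = CohortLog()

    ex = db.exposures[db.exposures["drug_class"].isin(comparison)]
    if ex.empty:
        log.check()
        empty = pd.DataFrame(columns=_COHORT_COLS)
        return empty, empty.copy(), log

    # step 1: first exposure to any study drug class defines candidacy
    ex = ex.sort_values(["person_id", "start_date", "drug_class"])
    first_date = ex.groupby("person_id")["start_date"].transform("min")
    firsts = ex[ex["start_date"] == first_date]
    ncls = firsts.groupby("person_id")["drug_class"].nunique()
    ambiguous = set(ncls.index[ncls > 1])
    cand = firsts.drop_duplicates("person_id").copy()
    log.candidates = len(cand)
    amb = cand["person_id"].isin(ambiguous)
    log.record("both_arms_same_day", amb.sum())
    cand = cand[~amb]

    cand = cand.merge(db.persons, on="person_id", how="left")
    cand = cand.rename(columns={"start_date": "index_date"})
    cand["age_at_index"] = (ORIGIN_YEAR + cand["index_date"] / 365.25
                            - cand["birth_year"])

    # step 2: age >= 35 at index
    ok = cand["age_at_index"] >= 35.0
    log.record("age_lt_35", (~ok).sum())
    cand = cand[ok]

    # step 3: >= 365 days of prior observation
    ok = cand["observation_start"] <= cand["index_date"] - 365
    log.record("prior_observation_lt_365d", (~ok).sum())
    cand = cand[ok]

    # step 4: indication recorded in [index-7, index]
    ind = cand[["person_id", "index_date"]].merge(
        db.indications, on="person_id", how="inner")
    hit = ind[(ind["date"] >= ind["index_date"] - 7)
              & (ind["date"] <= ind["index_date"])]
    ok = cand["person_id"].isin(hit["person_id"].unique())
    log.record("no_indication_7d", (~ok).sum())
    cand = cand[ok]

    # step 5: no hospitalization in [index-7, index]
    hos = cand[["person_id", "index_date"]].merge(
        db.hospitalizations, on="person_id", how="inner")
    hit = hos[(hos["date"] >= hos["index_date"] - 7)
              & (hos["date"] <= hos["index_date"])]
    ok = ~cand["person_id"].isin(hit["person_id"].unique())
    log.record("hospitalized_7d", (~ok).sum())
    cand = cand[ok]

    # step 6: no outcome event in [index-365, index-1] (any care setting)
    washed = prior_event_ids(db, cand, outcome_id)
    ok = ~cand["person_id"].isin(washed)
    log.record("prior_outcome_365d", (~ok).sum())
    cand = cand[ok]

    log.retained = len(cand)
    assert log.check()

    cand["arm"] = np.where(cand["drug_class"] == target_class,
                           "target", "comparator")
    cand = cand[_COHORT_COLS].reset_index(drop=True)
    target = cand[cand["arm"] == "target"].reset_index(drop=True)
    comparator = cand[cand["arm"] == "comparator"].reset_index(drop=True)
    return target, comparator, log


def prior_event_ids(db: SyntheticDatabase, cohort: pd.DataFrame,
                    outcome_id: int) -> np.ndarray:
    """person_ids with any record of ``outcome_id`` in [index-365, index-1]."""
    ev = db.outcome_events(outcome_id)
    if ev.empty or cohort.empty:
        return np.array([], dtype=np.int64)
    m = cohort[["person_id", "index_date"]].merge(ev, on="person_id", how="inner")
    hit = m[(m["date"] >= m["index_date"] - 365)
            & (m["date"] <= m["index_date"] - 1)]
    return hit["person_id"].unique()


def extract_survival(cohort: pd.DataFrame, db: SyntheticDatabase,
                     outcome_id: int, tar_days: int) -> pd.DataFrame:
    """Survival records for one cohort / outcome / time-at-risk window.

    event = 1 iff a qualifying-setting (hospital or ED) outcome occurs within
    the window and before end of observation; otherwise the subject is
    censored at min(tar_days, observation_end - index).
    """
    if cohort.empty:
        return pd.DataFrame(columns=["person_id", "arm", "time", "event",
                                     "person_years"])
    ev = db.outcome_events(outcome_id)
    qual = ev[ev["setting"] == "hospital_or_ed"]
    m = cohort[["person_id", "index_date"]].merge(qual, on="person_id",
                                                  how="inner")
    m = m[m["date"] >= m["index_date"]]
    first = m.groupby("person_id")["date"].min()

    idx = cohort["index_date"].to_numpy()
    tmax = np.minimum(float(tar_days),
                      (cohort["observation_end"] - cohort["index_date"])
                      .to_numpy(dtype=float))
    rel = (first.reindex(cohort["person_id"]).to_numpy(dtype=float) - idx)
    event = np.isfinite(rel) & (rel <= tmax)
    time = np.where(event, rel, tmax)
    time = np.maximum(time, DAY_ZERO_EVENT_TIME)
    return pd.DataFrame({
        "person_id": cohort["person_id"].to_numpy(),
        "arm": cohort["arm"].to_numpy(),
        "time": time,
        "event": event.astype(np.int8),
        "person_years": time / 365.25,
    })
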