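"""Pre-defined objective study diagnostics and meta-analysis gating.

Three diagnostics decide whether each (database, comparison) analysis is
valid: covariate balance (max |SMD| after matching < 0.1 across all
covariates), empirical equipoise (> 20% of patients in *both* cohorts with
preference scores in [0.3, 0.7]) and residual systematic error
(EASE < 0.25). All thresholds are strict inequalities — a value exactly at
the threshold fails. Only analyses passing all three enter evidence
synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .calibration import NullDistribution, ease
from .estimation import EstimationResult

__all__ = ["DEFAULT_THRESHOLDS", "DiagnosticsReport", "evaluate_diagnostics",
           "gate_for_meta"]

DEFAULT_THRESHOLDS = {"smd": 0.1, "equipoise": 0.2, "ease": 0.25}


@dataclass
class DiagnosticsReport:
    database_id: str
    comparison: str
    max_abs_smd_after: Optional[float]
    equipoise_t: Optional[float]
    equipoise_c: Optional[float]
    ease_value: Optional[float]
    pass_balance: Optional[bool]
    pass_equipoise: Optional[bool]
    pass_ease: Optional[bool]
    pass_all: bool
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    preference_overlap: Optional[float] = None   # auxiliary, not a gate

    def failures(self) -> list[str]:
        out = []
        for name, flag in (("balance", self.pass_balance),
                           ("equipoise", self.pass_equipoise),
                           ("ease", self.pass_ease)):
            if flag is not True:
                out.append(name if flag is False else f"{name} (not evaluable)")
        return out


def evaluate_diagnostics(balance: Optional[pd.DataFrame] = None,
                         equipoise: Optional[tuple[float, float]] = None,
                         null: Optional[NullDistribution] = None,
                         thresholds: Optional[dict] = None,
                         database_id: str = "", comparison: str = "",
                         preference_overlap: Optional[float] = None,
                         ) -> DiagnosticsReport:
    """Evaluate the three gates for one (database, comparison).

    A missing input marks that check not-evaluable (None) and forces
    ``pass_all = False``.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)

    max_smd = eq_t = eq_c = ease_val = None
    pass_balance = pass_equipoise = pass_ease = None
    if balance is not None and len(balance):
        max_smd = float(np.abs(balance["smd_after"].to_numpy()).max())
        pass_balance = bool(max_smd < th["smd"])
    if equipoise is not None:
        eq_t, eq_c = float(equipoise[0]), float(equipoise[1])
        pass_equipoise = bool(eq_t > th["equipoise"] and eq_c > th["equipoise"])
    if null is not None:
        ease_val = float(ease(null))
        pass_ease = bool(ease_val < th["ease"])

    pass_all = pass_balance is True and pass_equipoise is True and pass_ease is True
    return DiagnosticsReport(
        database_id=database_id, comparison=comparison,
        max_abs_smd_after=max_smd, equipoise_t=eq_t, equipoise_c=eq_c,
        ease_value=ease_val, pass_balance=pass_balance,
        pass_equipoise=pass_equipoise, pass_ease=pass_ease,
        pass_all=pass_all, thresholds=th,
        preference_overlap=preference_overlap)


def gate_for_meta(reports: list[DiagnosticsReport],
                  results: list[EstimationResult],
                  ) -> tuple[list[EstimationResult], list[dict]]:
    """Forward exactly the results whose diagnostics all passed.

    Returns ``(gated, exclusions)``; each exclusion records the database,
    comparison and failed checks. A result without a matching report is an
    error. Gating is idempotent and order-independent.
    """
    by_key = {(r.database_id, r.comparison): r for r in reports}
    gated, exclusions = [], []
    for res in results:
        key = (res.database_id, res.comparison)
        if key not in by_key:
            raise KeyError(f"no diagnostics report for {key}")
        rep = by_key[key]
        if rep.pass_all:
            gated.append(res)
        else:
            exclusions.append({
                "database_id": res.database_id,
                "comparison": res.comparison,
                "outcome_id": res.outcome_id,
                "tar_days": res.tar_days,
                "failed": rep.failures(),
            })
    return gated, exclusions
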