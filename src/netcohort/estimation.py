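"""Cox hazard-ratio estimation for a single binary treatment covariate.

The partial likelihood with Breslow handling of ties reduces, for a binary
covariate, to a sum over distinct event times t_j:

    pl(beta) = sum_j [ s_j * beta - d_j * log(n1_j * e^beta + n0_j) ]

where d_j events occur at t_j (s_j of them in the target arm) and the risk
set holds n1_j target and n0_j comparator subjects. The maximum is found by
Newton-Raphson on the scalar score; the same objective evaluated on an
equally spaced grid of log-HR values gives the likelihood profile used by
the evidence-synthesis stage (non-normal likelihood approximation, so that
databases with few or zero events contribute without normal-theory bias).

An Efron tie correction is available behind a flag; ties are sparse in the
continuous-time simulation and Breslow is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LikelihoodProfile", "EstimationResult", "IncidenceSummary",
           "fit_cox", "likelihood_profile", "incidence_summary",
           "mask_small_counts", "DEFAULT_PROFILE_BOUNDS",
           "DEFAULT_PROFILE_POINTS"]

DEFAULT_PROFILE_BOUNDS = (-3.0, 3.0)   # covers HR ~0.05 to ~20
DEFAULT_PROFILE_POINTS = 401


@dataclass
class LikelihoodProfile:
    """Log partial-likelihood on a log-HR grid, max-normalised.

    Interpolation contract: piecewise-linear between grid points, -inf
    outside the grid bounds. ``normal`` carries ``(mean, se)`` when the
    profile is an exact normal approximation, enabling conjugate updates in
    the meta-analysis sampler.
    """

    grid: np.ndarray
    loglik: np.ndarray
    normal: Optional[tuple[float, float]] = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.loglik = np.asarray(self.loglik, dtype=float)
        if self.grid.shape != self.loglik.shape or self.grid.ndim != 1:
            raise ValueError("grid and loglik must be 1-d arrays of equal length")

    @classmethod
    def from_normal(cls, mean: float, se: float,
                    bounds: tuple[float, float] | None = None,
                    n_points: int = DEFAULT_PROFILE_POINTS) -> "LikelihoodProfile":
        if se <= 0 or not np.isfinite(se) or not np.isfinite(mean):
            raise ValueError("normal profile requires finite mean and positive se")
        if bounds is None:
            lo = min(DEFAULT_PROFILE_BOUNDS[0], mean - 6 * se)
            hi = max(DEFAULT_PROFILE_BOUNDS[1], mean + 6 * se)
        else:
            lo, hi = bounds
        grid = np.linspace(lo, hi, n_points)
        ll = -0.5 * ((grid - mean) / se) ** 2
        return cls(grid, ll - ll.max(), normal=(float(mean), float(se)))

    def interp(self, beta):
        """Piecewise-linear interpolation; -inf outside the grid."""
        return np.interp(beta, self.grid, self.loglik,
                         left=-np.inf, right=-np.inf)

    @property
    def argmax(self) -> float:
        return float(self.grid[int(np.argmax(self.loglik))])


@dataclass
class IncidenceSummary:
    events_t: int
    events_c: int
    person_years_t: float
    person_years_c: float
    rate_t: float            # per 1000 person-years
    rate_c: float
    ard_per_1000py: float    # rate_t - rate_c


@dataclass
class EstimationResult:
    """Hazard-ratio estimate for one (database, comparison, outcome, TAR)."""

    log_hr: float
    se_log_hr: float
    hr: float
    ci95: tuple[float, float]          # HR scale, Wald
    p: float
    events_t: object                   # int, or "<k" string once masked
    events_c: object
    person_years_t: float
    person_years_c: float
    rate_t: float
    rate_c: float
    ard_per_1000py: float
    estimable: bool
    n_t: int = 0
    n_c: int = 0
    profile: Optional[LikelihoodProfile] = None
    database_id: Optional[str] = None
    comparison: Optional[str] = None
    outcome_id: Optional[int] = None
    tar_days: Optional[int] = None
    calibrated: Optional[object] = None   # CalibratedResult, set by the runner

    def summary(self) -> str:
        lines = [
            "Cox proportional hazards (Breslow ties, binary treatment)",
            f"  database={self.database_id} outcome={self.outcome_id} "
            f"tar={self.tar_days}d",
            f"  subjects: target={self.n_t} comparator={self.n_c}",
            f"  events:   target={self.events_t} comparator={self.events_c}",
            f"  rates/1000PY: target={self.rate_t:.2f} "
            f"comparator={self.rate_c:.2f} ARD={self.ard_per_1000py:.2f}",
        ]
        if self.estimable:
            lines.append(
                f"  HR={self.hr:.3f} (95% CI {self.ci95[0]:.3f}-"
                f"{self.ci95[1]:.3f}), log HR={self.log_hr:.4f} "
                f"(SE {self.se_log_hr:.4f}), p={self.p:.3g}")
        else:
            lines.append("  not estimable (zero events in at least one arm)")
        return "\n".join(lines)


def _arm_indicator(survival: pd.DataFrame) -> np.ndarray:
    a = (survival["arm"].to_numpy() == "target")
    if a.all() or not a.any():
        raise ValueError("survival records must include both arms")
    return a


def _event_table(time, event, is_target):
    """Breslow sufficient statistics at the distinct event times.

    Returns (s, d, n1, n0): target events, total events, and risk-set sizes
    per arm at each distinct event time, ascending.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    a = is_target[order]
    et = t[e == 1]
    uniq = np.unique(et)
    if uniq.size == 0:
        return (np.zeros(0), np.zeros(0), np.zeros(0), np.zeros(0))
    # events per arm at each distinct time
    et_t = np.sort(t[(e == 1) & a])
    et_c = np.sort(t[(e == 1) & ~a])
    s = (np.searchsorted(et_t, uniq, side="right")
         - np.searchsorted(et_t, uniq, side="left")).astype(float)
    d_c = (np.searchsorted(et_c, uniq, side="right")
           - np.searchsorted(et_c, uniq, side="left")).astype(float)
    d = s + d_c
    # risk sets: subjects with time >= t_j
    pos = np.searchsorted(t, uniq, side="left")
    cum_target = np.concatenate([[0], np.cumsum(a)])
    n_total = len(t)
    tot_target = cum_target[-1]
    n1 = tot_target - cum_target[pos]
    n0 = (n_total - pos) - n1
    return s, d, n1.astype(float), n0.astype(float)


def _breslow_loglik(beta, s, d, n1, n0):
    """Vectorised over an array of beta values."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eb = np.exp(beta)
    denom = np.log(n1[:, None] * eb[None, :] + n0[:, None])
    return s.sum() * beta - (d[:, None] * denom).sum(axis=0)


def _efron_loglik(beta, time, event, is_target):
    # evaluated only when the efron flag is set; scalar beta
    ll = 0.0
    t = time
    for tj in np.unique(t[event == 1]):
        at = (t == tj) & (event == 1)
        s = float(is_target[at].sum())
        dj = float(at.sum())
        risk = t >= tj
        r1 = float(is_target[risk].sum())
        r0 = float(risk.sum() - r1)
        e1 = s
        e0 = dj - s
        eb = np.exp(beta)
        for l in range(int(dj)):
            frac = l / dj
            ll -= np.log((r1 - frac * e1) * eb + (r0 - frac * e0))
        ll += s * beta
    return ll


def _newton(s, d, n1, n0, tol=1e-10, max_iter=100):
    beta = 0.0
    S1 = s.sum()
    for _ in range(max_iter):
        eb = np.exp(beta)
        r = n1 * eb / (n1 * eb + n0)
        score = S1 - (d * r).sum()
        info = (d * r * (1.0 - r)).sum()
        if info <= 0:
            break
        step = np.clip(score / info, -2.0, 2.0)
        beta += step
        if abs(step) < tol:
            break
    eb = np.exp(beta)
    r = n1 * eb / (n1 * eb + n0)
    info = (d * r * (1.0 - r)).sum()
    return beta, info


def incidence_summary(survival: pd.DataFrame) -> IncidenceSummary:
    """Event counts, person-years and rates per 1000 PY, with the ARD."""
    if survival.empty:
        raise ValueError("empty survival set")
    a = survival["arm"].to_numpy() == "target"
    ev = survival["event"].to_numpy()
    py = survival["person_years"].to_numpy()
    py_t, py_c = float(py[a].sum()), float(py[~a].sum())
    if py_t <= 0 or py_c <= 0:
        raise ValueError("zero person-years in one arm")
    et, ec = int(ev[a].sum()), int(ev[~a].sum())
    rt, rc = 1000.0 * et / py_t, 1000.0 * ec / py_c
    return IncidenceSummary(et, ec, py_t, py_c, rt, rc, rt - rc)


def fit_cox(survival: pd.DataFrame, compute_profile: bool = False,
            profile_bounds=DEFAULT_PROFILE_BOUNDS,
            profile_points: int = DEFAULT_PROFILE_POINTS,
            ties: str = "breslow", **labels) -> EstimationResult:
    """Maximum partial-likelihood estimate of the target-vs-comparator HR.

    When either arm has zero events the estimate is flagged non-estimable
    (point, SE, CI and p are NaN) but the one-sided likelihood profile is
    still computed if requested, so the database can enter evidence
    synthesis through its profile.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    a = _arm_indicator(survival)
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=np.int8)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")

    s, d, n1, n0 = _event_table(time, event, a)
    inc = incidence_summary(survival)
    estimable = inc.events_t > 0 and inc.events_c > 0

    profile = None
    if compute_profile:
        grid = np.linspace(profile_bounds[0], profile_bounds[1], profile_points)
        ll = _breslow_loglik(grid, s, d, n1, n0) if len(d) else np.zeros_like(grid)
        profile = LikelihoodProfile(grid, ll - ll.max())

    if estimable:
        beta, info = _newton(s, d, n1, n0)
        # monotone partial likelihood (e.g. every target event precedes every
        # comparator event): the MLE is unbounded even with events in both
        # arms; treat like the zero-event case and keep only the profile
        if not np.isfinite(beta) or abs(beta) > 10.0 or info <= 0:
            estimable = False
    if estimable:
        if ties == "efron":
            from scipy.optimize import minimize_scalar
            res = minimize_scalar(
                lambda b: -_efron_loglik(b, time, event, a),
                bracket=(beta - 1.0, beta, beta + 1.0))
            beta = float(res.x)
            h = 1e-5
            info = -(_efron_loglik(beta + h, time, event, a)
                     - 2 * _efron_loglik(beta, time, event, a)
                     + _efron_loglik(beta - h, time, event, a)) / h ** 2
        se = float(1.0 / np.sqrt(info))
        z = stats.norm.ppf(0.975)
        ci = (float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))
        p = float(2.0 * stats.norm.sf(abs(beta) / se))
    else:
        beta = se = p = float("nan")
        ci = (float("nan"), float("nan"))

    return EstimationResult(
        log_hr=float(beta), se_log_hr=se,
        hr=float(np.exp(beta)) if estimable else float("nan"),
        ci95=ci, p=p,
        events_t=inc.events_t, events_c=inc.events_c,
        person_years_t=inc.person_years_t, person_years_c=inc.person_years_c,
        rate_t=inc.rate_t, rate_c=inc.rate_c,
        ard_per_1000py=inc.ard_per_1000py,
        estimable=estimable, n_t=int(a.sum()), n_c=int((~a).sum()),
        profile=profile, **labels)


def likelihood_profile(survival: pd.DataFrame,
                       grid_bounds=DEFAULT_PROFILE_BOUNDS,
                       n_points: int = DEFAULT_PROFILE_POINTS) -> LikelihoodProfile:
    """Breslow log partial-likelihood on an equally spaced log-HR grid."""
    if n_points < 11:
        raise ValueError("n_points must be >= 11")
    lo, hi = grid_bounds
    if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
        raise ValueError("invalid grid bounds")
    a = _arm_indicator(survival)
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=np.int8)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    s, d, n1, n0 = _event_table(time, event, a)
    grid = np.linspace(lo, hi, n_points)
    ll = _breslow_loglik(grid, s, d, n1, n0) if len(d) else np.zeros_like(grid)
    return LikelihoodProfile(grid, ll - ll.max())


def mask_small_counts(result: EstimationResult,
                      min_cell: int = 5) -> EstimationResult:
    """Replace event counts below ``min_cell`` by a ``"<k"`` sentinel.

    Only the reported counts change; estimates, rates and person-years are
    untouched (rates on masked rows are what the study actually computed,
    the privacy rule suppresses exact small counts in the published table).
    """
    def m(v):
        return f"<{min_cell}" if isinstance(v, (int, np.integer)) and v < min_cell else v
    return replace(result, events_t=m(result.events_t),
                   events_c=m(result.events_c))
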