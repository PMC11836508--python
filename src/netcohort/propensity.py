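"""Large-scale regularised propensity scores, 1:1 matching and balance.

The propensity score is the modelled probability of receiving the target
drug given the baseline covariates, fitted by L1-penalised logistic
regression (intercept unpenalised). Matching is greedy nearest-neighbour
without replacement on logit(PS) with a caliper expressed in pooled
standard deviations of logit(PS). Balance is assessed by the standardised
difference of means (SMD), and clinical equipoise by the preference score
transform logit(F) = logit(S) - logit(P) which removes the effect of the
overall exposure prevalence P.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

__all__ = ["PropensityModel", "MatchedCohort", "fit_propensity",
           "preference_score", "match_1to1", "compute_smd", "balance_table",
           "equipoise_fraction", "preference_overlap"]


@dataclass
class PropensityModel:
    """Fitted penalised logistic model of target-arm membership."""

    intercept: float
    coefs: pd.Series                 # indexed by covariate column name
    reg_strength: float | str
    prevalence: float                # training-set proportion in target arm
    n_target: int
    n_comparator: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Propensity scores for the rows of ``X``."""
        Xv = X[self.coefs.index].to_numpy(dtype=float)
        return expit(self.intercept + Xv @ self.coefs.to_numpy())

    def summary(self) -> str:
        nz = int((self.coefs != 0).sum())
        return (f"PropensityModel: {len(self.coefs)} covariates "
                f"({nz} non-zero), reg_strength={self.reg_strength}, "
                f"prevalence={self.prevalence:.3f} "
                f"(n={self.n_target}+{self.n_comparator})")


@dataclass
class MatchedCohort:
    """1:1 matched pairs with the scores they were matched on."""

    pairs: pd.DataFrame              # target_id, comparator_id, ps_t, ps_c
    caliper: float                   # on the logit(PS) scale; inf = none
    caliper_sd_mult: float
    scale: str = "logit(ps)"

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def target_ids(self) -> np.ndarray:
        return self.pairs["target_id"].to_numpy()

    @property
    def comparator_ids(self) -> np.ndarray:
        return self.pairs["comparator_id"].to_numpy()


def fit_propensity(covariates: pd.DataFrame, target_ids, comparator_ids,
                   reg_strength: float | str = 1.0,
                   max_iter: int = 2000) -> PropensityModel:
    """Fit the L1-regularised propensity model.

    ``covariates`` is a dense 0/1 frame indexed by person_id (see
    ``SyntheticDatabase.covariate_matrix``). ``reg_strength`` is the inverse
    of scikit-learn's C (penalty on the summed log-likelihood); ``"cv"``
    selects the strength by 10-fold cross-validated deviance; ``0`` fits an
    unpenalised model and raises on complete separation.
    """
    t_ids = np.asarray(target_ids)
    c_ids = np.asarray(comparator_ids)
    if len(t_ids) == 0 or len(c_ids) == 0:
        raise ValueError("both arms must be non-empty")
    if len(np.intersect1d(t_ids, c_ids)) > 0:
        raise ValueError("target and comparator arms must be disjoint")
    ids = np.concatenate([t_ids, c_ids])
    X = covariates.loc[ids].to_numpy(dtype=float)
    y = np.concatenate([np.ones(len(t_ids)), np.zeros(len(c_ids))])

    if reg_strength == "cv":
        clf = LogisticRegressionCV(
            Cs=10, cv=10, l1_ratios=[1.0], solver="saga",
            scoring="neg_log_loss", max_iter=max_iter, tol=1e-6, n_jobs=1,
            random_state=0, use_legacy_attributes=False)
        clf.fit(X, y)
        eff_strength = float(1.0 / np.atleast_1d(clf.C_)[0])
    elif reg_strength == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs",
                                 max_iter=max_iter, tol=1e-8)
        clf.fit(X, y)
        if np.abs(clf.coef_).max() > 20:
            raise ValueError(
                "complete (or quasi-complete) separation with zero "
                "regularisation; refit with a positive reg_strength")
        eff_strength = 0.0
    else:
        rs = float(reg_strength)
        if rs < 0:
            raise ValueError("reg_strength must be non-negative or 'cv'")
        clf = LogisticRegression(l1_ratio=1.0, C=1.0 / rs, solver="saga",
                                 max_iter=max_iter, tol=1e-6, random_state=0)
        clf.fit(X, y)
        eff_strength = rs

    coefs = pd.Series(clf.coef_.ravel(), index=covariates.columns)
    if not np.isfinite(coefs).all() or not np.isfinite(clf.intercept_[0]):
        raise ValueError("propensity model coefficients are not finite")
    return PropensityModel(
        intercept=float(clf.intercept_[0]), coefs=coefs,
        reg_strength=reg_strength if reg_strength == "cv" else eff_strength,
        prevalence=len(t_ids) / len(ids),
        n_target=len(t_ids), n_comparator=len(c_ids))


def preference_score(ps, prevalence: float):
    """Preference score F with logit(F) = logit(S) - logit(P).

    Removes the effect of the overall exposure prevalence P so that F = 0.5
    means the subject was equally likely to receive either drug. Strictly
    monotone in ps at fixed P; equals ps when P = 0.5.
    """
    ps_arr = np.asarray(ps, dtype=float)
    if np.any(ps_arr <= 0.0) or np.any(ps_arr >= 1.0):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie strictly in (0, 1)")
    out = expit(logit(ps_arr) - logit(prevalence))
    return float(out) if np.isscalar(ps) else out


def match_1to1(target_ids, target_ps, comparator_ids, comparator_ps,
               caliper_sd_mult: float = 0.2) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbour matching without replacement on logit(PS).

    Targets are processed in order of descending PS (ties: lower person_id
    first); each is paired with the nearest unused comparator on the logit
    scale within the caliper ``caliper_sd_mult * SD(logit PS, pooled)``;
    equidistant comparators tie-break to the lower person_id.
    ``caliper_sd_mult = 0`` disables the caliper. Unmatched subjects are
    dropped.
    """
    if caliper_sd_mult < 0:
        raise ValueError("caliper_sd_mult must be non-negative")
    t_ids = np.asarray(target_ids)
    c_ids = np.asarray(comparator_ids)
    t_ps = np.asarray(target_ps, dtype=float)
    c_ps = np.asarray(comparator_ps, dtype=float)
    if len(t_ids) == 0 or len(c_ids) == 0:
        raise ValueError("both arms must be non-empty")
    lt = logit(np.clip(t_ps, 1e-12, 1 - 1e-12))
    lc = logit(np.clip(c_ps, 1e-12, 1 - 1e-12))

    pooled = np.concatenate([lt, lc])
    sd = float(np.std(pooled, ddof=1)) if len(pooled) > 1 else 0.0
    if caliper_sd_mult == 0 or sd == 0:
        caliper = np.inf if caliper_sd_mult == 0 else 0.0
    else:
        caliper = caliper_sd_mult * sd

    t_order = np.lexsort((t_ids, -t_ps))
    c_order = np.lexsort((c_ids, lc))
    cs_val = lc[c_order]
    cs_id = c_ids[c_order]
    cs_ps = c_ps[c_order]
    nc = len(cs_val)
    # skip pointers over the sorted comparator array, with path compression
    removed = np.zeros(nc, dtype=bool)
    nxt = np.arange(1, nc + 2)         # candidate next alive index > i
    prv = np.arange(-1, nc)            # candidate prev alive index < i

    def find_right(i):
        path = []
        while i < nc and removed[i]:
            path.append(i)
            i = nxt[i]
        for p in path:
            nxt[p] = i
        return i                       # nc = none

    def find_left(i):
        path = []
        while i >= 0 and removed[i]:
            path.append(i)
            i = prv[i]
        for p in path:
            prv[p] = i
        return i                       # -1 = none

    pairs_t, pairs_c, ps_pairs = [], [], []
    for ti in t_order:
        x = lt[ti]
        j = int(np.searchsorted(cs_val, x))
        jr = find_right(j)
        jl = find_left(j - 1)
        dr = cs_val[jr] - x if jr < nc else np.inf
        dl = x - cs_val[jl] if jl >= 0 else np.inf
        if dl < dr:
            pick, dist = jl, dl
        elif dr < dl:
            pick, dist = jr, dr
        elif jl >= 0 and jr < nc:                # exact tie: lower person_id
            pick = jl if cs_id[jl] < cs_id[jr] else jr
            dist = dl
        else:
            continue                             # no comparator left
        if dist > caliper:
            continue
        pairs_t.append(t_ids[ti])
        pairs_c.append(cs_id[pick])
        ps_pairs.append((t_ps[ti], cs_ps[pick]))
        removed[pick] = True

    pairs = pd.DataFrame({
        "target_id": np.asarray(pairs_t),
        "comparator_id": np.asarray(pairs_c),
        "ps_t": np.asarray([p[0] for p in ps_pairs]),
        "ps_c": np.asarray([p[1] for p in ps_pairs]),
    })
    return MatchedCohort(pairs=pairs, caliper=float(caliper),
                         caliper_sd_mult=float(caliper_sd_mult))


def compute_smd(mean_t: float, mean_c: float,
                var_t: Optional[float] = None,
                var_c: Optional[float] = None) -> float:
    """Standardised difference of means, (target - comparator) convention.

    smd = (mean_t - mean_c) / sqrt((var_t + var_c) / 2). For binary
    covariates (variances omitted) var = p(1 - p).
    """
    if var_t is None:
        var_t = mean_t * (1.0 - mean_t)
    if var_c is None:
        var_c = mean_c * (1.0 - mean_c)
    if var_t < 0 or var_c < 0:
        raise ValueError("variances must be non-negative")
    denom = np.sqrt((var_t + var_c) / 2.0)
    if denom == 0.0:
        if mean_t == mean_c:
            return 0.0
        raise ValueError("degenerate SMD: zero variance in both arms with "
                         "unequal means")
    return float((mean_t - mean_c) / denom)


def _smd_vector(p_t: np.ndarray, p_c: np.ndarray) -> np.ndarray:
    denom = np.sqrt((p_t * (1 - p_t) + p_c * (1 - p_c)) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        smd = (p_t - p_c) / denom
    smd = np.where(denom == 0, np.where(p_t == p_c, 0.0, np.inf), smd)
    return smd


def balance_table(covariates: pd.DataFrame, target_ids, comparator_ids,
                  matched: MatchedCohort) -> pd.DataFrame:
    """Per-covariate prevalences and SMDs before and after matching.

    ``target_ids``/``comparator_ids`` are the pre-matching cohorts. SMDs are
    reported at full precision; round to 2 decimals for display.
    """
    pt_b = covariates.loc[np.asarray(target_ids)].mean().to_numpy(dtype=float)
    pc_b = covariates.loc[np.asarray(comparator_ids)].mean().to_numpy(dtype=float)
    pt_a = covariates.loc[matched.target_ids].mean().to_numpy(dtype=float)
    pc_a = covariates.loc[matched.comparator_ids].mean().to_numpy(dtype=float)
    return pd.DataFrame({
        "covariate_id": list(covariates.columns),
        "mean_t_before": pt_b, "mean_c_before": pc_b,
        "smd_before": _smd_vector(pt_b, pc_b),
        "mean_t_after": pt_a, "mean_c_after": pc_a,
        "smd_after": _smd_vector(pt_a, pc_a),
    })


def equipoise_fraction(pref_t, pref_c,
                       lo: float = 0.3, hi: float = 0.7) -> tuple[float, float]:
    """Per-arm proportion with preference score in the closed band [lo, hi]."""
    ft = np.asarray(pref_t, dtype=float)
    fc = np.asarray(pref_c, dtype=float)
    if len(ft) == 0 or len(fc) == 0:
        raise ValueError("both arms must be non-empty")
    return (float(((ft >= lo) & (ft <= hi)).mean()),
            float(((fc >= lo) & (fc <= hi)).mean()))


def preference_overlap(pref_t, pref_c, n_bins: int = 50) -> float:
    """Overlap coefficient of the two preference-score densities.

    Auxiliary statistic (the study gate is the per-arm equipoise fraction):
    sum over bins of min(density_t, density_c) * bin width, in [0, 1].
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    ht, _ = np.histogram(np.asarray(pref_t, float), bins=edges, density=True)
    hc, _ = np.histogram(np.asarray(pref_c, float), bins=edges, density=True)
    return float(np.minimum(ht, hc).sum() / n_bins)
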