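"""Bayesian random-effects meta-analysis over profile likelihoods.

Per-database log hazard ratios beta_d scatter around a pooled effect theta
with between-database SD tau:

    beta_d ~ Normal(theta, tau^2),  theta ~ Normal(0, 2^2),
    tau ~ half-Normal(0, 0.5^2)

The data enter through each database's log partial-likelihood profile
(piecewise-linear interpolation on the log-HR grid, -inf outside the grid),
not through normal approximations, so databases with few or zero events
contribute their genuinely asymmetric evidence. The posterior is sampled by
Metropolis-within-Gibbs: random-walk Metropolis for each beta_d on its
profile, an exact Gibbs draw for theta, and random-walk Metropolis on
log(tau). When every profile carries an exact normal summary the beta_d
updates collapse to conjugate Gibbs draws (identical posterior, no
interpolation), which is the fast path used when pooling calibrated
normal-likelihood summaries for many outcomes.

Proposal scales adapt only during burn-in (deterministically, given the
seed), so the post-burn-in chain is a valid fixed-kernel sampler and the
whole procedure is reproducible bit-for-bit from the config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .estimation import LikelihoodProfile

__all__ = ["MetaConfig", "MetaResult", "RandomEffectsMeta", "pool"]

_TAU_FLOOR = 1e-3  # numerical floor on tau inside likelihood evaluations


@dataclass
class MetaConfig:
    prior_sd_theta: float = 2.0
    prior_sd_tau: float = 0.5       # half-normal scale for tau
    n_chains: int = 2
    n_iter: int = 4000              # kept iterations per chain
    n_burn: int = 1000
    seed: int = 0
    fix_tau: Optional[float] = None  # e.g. 0.0 for fixed-effect pooling

    def validate(self) -> None:
        if self.prior_sd_theta <= 0 or self.prior_sd_tau <= 0:
            raise ValueError("prior SDs must be positive")
        if self.n_chains < 1 or self.n_iter < 1 or self.n_burn < 0:
            raise ValueError("chain and iteration counts must be positive")
        if self.fix_tau is not None and self.fix_tau < 0:
            raise ValueError("fix_tau must be non-negative")


@dataclass
class MetaResult:
    """Posterior summary of the pooled hazard ratio."""

    theta_mean: float
    theta_median: float
    hr_median: float
    ci95_hr: tuple[float, float]     # equal-tailed credible interval
    tau_median: float
    ess: float
    n_databases: int
    shrunken_log_hr: np.ndarray      # posterior means of beta_d
    theta_draws: np.ndarray = field(repr=False)
    tau_draws: np.ndarray = field(repr=False)
    config: MetaConfig = field(default_factory=MetaConfig)

    def summary(self) -> str:
        lo, hi = self.ci95_hr
        return ("Bayesian random-effects meta-analysis "
                f"({self.n_databases} databases)\n"
                f"  pooled HR (posterior median) = {self.hr_median:.3f} "
                f"(95% CrI {lo:.3f}-{hi:.3f})\n"
                f"  pooled log HR: mean={self.theta_mean:.4f} "
                f"median={self.theta_median:.4f}\n"
                f"  between-database SD tau (median) = {self.tau_median:.4f}\n"
                f"  ESS(theta) = {self.ess:.0f}")


def _ess(x: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.dot(xc, xc))
    total = 1.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k] if 2 * k < n else acf[2 * k - 1]
        if pair < 0:
            break
        total += 2.0 * pair
    return float(n / max(total, 1.0))


class RandomEffectsMeta:
    """Model object pooling per-database likelihood profiles.

    ``RandomEffectsMeta(profiles, config).fit()`` returns a
    :class:`MetaResult`; :func:`pool` is the functional wrapper.
    """

    def __init__(self, profiles: Sequence[LikelihoodProfile],
                 config: Optional[MetaConfig] = None):
        if len(profiles) == 0:
            raise ValueError("at least one profile is required")
        self.profiles = list(profiles)
        self.config = config or MetaConfig()
        self.config.validate()
        self._fast = all(p.normal is not None for p in self.profiles)
        if not self._fast:
            los = [p.grid[0] for p in self.profiles]
            his = [p.grid[-1] for p in self.profiles]
            if max(los) >= min(his):
                raise ValueError("profile grids do not overlap")

    # -- sampling ---------------------------------------------------------
    def fit(self) -> MetaResult:
        cfg = self.config
        D = len(self.profiles)
        th_draws, ta_draws, be_draws = [], [], []
        for chain in range(cfg.n_chains):
            rng = np.random.default_rng([cfg.seed, 97, chain])
            if D == 1 or cfg.fix_tau == 0.0:
                th, ta, be = self._run_pooled_chain(rng)
            elif self._fast:
                th, ta, be = self._run_normal_chain(rng)
            else:
                th, ta, be = self._run_profile_chain(rng)
            th_draws.append(th)
            ta_draws.append(ta)
            be_draws.append(be)
        theta = np.concatenate(th_draws)
        tau = np.concatenate(ta_draws)
        beta = np.concatenate(be_draws, axis=0)
        lo, med, hi = np.percentile(theta, [2.5, 50.0, 97.5])
        return MetaResult(
            theta_mean=float(theta.mean()), theta_median=float(med),
            hr_median=float(np.exp(med)),
            ci95_hr=(float(np.exp(lo)), float(np.exp(hi))),
            tau_median=float(np.median(tau)), ess=_ess(theta),
            n_databases=D, shrunken_log_hr=beta.mean(axis=0),
            theta_draws=theta, tau_draws=tau, config=cfg)

    # log density pieces
    def _lp_theta_prior(self, theta):
        return -0.5 * (theta / self.config.prior_sd_theta) ** 2

    def _lp_tau(self, tau, beta, theta):
        # likelihood of the random effects + half-normal prior, tau > 0
        te = max(tau, _TAU_FLOOR)
        resid = np.sum((beta - theta) ** 2)
        return (-len(beta) * math.log(te) - resid / (2 * te * te)
                - 0.5 * (tau / self.config.prior_sd_tau) ** 2)

    def _init_beta(self):
        out = []
        for p in self.profiles:
            if p.normal is not None:
                out.append(p.normal[0])
            else:
                out.append(p.argmax)
        return np.array(out, dtype=float)

    def _gibbs_theta(self, beta, tau, rng):
        te = max(tau, _TAU_FLOOR)
        prec = len(beta) / te ** 2 + 1.0 / self.config.prior_sd_theta ** 2
        mean = beta.sum() / te ** 2 / prec
        return mean + rng.standard_normal() / math.sqrt(prec)

    def _mh_tau(self, tau, beta, theta, step, rng):
        lt = math.log(max(tau, _TAU_FLOOR))
        lt_new = lt + step * rng.standard_normal()
        tau_new = math.exp(lt_new)
        # Jacobian of the log transform: + log tau
        lp_old = self._lp_tau(tau, beta, theta) + lt
        lp_new = self._lp_tau(tau_new, beta, theta) + lt_new
        if math.log(rng.random()) < lp_new - lp_old:
            return tau_new, 1
        return tau, 0

    def _run_profile_chain(self, rng):
        """Metropolis-within-Gibbs on interpolated grid profiles."""
        cfg = self.config
        profs = self.profiles
        D = len(profs)
        beta = self._init_beta()
        theta = float(beta.mean())
        tau = cfg.fix_tau if cfg.fix_tau is not None else 0.1
        step_b = np.full(D, 0.3)
        step_t = 0.5
        acc_b = np.zeros(D)
        acc_t = 0
        lp_b = np.array([float(profs[d].interp(beta[d])) for d in range(D)])
        n_total = cfg.n_burn + cfg.n_iter
        th, ta = np.empty(cfg.n_iter), np.empty(cfg.n_iter)
        be = np.empty((cfg.n_iter, D))
        for it in range(n_total):
            te = max(tau, _TAU_FLOOR)
            for d in range(D):
                prop = beta[d] + step_b[d] * rng.standard_normal()
                lp_new = float(profs[d].interp(prop))
                if np.isfinite(lp_new):
                    delta = (lp_new - lp_b[d]
                             - 0.5 * ((prop - theta) ** 2
                                      - (beta[d] - theta) ** 2) / te ** 2)
                    if math.log(rng.random()) < delta:
                        beta[d] = prop
                        lp_b[d] = lp_new
                        acc_b[d] += 1
                else:
                    rng.random()  # keep stream advance comparable
            theta = self._gibbs_theta(beta, tau, rng)
            if cfg.fix_tau is None:
                tau, a = self._mh_tau(tau, beta, theta, step_t, rng)
                acc_t += a
            if it < cfg.n_burn and (it + 1) % 50 == 0:
                rate_b = acc_b / 50.0
                step_b *= np.where(rate_b > 0.5, 1.4,
                                   np.where(rate_b < 0.2, 0.7, 1.0))
                if cfg.fix_tau is None:
                    rate_t = acc_t / 50.0
                    step_t *= 1.4 if rate_t > 0.5 else (0.7 if rate_t < 0.2 else 1.0)
                acc_b[:] = 0
                acc_t = 0
            if it >= cfg.n_burn:
                j = it - cfg.n_burn
                th[j], ta[j] = theta, tau
                be[j] = beta
        return th, ta, be

    def _run_normal_chain(self, rng):
        """Conjugate Gibbs for beta_d when all profiles are normal."""
        cfg = self.config
        m = np.array([p.normal[0] for p in self.profiles])
        s2 = np.array([p.normal[1] ** 2 for p in self.profiles])
        D = len(m)
        theta = float(m.mean())
        tau = cfg.fix_tau if cfg.fix_tau is not None else 0.1
        step_t = 0.5
        acc_t = 0
        n_total = cfg.n_burn + cfg.n_iter
        th, ta = np.empty(cfg.n_iter), np.empty(cfg.n_iter)
        be = np.empty((cfg.n_iter, D))
        for it in range(n_total):
            te = max(tau, _TAU_FLOOR)
            prec = 1.0 / s2 + 1.0 / te ** 2
            mean = (m / s2 + theta / te ** 2) / prec
            beta = mean + rng.standard_normal(D) / np.sqrt(prec)
            theta = self._gibbs_theta(beta, tau, rng)
            if cfg.fix_tau is None:
                tau, a = self._mh_tau(tau, beta, theta, step_t, rng)
                acc_t += a
            if it < cfg.n_burn and (it + 1) % 50 == 0 and cfg.fix_tau is None:
                rate_t = acc_t / 50.0
                step_t *= 1.4 if rate_t > 0.5 else (0.7 if rate_t < 0.2 else 1.0)
                acc_t = 0
            if it >= cfg.n_burn:
                j = it - cfg.n_burn
                th[j], ta[j] = theta, tau
                be[j] = beta
        return th, ta, be

    def _run_pooled_chain(self, rng):
        """Single-parameter posterior: tau fixed at 0 or a single profile.

        The random effects degenerate to beta_d = theta; the target is the
        sum of the profiles plus the theta prior.
        """
        cfg = self.config
        profs = self.profiles
        D = len(profs)

        def logpost(theta):
            lp = self._lp_theta_prior(theta)
            for p in profs:
                lp += float(p.interp(theta))
            return lp

        theta = float(np.mean(self._init_beta()))
        lp = logpost(theta)
        if not np.isfinite(lp):
            theta = float(np.mean([p.grid[len(p.grid) // 2] for p in profs]))
            lp = logpost(theta)
        step = 0.3
        acc = 0
        n_total = cfg.n_burn + cfg.n_iter
        th = np.empty(cfg.n_iter)
        for it in range(n_total):
            prop = theta + step * rng.standard_normal()
            lp_new = logpost(prop)
            if np.isfinite(lp_new) and math.log(rng.random()) < lp_new - lp:
                theta, lp = prop, lp_new
                acc += 1
            if it < cfg.n_burn and (it + 1) % 50 == 0:
                rate = acc / 50.0
                step *= 1.4 if rate > 0.5 else (0.7 if rate < 0.2 else 1.0)
                acc = 0
            if it >= cfg.n_burn:
                th[it - cfg.n_burn] = theta
        ta = np.zeros(cfg.n_iter)
        be = np.repeat(th[:, None], D, axis=1)
        return th, ta, be


def pool(profiles: Sequence[LikelihoodProfile],
         config: Optional[MetaConfig] = None) -> MetaResult:
    """Pool per-database likelihood profiles into one hazard ratio."""
    return RandomEffectsMeta(profiles, config).fit()
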