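"""Empirical calibration from negative-control outcomes, and EASE.

Negative-control outcomes are believed to be unaffected by either exposure
(true HR = 1), so the spread of their estimates beyond what their standard
errors explain measures residual systematic error. The empirical null is a
normal model of that systematic error on the log-HR scale: each control
estimate b_i with SE t_i is modelled as

    b_i ~ Normal(mu, sigma^2 + t_i^2)

and (mu, sigma) are fitted by maximum likelihood. Calibrated p-values and
confidence intervals shift by mu and widen by sigma; the expected absolute
systematic error (EASE) is E|X| for X ~ Normal(mu, sigma^2) (a folded
normal mean), with lower values indicating less residual bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .estimation import LikelihoodProfile

__all__ = ["NullDistribution", "CalibratedResult", "fit_null",
           "calibrate_p", "calibrate_ci", "calibrate", "ease",
           "calibrated_profile"]


@dataclass
class NullDistribution:
    """Fitted systematic-error distribution Normal(mu, sigma^2)."""

    mu: float
    sigma: float
    n_controls_used: int
    loglik: float

    def summary(self) -> str:
        return (f"EmpiricalNull: mu={self.mu:.4f}, sigma={self.sigma:.4f} "
                f"(log-HR scale), {self.n_controls_used} controls, "
                f"EASE={ease(self):.4f}")


@dataclass
class CalibratedResult:
    """Bias-shifted point estimate with calibrated CI and p-value."""

    log_hr: float
    hr: float
    ci95: tuple[float, float]   # HR scale
    p: float


def fit_null(log_hrs, ses=None) -> NullDistribution:
    """Maximum-likelihood fit of the empirical null.

    Accepts either two arrays (estimates, standard errors) or an iterable of
    ``(log_hr, se)`` pairs. Controls with non-finite estimates or SEs (for
    example zero events in one arm) are excluded and not counted in
    ``n_controls_used``; at least two usable controls are required.
    """
    if ses is None:
        arr = np.asarray(list(log_hrs), dtype=float)
        b, s = arr[:, 0], arr[:, 1]
    else:
        b = np.asarray(log_hrs, dtype=float)
        s = np.asarray(ses, dtype=float)
    ok = np.isfinite(b) & np.isfinite(s) & (s >= 0)
    b, s = b[ok], s[ok]
    if len(b) < 2:
        raise ValueError(f"need >= 2 estimable negative controls, got {len(b)}")
    s2 = s ** 2

    def nll_and_grad(params):
        mu, sig = params
        v = sig ** 2 + s2
        r = b - mu
        nll = 0.5 * np.sum(np.log(2 * np.pi * v) + r ** 2 / v)
        dmu = np.sum(-r / v)
        dsig = sig * np.sum(1.0 / v - r ** 2 / v ** 2)
        return nll, np.array([dmu, dsig])

    x0 = np.array([b.mean(),
                   math.sqrt(max(b.var() - s2.mean(), 1e-4))])
    res = optimize.minimize(nll_and_grad, x0, jac=True, method="L-BFGS-B",
                            bounds=[(None, None), (0.0, None)])
    if not res.success:
        res2 = optimize.minimize(lambda p: nll_and_grad(p)[0], x0,
                                 method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-10})
        if res2.fun <= res.fun:
            res = res2
        if not res.success:
            raise RuntimeError(
                f"empirical-null optimisation did not converge: "
                f"{res.message} (x={res.x}, nll={res.fun:.6g})")
    mu, sigma = float(res.x[0]), float(max(res.x[1], 0.0))
    return NullDistribution(mu=mu, sigma=sigma, n_controls_used=len(b),
                            loglik=float(-np.atleast_1d(res.fun)[0]))


def _total_sd(se: float, null: NullDistribution) -> float:
    v = null.sigma ** 2 + se ** 2
    if v <= 0:
        raise ValueError("sigma^2 + se^2 must be positive")
    return math.sqrt(v)


def calibrate_p(log_hr: float, se: float, null: NullDistribution) -> float:
    """Calibrated two-sided p-value: 2*Phi(-|b - mu| / sqrt(sigma^2 + se^2))."""
    sd = _total_sd(se, null)
    return float(2.0 * stats.norm.sf(abs(log_hr - null.mu) / sd))


def calibrate_ci(log_hr: float, se: float, null: NullDistribution,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Calibrated (1 - alpha) CI on the HR scale."""
    sd = _total_sd(se, null)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    c = log_hr - null.mu
    return (float(np.exp(c - z * sd)), float(np.exp(c + z * sd)))


def calibrate(log_hr: float, se: float, null: NullDistribution,
              alpha: float = 0.05) -> CalibratedResult:
    c = log_hr - null.mu
    return CalibratedResult(log_hr=float(c), hr=float(np.exp(c)),
                            ci95=calibrate_ci(log_hr, se, null, alpha),
                            p=calibrate_p(log_hr, se, null))


def ease(null: NullDistribution) -> float:
    """Expected absolute systematic error: E|X|, X ~ Normal(mu, sigma^2).

    Folded-normal mean: mu*(1 - 2*Phi(-mu/sigma)) + sigma*sqrt(2/pi) *
    exp(-mu^2 / (2*sigma^2)); reduces to |mu| when sigma = 0. An EASE below
    0.25 is the conventional bar for limited systematic bias.
    """
    mu, sig = null.mu, null.sigma
    if sig * sig == 0.0:   # includes subnormal sigma whose square underflows
        return abs(mu)
    return float(mu * (1.0 - 2.0 * stats.norm.cdf(-mu / sig))
                 + sig * math.sqrt(2.0 / math.pi)
                 * math.exp(-mu ** 2 / (2.0 * sig ** 2)))


def calibrated_profile(profile: LikelihoodProfile,
                       null: NullDistribution,
                       n_nodes: int = 31) -> LikelihoodProfile:
    """Convolve a likelihood profile with the fitted null.

    The likelihood of the true effect theta after acknowledging systematic
    error b ~ Normal(mu, sigma^2) is integral L_data(theta + b) phi(b) db,
    computed by Gauss-Hermite quadrature on the profile grid. For a normal
    profile N(m, s^2) this reduces exactly to N(m - mu, s^2 + sigma^2), the
    same shift-and-widen as :func:`calibrate_ci`; for small-count profiles
    the non-normal shape is retained.
    """
    grid = profile.grid
    if null.sigma == 0.0:
        ll = profile.interp(grid + null.mu)
    else:
        x, w = np.polynomial.hermite.hermgauss(n_nodes)
        b = null.mu + math.sqrt(2.0) * null.sigma * x
        logw = np.log(w / math.sqrt(math.pi))
        vals = profile.interp(grid[:, None] + b[None, :]) + logw[None, :]
        with np.errstate(divide="ignore"):
            ll = np.logaddexp.reduce(vals, axis=1)
    mx = ll.max()
    if not np.isfinite(mx):
        raise ValueError("calibrated profile is degenerate (no support on grid)")
    normal = None
    if profile.normal is not None:
        m, s = profile.normal
        normal = (m - null.mu, math.hypot(s, null.sigma))
    return LikelihoodProfile(grid, ll - mx, normal=normal)
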