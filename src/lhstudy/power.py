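"""Analytic power for the repeated-measures between-factors design and for
correlation tests, plus Monte-Carlo cross-validation against the cohort
simulator.

The between-groups effect in a k-group design with m repeated measurements,
between-group effect size Cohen f, and compound-symmetric repeated-measures
correlation ρ is tested with F(k−1, N−k); under the alternative the statistic
is noncentral F with

    λ = f² · N · m / (1 + (m − 1) · ρ)

— the "repeated measures, between factors" convention of the standard a
priori power tools.  Averaging the m correlated measurements shrinks the
error variance by (1 + (m−1)ρ)/m relative to a single measurement, which is
exactly the denominator above.  Nonsphericity does not affect the between
effect (the test is on subject means), so ε enters only through the spec for
symmetry with within-subject designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "RMPowerSpec",
    "CorrPowerSpec",
    "PowerResult",
    "power_rm_between",
    "required_n_rm_between",
    "power_correlation",
    "required_n_correlation",
    "monte_carlo_power",
]


class PowerSpecError(ValueError):
    pass


@dataclass(frozen=True)
class RMPowerSpec:
    """Design parameters for the repeated-measures between-groups power."""

    k: int
    m: int
    f: float
    alpha: float = 0.05
    rho: float = 0.5
    epsilon: float = 1.0
    target_power: float = 0.95

    def __post_init__(self) -> None:
        if self.k < 2 or self.m < 1:
            raise PowerSpecError("need k >= 2 groups and m >= 1 measurements")
        if self.f < 0:
            raise PowerSpecError("f must be nonnegative")
        if not 0 < self.alpha < 1:
            raise PowerSpecError("alpha must lie in (0, 1)")
        if not 0 <= self.rho < 1:
            raise PowerSpecError("rho must lie in [0, 1)")


@dataclass(frozen=True)
class CorrPowerSpec:
    rho_alt: float
    alpha: float = 0.05
    tails: Literal["one", "two"] = "one"
    target_power: float = 0.95

    def __post_init__(self) -> None:
        if not abs(self.rho_alt) < 1:
            raise PowerSpecError("|rho_alt| must be < 1")
        if not 0 < self.alpha < 1:
            raise PowerSpecError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class PowerResult:
    achieved_power: float
    n_total: int
    ncp: float
    df: tuple[float, float]
    method: str = "noncentral_f"


def power_rm_between(spec: RMPowerSpec, n_total: int) -> PowerResult:
    """Power of the between-groups F test at total sample size ``n_total``."""
    if n_total < spec.k + 1:
        raise PowerSpecError("n_total must exceed the number of groups")
    lam = spec.f ** 2 * n_total * spec.m / (1.0 + (spec.m - 1) * spec.rho)
    df1, df2 = spec.k - 1, n_total - spec.k
    f_crit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    power = float(stats.ncf.sf(f_crit, df1, df2, lam)) if lam > 0 else spec.alpha
    return PowerResult(achieved_power=power, n_total=n_total, ncp=lam,
                       df=(df1, df2))


def required_n_rm_between(spec: RMPowerSpec, n_cap: int = 100_000) -> PowerResult:
    """Smallest N (a multiple of k, for equal groups) reaching target power."""
    if spec.f <= 0:
        raise PowerSpecError("required N is undefined at f = 0")
    n = spec.k * max(2, (spec.k + 1) // spec.k + 1)
    while n <= n_cap:
        res = power_rm_between(spec, n)
        if res.achieved_power >= spec.target_power:
            return res
        n += spec.k
    raise PowerSpecError(f"target power {spec.target_power} not reached below N={n_cap}")


def _r_critical(n: int, alpha: float, tails: str) -> float:
    a = alpha / 2 if tails == "two" else alpha
    t_crit = stats.t.ppf(1.0 - a, n - 2)
    return t_crit / math.sqrt(n - 2 + t_crit ** 2)


def _sample_r_pdf(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Exact density of the sample correlation under a bivariate normal."""
    r = np.asarray(r, dtype=float)
    log_c = (math.log(n - 2) + special.gammaln(n - 1)
             + 0.5 * (n - 1) * math.log1p(-rho ** 2)
             - 0.5 * math.log(2 * math.pi) - special.gammaln(n - 0.5))
    log_core = (0.5 * (n - 4) * np.log1p(-r ** 2)
                - (n - 1.5) * np.log1p(-rho * r))
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)
    return np.exp(log_c + log_core) * hyp


def power_correlation(spec: CorrPowerSpec, n: int,
                      method: Literal["exact", "fisher_z"] = "exact"
                      ) -> PowerResult:
    """Power of a correlation test under the bivariate-normal model.

    ``exact`` integrates the exact sampling density of r beyond the null
    critical value; ``fisher_z`` uses the variance-stabilizing normal
    approximation.  One-tailed tests assume the pre-registered direction
    matches the sign of ``rho_alt``.
    """
    if n < 4:
        raise PowerSpecError("need n >= 4")
    rho = abs(spec.rho_alt)  # orient toward the hypothesized direction
    if method == "fisher_z":
        a = spec.alpha / 2 if spec.tails == "two" else spec.alpha
        za = stats.norm.ppf(1.0 - a)
        se = 1.0 / math.sqrt(n - 3)
        power = float(stats.norm.sf(za - math.atanh(rho) / se))
        if spec.tails == "two":  # mass in the wrong tail, usually negligible
            power += float(stats.norm.cdf(-za - math.atanh(rho) / se))
        return PowerResult(achieved_power=power, n_total=n,
                           ncp=math.atanh(rho) * math.sqrt(n - 3),
                           df=(1, n - 2), method="fisher_z")
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    r_c = _r_critical(n, spec.alpha, spec.tails)
    upper, _ = integrate.quad(_sample_r_pdf, r_c, 1.0, args=(rho, n), limit=200)
    power = upper
    if spec.tails == "two":
        lower, _ = integrate.quad(_sample_r_pdf, -1.0, -r_c, args=(rho, n), limit=200)
        power += lower
    return PowerResult(achieved_power=float(power), n_total=n, ncp=rho,
                       df=(1, n - 2), method="exact")


def required_n_correlation(spec: CorrPowerSpec,
                           method: Literal["exact", "fisher_z"] = "fisher_z",
                           n_cap: int = 100_000) -> PowerResult:
    """Smallest n reaching target power for the correlation test."""
    if spec.rho_alt == 0:
        raise PowerSpecError("required n is undefined at rho = 0")
    n = 4
    while n <= n_cap:
        res = power_correlation(spec, n, method=method)
        if res.achieved_power >= spec.target_power:
            return res
        n += 1
    raise PowerSpecError(f"target power {spec.target_power} not reached below n={n_cap}")


def monte_carlo_power(config, analysis: str, reps: int, seed: int,
                      alpha: float = 0.05) -> dict:
    """Simulated rejection rate of a pre-registered test, with a 95% CI.

    ``analysis`` names the endpoint: ``"lh_latency"`` (between-groups effect
    on the 6 latency blocks) or ``"survey_group_time"`` (group x time
    interaction on the state-anhedonia score).  Cohorts are drawn from the
    cohort generative model via its vectorized block-score path.
    """
    from . import cohort as _cohort  # deferred to avoid an import cycle

    if reps < 100:
        raise ValueError("need reps >= 100 for a usable estimate")
    if analysis == "lh_latency":
        rejections = _cohort.simulate_latency_rejections(config, reps, seed, alpha)
    elif analysis == "survey_group_time":
        rejections = _cohort.simulate_survey_rejections(config, reps, seed, alpha)
    else:
        raise ValueError(f"unknown analysis endpoint {analysis!r}")
    k = int(np.sum(rejections))
    p_hat = k / reps
    half = 1.959963984540054 * math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / reps)
    return {
        "analysis": analysis,
        "reps": reps,
        "alpha": alpha,
        "power": p_hat,
        "ci95": (max(0.0, p_hat - half), min(1.0, p_hat + half)),
    }
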