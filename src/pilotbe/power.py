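"""Exact power and sample size for TOST in a 2x2x2 crossover.

On the log scale the estimated treatment difference d_hat is normal with
mean ln(GMR) and standard error se = sigma_w*sqrt(2/n), and the residual
variance estimate is an independent scaled chi-square with nu = n - 2
degrees of freedom.  Both one-sided t-tests reject simultaneously iff

    (d_hat - ln(L))/se_hat >  t(1-alpha, nu)   and
    (d_hat - ln(U))/se_hat < -t(1-alpha, nu),

whose probability is the bivariate noncentral-t (Owen's Q) expression.
Here it is evaluated exactly by integrating over the chi distribution of
se_hat/se:

    power = int_0^R [Phi(-t_a*x/sqrt(nu) - d2) - Phi(t_a*x/sqrt(nu) - d1)]
            f_chi_nu(x) dx,

with d1 = (ln GMR - ln L)/se, d2 = (ln GMR - ln U)/se and the upper limit
R = sqrt(nu)*(d1 - d2)/(2*t_a) beyond which the two rejection regions are
incompatible.  A noncentral-t difference approximation is available as a
cross-validated fallback.

The intra-subject CV% maps to the log-scale SD by the exact relation
sigma_w = sqrt(ln(1 + (CV/100)^2)), the inverse of ISCV% = 100*
sqrt(exp(s^2) - 1), so that sizing from an estimated ISCV round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

__all__ = ["TOSTSpec", "cv_to_sigma_w", "tost_power", "tost_sample_size"]


def cv_to_sigma_w(cv_percent: float) -> float:
    """Intra-subject CV% -> within-subject log-scale SD."""
    if cv_percent < 0:
        raise ValueError("cv must be >= 0")
    return float(np.sqrt(np.log1p((cv_percent / 100.0) ** 2)))


@dataclass(frozen=True)
class TOSTSpec:
    """Design assumptions for TOST power/sizing.

    cv is the intra-subject CV in %, gmr the assumed true test/reference
    ratio, alpha the one-sided significance level, and limits the
    bioequivalence acceptance range on the ratio scale.
    """

    cv: float
    gmr: float = 1.0
    alpha: float = 0.05
    target_power: float = 0.80
    limits: tuple[float, float] = (0.80, 1.25)

    def __post_init__(self) -> None:
        if self.gmr <= 0:
            raise ValueError("gmr must be > 0")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        lo, hi = self.limits
        if not lo < 1.0 < hi:
            raise ValueError("limits must straddle 1")


def _chi_logpdf_const(nu: float) -> float:
    # log of 1/(2^(nu/2-1) * Gamma(nu/2))
    return -special.gammaln(nu / 2.0) - (nu / 2.0 - 1.0) * np.log(2.0)


def _power_exact(d1: float, d2: float, t_a: float, nu: int) -> float:
    r = np.sqrt(nu) * (d1 - d2) / (2.0 * t_a)
    if r <= 0:
        return 0.0
    # the chi density carries no mass beyond this; keeps quad on target when r is huge
    r = min(r, float(np.sqrt(stats.chi2.ppf(1.0 - 1e-14, nu))))
    lc = _chi_logpdf_const(nu)

    def integrand(x: float) -> float:
        upper = stats.norm.cdf(-t_a * x / np.sqrt(nu) - d2)
        lower = stats.norm.cdf(t_a * x / np.sqrt(nu) - d1)
        dens = np.exp(lc + (nu - 1.0) * np.log(x) - x * x / 2.0) if x > 0 else 0.0
        return (upper - lower) * dens

    val, _ = integrate.quad(integrand, 0.0, r, limit=200)
    return float(min(max(val, 0.0), 1.0))


def _power_nct(d1: float, d2: float, t_a: float, nu: int) -> float:
    # difference of two noncentral-t tails; slightly liberal at small nu
    p = stats.nct.cdf(-t_a, nu, d2) - stats.nct.cdf(t_a, nu, d1)
    return float(min(max(p, 0.0), 1.0))


def tost_power(spec: TOSTSpec, n: int, method: str = "exact") -> float:
    """Probability that both one-sided tests reject for a total of n subjects."""
    if n < 3:
        raise ValueError("n must leave at least 1 residual df (n >= 3)")
    nu = n - 2
    sigma_w = cv_to_sigma_w(spec.cv)
    if sigma_w == 0.0:
        lo, hi = np.log(spec.limits[0]), np.log(spec.limits[1])
        return 1.0 if lo < np.log(spec.gmr) < hi else 0.0
    se = sigma_w * np.sqrt(2.0 / n)
    d1 = (np.log(spec.gmr) - np.log(spec.limits[0])) / se
    d2 = (np.log(spec.gmr) - np.log(spec.limits[1])) / se
    t_a = stats.t.ppf(1.0 - spec.alpha, nu)
    if method == "exact":
        return _power_exact(d1, d2, t_a, nu)
    if method == "nct":
        return _power_nct(d1, d2, t_a, nu)
    raise ValueError("method must be 'exact' or 'nct'")


def tost_sample_size(spec: TOSTSpec, n_max: int = 10_000) -> int:
    """Smallest even total n >= 4 achieving the target power.

    Searches by doubling to bracket the target, then bisects over even n.
    Raises when the assumed GMR lies on or outside the acceptance limits
    (power can never reach any positive target there).
    """
    lo_lim, hi_lim = spec.limits
    if not lo_lim < spec.gmr < hi_lim:
        raise ValueError("assumed GMR outside the acceptance limits; power unattainable")
    n = 4
    while tost_power(spec, n) < spec.target_power:
        if n >= n_max:
            raise ValueError(f"target power not reached by n = {n_max}")
        n *= 2
    if n == 4:
        return 4
    lo, hi = n // 2, n  # power(lo) < target <= power(hi)
    while hi - lo > 2:
        mid = (lo + hi) // 2
        mid += mid % 2
        if mid == hi:
            mid -= 2
        if tost_power(spec, mid) >= spec.target_power:
            hi = mid
        else:
            lo = mid
    return hi
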