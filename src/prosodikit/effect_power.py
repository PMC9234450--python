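"""Effect-size conversions and noncentral-F sensitivity power analysis.

Conversions::

    η²  = f² / (1 + f²)          f  = sqrt(η² / (1 − η²))
    ηp² = F·df1 / (F·df1 + df2)
    r   = sqrt(F / (F + df2))     (df1 = 1 designs only)

Power for the within-between interaction of a k-group × m-measurement
repeated-measures design uses the noncentral F distribution with

    df1 = (k−1)(m−1),  df2 = (N−k)(m−1),  λ = f²·N·m·ε/(1−ρ)

where ρ is the mean correlation among the repeated measures and ε the
nonsphericity correction (fixed at 1 here). That λ is the G*Power
"as in G*Power 3" effect-size convention; the "as in SPSS" convention
(λ = f²·N·ε, with the m/(1−ρ) factor folded into f) is available via
``convention="spss"``. A sensitivity analysis inverts the power function
for the minimal detectable f at a target power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import optimize, stats

from .errors import DomainError


@dataclass(frozen=True)
class PowerSpec:
    """Design and error-rate parameters of the interaction power analysis."""

    N: int
    k: int = 2
    m: int = 2
    rho: float = 0.5
    alpha: float = 0.05
    power: float = 0.80
    epsilon: float = 1.0
    f: float | None = None
    convention: str = "gpower"  # or "spss"

    def __post_init__(self) -> None:
        if self.N <= self.k:
            raise DomainError("N must exceed the number of groups k")
        if self.m < 2:
            raise DomainError("need m >= 2 repeated measurements")
        if not (-1.0 < self.rho < 1.0):
            raise DomainError("rho must lie in (-1, 1)")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise DomainError("alpha and power must lie in (0, 1)")
        if self.convention not in ("gpower", "spss"):
            raise DomainError("convention must be 'gpower' or 'spss'")

    @property
    def df1(self) -> int:
        return (self.k - 1) * (self.m - 1)

    @property
    def df2(self) -> int:
        return (self.N - self.k) * (self.m - 1)


def eta2_from_f(f: float) -> float:
    """Cohen's f → η²."""
    if f < 0:
        raise DomainError("f must be nonnegative")
    return f * f / (1.0 + f * f)


def f_from_eta2(eta2: float) -> float:
    """η² → Cohen's f (η² must be < 1)."""
    if not (0.0 <= eta2 < 1.0):
        raise DomainError("eta2 must lie in [0, 1)")
    return math.sqrt(eta2 / (1.0 - eta2))


def partial_eta_sq_from_F(F: float, df1: int, df2: int) -> float:
    """Partial η² recovered from an F ratio and its degrees of freedom."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise DomainError("need F >= 0 and dfs >= 1")
    return F * df1 / (F * df1 + df2)


def r_from_F(F: float, df2: int) -> float:
    """Correlation effect size from a single-df F (df1 = 1 designs only)."""
    if F < 0:
        raise DomainError("F must be nonnegative")
    return math.sqrt(F / (F + df2))


def noncentrality(spec: PowerSpec) -> float:
    if spec.f is None:
        raise DomainError("spec.f must be set")
    if spec.convention == "gpower":
        return spec.f**2 * spec.N * spec.m * spec.epsilon / (1.0 - spec.rho)
    return spec.f**2 * spec.N * spec.epsilon


def rm_interaction_power(spec: PowerSpec) -> float:
    """Power of the group × measurement interaction test at ``spec.f``."""
    lam = noncentrality(spec)
    f_crit = stats.f.isf(spec.alpha, spec.df1, spec.df2)
    if lam == 0.0:
        return spec.alpha
    return float(stats.ncf.sf(f_crit, spec.df1, spec.df2, lam))


def sensitivity_f(spec: PowerSpec) -> float:
    """Minimal detectable Cohen's f at the spec's target power.

    Solves rm_interaction_power(f) = power by bisection; the power
    function is strictly increasing in f, so the root is unique.
    """
    def gap(f: float) -> float:
        return rm_interaction_power(replace(spec, f=f)) - spec.power

    lo, hi = 1e-12, 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise DomainError("could not bracket the sensitivity solution")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-12, rtol=1e-14))


def required_n(spec: PowerSpec) -> int:
    """Smallest total N reaching the target power at ``spec.f``."""
    if spec.f is None or spec.f <= 0:
        raise DomainError("spec.f must be positive")
    n = spec.k + 1
    while n < 10**7:
        if rm_interaction_power(replace(spec, N=n)) >= spec.power:
            return n
        n += 1
    raise DomainError("required N exceeds search bound")
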