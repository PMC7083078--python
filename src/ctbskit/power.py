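"""Two-sample t-test power and sample-size computation.

Exact noncentral-t computation (the algorithm class used by dedicated power
calculators such as G*Power): for a two-tailed independent-samples t-test at
significance level α with group sizes n1, n2 and standardized effect size d
(Cohen's d, pooled-SD units), the achieved power is

    power = P(|T'| > t_crit),    T' ~ noncentral t(df = n1 + n2 − 2,
                                                   δ = d·√(n1·n2/(n1+n2)))

with t_crit the central-t two-tailed critical value. The sample-size solver
returns the smallest equal-group n reaching a target power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class PowerError(ValueError):
    """Invalid power-analysis specification."""


@dataclass(frozen=True)
class PowerSpec:
    """Specification of a two-sample t-test power problem."""

    d: float
    n1: int
    n2: int
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self):
        if self.d < 0:
            raise PowerError("effect size d must be >= 0")
        if not 0 < self.alpha < 1:
            raise PowerError("alpha must lie in (0, 1)")
        if self.n1 < 2 or self.n2 < 2:
            raise PowerError("group sizes must be >= 2")
        if not 0 < self.target_power < 1:
            raise PowerError("target power must lie in (0, 1)")


def power_two_sample_t(
    d: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Power of a two-tailed independent-samples t-test (exact noncentral t)."""
    spec = PowerSpec(d=d, n1=n1, n2=n2, alpha=alpha)
    df = spec.n1 + spec.n2 - 2
    delta = spec.d * np.sqrt(spec.n1 * spec.n2 / (spec.n1 + spec.n2))
    t_crit = stats.t.ppf(1 - spec.alpha / 2, df)
    return float(
        stats.nct.sf(t_crit, df, delta) + stats.nct.cdf(-t_crit, df, delta)
    )


def required_n_per_group(
    d: float, target_power: float = 0.80, alpha: float = 0.05, n_max: int = 100_000
) -> int:
    """Smallest equal-group size n with power(d, n, n, alpha) >= target_power.

    Starts from the large-sample normal approximation
    n ≈ 2 (z_{1−α/2} + z_{power})² / d² and walks to the exact minimal n.
    """
    if d <= 0:
        raise PowerError("sample-size solving requires d > 0")
    if not 0 < target_power < 1:
        raise PowerError("target power must lie in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(target_power)
    n = max(2, int(np.floor(2 * (z_a + z_b) ** 2 / d**2)) - 2)
    while n <= n_max and power_two_sample_t(d, n, n, alpha) < target_power:
        n += 1
    if n > n_max:
        raise PowerError(f"no n <= {n_max} reaches the target power")
    # walk down in case the approximation overshot the minimal n
    while n > 2 and power_two_sample_t(d, n - 1, n - 1, alpha) >= target_power:
        n -= 1
    return n
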