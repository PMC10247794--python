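"""Two-sample t-test power and minimal sample size.

Power of the two-sided two-sample t-test with equal group sizes n, pooled
standard deviation sd and true mean difference delta, computed from the
noncentral-t distribution with df = 2n - 2 and noncentrality
delta / (sd * sqrt(2/n)).  A normal-approximation closed form,
n = 2 * (z_{1-a/2} + z_{power})^2 * (sd/delta)^2, is exposed alongside for
cross-checking; the noncentral-t solver is the primary (the approximation
undershoots by a couple of subjects at moderate n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a two-sided two-sample t-test."""

    sd_pooled: float
    delta: float
    alpha: float = 0.05
    power_target: float = 0.8

    def __post_init__(self):
        if self.sd_pooled <= 0 or self.delta <= 0:
            raise ValueError("sd_pooled and delta must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power_target < 1:
            raise ValueError("alpha and power_target must be in (0, 1)")


def power_at_n(spec: PowerSpec, n_per_group: int) -> float:
    """Power of the test at ``n_per_group`` subjects per group."""
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    df = 2 * n_per_group - 2
    nc = spec.delta / (spec.sd_pooled * np.sqrt(2.0 / n_per_group))
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def n_per_group(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest per-group n with ``power_at_n(spec, n) >= power_target``.

    Doubles n until the target is reached, then bisects; minimality is
    guaranteed because power is increasing in n.
    """
    lo, hi = 2, 2
    while power_at_n(spec, hi) < spec.power_target:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError("sample size exceeds n_max")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at_n(spec, mid) >= spec.power_target:
            hi = mid
        else:
            lo = mid + 1
    return hi


def n_normal_approx(spec: PowerSpec) -> int:
    """Normal-approximation sample size (rounded up)."""
    za = stats.norm.ppf(1 - spec.alpha / 2)
    zb = stats.norm.ppf(spec.power_target)
    return int(np.ceil(2.0 * (za + zb) ** 2 * (spec.sd_pooled / spec.delta) ** 2))
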