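"""A-priori power analysis for the within-subject contrast.

Power of a two-sided paired (equivalently one-sample) t-test computed from
the noncentral-t distribution with df = n - 1 and noncentrality dz * sqrt(n),
and the smallest sample size reaching a target power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerSpec", "achieved_power", "required_sample_size"]


@dataclass(frozen=True)
class PowerSpec:
    """Effect size (Cohen's dz), two-sided alpha, and target power."""

    effect_size: float
    alpha: float = 0.05
    power: float = 0.8
    test: str = "paired"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("target power must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.test not in ("paired", "one-sample"):
            raise ValueError("test must be 'paired' or 'one-sample'")


def achieved_power(n: int, spec: PowerSpec) -> float:
    """Two-sided noncentral-t power at sample size ``n`` (n >= 2)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    nc = spec.effect_size * np.sqrt(n)
    t_crit = stats.t.isf(spec.alpha / 2.0, df)
    upper = stats.nct.sf(t_crit, df, nc)
    lower = stats.nct.cdf(-t_crit, df, nc)
    # scipy's nct underflows to NaN in the far tail; that tail is ~0
    if not np.isfinite(upper):
        upper = 0.0
    if not np.isfinite(lower):
        lower = 0.0
    return float(upper + lower)


def required_sample_size(spec: PowerSpec, max_n: int = 100_000) -> int:
    """Smallest n >= 2 whose power reaches the target."""
    if spec.effect_size == 0:
        raise ValueError("target power unattainable at zero effect size")
    for n in range(2, max_n + 1):
        if achieved_power(n, spec) >= spec.power:
            return n
    raise ValueError(f"target power not attainable with n <= {max_n}")
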