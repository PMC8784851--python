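"""Binary-outcome power for summary-statistic MR (mRnd-style approximation).

Forward: power = Φ( sqrt(N·R²·K·(1−K)) · |log OR| − z_{1−α/2} ).
Inverse: smallest detectable OR at a target power, by closed-form inversion
log OR = (z_{1−α/2} + z_{power}) / sqrt(N·R²·K·(1−K)). The round trip is
exact to floating-point precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as sps

__all__ = ["PowerQuery", "mr_power_binary", "detectable_or"]


@dataclass
class PowerQuery:
    """Inputs for the binary-outcome power approximation.

    n_total: outcome-study sample size; k: case fraction in (0, 1);
    r2: variance in exposure explained by the instruments, in (0, 1);
    or_: hypothesized odds ratio (> 0, forward mode);
    alpha: significance level; target_power: in (0, 1), inverse mode;
    one_sided: use z_{1−α} instead of z_{1−α/2}.
    """

    n_total: float
    k: float
    r2: float
    or_: float = 1.0
    alpha: float = 0.05
    target_power: float = 0.8
    one_sided: bool = False

    def validate(self, need_or: bool = True) -> None:
        if self.n_total <= 0:
            raise ValueError(f"n_total must be > 0, got {self.n_total}")
        for name in ("k", "r2", "alpha", "target_power"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly inside (0, 1), got {v}")
        if need_or and not self.or_ > 0:
            raise ValueError(f"or_ must be > 0, got {self.or_}")

    @property
    def z_alpha(self) -> float:
        q = 1.0 - self.alpha if self.one_sided else 1.0 - self.alpha / 2.0
        return float(sps.norm.ppf(q))

    @property
    def ncp_scale(self) -> float:
        """sqrt(N · R² · K · (1 − K)): non-centrality per unit log-OR."""
        return math.sqrt(self.n_total * self.r2 * self.k * (1.0 - self.k))


def mr_power_binary(q: PowerQuery) -> float:
    """Power to detect ``q.or_`` at significance ``q.alpha``."""
    q.validate(need_or=True)
    return float(sps.norm.cdf(q.ncp_scale * abs(math.log(q.or_)) - q.z_alpha))


def detectable_or(q: PowerQuery) -> float:
    """Smallest OR above 1 detectable with power ``q.target_power``."""
    q.validate(need_or=False)
    z_pow = float(sps.norm.ppf(q.target_power))
    log_or = (q.z_alpha + z_pow) / q.ncp_scale
    return math.exp(log_or)
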