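"""Closed-form power for two-sample MR with a binary (case-control) outcome.

The IVW/likelihood causal test behaves asymptotically like a normal z-test
whose non-centrality grows with the instrument strength.  For a case-control
study of N = n_cases + n_controls with case fraction K, an instrument
explaining a fraction R^2 of the exposure variance, and a true odds ratio
``OR`` per SD of exposure, the non-centrality is

    z = sqrt(N * R^2 * K * (1 - K)) * |ln OR|

and the two-sided power at level alpha is

    power = Phi(z - z_{1-alpha/2}) + Phi(-z - z_{1-alpha/2}).

The second (opposite-tail) term is negligible away from OR = 1 but makes
power(OR = 1) equal alpha exactly and preserves the log-scale symmetry
power(OR) = power(1/OR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["PowerQuery", "mr_power_binary", "min_detectable_or"]


@dataclass(frozen=True)
class PowerQuery:
    """Inputs for a binary-outcome MR power calculation.

    r2 is the fraction of exposure variance explained by the instrument set
    (e.g. 0.027 for a BMI-scale instrument); or_per_sd is the hypothesized
    odds ratio per SD of the exposure.
    """

    n_cases: int
    n_controls: int
    r2: float
    or_per_sd: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if not (0 < self.r2 < 1):
            raise ValueError("r2 must lie in (0, 1)")
        if not self.or_per_sd > 0:
            raise ValueError("or_per_sd must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def mr_power_binary(q: PowerQuery) -> float:
    """Two-sided power of the MR causal test under the normal approximation."""
    n_total = q.n_cases + q.n_controls
    k = q.n_cases / n_total
    z = np.sqrt(n_total * q.r2 * k * (1 - k)) * abs(np.log(q.or_per_sd))
    z_crit = stats.norm.ppf(1 - q.alpha / 2)
    return float(stats.norm.cdf(z - z_crit) + stats.norm.cdf(-z - z_crit))


def min_detectable_or(n_cases: int, n_controls: int, r2: float, alpha: float = 0.05,
                      target_power: float = 0.8) -> float:
    """Smallest odds ratio above 1 detectable at the target power.

    Solved by bisection over OR in (1, 10]; power is strictly increasing in
    OR on that bracket, so the root is unique when it exists.
    """
    if not (0 < target_power < 1):
        raise ValueError("target_power must lie in (0, 1)")
    power_at = lambda or_: mr_power_binary(
        PowerQuery(n_cases, n_controls, r2, or_, alpha)) - target_power
    lo, hi = 1.0 + 1e-12, 10.0
    if power_at(hi) < 0:
        raise ValueError("target power unreachable for OR <= 10 with these inputs")
    if power_at(lo) > 0:
        raise ValueError("target power already exceeded at OR -> 1 (alpha >= target?)")
    return float(optimize.brentq(power_at, lo, hi, xtol=1e-10))
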