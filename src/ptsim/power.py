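"""Closed-form two-proportion sample-size and power approximations.

Normal-approximation formulas for the two-sided Pearson chi-squared
comparison of two binomial proportions, without continuity correction.
With mortality rates 5% (drug) vs 10% (placebo), 80% power and a
two-sided 5% level at 1:1 allocation, the required size is 435 patients
per group — the per-arm cap used throughout the simulator.  These
formulas also serve as analytic cross-checks of the simulated rejection
rates.
"""

from __future__ import annotations

import math

from scipy.stats import norm

__all__ = ["required_n_per_group", "approx_power"]


def required_n_per_group(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    ratio: float = 1.0,
) -> int:
    """Smallest group-1 size n for the two-proportion chi-squared test.

    ``ratio`` is n2/n1 (the comparison group has ``ratio * n`` patients).
    Uses the standard pooled-variance normal approximation

        n = (z_{a/2} sqrt((1 + 1/r) pq) + z_b sqrt(p1 q1 + p2 q2 / r))^2
            / (p1 - p2)^2

    with p pooled as (p1 + r p2)/(1 + r), rounded up.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if p1 == p2:
        raise ValueError("no finite sample size when the rates are equal")
    if ratio <= 0:
        raise ValueError("allocation ratio must be positive")
    z_a = norm.ppf(1 - alpha / 2)
    z_b = norm.ppf(power)
    p_bar = (p1 + ratio * p2) / (1 + ratio)
    q_bar = 1 - p_bar
    num = (
        z_a * math.sqrt((1 + 1 / ratio) * p_bar * q_bar)
        + z_b * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2) / ratio)
    ) ** 2
    n = num / (p1 - p2) ** 2
    return math.ceil(n - 1e-9)


def approx_power(
    p1: float, p2: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Normal-approximation power of the two-sided chi-squared test of
    H0: p1 = p2 with group sizes n1, n2.

    Power = Phi((|p1 - p2| - z_{a/2} SE0) / SE1)
          + Phi((-|p1 - p2| - z_{a/2} SE0) / SE1),

    with SE0 from the pooled rate and SE1 from the unpooled rates;
    rejections in either direction are counted, so at p1 = p2 the power
    equals the test size (approximately alpha).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be at least 1")
    z_a = norm.ppf(1 - alpha / 2)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    se0 = math.sqrt(p_bar * (1 - p_bar) * (1 / n1 + 1 / n2))
    se1 = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    delta = abs(p1 - p2)
    if se1 == 0:
        return 1.0 if delta > z_a * se0 else 0.0
    return float(
        norm.cdf((delta - z_a * se0) / se1) + norm.cdf((-delta - z_a * se0) / se1)
    )
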