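"""Power-gain-per-placebo-patient regression.

Across a grid of (scenario, placebo rate, accrual mean) cells, the
dynamic-k platform design enrolls more placebo patients than its
equal-allocation counterpart and gains group-specific power.  This
module condenses that trade-off into a single number: the OLS slope of
the average power difference (unequal minus equal, in percentage
points) on the placebo-size difference, expressed per 100 additional
placebo patients, with a 95% confidence interval.

Cells with placebo mortality at or below 5% are excluded by default:
there both designs sit at 100% power and contribute no information
about the exchange rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .oc import OCSummary, compare_designs

__all__ = ["SlopePoint", "SlopeFit", "build_points", "fit_slope"]


@dataclass(frozen=True)
class SlopePoint:
    """One grid cell's paired difference: extra placebo patients vs the
    average power gained (percentage points).  ``delta_power_se`` is the
    Monte Carlo standard error of the power difference (percentage
    points), when known."""

    delta_placebo: float
    delta_power_pp: float
    scenario_index: int
    rp: float
    accrual_mean: float
    delta_power_se: float | None = None


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of power gain on placebo-size gain."""

    slope_per_100: float  # percentage points per 100 placebo patients
    ci95: tuple[float, float]
    intercept: float
    n_points: int
    stderr: float

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.slope_per_100 <= hi:
            raise ValueError("confidence interval must contain the estimate")


def build_points(
    pairs: list[tuple[OCSummary, OCSummary]],
    max_excluded_rp: float = 0.05,
    basis: str = "total",
) -> list[SlopePoint]:
    """Turn paired (unequal, equal) cell summaries into regression points.

    Each pair must have been simulated under the same scenario and
    settings.  Cells whose placebo rate is at or below
    ``max_excluded_rp`` (default 5%, where power saturates) and cells
    with no effective drug (the global null) are dropped.

    ``basis`` selects the placebo-size difference on the x-axis:
    ``"total"`` (default) uses the trial's total placebo enrollment;
    ``"concurrent"`` uses the mean per-drug concurrent-control size —
    the number of controls each comparison actually gains, the quantity
    on which power directly depends.
    """
    if basis not in ("concurrent", "total"):
        raise ValueError("basis must be 'concurrent' or 'total'")
    points = []
    for oc_unequal, oc_equal in pairs:
        cmp_ = compare_designs(oc_unequal, oc_equal)
        if cmp_.delta_avg_power is None:  # global null: no power to compare
            continue
        if cmp_.rp <= max_excluded_rp + 1e-12:
            continue
        if basis == "concurrent":
            delta = float(
                np.mean(oc_unequal.mean_concurrent) - np.mean(oc_equal.mean_concurrent)
            )
        else:
            delta = cmp_.delta_total_placebo
        # conservative MC SE of the power difference: per-drug SEs are
        # averaged without the 1/sqrt(m) reduction, since power estimates
        # of drugs sharing one control group are positively correlated
        se = 100.0 * float(
            np.hypot(
                np.mean([s for s, e in zip(oc_unequal.reject_se, oc_unequal.effective) if e]),
                np.mean([s for s, e in zip(oc_equal.reject_se, oc_equal.effective) if e]),
            )
        )
        points.append(
            SlopePoint(
                delta_placebo=delta,
                delta_power_pp=100.0 * cmp_.delta_avg_power,
                scenario_index=cmp_.scenario_index,
                rp=cmp_.rp,
                accrual_mean=cmp_.accrual_mean,
                delta_power_se=se,
            )
        )
    return points


def slope_mc_se(points: list[SlopePoint], through_origin: bool = False) -> float:
    """Monte Carlo standard error of the fitted slope, propagated from
    the per-point power-difference SEs through the OLS weights (the
    regressors are simulated size differences with negligible noise)."""
    x = np.array([p.delta_placebo for p in points]) / 100.0
    sig = np.array([p.delta_power_se for p in points], dtype=float)
    if np.isnan(sig).any():
        raise ValueError("points lack Monte Carlo standard errors")
    if through_origin:
        w = x / (x**2).sum()
    else:
        xc = x - x.mean()
        w = xc / (xc**2).sum()
    return float(np.sqrt(((w * sig) ** 2).sum()))


def fit_slope(points: list[SlopePoint], through_origin: bool = False) -> SlopeFit:
    """OLS of power difference (percentage points) on placebo-size
    difference / 100, with intercept (default) and 95% CI."""
    if len(points) < 3:
        raise ValueError("at least 3 points are required")
    x = np.array([p.delta_placebo for p in points]) / 100.0
    y = np.array([p.delta_power_pp for p in points])
    if np.ptp(x) == 0:
        raise ValueError("placebo-size differences are constant; slope undefined")
    design = x[:, None] if through_origin else sm.add_constant(x)
    res = sm.OLS(y, design).fit()
    k = 0 if through_origin else 1  # index of the slope coefficient
    ci = res.conf_int(alpha=0.05)
    return SlopeFit(
        slope_per_100=float(res.params[k]),
        ci95=(float(ci[k, 0]), float(ci[k, 1])),
        intercept=0.0 if through_origin else float(res.params[0]),
        n_points=len(points),
        stderr=float(res.bse[k]),
    )
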