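"""Replicate loop and operating-characteristic summaries.

Aggregates per-replicate efficacy decisions into the study's performance
indices: per-drug rejection proportions (type I error for ineffective
arms, group-specific power for effective arms), overall power (at least
one effective drug correctly declared efficacious), placebo sample-size
statistics, and the Monte Carlo standard error of every proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accrual import simulate_enrollment
from .design import DesignKind, DesignSpec, EntryKind, ScenarioSpec, SimSettings
from .outcomes import (
    DrugDecision,
    assign_outcomes,
    drug_table,
    needs_fisher,
    pearson_chi2_pvalues,
)

__all__ = ["OCSummary", "DesignComparison", "mc_se", "simulate_oc",
           "summarize", "compare_designs"]


def mc_se(p_hat: float | np.ndarray, n_reps: int) -> float | np.ndarray:
    """Monte Carlo standard error sqrt(p(1-p)/n) of a simulated
    proportion."""
    return np.sqrt(np.asarray(p_hat) * (1.0 - np.asarray(p_hat)) / n_reps)


@dataclass(frozen=True)
class OCSummary:
    """Aggregated operating characteristics of one (design, scenario,
    settings) cell."""

    design_label: str
    n_drugs: int
    scenario_index: int
    rp: float
    rd: float
    effective: tuple[bool, ...]
    accrual_mean: float
    alpha: float
    n_reps: int
    drug_ids: tuple[str, ...]
    reject_prop: tuple[float, ...]  # per drug
    reject_se: tuple[float, ...]
    mean_concurrent: tuple[float, ...]  # per-drug concurrent-control size
    mean_total_placebo: float
    mean_duration_months: float
    overall_power: float | None  # None when no drug is effective
    overall_power_se: float | None
    n_invalid: int = 0  # replicates x drugs with an empty comparison group

    @property
    def power_by_drug(self) -> dict[str, float]:
        """Group-specific power: rejection proportion of effective arms."""
        return {
            d: p
            for d, p, e in zip(self.drug_ids, self.reject_prop, self.effective)
            if e
        }

    @property
    def type_i_by_drug(self) -> dict[str, float]:
        """Type I error: rejection proportion of ineffective arms."""
        return {
            d: p
            for d, p, e in zip(self.drug_ids, self.reject_prop, self.effective)
            if not e
        }

    @property
    def avg_power(self) -> float | None:
        vals = list(self.power_by_drug.values())
        return float(np.mean(vals)) if vals else None

    @property
    def avg_type_i(self) -> float | None:
        vals = list(self.type_i_by_drug.values())
        return float(np.mean(vals)) if vals else None

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (metric, drug)."""
        base = {
            "design": self.design_label,
            "n_drugs": self.n_drugs,
            "scenario": self.scenario_index,
            "rp": self.rp,
            "rd": self.rd,
            "accrual_mean": self.accrual_mean,
            "n_reps": self.n_reps,
        }
        rows = []
        for d, p, se, cc, eff in zip(
            self.drug_ids,
            self.reject_prop,
            self.reject_se,
            self.mean_concurrent,
            self.effective,
        ):
            metric = "power" if eff else "type_i_error"
            rows.append({**base, "metric": metric, "drug": d, "estimate": p,
                         "mc_se": se})
            rows.append({**base, "metric": "mean_concurrent_control", "drug": d,
                         "estimate": cc, "mc_se": np.nan})
        if self.overall_power is not None:
            rows.append({**base, "metric": "overall_power", "drug": "",
                         "estimate": self.overall_power,
                         "mc_se": self.overall_power_se})
        rows.append({**base, "metric": "mean_total_placebo", "drug": "",
                     "estimate": self.mean_total_placebo, "mc_se": np.nan})
        rows.append({**base, "metric": "mean_duration_months", "drug": "",
                     "estimate": self.mean_duration_months, "mc_se": np.nan})
        return pd.DataFrame(rows)


def _aggregate(
    design: DesignSpec,
    scenario: ScenarioSpec,
    settings: SimSettings,
    rejected: np.ndarray,  # (reps, drugs) float with NaN for invalid
    n_cc: np.ndarray,  # (reps, drugs)
    total_placebo: np.ndarray,  # (reps,)
    duration: np.ndarray,  # (reps,)
) -> OCSummary:
    n_reps = rejected.shape[0]
    valid = ~np.isnan(rejected)
    n_invalid = int((~valid).sum())
    with np.errstate(invalid="ignore"):
        prop = np.nanmean(rejected, axis=0)
    prop_se = mc_se(prop, valid.sum(axis=0))
    eff = np.asarray(scenario.effective)
    if eff.any():
        any_eff = np.nansum(np.where(valid, rejected, 0.0)[:, eff], axis=1) > 0
        overall = float(any_eff.mean())
        overall_se = float(mc_se(overall, n_reps))
    else:
        overall = overall_se = None
    return OCSummary(
        design_label=design.label,
        n_drugs=design.n_drugs,
        scenario_index=scenario.index,
        rp=scenario.rp,
        rd=scenario.rd,
        effective=scenario.effective,
        accrual_mean=settings.accrual_mean,
        alpha=settings.alpha,
        n_reps=n_reps,
        drug_ids=design.drug_ids,
        reject_prop=tuple(float(p) for p in prop),
        reject_se=tuple(float(s) for s in prop_se),
        mean_concurrent=tuple(float(c) for c in n_cc.mean(axis=0)),
        mean_total_placebo=float(total_placebo.mean()),
        mean_duration_months=float(duration.mean()),
        overall_power=overall,
        overall_power_se=overall_se,
        n_invalid=n_invalid,
    )


def simulate_oc(
    design: DesignSpec,
    scenario: ScenarioSpec,
    settings: SimSettings,
    rng: np.random.Generator | None = None,
    exact_simultaneous: bool = True,
) -> OCSummary:
    """Run ``settings.n_reps`` replicates of (enroll, assign outcomes,
    analyze) and summarize.

    Replicates are streamed: only the per-drug 2x2 counts and placebo
    statistics are retained.  The chi-squared p-values are evaluated in
    one vectorized pass at the end; the rare tables triggering the
    Fisher fallback are tested individually.

    For simultaneous designs (stand-alone set and MATs) the group sizes
    and concurrency are deterministic — every arm reaches its planned
    cap and the whole placebo group is concurrent with every drug — so
    by default the month-by-month enrollment loop is skipped and the
    death counts are drawn directly on the fixed group sizes, which is
    distributionally identical (``exact_simultaneous=False`` forces the
    full enrollment simulation instead).
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    if exact_simultaneous and design.entry.kind is EntryKind.SIMULTANEOUS:
        return _simulate_oc_simultaneous(design, scenario, settings, rng)
    n_reps, m = settings.n_reps, design.n_drugs
    a = np.zeros((n_reps, m), dtype=np.int64)  # deaths, drug
    b = np.zeros((n_reps, m), dtype=np.int64)  # survivors, drug
    c = np.zeros((n_reps, m), dtype=np.int64)  # deaths, control
    d = np.zeros((n_reps, m), dtype=np.int64)  # survivors, control
    n_cc = np.zeros((n_reps, m), dtype=np.int64)
    total_placebo = np.zeros(n_reps, dtype=np.int64)
    duration = np.zeros(n_reps, dtype=np.int64)

    for r in range(n_reps):
        ledger = simulate_enrollment(design, settings, rng)
        assign_outcomes(ledger, scenario, rng)
        total_placebo[r] = ledger.total_placebo()
        duration[r] = ledger.months_elapsed
        for j, drug in enumerate(design.drug_ids):
            t = drug_table(ledger, drug)
            a[r, j], b[r, j] = t.deaths_drug, t.survivors_drug
            c[r, j], d[r, j] = t.deaths_control, t.survivors_control
            n_cc[r, j] = t.n_control

    p = pearson_chi2_pvalues(a, b, c, d)
    fisher_mask = needs_fisher(a, b, c, d)
    for r, j in zip(*np.nonzero(fisher_mask)):
        from scipy.stats import fisher_exact

        p[r, j] = fisher_exact(
            [[a[r, j], b[r, j]], [c[r, j], d[r, j]]], alternative="two-sided"
        ).pvalue
    rejected = (p < settings.alpha).astype(float)
    rejected[(n_cc == 0) | ((a + b) == 0)] = np.nan  # empty group: no decision
    return _aggregate(design, scenario, settings, rejected, n_cc,
                      total_placebo, duration)


def _simulate_oc_simultaneous(
    design: DesignSpec,
    scenario: ScenarioSpec,
    settings: SimSettings,
    rng: np.random.Generator,
) -> OCSummary:
    """Exact fast path for simultaneous designs.

    Group sizes are the planned caps; each replicate draws one binomial
    death count per drug arm and per placebo group (one shared placebo
    for MATs, one per sub-trial for the stand-alone set).  The trial
    duration is the first month at which cumulative Poisson accrual
    reaches the planned total.
    """
    n_reps, m = settings.n_reps, design.n_drugs
    n_drug = design.per_drug_cap
    n_pl = design.placebo_cap
    drug_rates = scenario.drug_rates()
    a = rng.binomial(n_drug, drug_rates[np.newaxis, :], size=(n_reps, m))
    if design.kind is DesignKind.STAND_ALONE_SET:
        c = rng.binomial(n_pl, scenario.rp, size=(n_reps, m))
        total_placebo = np.full(n_reps, m * n_pl)
        stream_totals = [2 * n_drug] * m
    else:
        c = np.repeat(rng.binomial(n_pl, scenario.rp, size=(n_reps, 1)), m, axis=1)
        total_placebo = np.full(n_reps, n_pl)
        stream_totals = [m * n_drug + n_pl]
    b = n_drug - a
    d = n_pl - c
    n_cc = np.full((n_reps, m), n_pl)

    # duration: months until cumulative accrual covers the planned total
    # (every arrival enrolls while any arm is below its cap)
    duration = np.zeros(n_reps, dtype=np.int64)
    for total in stream_totals:
        remaining = np.full(n_reps, total, dtype=np.int64)
        months = np.zeros(n_reps, dtype=np.int64)
        active = remaining > 0
        while active.any():
            draws = rng.poisson(settings.accrual_mean, size=int(active.sum()))
            remaining[active] -= draws
            months[active] += 1
            active = remaining > 0
        duration = np.maximum(duration, months)

    p = pearson_chi2_pvalues(a, b, c, d)
    fisher_mask = needs_fisher(a, b, c, d)
    for r, j in zip(*np.nonzero(fisher_mask)):
        from scipy.stats import fisher_exact

        p[r, j] = fisher_exact(
            [[a[r, j], b[r, j]], [c[r, j], d[r, j]]], alternative="two-sided"
        ).pvalue
    rejected = (p < settings.alpha).astype(float)
    return _aggregate(design, scenario, settings, rejected, n_cc,
                      total_placebo, duration)


def summarize(
    decisions: list[list[DrugDecision]],
    design: DesignSpec,
    scenario: ScenarioSpec,
    settings: SimSettings,
    total_placebo: np.ndarray | None = None,
    duration: np.ndarray | None = None,
) -> OCSummary:
    """Aggregate explicit per-replicate decision lists (the object-level
    counterpart of :func:`simulate_oc`'s streamed reduction)."""
    if not decisions:
        raise ValueError("at least one replicate is required")
    n_reps = len(decisions)
    m = design.n_drugs
    rejected = np.full((n_reps, m), np.nan)
    n_cc = np.zeros((n_reps, m))
    for r, decs in enumerate(decisions):
        by_id = {dd.drug_id: dd for dd in decs}
        for j, drug in enumerate(design.drug_ids):
            dd = by_id[drug]
            n_cc[r, j] = dd.n_concurrent_control
            if dd.n_concurrent_control > 0 and dd.n_drug > 0:
                rejected[r, j] = float(dd.rejected)
    if total_placebo is None:
        total_placebo = np.full(n_reps, np.nan)
    if duration is None:
        duration = np.full(n_reps, np.nan)
    return _aggregate(design, scenario, settings, rejected, n_cc,
                      np.asarray(total_placebo), np.asarray(duration))


@dataclass(frozen=True)
class DesignComparison:
    """Signed paired differences (A - B) between two designs run under
    identical scenario and settings."""

    label_a: str
    label_b: str
    scenario_index: int
    rp: float
    accrual_mean: float
    delta_avg_power: float | None  # averaged over effective arms
    delta_avg_type_i: float | None  # averaged over ineffective arms
    delta_total_placebo: float


def compare_designs(oc_a: OCSummary, oc_b: OCSummary) -> DesignComparison:
    """Difference in average power / type I error / total placebo size
    between two designs evaluated on the same cell (e.g. dynamic-k minus
    equal allocation)."""
    same = (
        oc_a.scenario_index == oc_b.scenario_index
        and oc_a.rp == oc_b.rp
        and oc_a.rd == oc_b.rd
        and oc_a.effective == oc_b.effective
        and oc_a.accrual_mean == oc_b.accrual_mean
        and oc_a.alpha == oc_b.alpha
    )
    if not same:
        raise ValueError("designs were not evaluated on the same cell")

    def diff(x, y):
        return None if x is None or y is None else x - y

    return DesignComparison(
        label_a=oc_a.design_label,
        label_b=oc_b.design_label,
        scenario_index=oc_a.scenario_index,
        rp=oc_a.rp,
        accrual_mean=oc_a.accrual_mean,
        delta_avg_power=diff(oc_a.avg_power, oc_b.avg_power),
        delta_avg_type_i=diff(oc_a.avg_type_i, oc_b.avg_type_i),
        delta_total_placebo=oc_a.mean_total_placebo - oc_b.mean_total_placebo,
    )
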