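"""Bernoulli mortality outcomes, concurrent-control extraction and the
per-drug two-proportion test.

Each drug is compared against its *concurrent* controls only: the
placebo patients randomized between the drug arm's first and last
enrolled patient.  For designs whose arms open simultaneously (the
stand-alone set and multi-arm trials) the enrollment periods coincide
by construction and the whole placebo group is concurrent with every
drug — giving exactly 435 (equal) or 870 (2:1) controls per
comparison; in platform trials the window is evaluated on the
randomization sequence, so an equal-allocation platform trial yields
~435 concurrent controls per drug on average while the dynamic
square-root rule yields up to sqrt(k) times more.

The comparison is a Pearson chi-squared test on the 2x2 death/survival
table without continuity correction, falling back to Fisher's exact
test (two-sided, point-probability method) whenever any expected cell
count drops below 5 (Cochran's rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .accrual import EnrollmentLedger, Stream
from .design import EntryKind, ScenarioSpec

__all__ = [
    "Table2x2",
    "DrugDecision",
    "assign_outcomes",
    "concurrent_controls",
    "concurrent_control_counts",
    "test_2x2",
    "analyze_trial",
    "pearson_chi2_pvalues",
    "needs_fisher",
]


@dataclass(frozen=True)
class Table2x2:
    """Death/survival contingency table for one drug vs its controls."""

    deaths_drug: int
    survivors_drug: int
    deaths_control: int
    survivors_control: int

    def __post_init__(self) -> None:
        if min(
            self.deaths_drug,
            self.survivors_drug,
            self.deaths_control,
            self.survivors_control,
        ) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_drug(self) -> int:
        return self.deaths_drug + self.survivors_drug

    @property
    def n_control(self) -> int:
        return self.deaths_control + self.survivors_control


@dataclass(frozen=True)
class DrugDecision:
    """Efficacy decision for one drug arm."""

    drug_id: str
    p_value: float
    rejected: bool
    n_drug: int
    n_concurrent_control: int
    deaths_drug: int
    deaths_control: int
    method: str  # "chi2" or "fisher"

    @property
    def observed_rate_drug(self) -> float:
        return self.deaths_drug / self.n_drug

    @property
    def observed_rate_control(self) -> float:
        return self.deaths_control / self.n_concurrent_control


def assign_outcomes(
    ledger: EnrollmentLedger,
    scenario: ScenarioSpec,
    rng: np.random.Generator,
) -> EnrollmentLedger:
    """Draw each patient's death indicator from its arm's true rate.

    Patients die independently with the Bernoulli probability of their
    arm (``rd`` for effective drugs, ``rp`` otherwise); the per-cell
    death counts are drawn binomially, which is equivalent.  Fills
    ``ledger.deaths`` in place and returns the ledger.
    """
    if scenario.n_drugs != ledger.design.n_drugs:
        raise ValueError("scenario and design disagree on the number of drugs")
    drug_rate = dict(zip(ledger.design.drug_ids, scenario.drug_rates()))
    if not (0.0 <= scenario.rp <= 1.0) or any(
        not 0.0 <= r <= 1.0 for r in drug_rate.values()
    ):
        raise ValueError("mortality rates must lie in [0, 1]")
    deaths = []
    placebo_cum = []
    for s in ledger.streams:
        ci = s.arm_index(s.control_id)
        rates = np.array(
            [0.0 if a.is_placebo else drug_rate[a.arm_id] for a in s.arms]
        )
        d = rng.binomial(s.counts, rates[np.newaxis, :])
        # placebo outcomes are drawn per patient, in randomization order,
        # so that any sequence window has a well-defined death count
        total_p = int(s.counts[:, ci].sum())
        flags = (rng.random(total_p) < scenario.rp).astype(np.int64)
        cum = np.concatenate([[0], np.cumsum(flags)])
        offs = s.placebo_offsets()
        d[:, ci] = cum[offs[1:]] - cum[offs[:-1]]
        deaths.append(d)
        placebo_cum.append(cum)
    ledger.deaths = deaths
    ledger.placebo_death_cum = placebo_cum
    return ledger


def _sequence_window(stream: Stream, drug_id: str) -> tuple[int, int]:
    """(start, end) positions of the drug's concurrency window within
    the stream's placebo randomization sequence."""
    arm = stream.arms[stream.arm_index(drug_id)]
    if arm.first_enroll_month is None:
        raise ValueError(f"drug {drug_id!r} never enrolled a patient")
    offs = stream.placebo_offsets()
    if arm.at_cap and arm.close_placebo_prefix is not None:
        end = offs[arm.last_enroll_month] + arm.close_placebo_prefix
    else:  # drug still enrolling: window extends to the present
        end = offs[-1]
    start = offs[arm.first_enroll_month] + (arm.first_prior_placebo or 0)
    return int(start), int(end)


def concurrent_control_counts(
    ledger: EnrollmentLedger, drug_id: str
) -> tuple[int, int]:
    """(number, deaths) of placebo patients concurrent with ``drug_id``.

    The whole placebo group for simultaneous designs; the placebo
    patients randomized between the drug's first and last patient for
    staggered (platform) designs.
    """
    s = ledger.stream_for(drug_id)
    si = ledger.streams.index(s)
    ci = s.arm_index(s.control_id)
    if ledger.design.entry.kind is EntryKind.SIMULTANEOUS:
        n = int(s.counts[:, ci].sum())
        d = int(ledger.deaths[si][:, ci].sum()) if ledger.deaths else 0
        return n, d
    start, end = _sequence_window(s, drug_id)
    n = end - start
    if ledger.placebo_death_cum is None:
        return n, 0
    cum = ledger.placebo_death_cum[si]
    return n, int(cum[end] - cum[start])


def concurrent_controls(ledger: EnrollmentLedger, drug_id: str) -> np.ndarray:
    """Patient ids (as in :meth:`EnrollmentLedger.to_frame`) of the
    placebo patients concurrent with ``drug_id``."""
    s = ledger.stream_for(drug_id)
    frame = ledger.to_frame()
    placebo_ids = frame.loc[frame["arm"] == s.control_id, "patient_id"].to_numpy()
    if ledger.design.entry.kind is EntryKind.SIMULTANEOUS:
        return placebo_ids
    start, end = _sequence_window(s, drug_id)
    return placebo_ids[start:end]


def pearson_chi2_pvalues(
    deaths_drug, surv_drug, deaths_ctrl, surv_ctrl
) -> np.ndarray:
    """Vectorized Pearson chi-squared p-values (1 df, no continuity
    correction) via the closed form N(ad-bc)^2 / product of margins.
    Tables with a zero margin get p = 1 (no evidence either way)."""
    a = np.asarray(deaths_drug, dtype=float)
    b = np.asarray(surv_drug, dtype=float)
    c = np.asarray(deaths_ctrl, dtype=float)
    d = np.asarray(surv_ctrl, dtype=float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        x2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    return stats.chi2.sf(x2, df=1)


def needs_fisher(deaths_drug, surv_drug, deaths_ctrl, surv_ctrl) -> np.ndarray:
    """True where any expected cell count is below 5 (Cochran's rule)."""
    a = np.asarray(deaths_drug, dtype=float)
    b = np.asarray(surv_drug, dtype=float)
    c = np.asarray(deaths_ctrl, dtype=float)
    d = np.asarray(surv_ctrl, dtype=float)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        e11 = (a + b) * (a + c) / n
        e12 = (a + b) * (b + d) / n
        e21 = (c + d) * (a + c) / n
        e22 = (c + d) * (b + d) / n
    expected_min = np.minimum(np.minimum(e11, e12), np.minimum(e21, e22))
    return (n == 0) | (expected_min < 5)


def test_2x2(table: Table2x2, alpha: float = 0.05, drug_id: str = "") -> DrugDecision:
    """Two-sided test of equal mortality on a 2x2 table.

    Pearson chi-squared without continuity correction; Fisher's exact
    test when any expected cell count is below 5.
    """
    if table.n_drug == 0 or table.n_control == 0:
        raise ValueError("both group sizes must be positive")
    if needs_fisher(
        table.deaths_drug,
        table.survivors_drug,
        table.deaths_control,
        table.survivors_control,
    ):
        method = "fisher"
        p = float(
            stats.fisher_exact(
                [
                    [table.deaths_drug, table.survivors_drug],
                    [table.deaths_control, table.survivors_control],
                ],
                alternative="two-sided",
            ).pvalue
        )
    else:
        method = "chi2"
        p = float(
            pearson_chi2_pvalues(
                table.deaths_drug,
                table.survivors_drug,
                table.deaths_control,
                table.survivors_control,
            )
        )
    return DrugDecision(
        drug_id=drug_id,
        p_value=p,
        rejected=bool(p < alpha),
        n_drug=table.n_drug,
        n_concurrent_control=table.n_control,
        deaths_drug=table.deaths_drug,
        deaths_control=table.deaths_control,
        method=method,
    )


def drug_table(ledger: EnrollmentLedger, drug_id: str) -> Table2x2:
    """Build the drug-vs-concurrent-control 2x2 table from a ledger with
    outcomes assigned."""
    if ledger.deaths is None:
        raise ValueError("assign_outcomes must be called first")
    s = ledger.stream_for(drug_id)
    si = ledger.streams.index(s)
    di = s.arm_index(drug_id)
    n_drug = int(s.counts[:, di].sum())
    deaths_drug = int(ledger.deaths[si][:, di].sum())
    n_ctrl, deaths_ctrl = concurrent_control_counts(ledger, drug_id)
    return Table2x2(
        deaths_drug=deaths_drug,
        survivors_drug=n_drug - deaths_drug,
        deaths_control=deaths_ctrl,
        survivors_control=n_ctrl - deaths_ctrl,
    )


def analyze_trial(
    ledger: EnrollmentLedger,
    scenario: ScenarioSpec,
    alpha: float = 0.05,
) -> list[DrugDecision]:
    """One efficacy decision per drug arm, each against its own
    concurrent-control table."""
    return [
        test_2x2(drug_table(ledger, d), alpha=alpha, drug_id=d)
        for d in ledger.design.drug_ids
    ]
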