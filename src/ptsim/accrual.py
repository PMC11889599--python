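"""Monthly Poisson accrual and per-patient randomization.

Time is discrete months 0, 1, 2, ...  Each month the number of arriving
patients is Poisson with the design's mean accrual; arrivals are
randomized one at a time among the arms open at that moment, with
probability proportional to the allocation weights.  An arm that reaches
its cap closes immediately — mid-month — and, under the dynamic rule,
the placebo weight is re-evaluated before the next patient.  An
uncapped (platform-trial) placebo stops enrolling the moment the last
drug arm closes; a capped placebo completes its planned size.

Internally each independent accrual stream is stored as a month-by-arm
count matrix rather than one row per patient; the two representations
are distributionally identical because patients within a month and arm
are exchangeable.  :meth:`EnrollmentLedger.to_frame` expands to the
patient-level view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import AllocationRule, DesignKind, DesignSpec, SimSettings

__all__ = [
    "ArmState",
    "Stream",
    "EnrollmentLedger",
    "open_arms",
    "allocate_month",
    "simulate_enrollment",
]

PLACEBO = "placebo"

# hard stop against non-terminating loops (a cell at the slowest studied
# accrual finishes in well under 60 months)
MAX_MONTHS = 5000


@dataclass
class ArmState:
    """Mutable enrollment state of one arm within one accrual stream.

    Besides month-level first/last enrollment months, two
    randomization-sequence offsets are tracked so that concurrency can
    be evaluated at patient granularity: ``first_prior_placebo`` counts
    the placebo patients randomized in ``first_enroll_month`` *before*
    this arm's first patient, and ``close_placebo_prefix`` counts the
    placebo patients randomized in the arm's closing month up to (and
    necessarily before) the patient that filled the arm.
    """

    arm_id: str
    open_from: float  # continuous entry time; participates from floor(open_from)
    cap: int | None  # None = unbounded (platform-trial placebo)
    is_placebo: bool = False
    enrolled: int = 0
    first_enroll_month: int | None = None
    last_enroll_month: int | None = None
    first_prior_placebo: int | None = None
    close_placebo_prefix: int | None = None

    @property
    def at_cap(self) -> bool:
        return self.cap is not None and self.enrolled >= self.cap

    def remaining(self) -> float:
        return math.inf if self.cap is None else self.cap - self.enrolled


@dataclass
class Stream:
    """One independent accrual stream: its arms and month-by-arm counts."""

    arms: list[ArmState]
    counts: np.ndarray  # shape (months, n_arms), int
    drug_ids: list[str]
    control_id: str

    @property
    def months_elapsed(self) -> int:
        return self.counts.shape[0]

    def arm_index(self, arm_id: str) -> int:
        for i, a in enumerate(self.arms):
            if a.arm_id == arm_id:
                return i
        raise KeyError(arm_id)

    def placebo_offsets(self) -> np.ndarray:
        """Cumulative placebo counts by month: element m is the number
        of placebo patients randomized before month m (length
        months + 1), indexing the placebo randomization sequence."""
        ci = self.arm_index(self.control_id)
        return np.concatenate([[0], np.cumsum(self.counts[:, ci])])


@dataclass
class EnrollmentLedger:
    """Per-replicate enrollment record.

    Shared-control designs have a single stream; the stand-alone set has
    one stream per drug, each with its own placebo and accrual process.
    ``deaths`` is filled by :func:`ptsim.outcomes.assign_outcomes`.
    """

    design: DesignSpec
    streams: list[Stream]
    deaths: list[np.ndarray] | None = None
    # per stream: cumulative deaths over the placebo randomization
    # sequence (length total placebo + 1); lets any sequence window's
    # death count be read off in O(1)
    placebo_death_cum: list[np.ndarray] | None = None

    def stream_for(self, drug_id: str) -> Stream:
        for s in self.streams:
            if drug_id in s.drug_ids:
                return s
        raise KeyError(f"no arm {drug_id!r} in this ledger")

    def arm_total(self, arm_id: str) -> int:
        for s in self.streams:
            for a in s.arms:
                if a.arm_id == arm_id:
                    return a.enrolled
        raise KeyError(arm_id)

    def total_placebo(self) -> int:
        return sum(a.enrolled for s in self.streams for a in s.arms if a.is_placebo)

    @property
    def months_elapsed(self) -> int:
        return max(s.months_elapsed for s in self.streams)

    def to_frame(self, with_outcomes: bool = False) -> pd.DataFrame:
        """Patient-level view: one row per patient with columns
        ``patient_id, arm, month`` (plus ``outcome`` once assigned).

        Patient ids run in (stream, month, arm) order, with the placebo
        listed last within each month so that placebo ids follow the
        randomization sequence.  Within a drug's month-arm cell the
        patients flagged as deaths are listed first (an arbitrary but
        deterministic convention — patients within a cell are
        exchangeable); placebo outcomes follow the per-patient sequence
        draws.
        """
        rows: list[tuple] = []
        pid = 0
        for si, s in enumerate(self.streams):
            deaths = self.deaths[si] if (with_outcomes and self.deaths) else None
            cum = (
                self.placebo_death_cum[si]
                if (with_outcomes and self.placebo_death_cum)
                else None
            )
            offs = s.placebo_offsets() if cum is not None else None
            for month in range(s.months_elapsed):
                for ai, arm in enumerate(s.arms):
                    n = int(s.counts[month, ai])
                    if arm.is_placebo and cum is not None:
                        flags = np.diff(cum[offs[month] : offs[month + 1] + 1])
                    else:
                        d = int(deaths[month, ai]) if deaths is not None else 0
                        flags = None
                    for j in range(n):
                        rec = [pid, arm.arm_id, month]
                        if with_outcomes:
                            rec.append(
                                int(flags[j]) if flags is not None else (1 if j < d else 0)
                            )
                        rows.append(tuple(rec))
                        pid += 1
        cols = ["patient_id", "arm", "month"] + (["outcome"] if with_outcomes else [])
        return pd.DataFrame(rows, columns=cols)


def open_arms(arms: list[ArmState], month: int) -> set[str]:
    """Arm ids open for enrollment at ``month``.

    A drug arm is open iff it has entered (floor of its entry time is at
    or before ``month``) and is below cap.  A capped placebo (stand-alone
    and multi-arm designs) stays open until it reaches its planned size,
    so the planned totals are hit exactly; an uncapped placebo (platform
    trials) is open only while at least one drug arm is open.
    """
    open_ids = {
        a.arm_id
        for a in arms
        if not a.is_placebo and math.floor(a.open_from) <= month and not a.at_cap
    }
    any_drug_open = bool(open_ids)
    for a in arms:
        if a.is_placebo and not a.at_cap and (a.cap is not None or any_drug_open):
            open_ids.add(a.arm_id)
    return open_ids


def allocate_month(
    arms: list[ArmState],
    rule: AllocationRule,
    n_arrivals: int,
    month: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Randomize one month's arrivals among the open arms; returns the
    per-arm counts (aligned with ``arms``) and updates arm states.

    Patients are assigned sequentially, each to arm ``a`` with
    probability ``weight(a) / sum of weights`` over the arms open at that
    instant.  Exact sequential semantics are preserved while drawing in
    vectorized segments: whenever no arm can possibly fill this month the
    whole remainder is one multinomial draw; otherwise individual
    assignments are drawn and the segment is cut at the first arm
    closure, after which the open set and weights are refreshed.  The
    assigned total can fall short of ``n_arrivals`` only if every drug
    arm closed mid-month (late arrivals are simply not enrolled).
    """
    if n_arrivals < 0:
        raise ValueError("negative number of arrivals")
    n_arms = len(arms)
    alloc = np.zeros(n_arms, dtype=np.int64)
    remaining = int(n_arrivals)
    placebo_so_far = 0  # placebo patients randomized earlier this month

    while remaining > 0:
        open_drug_idx = [
            i
            for i, a in enumerate(arms)
            if not a.is_placebo
            and math.floor(a.open_from) <= month
            and (a.remaining() - alloc[i]) > 0
        ]
        open_idx = list(open_drug_idx)
        weights = [1.0] * len(open_drug_idx)
        placebo_pos = None
        for i, a in enumerate(arms):
            # a capped placebo finishes its planned size even after the
            # drugs are done; an uncapped one closes with the last drug
            if (
                a.is_placebo
                and (a.remaining() - alloc[i]) > 0
                and (a.cap is not None or open_drug_idx)
            ):
                placebo_pos = len(open_idx)
                open_idx.append(i)
                weights.append(rule.weight(len(open_drug_idx)) if open_drug_idx else 1.0)
        if not open_idx:
            break  # everything closed; late arrivals are not enrolled
        p = np.asarray(weights) / sum(weights)
        rem_caps = np.array([arms[i].remaining() - alloc[i] for i in open_idx])

        closed_j = None
        x_seg = None
        if remaining < rem_caps.min():
            # no closure possible: aggregate draw is exact
            seg = rng.multinomial(remaining, p)
            take = remaining
        else:
            # patient-level draw, cut at the first arm that fills
            x = rng.choice(len(open_idx), size=remaining, p=p)
            cut = None
            for j in np.flatnonzero(rem_caps <= remaining):
                occ = np.flatnonzero(x == j)
                if occ.size >= rem_caps[j]:
                    pos = occ[int(rem_caps[j]) - 1]
                    if cut is None or pos < cut:
                        cut = pos
                        closed_j = j
            take = remaining if cut is None else int(cut) + 1
            x_seg = x[:take]
            seg = np.bincount(x_seg, minlength=len(open_idx))

        seg_placebo = int(seg[placebo_pos]) if placebo_pos is not None else 0
        for j, i in enumerate(open_idx):
            if seg[j] == 0:
                continue
            arm = arms[i]
            if not arm.is_placebo and arm.enrolled == 0 and alloc[i] == 0:
                # arm's very first patient: placebo randomized before it
                if x_seg is not None:
                    first_pos = int(np.flatnonzero(x_seg == j)[0])
                    before = (
                        int((x_seg[:first_pos] == placebo_pos).sum())
                        if placebo_pos is not None
                        else 0
                    )
                else:
                    # aggregate segment: patients are exchangeable, so the
                    # interleaving of this arm's and the placebo's patients
                    # is uniform given the counts
                    before = _placebo_before_first(int(seg[j]), seg_placebo, rng)
                arm.first_prior_placebo = placebo_so_far + before
            alloc[i] += seg[j]
        if closed_j is not None and not arms[open_idx[closed_j]].is_placebo:
            # the cut patient filled this drug arm; every placebo patient
            # of the segment was randomized before it
            arms[open_idx[closed_j]].close_placebo_prefix = (
                placebo_so_far + seg_placebo
            )
        placebo_so_far += seg_placebo
        remaining -= take

    for i, a in enumerate(arms):
        if alloc[i] > 0:
            a.enrolled += int(alloc[i])
            if a.first_enroll_month is None:
                a.first_enroll_month = month
            a.last_enroll_month = month
    return alloc


def _placebo_before_first(n_drug: int, n_placebo: int, rng: np.random.Generator) -> int:
    """Number of placebo patients preceding the first drug patient in a
    uniform interleaving of ``n_drug`` drug and ``n_placebo`` placebo
    patients (exchangeability within an allocation segment)."""
    count = 0
    left_p, total = n_placebo, n_drug + n_placebo
    while left_p > 0 and rng.random() < left_p / total:
        count += 1
        left_p -= 1
        total -= 1
    return count


def _new_stream(
    drug_ids: list[str],
    entry_times: np.ndarray,
    per_drug_cap: int,
    placebo_cap: int | None,
    placebo_id: str = PLACEBO,
) -> Stream:
    arms = [
        ArmState(arm_id=d, open_from=float(t), cap=per_drug_cap)
        for d, t in zip(drug_ids, entry_times)
    ]
    arms.append(ArmState(arm_id=placebo_id, open_from=0.0, cap=placebo_cap, is_placebo=True))
    return Stream(
        arms=arms,
        counts=np.zeros((0, len(arms)), dtype=np.int64),
        drug_ids=list(drug_ids),
        control_id=placebo_id,
    )


def _run_stream(stream: Stream, rule: AllocationRule, accrual_mean: float,
                rng: np.random.Generator) -> None:
    rows = []
    month = 0
    arms = stream.arms
    while any(
        not a.at_cap for a in arms if not a.is_placebo or a.cap is not None
    ):
        n = int(rng.poisson(accrual_mean))
        rows.append(allocate_month(arms, rule, n, month, rng))
        month += 1
        if month > MAX_MONTHS:
            raise RuntimeError("enrollment did not terminate")
    stream.counts = (
        np.vstack(rows) if rows else np.zeros((0, len(arms)), dtype=np.int64)
    )


def simulate_enrollment(
    design: DesignSpec,
    settings: SimSettings,
    rng: np.random.Generator | None = None,
) -> EnrollmentLedger:
    """Simulate one replicate's enrollment for ``design``.

    Runs months of Poisson(``accrual_mean``) arrivals through
    :func:`allocate_month` until every drug arm reaches its cap.  The
    stand-alone set is simulated as ``n_drugs`` independent two-arm
    trials, each with its own accrual stream at the same mean.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)

    if design.kind is DesignKind.STAND_ALONE_SET:
        streams = []
        for d in design.drug_ids:
            s = _new_stream(
                [d],
                np.zeros(1),
                design.per_drug_cap,
                design.placebo_cap,
                placebo_id=f"{PLACEBO}_{d}",
            )
            _run_stream(s, design.allocation, settings.accrual_mean, rng)
            streams.append(s)
        return EnrollmentLedger(design=design, streams=streams)

    entry = design.entry.entry_times(design.n_drugs, rng)
    stream = _new_stream(
        list(design.drug_ids), entry, design.per_drug_cap, design.placebo_cap
    )
    _run_stream(stream, design.allocation, settings.accrual_mean, rng)
    return EnrollmentLedger(design=design, streams=[stream])
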