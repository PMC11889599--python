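"""Trial-design, scenario and simulation-setting definitions.

The simulator compares seven design families for evaluating several drugs
against a placebo on a binary mortality endpoint:

* a set of independent stand-alone two-arm trials (one per drug),
* a multi-arm trial (MAT) in which all drug arms and the shared placebo
  open simultaneously, with either equal allocation or a fixed 2:1
  placebo weighting,
* a platform trial (PT) in which drug arms are added over time (one per
  month, or at uniform-random offsets) and the placebo weight either
  stays at 1 or tracks ``k``, the number of drug arms currently
  enrolling, through the square-root rule (placebo weight sqrt(k), so
  each drug-vs-placebo comparison is randomized sqrt(k):1).

Drug arms always carry weight 1 each.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "AllocationMode",
    "AllocationRule",
    "EntryKind",
    "EntrySchedule",
    "DesignKind",
    "DesignSpec",
    "ScenarioSpec",
    "SimSettings",
    "build_design",
    "scenario_table",
    "RP_GRID",
    "DEFAULT_PER_DRUG_CAP",
]

#: Placebo-group true mortality rates used throughout the study grid.
RP_GRID = (0.05, 0.075, 0.10, 0.125, 0.15)

#: Per-drug-arm planned enrollment, from a two-proportion sample-size
#: calculation at 80% power, two-sided alpha 5%, rates 5% vs 10%, 1:1.
DEFAULT_PER_DRUG_CAP = 435


class AllocationMode(Enum):
    EQUAL = "equal"
    FIXED_UNEQUAL = "fixed_unequal"
    DYNAMIC_K = "dynamic_k"


@dataclass(frozen=True)
class AllocationRule:
    """Randomization weights for the placebo arm relative to each drug arm.

    Every open drug arm always has weight ``drug_weight`` (= 1).  The
    placebo weight is 1 (EQUAL), a fixed constant (FIXED_UNEQUAL, e.g. 2),
    or a function ``k ** dynamic_exponent`` of the current number ``k``
    of open drug arms (DYNAMIC_K).

    The default dynamic exponent is 1/2: the square-root allocation rule,
    under which the placebo-to-drug randomization ratio is sqrt(k):1 —
    the weighting that maximizes the precision of k simultaneous
    drug-vs-control comparisons for a given total sample size, and the
    rule behind the ``2`` in the four-drug ``MAT(1:1:1:1:2)`` benchmark
    (sqrt(4) = 2).  Setting ``dynamic_exponent = 1`` gives proportional
    k:1 weighting instead, under which the placebo always receives half
    of all accrual.
    """

    mode: AllocationMode
    placebo_weight: float = 1.0
    drug_weight: float = 1.0
    dynamic_exponent: float = 0.5

    def __post_init__(self) -> None:
        if self.drug_weight != 1.0:
            raise ValueError("drug arms always carry weight 1")
        if self.mode is AllocationMode.EQUAL and self.placebo_weight != 1.0:
            raise ValueError("EQUAL allocation implies placebo weight 1")
        if self.placebo_weight <= 0:
            raise ValueError("placebo weight must be positive")
        if self.dynamic_exponent <= 0:
            raise ValueError("dynamic exponent must be positive")

    def weight(self, k_open_drugs: int) -> float:
        """Placebo weight when ``k_open_drugs`` drug arms are enrolling."""
        if self.mode is AllocationMode.DYNAMIC_K:
            return float(k_open_drugs) ** self.dynamic_exponent
        return self.placebo_weight


class EntryKind(Enum):
    SIMULTANEOUS = "simultaneous"
    FIXED_MONTHLY = "fixed_monthly"
    UNIFORM_IRREGULAR = "uniform_irregular"


@dataclass(frozen=True)
class EntrySchedule:
    """When each drug arm opens for enrollment.

    The first drug arm always opens at month 0.  FIXED_MONTHLY opens arm
    ``i`` at month ``i``; UNIFORM_IRREGULAR draws the entry times of arms
    1..m-1 i.i.d. Uniform(0, ``uniform_upper``) — with upper bounds of
    2, 3 and 4 months for 3, 4 and 5 drug arms respectively.
    """

    kind: EntryKind
    uniform_upper: float | None = None

    def __post_init__(self) -> None:
        if self.kind is EntryKind.UNIFORM_IRREGULAR:
            if self.uniform_upper is None or self.uniform_upper <= 0:
                raise ValueError("UNIFORM_IRREGULAR needs a positive upper bound")

    def entry_times(self, n_drugs: int, rng: np.random.Generator) -> np.ndarray:
        """Continuous entry times (months) for each drug arm."""
        if self.kind is EntryKind.SIMULTANEOUS:
            return np.zeros(n_drugs)
        if self.kind is EntryKind.FIXED_MONTHLY:
            return np.arange(n_drugs, dtype=float)
        times = np.empty(n_drugs)
        times[0] = 0.0
        times[1:] = rng.uniform(0.0, self.uniform_upper, size=n_drugs - 1)
        return times


class DesignKind(Enum):
    STAND_ALONE_SET = "stand-alone"
    MAT = "MAT"
    PT = "PT"
    PT_IRR = "PT-irr"


@dataclass(frozen=True)
class DesignSpec:
    """A fully specified trial design.

    ``placebo_cap`` is the total placebo enrollment cap: equal to the
    per-drug cap for stand-alone / MAT-equal designs, ``weight x cap``
    for the fixed-unequal MAT, and ``None`` (unbounded) for platform
    trials, whose placebo enrolls for as long as any drug arm is open.
    """

    kind: DesignKind
    n_drugs: int
    allocation: AllocationRule
    entry: EntrySchedule
    per_drug_cap: int = DEFAULT_PER_DRUG_CAP
    placebo_cap: int | None = None

    def __post_init__(self) -> None:
        if self.n_drugs not in (3, 4, 5):
            raise ValueError(f"n_drugs must be 3, 4 or 5, got {self.n_drugs}")
        if self.per_drug_cap < 1:
            raise ValueError("per_drug_cap must be positive")
        if self.kind in (DesignKind.PT, DesignKind.PT_IRR):
            if self.placebo_cap is not None:
                raise ValueError("platform-trial placebo has no fixed cap")
        elif self.placebo_cap is None:
            raise ValueError(f"{self.kind.value} requires a placebo cap")

    @property
    def label(self) -> str:
        """Canonical design name, e.g. ``PT(1:1:1:1:k)``."""
        if self.kind is DesignKind.STAND_ALONE_SET:
            return "stand-alone"
        if self.allocation.mode is AllocationMode.EQUAL:
            tail = "1"
        elif self.allocation.mode is AllocationMode.DYNAMIC_K:
            tail = "k"
        else:
            tail = str(int(self.allocation.placebo_weight))
        ratio = ":".join(["1"] * self.n_drugs + [tail])
        return f"{self.kind.value}({ratio})"

    @property
    def drug_ids(self) -> tuple[str, ...]:
        """Drug arm labels A, B, C, ..."""
        return tuple("ABCDE"[: self.n_drugs])

    @property
    def planned_total(self) -> int | None:
        """Planned total enrollment; ``None`` for platform trials, whose
        placebo total depends on accrual speed."""
        if self.kind is DesignKind.STAND_ALONE_SET:
            return 2 * self.per_drug_cap * self.n_drugs
        if self.kind is DesignKind.MAT:
            return self.n_drugs * self.per_drug_cap + self.placebo_cap
        return None


_LABEL_RE = re.compile(
    r"^(?P<prefix>stand-?alone(?: set)?|MAT|PT-irr|PT)"
    r"(?:\((?P<ratio>[1k:0-9]+)(?:\s*\(=\d+\))?\))?$",
    re.IGNORECASE,
)


def build_design(
    name: str,
    n_drugs: int | None = None,
    per_drug_cap: int = DEFAULT_PER_DRUG_CAP,
) -> DesignSpec:
    """Build a validated :class:`DesignSpec` from its canonical label.

    Accepted names: ``stand-alone``, ``MAT(1:...:1)``, ``MAT(1:...:2)``,
    ``PT(1:...:1)``, ``PT(1:...:k)`` and the ``PT-irr`` variants, with the
    number of ``1`` slots giving the number of drug arms.  An annotation
    such as ``MAT(1:1:1:1:2 (=4))`` is tolerated (the ``(=4)`` restates
    the number of drug arms).  ``n_drugs`` may be passed instead of, or as
    a cross-check against, the ratio in the label.
    """
    m = _LABEL_RE.match(name.strip())
    if m is None:
        raise ValueError(f"unknown design name: {name!r}")
    prefix = m.group("prefix").lower()
    ratio = m.group("ratio")

    if ratio is not None:
        parts = ratio.split(":")
        if len(parts) < 2 or any(p != "1" for p in parts[:-1]):
            raise ValueError(f"malformed allocation ratio in {name!r}")
        label_drugs = len(parts) - 1
        if n_drugs is not None and n_drugs != label_drugs:
            raise ValueError(
                f"label {name!r} implies {label_drugs} drugs, got n_drugs={n_drugs}"
            )
        n_drugs = label_drugs
        tail = parts[-1].lower()
    else:
        tail = None
    if n_drugs is None:
        if prefix.startswith("stand"):
            n_drugs = 4  # the study's reference configuration
        else:
            raise ValueError("n_drugs is required when the label has no ratio")
    if n_drugs not in (3, 4, 5):
        raise ValueError(f"n_drugs must be 3, 4 or 5, got {n_drugs}")

    if prefix.startswith("stand"):
        return DesignSpec(
            kind=DesignKind.STAND_ALONE_SET,
            n_drugs=n_drugs,
            allocation=AllocationRule(AllocationMode.EQUAL),
            entry=EntrySchedule(EntryKind.SIMULTANEOUS),
            per_drug_cap=per_drug_cap,
            placebo_cap=per_drug_cap,
        )

    if tail is None:
        raise ValueError(f"{name!r} needs an explicit allocation ratio")
    if tail == "k":
        rule = AllocationRule(AllocationMode.DYNAMIC_K)
    elif tail == "1":
        rule = AllocationRule(AllocationMode.EQUAL)
    else:
        w = int(tail)
        if w < 2:
            raise ValueError(f"fixed unequal placebo weight must be >= 2, got {w}")
        rule = AllocationRule(AllocationMode.FIXED_UNEQUAL, placebo_weight=float(w))

    if prefix == "mat":
        if rule.mode is AllocationMode.DYNAMIC_K:
            raise ValueError("a MAT has no staggered entry; use a fixed ratio")
        cap = per_drug_cap * (int(rule.placebo_weight) if rule.mode is AllocationMode.FIXED_UNEQUAL else 1)
        return DesignSpec(
            kind=DesignKind.MAT,
            n_drugs=n_drugs,
            allocation=rule,
            entry=EntrySchedule(EntryKind.SIMULTANEOUS),
            per_drug_cap=per_drug_cap,
            placebo_cap=cap,
        )

    kind = DesignKind.PT_IRR if prefix == "pt-irr" else DesignKind.PT
    if rule.mode is AllocationMode.FIXED_UNEQUAL:
        raise ValueError("platform trials use EQUAL or DYNAMIC_K allocation")
    entry = (
        EntrySchedule(EntryKind.UNIFORM_IRREGULAR, uniform_upper=float(n_drugs - 1))
        if kind is DesignKind.PT_IRR
        else EntrySchedule(EntryKind.FIXED_MONTHLY)
    )
    return DesignSpec(
        kind=kind,
        n_drugs=n_drugs,
        allocation=rule,
        entry=entry,
        per_drug_cap=per_drug_cap,
        placebo_cap=None,
    )


def all_design_labels(n_drugs: int = 4) -> list[str]:
    """The seven design labels compared in the study, for ``n_drugs`` arms."""
    ones = ":".join(["1"] * n_drugs)
    return [
        "stand-alone",
        f"MAT({ones}:1)",
        f"MAT({ones}:2)",
        f"PT({ones}:1)",
        f"PT({ones}:k)",
        f"PT-irr({ones}:1)",
        f"PT-irr({ones}:k)",
    ]


@dataclass(frozen=True)
class ScenarioSpec:
    """True mortality rates for every arm.

    ``rp`` is the placebo rate; effective drugs have rate ``rd`` (by
    default 5 percentage points below ``rp``); ineffective drugs share the
    placebo rate.  ``effective`` flags each drug arm, assigned from the
    last-indexed drug backwards, so scenario ``s`` (1-based) has exactly
    ``s - 1`` effective drugs.
    """

    index: int
    rp: float
    rd: float
    effective: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.rp <= 1.0:
            raise ValueError("placebo mortality must lie in [0, 1]")
        if not 0.0 <= self.rd <= 1.0:
            raise ValueError("drug mortality must lie in [0, 1]")
        if any(self.effective) and self.rd >= self.rp:
            raise ValueError("an effective drug must have rd < rp")
        if self.rp not in RP_GRID:
            warnings.warn(
                f"placebo rate {self.rp} is outside the standard grid {RP_GRID}",
                stacklevel=2,
            )

    @property
    def n_drugs(self) -> int:
        return len(self.effective)

    @property
    def n_effective(self) -> int:
        return sum(self.effective)

    def drug_rates(self) -> np.ndarray:
        """True mortality rate per drug arm (placebo rate for ineffective)."""
        return np.where(np.asarray(self.effective), self.rd, self.rp)


def scenario_table(
    n_drugs: int, rp: float, rd: float | None = None
) -> list[ScenarioSpec]:
    """The ``n_drugs + 1`` effectiveness scenarios at placebo rate ``rp``.

    Scenario 1 is the global null (every arm at ``rp``); each subsequent
    scenario makes one more drug effective, starting from the last drug.
    ``rd`` defaults to ``rp - 0.05`` (e.g. 10% placebo vs 5% drug).
    """
    if n_drugs not in (3, 4, 5):
        raise ValueError(f"n_drugs must be 3, 4 or 5, got {n_drugs}")
    if rd is None:
        rd = round(rp - 0.05, 10)
    return [
        ScenarioSpec(
            index=s,
            rp=rp,
            rd=rd,
            effective=tuple(i >= n_drugs - (s - 1) for i in range(n_drugs)),
        )
        for s in range(1, n_drugs + 2)
    ]


@dataclass(frozen=True)
class SimSettings:
    """Monte Carlo settings: mean monthly accrual, replicate count,
    two-sided test level and master seed."""

    accrual_mean: float
    n_reps: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accrual_mean <= 0:
            raise ValueError("accrual_mean must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
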