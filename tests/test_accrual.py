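"""Poisson accrual, randomization among open arms, caps and stop rules."""

import numpy as np
import pytest
from scipy import stats

from ptsim import (
    AllocationMode,
    AllocationRule,
    SimSettings,
    allocate_month,
    build_design,
    open_arms,
    simulate_enrollment,
)
from ptsim.accrual import ArmState


def _arms(caps, placebo_cap=None, entries=None):
    entries = entries or [0.0] * len(caps)
    arms = [
        ArmState(arm_id=f"D{i}", open_from=t, cap=c)
        for i, (c, t) in enumerate(zip(caps, entries))
    ]
    arms.append(ArmState(arm_id="placebo", open_from=0.0, cap=placebo_cap, is_placebo=True))
    return arms


class TestOpenArms:
    def test_staggered_entry_monthly(self):
        arms = _arms([435] * 4, entries=[0, 1, 2, 3])
        assert open_arms(arms, 0) == {"D0", "placebo"}
        assert open_arms(arms, 3) == {"D0", "D1", "D2", "D3", "placebo"}

    def test_fractional_entry_participates_from_floor_month(self):
        arms = _arms([435], entries=[1.7])
        assert open_arms(arms, 0) == set()
        assert open_arms(arms, 1) == {"D0", "placebo"}

    def test_placebo_closes_with_last_drug(self):
        arms = _arms([10, 10])
        arms[0].enrolled = 10
        arms[1].enrolled = 10
        assert open_arms(arms, 5) == set()


class TestAllocateMonth:
    @pytest.mark.parametrize(
        "rule, n_drugs, expected_share",
        [
            (AllocationRule(AllocationMode.EQUAL), 4, 1 / 5),
            (AllocationRule(AllocationMode.DYNAMIC_K), 1, 1 / 2),
            (AllocationRule(AllocationMode.DYNAMIC_K), 4, 2 / 6),
            (AllocationRule(AllocationMode.DYNAMIC_K, dynamic_exponent=1.0), 4, 1 / 2),
            (AllocationRule(AllocationMode.FIXED_UNEQUAL, placebo_weight=2.0), 4, 2 / 6),
        ],
    )
    def test_placebo_share_matches_weights(self, rule, n_drugs, expected_share):
        """Observed allocation fractions agree with the weight fractions
        (chi-squared goodness of fit over 1e5 patients)."""
        rng = np.random.default_rng(42)
        n = 100_000
        arms = _arms([n] * n_drugs)  # caps never bind
        counts = allocate_month(arms, rule, n, month=0, rng=rng)
        placebo = counts[-1]
        drug_share = (1 - expected_share) / n_drugs
        expected = [drug_share * n] * n_drugs + [expected_share * n]
        p = stats.chisquare(counts, expected).pvalue
        assert p > 1e-3
        assert placebo / n == pytest.approx(expected_share, abs=0.01)

    def test_caps_respected_and_mid_month_closure(self):
        rng = np.random.default_rng(1)
        arms = _arms([30, 5000], placebo_cap=None)
        rule = AllocationRule(AllocationMode.EQUAL)
        counts = allocate_month(arms, rule, 3000, month=0, rng=rng)
        assert counts[0] == 30  # exactly at cap, never beyond
        assert counts.sum() == 3000  # other arms absorb the rest

    def test_all_drugs_closing_stops_placebo(self):
        rng = np.random.default_rng(2)
        arms = _arms([10], placebo_cap=None)
        counts = allocate_month(arms, AllocationRule(AllocationMode.EQUAL), 1000, 0, rng)
        assert counts[0] == 10
        # placebo stops the moment the only drug closes: roughly half of
        # the preceding patients, never the full month
        assert counts[1] < 100

    def test_negative_arrivals_rejected(self):
        with pytest.raises(ValueError):
            allocate_month(_arms([10]), AllocationRule(AllocationMode.EQUAL), -1, 0,
                           np.random.default_rng(0))


class TestSimulateEnrollment:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("MAT(1:1:1:1:2)", {"A": 435, "B": 435, "C": 435, "D": 435, "placebo": 870}),
            ("MAT(1:1:1:1:1)", {"A": 435, "B": 435, "C": 435, "D": 435, "placebo": 435}),
        ],
    )
    def test_mat_final_totals_exact(self, label, expected):
        d = build_design(label)
        led = simulate_enrollment(d, SimSettings(accrual_mean=300, n_reps=1, seed=3))
        totals = {a.arm_id: a.enrolled for a in led.streams[0].arms}
        assert totals == expected

    def test_platform_drug_arms_fill_exactly(self):
        d = build_design("PT(1:1:1:1:k)")
        for seed in range(5):
            led = simulate_enrollment(d, SimSettings(accrual_mean=250, n_reps=1, seed=seed))
            for drug in d.drug_ids:
                assert led.arm_total(drug) == 435

    def test_stand_alone_decomposes_into_independent_trials(self):
        d = build_design("stand-alone", 4)
        led = simulate_enrollment(d, SimSettings(accrual_mean=200, n_reps=1, seed=8))
        assert len(led.streams) == 4
        for s in led.streams:
            assert sum(a.enrolled for a in s.arms) == 870

    def test_identical_seed_identical_ledger(self):
        d = build_design("PT-irr(1:1:1:1:k)")
        settings = SimSettings(accrual_mean=150, n_reps=1, seed=11)
        a = simulate_enrollment(d, settings)
        b = simulate_enrollment(d, settings)
        assert len(a.streams[0].counts) == len(b.streams[0].counts)
        np.testing.assert_array_equal(a.streams[0].counts, b.streams[0].counts)

    def test_conservation_within_months(self):
        """Monthly totals never exceed the arrivals; a shortfall can only
        happen in the final month when every arm has closed."""
        d = build_design("MAT(1:1:1:1:1)")
        rng = np.random.default_rng(21)
        settings = SimSettings(accrual_mean=500, n_reps=1, seed=21)
        led = simulate_enrollment(d, settings, rng)
        total = led.streams[0].counts.sum()
        assert total == 2175

    def test_dynamic_total_placebo_grows_with_accrual(self):
        """Under the dynamic rule the total placebo group grows with the
        accrual rate (coarser month granularity around arm closures),
        while staying inside the planned envelope."""
        d = build_design("PT(1:1:1:1:k)")
        means = []
        for lam in (100, 400):
            tot = [
                simulate_enrollment(
                    d, SimSettings(accrual_mean=lam, n_reps=1, seed=s)
                ).total_placebo()
                for s in range(40)
            ]
            means.append(np.mean(tot))
        # total placebo grows with accrual (coarser month granularity),
        # while the dynamic design's per-drug concurrent share shrinks --
        # checked in the OC tests; here: totals stay within the planned
        # envelope of 435..1740 placebo patients
        assert 435 < means[0] < means[1] < 1740

    def test_patient_frame_matches_counts(self):
        d = build_design("PT(1:1:1:1:1)")
        led = simulate_enrollment(d, SimSettings(accrual_mean=300, n_reps=1, seed=4))
        frame = led.to_frame()
        assert len(frame) == led.streams[0].counts.sum()
        assert frame["patient_id"].is_unique
        assert (frame.groupby("arm").size()["placebo"]) == led.total_placebo()
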