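"""Outcome generation, concurrent-control extraction and the 2x2 test."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.special import comb

from ptsim import (
    ScenarioSpec,
    SimSettings,
    Table2x2,
    analyze_trial,
    assign_outcomes,
    build_design,
    concurrent_control_counts,
    concurrent_controls,
    scenario_table,
    simulate_enrollment,
)
from ptsim.outcomes import test_2x2 as run_2x2_test


def _simulated_ledger(label="MAT(1:1:1:1:1)", rp=0.10, scenario=5, lam=300, seed=0):
    d = build_design(label)
    led = simulate_enrollment(d, SimSettings(accrual_mean=lam, n_reps=1, seed=seed))
    scen = scenario_table(d.n_drugs, rp)[scenario - 1]
    return assign_outcomes(led, scen, np.random.default_rng(seed)), scen


class TestAssignOutcomes:
    @pytest.mark.parametrize("rp, expected", [(0.0, 0), (1.0, 2175)])
    def test_degenerate_rates(self, rp, expected):
        d = build_design("MAT(1:1:1:1:1)")
        led = simulate_enrollment(d, SimSettings(accrual_mean=300, n_reps=1, seed=1))
        with pytest.warns(UserWarning):  # off-grid placebo rate
            scen = ScenarioSpec(index=1, rp=rp, rd=rp, effective=(False,) * 4)
        assign_outcomes(led, scen, np.random.default_rng(1))
        assert sum(m.sum() for m in led.deaths) == expected

    def test_death_counts_binomial(self):
        """Placebo deaths over replicates behave as Binomial(870, 0.10)."""
        d = build_design("MAT(1:1:1:1:2)")
        scen = scenario_table(4, 0.10)[4]
        rng = np.random.default_rng(7)
        deaths = []
        led = simulate_enrollment(d, SimSettings(accrual_mean=300, n_reps=1, seed=7))
        pi = led.streams[0].arm_index("placebo")
        for _ in range(200):
            assign_outcomes(led, scen, rng)
            deaths.append(led.deaths[0][:, pi].sum())
        mean = np.mean(deaths)
        se = np.sqrt(870 * 0.1 * 0.9 / 200)
        assert abs(mean - 87.0) < 3 * se


class TestConcurrentControls:
    def test_simultaneous_designs_use_whole_placebo_group(self):
        led, _ = _simulated_ledger("MAT(1:1:1:1:2)")
        for drug in "ABCD":
            n, _ = concurrent_control_counts(led, drug)
            assert n == 870

    def test_platform_excludes_pre_entry_placebo(self):
        """Drug D opens at month 3 of a monthly-staggered platform trial:
        every placebo patient randomized before D's first patient is
        non-concurrent for D."""
        led, _ = _simulated_ledger("PT(1:1:1:1:1)", lam=200, seed=5)
        stream = led.streams[0]
        pi = stream.arm_index("placebo")
        early = stream.counts[:3, pi].sum()  # months before D enters
        n, _ = concurrent_control_counts(led, "D")
        assert n <= led.total_placebo() - early
        ids = concurrent_controls(led, "D")
        assert len(ids) == n

    def test_window_never_exceeds_total_placebo(self):
        for seed in range(5):
            led, _ = _simulated_ledger("PT(1:1:1:1:k)", lam=150, seed=seed)
            total = led.total_placebo()
            for drug in "ABCD":
                n, d = concurrent_control_counts(led, drug)
                assert 0 < n <= total
                assert 0 <= d <= n

    def test_equal_platform_concurrent_mean_near_cap(self):
        """With equal weights the placebo accrues at each drug's own rate
        inside its window, so the concurrent-control size averages ~435."""
        counts = []
        for seed in range(30):
            led, _ = _simulated_ledger("PT(1:1:1:1:1)", lam=300, seed=seed)
            counts += [concurrent_control_counts(led, d)[0] for d in "ABCD"]
        assert np.mean(counts) == pytest.approx(435, rel=0.03)

    def test_window_deaths_match_patient_frame(self):
        led, _ = _simulated_ledger("PT(1:1:1:1:k)", lam=250, seed=9)
        frame = led.to_frame(with_outcomes=True)
        for drug in "ABCD":
            ids = concurrent_controls(led, drug)
            n, d = concurrent_control_counts(led, drug)
            sub = frame[frame["patient_id"].isin(ids)]
            assert len(sub) == n
            assert sub["outcome"].sum() == d


def _pearson_oracle(a, b, c, d):
    """Textbook Pearson statistic N(ad - bc)^2 / (margin product)."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return stats.chi2.sf(num / den, df=1)


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration: sum the
    probabilities of all tables with the same margins whose point
    probability does not exceed the observed one."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def pt(x):
        return (
            comb(col1, x, exact=True)
            * comb(n - col1, row1 - x, exact=True)
            / comb(n, row1, exact=True)
        )

    p_obs = pt(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(p for x in range(lo, hi + 1) if (p := pt(x)) <= p_obs * (1 + 1e-12))


class TestTest2x2:
    def test_identical_proportions_give_p_one(self):
        dec = run_2x2_test(Table2x2(20, 415, 20, 415))
        assert dec.p_value == pytest.approx(1.0)
        assert not dec.rejected

    def test_chi2_matches_textbook_formula(self):
        """Chi-squared p-values agree with the closed-form Pearson oracle
        to 1e-10 on 200 random large tables."""
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 200:
            a, c = rng.integers(10, 120, size=2)
            b, d = rng.integers(200, 900, size=2)
            t = Table2x2(int(a), int(b), int(c), int(d))
            dec = run_2x2_test(t)
            if dec.method != "chi2":
                continue
            assert dec.p_value == pytest.approx(_pearson_oracle(a, b, c, d), abs=1e-10)
            checked += 1

    def test_chi2_matches_scipy_contingency(self):
        obs = [[22, 413], [44, 826]]
        dec = run_2x2_test(Table2x2(22, 413, 44, 826))
        ref = stats.chi2_contingency(obs, correction=False).pvalue
        assert dec.p_value == pytest.approx(ref, abs=1e-12)

    def test_fisher_fallback_matches_enumeration(self):
        """Sparse tables (any expected cell < 5) switch to Fisher's exact
        test, matching exhaustive hypergeometric enumeration on all
        tables with N <= 60 and sparse margins."""
        count = 0
        for a, b, c, d in itertools.product(range(0, 7), repeat=4):
            if min(a + b, c + d) == 0 or (a + b + c + d) > 60:
                continue
            t = Table2x2(a, b, c, d)
            dec = run_2x2_test(t)
            if dec.method != "fisher":
                continue
            assert dec.p_value == pytest.approx(_fisher_oracle(a, b, c, d), rel=1e-9)
            count += 1
        assert count > 100

    def test_fisher_triggered_by_small_expected_cells(self):
        assert run_2x2_test(Table2x2(0, 10, 5, 5)).method == "fisher"
        assert run_2x2_test(Table2x2(50, 400, 60, 390)).method == "chi2"

    def test_row_swap_symmetry(self):
        for a, b, c, d in [(12, 423, 30, 840), (3, 40, 9, 31), (0, 10, 5, 5)]:
            p1 = run_2x2_test(Table2x2(a, b, c, d)).p_value
            p2 = run_2x2_test(Table2x2(c, d, a, b)).p_value
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            run_2x2_test(Table2x2(0, 0, 5, 5))


class TestAnalyzeTrial:
    def test_one_decision_per_drug_with_own_controls(self):
        led, scen = _simulated_ledger("PT(1:1:1:1:k)", rp=0.125, lam=200, seed=3)
        decisions = analyze_trial(led, scen, alpha=0.05)
        assert [d.drug_id for d in decisions] == ["A", "B", "C", "D"]
        for dec in decisions:
            assert dec.n_drug == 435
            assert dec.rejected == (dec.p_value < 0.05)
            n, _ = concurrent_control_counts(led, dec.drug_id)
            assert dec.n_concurrent_control == n

    def test_single_drug_reduction_matches_stand_alone(self):
        """A shared-control trial with one drug is analyzed exactly like a
        stand-alone trial: same table, same decision."""
        led, scen = _simulated_ledger("stand-alone", rp=0.10, seed=6)
        decisions = analyze_trial(led, scen, alpha=0.05)
        for dec in decisions:
            assert dec.n_concurrent_control == 435
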