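"""Batch execution over design/scenario grids with reproducible seeding.

Every grid cell (design, scenario, placebo rate, accrual mean) gets its
own independent random stream derived from the master seed and the cell
index, so adding or removing cells never perturbs the others and a rerun
of the same configuration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import SimSettings, build_design, scenario_table
from .oc import OCSummary, simulate_oc
from .slope import SlopePoint, build_points

__all__ = ["cell_rng", "run_grid", "paired_power_points"]


def cell_rng(master_seed: int, cell_index: int) -> np.random.Generator:
    """Independent generator for cell ``cell_index`` of a grid run."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_index,))
    )


def run_grid(
    designs: Sequence[str],
    n_drugs: int,
    rps: Sequence[float],
    accrual_means: Sequence[float],
    scenarios: Sequence[int] | None = None,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    progress: bool = False,
) -> list[OCSummary]:
    """Simulate every (design, scenario, rp, accrual mean) cell.

    Cells are enumerated in the deterministic order
    design x scenario x rp x accrual mean (each in the order given) and
    seeded by their enumeration index; ``scenarios`` defaults to all
    ``n_drugs + 1`` effectiveness patterns.
    """
    if scenarios is None:
        scenarios = list(range(1, n_drugs + 2))
    results = []
    cells = list(product(designs, scenarios, rps, accrual_means))
    for idx, (label, s_idx, rp, lam) in enumerate(cells):
        design = build_design(label, n_drugs)
        scen = scenario_table(n_drugs, rp)[s_idx - 1]
        settings = SimSettings(accrual_mean=lam, n_reps=n_reps, alpha=alpha, seed=seed)
        oc = simulate_oc(design, scen, settings, rng=cell_rng(seed, idx))
        results.append(oc)
        if progress:
            print(
                f"[{idx + 1}/{len(cells)}] {label} scenario {s_idx} "
                f"rp={rp} lambda={lam}: done",
                flush=True,
            )
    return results


def paired_power_points(
    n_drugs: int,
    unequal: str,
    equal: str,
    rps: Sequence[float],
    accrual_means: Sequence[float],
    scenarios: Sequence[int] | None = None,
    n_reps: int = 2_000,
    alpha: float = 0.05,
    seed: int = 0,
    basis: str = "total",
    progress: bool = False,
) -> list[SlopePoint]:
    """Power-gain regression points for an (unequal, equal) design pair.

    ``scenarios`` defaults to every scenario with at least one effective
    drug (2 .. n_drugs + 1); placebo rates at or below 5% are dropped by
    :func:`ptsim.slope.build_points`.
    """
    if scenarios is None:
        scenarios = list(range(2, n_drugs + 2))
    ocs = run_grid(
        [unequal, equal],
        n_drugs,
        rps,
        accrual_means,
        scenarios=scenarios,
        n_reps=n_reps,
        alpha=alpha,
        seed=seed,
        progress=progress,
    )
    half = len(ocs) // 2
    pairs = list(zip(ocs[:half], ocs[half:]))
    return build_points(pairs, basis=basis)


def grid_frame(results: Iterable[OCSummary]) -> pd.DataFrame:
    """Concatenated tidy table of grid results."""
    return pd.concat([oc.to_frame() for oc in results], ignore_index=True)


def replicate_decisions_frame(
    design_label: str,
    n_drugs: int,
    scenario_index: int,
    rp: float,
    accrual_mean: float,
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-replicate, per-drug decision records (one row per 2x2 test).

    Unlike :func:`ptsim.oc.simulate_oc` this retains every decision, so
    it is meant for export and debugging at moderate replicate counts.
    """
    from .accrual import simulate_enrollment
    from .outcomes import analyze_trial, assign_outcomes

    design = build_design(design_label, n_drugs)
    scen = scenario_table(n_drugs, rp)[scenario_index - 1]
    settings = SimSettings(accrual_mean=accrual_mean, n_reps=n_reps,
                           alpha=alpha, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    rows = []
    for rep in range(n_reps):
        ledger = simulate_enrollment(design, settings, rng)
        assign_outcomes(ledger, scen, rng)
        for dec in analyze_trial(ledger, scen, alpha=alpha):
            rows.append(
                {
                    "replicate": rep,
                    "design": design.label,
                    "scenario": scen.index,
                    "rp": scen.rp,
                    "drug": dec.drug_id,
                    "n_drug": dec.n_drug,
                    "n_concurrent": dec.n_concurrent_control,
                    "deaths_drug": dec.deaths_drug,
                    "deaths_control": dec.deaths_control,
                    "p_value": dec.p_value,
                    "rejected": dec.rejected,
                }
            )
    return pd.DataFrame(rows)
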