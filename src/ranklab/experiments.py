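"""Headline computations of the composite-indicator rankability study.

Each function runs one self-contained experiment end to end — building the
scenario grid, calibrating the generator, simulating and (where needed)
fitting models — and returns the summary quantity the study reports.  They
are used by the reproduction script and by the acceptance test suite.

Problem sizes: the prevalence check runs the full 48-scenario grid at its
design volumes with a fit-free analytic calibration; the dominance checks
run reduced grids (50 hospitals x 200 patients, 10 replicates) with the
simulation-based grid-search calibration, which keeps a full run on one
CPU within minutes while preserving the qualitative structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .study_pipeline import ScenarioResultB, build_grid_B, run_study
from .synthetic_data import (
    DEFAULT_RANKABILITY_SETS,
    calibrate_intercept,
    calibrate_tau,
    seed_sequence,
    simulate_composite_dataset,
    CalibrationResult,
)

__all__ = ["prevalence_check", "dominance_fraction", "PrevalenceCheck", "DominanceCheck"]


@dataclass
class PrevalenceCheck:
    mean_prevalences: np.ndarray  # (3,) across scenarios and replicates
    n_scenarios: int
    n_reps: int


@dataclass
class DominanceCheck:
    percent_composite_beats_all: float
    results: list  # per-scenario ScenarioResultB


def prevalence_check(
    master_seed: int = 0,
    n_reps: int = 5,
    equal_prevalence: bool = False,
) -> PrevalenceCheck:
    """Mean empirical prevalences over the full 48-scenario composite grid.

    Calibrates each scenario's intercepts by bisection against the
    quadrature marginal-prevalence function (with the random-effect SDs
    from the fit-free analytic rankability calibration), simulates
    ``n_reps`` replicate datasets per scenario, and averages the empirical
    rates of the three binary indicators.  No model fitting is involved.
    """
    grid = build_grid_B(equal_prevalence=equal_prevalence)
    cal_cache: dict = {}
    sums = np.zeros(3)
    count = 0
    for si, s in enumerate(grid):
        comps = []
        for k in range(3):
            key = (s.target_rankabilities[k], s.prevalences[k], s.slopes[k], s.n_per_hospital)
            if key not in cal_cache:
                cal_cache[key] = calibrate_tau(
                    s.target_rankabilities[k], s.prevalences[k], s.slopes[k],
                    s.n_hospitals, s.n_per_hospital, method="analytic",
                )
            comps.append(cal_cache[key])
        cal = CalibrationResult(
            alpha0=[c.alpha0 for c in comps],
            tau=[c.tau for c in comps],
            achieved_prevalences=[c.achieved_prevalence for c in comps],
            achieved_rankabilities=[c.achieved_rankability for c in comps],
        )
        for rep in range(n_reps):
            df = simulate_composite_dataset(s, cal, seed_sequence(master_seed, si, rep))
            sums += [df["y1"].mean(), df["y2"].mean(), df["y3"].mean()]
            count += 1
    return PrevalenceCheck(mean_prevalences=sums / count, n_scenarios=len(grid), n_reps=n_reps)


def dominance_fraction(
    master_seed: int = 0,
    correlations: tuple = (0.5, 0.75, 0.9),
    equal_prevalence: bool = False,
    n_hospitals: int = 50,
    n_per_hospital: int = 200,
    n_reps: int = 10,
    calibration_method: str = "simulate",
    n_cal_reps: int = 25,
    workers: int = 1,
) -> DominanceCheck:
    """Percentage of scenarios where the composite's mean rankability beats all components.

    Grid: the given correlations x the three target-rankability sets, at one
    hospital volume.  Per scenario, ``n_reps`` replicates are simulated and
    all four indicators' rankabilities estimated with paired fixed/random
    fits; the composite "beats all" when its mean exceeds each component's.
    """
    grid = build_grid_B(
        equal_prevalence=equal_prevalence,
        correlations=correlations,
        volumes=(n_per_hospital,),
        rankability_sets=DEFAULT_RANKABILITY_SETS,
        n_hospitals=n_hospitals,
        n_reps=n_reps,
    )
    results = run_study(
        grid,
        master_seed=master_seed,
        calibration_method=calibration_method,
        n_cal_reps=n_cal_reps,
        workers=workers,
    )
    ok = [r for r in results if isinstance(r, ScenarioResultB) and r.n_converged > 0]
    if not ok:
        raise RuntimeError("no scenario produced converged replicates")
    frac = float(np.mean([r.composite_beats_all for r in ok]))
    return DominanceCheck(percent_composite_beats_all=100.0 * frac, results=results)
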