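"""Monte Carlo scenario studies of indicator rankability.

Two replicated studies are supported:

* **Study A** (single binary indicator): a full factorial over the
  generating ICC (13 values, 0 to 0.24 by 0.02), the average intercept
  (-3, -2, -1.5, -1) and the risk-score slope (-0.25, 0, 0.25) — 156
  scenarios of 100 hospitals x 500 patients, 100 replicates each —
  mapping the between-hospital variance onto estimated rankability.

* **Study B** (composite ordinal indicator): 8 random-effect correlations
  (-0.25 to 0.90) x 2 hospital volumes (500, 1000) x 3 target-rankability
  sets = 48 scenarios.  Per replicate, the rankability of the three binary
  components and of the 5-level ordinal composite are estimated with paired
  fixed/random fits; per scenario the means are compared to flag whether
  the composite beats every component.  An equal-prevalence variant sets
  all three prevalences to 0.10.

Aggregation utilities compute the fraction of scenarios in which the
composite dominates, per correlation level, and an OLS meta-regression of
the composite's mean rankability on the component rankabilities, hospital
volume and random-effect correlation.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from joblib import Parallel, delayed

from . import __version__
from .rankability import estimate_rankability
from .synthetic_data import (
    DEFAULT_RANKABILITY_SETS,
    CalibrationError,
    CalibrationResult,
    ScenarioA,
    ScenarioB,
    calibrate_tau,
    seed_sequence,
    simulate_binary_dataset,
    simulate_composite_dataset,
)

__all__ = [
    "ScenarioResultA",
    "ScenarioResultB",
    "MetaRegressionResult",
    "build_grid_A",
    "build_grid_B",
    "run_study",
    "summarize_by_correlation",
    "meta_regression",
    "write_report",
    "results_to_frame",
]

INDICATORS = ("y1", "y2", "y3", "ordinal")


@dataclass
class ScenarioResultA:
    scenario: ScenarioA
    mean_rho: float
    sd_rho: float
    n_converged: int


@dataclass
class ScenarioResultB:
    scenario: ScenarioB
    mean_rho: np.ndarray  # (y1, y2, y3, ordinal)
    sd_rho: np.ndarray
    composite_beats_all: bool
    composite_below_best: bool
    n_converged: int
    calibration: CalibrationResult | None = None
    error: str | None = None


@dataclass
class MetaRegressionResult:
    coefficients: dict  # name -> {"estimate", "se", "p_value"}
    r_squared: float
    adj_r_squared: float
    n_scenarios: int


# --------------------------------------------------------------------------
# grids


def build_grid_A(
    n_hospitals: int = 100, n_per_hospital: int = 500, n_reps: int = 100
) -> list[ScenarioA]:
    """Full factorial 13 ICC x 4 intercepts x 3 slopes = 156 scenarios."""
    iccs = np.round(np.arange(0.0, 0.2401, 0.02), 10)
    grid = [
        ScenarioA(icc=float(icc), alpha0=a0, alpha1=a1,
                  n_hospitals=n_hospitals, n_per_hospital=n_per_hospital, n_reps=n_reps)
        for icc in iccs
        for a0 in (-3.0, -2.0, -1.5, -1.0)
        for a1 in (-0.25, 0.0, 0.25)
    ]
    assert len(grid) == 156
    return grid


def build_grid_B(
    equal_prevalence: bool = False,
    correlations: tuple = (-0.25, -0.10, 0.0, 0.10, 0.25, 0.50, 0.75, 0.90),
    volumes: tuple = (500, 1000),
    rankability_sets: tuple = DEFAULT_RANKABILITY_SETS,
    n_hospitals: int = 100,
    n_reps: int = 100,
) -> list[ScenarioB]:
    """Composite-study grid: correlations x volumes x rankability sets."""
    prev = (0.10, 0.10, 0.10) if equal_prevalence else (0.05, 0.10, 0.25)
    return [
        ScenarioB(
            prevalences=prev,
            slopes=(-0.25, 0.50, 1.0),
            target_rankabilities=tuple(rset),
            re_correlation=float(r),
            n_hospitals=n_hospitals,
            n_per_hospital=int(v),
            n_reps=n_reps,
        )
        for r in correlations
        for v in volumes
        for rset in rankability_sets
    ]


# --------------------------------------------------------------------------
# study execution


def _run_rep_A(scenario: ScenarioA, seed_seq, include_x: bool, n_quad: int):
    df = simulate_binary_dataset(scenario, seed_seq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # exclusions are tallied in the fits
        return estimate_rankability(df, indicator="y1", include_x=include_x, n_quad=n_quad)


def _run_rep_B(scenario: ScenarioB, cal: CalibrationResult, seed_seq, include_x: bool, n_quad: int):
    df = simulate_composite_dataset(scenario, cal, seed_seq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return [
            estimate_rankability(df, indicator=ind, include_x=include_x, n_quad=n_quad)
            for ind in INDICATORS
        ]


def _component_keys(grid: list[ScenarioB]):
    """Unique per-component calibration keys, in a grid-order-independent order."""
    keys = set()
    for s in grid:
        for k in range(3):
            keys.add((s.target_rankabilities[k], s.prevalences[k], s.slopes[k],
                      s.n_hospitals, s.n_per_hospital))
    return {key: i for i, key in enumerate(sorted(keys))}


def run_study(
    grid: list,
    n_reps: int | None = None,
    master_seed: int = 0,
    workers: int = 1,
    calibration_method: str = "simulate",
    include_x: bool = True,
    n_quad: int = 15,
    n_cal_reps: int = 10,
) -> list:
    """Run a replicated study over a grid of ScenarioA or ScenarioB cells.

    Each component calibration is performed once (and shared between
    scenarios with the same marginal targets — the random-effect correlation
    does not enter the marginal calibration).  Replicate seeds are derived
    from ``(master_seed, scenario index, replicate)`` so results are
    identical for any worker count.  Replicates in which any required fit
    failed to converge are dropped from the scenario means and counted.
    """
    if not grid:
        return []
    if isinstance(grid[0], ScenarioA):
        return _run_study_A(grid, n_reps, master_seed, workers, include_x, n_quad)
    return _run_study_B(grid, n_reps, master_seed, workers, calibration_method,
                        include_x, n_quad, n_cal_reps)


def _run_study_A(grid, n_reps, master_seed, workers, include_x, n_quad):
    tasks = []
    for si, s in enumerate(grid):
        reps = n_reps if n_reps is not None else s.n_reps
        for rep in range(reps):
            tasks.append((si, s, seed_sequence(master_seed, si, rep)))
    if workers == 1:
        ests = [_run_rep_A(s, ss, include_x, n_quad) for _, s, ss in tasks]
    else:
        ests = Parallel(n_jobs=workers)(
            delayed(_run_rep_A)(s, ss, include_x, n_quad) for _, s, ss in tasks
        )
    results = []
    for si, s in enumerate(grid):
        rhos = [e.rho for (ti, _, _), e in zip(tasks, ests) if ti == si and e.converged]
        results.append(
            ScenarioResultA(
                scenario=s,
                mean_rho=float(np.mean(rhos)) if rhos else float("nan"),
                sd_rho=float(np.std(rhos, ddof=1)) if len(rhos) > 1 else float("nan"),
                n_converged=len(rhos),
            )
        )
    return results


def _run_study_B(grid, n_reps, master_seed, workers, calibration_method,
                 include_x, n_quad, n_cal_reps):
    key_index = _component_keys(grid)
    cal_cache: dict = {}
    for key, idx in sorted(key_index.items(), key=lambda kv: kv[1]):
        target_rank, prev, slope, K, n = key
        try:
            cal_cache[key] = calibrate_tau(
                target_rank, prev, slope, K, n,
                seed=seed_sequence(master_seed, 900_000 + idx),
                method=calibration_method,
                n_cal_reps=n_cal_reps,
                include_x=include_x,
            )
        except CalibrationError as exc:
            cal_cache[key] = exc

    results = []
    tasks = []
    scenario_cals: list = []
    for si, s in enumerate(grid):
        comps = [cal_cache[(s.target_rankabilities[k], s.prevalences[k], s.slopes[k],
                            s.n_hospitals, s.n_per_hospital)] for k in range(3)]
        failed = [c for c in comps if isinstance(c, CalibrationError)]
        if failed:
            scenario_cals.append(str(failed[0]))
            continue
        cal = CalibrationResult(
            alpha0=[c.alpha0 for c in comps],
            tau=[c.tau for c in comps],
            achieved_prevalences=[c.achieved_prevalence for c in comps],
            achieved_rankabilities=[c.achieved_rankability for c in comps],
            diagnostics={f"y{k + 1}": {"method": comps[k].method} for k in range(3)},
        )
        scenario_cals.append(cal)
        reps = n_reps if n_reps is not None else s.n_reps
        for rep in range(reps):
            tasks.append((si, s, cal, seed_sequence(master_seed, si, rep)))

    if workers == 1:
        all_ests = [_run_rep_B(s, cal, ss, include_x, n_quad) for _, s, cal, ss in tasks]
    else:
        all_ests = Parallel(n_jobs=workers)(
            delayed(_run_rep_B)(s, cal, ss, include_x, n_quad) for _, s, cal, ss in tasks
        )

    for si, s in enumerate(grid):
        cal = scenario_cals[si]
        if isinstance(cal, str):
            results.append(
                ScenarioResultB(
                    scenario=s,
                    mean_rho=np.full(4, np.nan),
                    sd_rho=np.full(4, np.nan),
                    composite_beats_all=False,
                    composite_below_best=False,
                    n_converged=0,
                    calibration=None,
                    error=cal,
                )
            )
            continue
        rep_rhos = [
            [e.rho for e in ests]
            for (ti, _, _, _), ests in zip(tasks, all_ests)
            if ti == si and all(e.converged for e in ests)
        ]
        arr = np.asarray(rep_rhos, dtype=float)
        if arr.size:
            mean_rho = arr.mean(axis=0)
            sd_rho = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.full(4, np.nan)
        else:
            mean_rho = np.full(4, np.nan)
            sd_rho = np.full(4, np.nan)
        beats_all = bool(arr.size and mean_rho[3] > mean_rho[:3].max())
        below_best = bool(arr.size and mean_rho[3] < mean_rho[:3].max())
        results.append(
            ScenarioResultB(
                scenario=s,
                mean_rho=mean_rho,
                sd_rho=sd_rho,
                composite_beats_all=beats_all,
                composite_below_best=below_best,
                n_converged=len(rep_rhos),
                calibration=cal,
            )
        )
    return results


# --------------------------------------------------------------------------
# aggregation


def results_to_frame(results: list) -> pd.DataFrame:
    """One row per scenario, stable column order, CSV-roundtrip safe."""
    if results and isinstance(results[0], ScenarioResultA):
        rows = [
            {
                "label": r.scenario.label(),
                "icc": r.scenario.icc,
                "alpha0": r.scenario.alpha0,
                "alpha1": r.scenario.alpha1,
                "n_hospitals": r.scenario.n_hospitals,
                "n_per_hospital": r.scenario.n_per_hospital,
                "mean_rho": r.mean_rho,
                "sd_rho": r.sd_rho,
                "n_converged": r.n_converged,
            }
            for r in results
        ]
        return pd.DataFrame(rows)
    rows = []
    for r in results:
        s = r.scenario
        row = {
            "label": s.label(),
            "re_correlation": s.re_correlation,
            "n_hospitals": s.n_hospitals,
            "n_per_hospital": s.n_per_hospital,
        }
        for k in range(3):
            row[f"prevalence_y{k + 1}"] = s.prevalences[k]
            row[f"slope_y{k + 1}"] = s.slopes[k]
            row[f"target_rank_y{k + 1}"] = s.target_rankabilities[k]
        for i, ind in enumerate(INDICATORS):
            row[f"mean_rho_{ind}"] = float(r.mean_rho[i])
        for i, ind in enumerate(INDICATORS):
            row[f"sd_rho_{ind}"] = float(r.sd_rho[i])
        row["composite_beats_all"] = bool(r.composite_beats_all)
        row["composite_below_best"] = bool(r.composite_below_best)
        row["n_converged"] = r.n_converged
        row["error"] = r.error or ""
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_by_correlation(results) -> pd.DataFrame:
    """Fraction of scenarios with composite dominance, per correlation level.

    Accepts a list of ScenarioResultB or the scenarios frame.  The final
    row (``re_correlation == 'all'``) is the overall fraction.
    """
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    if "re_correlation" not in df.columns:
        raise ValueError("summarize_by_correlation needs composite-study results")
    rows = []
    for r, grp in df.groupby("re_correlation"):
        rows.append(
            {
                "re_correlation": r,
                "n_scenarios": len(grp),
                "frac_composite_beats_all": grp["composite_beats_all"].mean(),
                "frac_composite_below_best": grp["composite_below_best"].mean(),
            }
        )
    rows.append(
        {
            "re_correlation": "all",
            "n_scenarios": len(df),
            "frac_composite_beats_all": df["composite_beats_all"].mean(),
            "frac_composite_below_best": df["composite_below_best"].mean(),
        }
    )
    return pd.DataFrame(rows)


_META_COLUMNS = ["intercept", "mean_rho_y1", "mean_rho_y2", "mean_rho_y3",
                 "volume_1000", "re_correlation"]


def meta_regression(results) -> MetaRegressionResult:
    """OLS of the composite's mean rankability on its scenario descriptors.

    Covariates: the three component mean rankabilities (continuous), an
    indicator for 1000 vs 500 patients per hospital, and the random-effect
    correlation (continuous).  Classical (homoskedastic) standard errors
    and t-test p-values are reported together with R^2 and adjusted R^2.
    """
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    df = df[df["n_converged"] > 0].copy()
    n = len(df)
    if n < 7:
        raise ValueError(f"need at least 7 scenarios, got {n}")
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "mean_rho_y1": df["mean_rho_y1"].to_numpy(),
            "mean_rho_y2": df["mean_rho_y2"].to_numpy(),
            "mean_rho_y3": df["mean_rho_y3"].to_numpy(),
            "volume_1000": (df["n_per_hospital"].to_numpy() == 1000).astype(float),
            "re_correlation": df["re_correlation"].to_numpy(dtype=float),
        }
    )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = [c for c in X.columns[1:]
               if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    y = df["mean_rho_ordinal"].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    coeffs = {
        name: {
            "estimate": float(fit.params[name]),
            "se": float(fit.bse[name]),
            "p_value": float(fit.pvalues[name]),
        }
        for name in _META_COLUMNS
    }
    return MetaRegressionResult(
        coefficients=coeffs,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        n_scenarios=n,
    )


# --------------------------------------------------------------------------
# reporting


def write_report(results: list, meta: MetaRegressionResult | None, path,
                 master_seed: int | None = None, elapsed: float | None = None) -> dict:
    """Write scenarios.csv, by_correlation.csv (Study B), meta.json and manifest.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    df = results_to_frame(results)
    written = {}
    df.to_csv(path / "scenarios.csv", index=False, lineterminator="\n")
    written["scenarios"] = str(path / "scenarios.csv")
    if results and isinstance(results[0], ScenarioResultB):
        summarize_by_correlation(df).to_csv(
            path / "by_correlation.csv", index=False, lineterminator="\n"
        )
        written["by_correlation"] = str(path / "by_correlation.csv")
    if meta is not None:
        with open(path / "meta.json", "w") as fh:
            json.dump(
                {
                    "coefficients": meta.coefficients,
                    "r_squared": meta.r_squared,
                    "adj_r_squared": meta.adj_r_squared,
                    "n_scenarios": meta.n_scenarios,
                },
                fh,
                indent=2,
            )
        written["meta"] = str(path / "meta.json")
    manifest = {
        "package_version": __version__,
        "master_seed": master_seed,
        "n_scenarios": len(results),
        "scenarios": [r.scenario.label() for r in results],
        "n_converged": {r.scenario.label(): r.n_converged for r in results},
        "elapsed_seconds": elapsed,
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    written["manifest"] = str(path / "manifest.json")
    return written
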