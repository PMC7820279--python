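"""Reproduction harnesses for the numerical experiments.

Two standard studies are provided:

* :func:`run_accuracy_sweep` — accuracy of the two-stage inference (equipartition
  stiffness, then Kalman MAP rheology) across a grid of total sampling times
  and sampling steps, both expressed in the process' own units: ``Ts/tau1``
  and ``dt/tau_S``.  Replicated per cell; reports the replicate mean and SD
  and the mean Hessian error of each parameter.

* :func:`run_fit_range_study` — the ACF fit-range study: one long series,
  its empirical ACF, and the model fitted over a set of nested lag ranges,
  reported as a table in mPa s / s with the best range flagged.

Per-replicate seeds follow a documented counter scheme: replicate ``r`` of
cell ``c`` under master seed ``s`` uses ``numpy.random.default_rng([s, c, r])``,
so results are deterministic given the master seed and invariant to the order
in which cells are executed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .acf import ACFSweepResult, empirical_acf, fit_range_sweep
from .kalman import fit_map
from .model import FluidTrapParams, Trajectory, timescales
from .simulate import SimConfig, simulate_trajectory
from .stiffness import estimate_stiffness

__all__ = [
    "STUDY_INPUT_PARAMS",
    "SweepConfig",
    "SweepResult",
    "FitRangeStudyResult",
    "run_accuracy_sweep",
    "run_fit_range_study",
    "DEFAULT_FIT_RANGES",
]

logger = logging.getLogger(__name__)

#: Input parameter set of the numerical study: a 1.95 um bead in a fluid with
#: solvent viscosity 1 mPa s, polymer viscosity 100 mPa s and relaxation time
#: 1 s, held by a 0.1 uN/m trap at 25 C.
STUDY_INPUT_PARAMS = FluidTrapParams(eta0=1e-3, eta1=0.1, tau1=1.0, k=1e-7)

#: Nested fit ranges (t_max in seconds) of the range study.
DEFAULT_FIT_RANGES = (0.1, 0.5, 1.0, 5.0, 10.0, 20.0, 30.0)


@dataclass
class SweepConfig:
    """Grid of normalized sampling conditions for the accuracy sweep."""

    ts_over_tau1: Sequence[float] = (50, 100, 200, 500, 1000, 2000)
    dt_over_tauS: Sequence[float] = (0.1, 0.5, 1.0, 2.0)
    replicates: int = 10
    seed: int = 0
    params: FluidTrapParams = STUDY_INPUT_PARAMS

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(v <= 0 for v in self.ts_over_tau1) or any(
            v <= 0 for v in self.dt_over_tauS
        ):
            raise ValueError("all grid values must be positive")


@dataclass
class SweepResult:
    """Aggregated sweep output.

    ``table`` has one row per (cell, parameter) with the replicate mean, the
    replicate standard deviation and the mean Hessian standard error, each
    normalized by the generating value.  ``failures`` lists cells whose fits
    raised, which are skipped rather than fatal.
    """

    table: pd.DataFrame
    provenance: dict
    failures: list = field(default_factory=list)


def _replicate_seed(master: int, cell: int, rep: int) -> list:
    return [int(master), int(cell), int(rep)]


def run_pipeline(
    traj: Trajectory, params_template: FluidTrapParams
) -> dict:
    """Two-stage inference on one trajectory: stiffness, then Kalman MAP.

    Returns the estimates normalized by nothing — raw physical units —
    together with the Hessian errors.
    """
    k_est = estimate_stiffness(traj.x, temperature=params_template.temperature)
    map_est = fit_map(
        traj.x,
        traj.dt,
        k_fixed=k_est.k_star,
        radius=params_template.radius,
        temperature=params_template.temperature,
    )
    return {
        "k": k_est.k_star,
        "k_err": k_est.std_error,
        "eta0": map_est.theta["eta0"],
        "eta1": map_est.theta["eta1"],
        "tau1": map_est.theta["tau1"],
        "eta0_err": map_est.std_errors["eta0"],
        "eta1_err": map_est.std_errors["eta1"],
        "tau1_err": map_est.std_errors["tau1"],
        "converged": map_est.converged,
    }


def run_accuracy_sweep(cfg: SweepConfig) -> SweepResult:
    """Replicate the accuracy study over the (Ts/tau1, dt/tau_S) grid."""
    params = cfg.params
    tau_s, tau1 = timescales(params)
    n_grid_points = sum(
        int(round(ts * tau1 / (r * tau_s)))
        for ts in cfg.ts_over_tau1
        for r in cfg.dt_over_tauS
    ) * cfg.replicates
    if n_grid_points > 1e8:
        logger.warning(
            "sweep will simulate %.2g total points; this may take long",
            n_grid_points,
        )
    truth = {"k": params.k, "eta0": params.eta0, "eta1": params.eta1,
             "tau1": params.tau1}
    rows = []
    failures = []
    cell = 0
    for ts_norm in cfg.ts_over_tau1:
        for dt_norm in cfg.dt_over_tauS:
            dt = dt_norm * tau_s
            n = int(round(ts_norm * tau1 / dt))
            reps = []
            for rep in range(cfg.replicates):
                sim_cfg = SimConfig(
                    params=params,
                    dt=dt,
                    n_samples=n,
                    seed=_replicate_seed(cfg.seed, cell, rep),
                )
                try:
                    traj = simulate_trajectory(sim_cfg)
                    reps.append(run_pipeline(traj, params))
                except Exception as exc:  # per-cell failures logged, not fatal
                    logger.warning(
                        "cell (Ts/tau1=%g, dt/tauS=%g) replicate %d failed: %s",
                        ts_norm, dt_norm, rep, exc,
                    )
                    failures.append((ts_norm, dt_norm, rep, str(exc)))
            if not reps:
                continue
            frame = pd.DataFrame(reps)
            for name in ("k", "eta0", "eta1", "tau1"):
                est = frame[name] / truth[name]
                rows.append(
                    {
                        "ts_over_tau1": ts_norm,
                        "dt_over_tauS": dt_norm,
                        "param": name,
                        "mean_norm": est.mean(),
                        "sd_norm": est.std(ddof=1) if len(est) > 1 else 0.0,
                        "mean_hessian_err_norm": (
                            frame[f"{name}_err"].mean() / truth[name]
                        ),
                        "replicates": len(est),
                    }
                )
            cell += 1
    table = pd.DataFrame(rows)
    provenance = {
        "seed": cfg.seed,
        "seed_scheme": "default_rng([seed, cell, replicate])",
        "params": {
            "eta0": params.eta0, "eta1": params.eta1, "tau1": params.tau1,
            "k": params.k, "radius": params.radius,
            "temperature": params.temperature,
        },
        "tau_S": tau_s,
    }
    return SweepResult(table=table, provenance=provenance, failures=failures)


@dataclass
class FitRangeStudyResult:
    """Output of the ACF fit-range study."""

    sweep: ACFSweepResult
    k_star: float  # stage-I stiffness used in all fits, N/m
    n_samples: int
    dt: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return self.sweep.to_frame()


def run_fit_range_study(
    seed: int,
    params: FluidTrapParams = STUDY_INPUT_PARAMS,
    ts_over_tau1: float = 2000.0,
    dt_over_tauS: float = 0.1,
    ranges: Sequence[float] = DEFAULT_FIT_RANGES,
) -> FitRangeStudyResult:
    """One long simulated series, its empirical ACF, and the fit-range sweep.

    Defaults reproduce the published study conditions (``Ts/tau1 = 2000``,
    ``dt/tau_S = 0.1``); smaller values allow quick structural checks.  The
    trap stiffness is estimated from the same series (stage I, uncentered —
    the simulation is zero-mean by construction) and held fixed in every fit.
    """
    tau_s, tau1 = timescales(params)
    dt = dt_over_tauS * tau_s
    n = int(round(ts_over_tau1 * tau1 / dt))
    traj = simulate_trajectory(
        SimConfig(params=params, dt=dt, n_samples=n, seed=_replicate_seed(seed, 0, 0))
    )
    k_est = estimate_stiffness(traj.x, temperature=params.temperature)
    max_lag = min(max(ranges) * 1.02, (n - 1) * dt * 0.5)
    acf = empirical_acf(traj.x, dt, max_lag=max_lag, center=False)
    sweep = fit_range_sweep(
        acf,
        k_fixed=k_est.k_star,
        ranges=[r for r in ranges if r <= max_lag],
        radius=params.radius,
        temperature=params.temperature,
    )
    return FitRangeStudyResult(
        sweep=sweep, k_star=k_est.k_star, n_samples=n, dt=dt, seed=seed
    )
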