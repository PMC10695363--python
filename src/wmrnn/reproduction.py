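"""Desk-scale reproduction of the headline simulation quantities.

Four experiment arms, all derived from one master seed:

* ``scalar_arm``  — 25-unit agents on Match-First (set 5, trial 4, scalar
  cues, original rewards) across the full checkpoint grid: learning
  trajectories (performance, SPC slope/residual), match-error shares,
  sorting-direction angles, and final-state PC variance.
* ``recency_arm`` — matched-seed agents trained under the recency-based
  reward scheme, evaluated at the 12k checkpoint.
* ``one_hot_arm`` — agents trained with one-hot cue encoding to 20k;
  per-replicate correlation of intercluster distances with paired
  match-error rates.
* ``grid_arm``    — a reduced size x experience grid for the
  residual-vs-performance correlation.

Replicate arms default to 10 independently seeded agents (the replicate
count used for all figure-level averages); the grid uses 3 seeds per cell.
Every value is computed from freshly trained agents at call time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .behavior import fit_spc, match_error_profile, serial_position_curve, spc_summary
from .experiments import (
    GridConfig,
    encoding_geometry_summary,
    evaluate_checkpoint,
    residual_performance_correlation,
    run_grid,
    train_run,
)
from .taskgen import TaskSpec
from .training import DEFAULT_CHECKPOINTS

REPLICATES = 10
GRID_REPLICATES = 3
N_TEST = 5000


@dataclass
class ScalarArm:
    """Per-replicate summaries of the scalar-encoding, original-reward runs."""

    trajectory: pd.DataFrame        # rows: (seed, n_ep) x performance/slope/residual
    theta12_20k: np.ndarray
    theta12_50k: np.ndarray
    share_lead2: np.ndarray         # % of X-1-X-1 errors with lead 2, per replicate
    share_lead5: np.ndarray
    variance_top3_50k: np.ndarray   # final-state top-3 PC variance per replicate
    stratified_slopes_20k: pd.DataFrame  # rows: seed, columns: target cue 1..5

    @property
    def performance_20k(self) -> np.ndarray:
        t = self.trajectory
        return t[t.n_ep == 20_000].sort_values("seed").performance.to_numpy()


def scalar_arm(
    master_seed: int,
    replicates: int = REPLICATES,
    n_test: int = N_TEST,
    checkpoints: tuple[int, ...] = DEFAULT_CHECKPOINTS,
) -> ScalarArm:
    spec = TaskSpec()
    cfg = GridConfig(
        spec=spec, sizes=(25,), checkpoints=checkpoints,
        replicates=replicates, master_seed=master_seed, n_test=n_test,
    )
    rows = []
    th20, th50, sh2, sh5, var3 = [], [], [], [], []
    strat_rows = []
    for rep in range(replicates):
        cks = train_run(cfg, 25, rep)
        for n_ep in sorted(set(checkpoints)):
            record = n_ep in (20_000, 50_000)
            log = evaluate_checkpoint(cfg, cks[n_ep], 25, rep, n_ep, record_states=record)
            summ = spc_summary(log, spec)
            rows.append(
                {"seed": rep, "n_ep": n_ep, "performance": summ["performance"],
                 "slope": summ["slope"], "residual": summ["residual"]}
            )
            if n_ep == 20_000:
                prof = match_error_profile(log, spec)
                sh2.append(prof.share(1, 2, "X-A-X-A"))
                sh5.append(prof.share(1, 5, "X-A-X-A"))
                sm = geometry.collect_states(log, 3, "correct")
                th20.append(geometry.sorting_geometry(sm).angles["theta_12"])
                srow = {"seed": rep}
                for A in range(1, spec.set_size + 1):
                    curve = serial_position_curve(log, spec, stratify=A)
                    srow[A] = fit_spc(curve).slope
                strat_rows.append(srow)
            if n_ep == 50_000:
                sm = geometry.collect_states(log, 3, "correct")
                th50.append(geometry.sorting_geometry(sm).angles["theta_12"])
                sm4 = geometry.collect_states(log, 4, "correct")
                _, var = geometry.pca_embed(sm4)
                var3.append(float(var[:3].sum()))
    return ScalarArm(
        trajectory=pd.DataFrame(rows),
        theta12_20k=np.asarray(th20),
        theta12_50k=np.asarray(th50),
        share_lead2=np.asarray(sh2),
        share_lead5=np.asarray(sh5),
        variance_top3_50k=np.asarray(var3),
        stratified_slopes_20k=pd.DataFrame(strat_rows).set_index("seed"),
    )


def recency_arm(
    master_seed: int, replicates: int = REPLICATES, n_test: int = N_TEST
) -> np.ndarray:
    """Test performance at the 12k checkpoint under the recency reward scheme."""
    spec = TaskSpec(reward_scheme="recency")
    cfg = GridConfig(
        spec=spec, sizes=(25,), checkpoints=(0, 12_000),
        replicates=replicates, master_seed=master_seed, n_test=n_test,
    )
    perfs = []
    for rep in range(replicates):
        cks = train_run(cfg, 25, rep)
        log = evaluate_checkpoint(cfg, cks[12_000], 25, rep, 12_000)
        perfs.append(log.performance)
    return np.asarray(perfs)


def one_hot_arm(
    master_seed: int, replicates: int = REPLICATES, n_test: int = N_TEST
) -> pd.DataFrame:
    """Distance-error correlations for one-hot-encoded agents at 20k."""
    spec = TaskSpec(encoding="one_hot")
    cfg = GridConfig(
        spec=spec, sizes=(25,), checkpoints=(0, 20_000),
        replicates=replicates, master_seed=master_seed, n_test=n_test,
    )
    return encoding_geometry_summary(cfg, 20_000)


def grid_arm(
    master_seed: int,
    scalar: ScalarArm | None = None,
    replicates: int = GRID_REPLICATES,
    n_test: int = N_TEST,
) -> tuple[pd.DataFrame, float]:
    """Reduced size x experience grid; returns (cells table, correlation).

    Sizes {10, 25, 50} x checkpoints {0, 10, 20, 50}k x ``replicates``
    seeds.  When a scalar-arm result is supplied, its first replicates stand
    in for the 25-unit runs (same task configuration and seed scheme).
    """
    checkpoints = (0, 10_000, 20_000, 50_000)
    sizes = (10, 50) if scalar is not None else (10, 25, 50)
    cfg = GridConfig(
        spec=TaskSpec(), sizes=sizes, checkpoints=checkpoints,
        replicates=replicates, master_seed=master_seed, n_test=n_test,
    )
    table = run_grid(cfg)
    if scalar is not None:
        reuse = scalar.trajectory[
            (scalar.trajectory.seed < replicates)
            & scalar.trajectory.n_ep.isin(checkpoints)
        ].copy()
        reuse["n_units"] = 25
        table = pd.concat(
            [table, reuse[["seed", "n_units", "n_ep", "performance", "slope", "residual"]]],
            ignore_index=True,
        )
    return table, residual_performance_correlation(table)


@dataclass
class Reproduction:
    scalar: ScalarArm
    recency_perf_12k: np.ndarray
    one_hot: pd.DataFrame
    grid_table: pd.DataFrame
    grid_correlation: float

    def targets(self) -> dict[str, dict]:
        """Headline quantities in the units the figures report."""
        sc = self.scalar
        n_rep = len(sc.theta12_20k)
        best = int(np.argmax(
            sc.trajectory[sc.trajectory.n_ep == 50_000]
            .sort_values("seed").performance.to_numpy()
        ))
        n_cells = len(self.grid_table.groupby(["n_units", "n_ep"]))
        return {
            "t1": {"value": 100.0 * float(sc.performance_20k.mean()), "n": n_rep},
            "t2": {"value": 100.0 * float(self.recency_perf_12k.mean()),
                   "n": len(self.recency_perf_12k)},
            "t3": {"value": float(sc.theta12_20k.mean()), "n": n_rep},
            "t4": {"value": float(sc.theta12_50k.mean()), "n": n_rep},
            "t5": {"value": float(self.one_hot.pearson_r.mean()),
                   "n": len(self.one_hot)},
            "t6": {"value": 100.0 * float(sc.variance_top3_50k[best]), "n": n_rep},
            "t7": {"value": float(np.nanmean(sc.share_lead2)), "n": n_rep},
            "t8": {"value": float(self.grid_correlation), "n": n_cells},
        }


def reproduce(master_seed: int, replicates: int = REPLICATES,
              grid_replicates: int = GRID_REPLICATES,
              n_test: int = N_TEST) -> Reproduction:
    """Run all four arms from scratch under one master seed."""
    sc = scalar_arm(master_seed, replicates, n_test)
    rec = recency_arm(master_seed, replicates, n_test)
    oh = one_hot_arm(master_seed, replicates, n_test)
    grid_table, grid_r = grid_arm(master_seed, sc, grid_replicates, n_test)
    return Reproduction(
        scalar=sc, recency_perf_12k=rec, one_hot=oh,
        grid_table=grid_table, grid_correlation=grid_r,
    )
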