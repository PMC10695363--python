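"""Orchestration: size x experience grids, scheme and encoding comparisons.

These drivers train replicate agents across network sizes and training
checkpoints, evaluate each checkpoint on frozen-parameter test episodes,
and assemble tidy long-form tables (one row per seed x size x checkpoint)
of performance, SPC slope/residual, and geometry summaries.  Replicates are
seeded deterministically from one master seed; the seed of a run does not
depend on the reward scheme, so original-vs-recency comparisons are over
matched seeds (identical initialisation and trial streams).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, geometry
from .lstm import AgentParams, load_checkpoint, save_checkpoint
from .taskgen import TaskSpec
from .training import DEFAULT_CHECKPOINTS, EpisodeLog, TrainConfig, evaluate, train

_TASK_CODE = {"same_different": 1, "match_first": 2, "match_any": 3}
_ENC_CODE = {"scalar": 1, "one_hot": 2}


def run_seed(master_seed: int, spec: TaskSpec, n_units: int, replicate: int):
    """Deterministic per-run seed; independent of the reward scheme."""
    return np.random.SeedSequence(
        [
            int(master_seed),
            _TASK_CODE[spec.task],
            spec.set_size,
            spec.trial_size,
            _ENC_CODE[spec.encoding],
            int(n_units),
            int(replicate),
        ]
    )


def eval_seed(run_ss: np.random.SeedSequence, n_ep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(list(run_ss.entropy) + [7, int(n_ep)])


@dataclass(frozen=True)
class GridConfig:
    """A size x experience grid of training runs.

    Defaults target the desk-scale Match-First configuration; the full
    published-scale grid (sizes up to 500, 10 replicates) is reachable by
    configuration.
    """

    spec: TaskSpec = field(default_factory=TaskSpec)
    sizes: tuple[int, ...] = (25,)
    checkpoints: tuple[int, ...] = DEFAULT_CHECKPOINTS
    replicates: int = 5
    master_seed: int = 0
    n_test: int = 5000
    train_config: TrainConfig | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.sizes or not self.checkpoints:
            raise ValueError("sizes and checkpoints must be nonempty")

    def resolved_train_config(self) -> TrainConfig:
        base = self.train_config or TrainConfig()
        return dataclasses.replace(
            base, checkpoint_episodes=tuple(sorted(set(self.checkpoints)))
        )


def train_run(
    config: GridConfig, n_units: int, replicate: int, outdir: Path | None = None
) -> dict[int, AgentParams]:
    """Train (or reload) one replicate, returning its checkpoint snapshots."""
    tc = config.resolved_train_config()
    ss = run_seed(config.master_seed, config.spec, n_units, replicate)
    if outdir is not None:
        rundir = Path(outdir) / f"n{n_units}_r{replicate}_{config.spec.reward_scheme}"
        if rundir.exists():
            cks = {}
            for f in sorted(rundir.glob("ck_*.npz")):
                p = load_checkpoint(f)
                cks[int(p.meta["n_ep"])] = p
            if set(cks) >= set(config.checkpoints):
                return cks
        rundir.mkdir(parents=True, exist_ok=True)
    checkpoints = train(config.spec, n_units, tc, seed=ss)
    if outdir is not None:
        for ep, p in checkpoints.items():
            save_checkpoint(rundir / f"ck_{ep:06d}.npz", p)
    return checkpoints


def evaluate_checkpoint(
    config: GridConfig,
    params: AgentParams,
    n_units: int,
    replicate: int,
    n_ep: int,
    record_states: bool = False,
) -> EpisodeLog:
    ss = run_seed(config.master_seed, config.spec, n_units, replicate)
    return evaluate(
        params,
        config.spec,
        n_test=config.n_test,
        record_states=record_states,
        seed=eval_seed(ss, n_ep),
    )


def run_grid(config: GridConfig, outdir: Path | None = None) -> pd.DataFrame:
    """Train and evaluate every (size, replicate, checkpoint) cell.

    Returns a long-form table; with ``outdir`` set, checkpoints and per-run
    metric rows are persisted and reloaded, so an interrupted grid resumes
    to an identical table.
    """
    rows = []
    spec = config.spec
    for n_units in config.sizes:
        for rep in range(config.replicates):
            metrics_file = None
            if outdir is not None:
                metrics_file = (
                    Path(outdir)
                    / f"n{n_units}_r{rep}_{spec.reward_scheme}"
                    / "metrics.csv"
                )
                if metrics_file.exists():
                    rows.append(pd.read_csv(metrics_file))
                    continue
            try:
                checkpoints = train_run(config, n_units, rep, outdir=outdir)
            except Exception as err:  # record the failure, keep the grid going
                rows.append(
                    pd.DataFrame(
                        [{"seed": rep, "n_units": n_units, "error": str(err)}]
                    )
                )
                continue
            run_rows = []
            for n_ep in sorted(set(config.checkpoints)):
                log = evaluate_checkpoint(config, checkpoints[n_ep], n_units, rep, n_ep)
                summ = behavior.spc_summary(log, spec)
                run_rows.append(
                    {
                        "seed": rep,
                        "n_units": n_units,
                        "n_ep": n_ep,
                        "task": spec.task,
                        "set_size": spec.set_size,
                        "trial_size": spec.trial_size,
                        "encoding": spec.encoding,
                        "scheme": spec.reward_scheme,
                        "performance": summ["performance"],
                        "slope": summ["slope"],
                        "residual": summ["residual"],
                        "hit_rate": summ["hit_rate"],
                    }
                )
            frame = pd.DataFrame(run_rows)
            if metrics_file is not None:
                frame.to_csv(metrics_file, index=False)
            rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def aggregate(table: pd.DataFrame, by=("n_units", "n_ep")) -> pd.DataFrame:
    """Mean and SEM over replicates for each grid cell."""
    metrics = [c for c in ("performance", "slope", "residual", "hit_rate") if c in table]
    g = table.groupby(list(by))[metrics]
    out = g.agg(["mean", "sem"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()


def residual_performance_correlation(table: pd.DataFrame) -> float:
    """Pearson r between mean residual and mean performance across cells."""
    cells = aggregate(table)
    r = np.corrcoef(cells["residual_mean"], cells["performance_mean"])[0, 1]
    return float(r)


def compare_reward_schemes(
    base: GridConfig, checkpoints: tuple[int, ...] | None = None
) -> pd.DataFrame:
    """Paired original-vs-recency learning curves with matched seeds.

    Returns the concatenated long-form tables of both schemes (the run seed
    ignores the scheme, so replicate k shares its initialisation and trial
    stream across schemes).
    """
    if base.spec.task != "match_first":
        raise ValueError("reward-scheme comparison is defined for match_first")
    cks = checkpoints or base.checkpoints
    tables = []
    for scheme in ("original", "recency"):
        spec = dataclasses.replace(base.spec, reward_scheme=scheme)
        cfg = dataclasses.replace(base, spec=spec, checkpoints=tuple(cks))
        tables.append(run_grid(cfg))
    out = pd.concat(tables, ignore_index=True)
    if set(out[out.scheme == "original"].seed) != set(out[out.scheme == "recency"].seed):
        raise ValueError("unmatched replicate sets across schemes")
    return out


def encoding_geometry_summary(
    config: GridConfig, n_ep: int, fold_angles: bool | None = None
) -> pd.DataFrame:
    """Per-replicate error profiles and distance-error correlations.

    For each replicate at checkpoint ``n_ep``: evaluate with state
    recording, build the lead-cue cluster geometry (states after the first
    3 cues on correct trials, top-3 PC space), and correlate intercluster
    distances with paired match-error rates.  Returns one row per replicate
    with the Pearson r/p, top-3 variance, and sorting angles; the per-seed
    error-profile tables are attached in the ``profile`` column.
    """
    spec = config.spec
    if fold_angles is None:
        fold_angles = spec.encoding == "one_hot"
    rows = []
    for n_units in config.sizes:
        for rep in range(config.replicates):
            checkpoints = train_run(config, n_units, rep)
            log = evaluate_checkpoint(
                config, checkpoints[n_ep], n_units, rep, n_ep, record_states=True
            )
            profile = behavior.match_error_profile(log, spec)
            sm = geometry.collect_states(log, after_cue=3, filter="correct")
            geo = geometry.sorting_geometry(sm, fold=fold_angles)
            values, D = geometry.intercluster_distances(
                geo.embedding, sm.labels["cue1"].to_numpy()
            )
            r, p, degenerate = geometry.distance_error_correlation(values, D, profile)
            rows.append(
                {
                    "seed": rep,
                    "n_units": n_units,
                    "n_ep": n_ep,
                    "encoding": spec.encoding,
                    "performance": log.performance,
                    "pearson_r": r,
                    "pearson_p": p,
                    "degenerate": degenerate,
                    "variance_top3": geo.variance_top3,
                    **geo.angles,
                    "profile": profile,
                }
            )
    return pd.DataFrame(rows)


def compare_encodings(
    scalar_config: GridConfig, one_hot_config: GridConfig, n_ep: int
) -> dict[str, pd.DataFrame]:
    """Behavior + geometry summaries for scalar vs one-hot cue encodings.

    Returns per-encoding replicate tables plus aggregate error-profile
    shares (mean over replicates per target/lead/category).
    """
    out = {}
    for name, cfg in (("scalar", scalar_config), ("one_hot", one_hot_config)):
        summary = encoding_geometry_summary(cfg, n_ep)
        shares = pd.concat(
            [p.table.assign(seed=s) for p, s in zip(summary["profile"], summary["seed"])],
            ignore_index=True,
        )
        agg = (
            shares.groupby(["target_cue", "lead_cue", "category"])["percent"]
            .mean()
            .reset_index()
        )
        out[name] = summary
        out[f"{name}_profile"] = agg
    return out


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------


def load_config(path) -> GridConfig:
    """Build a GridConfig from a YAML file with ``task``/``train``/``grid`` blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    spec = TaskSpec(**raw.get("task", {}))
    train_cfg = TrainConfig(**raw.get("train", {})) if "train" in raw else None
    grid = raw.get("grid", {})
    return GridConfig(
        spec=spec,
        sizes=tuple(grid.get("sizes", (25,))),
        checkpoints=tuple(grid.get("checkpoints", DEFAULT_CHECKPOINTS)),
        replicates=int(grid.get("replicates", 5)),
        master_seed=int(grid.get("master_seed", 0)),
        n_test=int(grid.get("n_test", 5000)),
        train_config=train_cfg,
    )
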