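"""Figure-level experiment orchestration.

Each experiment trains networks over an ensemble of behavioral matrices and
a grid of hidden sizes, then writes tidy CSV tables, a JSON summary, and a
manifest (config + master seed) to an output directory.  Rerunning with an
identical config reproduces every number, since all per-run seeds are
derived deterministically from the master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .behaviors import (
    BehavioralMatrix,
    describe,
    generate_modular_matrix,
    generate_random_matrix,
    save_matrix,
)
from .capacity import estimate_R_robust, sweep_fraction_learned
from .information import state_dependency_curve
from .network import TrainingConfig
from .perturbation import robustness_curve

__all__ = ["ExperimentConfig", "run_experiment", "summarize"]

EXPERIMENTS = (
    "sparsity_sweep",
    "modularity_sweep",
    "size_scaling",
    "robustness",
    "deactivation",
    "pair_activation",
    "state_dependency",
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one experiment.

    ``k_values`` drives sparsity experiments; ``sigma_values`` (with
    ``n_modules``) drives modularity experiments; ``sizes`` drives size
    scaling.  Any ensemble axis left at its default contributes a single
    condition.
    """

    experiment: str
    N: int = 100
    M: int = 100
    k_values: tuple[int, ...] = (10,)
    n_modules: int | None = None
    sigma_values: tuple[int, ...] = (0,)
    sizes: tuple[int, ...] = ()
    R_grid: tuple[int, ...] = ()
    replicates: int = 10
    epochs: int = 100_000
    learning_rate: float = 10.0
    momentum: float = 0.9
    master_seed: int = 0
    max_pairs: int | None = 200

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        if not self.R_grid:
            raise ValueError("R_grid must be non-empty")

    def training_config(self, seed: int) -> TrainingConfig:
        return TrainingConfig(
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            seed=seed,
        )

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _ensemble(
    cfg: ExperimentConfig, N: int, M: int, k: int, sigma: int | None, seed: int
) -> list[BehavioralMatrix]:
    mats = []
    for r in range(cfg.replicates):
        s = seed + 104729 * r
        if cfg.n_modules is None or sigma is None:
            mats.append(generate_random_matrix(N, M, k, seed=s))
        else:
            mats.append(generate_modular_matrix(N, M, k, cfg.n_modules, sigma, seed=s))
    return mats


def _conditions(cfg: ExperimentConfig):
    """Yield (label, N, M, k, sigma) tuples for the experiment's ensemble axis."""
    if cfg.experiment == "sparsity_sweep":
        for k in cfg.k_values:
            yield f"k={k}", cfg.N, cfg.M, k, None
    elif cfg.experiment == "size_scaling":
        for size in cfg.sizes or (cfg.N,):
            for sigma in cfg.sigma_values:
                yield f"N=M={size},sigma={sigma}", size, size, cfg.k_values[0], sigma
    else:
        for k in cfg.k_values:
            for sigma in cfg.sigma_values:
                label = f"k={k},sigma={sigma}" if cfg.n_modules else f"k={k}"
                yield label, cfg.N, cfg.M, k, (sigma if cfg.n_modules else None)


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path) -> Path:
    """Run one experiment and write its result bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    summary: dict = {"experiment": cfg.experiment, "conditions": {}}
    for ci, (label, N, M, k, sigma) in enumerate(_conditions(cfg)):
        seed = cfg.master_seed + 15485863 * ci
        mats = _ensemble(cfg, N, M, k, sigma, seed)
        mu = float(np.mean([describe(m).modularity_mu for m in mats]))
        save_matrix(mats[0], out / f"matrix_{ci}_{label.replace('=', '').replace(',', '_')}.csv")
        tcfg = cfg.training_config(seed)
        cond: dict = {"label": label, "realized_modularity": mu}
        if cfg.experiment in ("sparsity_sweep", "modularity_sweep", "size_scaling"):
            sweep = sweep_fraction_learned(mats, cfg.R_grid, tcfg)
            for R, vals in zip(sweep.R_grid, sweep.values):
                for rep, v in enumerate(vals):
                    rows.append(dict(condition=label, R=R, replicate=rep,
                                     fraction_learned=v))
            cond.update(R_c=sweep.R_c, mean_fraction=sweep.mean_fraction_learned,
                        per_matrix_Rc=sweep.per_matrix_Rc)
        elif cfg.experiment in ("robustness", "deactivation", "pair_activation"):
            mode = {"robustness": "activate", "deactivation": "deactivate",
                    "pair_activation": "activate_pair"}[cfg.experiment]
            curve = robustness_curve(mats, cfg.R_grid, mode, tcfg,
                                     max_pairs=cfg.max_pairs)
            for R, vals in zip(curve["R_grid"], curve["values"]):
                for rep, v in enumerate(vals):
                    rows.append(dict(condition=label, R=R, replicate=rep,
                                     robustness=v))
            cond.update(mean_robustness=curve["mean_robustness"],
                        R_robust=estimate_R_robust(curve))
        else:  # state_dependency
            curve = state_dependency_curve(mats, cfg.R_grid, tcfg)
            for R, vals in zip(curve["R_grid"], curve["values"]):
                for rep, v in enumerate(vals):
                    rows.append(dict(condition=label, R=R, replicate=rep,
                                     mi_bits=v))
            cond.update(mean_mi_bits=curve["mean_mi_bits"])
        summary["conditions"][label] = cond
    pd.DataFrame(rows).to_csv(out / "results.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    manifest = {"config": asdict(cfg), "digest": cfg.digest(), "version": 1}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def summarize(results_dir: str | Path) -> pd.DataFrame:
    """Aggregate a completed bundle into one row per (condition, R)."""
    d = Path(results_dir)
    manifest = d / "manifest.json"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.json in {d}")
    df = pd.read_csv(d / "results.csv")
    value_col = [c for c in df.columns if c not in ("condition", "R", "replicate")][0]
    agg = (
        df.groupby(["condition", "R"])[value_col]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": f"{value_col}_mean", "std": f"{value_col}_sd"})
    )
    return agg
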