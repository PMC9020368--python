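"""Critical bottleneck size estimation.

``R_c`` is the smallest hidden-layer size whose mean fraction of behaviors
learned (over replicate behavioral matrices) reaches the 98% accuracy
threshold.  ``R_robust`` is the analogous threshold on mean robustness to
single-unit forced activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .behaviors import BehavioralMatrix
from .network import TrainingConfig, train

__all__ = [
    "SweepResult",
    "estimate_Rc",
    "estimate_R_robust",
    "minimal_bottleneck",
    "sweep_fraction_learned",
]


def minimal_bottleneck(N: int) -> int:
    """Information-theoretic lower bound on the hidden size.

    A binary hidden code of R units can address at most 2**R distinct
    behaviors, so representing N of them needs at least ceil(log2 N) units
    (7 for N = 100).  Trained networks need substantially more.
    """
    if N < 1:
        raise ValueError("N must be positive")
    return int(np.ceil(np.log2(N))) if N > 1 else 0

#: Sentinel returned when no grid point reaches the threshold.
NOT_REACHED = "not reached"


@dataclass
class SweepResult:
    """Fraction of behaviors learned versus hidden-layer size.

    ``per_matrix_Rc`` holds, for each replicate matrix, the smallest grid R
    at which that matrix individually crossed the threshold (or None); the
    headline ``R_c`` thresholds the mean curve.
    """

    R_grid: list[int]
    mean_fraction_learned: list[float]
    sd_fraction_learned: list[float]
    values: list[list[float]]  # per R, per replicate
    threshold: float
    replicates: int
    R_c: int | str = NOT_REACHED
    per_matrix_Rc: list[int | None] = field(default_factory=list)
    failures: list[tuple[int, int]] = field(default_factory=list)


def sweep_fraction_learned(
    ensemble: Sequence[BehavioralMatrix],
    R_grid: Sequence[int],
    config: TrainingConfig = TrainingConfig(),
) -> SweepResult:
    """Train one network per (R, matrix) cell and average fraction learned.

    Replicate seeds are derived deterministically from ``config.seed``.
    Training failures are recorded per cell and excluded from the mean.
    """
    if len(ensemble) == 0 or len(R_grid) == 0:
        raise ValueError("ensemble and R_grid must be non-empty")
    R_grid = sorted(int(R) for R in R_grid)
    values: list[list[float]] = []
    failures: list[tuple[int, int]] = []
    for R in R_grid:
        row = []
        for j, mat in enumerate(ensemble):
            cfg = TrainingConfig(**{**config.__dict__, "seed": config.seed + 7919 * j})
            try:
                row.append(train(mat, R, cfg).fraction_learned)
            except Exception:
                failures.append((R, j))
                row.append(np.nan)
        values.append(row)
    arr = np.array(values)
    mean = np.nanmean(arr, axis=1)
    sd = np.nanstd(arr, axis=1)
    per_matrix: list[int | None] = []
    for j in range(len(ensemble)):
        crossed = [R for R, v in zip(R_grid, arr[:, j]) if v >= config.accuracy_target]
        per_matrix.append(min(crossed) if crossed else None)
    result = SweepResult(
        R_grid=list(R_grid),
        mean_fraction_learned=mean.tolist(),
        sd_fraction_learned=sd.tolist(),
        values=arr.tolist(),
        threshold=config.accuracy_target,
        replicates=len(ensemble),
        per_matrix_Rc=per_matrix,
        failures=failures,
    )
    result.R_c = estimate_Rc(result, config.accuracy_target)
    return result


def estimate_Rc(sweep: SweepResult, threshold: float = 0.98) -> int | str:
    """Smallest grid R whose mean fraction learned reaches the threshold."""
    if not sweep.R_grid:
        raise ValueError("empty sweep")
    for R, frac in zip(sweep.R_grid, sweep.mean_fraction_learned):
        if frac >= threshold:
            return int(R)
    return NOT_REACHED


def estimate_R_robust(
    robustness_by_R: dict | Sequence[tuple[int, float]],
    threshold: float = 0.98,
) -> int | str:
    """Smallest R whose mean robustness reaches the threshold.

    Accepts either the dict produced by
    :func:`bottlenet.perturbation.robustness_curve` or (R, robustness) pairs.
    """
    if isinstance(robustness_by_R, dict):
        pairs = list(zip(robustness_by_R["R_grid"], robustness_by_R["mean_robustness"]))
    else:
        pairs = [(int(R), float(v)) for R, v in robustness_by_R]
    if not pairs:
        raise ValueError("empty robustness curve")
    for R, v in sorted(pairs):
        if v >= threshold:
            return int(R)
    return NOT_REACHED
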