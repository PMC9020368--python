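"""State-dependency: mutual information under forced activation.

After forcing a hidden unit, each of the ``N`` one-hot commands maps to some
binarized output row.  Three things can happen to a command: its original
output is preserved; it lands on a *different* member of the original output
set (stereotypy); or it lands on a novel row, which carries no information
about the input.  With uniform priors P(x) = 1/N, P(y) = 1/M over the
original outputs, the mutual information between intended behavior and
perturbed output has the closed form

    I(X; Y) = (1/M) * sum over original outputs with n_i > 0 of log2(N / n_i)

where ``n_i`` counts the inputs mapped onto original output ``y_i``.  When
there is no stereotypy (every ``n_i`` is 0 or 1) this reduces to
``(m/M) log2 N`` with ``m`` the number of conserved outputs — i.e. MI is
proportional to robustness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .behaviors import BehavioralMatrix
from .network import TrainingConfig, network_outputs, train
from .perturbation import PerturbationSpec, all_perturbed_outputs

__all__ = [
    "MappingCensus",
    "census",
    "mutual_information",
    "mean_mutual_information",
    "state_dependency_curve",
]


@dataclass(frozen=True)
class MappingCensus:
    """How perturbed outputs redistribute over the original output set.

    ``n_i[i]`` — number of inputs whose perturbed output equals original
    output row ``i``; ``novel_count`` — inputs mapped to rows outside the
    original output set.  ``M_outputs`` is the size of the original output
    set (equal to ``N_inputs`` under the perfect-learning premise), not the
    number of motor units.
    """

    n_i: tuple[int, ...]
    novel_count: int
    N_inputs: int
    M_outputs: int

    def __post_init__(self) -> None:
        if sum(self.n_i) + self.novel_count != self.N_inputs:
            raise ValueError("census does not account for every input")


def census(original_outputs: np.ndarray, perturbed_outputs: np.ndarray) -> MappingCensus:
    """Match each perturbed output row against the original output set.

    ``original_outputs`` rows must be distinct (the perfect-learning
    premise); duplicate rows raise.
    """
    O = np.asarray(original_outputs)
    P = np.asarray(perturbed_outputs)
    if O.shape != P.shape:
        raise ValueError("original and perturbed outputs must have equal shape")
    if len({r.tobytes() for r in O}) != O.shape[0]:
        raise ValueError("original output rows must be distinct")
    index = {r.tobytes(): i for i, r in enumerate(O)}
    n = [0] * O.shape[0]
    novel = 0
    for row in P:
        i = index.get(row.tobytes())
        if i is None:
            novel += 1
        else:
            n[i] += 1
    return MappingCensus(
        n_i=tuple(n),
        novel_count=novel,
        N_inputs=P.shape[0],
        M_outputs=O.shape[0],
    )


def mutual_information(c: MappingCensus) -> float:
    """Closed-form MI in bits: ``(1/M) * sum_{n_i > 0} log2(N / n_i)``."""
    return sum(
        math.log2(c.N_inputs / n) for n in c.n_i if n > 0
    ) / c.M_outputs


def mean_mutual_information(params, mechanism: str = "clamp") -> float:
    """MI averaged over forced activation of each hidden unit of one network.

    When learning is imperfect the unperturbed outputs can collide; the
    original output set is then the distinct rows, and ``n_i`` counts
    perturbed rows landing on each of them.
    """
    Y0 = network_outputs(params)
    seen: dict[bytes, int] = {}
    keep = []
    for i, row in enumerate(Y0):
        b = row.tobytes()
        if b not in seen:
            seen[b] = i
            keep.append(i)
    O = Y0[keep]
    R = params.shape[1]
    vals = []
    for u in range(R):
        spec = PerturbationSpec("activate", (u,), mechanism)
        Yp = all_perturbed_outputs(params, spec)
        index = {r.tobytes(): i for i, r in enumerate(O)}
        n = [0] * O.shape[0]
        novel = 0
        for row in Yp:
            j = index.get(row.tobytes())
            if j is None:
                novel += 1
            else:
                n[j] += 1
        c = MappingCensus(
            n_i=tuple(n), novel_count=novel,
            N_inputs=Yp.shape[0], M_outputs=O.shape[0],
        )
        vals.append(mutual_information(c))
    return float(np.mean(vals))


def state_dependency_curve(
    ensemble: Sequence[BehavioralMatrix],
    R_grid: Sequence[int],
    config: TrainingConfig = TrainingConfig(),
) -> dict:
    """Mean MI (with dispersion) per hidden size over an ensemble.

    For each R and matrix: train, force each hidden unit on in turn, compute
    the closed-form MI against the network's own unperturbed outputs, and
    average over units and matrices.
    """
    if len(ensemble) == 0 or len(R_grid) == 0:
        raise ValueError("ensemble and R_grid must be non-empty")
    means, sds, values, failures = [], [], [], []
    for R in R_grid:
        vals = []
        for j, mat in enumerate(ensemble):
            cfg = TrainingConfig(**{**config.__dict__, "seed": config.seed + 7919 * j})
            try:
                out = train(mat, R, cfg)
            except Exception:
                failures.append((R, j))
                continue
            vals.append(mean_mutual_information(out.params))
        values.append(vals)
        means.append(float(np.mean(vals)) if vals else np.nan)
        sds.append(float(np.std(vals)) if vals else np.nan)
    return {
        "R_grid": list(R_grid),
        "mean_mi_bits": means,
        "sd_mi_bits": sds,
        "values": values,
        "failures": failures,
    }
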