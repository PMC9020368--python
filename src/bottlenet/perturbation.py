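"""Forced activation/silencing of hidden units and robustness measures.

Mimics optogenetic perturbation of descending neurons: a trained network is
re-run with one hidden unit (or a pair) forced fully on or fully off, and
the binarized motor outputs are compared with the unperturbed ones.  A
behavioral command is *conserved* when its output row is unchanged; the
robustness of a perturbation is the fraction of conserved commands.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np

from .behaviors import BehavioralMatrix
from .network import NetworkParameters, TrainingConfig, _sigmoid, binarize, train

__all__ = [
    "PerturbationSpec",
    "PerturbationOutcome",
    "affected_distribution",
    "all_perturbed_outputs",
    "evaluate_perturbation",
    "perturb_forward",
    "robustness_curve",
]

Mode = Literal["activate", "deactivate", "activate_pair"]
Mechanism = Literal["clamp", "weight_injection"]

#: Magnitude used for the weight-injection mechanism: the incoming weights of
#: the forced unit are set to +/- this value, saturating its sigmoid.
INJECTION_VALUE = 1e3


@dataclass(frozen=True)
class PerturbationSpec:
    """Which hidden unit(s) to force, in which direction, and how."""

    mode: Mode
    units: tuple[int, ...]
    mechanism: Mechanism = "clamp"

    def __post_init__(self) -> None:
        units = tuple(int(u) for u in self.units)
        object.__setattr__(self, "units", units)
        if self.mode == "activate_pair":
            if len(units) != 2 or units[0] == units[1]:
                raise ValueError("activate_pair needs exactly two distinct units")
        elif len(units) != 1:
            raise ValueError(f"mode {self.mode!r} takes exactly one unit")

    @property
    def forced_value(self) -> float:
        return 0.0 if self.mode == "deactivate" else 1.0


@dataclass
class PerturbationOutcome:
    """Effect of one perturbation on all N behavioral commands.

    ``flip_map`` is ``N x M`` over {-1, 0, +1}: -1 where a motor unit that
    was on turned off, +1 where one turned on, 0 unchanged.
    """

    flip_map: np.ndarray
    conserved: np.ndarray
    robustness: float
    affected_count: int
    conserved_active_only: np.ndarray | None = None
    robustness_active_only: float | None = None


def _check_units(params: NetworkParameters, spec: PerturbationSpec) -> None:
    R = params.shape[1]
    for u in spec.units:
        if not 0 <= u < R:
            raise ValueError(f"hidden unit {u} outside [0, {R})")


def _perturbed_hidden(params: NetworkParameters, spec: PerturbationSpec) -> np.ndarray:
    """Hidden activations for all commands under the forced perturbation."""
    if spec.mechanism == "clamp":
        H = _sigmoid(params.W1 - params.B1)
        H[:, list(spec.units)] = spec.forced_value
        return H
    # weight injection: overwrite the unit's incoming weights with a value
    # large enough to saturate its sigmoid for every command
    W1 = params.W1.copy()
    sign = 1.0 if spec.forced_value == 1.0 else -1.0
    W1[:, list(spec.units)] = sign * INJECTION_VALUE
    return _sigmoid(W1 - params.B1)


def all_perturbed_outputs(
    params: NetworkParameters, spec: PerturbationSpec
) -> np.ndarray:
    """Binarized outputs of all N commands under the perturbation."""
    _check_units(params, spec)
    H = _perturbed_hidden(params, spec)
    a2 = H @ params.W2 - params.B2
    return binarize(_sigmoid(a2) if params.sigmoid_output else a2)


def perturb_forward(
    params: NetworkParameters, spec: PerturbationSpec, x: np.ndarray
) -> np.ndarray:
    """Binarized output for one one-hot command under the perturbation."""
    x = np.asarray(x)
    if not (np.isin(x, (0, 1)).all() and x.sum() == 1):
        raise ValueError("input must be one-hot")
    return all_perturbed_outputs(params, spec)[int(np.argmax(x))]


def evaluate_perturbation(
    params: NetworkParameters,
    target: BehavioralMatrix | np.ndarray | None,
    spec: PerturbationSpec,
) -> PerturbationOutcome:
    """Compare perturbed and unperturbed binarized outputs row by row.

    The reference is the *trained network's own* unperturbed output (not the
    target matrix), so partial learning does not bias the robustness score.
    Two conservation statistics are reported: strict full-row equality
    (default ``robustness``) and a lenient variant that only requires the
    originally active motor units to stay on (``robustness_active_only``).
    """
    from .network import network_outputs

    _check_units(params, spec)
    Y0 = network_outputs(params)
    Yp = all_perturbed_outputs(params, spec)
    flip_map = (Yp.astype(np.int8) - Y0.astype(np.int8)).astype(np.int8)
    conserved = (flip_map == 0).all(axis=1)
    active_hit = ((Y0 == 1) & (Yp == 0)).any(axis=1)
    conserved_active = ~active_hit
    return PerturbationOutcome(
        flip_map=flip_map,
        conserved=conserved,
        robustness=float(conserved.mean()),
        affected_count=int((~conserved).sum()),
        conserved_active_only=conserved_active,
        robustness_active_only=float(conserved_active.mean()),
    )


def _specs_for_mode(R: int, mode: Mode, mechanism: Mechanism,
                    max_pairs: int | None = None,
                    rng: np.random.Generator | None = None) -> list[PerturbationSpec]:
    if mode == "activate_pair":
        pairs = list(combinations(range(R), 2))
        if max_pairs is not None and len(pairs) > max_pairs:
            assert rng is not None
            sel = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[int(i)] for i in sel]
        return [PerturbationSpec(mode, p, mechanism) for p in pairs]
    return [PerturbationSpec(mode, (u,), mechanism) for u in range(R)]


def mean_robustness(
    params: NetworkParameters,
    mode: Mode = "activate",
    mechanism: Mechanism = "clamp",
    max_pairs: int | None = None,
    seed: int = 0,
) -> tuple[float, list[PerturbationOutcome]]:
    """Average robustness over every unit (or unit pair) of one network."""
    R = params.shape[1]
    rng = np.random.default_rng(seed)
    outcomes = [
        evaluate_perturbation(params, None, s)
        for s in _specs_for_mode(R, mode, mechanism, max_pairs, rng)
    ]
    return float(np.mean([o.robustness for o in outcomes])), outcomes


def robustness_curve(
    ensemble: Sequence[BehavioralMatrix],
    R_grid: Sequence[int],
    spec_mode: Mode = "activate",
    config: TrainingConfig = TrainingConfig(),
    mechanism: Mechanism = "clamp",
    max_pairs: int | None = None,
) -> dict:
    """Mean robustness (with dispersion) per hidden size over an ensemble.

    For each R and each matrix: train a fresh network, force every hidden
    unit (or pair) in turn, and average the conserved-command fraction.
    Training failures are recorded per cell rather than raised.
    """
    if len(ensemble) == 0 or len(R_grid) == 0:
        raise ValueError("ensemble and R_grid must be non-empty")
    per_R_means, per_R_sds, per_R_values, failures = [], [], [], []
    for R in R_grid:
        vals = []
        for j, mat in enumerate(ensemble):
            cfg = TrainingConfig(**{**config.__dict__, "seed": config.seed + 7919 * j})
            try:
                out = train(mat, R, cfg)
            except Exception:
                failures.append((R, j))
                continue
            rob, _ = mean_robustness(
                out.params, spec_mode, mechanism, max_pairs, seed=cfg.seed
            )
            vals.append(rob)
        per_R_values.append(vals)
        per_R_means.append(float(np.mean(vals)) if vals else np.nan)
        per_R_sds.append(float(np.std(vals)) if vals else np.nan)
    return {
        "R_grid": list(R_grid),
        "mean_robustness": per_R_means,
        "sd_robustness": per_R_sds,
        "values": per_R_values,
        "failures": failures,
    }


def affected_distribution(outcomes: Iterable[PerturbationOutcome]) -> dict[int, int]:
    """Histogram of the number of commands affected per perturbation."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("need at least one outcome")
    hist: dict[int, int] = {}
    for o in outcomes:
        hist[o.affected_count] = hist.get(o.affected_count, 0) + 1
    return dict(sorted(hist.items()))
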