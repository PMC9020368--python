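"""The bottleneck network and its trainer.

Architecture: one-hot command ``x`` (length ``N``) -> hidden "descending"
layer of size ``R`` -> motor output layer of size ``M``::

    a1 = W1.T x - B1          hidden pre-activation
    h  = sigmoid(a1)          descending-neuron activity
    a2 = W2.T h - B2          motor pre-activation
    y  = sigmoid(a2)          motor activity  (default output nonlinearity)

Outputs are binarized by thresholding at 0.5; a behavior counts as learned
only when its entire binarized output row matches the target row.

Training is gradient descent with momentum on the mean-squared error over
all ``N`` one-hot inputs (full batch by default; a seeded mini-batch mode is
available).  Implemented directly in numpy: the whole forward pass is three
dense matrix products, and with one-hot inputs the first layer's activations
are just rows of ``W1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .behaviors import BehavioralMatrix

__all__ = [
    "NetworkParameters",
    "TrainingConfig",
    "TrainOutcome",
    "TrainingFailure",
    "binarize",
    "forward",
    "fraction_learned",
    "hidden_activations",
    "load_params",
    "save_params",
    "train",
]

_CLIP = 500.0  # sigmoid argument clip; sigmoid(±500) rounds exactly to 1/0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_CLIP, _CLIP)))


class TrainingFailure(RuntimeError):
    """Raised when the loss becomes non-finite during training."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")


@dataclass
class NetworkParameters:
    """Weights and biases of the two-layer bottleneck network.

    ``W1`` is ``N x R``, ``W2`` is ``R x M``; biases are subtracted
    (``a = W.T x - B``).  ``sigmoid_output`` records whether the output
    layer applies the sigmoid (default) or is linear.
    """

    W1: np.ndarray
    B1: np.ndarray
    W2: np.ndarray
    B2: np.ndarray
    sigmoid_output: bool = True

    def __post_init__(self) -> None:
        N, R = self.W1.shape
        R2, M = self.W2.shape
        if R2 != R or self.B1.shape != (R,) or self.B2.shape != (M,):
            raise ValueError("inconsistent parameter shapes")
        for a in (self.W1, self.B1, self.W2, self.B2):
            if not np.isfinite(a).all():
                raise ValueError("parameters must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        """(N, R, M)."""
        return (self.W1.shape[0], self.W1.shape[1], self.W2.shape[1])


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the gradient-descent trainer.

    epochs : full passes over the N commands (1e5 matches the study design;
        reduce for desk-scale runs).
    learning_rate : step size on the mean-reduced MSE gradient.  The default
        10.0 corresponds to a per-entry step of 1e-3 at N = M = 100.
    momentum : classical momentum coefficient.
    batch_size : None for full-batch; otherwise seeded shuffled mini-batches.
    sigmoid_output : apply sigmoid to the output layer (default True); set
        False for a linear readout.
    accuracy_target : fraction of behaviors regarded as "learned" when
        reporting sweep thresholds (0.98).
    """

    epochs: int = 100_000
    learning_rate: float = 10.0
    momentum: float = 0.9
    seed: int = 0
    batch_size: int | None = None
    sigmoid_output: bool = True
    accuracy_target: float = 0.98
    loss_trace_points: int = 200

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")


@dataclass
class TrainOutcome:
    """Result of a training run."""

    params: NetworkParameters
    loss_trace: np.ndarray  # (epoch, loss) pairs, subsampled
    fraction_learned: float
    binary_outputs: np.ndarray


def forward(params: NetworkParameters, x: np.ndarray) -> np.ndarray:
    """Network output for a single one-hot command vector."""
    x = np.asarray(x, dtype=float)
    N = params.shape[0]
    if x.shape != (N,):
        raise ValueError(f"expected input of shape ({N},), got {x.shape}")
    if not (np.isin(x, (0, 1)).all() and x.sum() == 1):
        raise ValueError("input must be one-hot")
    h = _sigmoid(x @ params.W1 - params.B1)
    a2 = h @ params.W2 - params.B2
    return _sigmoid(a2) if params.sigmoid_output else a2


def hidden_activations(params: NetworkParameters) -> np.ndarray:
    """Hidden-layer activity for every one-hot command (N x R matrix).

    With one-hot inputs the pre-activation of command ``i`` is simply
    ``W1[i] - B1``.
    """
    return _sigmoid(params.W1 - params.B1)


def _all_outputs(params: NetworkParameters) -> np.ndarray:
    a2 = hidden_activations(params) @ params.W2 - params.B2
    return _sigmoid(a2) if params.sigmoid_output else a2


def binarize(y: np.ndarray) -> np.ndarray:
    """Threshold activities at 0.5 (ties round up)."""
    y = np.asarray(y)
    if not np.isfinite(y).all():
        raise ValueError("cannot binarize non-finite values")
    return (y >= 0.5).astype(np.int8)


def network_outputs(params: NetworkParameters) -> np.ndarray:
    """Binarized output rows for all N commands."""
    return binarize(_all_outputs(params))


def fraction_learned(
    params: NetworkParameters, target: BehavioralMatrix | np.ndarray
) -> float:
    """Fraction of behaviors whose entire binarized output row is correct."""
    T = target.values if isinstance(target, BehavioralMatrix) else np.asarray(target)
    return float((network_outputs(params) == T).all(axis=1).mean())


def _init_params(N: int, R: int, M: int, rng: np.random.Generator, sig: bool):
    s1, s2 = 1.0 / np.sqrt(N), 1.0 / np.sqrt(R)
    return NetworkParameters(
        W1=rng.uniform(-s1, s1, (N, R)),
        B1=rng.uniform(-s1, s1, R),
        W2=rng.uniform(-s2, s2, (R, M)),
        B2=rng.uniform(-s2, s2, M),
        sigmoid_output=sig,
    )


def train(
    target: BehavioralMatrix | np.ndarray,
    R: int,
    config: TrainingConfig = TrainingConfig(),
) -> TrainOutcome:
    """Train the bottleneck network on a behavioral matrix.

    Gradient descent with momentum on the mean-squared error between the
    network output and the target rows, over the ``N`` one-hot commands.
    Deterministic given ``config.seed``.
    """
    if R < 1:
        raise ValueError("hidden size R must be >= 1")
    T = (target.values if isinstance(target, BehavioralMatrix) else np.asarray(target))
    T = T.astype(float)
    N, M = T.shape
    rng = np.random.default_rng(config.seed)
    p = _init_params(N, R, M, rng, config.sigmoid_output)
    W1, B1, W2, B2 = p.W1, p.B1, p.W2, p.B2
    vW1 = np.zeros_like(W1)
    vB1 = np.zeros_like(B1)
    vW2 = np.zeros_like(W2)
    vB2 = np.zeros_like(B2)
    lr, mom = config.learning_rate, config.momentum
    trace_every = max(1, config.epochs // config.loss_trace_points)
    trace: list[tuple[int, float]] = []
    idx = np.arange(N)

    for epoch in range(config.epochs):
        if config.batch_size is None:
            batches = [idx]
        else:
            rng.shuffle(idx)
            batches = [
                idx[s : s + config.batch_size]
                for s in range(0, N, config.batch_size)
            ]
        epoch_loss = 0.0
        for b in batches:
            H = _sigmoid(W1[b] - B1)
            A2 = H @ W2 - B2
            if config.sigmoid_output:
                Y = _sigmoid(A2)
                dA2 = 2.0 * (Y - T[b]) * Y * (1.0 - Y) / (len(b) * M)
            else:
                Y = A2
                dA2 = 2.0 * (Y - T[b]) / (len(b) * M)
            epoch_loss += float(((Y - T[b]) ** 2).mean()) * len(b) / N
            dA1 = (dA2 @ W2.T) * H * (1.0 - H)
            vW2 = mom * vW2 - lr * (H.T @ dA2)
            W2 += vW2
            vB2 = mom * vB2 + lr * dA2.sum(axis=0)
            B2 += vB2
            gW1 = np.zeros_like(W1)
            gW1[b] = dA1
            vW1 = mom * vW1 - lr * gW1
            W1 += vW1
            vB1 = mom * vB1 + lr * dA1.sum(axis=0)
            B1 += vB1
        if epoch % trace_every == 0 or epoch == config.epochs - 1:
            if not np.isfinite(epoch_loss):
                raise TrainingFailure(epoch)
            trace.append((epoch, epoch_loss))

    params = NetworkParameters(W1, B1, W2, B2, sigmoid_output=config.sigmoid_output)
    outputs = network_outputs(params)
    Tint = T.astype(np.int8)
    return TrainOutcome(
        params=params,
        loss_trace=np.array(trace),
        fraction_learned=float((outputs == Tint).all(axis=1).mean()),
        binary_outputs=outputs,
    )


def save_params(params: NetworkParameters, path: str | Path) -> None:
    """Persist parameters as a JSON archive with shape metadata."""
    payload = {
        "shape": list(params.shape),
        "sigmoid_output": params.sigmoid_output,
        "W1": params.W1.tolist(),
        "B1": params.B1.tolist(),
        "W2": params.W2.tolist(),
        "B2": params.B2.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_params(path: str | Path) -> NetworkParameters:
    d = json.loads(Path(path).read_text())
    return NetworkParameters(
        W1=np.array(d["W1"]),
        B1=np.array(d["B1"]),
        W2=np.array(d["W2"]),
        B2=np.array(d["B2"]),
        sigmoid_output=d["sigmoid_output"],
    )
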