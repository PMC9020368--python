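"""Synthetic behavioral matrices and their structural descriptors.

A behavioral matrix is an ``N x M`` binary matrix: row ``i`` lists the motor
units that must switch on to execute behavior ``i``.  Two ensembles are
provided: fully random rows with ``k`` active units each, and modular
matrices in which behaviors are grouped into ``m`` equal blocks that mostly
recruit their own block of motor units, with ``sigma`` active units placed
outside the home block ("cross-module noise").

Descriptors: Newman modularity of the matrix viewed as a graph adjacency,
and the exact combinatorial entropy of the ensemble the matrix was drawn
from.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "BehavioralMatrix",
    "MatrixDescriptor",
    "describe",
    "entropy_modular",
    "entropy_random",
    "generate_modular_matrix",
    "generate_random_matrix",
    "load_matrix",
    "modularity",
    "save_matrix",
]


@dataclass(frozen=True)
class BehavioralMatrix:
    """Binary target mapping from behaviors (rows) to motor units (columns).

    Attributes
    ----------
    values : ndarray of shape (N, M)
        0/1 integer matrix; every row sums to ``k``.
    k : int
        Number of active motor units per behavior.
    n_modules : int or None
        Number of equal modules ``m``; ``None`` for the random ensemble.
    sigma : int or None
        Active units per row placed outside the home module (``None`` for
        random matrices).
    seed : int
        Seed the matrix was generated from.
    """

    values: np.ndarray
    k: int
    n_modules: int | None = None
    sigma: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("entries must be 0/1")
        if not (v.sum(axis=1) == self.k).all():
            raise ValueError(f"every row must sum to k={self.k}")
        object.__setattr__(self, "values", v.astype(np.int8))

    @property
    def n_behaviors(self) -> int:
        return self.values.shape[0]

    @property
    def n_motor_units(self) -> int:
        return self.values.shape[1]

    @property
    def module_size(self) -> int | None:
        if self.n_modules is None:
            return None
        return self.n_motor_units // self.n_modules

    def row_module(self, i: int) -> int:
        """Home module of behavior ``i`` (rows are split into equal blocks)."""
        if self.n_modules is None:
            raise ValueError("matrix has no module structure")
        return i // (self.n_behaviors // self.n_modules)

    def column_communities(self) -> list[set[int]]:
        """Column-block communities used for the modularity score."""
        if self.n_modules is None:
            raise ValueError("matrix has no module structure")
        ms = self.module_size
        assert ms is not None
        return [set(range(b * ms, (b + 1) * ms)) for b in range(self.n_modules)]


@dataclass(frozen=True)
class MatrixDescriptor:
    """Structural summary of a behavioral matrix."""

    modularity_mu: float
    entropy_bits: float


def _check_dims(N: int, M: int, k: int) -> None:
    if N < 1 or M < 1:
        raise ValueError(f"dimensions must be positive, got N={N}, M={M}")
    if not 0 <= k <= M:
        raise ValueError(f"need 0 <= k <= M, got k={k}, M={M}")


def generate_random_matrix(N: int, M: int, k: int, seed: int = 0) -> BehavioralMatrix:
    """Random behavioral matrix: each row has ``k`` ones placed uniformly.

    Placement is without replacement and independent across rows.
    """
    _check_dims(N, M, k)
    rng = np.random.default_rng(seed)
    values = np.zeros((N, M), dtype=np.int8)
    for i in range(N):
        values[i, rng.choice(M, size=k, replace=False)] = 1
    return BehavioralMatrix(values=values, k=k, seed=seed)


def generate_modular_matrix(
    N: int, M: int, k: int, m: int, sigma: int = 0, seed: int = 0
) -> BehavioralMatrix:
    """Modular behavioral matrix with ``m`` equal blocks and noise ``sigma``.

    Rows are split into ``m`` equal groups; a row in group ``b`` activates
    ``k - sigma`` units inside the columns of block ``b`` and ``sigma`` units
    outside it, so the per-row sparsity ``k`` is preserved.  ``sigma = 0``
    is the perfectly modular case.
    """
    _check_dims(N, M, k)
    if m < 1 or M % m != 0 or N % m != 0:
        raise ValueError(f"m={m} must divide both N={N} and M={M}")
    if sigma < 0 or sigma > k:
        raise ValueError(f"need 0 <= sigma <= k, got sigma={sigma}, k={k}")
    m_size = M // m
    if k - sigma > m_size:
        raise ValueError(f"k - sigma = {k - sigma} exceeds module size {m_size}")
    if sigma > M - m_size:
        raise ValueError(f"sigma={sigma} exceeds out-of-module columns {M - m_size}")

    rng = np.random.default_rng(seed)
    rows_per_module = N // m
    values = np.zeros((N, M), dtype=np.int8)
    all_cols = np.arange(M)
    for i in range(N):
        b = i // rows_per_module
        inside = all_cols[b * m_size : (b + 1) * m_size]
        outside = np.concatenate([all_cols[: b * m_size], all_cols[(b + 1) * m_size :]])
        values[i, rng.choice(inside, size=k - sigma, replace=False)] = 1
        if sigma:
            values[i, rng.choice(outside, size=sigma, replace=False)] = 1
    return BehavioralMatrix(values=values, k=k, n_modules=m, sigma=sigma, seed=seed)


def modularity(
    matrix: BehavioralMatrix | np.ndarray,
    communities: Sequence[set[int]] | None = None,
) -> float:
    """Newman modularity of the matrix treated as a directed graph adjacency.

    Node ``j`` receives an edge from node ``i`` whenever entry ``(i, j)`` is 1
    (the graph has ``max(N, M)`` nodes, so row-block ``b`` and column-block
    ``b`` are the same nodes).  ``communities`` is a partition of the node
    set; by default the matrix's own column blocks are used.  The score is

        mu = sum_c [ e_c / E  -  (out_c * in_c) / E^2 ]

    with ``E`` total edges, ``e_c`` edges inside community ``c`` and
    ``out_c``/``in_c`` the community's total out-/in-degree — the directed
    Newman measure, exactly ``(m - 1) / m`` for ``m`` perfect equal blocks.
    """
    if isinstance(matrix, BehavioralMatrix):
        if communities is None:
            communities = matrix.column_communities()
        A = matrix.values
    else:
        A = np.asarray(matrix)
        if communities is None:
            raise ValueError("communities required for a bare matrix")
    n_nodes = max(A.shape)
    covered = set().union(*communities)
    if covered != set(range(n_nodes)):
        raise ValueError("communities must partition all graph nodes exactly")
    square = np.zeros((n_nodes, n_nodes))
    square[: A.shape[0], : A.shape[1]] = A
    G = nx.from_numpy_array(square, create_using=nx.DiGraph)
    return float(nx.community.modularity(G, communities))


def entropy_random(N: int, M: int, k: int) -> float:
    """Entropy (bits) of the random ensemble: ``N * log2(C(M, k))``.

    Exact big-integer binomial evaluation, so no overflow at ``C(100, 50)``.
    """
    _check_dims(N, M, k)
    return N * math.log2(math.comb(M, k))


def entropy_modular(N: int, M: int, k: int, m: int, sigma: int = 0) -> float:
    """Entropy (bits) of the modular ensemble.

    ``N * log2( C(m_size, k - sigma) * C(M - m_size, sigma) )`` with
    ``m_size = M / m``: each row chooses its in-module and out-of-module
    active sets independently.
    """
    _check_dims(N, M, k)
    if m < 1 or M % m != 0:
        raise ValueError(f"m={m} must divide M={M}")
    if sigma < 0 or sigma > k:
        raise ValueError(f"need 0 <= sigma <= k, got sigma={sigma}")
    m_size = M // m
    if k - sigma > m_size or sigma > M - m_size:
        raise ValueError("sigma incompatible with module size")
    return N * math.log2(math.comb(m_size, k - sigma) * math.comb(M - m_size, sigma))


def describe(matrix: BehavioralMatrix) -> MatrixDescriptor:
    """Realized modularity and ensemble entropy of a generated matrix."""
    N, M = matrix.values.shape
    if matrix.n_modules is None:
        mu = modularity(matrix.values, [set(range(max(N, M)))])
        S = entropy_random(N, M, matrix.k)
    else:
        mu = modularity(matrix)
        S = entropy_modular(N, M, matrix.k, matrix.n_modules, matrix.sigma or 0)
    return MatrixDescriptor(modularity_mu=mu, entropy_bits=S)


def save_matrix(matrix: BehavioralMatrix, path: str | Path) -> None:
    """Write the matrix as header-free CSV plus a JSON sidecar of metadata."""
    path = Path(path)
    np.savetxt(path, matrix.values, fmt="%d", delimiter=",")
    desc = describe(matrix)
    sidecar = {
        "N": matrix.n_behaviors,
        "M": matrix.n_motor_units,
        "k": matrix.k,
        "m": matrix.n_modules,
        "sigma": matrix.sigma,
        "seed": matrix.seed,
        "modularity": desc.modularity_mu,
        "entropy_bits": desc.entropy_bits,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_matrix(path: str | Path) -> BehavioralMatrix:
    """Read a matrix written by :func:`save_matrix`."""
    path = Path(path)
    values = np.loadtxt(path, dtype=np.int8, delimiter=",", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return BehavioralMatrix(
        values=values,
        k=meta["k"],
        n_modules=meta["m"],
        sigma=meta["sigma"],
        seed=meta["seed"],
    )
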