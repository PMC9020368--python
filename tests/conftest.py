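import numpy as np
import pytest

import bottlenet as bn


@pytest.fixture(scope="session")
def small_random_matrix() -> bn.BehavioralMatrix:
    return bn.generate_random_matrix(N=10, M=10, k=3, seed=11)


@pytest.fixture(scope="session")
def trained_small(small_random_matrix) -> bn.TrainOutcome:
    """Unbottlenecked 10x10 instance trained to convergence."""
    cfg = bn.TrainingConfig(epochs=20_000, seed=5, learning_rate=2.0)
    return bn.train(small_random_matrix, R=10, config=cfg)


@pytest.fixture(scope="session")
def trained_medium() -> tuple[bn.BehavioralMatrix, bn.TrainOutcome]:
    """A 20x20 instance trained well; used by the perturbation suite."""
    mat = bn.generate_random_matrix(N=20, M=20, k=4, seed=7)
    cfg = bn.TrainingConfig(epochs=30_000, seed=3, learning_rate=2.0)
    return mat, bn.train(mat, R=10, config=cfg)


@pytest.fixture(scope="session")
def perfect_modular_matrix() -> bn.BehavioralMatrix:
    return bn.generate_modular_matrix(N=100, M=100, k=10, m=5, sigma=0, seed=2)
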