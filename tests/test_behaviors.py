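"""Behavioral-matrix generators, modularity, and entropy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bottlenet as bn
from bottlenet.behaviors import load_matrix, save_matrix


def brute_force_directed_modularity(A, labels):
    """Term-by-term Newman modularity of a directed adjacency matrix.

    Q = (1/E) * sum_ij (A_ij - kout_i * kin_j / E) * delta(c_i, c_j)
    """
    A = np.asarray(A, dtype=float)
    E = A.sum()
    kout = A.sum(axis=1)
    kin = A.sum(axis=0)
    Q = 0.0
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                Q += (A[i, j] - kout[i] * kin[j] / E) / E
    return Q


class TestGenerators:
    def test_empty_and_saturated_rows(self):
        assert not bn.generate_random_matrix(3, 5, 0).values.any()
        assert bn.generate_random_matrix(3, 5, 5).values.all()

    def test_row_sums_and_column_statistics(self):
        """Every row sums to k; column sums are Binomial(N, k/M) on average."""
        col_means = []
        for seed in range(30):
            mat = bn.generate_random_matrix(100, 100, 10, seed=seed)
            assert (mat.values.sum(axis=1) == 10).all()
            col_means.append(mat.values.sum(axis=0).mean())
        assert np.mean(col_means) == pytest.approx(10.0, abs=0.5)

    def test_modular_placement(self):
        mat = bn.generate_modular_matrix(100, 100, 10, m=5, sigma=3, seed=4)
        ms = mat.module_size
        for i in range(100):
            b = mat.row_module(i)
            inside = mat.values[i, b * ms : (b + 1) * ms].sum()
            assert inside == 10 - 3
            assert mat.values[i].sum() == 10

    def test_sigma_zero_confined_to_home_module(self):
        mat = bn.generate_modular_matrix(20, 20, 4, m=4, sigma=0, seed=1)
        ms = mat.module_size
        for i in range(20):
            b = mat.row_module(i)
            outside = np.delete(mat.values[i], np.arange(b * ms, (b + 1) * ms))
            assert not outside.any()

    @pytest.mark.parametrize(
        "call",
        [
            lambda: bn.generate_random_matrix(3, 5, 6),
            lambda: bn.generate_random_matrix(0, 5, 1),
            lambda: bn.generate_modular_matrix(100, 100, 10, m=3),  # 3 ∤ 100
            lambda: bn.generate_modular_matrix(100, 100, 10, m=5, sigma=11),
            lambda: bn.generate_modular_matrix(100, 100, 30, m=5, sigma=0),  # k>m_size
        ],
    )
    def test_invalid_parameters_raise(self, call):
        with pytest.raises(ValueError):
            call()

    def test_determinism_and_roundtrip(self, tmp_path):
        a = bn.generate_modular_matrix(20, 20, 4, m=5, sigma=1, seed=9)
        b = bn.generate_modular_matrix(20, 20, 4, m=5, sigma=1, seed=9)
        assert (a.values == b.values).all()
        save_matrix(a, tmp_path / "m.csv")
        c = load_matrix(tmp_path / "m.csv")
        assert (c.values == a.values).all()
        assert (c.k, c.n_modules, c.sigma) == (4, 5, 1)

    @given(st.integers(0, 8), st.integers(1, 12))
    @settings(max_examples=30, deadline=None)
    def test_row_sum_conservation_property(self, k, N):
        M = 8
        mat = bn.generate_random_matrix(N, M, min(k, M), seed=0)
        assert (mat.values.sum(axis=1) == min(k, M)).all()


class TestModularity:
    def test_perfect_five_block_is_exactly_point_eight(self, perfect_modular_matrix):
        assert bn.modularity(perfect_modular_matrix) == pytest.approx(0.8, abs=1e-12)

    def test_single_community_is_exactly_zero(self, perfect_modular_matrix):
        mu = bn.modularity(perfect_modular_matrix.values, [set(range(100))])
        assert mu == pytest.approx(0.0, abs=1e-12)

    def test_perfect_block_closed_form(self):
        """m equal perfect blocks give mu = (m - 1) / m exactly."""
        for m in (2, 4, 5):
            mat = bn.generate_modular_matrix(20, 20, 3, m=m, sigma=0, seed=m)
            assert bn.modularity(mat) == pytest.approx((m - 1) / m, abs=1e-12)

    def test_matches_brute_force_on_toy_graph(self):
        A = np.array(
            [[0, 1, 0, 0], [1, 0, 1, 0], [0, 0, 0, 1], [0, 1, 1, 0]]
        )
        labels = [0, 0, 1, 1]
        expected = brute_force_directed_modularity(A, labels)
        got = bn.modularity(A, [{0, 1}, {2, 3}])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_mu_strictly_decreasing_in_sigma(self):
        mus = [
            bn.modularity(bn.generate_modular_matrix(100, 100, 10, 5, s, seed=1))
            for s in (0, 1, 2, 4, 6)
        ]
        assert all(a > b for a, b in zip(mus, mus[1:]))

    def test_incomplete_communities_raise(self, perfect_modular_matrix):
        with pytest.raises(ValueError):
            bn.modularity(perfect_modular_matrix.values, [{0, 1}, {2}])


class TestEntropy:
    def test_degenerate_cases_are_zero(self):
        assert bn.entropy_random(10, 7, 0) == 0.0
        assert bn.entropy_random(10, 7, 7) == 0.0
        # sigma=0 and k = m_size: rows fully determined
        assert bn.entropy_modular(10, 10, 5, m=2, sigma=0) == 0.0

    def test_exact_combinatorial_value(self):
        expected = 100 * math.log2(math.comb(100, 10))
        assert bn.entropy_random(100, 100, 10) == pytest.approx(expected, rel=0)
        expected_mod = 100 * math.log2(math.comb(20, 8) * math.comb(80, 2))
        assert bn.entropy_modular(100, 100, 10, m=5, sigma=2) == pytest.approx(
            expected_mod, rel=0
        )

    def test_symmetry_and_maximum_at_half(self):
        S = [bn.entropy_random(100, 100, k) for k in range(101)]
        assert S == pytest.approx(S[::-1])
        assert max(range(101), key=lambda k: S[k]) == 50

    def test_modular_reduces_to_within_block_choice_at_sigma_zero(self):
        assert bn.entropy_modular(50, 100, 10, m=5, sigma=0) == pytest.approx(
            50 * math.log2(math.comb(20, 10))
        )

    def test_modular_increasing_in_sigma_on_grid(self):
        S = [bn.entropy_modular(100, 100, 10, 5, s) for s in range(0, 7)]
        assert all(a < b for a, b in zip(S, S[1:]))

    def test_no_overflow_at_dense_half(self):
        assert np.isfinite(bn.entropy_random(100, 100, 50))


def test_describe_reports_realized_modularity_and_entropy(perfect_modular_matrix):
    d = bn.describe(perfect_modular_matrix)
    assert d.modularity_mu == pytest.approx(0.8)
    assert d.entropy_bits == pytest.approx(100 * math.log2(math.comb(20, 10)))
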