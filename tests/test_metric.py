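"""Unit and property tests for the UNODF metric core."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from unodf import (
    BinaryNetwork,
    degrees,
    gen_perfectly_nested,
    gen_regular,
    pair_contribution,
    s_lee,
    unodf,
    unodf_reference,
)
from conftest import random_binary_network


def directed_chain() -> BinaryNetwork:
    A = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=np.int8)
    return BinaryNetwork(A, directed=True)


class TestBinaryNetwork:
    def test_rejects_tiny_nonsquare_and_bad_entries(self):
        with pytest.raises(ValueError):
            BinaryNetwork(np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError):
            BinaryNetwork(np.zeros((3, 4), dtype=int))
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = 2
        with pytest.raises(ValueError):
            BinaryNetwork(A)

    def test_rejects_nonzero_diagonal_and_asymmetry(self):
        A = np.eye(3, dtype=int)
        with pytest.raises(ValueError):
            BinaryNetwork(A)
        B = np.zeros((3, 3), dtype=int)
        B[0, 1] = 1
        with pytest.raises(ValueError):
            BinaryNetwork(B, directed=False)
        BinaryNetwork(B, directed=True)  # fine when directed

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            BinaryNetwork(np.zeros((3, 3), dtype=int), labels=("a", "a", "b"))


class TestDegrees:
    def test_triangle_pendant_rows(self, triangle_pendant):
        assert degrees(triangle_pendant, "rows").values.tolist() == [3, 2, 2, 1]

    def test_cycle_is_2_regular(self):
        assert degrees(gen_regular(10, 2), "rows").values.tolist() == [2] * 10

    def test_directed_chain_rows_vs_columns(self):
        net = directed_chain()
        assert degrees(net, "rows").values.tolist() == [1, 1, 0]
        assert degrees(net, "columns").values.tolist() == [0, 1, 1]

    def test_degree_sum_equals_link_count(self, triangle_pendant):
        assert degrees(triangle_pendant).values.sum() == 2 * triangle_pendant.n_links


class TestPairContribution:
    @pytest.mark.parametrize(
        "i,j,shared,mindeg,tied,value",
        [
            (0, 1, 1, 2, False, Fraction(1, 2)),
            (1, 2, 1, 2, True, Fraction(0)),
            (1, 3, 1, 1, False, Fraction(1)),
        ],
    )
    def test_hand_enumerated_pairs(
        self, triangle_pendant, i, j, shared, mindeg, tied, value
    ):
        pc = pair_contribution(triangle_pendant, i, j, "rows")
        assert pc.shared_count == shared
        assert pc.min_degree == mindeg
        assert pc.tied is tied
        assert pc.value == value

    def test_invalid_indices(self, triangle_pendant):
        with pytest.raises(IndexError):
            pair_contribution(triangle_pendant, 0, 9)
        with pytest.raises(ValueError):
            pair_contribution(triangle_pendant, 1, 1)

    def test_zero_min_degree_contributes_zero(self):
        A = np.zeros((4, 4), dtype=int)
        A[0, 1] = A[1, 0] = 1
        net = BinaryNetwork(A)
        pc = pair_contribution(net, 2, 0)  # node 2 is isolated
        assert pc.min_degree == 0 and pc.value == 0


class TestUnodf:
    def test_cycle_is_zero(self):
        res = unodf(gen_regular(10, 2))
        assert res.unodf_rows == 0.0 and res.unodf_cols == 0.0

    def test_triangle_pendant_is_half(self, triangle_pendant):
        res = unodf(triangle_pendant)
        assert res.unodf_rows == 0.5
        assert res.n_pairs == 6 and res.n_tied_rows == 1

    def test_perfectly_nested_six(self):
        # brute-force oracle over all 15 pairs gives 25/36
        res = unodf(gen_perfectly_nested(6))
        assert res.unodf_rows == float(Fraction(25, 36))
        assert unodf_reference(gen_perfectly_nested(6)).unodf_rows == res.unodf_rows

    def test_star_is_zero(self):
        A = np.zeros((5, 5), dtype=int)
        A[0, 1:] = 1
        A[1:, 0] = 1
        assert unodf(BinaryNetwork(A)).unodf_rows == 0.0

    def test_small_network_rejected(self):
        with pytest.raises(ValueError):
            BinaryNetwork(np.zeros((2, 2), dtype=int))


class TestSLee:
    def test_four_cycle_shows_delta_distinction(self):
        net = gen_regular(4, 2)
        assert s_lee(net) == pytest.approx(1 / 3)
        assert unodf(net).unodf_rows == 0.0

    def test_triangle_pendant(self, triangle_pendant):
        assert s_lee(triangle_pendant) == pytest.approx(7 / 12)


class TestProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(3, 10),
        density=st.floats(0.0, 1.0),
        directed=st.booleans(),
        seed=st.integers(0, 2**31 - 1),
        permseed=st.integers(0, 2**31 - 1),
    )
    def test_permutation_invariance(self, n, density, directed, seed, permseed):
        net = random_binary_network(n, density, directed, seed)
        order = np.random.default_rng(permseed).permutation(n)
        base, perm = unodf(net), unodf(net.permuted(order))
        assert base.unodf_rows == perm.unodf_rows
        assert base.unodf_cols == perm.unodf_cols

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(3, 10),
        density=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_transpose_duality_and_range(self, n, density, seed):
        net = random_binary_network(n, density, True, seed)
        res = unodf(net)
        assert res.unodf_cols == unodf(net.transpose()).unodf_rows
        assert 0.0 <= res.unodf_rows < 1.0
        assert 0.0 <= res.unodf_cols < 1.0

    @pytest.mark.parametrize("n,k", [(10, 2), (12, 4), (9, 6)])
    def test_regular_graphs_are_zero(self, n, k):
        res = unodf(gen_regular(n, k))
        assert res.unodf_rows == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(3, 10),
        density=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_undirected_symmetry(self, n, density, seed):
        net = random_binary_network(n, density, False, seed)
        # recompute columns independently by flagging the matrix directed
        forced = BinaryNetwork(net.adjacency.copy(), directed=True)
        res = unodf(forced)
        assert res.unodf_rows == res.unodf_cols
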