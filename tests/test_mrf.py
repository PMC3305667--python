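"""The odds-ratio parameterisation, Gibbs sampler and enumeration oracle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import binmrf as bm
from binmrf.errors import (
    CapacityError,
    InvalidInteractionMatrixError,
    PresetLookupError,
)
from binmrf.mrf import DEFAULT_BURN_IN, PAPER19_EDGES


def matrix(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"X{i+1}" for i in range(values.shape[0])]
    return bm.InteractionMatrix(values=values, names=names)


def independence(p):
    return matrix(np.ones((p, p)))


class TestInteractionMatrix:
    def test_rejects_nonpositive_entry_naming_cell(self):
        vals = np.ones((3, 3))
        vals[0, 2] = vals[2, 0] = -1.0
        with pytest.raises(InvalidInteractionMatrixError, match="X1.*X3"):
            matrix(vals)

    def test_rejects_asymmetry_and_bad_names(self):
        vals = np.ones((2, 2))
        vals[0, 1] = 2.0
        with pytest.raises(InvalidInteractionMatrixError, match="symmetric"):
            matrix(vals)
        with pytest.raises(InvalidInteractionMatrixError, match="unique"):
            matrix(np.ones((2, 2)), names=["a", "a"])


class TestLogPotentials:
    def test_all_ones_gives_zero_potentials(self):
        pot = bm.log_potentials(independence(2))
        assert np.array_equal(pot.h, np.zeros(2))
        assert np.array_equal(pot.J, np.zeros((2, 2)))

    def test_m6_pattern(self, m6):
        pot = bm.log_potentials(m6)
        assert np.array_equal(pot.h, np.zeros(6))
        ln2 = math.log(2.0)
        expected = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 3), (2, 3)]:
            expected[i, j] = expected[j, i] = ln2
        assert np.allclose(pot.J, expected)

    def test_fractional_odds_ratio_gives_negative_coupling(self):
        vals = np.ones((3, 3))
        vals[0, 1] = vals[1, 0] = 0.5
        pot = bm.log_potentials(matrix(vals))
        assert pot.J[0, 1] == pytest.approx(-math.log(2.0), abs=1e-12)

    def test_round_trip(self, m6):
        pot = bm.log_potentials(m6)
        off = np.exp(pot.J)
        np.fill_diagonal(off, np.exp(pot.h))
        assert np.allclose(off, m6.values)


class TestConditionalProbability:
    def test_independence_is_half_everywhere(self):
        pot = bm.log_potentials(independence(4))
        for state in ([0, 0, 0, 0], [1, 1, 1, 1], [1, 0, 1, 0]):
            for i in range(4):
                assert bm.conditional_probability(pot, state, i) == pytest.approx(0.5)

    def test_m6_two_active_neighbors(self, m6):
        # logit = ln 2 + ln 2 = ln 4, so P = 4/5
        pot = bm.log_potentials(m6)
        state = [0, 1, 1, 0, 0, 0]
        assert bm.conditional_probability(pot, state, 0) == pytest.approx(0.8)

    def test_matches_exact_joint_conditionals_exhaustively(self, m6):
        """Direct conditionals equal those marginalised from the joint table."""
        pot = bm.log_potentials(m6)
        joint = bm.exact_joint(m6)
        p = m6.p
        for i in range(p):
            for s, state in enumerate(joint.states):
                partner = s ^ (1 << i)  # same state with bit i flipped
                s1 = s if state[i] == 1 else partner
                s0 = partner if state[i] == 1 else s
                denom = joint.probs[s0] + joint.probs[s1]
                cond = joint.probs[s1] / denom
                assert bm.conditional_probability(pot, state, i) == pytest.approx(
                    cond, abs=1e-12
                )


class TestExactJoint:
    def test_independent_pair_is_uniform(self):
        joint = bm.exact_joint(independence(2))
        assert np.allclose(joint.probs, 0.25)

    def test_cross_product_ratio_recovers_odds_ratio(self):
        vals = np.ones((2, 2))
        vals[0, 1] = vals[1, 0] = 2.0
        probs = bm.exact_joint(matrix(vals)).probs
        # states indexed by bits: 0=(0,0), 1=(1,0), 2=(0,1), 3=(1,1)
        assert probs[3] * probs[0] / (probs[1] * probs[2]) == pytest.approx(2.0)

    @given(
        st.lists(st.floats(0.25, 4.0), min_size=6, max_size=6),
        st.lists(st.floats(0.5, 2.0), min_size=4, max_size=4),
    )
    def test_normalization_and_permutation_symmetry(self, off, diag):
        p = 4
        vals = np.ones((p, p))
        k = 0
        for i in range(p):
            vals[i, i] = diag[i]
            for j in range(i + 1, p):
                vals[i, j] = vals[j, i] = off[k]
                k += 1
        M = matrix(vals)
        joint = bm.exact_joint(M)
        assert joint.probs.sum() == pytest.approx(1.0, abs=1e-12)
        # permute variables, recompute, map states back
        perm = [2, 0, 3, 1]
        Mp = matrix(vals[np.ix_(perm, perm)], names=[M.names[i] for i in perm])
        jp = bm.exact_joint(Mp)
        for s, state in enumerate(joint.states):
            sp = sum(int(state[perm[k]]) << k for k in range(p))
            assert jp.probs[sp] == pytest.approx(joint.probs[s], abs=1e-12)

    def test_enumeration_bound(self):
        with pytest.raises(CapacityError):
            bm.exact_joint(independence(21))


class TestGibbsSample:
    def test_reproducible_bit_identical(self, m6):
        a = bm.gibbs_sample(m6, 50, burn_in=50, spacing=2, seed=9)
        b = bm.gibbs_sample(m6, 50, burn_in=50, spacing=2, seed=9)
        assert np.array_equal(a.data, b.data)
        assert a.names == b.names

    def test_independence_means_near_half(self):
        n = 4000
        data = bm.gibbs_sample(independence(4), n, burn_in=100, spacing=1, seed=3)
        se = 0.5 / math.sqrt(n)
        assert np.all(np.abs(data.data.mean(axis=0) - 0.5) < 3 * se)

    def test_default_burn_in_recorded(self, m6):
        data = bm.gibbs_sample(m6, 5, seed=0)
        assert DEFAULT_BURN_IN == 5000
        assert "burn_in=5000" in data.provenance

    def test_argument_validation(self, m6):
        with pytest.raises(ValueError):
            bm.gibbs_sample(m6, 0, seed=0)
        with pytest.raises(ValueError):
            bm.gibbs_sample(m6, 5, spacing=0, seed=0)


class TestTrueGraph:
    def test_independence_has_no_edges(self):
        assert bm.true_graph(independence(3)).edges == frozenset()

    def test_m6_edges(self, m6, m6_truth):
        assert m6_truth.edges == {
            ("X1", "X2"),
            ("X1", "X3"),
            ("X2", "X4"),
            ("X3", "X4"),
        }

    def test_single_interaction(self):
        vals = np.ones((5, 5))
        vals[1, 4] = vals[4, 1] = 3.0
        g = bm.true_graph(matrix(vals))
        assert g.edges == {("X2", "X5")}


class TestPresets:
    def test_m6_matches_printed_matrix(self, m6):
        expected = np.array(
            [
                [1, 2, 2, 1, 1, 1],
                [2, 1, 1, 2, 1, 1],
                [2, 1, 1, 2, 1, 1],
                [1, 2, 2, 1, 1, 1],
                [1, 1, 1, 1, 1, 1],
                [1, 1, 1, 1, 1, 1],
            ],
            dtype=float,
        )
        assert np.array_equal(m6.values, expected)

    def test_paper19_structure(self, paper19, paper19_truth):
        import networkx as nx

        assert paper19.p == 20
        assert len(paper19_truth.edges) == 19
        degrees = {n: 0 for n in paper19_truth.nodes}
        for a, b in paper19_truth.edges:
            degrees[a] += 1
            degrees[b] += 1
        isolated = [n for n, d in degrees.items() if d == 0]
        assert sorted(isolated) == ["V19", "V20"]
        g = nx.Graph(list(PAPER19_EDGES))
        assert g.number_of_nodes() == 18 and nx.is_connected(g)
        # all present interactions have odds ratio 2, baseline odds 1
        assert set(np.unique(paper19.values)) == {1.0, 2.0}
        assert np.all(np.diag(paper19.values) == 1.0)

    def test_unknown_preset_lists_options(self):
        with pytest.raises(PresetLookupError, match="m6"):
            bm.preset_structure("nope")
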