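"""Statevector engine: rotations, CX ordering, register combination, endianness."""

import math

import numpy as np
import pytest

from qsimcells import (
    GeneSpec,
    Topology,
    apply_cx_sequence,
    build_final_state,
    combine_registers,
    exact_distribution,
    prepare_initial_state,
    pushforward_distribution,
    reverse_bitstring,
)
from qsimcells.kernel import (
    ConfigurationError,
    bitstring_to_index,
    index_to_bitstring,
)

from conftest import single_gene


def p_on(activation):
    return math.sin(activation * math.pi / 2.0) ** 2


class TestInitialState:
    @pytest.mark.parametrize(
        "activation,expected_p1",
        [(0.0, 0.0), (1.0, 1.0), (0.8, p_on(0.8)), (0.5, 0.5)],
    )
    def test_single_gene_marginal(self, activation, expected_p1):
        state = prepare_initial_state([single_gene(activation)])
        assert state.marginal_on(0) == pytest.approx(expected_p1, abs=1e-12)

    def test_activation_08_amplitudes_match_brute_force_product(self):
        # brute-force two-amplitude product: (cos(theta/2), sin(theta/2))
        theta = 0.8 * math.pi
        state = prepare_initial_state([single_gene(0.8)])
        np.testing.assert_allclose(
            state.amplitudes, [math.cos(theta / 2), math.sin(theta / 2)], atol=1e-15
        )
        assert state.marginal_on(0) == pytest.approx(0.9045084971874737, abs=1e-12)

    def test_theta_is_activation_times_pi_exactly(self):
        g = single_gene(0.37)
        assert g.theta == 0.37 * math.pi

    def test_product_state_marginals(self, demo_genes):
        state = prepare_initial_state(demo_genes)
        for g in demo_genes:
            assert state.marginal_on(g.global_index) == pytest.approx(g.p_on, abs=1e-12)

    def test_normalized(self, demo_genes):
        state = prepare_initial_state(demo_genes)
        assert np.sum(state.amplitudes**2) == pytest.approx(1.0, abs=1e-12)

    def test_non_contiguous_indices_rejected(self):
        genes = [single_gene(0.5, index=0), single_gene(0.5, name="h", index=2)]
        with pytest.raises(ConfigurationError):
            prepare_initial_state(genes)

    def test_duplicate_indices_rejected(self):
        genes = [single_gene(0.5, index=0), single_gene(0.5, name="h", index=0)]
        with pytest.raises(ConfigurationError):
            prepare_initial_state(genes)

    def test_activation_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            single_gene(1.2)

    def test_qubit_cap(self):
        genes = [single_gene(0.5, name=f"g{i}", index=i) for i in range(21)]
        with pytest.raises(ConfigurationError):
            prepare_initial_state(genes)


class TestCxSequence:
    def test_cnot_truth_table(self):
        # |control=1, target=0> -> |11>
        genes = [single_gene(1.0, name="c", index=0), single_gene(0.0, name="t", index=1)]
        state = prepare_initial_state(genes)
        state = apply_cx_sequence(state, Topology(((0, 1),)))
        assert exact_distribution(state) == pytest.approx({"11": 1.0})

    def test_control_off_leaves_target(self):
        genes = [single_gene(0.0, name="c", index=0), single_gene(0.0, name="t", index=1)]
        state = apply_cx_sequence(prepare_initial_state(genes), Topology(((0, 1),)))
        assert exact_distribution(state) == pytest.approx({"00": 1.0})

    def test_empty_topology_is_identity(self, demo_genes):
        state = prepare_initial_state(demo_genes)
        after = apply_cx_sequence(state, Topology(()))
        np.testing.assert_array_equal(state.amplitudes, after.amplitudes)

    def test_gate_order_matters(self):
        # [(0,1),(1,2)] vs [(1,2),(0,1)] on a superposed 3-qubit state
        genes = [
            single_gene(0.5, name="a", index=0),
            single_gene(0.3, name="b", index=1),
            single_gene(0.2, name="c", index=2),
        ]
        state = prepare_initial_state(genes)
        d_ab = exact_distribution(apply_cx_sequence(state, Topology(((0, 1), (1, 2)))))
        d_ba = exact_distribution(apply_cx_sequence(state, Topology(((1, 2), (0, 1)))))
        assert d_ab != pytest.approx(d_ba)
        # each order agrees with the independent enumeration oracle
        for pairs, dist in ((((0, 1), (1, 2)), d_ab), (((1, 2), (0, 1)), d_ba)):
            oracle = pushforward_distribution(genes, [Topology(pairs)])
            assert dist == pytest.approx(oracle, abs=1e-10)

    def test_cx_permutes_probability_multiset(self, demo_genes, cascade):
        state = prepare_initial_state(demo_genes)
        before = np.sort(state.probabilities())
        after = np.sort(apply_cx_sequence(state, cascade).probabilities())
        np.testing.assert_allclose(before, after, atol=1e-14)

    def test_self_pair_rejected(self):
        with pytest.raises(ConfigurationError):
            Topology(((2, 2),))

    def test_out_of_range_pair_rejected(self, demo_genes):
        state = prepare_initial_state(demo_genes)
        with pytest.raises(ConfigurationError):
            apply_cx_sequence(state, Topology(((0, 10),)))


class TestCombineRegisters:
    def test_deterministic_product(self):
        ct1 = [single_gene(1.0, name="a", cell_type="CT1", index=0)]
        ct2 = [GeneSpec("b", 0.0, "CT2", 1, 0)]
        state = combine_registers(ct1, ct2)
        assert exact_distribution(state) == pytest.approx({"10": 1.0})
        assert state.marginal_on(0) == pytest.approx(1.0)

    def test_balanced_product_is_uniform(self):
        ct1 = [single_gene(0.5, name="a", index=0)]
        ct2 = [GeneSpec("b", 0.5, "CT2", 1, 0)]
        dist = exact_distribution(combine_registers(ct1, ct2))
        assert dist == pytest.approx({k: 0.25 for k in ("00", "10", "01", "11")})

    def test_cross_register_covariance_is_zero(self, demo_genes):
        """Without inter-register gates the two cell types are independent."""
        ct1 = [g for g in demo_genes if g.cell_type == "CT1"]
        ct2 = [g for g in demo_genes if g.cell_type == "CT2"]
        state = combine_registers(ct1, ct2)
        probs = state.probabilities()
        idx = np.arange(probs.size)
        bits = (idx[:, None] >> np.arange(10)) & 1
        mean = probs @ bits
        for i in range(5):
            for j in range(5, 10):
                joint = probs @ (bits[:, i] * bits[:, j])
                assert abs(joint - mean[i] * mean[j]) < 1e-12

    def test_overlapping_registers_rejected(self):
        ct1 = [single_gene(0.5, name="a", index=0)]
        ct2 = [GeneSpec("b", 0.5, "CT2", 0, 0)]
        with pytest.raises(ConfigurationError):
            combine_registers(ct1, ct2)


class TestExactDistribution:
    def test_all_off_concentrates_on_zero_string(self):
        genes = [single_gene(0.0, name=f"g{i}", index=i) for i in range(4)]
        dist = exact_distribution(prepare_initial_state(genes))
        assert dist == pytest.approx({"0000": 1.0})

    def test_probabilities_sum_to_one(self, demo_genes, cascade):
        state = build_final_state(demo_genes, [cascade])
        assert sum(exact_distribution(state).values()) == pytest.approx(1.0, abs=1e-12)

    def test_cascade_g5_marginal_closed_form(self, demo_genes, cascade):
        """After CX(3,5), gene 5 reads b5 XOR b3: P = p5(1-p3) + p3(1-p5)."""
        p3, p5 = p_on(0.9), p_on(0.2)
        expected = p5 * (1 - p3) + p3 * (1 - p5)
        state = build_final_state(demo_genes, [cascade])
        dist = exact_distribution(state)
        marginal = sum(p for b, p in dist.items() if b[5] == "1")
        assert marginal == pytest.approx(expected, abs=1e-12)
        assert state.marginal_on(5) == pytest.approx(expected, abs=1e-12)


class TestEndianness:
    def test_reversal_round_trip(self):
        assert reverse_bitstring(reverse_bitstring("0110010011")) == "0110010011"

    def test_logical_position_is_gene_index(self):
        # only gene 3 of 5 is ON: logical string has the 1 at position 3
        genes = [
            single_gene(1.0 if i == 3 else 0.0, name=f"g{i}", index=i)
            for i in range(5)
        ]
        dist = exact_distribution(prepare_initial_state(genes))
        assert dist == pytest.approx({"00010": 1.0})

    def test_index_bitstring_round_trip(self):
        for k in range(32):
            assert bitstring_to_index(index_to_bitstring(k, 5)) == k
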