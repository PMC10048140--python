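import numpy as np
import pandas as pd
import pytest

from edrw.io import DirectedPathwayNetwork
from edrw.walk import (
    bi_random_walk,
    build_entropy_transition,
    entropy_weights,
    gene_entropy,
    shannon_entropy,
    uniform_transition,
    walk_with_restart,
)
from oracles import rwr_linear_solve


def frame_of(rows, genes=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return pd.DataFrame(
        rows,
        index=genes or [f"G{i}" for i in range(rows.shape[0])],
        columns=[f"s{j}" for j in range(rows.shape[1])],
    )


class TestEntropy:
    def test_uniform_row_has_maximal_entropy(self):
        assert shannon_entropy([4, 4, 4, 4]) == pytest.approx(1.0)

    def test_degenerate_mass_has_zero_entropy(self):
        assert shannon_entropy([0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_two_mass_example(self):
        # -(0.25 ln 0.25 + 0.75 ln 0.75)/ln 2
        assert shannon_entropy([0.25, 0.75]) == pytest.approx(0.811278, abs=1e-6)

    def test_gene_entropy_bounds_and_uniform_row(self):
        frame = frame_of([[4.0, 4.0, 4.0, 4.0], [0.0, 1.0, 0.1, 0.2]])
        entropy = gene_entropy(frame)
        assert entropy.iloc[0] == pytest.approx(1.0)
        assert ((entropy >= 0) & (entropy <= 1)).all()

    def test_mass_on_single_sample_is_near_zero(self):
        entropy = gene_entropy(frame_of([[0.0, 1.0]]))
        assert entropy.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            gene_entropy(frame_of([[1.0]]))


class TestEntropyWeights:
    def test_symmetry(self):
        assert np.allclose(entropy_weights(np.array([0.5, 0.5])), [0.5, 0.5])

    def test_arithmetic(self):
        assert np.allclose(entropy_weights(np.array([0.2, 0.6])), [2 / 3, 1 / 3])

    def test_normalisation(self, rng):
        w = entropy_weights(rng.uniform(0, 0.99, size=50))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_entropy_one_raises(self):
        with pytest.raises(ValueError, match="uniform"):
            entropy_weights(np.ones(4))


class TestTransition:
    def test_out_edges_weighted_by_target_entropy_weight(self):
        net = DirectedPathwayNetwork("t", ["u", "v1", "v2"],
                                     [("u", "v1"), ("u", "v2")])
        built = build_entropy_transition(net, {"u": 0.1, "v1": 2 / 3, "v2": 1 / 3})
        row = built.transition[built.node_index["u"]].toarray().ravel()
        assert row[built.node_index["v1"]] == pytest.approx(2 / 3)
        assert row[built.node_index["v2"]] == pytest.approx(1 / 3)

    def test_dangling_node_gets_self_loop(self):
        net = DirectedPathwayNetwork("t", ["a", "b"], [("a", "b")])
        built = build_entropy_transition(net, {"a": 0.5, "b": 0.5})
        i = built.node_index["b"]
        assert built.transition[i, i] == 1.0

    def test_zero_weight_targets_fall_back_to_uniform(self):
        net = DirectedPathwayNetwork("t", ["u", "v1", "v2"],
                                     [("u", "v1"), ("u", "v2")])
        built = build_entropy_transition(net, {"u": 1.0, "v1": 0.0, "v2": 0.0})
        row = built.transition[built.node_index["u"]].toarray().ravel()
        assert row[built.node_index["v1"]] == pytest.approx(0.5)

    def test_equal_weights_reduce_to_out_degree_normalisation(self, rng):
        nodes = [f"N{i}" for i in range(10)]
        edges = sorted({
            (nodes[int(rng.integers(10))], nodes[int(rng.integers(10))])
            for _ in range(25)
        })
        edges = [(u, v) for u, v in edges if u != v]
        net = DirectedPathwayNetwork("t", nodes, edges)
        ew = build_entropy_transition(net, {n: 0.37 for n in nodes})
        uni = uniform_transition(net)
        assert np.allclose(ew.transition.toarray(), uni.transition.toarray(),
                           atol=1e-14)

    def test_rows_are_stochastic(self, rng):
        nodes = [f"N{i}" for i in range(15)]
        edges = sorted({
            (nodes[int(rng.integers(15))], nodes[int(rng.integers(15))])
            for _ in range(50)
        })
        net = DirectedPathwayNetwork("t", nodes, [(u, v) for u, v in edges if u != v])
        built = build_entropy_transition(
            net, dict(zip(nodes, rng.uniform(0.01, 1, size=15)))
        )
        rowsums = np.asarray(built.transition.sum(axis=1)).ravel()
        assert np.abs(rowsums - 1).max() < 1e-12


class TestWalkWithRestart:
    def test_restart_one_returns_h0(self):
        net = uniform_transition(
            DirectedPathwayNetwork("t", ["a", "b"], [("a", "b"), ("b", "a")])
        )
        res = walk_with_restart(net, np.array([0.3, 0.7]), r=1.0)
        assert np.allclose(res.h_inf, [0.3, 0.7])
        assert res.converged

    def test_symmetric_two_cycle_fixed_point(self):
        net = uniform_transition(
            DirectedPathwayNetwork("t", ["a", "b"], [("a", "b"), ("b", "a")])
        )
        for r in (0.1, 0.5, 0.9):
            res = walk_with_restart(net, np.array([0.5, 0.5]), r=r)
            assert np.allclose(res.h_inf, [0.5, 0.5], atol=1e-12)

    def test_three_node_chain_matches_linear_solve(self):
        net = uniform_transition(
            DirectedPathwayNetwork("t", ["A", "B", "C"], [("A", "B"), ("B", "C")])
        )
        h0 = np.array([1.0, 0.0, 0.0])
        res = walk_with_restart(net, h0, r=0.5)
        expected = rwr_linear_solve(net.transition.toarray(), h0, 0.5)
        assert np.abs(res.h_inf.to_numpy() - expected).max() < 1e-8
        assert np.allclose(res.h_inf, [0.5, 0.25, 0.25], atol=1e-8)

    def test_mass_conserved_every_iteration(self):
        net = uniform_transition(
            DirectedPathwayNetwork(
                "t", ["a", "b", "c"], [("a", "b"), ("b", "c"), ("c", "a")]
            )
        )
        res = walk_with_restart(net, np.array([0.2, 0.3, 0.5]), r=0.3)
        assert np.abs(np.array(res.mass_history) - 1.0).max() < 1e-9

    def test_invalid_inputs_raise(self):
        net = uniform_transition(
            DirectedPathwayNetwork("t", ["a", "b"], [("a", "b")])
        )
        with pytest.raises(ValueError):
            walk_with_restart(net, np.array([0.5, 0.6]), r=0.5)
        with pytest.raises(ValueError):
            walk_with_restart(net, np.array([0.5, 0.5]), r=0.0)

    def test_permutation_equivariance(self, rng):
        nodes = [f"N{i}" for i in range(8)]
        edges = sorted({
            (nodes[int(rng.integers(8))], nodes[int(rng.integers(8))])
            for _ in range(20)
        })
        edges = [(u, v) for u, v in edges if u != v]
        ew = dict(zip(nodes, rng.uniform(0.1, 1, size=8)))
        h0 = pd.Series(rng.dirichlet(np.ones(8)), index=nodes)

        net1 = build_entropy_transition(
            DirectedPathwayNetwork("t", nodes, edges), ew
        )
        perm = [nodes[i] for i in rng.permutation(8)]
        net2 = build_entropy_transition(
            DirectedPathwayNetwork("t", perm, list(edges)), ew
        )
        r1 = walk_with_restart(net1, h0, r=0.4).h_inf
        r2 = walk_with_restart(net2, h0, r=0.4).h_inf
        assert np.abs((r1 - r2.reindex(r1.index)).to_numpy()).max() < 1e-12


class TestBiRandomWalk:
    def _prepared(self, name, rng):
        nodes = [f"{name}{i}" for i in range(6)]
        edges = [(nodes[i], nodes[(i + 1) % 6]) for i in range(6)]
        return build_entropy_transition(
            DirectedPathwayNetwork(name, nodes, edges),
            dict(zip(nodes, rng.uniform(0.2, 1, size=6))),
        )

    def test_identical_networks_give_identical_results(self, rng):
        net = self._prepared("X", rng)
        w0 = pd.Series(rng.uniform(size=6), index=net.nodes)
        r1, r2 = bi_random_walk([net, net], w0, r=0.5)
        assert np.allclose(r1.h_inf, r2.h_inf, atol=0)

    def test_disjoint_networks_walk_independently(self, rng):
        net_a, net_b = self._prepared("A", rng), self._prepared("B", rng)
        w0 = pd.Series(
            rng.uniform(size=12), index=list(net_a.nodes) + list(net_b.nodes)
        )
        res_a, res_b = bi_random_walk([net_a, net_b], w0, r=0.5)
        assert set(res_a.h_inf.index) == set(net_a.nodes)
        assert set(res_b.h_inf.index) == set(net_b.nodes)
        assert res_a.h_inf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_shared_genes_raises_with_network_name(self, rng):
        net = self._prepared("Z", rng)
        w0 = pd.Series([0.5, 0.5], index=["other1", "other2"])
        with pytest.raises(ValueError, match="Z"):
            bi_random_walk([net], w0, r=0.5)
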