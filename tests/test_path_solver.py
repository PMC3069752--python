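"""Minimum-weight path extraction: Bellman-Ford vs independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tracefuse.graph_builder import ConsensusGraph, EdgeWeightParams
from tracefuse.model_io import Residue, TargetSequence
from tracefuse.path_solver import (assemble_model, bellman_ford_path,
                                   bidirectional_consensus,
                                   brute_force_min_path, dag_dp_path)

from conftest import random_layered_graph


def _toy_graph(layer_costs):
    """Layered graph where every edge into a vertex costs that vertex's
    hand-set value (weights independent of the source vertex)."""
    L = len(layer_costs)
    g = ConsensusGraph(L, EdgeWeightParams())
    for i, costs in enumerate(layer_costs, start=1):
        for j, c in enumerate(costs):
            g.add_residue_vertex(Residue(i, "L", []), f"t{j}", 0, 0.0, 1, 0)
    prev = [g.source]
    for i, costs in enumerate(layer_costs, start=1):
        for u in prev:
            for v, c in zip(g.layers[i], costs):
                g.add_edge(u, v, float(c))
        prev = g.layers[i]
    for u in prev:
        g.add_edge(u, g.sink, 0.0)
    return g


class TestToyGraphs:
    def test_three_layer_hand_example(self):
        # {a:1,b:2} x {c:5,d:1} x {e:2} -> a-d-e, weight 4
        g = _toy_graph([(1, 2), (5, 1), (2,)])
        res = bellman_ford_path(g)
        assert res.total_weight == pytest.approx(4.0)
        chosen = [g.vertices[res.per_layer_choice[i]].trace_id for i in (1, 2, 3)]
        assert chosen == ["t0", "t1", "t0"]
        assert brute_force_min_path(g).total_weight == pytest.approx(4.0)

    def test_all_dummy_graph_costs_one_gap(self):
        L = 12
        params = EdgeWeightParams()
        g = ConsensusGraph(L, params)
        for i in range(1, L + 1):
            g.add_dummy_vertex(i)
        g.connect_layers()
        res = bellman_ford_path(g)
        assert res.total_weight == pytest.approx(
            params.g_open + (L - 1) * params.g_ext)

    def test_single_vertex_per_layer(self):
        g = _toy_graph([(2,), (3,), (1,)])
        assert brute_force_min_path(g).total_weight == pytest.approx(6.0)

    def test_negative_weights_safe_in_dag(self):
        g = _toy_graph([(-1, 2), (5, -3), (-2,)])
        bf = bellman_ford_path(g)
        assert bf.total_weight == pytest.approx(-6.0)
        assert bf.total_weight == brute_force_min_path(g).total_weight

    def test_brute_force_size_guard(self):
        g = _toy_graph([(1,) * 4] * 6)
        with pytest.raises(ValueError):
            brute_force_min_path(g, max_paths=100)


class TestOracleEquivalence:
    @pytest.mark.parametrize("base_seed", [0, 1000, 2000])
    def test_three_solvers_agree(self, base_seed):
        for k in range(100):
            rng = np.random.default_rng(base_seed + k)
            g = random_layered_graph(rng)
            bf = bellman_ford_path(g)
            dp = dag_dp_path(g)
            brute = brute_force_min_path(g)
            assert bf.total_weight == pytest.approx(brute.total_weight, abs=1e-9)
            assert bf.vertices == brute.vertices == dp.vertices

    def test_agreement_with_networkx_bellman_ford(self):
        import networkx as nx

        for k in range(50):
            rng = np.random.default_rng(31_000 + k)
            g = random_layered_graph(rng)
            G = nx.DiGraph()
            for (u, v), w in g.edges.items():
                G.add_edge(u, v, weight=w)
            nx_len = nx.shortest_path_length(G, g.source, g.sink,
                                             weight="weight",
                                             method="bellman-ford")
            assert bellman_ford_path(g).total_weight == pytest.approx(nx_len, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_solver_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        g = random_layered_graph(rng)
        bf = bellman_ford_path(g)
        brute = brute_force_min_path(g)
        assert bf.total_weight == pytest.approx(brute.total_weight, abs=1e-9)
        assert bf.vertices == brute.vertices


class TestBidirectional:
    def test_directions_agree_on_weight(self):
        for k in range(20):
            rng = np.random.default_rng(7000 + k)
            g = random_layered_graph(rng)
            fwd = bellman_ford_path(g, "N2C")
            rev = bellman_ford_path(g, "C2N")
            assert fwd.total_weight == pytest.approx(rev.total_weight, abs=1e-9)

    def test_tie_broken_by_higher_cc(self):
        # two equal-weight rails; the higher-cc rail must win deterministically
        g = ConsensusGraph(3, EdgeWeightParams())
        for i in (1, 2, 3):
            g.add_residue_vertex(Residue(i, "L", []), "tA", 0, 0.25, 1, 0)
            g.add_residue_vertex(Residue(i, "L", []), "tB", 0, 0.75, 1, 0)
        prev = [g.source]
        for i in (1, 2, 3):
            for u in prev:
                for v in g.layers[i]:
                    g.add_edge(u, v, 1.0)
            prev = g.layers[i]
        for u in prev:
            g.add_edge(u, g.sink, 0.0)
        res = bidirectional_consensus(g)
        assert all(g.vertices[res.per_layer_choice[i]].trace_id == "tB"
                   for i in (1, 2, 3))
        assert res.vertices == brute_force_min_path(g).vertices

    def test_invalid_direction(self):
        g = _toy_graph([(1,)])
        with pytest.raises(ValueError):
            bellman_ford_path(g, "sideways")


class TestLocalOptimality:
    def test_no_single_vertex_swap_improves(self):
        for k in range(10):
            rng = np.random.default_rng(9000 + k)
            g = random_layered_graph(rng)
            res = bellman_ford_path(g)
            base = res.total_weight
            vids = res.vertices
            for pos in range(1, len(vids) - 1):
                layer = g.vertices[vids[pos]].seq_num
                for alt in g.layers[layer]:
                    if alt == vids[pos]:
                        continue
                    trial = vids[:pos] + [alt] + vids[pos + 1:]
                    assert g.path_weight(trial) >= base - 1e-9


class TestAssembly:
    def test_identity_model_from_single_trace(self, identity_fixture):
        from conftest import consensus_pipeline

        truth, frame, target, traces, dmap, _ = identity_fixture
        graph, path, model = consensus_pipeline(identity_fixture)
        inp = list(traces[0].docked_residues())
        assert len(model.residues) == len(inp)
        for a, b in zip(inp, model.residues):
            assert (a.seq_num, a.aa_type) == (b.seq_num, b.aa_type)
            assert b.source_trace == traces[0].trace_id
        assert model.gap_ranges == []

    def test_dummy_run_becomes_gap_annotation(self):
        target = TargetSequence("L" * 300)
        g = ConsensusGraph(300, EdgeWeightParams())
        for i in range(1, 301):
            if not 249 <= i <= 256:
                g.add_residue_vertex(Residue(i, "L", []), "t0", 0, 1.0, 1, 0)
            g.add_dummy_vertex(i)
        g.connect_layers()
        res = bellman_ford_path(g)
        model = assemble_model(res, g, target, overlap_postpass=False)
        assert model.gap_ranges == [(249, 256)]
        assert 256 - 249 + 1 == 8

    def test_per_position_uniqueness_and_order(self, frameshift_fixture):
        from conftest import consensus_pipeline

        _, path, model = consensus_pipeline(frameshift_fixture)
        seqs = [r.seq_num for r in model.residues]
        assert seqs == sorted(set(seqs))
        covered = set(seqs) | {i for s, e in model.gap_ranges
                               for i in range(s, e + 1)}
        assert covered == set(range(1, model.target_length + 1))

    def test_provenance_closure(self, complementary_fixture):
        from conftest import consensus_pipeline

        truth, frame, target, traces, dmap, _ = complementary_fixture
        *_, model = consensus_pipeline(complementary_fixture)
        valid = {t.trace_id for t in traces}
        assert {r.source_trace for r in model.residues} <= valid
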