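"""Shared fixtures: synthetic datasets are generated once per session."""

import numpy as np
import pytest

import tracefuse as tf
from tracefuse.crystal_frame import align_crystallographic, align_ncs, align_to_map
from tracefuse.fixtures import FixtureSpec, make_ground_truth


@pytest.fixture(scope="session")
def identity_fixture():
    return tf.make_fixture_suite("identity", seed=1)


@pytest.fixture(scope="session")
def complementary_fixture():
    return tf.make_fixture_suite("complementary-halves", seed=1)


@pytest.fixture(scope="session")
def frameshift_fixture():
    return tf.make_fixture_suite("frame-shift", seed=1)


@pytest.fixture(scope="session")
def small_truth():
    """A 30-residue ground truth in P212121, undisplaced."""
    spec = FixtureSpec(length=30, seed=7, n_traces=1, displace=False)
    truth, frame, target = make_ground_truth(spec)
    return truth, frame, target


def consensus_pipeline(fixture, **build_kwargs):
    """In-memory pipeline mirroring run_consensus on a generated fixture."""
    truth, frame, target, traces, dmap, manifest = fixture
    ref, _ = align_to_map(traces[0], dmap, frame)
    aligned = [ref]
    for t in traces[1:]:
        moved, _ = align_crystallographic(t, ref, frame)
        aligned.append(moved)
    aligned = align_ncs(aligned, (aligned[0].trace_id,
                                  next(iter(aligned[0].chains))))
    graph = tf.build_graph(aligned, dmap, target, **build_kwargs)
    path = tf.bidirectional_consensus(graph)
    model = tf.assemble_model(path, graph, target)
    model.cell, model.spacegroup = truth.cell, truth.spacegroup
    return graph, path, model


def random_layered_graph(rng, max_layers=6, max_width=4, sigma=2.0):
    """Small random layered graph with N(0, sigma) edge weights and random
    per-vertex density scores for tie-breaking."""
    from tracefuse.graph_builder import ConsensusGraph, EdgeWeightParams
    from tracefuse.model_io import Residue

    L = int(rng.integers(2, max_layers + 1))
    params = EdgeWeightParams()
    g = ConsensusGraph(L, params)
    for i in range(1, L + 1):
        width = int(rng.integers(1, max_width + 1))
        for j in range(width):
            r = Residue(i, "L", [], source_trace=f"t{j}")
            uid = g.add_residue_vertex(r, f"t{j}", 0,
                                       float(np.round(rng.random(), 6)), 1, 0)
    prev = [g.source]
    for i in range(1, L + 1):
        for u in prev:
            for v in g.layers[i]:
                g.add_edge(u, v, float(rng.normal(0.0, sigma)))
        prev = g.layers[i]
    for u in prev:
        g.add_edge(u, g.sink, 0.0)
    return g
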