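"""Minimum-weight consensus path extraction.

The consensus trace is the minimum-weight source-to-sink path of the layered
graph.  Bellman-Ford is the production solver (negative edge weights from
agreement rewards are legal; the graph is acyclic so no negative cycles
exist) and is run in both chain directions, keeping the better result.  Two
independent solvers — a layer-by-layer dynamic program and exhaustive path
enumeration — exist as test oracles.

All solvers share one total order on paths: first total weight, then the
lexicographic tuple of vertex tie-break keys (higher density CC, then lower
trace id, then lower subunit), so ties resolve identically everywhere.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math

import numpy as np

from .graph_builder import ConsensusGraph, Vertex
from .model_io import ConsensusModel, Residue, TargetSequence

__all__ = [
    "PathResult",
    "bellman_ford_path",
    "dag_dp_path",
    "brute_force_min_path",
    "bidirectional_consensus",
    "assemble_model",
]

logger = logging.getLogger(__name__)

_EPS = 1e-9  # weight-equality tolerance for tie-breaking


@dataclasses.dataclass
class PathResult:
    vertices: list[int]            # vertex uids, source..sink
    total_weight: float
    direction: str                 # "N2C" | "C2N"
    per_layer_choice: dict[int, int]

    @classmethod
    def from_vertices(cls, graph: ConsensusGraph, vids: list[int],
                      direction: str) -> "PathResult":
        choice = {graph.vertices[u].seq_num: u for u in vids[1:-1]}
        return cls(list(vids), graph.path_weight(vids), direction, choice)


def _path_key(graph: ConsensusGraph, vids: list[int]) -> tuple:
    return tuple(graph.vertices[u].sort_key for u in vids)


def _better(w_a: float, key_a: tuple, w_b: float, key_b: tuple) -> bool:
    """Is path a strictly better than path b under the shared total order?"""
    if w_a < w_b - _EPS:
        return True
    if w_a > w_b + _EPS:
        return False
    return key_a < key_b


# ---------------------------------------------------------------------------
# Bellman-Ford (production solver)

def bellman_ford_path(graph: ConsensusGraph, direction: str = "N2C") -> PathResult:
    """Minimum-weight path by Bellman-Ford edge relaxation.

    For ``direction="C2N"`` the edges are reversed and the path found from
    sink to source, then reported in forward order.  Relaxation runs until a
    full pass makes no update (at most V-1 passes).
    """
    if direction not in ("N2C", "C2N"):
        raise ValueError("direction must be 'N2C' or 'C2N'")
    if direction == "N2C":
        edges = [(u, v, w) for (u, v), w in graph.edges.items()]
        start, goal = graph.source, graph.sink
    else:
        edges = [(v, u, w) for (u, v), w in graph.edges.items()]
        start, goal = graph.sink, graph.source
    edges.sort()  # deterministic relaxation order

    nv = graph.n_vertices
    dist = [math.inf] * nv
    paths: list[list[int] | None] = [None] * nv
    dist[start] = 0.0
    paths[start] = [start]
    for _ in range(nv - 1):
        updated = False
        for u, v, w in edges:
            if paths[u] is None:
                continue
            nd = dist[u] + w
            cand = paths[u] + [v]
            if paths[v] is None or _better(nd, _path_key(graph, cand),
                                           dist[v], _path_key(graph, paths[v])):
                dist[v] = nd
                paths[v] = cand
                updated = True
        if not updated:
            break
    if paths[goal] is None:
        raise RuntimeError("sentinel unreachable: graph is malformed")
    vids = paths[goal] if direction == "N2C" else paths[goal][::-1]
    return PathResult.from_vertices(graph, vids, direction)


# ---------------------------------------------------------------------------
# independent oracles

def dag_dp_path(graph: ConsensusGraph) -> PathResult:
    """Layer-ordered dynamic program (independent of Bellman-Ford)."""
    best: dict[int, tuple[float, list[int]]] = {graph.source: (0.0, [graph.source])}
    order = [[graph.source]] + [graph.layers[i] for i in range(1, graph.L + 1)] \
        + [[graph.sink]]
    for layer in order[1:]:
        for v in layer:
            chosen = None
            for u in graph.in_edges[v]:
                if u not in best:
                    continue
                w = best[u][0] + graph.edges[(u, v)]
                cand = best[u][1] + [v]
                if chosen is None or _better(w, _path_key(graph, cand),
                                             chosen[0], _path_key(graph, chosen[1])):
                    chosen = (w, cand)
            if chosen is not None:
                best[v] = chosen
    w, vids = best[graph.sink]
    return PathResult.from_vertices(graph, vids, "N2C")


def brute_force_min_path(graph: ConsensusGraph,
                         max_paths: int = 10 ** 6) -> PathResult:
    """Exhaustive enumeration over one-vertex-per-layer choices."""
    sizes = [len(graph.layers[i]) for i in range(1, graph.L + 1)]
    n_paths = math.prod(sizes) if sizes else 1
    if n_paths > max_paths:
        raise ValueError(f"{n_paths} paths exceed the enumeration bound {max_paths}")
    best_vids = None
    best_w = math.inf
    best_key: tuple = ()
    for combo in itertools.product(*(graph.layers[i] for i in range(1, graph.L + 1))):
        vids = [graph.source, *combo, graph.sink]
        if any((u, v) not in graph.edges for u, v in itertools.pairwise(vids)):
            continue
        w = graph.path_weight(vids)
        key = _path_key(graph, vids)
        if best_vids is None or _better(w, key, best_w, best_key):
            best_vids, best_w, best_key = vids, w, key
    if best_vids is None:
        raise RuntimeError("no source-to-sink path exists")
    return PathResult.from_vertices(graph, best_vids, "N2C")


# ---------------------------------------------------------------------------
# bidirectional run and model assembly

def bidirectional_consensus(graph: ConsensusGraph) -> PathResult:
    """Run Bellman-Ford N->C and C->N; keep the lower-weight result.

    On exact arithmetic a DAG shortest path is direction-independent, so a
    weight difference indicates a defect and is logged loudly; differing
    per-layer choices at equal weight are tie-break artifacts of the
    reversed traversal and the N->C result wins.
    """
    fwd = bellman_ford_path(graph, "N2C")
    rev = bellman_ford_path(graph, "C2N")
    if abs(fwd.total_weight - rev.total_weight) > 1e-6:
        logger.error("direction-dependent path weight: N2C %.6f vs C2N %.6f",
                     fwd.total_weight, rev.total_weight)
        return fwd if fwd.total_weight <= rev.total_weight else rev
    if fwd.per_layer_choice != rev.per_layer_choice:
        logger.info("N2C and C2N paths differ only by tie-breaking; keeping N2C")
    return fwd


def _gap_ranges_from_path(graph: ConsensusGraph, path: PathResult
                          ) -> list[tuple[int, int]]:
    gaps = []
    run_start = None
    for i in range(1, graph.L + 1):
        v = graph.vertices[path.per_layer_choice[i]]
        if v.kind == "dummy":
            if run_start is None:
                run_start = i
        elif run_start is not None:
            gaps.append((run_start, i - 1))
            run_start = None
    if run_start is not None:
        gaps.append((run_start, graph.L))
    return gaps


def _overlapping_chosen_pairs(graph: ConsensusGraph, path: PathResult,
                              pos_tol: float) -> list[tuple[int, int]]:
    chosen = [path.per_layer_choice[i] for i in range(1, graph.L + 1)]
    res = [(u, graph.vertices[u]) for u in chosen
           if graph.vertices[u].kind == "residue"]
    pairs = []
    for (u1, v1), (u2, v2) in itertools.combinations(res, 2):
        ca1, ca2 = v1.residue.ca, v2.residue.ca
        if ca1 is not None and ca2 is not None \
                and float(np.linalg.norm(ca1 - ca2)) <= pos_tol:
            pairs.append((u1, u2))
    return pairs


def _remove_vertices(graph: ConsensusGraph, dead: set[int]) -> ConsensusGraph:
    """Copy of the graph without the given residue vertices (dummies keep
    every layer connected)."""
    import copy

    g = copy.copy(graph)
    g.layers = {i: [u for u in graph.layers[i] if u not in dead]
                for i in graph.layers}
    g.edges = {(u, v): w for (u, v), w in graph.edges.items()
               if u not in dead and v not in dead}
    g.out_edges = {u: [v for v in vs if v not in dead]
                   for u, vs in graph.out_edges.items() if u not in dead}
    g.in_edges = {v: [u for u in us if u not in dead]
                  for v, us in graph.in_edges.items() if v not in dead}
    return g


def assemble_model(path: PathResult, graph: ConsensusGraph,
                   target: TargetSequence, overlap_postpass: bool = True,
                   pos_tol: float = 1.0) -> ConsensusModel:
    """Turn the chosen path into the output consensus model.

    Residue vertices become output residues with their source-trace
    provenance; maximal dummy runs become gap ranges.  If two chosen
    residues still overlap in space after the static overlap penalty, the
    lower-CC one is removed from the graph and the path re-solved once.
    """
    if overlap_postpass:
        pairs = _overlapping_chosen_pairs(graph, path, pos_tol)
        if pairs:
            dead = set()
            for u1, u2 in pairs:
                v1, v2 = graph.vertices[u1], graph.vertices[u2]
                dead.add(u1 if v1.cc <= v2.cc else u2)
            logger.info("overlap post-pass removes %d residue(s); re-solving path",
                        len(dead))
            pruned = _remove_vertices(graph, dead)
            path = bidirectional_consensus(pruned)
            graph = pruned

    residues = []
    for i in range(1, graph.L + 1):
        v = graph.vertices[path.per_layer_choice[i]]
        if v.kind == "residue":
            r = v.residue.copy()
            r.chain_id = "A"
            residues.append(r)
    gaps = _gap_ranges_from_path(graph, path)
    return ConsensusModel(residues, gaps, target.length,
                          total_weight=path.total_weight)
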