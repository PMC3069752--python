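"""Layered consensus graph over superposed traces.

Every docked residue of every (filtered, superposed) trace becomes a vertex
in the layer of its sequence number; each layer also holds one dummy vertex
so a gap is always available.  Directed edges connect every vertex at
position i-1 to every vertex at position i (plus source/sink sentinels), so
any source-to-sink path selects exactly one residue or gap per position.

Edge weights combine five terms:

(i)   density fit          w_cc * (1 - cc) for the destination residue;
(ii)  agreement reward    -w_agree * (agreement_count - 1), where agreement
      counts distinct traces placing the *same* residue at that spot;
(iii) geometry penalties   p_rama for a disallowed junction conformation and
      p_ca per A of CA-CA deviation from 3.8 A beyond a 0.5 A tolerance;
(iv)  overlap penalty      p_overlap per spatial rival (a residue of a
      *different* sequence number sharing the spot — register errors overlap
      in space) that fits the density strictly better than this residue.
      Penalizing only the worse-fitting member of an overlap pushes the
      impostor out while leaving the correct residue cheaper than a gap;
      a leftover both-chosen overlap is resolved by the post-path pass;
(v)   gap terms            g_open once to open a gap, g_ext per dummy to
      continue it; closing a gap is free.

Residue-level terms are folded into the incoming edges of the destination
vertex, the usual DAG reduction making the path sum equal the model score.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .density import DensityMap, residue_density_cc
from .model_io import Residue, TargetSequence, Trace

__all__ = [
    "Vertex",
    "EdgeWeightParams",
    "ConsensusGraph",
    "cluster_positions",
    "edge_weight",
    "build_graph",
    "dihedral",
    "rama_allowed",
]

logger = logging.getLogger(__name__)

SOURCE = -1  #: sentinel layer before position 1
_RAMA_BIN = 10  # degrees per mask bin


@dataclasses.dataclass
class Vertex:
    kind: str                      # "residue" | "dummy" | "source" | "sink"
    seq_num: int
    residue: Residue | None = None
    trace_id: str = ""
    subunit: int = 0
    agreement_count: int = 1
    overlap_count: int = 0
    cc: float = 0.0
    uid: int = -1
    #: overlapping rivals with strictly better density fit; this is the count
    #: the overlap penalty applies to (falls back to overlap_count when the
    #: vertex is built without density information)
    overlap_penalized: int | None = None

    @property
    def effective_overlap(self) -> int:
        return self.overlap_count if self.overlap_penalized is None \
            else self.overlap_penalized

    @property
    def sort_key(self) -> tuple:
        """Deterministic tie-break: residues before dummies, then higher cc,
        lower trace_id, lower subunit."""
        if self.kind == "residue":
            return (0, -self.cc, self.trace_id, self.subunit, self.uid)
        if self.kind == "dummy":
            return (1, 0.0, "", 0, self.uid)
        return (2, 0.0, "", 0, self.uid)


@dataclasses.dataclass
class EdgeWeightParams:
    """Tunable weights of the five edge-score components.

    Defaults are shipped in ``data/default_weights.yaml`` and chosen so that
    one extra agreeing trace (w_agree) outweighs a 0.5 loss of density CC,
    and one spatial overlap (p_overlap) outweighs two agreements.
    """

    w_cc: float = 1.0
    w_agree: float = 0.5
    p_rama: float = 2.0
    p_ca: float = 2.0
    d_ca: float = 3.8
    tol_ca: float = 0.5
    p_overlap: float = 3.0
    g_open: float = 5.0
    g_ext: float = 1.5

    def __post_init__(self) -> None:
        for name in ("w_cc", "w_agree", "p_rama", "p_ca", "p_overlap",
                     "g_open", "g_ext"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.g_open <= self.g_ext:
            raise ValueError("gap opening must cost more than gap extension")

    @classmethod
    def default(cls) -> "EdgeWeightParams":
        text = resources.files("tracefuse.data").joinpath(
            "default_weights.yaml").read_text()
        return cls(**yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "EdgeWeightParams":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        base = dataclasses.asdict(cls.default())
        unknown = set(overrides) - set(base)
        if unknown:
            raise ValueError(f"unknown weight parameters: {sorted(unknown)}")
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# Ramachandran mask (coarse 10-degree boolean grids, packaged data)

_rama_masks: dict[str, np.ndarray] | None = None


def _load_rama_masks() -> dict[str, np.ndarray]:
    global _rama_masks
    if _rama_masks is None:
        text = resources.files("tracefuse.data").joinpath(
            "rama_masks.json").read_text()
        raw = json.loads(text)
        _rama_masks = {k: np.array(v, dtype=bool) for k, v in raw.items()}
    return _rama_masks


def rama_allowed(phi: float, psi: float, aa_type: str = "L") -> bool:
    """Is (phi, psi) inside the coarse allowed region for this residue type?

    Three masks: general, glycine (symmetric) and proline (phi-restricted),
    each a 36x36 boolean grid over [-180, 180) in 10-degree bins.
    """
    masks = _load_rama_masks()
    key = {"G": "GLY", "P": "PRO"}.get(aa_type, "general")
    m = masks[key]
    i = int((phi + 180.0) // _RAMA_BIN) % 36
    j = int((psi + 180.0) // _RAMA_BIN) % 36
    return bool(m[i, j])


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in [-180, 180)."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = float(np.degrees(np.arctan2(y, x)))
    return ang if ang < 180.0 else -180.0


# ---------------------------------------------------------------------------
# spatial clustering: agreement & overlap counts

@dataclasses.dataclass
class ClusterInfo:
    """Spatial-cluster statistics of one residue."""

    agreement_count: int   # distinct traces with the same residue here (incl. self)
    overlap_count: int     # cluster members carrying a different seq_num
    rivals: list = dataclasses.field(default_factory=list)  # those members


def cluster_positions(traces: Sequence[Trace], pos_tol: float = 1.0
                      ) -> dict[int, ClusterInfo]:
    """Single-linkage clusters of docked residues whose CA atoms coincide.

    Returns a mapping from ``id(residue)`` to its :class:`ClusterInfo`:
    agreement counts distinct traces contributing a residue of the *same*
    sequence number to the cluster (self included); overlap counts cluster
    members carrying a *different* sequence number (the ``rivals``).
    """
    entries = []  # (residue, trace_id, ca)
    for t in traces:
        for r in t.docked_residues():
            if r.ca is not None:
                entries.append((r, t.trace_id, r.ca))
    result: dict[int, ClusterInfo] = {}
    if not entries:
        return result
    xyz = np.array([e[2] for e in entries])
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(pos_tol)
    parent = list(range(len(entries)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    clusters: dict[int, list[int]] = {}
    for i in range(len(entries)):
        clusters.setdefault(find(i), []).append(i)
    for members in clusters.values():
        for i in members:
            res_i, _, _ = entries[i]
            traces_same = {entries[j][1] for j in members
                           if entries[j][0].seq_num == res_i.seq_num}
            rivals = [entries[j][0] for j in members
                      if entries[j][0].seq_num != res_i.seq_num]
            result[id(res_i)] = ClusterInfo(len(traces_same), len(rivals), rivals)
    return result


# ---------------------------------------------------------------------------
# edge weights

def _junction_geometry(u: Vertex, v: Vertex, params: EdgeWeightParams) -> float:
    """Geometry terms for a residue->residue step: CA-CA deviation penalty
    and the junction Ramachandran check.

    With only residues i-1 and i in hand, the torsions that depend on their
    shared peptide bond are psi(i-1) (via N of i) and phi(i) (via C of i-1);
    the pair is tested against the coarse allowed mask of the destination
    residue's type.  Missing atoms skip the corresponding term.
    """
    w = 0.0
    ru, rv = u.residue, v.residue
    ca_u, ca_v = ru.ca, rv.ca
    if ca_u is not None and ca_v is not None:
        d = float(np.linalg.norm(ca_v - ca_u))
        w += params.p_ca * max(0.0, abs(d - params.d_ca) - params.tol_ca)
    n_u, c_u = ru.atom("N"), ru.atom("C")
    n_v, c_v = rv.atom("N"), rv.atom("C")
    if all(a is not None for a in (n_u, c_u, n_v, c_v)) \
            and ca_u is not None and ca_v is not None:
        psi_u = dihedral(n_u.xyz, ca_u, c_u.xyz, n_v.xyz)
        phi_v = dihedral(c_u.xyz, n_v.xyz, ca_v, c_v.xyz)
        if not rama_allowed(phi_v, psi_u, rv.aa_type):
            w += params.p_rama
    return w


def edge_weight(u: Vertex, v: Vertex, params: EdgeWeightParams) -> float:
    """Weight of the directed edge u -> v (destination-residue terms folded in)."""
    w = 0.0
    if v.kind == "residue":
        w += params.w_cc * (1.0 - v.cc)
        w -= params.w_agree * (v.agreement_count - 1)
        w += params.p_overlap * v.effective_overlap
        if u.kind == "residue":
            w += _junction_geometry(u, v, params)
        # entering a residue from a dummy (gap closing) adds nothing
    elif v.kind == "dummy":
        w += params.g_ext if u.kind == "dummy" else params.g_open
    # sink edges carry 0
    return w


# ---------------------------------------------------------------------------
# graph construction

class ConsensusGraph:
    """Sequence-position-layered DAG of residue and dummy vertices."""

    def __init__(self, target_length: int, params: EdgeWeightParams):
        self.L = target_length
        self.params = params
        self.vertices: list[Vertex] = []
        self.layers: dict[int, list[int]] = {i: [] for i in range(1, target_length + 1)}
        self.edges: dict[tuple[int, int], float] = {}
        self.out_edges: dict[int, list[int]] = {}
        self.in_edges: dict[int, list[int]] = {}
        self.source = self._add_vertex(Vertex("source", 0))
        self.sink = self._add_vertex(Vertex("sink", target_length + 1))

    def _add_vertex(self, v: Vertex) -> int:
        v.uid = len(self.vertices)
        self.vertices.append(v)
        self.out_edges[v.uid] = []
        self.in_edges[v.uid] = []
        if 1 <= v.seq_num <= self.L and v.kind in ("residue", "dummy"):
            self.layers[v.seq_num].append(v.uid)
        return v.uid

    def add_residue_vertex(self, res: Residue, trace_id: str, subunit: int,
                           cc: float, agreement: int, overlap: int) -> int:
        return self._add_vertex(Vertex("residue", res.seq_num, res, trace_id,
                                       subunit, agreement, overlap, cc))

    def add_dummy_vertex(self, seq_num: int) -> int:
        return self._add_vertex(Vertex("dummy", seq_num))

    def add_edge(self, u: int, v: int, weight: float) -> None:
        self.edges[(u, v)] = weight
        self.out_edges[u].append(v)
        self.in_edges[v].append(u)

    def connect_layers(self) -> None:
        """Fully connect consecutive layers plus source/sink sentinels."""
        prev = [self.source]
        for i in range(1, self.L + 1):
            for u in prev:
                for v in self.layers[i]:
                    self.add_edge(u, v, edge_weight(self.vertices[u],
                                                    self.vertices[v],
                                                    self.params))
            prev = self.layers[i]
        for u in prev:
            self.add_edge(u, self.sink, 0.0)

    def path_weight(self, vertex_ids: Sequence[int]) -> float:
        return sum(self.edges[(u, v)] for u, v in itertools.pairwise(vertex_ids))

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_graph(traces: Sequence[Trace], dmap: DensityMap | None,
                target: TargetSequence,
                params: EdgeWeightParams | None = None,
                pos_tol: float = 1.0, resolution: float = 2.5,
                cc_mainchain_only: bool = False,
                cross_subunit: bool = True) -> ConsensusGraph:
    """Build the full consensus graph from filtered, superposed traces.

    Undocked fragments are set aside (they carry no sequence assignment and
    cannot occupy a layer).  With ``cross_subunit=False``, edges are kept
    within one NCS copy; by default paths may cross copies, with geometry
    penalties applying in the common frame.
    """
    if not traces:
        raise ValueError("no input traces")
    params = params or EdgeWeightParams.default()
    if dmap is not None:
        for t in traces:
            dmap.check_cell(t.cell)
    counts = cluster_positions(traces, pos_tol)
    # density fit first: the overlap penalty needs every rival's cc
    cc_of: dict[int, float] = {}
    for t in traces:
        for residues in t.chains.values():
            by_seq = {r.seq_num: r for r in residues}
            for r in residues:
                if dmap is None:
                    cc_of[id(r)] = 0.0
                    continue
                context = tuple(by_seq[s] for s in (r.seq_num - 1, r.seq_num + 1)
                                if s in by_seq)
                score = residue_density_cc(
                    r, dmap, resolution=resolution,
                    mainchain_only=cc_mainchain_only, context=context)
                cc_of[id(r)] = score.cc if score.scorable else 0.0

    g = ConsensusGraph(target.length, params)
    for t in traces:
        for subunit, (cid, residues) in enumerate(t.chains.items()):
            for r in residues:
                cc = cc_of[id(r)]
                info = counts.get(id(r))
                if info is None:
                    agree, over, pen = 1, 0, 0
                else:
                    agree, over = info.agreement_count, info.overlap_count
                    pen = sum(1 for rv in info.rivals
                              if cc_of.get(id(rv), 0.0) > cc + 1e-12)
                uid = g.add_residue_vertex(r, t.trace_id, subunit, cc, agree, over)
                g.vertices[uid].overlap_penalized = pen
    for i in range(1, target.length + 1):
        g.add_dummy_vertex(i)
    if cross_subunit:
        g.connect_layers()
    else:
        _connect_within_subunit(g)
    logger.info("graph: %d vertices, %d edges over %d layers",
                g.n_vertices, g.n_edges, g.L)
    return g


def _connect_within_subunit(g: ConsensusGraph) -> None:
    """Variant wiring: residue->residue edges only within one (trace, subunit);
    dummies connect to everything, so the graph stays connected."""
    prev = [g.source]
    for i in range(1, g.L + 1):
        for u in prev:
            vu = g.vertices[u]
            for v in g.layers[i]:
                vv = g.vertices[v]
                if (vu.kind == "residue" and vv.kind == "residue"
                        and (vu.trace_id, vu.subunit) != (vv.trace_id, vv.subunit)):
                    continue
                g.add_edge(u, v, edge_weight(vu, vv, g.params))
        prev = g.layers[i]
    for u in prev:
        g.add_edge(u, g.sink, 0.0)
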