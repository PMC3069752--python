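"""Synthetic ground truths, degraded traces and matching maps.

Every algorithmic claim of the package is testable without crystallographic
data: this module builds an idealized-geometry polypeptide (trans peptides,
CA steps of ~3.8 A, torsions drawn from allowed Ramachandran regions) inside
a derived unit cell, derives input traces from it with controlled error
modes — deletions, register ("frame") shifts, mistraced segments, undocked
conversion and a global crystallographic displacement — and synthesizes a
density map from the truth.  Everything an error mode does is recorded in a
manifest so metric oracles are exact rather than statistical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation
from scipy.spatial import cKDTree

from .crystal_frame import CrystalFrame
from .density import DensityMap, synthesize_map, write_map
from .model_io import Atom, Residue, TargetSequence, Trace, write_trace, _AA1

__all__ = ["FixtureSpec", "make_ground_truth", "degrade", "make_fixture_suite",
           "FIXTURE_NAMES"]

# idealized backbone internal coordinates (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_B_C_O, _B_CA_CB, _B_CB_CG = 1.231, 1.530, 1.520
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 117.2, 121.7
_A_CA_C_O, _A_N_CA_CB, _A_CA_CB_CG = 120.5, 110.6, 114.0
_OMEGA = 180.0

#: torsion library sampled by the generator: (phi, psi, weight)
_PHI_PSI_LIBRARY = [(-62.0, -42.0, 0.70), (-120.0, 135.0, 0.30)]

#: residue alphabet for generated targets; G/A/P excluded so every residue
#: carries a side chain beyond CB and uses the general Ramachandran mask
_GEN_ALPHABET = "LIVFMSTNQDEKRHWYC"

FIXTURE_NAMES = ("identity", "complementary-halves", "frame-shift",
                 "mistrace", "ncs-2copies")


@dataclasses.dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``deletion_frac``, ``frameshift_segments`` and ``mistrace_segments`` are
    per-trace lists; ``keep_ranges`` (optional, per trace) restricts a trace
    to explicit 1-based inclusive residue ranges before random deletion.
    """

    length: int = 100
    n_ncs: int = 1
    spacegroup: str = "P 21 21 21"
    n_traces: int = 2
    deletion_frac: list[float] = dataclasses.field(default_factory=list)
    keep_ranges: list[list[tuple[int, int]] | None] = dataclasses.field(default_factory=list)
    frameshift_segments: list[list[tuple[int, int, int]]] = dataclasses.field(default_factory=list)
    mistrace_segments: list[list[tuple[int, int, float]]] = dataclasses.field(default_factory=list)
    strip_sidechain_ranges: list[list[tuple[int, int]] | None] = dataclasses.field(default_factory=list)
    undocked_frac: list[float] = dataclasses.field(default_factory=list)
    displace: bool = True
    map_resolution: float = 2.5
    map_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in self.deletion_frac + self.undocked_frac:
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        for segs in self.frameshift_segments:
            for _, _, shift in segs:
                if shift == 0:
                    raise ValueError("frame-shift of 0 is not a shift")

    def per_trace(self, field: str, i: int, default):
        vals = getattr(self, field)
        return vals[i] if i < len(vals) else default

    @classmethod
    def from_yaml(cls, path) -> "FixtureSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("frameshift_segments", "mistrace_segments"):
            if key in raw:
                raw[key] = [[tuple(seg) for seg in per_trace]
                            for per_trace in raw[key]]
        for key in ("keep_ranges", "strip_sidechain_ranges"):
            if key in raw:
                raw[key] = [None if pr is None else [tuple(s) for s in pr]
                            for pr in raw[key]]
        return cls(**raw)


# ---------------------------------------------------------------------------
# backbone construction (NeRF placement)

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    ang, tor = np.radians(angle), -np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(tor),
                        bond * np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _sample_phi_psi(rng: np.random.Generator, n: int) -> list[tuple[float, float]]:
    """Segment-wise torsion sampling: helix- or strand-like runs of 5-15
    residues, jittered within the allowed regions."""
    out: list[tuple[float, float]] = []
    weights = np.array([w for _, _, w in _PHI_PSI_LIBRARY])
    while len(out) < n:
        k = rng.choice(len(_PHI_PSI_LIBRARY), p=weights / weights.sum())
        phi0, psi0, _ = _PHI_PSI_LIBRARY[k]
        seg = int(rng.integers(5, 16))
        for _ in range(min(seg, n - len(out))):
            out.append((phi0 + float(rng.uniform(-8, 8)),
                        psi0 + float(rng.uniform(-8, 8))))
    return out


def _build_backbone(seq: str, rng: np.random.Generator,
                    max_attempts: int = 100) -> list[dict[str, np.ndarray]]:
    """Self-avoiding idealized backbone with CB and a CG stub per residue."""
    n = len(seq)
    for _ in range(max_attempts):
        torsions = _sample_phi_psi(rng, n)
        residues: list[dict[str, np.ndarray]] = []
        # residue 1 in a canonical local frame
        N = np.zeros(3)
        CA = np.array([_B_N_CA, 0.0, 0.0])
        ang = np.radians(_A_N_CA_C)
        C = CA + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        residues.append({"N": N, "CA": CA, "C": C})
        ok = True
        for i in range(1, n):
            phi, _ = torsions[i]
            _, psi_prev = torsions[i - 1]
            prev = residues[-1]
            Nn = _place_atom(prev["N"], prev["CA"], prev["C"],
                             _B_C_N, _A_CA_C_N, psi_prev)
            CAn = _place_atom(prev["CA"], prev["C"], Nn,
                              _B_N_CA, _A_C_N_CA, _OMEGA)
            Cn = _place_atom(prev["C"], Nn, CAn, _B_CA_C, _A_N_CA_C, phi)
            residues.append({"N": Nn, "CA": CAn, "C": Cn})
        # decorate: O, CB, CG (CG only for residues with side chains past CB)
        for i, res in enumerate(residues):
            nxt_n = residues[i + 1]["N"] if i + 1 < n else None
            psi = torsions[i][1]
            res["O"] = _place_atom(res["N"], res["CA"], res["C"],
                                   _B_C_O, _A_CA_C_O, psi + 180.0)
            if seq[i] != "G":
                res["CB"] = _place_atom(res["C"], res["N"], res["CA"],
                                        _B_CA_CB, _A_N_CA_CB, 122.5)
                if seq[i] != "A":
                    res["CG"] = _place_atom(res["N"], res["CA"], res["CB"],
                                            _B_CB_CG, _A_CA_CB_CG, -65.0)
        cas = np.array([r["CA"] for r in residues])
        tree = cKDTree(cas)
        for i, j in tree.query_pairs(3.5):
            if abs(i - j) >= 3:
                ok = False
                break
        if ok:
            return residues
    raise RuntimeError("could not build a self-avoiding backbone")


def _cell_for(coords: np.ndarray, spacegroup: str, margin: float = 9.0
              ) -> tuple[tuple[float, ...], np.ndarray]:
    """Derive a cell holding the content with roughly half the volume as
    solvent: bounding box plus margin, axes constrained by the crystal
    system.  Returns (cell, shift) where shift anchors the content near the
    origin with slightly different offsets per axis, keeping it off special
    positions (axes and diagonals) where symmetry images would collide."""
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    ext = hi - lo + 2 * margin
    sg = spacegroup.replace(" ", "").upper()
    a, b, c = ext
    if sg.startswith(("P4", "I4", "P3", "P6", "H3", "R3")):
        a = b = max(a, b)
    if sg.startswith(("P3", "P6", "H3", "R3")):
        gamma = 120.0
    else:
        gamma = 90.0
    cell = (float(a), float(b), float(c), 90.0, 90.0, gamma)
    shift = np.array([7.0, 9.5, 12.0]) - lo
    return cell, shift


def _min_symmetry_contact(frame: CrystalFrame, xyz: np.ndarray) -> float:
    """Smallest distance between the content and any non-identity symmetry
    image (nearest periodic image per axis)."""
    frac = frame.fractionalize(xyz)
    tree = cKDTree(xyz)
    best = np.inf
    for R, t in frame.sym_ops[1:]:
        img = frac @ R.T + t
        # bring each image atom to its nearest periodic copy w.r.t. content
        diff_center = img.mean(axis=0) - frac.mean(axis=0)
        img = img - np.round(diff_center)
        img_cart = frame.orthogonalize(img)
        d, _ = tree.query(img_cart, k=1)
        best = min(best, float(d.min()))
    return best


def make_ground_truth(spec: FixtureSpec) -> tuple[Trace, CrystalFrame, TargetSequence]:
    """Ground-truth trace (all residues docked, full stub side chains), its
    crystal frame, and the target sequence."""
    rng = np.random.default_rng(spec.seed)
    seq = "".join(_GEN_ALPHABET[rng.integers(0, len(_GEN_ALPHABET))]
                  for _ in range(spec.length))
    target = TargetSequence(seq)
    backbone = _build_backbone(seq, rng)

    copies = [backbone]
    base = np.array([r["CA"] for r in backbone])
    extent = float(np.linalg.norm(base.max(axis=0) - base.min(axis=0)))
    for _ in range(1, spec.n_ncs):
        for _attempt in range(100):
            R = Rotation.random(random_state=rng).as_matrix()
            offset = rng.uniform(0.6, 1.0) * (extent + 10.0) * _random_unit(rng)
            moved = [{k: R @ v + offset for k, v in res.items()} for res in backbone]
            all_prev = np.concatenate([[v for res in c for v in res.values()]
                                       for c in copies])
            new_xyz = np.array([v for res in moved for v in res.values()])
            d, _ = cKDTree(all_prev).query(new_xyz, k=1)
            if d.min() >= 2.0:
                copies.append(moved)
                break
        else:
            raise RuntimeError("could not place NCS copy without clashes; "
                               "consider a larger cell")

    all_xyz = np.array([v for c in copies for res in c for v in res.values()])
    for _attempt in range(100):
        cell, shift = _cell_for(all_xyz, spec.spacegroup,
                                margin=9.0 + 3.0 * _attempt)
        frame = CrystalFrame(cell, spec.spacegroup)
        shifted = all_xyz + shift
        if len(frame.sym_ops) == 1 or _min_symmetry_contact(frame, shifted) >= 2.0:
            break
    else:
        raise RuntimeError("symmetry packing failed; consider a larger cell")

    chains = {}
    for ci, copy_atoms in enumerate(copies):
        cid = chr(ord("A") + ci)
        residues = []
        for i, res in enumerate(copy_atoms, start=1):
            atoms = [Atom(name, "C" if name.startswith("C") else name[0],
                          np.asarray(v, dtype=float) + shift)
                     for name, v in res.items()]
            residues.append(Residue(i, seq[i - 1], atoms, cid, True, "truth"))
        chains[cid] = residues
    truth = Trace("truth", chains, [], spec.length, cell, spec.spacegroup)
    return truth, frame, target


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# degradation

def degrade(truth: Trace, spec: FixtureSpec, trace_index: int,
            frame: CrystalFrame | None = None) -> tuple[Trace, dict]:
    """Derive input trace ``trace_index`` from the ground truth.

    Applies, in order: explicit keep-ranges, random deletions, frame shifts
    (segment residues relabeled ``seq_num + shift``, collisions dropped),
    mistraced segments (rigid random displacement of the stated magnitude),
    undocked conversion (residues stripped to UNK fragments), and a global
    crystallographic displacement (random symmetry operator plus allowed
    origin shift) so superposition recovery is always exercised.

    Returns the trace and a manifest recording every injected error.
    """
    rng = np.random.default_rng((spec.seed, 1000 + trace_index))
    tid = f"trace{trace_index}"
    manifest: dict = {"trace_id": tid}
    L = truth.target_length
    trace = truth.copy()
    trace.trace_id = tid
    for r in trace.all_residues():
        r.source_trace = tid

    keep = spec.per_trace("keep_ranges", trace_index, None)
    if keep is not None:
        allowed = set()
        for s, e in keep:
            allowed.update(range(s, e + 1))
        for cid in trace.chains:
            trace.chains[cid] = [r for r in trace.chains[cid]
                                 if r.seq_num in allowed]
        manifest["keep_ranges"] = [list(r) for r in keep]

    frac = spec.per_trace("deletion_frac", trace_index, 0.0)
    deleted: list[int] = []
    if frac > 0:
        for cid in trace.chains:
            kept = []
            for r in trace.chains[cid]:
                if rng.random() < frac:
                    deleted.append(r.seq_num)
                else:
                    kept.append(r)
            trace.chains[cid] = kept
    manifest["deleted"] = sorted(deleted)

    aa_of = {r.seq_num: r.aa_type for r in truth.docked_residues()}
    shifts = spec.per_trace("frameshift_segments", trace_index, [])
    shifted_log = []
    for start, length, shift in shifts:
        for cid, residues in trace.chains.items():
            seg_ids = {id(r) for r in residues
                       if start <= r.seq_num < start + length}
            others = {r.seq_num for r in residues if id(r) not in seg_ids}
            kept = []
            for r in residues:
                if id(r) not in seg_ids:
                    kept.append(r)
                    continue
                new_seq = r.seq_num + shift
                if new_seq < 1 or new_seq > L or new_seq in others:
                    continue  # clipped or colliding: drop the shifted residue
                shifted_log.append({"chain": cid, "old": r.seq_num, "new": new_seq})
                r.seq_num = new_seq
                # the trace believes its new number: label accordingly
                r.aa_type = aa_of.get(new_seq, r.aa_type)
                kept.append(r)
            kept.sort(key=lambda r: r.seq_num)
            trace.chains[cid] = kept
    manifest["frameshifted"] = shifted_log

    mist = spec.per_trace("mistrace_segments", trace_index, [])
    mist_log = []
    for start, length, magnitude in mist:
        R = Rotation.from_rotvec(np.radians(rng.uniform(5, 15)) *
                                 _random_unit(rng)).as_matrix()
        tvec = magnitude * _random_unit(rng)
        for cid, residues in trace.chains.items():
            seg = [r for r in residues if start <= r.seq_num < start + length]
            if not seg:
                continue
            center = np.mean([r.ca for r in seg], axis=0)
            for r in seg:
                for a in r.atoms:
                    a.xyz = R @ (a.xyz - center) + center + tvec
            mist_log.append({"chain": cid, "start": start, "length": len(seg),
                             "displacement": float(magnitude)})
    manifest["mistraced"] = mist_log

    strip = spec.per_trace("strip_sidechain_ranges", trace_index, None)
    stripped_log = []
    if strip:
        in_strip = set()
        for s, e in strip:
            in_strip.update(range(s, e + 1))
        for residues in trace.chains.values():
            for r in residues:
                if r.seq_num in in_strip:
                    r.atoms = [a for a in r.atoms
                               if a.name in ("N", "CA", "C", "O", "CB")]
                    stripped_log.append(r.seq_num)
    manifest["sidechain_stripped"] = sorted(stripped_log)

    ufrac = spec.per_trace("undocked_frac", trace_index, 0.0)
    undocked_log = []
    if ufrac > 0:
        for cid in trace.chains:
            kept = []
            for r in trace.chains[cid]:
                if rng.random() < ufrac:
                    r.docked = False
                    r.aa_type = "X"
                    r.atoms = [a for a in r.atoms if a.name in ("N", "CA", "C", "O")]
                    trace.undocked_fragments.append([r])
                    undocked_log.append(r.seq_num)
                else:
                    kept.append(r)
            trace.chains[cid] = kept
    manifest["undocked"] = sorted(undocked_log)

    if not any(trace.chains.values()):
        raise ValueError("degradation removed every docked residue")

    if spec.displace and frame is not None:
        op_idx = int(rng.integers(0, len(frame.sym_ops)))
        R_f, t_f = frame.sym_ops[op_idx]
        shift_f = frame.origin_shifts[
            int(rng.integers(0, len(frame.origin_shifts)))].copy()
        for k in frame.polar_axes:
            shift_f[k] = float(rng.uniform(0, 1))
        R_c = frame._orth @ R_f @ frame._frac
        t_c = frame._orth @ (t_f + shift_f)
        for r in trace.all_residues():
            for a in r.atoms:
                a.xyz = R_c @ a.xyz + t_c
        manifest["displacement"] = {"sym_op": op_idx,
                                    "origin_shift": [float(x) for x in shift_f]}
    else:
        manifest["displacement"] = None

    return trace, manifest


# ---------------------------------------------------------------------------
# named fixture suite

def _base_spec(name: str, seed: int) -> FixtureSpec:
    if name == "identity":
        return FixtureSpec(length=60, n_traces=1, seed=seed, displace=False)
    if name == "complementary-halves":
        # trace0: N-terminal 57% with side chains; trace1: residues 44-100
        # but side chains only on 62-100 (39%).  Union covers the target;
        # the 44-57 overlap provides superposition correspondence.
        return FixtureSpec(length=100, n_traces=2, seed=seed,
                           keep_ranges=[[(1, 57)], [(44, 100)]],
                           strip_sidechain_ranges=[None, [(44, 61)]])
    if name == "frame-shift":
        # the shifted trace skips 50-53, so the +4 relabeling of 40-49 is
        # collision-free: a 10-residue register error next to a skipped loop
        return FixtureSpec(length=80, n_traces=2, seed=seed,
                           keep_ranges=[None, [(1, 49), (54, 80)]],
                           frameshift_segments=[[], [(40, 10, 4)]])
    if name == "mistrace":
        return FixtureSpec(length=80, n_traces=2, seed=seed,
                           mistrace_segments=[[], [(30, 10, 8.0)]])
    if name == "ncs-2copies":
        return FixtureSpec(length=60, n_ncs=2, n_traces=2, seed=seed,
                           deletion_frac=[0.1, 0.1])
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def make_fixture_suite(name: str, seed: int = 0,
                       outdir: str | Path | None = None,
                       spec: FixtureSpec | None = None):
    """Build a named regression fixture (or any explicit spec).

    Returns ``(truth, frame, target, traces, dmap, manifest)``; with
    ``outdir`` set, also writes truth/trace PDBs, the CCP4 map, the target
    FASTA and a JSON manifest.  Identical (spec, seed) give byte-identical
    files: coordinates are serialized at fixed PDB precision.
    """
    spec = spec or _base_spec(name, seed)
    truth, frame, target = make_ground_truth(spec)
    traces = []
    manifest = {"fixture": name, "seed": spec.seed,
                "spec": _spec_to_jsonable(spec), "traces": []}
    for i in range(spec.n_traces):
        t, m = degrade(truth, spec, i, frame)
        traces.append(t)
        manifest["traces"].append(m)
    dmap = synthesize_map(truth, spec.map_resolution,
                          noise_sigma=spec.map_noise,
                          rng=np.random.default_rng((spec.seed, 7)))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trace(truth, outdir / "truth.pdb")
        for t in traces:
            write_trace(t, outdir / f"{t.trace_id}.pdb")
        write_map(dmap, outdir / "map.ccp4")
        (outdir / "target.fasta").write_text(
            f">target\n{target.residues}\n")
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return truth, frame, target, traces, dmap, manifest


def _spec_to_jsonable(spec: FixtureSpec) -> dict:
    d = dataclasses.asdict(spec)
    return json.loads(json.dumps(d))
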