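"""Crystallographic frame and trace superposition.

Independently phased traces of the same crystal can differ by a space-group
symmetry operator, an allowed origin shift (continuous along polar axes) and,
for some point groups, an indexing-ambiguity operator.  This module brings
all traces into one common frame by searching those operators, and then
superposes NCS copies onto a reference chain with sequence-guided Kabsch
fitting.

Allowed origin shifts are the translations ``t`` with ``(R - I) t`` in the
lattice for every symmetry rotation ``R`` — the translation part of the
Euclidean normalizer.  Axes fixed by every rotation are polar: the shift
component along them is continuous.  Both are derived from the space-group
operators rather than tabulated, so any group gemmi knows is covered.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Sequence

import gemmi
import numpy as np

from .model_io import Trace

__all__ = [
    "CrystalFrame",
    "Superposition",
    "AlignmentError",
    "kabsch_superpose",
    "align_crystallographic",
    "align_ncs",
    "align_to_map",
]

logger = logging.getLogger(__name__)


class AlignmentError(RuntimeError):
    """No usable correspondence between traces."""


@dataclasses.dataclass
class Superposition:
    rotation: np.ndarray      # 3x3, Cartesian
    translation: np.ndarray   # Angstrom
    rmsd: float
    n_matched: int
    op_used: tuple | str = "NCS"

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


class CrystalFrame:
    """Unit cell, space-group operators, origin shifts and reindex operators."""

    def __init__(self, cell: tuple[float, float, float, float, float, float],
                 spacegroup: str):
        self.cell = gemmi.UnitCell(*cell)
        sg = gemmi.find_spacegroup_by_name(spacegroup)
        if sg is None:
            raise ValueError(f"unknown space group {spacegroup!r}")
        self.spacegroup = sg
        ops = list(sg.operations())
        den = float(ops[0].DEN)
        self.sym_ops: list[tuple[np.ndarray, np.ndarray]] = [
            (np.array(op.rot, dtype=float) / den, np.array(op.tran, dtype=float) / den)
            for op in ops
        ]
        self.polar_axes = self._find_polar_axes()
        self.origin_shifts = self._find_origin_shifts()
        self.reindex_ops = self._find_reindex_ops()
        self._orth = np.array(self.cell.orth.mat.tolist())
        self._frac = np.linalg.inv(self._orth)

    # -- coordinate conversion ------------------------------------------------
    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self._frac.T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return frac @ self._orth.T

    # -- operator derivation --------------------------------------------------
    def _find_polar_axes(self) -> tuple[int, ...]:
        axes = []
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1.0
            if all(np.allclose(R @ e, e) for R, _ in self.sym_ops):
                axes.append(k)
        return tuple(axes)

    def _find_origin_shifts(self) -> list[np.ndarray]:
        """Discrete allowed origin shifts (polar components set to 0)."""
        candidates = sorted({k / 12 for k in range(12)} | {0.25, 0.75})
        per_axis = [[0.0] if k in self.polar_axes else candidates for k in range(3)]
        shifts = []
        for t in itertools.product(*per_axis):
            tv = np.array(t)
            ok = True
            for R, _ in self.sym_ops:
                d = (R - np.eye(3)) @ tv
                if not np.allclose(d - np.round(d), 0, atol=1e-9):
                    ok = False
                    break
            if ok:
                shifts.append(tv)
        # zero shift first, then by magnitude for deterministic search order
        shifts.sort(key=lambda v: (float(v @ v), tuple(v)))
        return shifts

    def _find_reindex_ops(self) -> list[np.ndarray]:
        """Indexing-ambiguity operators: lattice-metric-preserving integer
        basis changes not already in the point group, one per coset."""
        G = self._metric_tensor()
        point_rots = [R for R, _ in self.sym_ops]
        ops = [np.eye(3)]
        entries = (-1, 0, 1)
        for flat in itertools.product(entries, repeat=9):
            M = np.array(flat, dtype=float).reshape(3, 3)
            if abs(np.linalg.det(M) - 1.0) > 1e-9:
                continue
            if not np.allclose(M.T @ G @ M, G, rtol=1e-6, atol=1e-6):
                continue
            # skip if M is point-group-equivalent to an already accepted op
            new = True
            for kept in ops:
                for R in point_rots:
                    if np.allclose(M, R @ kept, atol=1e-9):
                        new = False
                        break
                if not new:
                    break
            if new:
                ops.append(M)
        return ops

    def _metric_tensor(self) -> np.ndarray:
        A = np.array(self.cell.orth.mat.tolist())
        return A.T @ A


# ---------------------------------------------------------------------------
# Kabsch superposition

def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns the proper rotation and translation minimizing the RMSD of
    ``moving`` onto ``fixed`` (SVD solution).
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise AlignmentError("coordinate sets must be paired Nx3 arrays")
    n = len(moving)
    if n < 3:
        raise AlignmentError("need at least 3 paired atoms")
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    P, Q = moving - cm, fixed - cf
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise AlignmentError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    moved = moving @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return Superposition(R, t, rmsd, n, op_used="kabsch")


# ---------------------------------------------------------------------------
# crystallographic alignment

def _ca_table(trace: Trace) -> tuple[np.ndarray, np.ndarray]:
    """(seq_nums, CA xyz) over all docked residues of all chains."""
    seqs, xyz = [], []
    for r in trace.docked_residues():
        if r.ca is not None:
            seqs.append(r.seq_num)
            xyz.append(r.ca)
    if not seqs:
        return np.empty(0, dtype=int), np.empty((0, 3))
    return np.array(seqs), np.array(xyz)


def _mode_translation(diffs: np.ndarray, bin_width: float = 0.05
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Dominant constant offset among per-residue fractional differences.

    Rigidly consistent residues all share one exact difference vector; the
    mode of the quantized differences finds it in the presence of deleted,
    shifted or mistraced residues.  Returns (offset, inlier mask).
    """
    keys = np.round(diffs / bin_width).astype(int)
    uniq, counts = np.unique(keys, axis=0, return_counts=True)
    center = uniq[np.argmax(counts)] * bin_width
    inliers = np.all(np.abs(diffs - center) <= 1.5 * bin_width, axis=1)
    if not inliers.any():
        return center, inliers
    return diffs[inliers].mean(axis=0), inliers


def _transform_trace(trace: Trace, R: np.ndarray, t: np.ndarray) -> Trace:
    out = trace.copy()
    for res in out.all_residues():
        for a in res.atoms:
            a.xyz = R @ a.xyz + t
    return out


def align_crystallographic(trace: Trace, reference: Trace, frame: CrystalFrame,
                           ca_match_tol: float = 3.0) -> tuple[Trace, Superposition]:
    """Bring ``trace`` into the frame of ``reference``.

    Searches symmetry operators x reindex operators; for each candidate the
    residual translation (allowed origin shift, continuous along polar axes,
    plus any lattice translation) follows in closed form as the dominant
    per-residue fractional offset between same-numbered CA atoms.  The
    operator maximizing the number of CA matches within ``ca_match_tol``
    wins; ties go to the lower RMSD over matched pairs.
    """
    seq_m, xyz_m = _ca_table(trace)
    seq_f, xyz_f = _ca_table(reference)
    if len(seq_f) == 0 or len(seq_m) == 0:
        raise AlignmentError("empty trace or reference")
    common, im, if_ = np.intersect1d(seq_m, seq_f, return_indices=True)
    if len(common) < 3:
        raise AlignmentError("fewer than 3 common sequence positions")
    fm = frame.fractionalize(xyz_m[im])
    ff = frame.fractionalize(xyz_f[if_])

    best = None
    for ridx, M in enumerate(frame.reindex_ops):
        for sidx, (R, t0) in enumerate(frame.sym_ops):
            F = R @ M
            moved = fm @ F.T + t0
            shift, inliers = _mode_translation(ff - moved)
            if inliers.sum() < 3:
                continue
            moved_cart = frame.orthogonalize(moved + shift)
            fixed_cart = frame.orthogonalize(ff)
            d = np.linalg.norm(moved_cart - fixed_cart, axis=1)
            matched = d <= ca_match_tol
            n_match = int(matched.sum())
            if n_match < 3:
                continue
            rmsd = float(np.sqrt(np.mean(d[matched] ** 2)))
            key = (-n_match, rmsd)
            if best is None or key < best[0]:
                best = (key, sidx, ridx, F, t0 + shift, n_match, rmsd)
    if best is None:
        raise AlignmentError("no crystallographic correspondence "
                             f"(no operator matches >= 3 CA atoms within {ca_match_tol} A)")

    _, sidx, ridx, F, t_frac, n_match, rmsd = best
    R_cart = frame._orth @ F @ frame._frac
    t_cart = frame._orth @ t_frac
    shift_report = tuple(float(x) for x in np.round(
        _nearest_allowed_shift(frame, t_frac), 6))
    sup = Superposition(R_cart, t_cart, rmsd, n_match,
                        op_used=(sidx, shift_report, ridx))
    logger.info("crystallographic alignment of %s: sym_op #%d, shift %s, "
                "reindex #%d, %d CA matched, rmsd %.4f A",
                trace.trace_id, sidx, shift_report, ridx, n_match, rmsd)
    return _transform_trace(trace, R_cart, t_cart), sup


def _nearest_allowed_shift(frame: CrystalFrame, t_frac: np.ndarray) -> np.ndarray:
    """Reduce a recovered translation to the allowed-origin-shift convention:
    lattice part removed, non-polar components snapped to the nearest
    tabulated shift when within rounding distance."""
    t = t_frac - np.round(t_frac)
    if not frame.origin_shifts:
        return t
    cands = np.array(frame.origin_shifts)
    d = cands - t
    d -= np.round(d)
    for k in frame.polar_axes:
        d[:, k] = 0.0
    i = int(np.argmin(np.sum(d * d, axis=1)))
    snapped = cands[i].copy()
    for k in frame.polar_axes:
        snapped[k] = t[k]
    if np.max(np.abs((snapped - t) - np.round(snapped - t))) < 1e-3:
        return snapped
    return t


# ---------------------------------------------------------------------------
# trace-to-map registration

def align_to_map(trace: Trace, dmap, frame: CrystalFrame,
                 polar_step_ang: float = 1.0) -> tuple[Trace, Superposition]:
    """Register a trace onto the density map's frame.

    A trace phased independently of the map can differ from it by a symmetry
    operator and an allowed origin shift; unlike trace-to-trace alignment
    there is no residue correspondence to exploit, so the search is driven
    by density fit: mean interpolated map value at the transformed CA
    positions.  Continuous polar-axis shift components are scanned
    sequentially at ~``polar_step_ang`` Angstrom resolution and refined by
    bounded 1-D minimization.  (With two or more polar axes the sequential
    scan can in principle settle on a local optimum; in practice traces fill
    enough of the cell that the marginal scans are informative.)
    """
    from scipy.optimize import minimize_scalar

    _, xyz = _ca_table(trace)
    if len(xyz) == 0:
        raise AlignmentError("empty trace")
    fm = frame.fractionalize(xyz)

    def score(F: np.ndarray, t: np.ndarray) -> float:
        return float(np.mean(dmap.interpolate(np.mod(fm @ F.T + t, 1.0))))

    polar = frame.polar_axes
    lengths = (frame.cell.a, frame.cell.b, frame.cell.c)
    best = None  # (score, sidx, R, t, shift)
    for sidx, (R, t0) in enumerate(frame.sym_ops):
        for shift in frame.origin_shifts:
            t = t0 + shift
            for _sweep in range(2 if len(polar) > 1 else 1):
                for k in polar:
                    n = max(8, int(np.ceil(lengths[k] / polar_step_ang)))
                    vals = np.arange(n) / n
                    scores = []
                    for x in vals:
                        tt = t.copy()
                        tt[k] = x
                        scores.append(score(R, tt))
                    t[k] = float(vals[int(np.argmax(scores))])
            s = score(R, t)
            # symmetry images of a symmetry-expanded map score identically up
            # to interpolation noise: near-ties keep the earlier candidate
            # (identity operator, zero shift first)
            tol = 1e-6 * max(1.0, abs(s))
            if best is None or s > best[0] + tol:
                best = (s, sidx, R, t.copy(), shift)
    _, sidx, R, t, shift = best
    # refine polar components by bounded 1-D minimization around the scan hit
    for k in polar:
        step = 1.0 / max(8, int(np.ceil(lengths[k] / polar_step_ang)))

        def f(x, axis=k, base=t.copy()):
            tt = base.copy()
            tt[axis] = x
            return -score(R, tt)

        res = minimize_scalar(f, bounds=(t[k] - step, t[k] + step),
                              method="bounded", options={"xatol": 1e-7})
        t[k] = float(res.x)
    R_cart = frame._orth @ R @ frame._frac
    t_cart = frame._orth @ t
    shift_report = tuple(float(x) for x in
                         np.round(t - frame.sym_ops[sidx][1], 6))
    sup = Superposition(R_cart, t_cart, float("nan"), len(xyz),
                        op_used=(sidx, shift_report, 0))
    logger.info("map registration of %s: sym_op #%d, translation %s",
                trace.trace_id, sidx, shift_report)
    return _transform_trace(trace, R_cart, t_cart), sup


# ---------------------------------------------------------------------------
# NCS alignment

def align_ncs(traces: Sequence[Trace], reference: tuple[str, str] | None = None,
              max_cycles: int = 5) -> list[Trace]:
    """Superpose every NCS copy (chain) onto one reference chain.

    Correspondence is by sequence number (all traces share one target
    sequence), fitted with Kabsch superposition and iterative rejection of
    pairs beyond twice the median pair distance, up to ``max_cycles``
    cycles, so a mistraced loop does not drag the core fit.  (The median is
    the rejection scale rather than the RMSD: with a contaminated fit the
    least-squares compromise parks outliers near 2x the core distance, which
    an RMSD-based cut can provably never reject.)
    """
    if not traces:
        return []
    if reference is None:
        t0 = traces[0]
        reference = (t0.trace_id, next(iter(t0.chains)))
    ref_tid, ref_cid = reference
    ref_trace = next(t for t in traces if t.trace_id == ref_tid)
    ref_res = ref_trace.chains[ref_cid]
    ref_map = {r.seq_num: r.ca for r in ref_res if r.ca is not None}

    out = []
    for trace in traces:
        new = trace.copy()
        for cid, residues in new.chains.items():
            if trace.trace_id == ref_tid and cid == ref_cid:
                continue
            pairs = [(r.ca, ref_map[r.seq_num]) for r in residues
                     if r.ca is not None and r.seq_num in ref_map]
            if len(pairs) < 3:
                logger.warning("chain %s of %s: <3 common positions with "
                               "reference, left unaligned", cid, trace.trace_id)
                continue
            mv = np.array([p[0] for p in pairs])
            fx = np.array([p[1] for p in pairs])
            sup = _iterative_kabsch(mv, fx, max_cycles)
            for res in residues:
                for a in res.atoms:
                    a.xyz = sup.apply(a.xyz)
        out.append(new)
    return out


def _iterative_kabsch(moving: np.ndarray, fixed: np.ndarray,
                      max_cycles: int) -> Superposition:
    keep = np.ones(len(moving), dtype=bool)
    sup = kabsch_superpose(moving, fixed)
    for _ in range(max_cycles):
        moved = sup.apply(moving)
        d = np.linalg.norm(moved - fixed, axis=1)
        new_keep = d <= max(2.0 * float(np.median(d)), 1e-6)
        if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
        sup = kabsch_superpose(moving[keep], fixed[keep])
    sup.op_used = "NCS"
    return sup
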