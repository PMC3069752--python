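"""Symmetry bookkeeping, Kabsch fitting, and superposition recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tracefuse as tf
from tracefuse.crystal_frame import (AlignmentError, CrystalFrame,
                                     align_crystallographic, align_ncs,
                                     kabsch_superpose)
from tracefuse.fixtures import FixtureSpec, make_ground_truth

SHIPPED_GROUPS = ("P 1", "P 21", "P 21 21 21", "P 43 21 2")


@pytest.fixture(scope="module", params=SHIPPED_GROUPS)
def group_fixture(request):
    spec = FixtureSpec(length=50, spacegroup=request.param, seed=13,
                       n_traces=1, displace=False)
    return make_ground_truth(spec)


class TestCrystalFrame:
    def test_identity_and_zero_shift_present(self, group_fixture):
        _, frame, _ = group_fixture
        R0, t0 = frame.sym_ops[0]
        assert np.allclose(R0, np.eye(3)) and np.allclose(t0, 0)
        assert any(np.allclose(s, 0) for s in frame.origin_shifts)

    def test_sym_ops_closed_under_composition(self, group_fixture):
        _, frame, _ = group_fixture
        ops = frame.sym_ops
        for Ra, ta in ops:
            for Rb, tb in ops:
                Rc, tc = Ra @ Rb, Ra @ tb + ta
                found = any(
                    np.allclose(Rc, R) and
                    np.allclose((tc - t) - np.round(tc - t), 0, atol=1e-9)
                    for R, t in ops)
                assert found

    def test_origin_shifts_commute_with_group(self, group_fixture):
        _, frame, _ = group_fixture
        for s in frame.origin_shifts:
            for R, _ in frame.sym_ops:
                d = (R - np.eye(3)) @ s
                assert np.allclose(d - np.round(d), 0, atol=1e-9)

    def test_tetragonal_reindex_ambiguity(self):
        frame = CrystalFrame((40, 40, 60, 90, 90, 90), "P 43")
        assert len(frame.reindex_ops) == 2  # identity + (k,h,-l)-type
        assert frame.polar_axes == (2,)

    def test_unknown_spacegroup_rejected(self):
        with pytest.raises(ValueError):
            CrystalFrame((40, 40, 60, 90, 90, 90), "Q 1")


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd < 1e-12
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-12)

    def test_recovers_exact_rigid_motion(self):
        rng = np.random.default_rng(1)
        fixed = rng.normal(size=(30, 3)) * 5
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moving = fixed @ Rz.T + np.array([5.0, 0.0, 0.0])
        sup = kabsch_superpose(moving, fixed)
        assert sup.rmsd < 1e-9
        assert np.allclose(sup.apply(moving), fixed, atol=1e-9)
        assert abs(np.linalg.det(sup.rotation) - 1.0) < 1e-9

    def test_noise_rmsd_matches_monte_carlo_expectation(self):
        # rmsd of sigma-per-coordinate noise approaches sigma * sqrt(3)
        sigma, n = 0.3, 100
        rmsds = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fixed = rng.normal(size=(n, 3)) * 10
            moving = fixed + rng.normal(0.0, sigma, size=(n, 3))
            rmsds.append(kabsch_superpose(moving, fixed).rmsd)
        assert 0.8 * sigma * np.sqrt(3) < np.mean(rmsds) < 1.2 * sigma * np.sqrt(3)

    def test_too_few_or_degenerate_points(self):
        with pytest.raises(AlignmentError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(10.0), [1.0, 0.0, 0.0])
        with pytest.raises(AlignmentError):
            kabsch_superpose(line, line)


def _apply_random_op(trace, frame, rng):
    op_idx = int(rng.integers(len(frame.sym_ops)))
    R_f, t_f = frame.sym_ops[op_idx]
    shift = frame.origin_shifts[int(rng.integers(len(frame.origin_shifts)))].copy()
    for k in frame.polar_axes:
        shift[k] = rng.uniform(0, 1)
    R_c = frame._orth @ R_f @ frame._frac
    t_c = frame._orth @ (t_f + shift)
    moved = trace.copy()
    for r in moved.all_residues():
        for a in r.atoms:
            a.xyz = R_c @ a.xyz + t_c
    return moved, (op_idx, shift)


def _post_alignment_rmsd(aligned, reference):
    ref = {r.seq_num: r.ca for r in reference.docked_residues()}
    d = [np.linalg.norm(r.ca - ref[r.seq_num])
         for r in aligned.docked_residues() if r.seq_num in ref]
    return float(np.sqrt(np.mean(np.square(d))))


class TestCrystallographicAlignment:
    def test_untouched_trace_selects_identity(self, group_fixture):
        truth, frame, _ = group_fixture
        moved, sup = align_crystallographic(truth.copy(), truth, frame)
        assert sup.op_used[0] == 0
        assert sup.rmsd < 1e-9

    def test_apply_and_recover(self, group_fixture):
        truth, frame, _ = group_fixture
        rng = np.random.default_rng(5)
        for _ in range(10):
            moved, _ = _apply_random_op(truth, frame, rng)
            back, sup = align_crystallographic(moved, truth, frame)
            assert _post_alignment_rmsd(back, truth) < 1e-6

    def test_recovery_with_half_deleted(self, group_fixture):
        truth, frame, _ = group_fixture
        rng = np.random.default_rng(9)
        moved, _ = _apply_random_op(truth, frame, rng)
        keep = [r for r in moved.chains["A"] if rng.random() > 0.5]
        moved.chains["A"] = keep
        back, sup = align_crystallographic(moved, truth, frame)
        assert sup.n_matched == len(keep)
        assert _post_alignment_rmsd(back, truth) < 1e-6

    def test_composed_motion_is_identity(self, group_fixture):
        truth, frame, _ = group_fixture
        rng = np.random.default_rng(3)
        moved, _ = _apply_random_op(truth, frame, rng)
        back, sup = align_crystallographic(moved, truth, frame)
        ca_m = next(iter(moved.docked_residues())).ca
        assert np.allclose(sup.apply(ca_m),
                           next(iter(back.docked_residues())).ca, atol=1e-9)

    def test_no_correspondence_raises(self, small_truth):
        truth, frame, target = small_truth
        a = truth.copy()
        b = truth.copy()
        a.chains["A"] = a.chains["A"][:10]
        b.chains["A"] = b.chains["A"][20:]
        with pytest.raises(AlignmentError):
            align_crystallographic(a, b, frame)

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_recovery_is_exact_for_random_draws(self, seed):
        spec = FixtureSpec(length=40, seed=17, n_traces=1, displace=False)
        truth, frame, _ = make_ground_truth(spec)
        rng = np.random.default_rng(seed)
        moved, _ = _apply_random_op(truth, frame, rng)
        back, _ = align_crystallographic(moved, truth, frame)
        assert _post_alignment_rmsd(back, truth) < 1e-6


class TestNCS:
    def _two_copy_trace(self, base, rng, displace_loop=None):
        truth, frame, _ = base
        t = truth.copy()
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=rng).as_matrix()
        off = rng.uniform(20, 30, size=3)
        copy_b = [r.copy() for r in t.chains["A"]]
        for r in copy_b:
            r.chain_id = "B"
            for a in r.atoms:
                a.xyz = R @ a.xyz + off
        if displace_loop:
            lo, hi, dist = displace_loop
            for r in copy_b:
                if lo <= r.seq_num <= hi:
                    for a in r.atoms:
                        a.xyz = a.xyz + np.array([dist, 0.0, 0.0])
        t.chains["B"] = copy_b
        return t

    def test_known_rigid_motion_recovered(self, small_truth):
        rng = np.random.default_rng(2)
        t = self._two_copy_trace(small_truth, rng)
        out = align_ncs([t], (t.trace_id, "A"))[0]
        ref = {r.seq_num: r.ca for r in out.chains["A"]}
        d = [np.linalg.norm(r.ca - ref[r.seq_num]) for r in out.chains["B"]]
        assert max(d) < 1e-6

    def test_mistraced_loop_rejected_from_fit(self):
        # 10 of 50 residues displaced 8 A: the loop must not drag the core fit
        spec = FixtureSpec(length=50, seed=23, n_traces=1, displace=False)
        base = make_ground_truth(spec)
        rng = np.random.default_rng(4)
        t = self._two_copy_trace(base, rng, displace_loop=(10, 19, 8.0))
        out = align_ncs([t], (t.trace_id, "A"))[0]
        ref = {r.seq_num: r.ca for r in out.chains["A"]}
        core = [np.linalg.norm(r.ca - ref[r.seq_num]) for r in out.chains["B"]
                if not 10 <= r.seq_num <= 19]
        assert float(np.sqrt(np.mean(np.square(core)))) < 0.1

    def test_single_chain_returned_unchanged(self, small_truth):
        truth, _, _ = small_truth
        out = align_ncs([truth], (truth.trace_id, "A"))[0]
        for a, b in zip(truth.chains["A"], out.chains["A"]):
            assert np.allclose(a.ca, b.ca)
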