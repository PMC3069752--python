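"""Gap detection and model quality metrics.

Gaps shorter than 15 residues that are anchored on both sides are flagged as
candidates for fragment rebuilding by an external loop-building tool; this
package only identifies and exports them.  Metrics cover completeness (the
fraction of target positions with a side-chain-docked residue, and the
fraction covered by any modeled residue) and, when a ground truth is
available, correctness (CA within 1.5 A of the true position — under half a
CA step, so register-shifted residues count as wrong).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .model_io import ConsensusModel, TargetSequence, Trace

__all__ = ["GapAnnotation", "TraceMetrics", "detect_gaps", "score_model",
           "write_gap_worklist"]

#: CA distance below which a residue counts as correctly placed (A)
CORRECT_CA_TOL = 1.5


@dataclasses.dataclass
class GapAnnotation:
    start_seq: int
    end_seq: int
    anchored: bool
    rebuild_candidate: bool

    @property
    def length(self) -> int:
        return self.end_seq - self.start_seq + 1


@dataclasses.dataclass
class TraceMetrics:
    frac_docked: float           # side-chain-docked positions / L
    frac_modeled: float          # any docked residue / L
    frac_correct: float | None   # CA within tolerance of truth (needs truth)
    n_gaps: int
    longest_fragment: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        d = dataclasses.asdict(self)
        keys = sorted(d)
        fmt = lambda v: "NA" if v is None else (f"{v:.4f}" if isinstance(v, float) else str(v))
        return "\t".join(keys) + "\n" + "\t".join(fmt(d[k]) for k in keys) + "\n"


def detect_gaps(model: ConsensusModel, max_rebuild_len: int = 14
                ) -> list[GapAnnotation]:
    """Annotate the model's maximal gap runs.

    A gap is a rebuild candidate when residues exist on both sides (anchored)
    and it spans at most ``max_rebuild_len`` residues (default 14: "fewer
    than 15").  Terminal gaps are never candidates.
    """
    modeled = {r.seq_num for r in model.residues}
    anns = []
    for start, end in model.gap_ranges:
        anchored = (start - 1) in modeled and (end + 1) in modeled
        length = end - start + 1
        anns.append(GapAnnotation(start, end, anchored,
                                  anchored and length <= max_rebuild_len))
    return anns


def write_gap_worklist(gaps: list[GapAnnotation], path: str | Path) -> None:
    """Plain-text range file of rebuild candidates for an external tool."""
    lines = [f"{g.start_seq} {g.end_seq} {g.length}"
             for g in gaps if g.rebuild_candidate]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _positions_and_cas(obj) -> dict[int, np.ndarray]:
    out = {}
    for r in obj.docked_residues():
        if r.ca is not None:
            out.setdefault(r.seq_num, r.ca)
    return out


def score_model(model: ConsensusModel | Trace, truth: Trace | None,
                target: TargetSequence, frame=None) -> TraceMetrics:
    """Completeness and (with ground truth) correctness of a model.

    ``frac_correct`` is evaluated over the model's docked positions: the
    fraction whose CA lies within CORRECT_CA_TOL of the ground-truth CA at
    the same sequence number.  A model frame differing from the truth frame
    by a symmetry operator / origin shift is legitimate; pass the
    ``CrystalFrame`` to superpose crystallographically before comparing.
    """
    if truth is not None and frame is not None:
        from .crystal_frame import AlignmentError, align_crystallographic

        shim = Trace("model", {"A": [r for r in model.docked_residues()]},
                     [], target.length,
                     getattr(model, "cell", None), getattr(model, "spacegroup", None))
        try:
            aligned, _ = align_crystallographic(shim, truth, frame)
            model = aligned
        except AlignmentError:
            pass  # fall back to the raw frame
    positions = sorted({r.seq_num for r in model.docked_residues()})
    sc_positions = {r.seq_num for r in model.docked_residues() if r.has_side_chain()}
    L = target.length
    frac_docked = len(sc_positions) / L if L else 0.0
    frac_modeled = len(positions) / L if L else 0.0

    frac_correct = None
    if truth is not None:
        t_cell = getattr(truth, "cell", None)
        m_cell = getattr(model, "cell", None)
        if t_cell is not None and m_cell is not None:
            for a, b in zip(t_cell[:3], m_cell[:3]):
                if abs(a - b) > 0.005 * max(a, b):
                    raise ValueError("ground-truth cell does not match the model cell")
        truth_cas = _positions_and_cas(truth)
        model_cas = _positions_and_cas(model)
        n_ok = n_tot = 0
        for seq, ca in model_cas.items():
            if seq in truth_cas:
                n_tot += 1
                if float(np.linalg.norm(ca - truth_cas[seq])) <= CORRECT_CA_TOL:
                    n_ok += 1
            else:
                n_tot += 1  # modeled where truth has nothing: wrong
        frac_correct = n_ok / n_tot if n_tot else 0.0

    # coverage pattern: number of maximal absent runs, longest present run
    pos_set = set(positions)
    longest = run = 0
    for i in range(1, L + 1):
        run = run + 1 if i in pos_set else 0
        longest = max(longest, run)
    n_gaps = _count_absent_runs(positions, L)
    return TraceMetrics(frac_docked, frac_modeled, frac_correct, n_gaps, longest)


def _count_absent_runs(positions: list[int], L: int) -> int:
    present = np.zeros(L + 2, dtype=bool)
    present[np.array(positions, dtype=int)] = True if positions else False
    absent = ~present[1:L + 1]
    return int(np.sum(absent[1:] & ~absent[:-1]) + (1 if absent.size and absent[0] else 0))
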