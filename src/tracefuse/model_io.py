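"""Trace and sequence I/O.

Reads partially built protein models ("traces") produced by automated
model-building programs from PDB files, normalizes them into the internal
data model, and writes consensus models back out.  A *docked* residue is one
whose amino-acid identity has been assigned and whose sequence number refers
to a position of the target sequence; UNK residues are undocked fragments.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Trace",
    "TargetSequence",
    "ConsensusModel",
    "TraceFormatError",
    "EmptyTraceError",
    "read_fasta",
    "read_trace",
    "write_trace",
    "write_model",
    "filter_traces",
]

#: residues whose side chain is complete at CB (no atoms beyond CB expected)
_NO_SIDECHAIN_BEYOND_CB = {"G", "A"}

#: backbone + CB atom names; anything else counts as "beyond CB"
_MAINCHAIN_ATOMS = {"N", "CA", "C", "O", "OXT", "CB", "H", "HA", "H1", "H2", "H3"}

_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1 = {v: k for k, v in _AA3.items()}
_AA1["X"] = "UNK"


class TraceFormatError(ValueError):
    """Raised for unparsable or unsupported input files."""


class EmptyTraceError(ValueError):
    """Raised when a trace file contains no usable CA atoms."""


@dataclasses.dataclass(eq=False)
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # Cartesian, Angstrom
    occ: float = 1.0
    b: float = 20.0

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.xyz.copy(), self.occ, self.b)


@dataclasses.dataclass(eq=False)
class Residue:
    """One residue of a trace.

    ``seq_num`` is the 1-based position in the target sequence for docked
    residues; for undocked (UNK) residues it is only a running index within
    the fragment.  ``aa_type`` is a one-letter code, ``'X'`` for undocked.
    """

    seq_num: int
    aa_type: str
    atoms: list[Atom]
    chain_id: str = "A"
    docked: bool = True
    source_trace: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> np.ndarray | None:
        a = self.atom("CA")
        return None if a is None else a.xyz

    def has_side_chain(self) -> bool:
        """True if the residue is sequence-assigned and carries its side chain.

        GLY and ALA have no atoms beyond CB, so an assigned identity alone
        qualifies; every other type needs at least one atom past CB.
        """
        if not self.docked or self.aa_type == "X":
            return False
        if self.aa_type in _NO_SIDECHAIN_BEYOND_CB:
            return True
        return any(a.name not in _MAINCHAIN_ATOMS for a in self.atoms)

    def copy(self) -> "Residue":
        return Residue(self.seq_num, self.aa_type, [a.copy() for a in self.atoms],
                       self.chain_id, self.docked, self.source_trace)


@dataclasses.dataclass
class TargetSequence:
    residues: str

    def __post_init__(self) -> None:
        allowed = set(_AA1)
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(f"non-standard residue codes in target sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos: int) -> str:
        """One-letter code at 1-based position ``pos``."""
        return self.residues[pos - 1]


@dataclasses.dataclass
class Trace:
    """An autobuilt model: chains of docked residues plus undocked fragments."""

    trace_id: str
    chains: dict[str, list[Residue]]
    undocked_fragments: list[list[Residue]]
    target_length: int
    cell: tuple[float, float, float, float, float, float] | None = None
    spacegroup: str | None = None
    conflicts: list[tuple[int, str, str]] = dataclasses.field(default_factory=list)

    def docked_residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def all_residues(self) -> Iterator[Residue]:
        yield from self.docked_residues()
        for frag in self.undocked_fragments:
            yield from frag

    @property
    def frac_docked(self) -> float:
        """Fraction of target positions with a side-chain-docked residue."""
        positions = {r.seq_num for r in self.docked_residues() if r.has_side_chain()}
        return len(positions) / self.target_length if self.target_length else 0.0

    @property
    def frac_modeled(self) -> float:
        """Fraction of target positions covered by any docked residue."""
        positions = {r.seq_num for r in self.docked_residues()}
        return len(positions) / self.target_length if self.target_length else 0.0

    def copy(self) -> "Trace":
        return Trace(
            self.trace_id,
            {cid: [r.copy() for r in rs] for cid, rs in self.chains.items()},
            [[r.copy() for r in frag] for frag in self.undocked_fragments],
            self.target_length,
            self.cell,
            self.spacegroup,
            list(self.conflicts),
        )


@dataclasses.dataclass
class ConsensusModel:
    """Output of the consensus path: one residue or one gap per position."""

    residues: list[Residue]
    gap_ranges: list[tuple[int, int]]
    target_length: int
    total_weight: float = 0.0
    cell: tuple[float, float, float, float, float, float] | None = None
    spacegroup: str | None = None

    def docked_residues(self) -> Iterator[Residue]:
        yield from self.residues

    @property
    def frac_docked(self) -> float:
        positions = {r.seq_num for r in self.residues if r.has_side_chain()}
        return len(positions) / self.target_length if self.target_length else 0.0

    @property
    def frac_modeled(self) -> float:
        return len({r.seq_num for r in self.residues}) / self.target_length


# ---------------------------------------------------------------------------
# readers

def read_fasta(path: str | Path) -> TargetSequence:
    """Read the target amino-acid sequence from a FASTA file (first record)."""
    from Bio import SeqIO

    try:
        record = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise TraceFormatError(f"{path}: no FASTA records") from None
    return TargetSequence(str(record.seq).upper())


def _residue_from_gemmi(res: gemmi.Residue, chain_id: str, trace_id: str,
                        docked: bool, seq_num: int, aa: str) -> Residue:
    atoms = []
    for at in res:
        if at.altloc not in ("", "\0", "A"):
            continue  # keep altloc A only
        atoms.append(Atom(at.name, at.element.name,
                          np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float),
                          at.occ, at.b_iso))
    return Residue(seq_num, aa, atoms, chain_id, docked, trace_id)


def read_trace(path: str | Path, target: TargetSequence,
               trace_id: str | None = None) -> Trace:
    """Read a PDB trace and partition residues into docked and undocked.

    Standard amino acids with a sequence number inside the target range are
    docked; UNK residues form undocked fragments (split at chain breaks).
    A residue type disagreeing with the target sequence at its position is
    kept but recorded in ``Trace.conflicts``.
    """
    path = Path(path)
    tid = trace_id or path.stem
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise TraceFormatError(f"{path}: cannot parse PDB: {exc}") from exc
    if not len(st):
        raise TraceFormatError(f"{path}: no models in file")

    chains: dict[str, list[Residue]] = {}
    fragments: list[list[Residue]] = []
    conflicts: list[tuple[int, str, str]] = []
    n_ca = 0
    for chain in st[0]:
        docked_list: list[Residue] = []
        frag: list[Residue] = []
        prev_undocked_seq = None
        for res in chain:
            if res.seqid.icode not in (" ", "\0", ""):
                raise TraceFormatError(
                    f"{path}: insertion code on residue {chain.name} {res.seqid.num}"
                    f"{res.seqid.icode!r} not supported")
            aa = _AA3.get(res.name)
            if res.het_flag == "H" and aa is None and res.name != "UNK":
                continue  # ligands/waters out of scope
            seq = res.seqid.num
            if any(a.name == "CA" for a in res):
                n_ca += 1
            if aa is not None and 1 <= seq <= target.length:
                r = _residue_from_gemmi(res, chain.name, tid, True, seq, aa)
                if r.ca is None or not np.all(np.isfinite(r.ca)):
                    continue
                if target[seq] != aa:
                    conflicts.append((seq, aa, target[seq]))
                docked_list.append(r)
            else:
                r = _residue_from_gemmi(res, chain.name, tid, False, seq, "X")
                if r.ca is None:
                    continue
                if frag and prev_undocked_seq is not None and seq != prev_undocked_seq + 1:
                    fragments.append(frag)
                    frag = []
                frag.append(r)
                prev_undocked_seq = seq
        if frag:
            fragments.append(frag)
        if docked_list:
            docked_list.sort(key=lambda r: r.seq_num)
            chains[chain.name] = docked_list
    if n_ca == 0:
        raise EmptyTraceError(f"{path}: no CA atoms found")

    cell = st.cell
    cell_t = ((cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
              if cell.is_crystal() else None)
    sg = st.spacegroup_hm or None
    return Trace(tid, chains, fragments, target.length, cell_t, sg, conflicts)


# ---------------------------------------------------------------------------
# writers

def _structure_from_residues(groups: list[tuple[str, list[Residue]]],
                             cell, spacegroup) -> gemmi.Structure:
    st = gemmi.Structure()
    if cell is not None:
        st.cell = gemmi.UnitCell(*cell)
    if spacegroup:
        st.spacegroup_hm = spacegroup
    model = gemmi.Model("1")
    for chain_id, residues in groups:
        ch = gemmi.Chain(chain_id)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = _AA1.get(r.aa_type, "UNK")
            gr.seqid = gemmi.SeqId(int(r.seq_num), " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*np.round(a.xyz, 3))
                ga.occ = float(a.occ)
                ga.b_iso = float(a.b)
                gr.add_atom(ga)
            ch.add_residue(gr)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace (docked chains plus undocked UNK fragments) as PDB."""
    groups: list[tuple[str, list[Residue]]] = list(trace.chains.items())
    frag_chain_ids = [c for c in "ZYXWVUTSRQ" if c not in trace.chains]
    for i, frag in enumerate(trace.undocked_fragments):
        cid = frag_chain_ids[i % len(frag_chain_ids)] if frag_chain_ids else "Z"
        groups.append((cid, frag))
    st = _structure_from_residues(groups, trace.cell, trace.spacegroup)
    Path(path).write_text(st.make_pdb_string())


def write_model(model: ConsensusModel, path: str | Path) -> None:
    """Write a consensus model as PDB.

    Gap positions are not written as atoms; each maximal gap appears as a
    ``REMARK 300 GAP <start> <end>`` line.  Per-residue provenance is written
    as a ``REMARK 301`` table mapping sequence number to source trace.
    """
    if not model.residues:
        raise ValueError("model has no residues")
    st = _structure_from_residues([("A", model.residues)],
                                  model.cell, model.spacegroup)
    remarks = []
    for start, end in model.gap_ranges:
        remarks.append(f"REMARK 300 GAP {start} {end}")
    remarks.append("REMARK 301 SOURCE TRACE PER RESIDUE")
    for r in model.residues:
        remarks.append(f"REMARK 301 {r.seq_num:5d} {r.source_trace}")
    Path(path).write_text("\n".join(remarks) + "\n" + st.make_pdb_string())


# ---------------------------------------------------------------------------
# filtering

def filter_traces(traces: Iterable[Trace], threshold: float = 0.40,
                  strict: bool = True) -> list[Trace]:
    """Keep traces whose side-chain-docked fraction exceeds ``threshold``.

    The default is strictly greater than 0.40: autobuilt models at or below
    40% side chains docked tend to carry severe tracing errors.  Set
    ``strict=False`` for >=.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if strict:
        kept = [t for t in traces if t.frac_docked > threshold]
    else:
        kept = [t for t in traces if t.frac_docked >= threshold]
    if not kept:
        warnings.warn("no traces pass the docked-fraction filter", stacklevel=2)
    return kept
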