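# Methods

## Problem and model

`tracefuse` fuses several partially complete, independently built protein
traces of one crystal into a single consensus model.  The central object is
a sequence-position-layered directed acyclic graph: layer *i* holds one
vertex per docked residue at position *i* from every trace and NCS copy,
plus one dummy (gap) vertex, with source and sink sentinels before position
1 and after position *L*.  Edges connect consecutive layers completely, so
any source-to-sink path selects exactly one residue or one gap per
position.  Minimizing total edge weight over paths therefore minimizes a
per-position model score plus junction terms — the standard reduction of a
per-vertex score to edge weights on a layered DAG (residue-level terms are
folded into the incoming edges of the destination vertex).

The minimum path is extracted with Bellman–Ford, run once from the
N-terminus and once (on reversed edges) from the C-terminus, keeping the
lower-weight result.  On exact arithmetic a DAG shortest path is
direction-independent, so a weight difference between directions would
indicate a defect and is logged as an error; with the exact tie-break below
the two directions may still differ in which of several *equal-weight*
paths they report, in which case the N→C result wins.  Two independent
solvers — a layer-ordered dynamic program and exhaustive path enumeration
— are kept in the package for cross-checking; the test suite requires all
three to return identical paths on randomized graphs, which is the
strongest correctness instrument available given that the weight
coefficients of the original method were never published.

Ties between equal-weight paths are resolved by a single total order used
by every solver: higher density CC first, then lower trace identifier, then
lower NCS-copy index, applied lexicographically along the path.  This makes
every run bit-reproducible.

## Edge-weight components

Weights live in `data/default_weights.yaml`, not in code.  Defaults
(dimensionless except where noted):

| parameter   | default | meaning |
|-------------|---------|---------|
| `w_cc`      | 1.0     | weight on `1 − CC` of the destination residue |
| `w_agree`   | 0.5     | reward per additional trace agreeing on the residue |
| `p_rama`    | 2.0     | penalty for a disallowed junction conformation |
| `p_ca`      | 2.0     | per-Å penalty beyond the Cα–Cα tolerance |
| `d_ca`      | 3.8 Å   | ideal consecutive Cα distance (trans peptide) |
| `tol_ca`    | 0.5 Å   | dead zone before the Cα penalty applies |
| `p_overlap` | 3.0     | penalty per better-fitting spatial rival |
| `g_open`    | 5.0     | one-time gap opening |
| `g_ext`     | 1.5     | per-dummy gap extension (must stay below `g_open`) |

They are chosen so that one agreeing trace (0.5) outweighs a 0.5 loss of
CC, and one overlap penalty (3.0) outweighs two agreements.  Cis-peptides
(Cα step ≈ 2.9 Å) incur the Cα penalty; this is an accepted simplification.

Two design points deserve explanation:

**Overlap term.**  Register errors put residues with different sequence
numbers at the same spatial position.  A static penalty applied
symmetrically to both members of such a pair cannot work: the least-squares
structure of the problem means both rails through a shifted region carry
the same penalty, and any per-residue penalty larger than `g_ext` makes a
gap cheaper than *either* rail, deleting the region outright.  The penalty
here therefore counts only rivals whose density CC is strictly better than
the residue's own — the density decides which member is the impostor.  The
correct residue passes at no extra cost, the impostor pays, and mutual
exclusion of any residual both-chosen overlap is enforced by a post-path
pass that deletes the lower-CC member and re-solves the path once.
`Vertex.overlap_count` still reports the raw rival count.

**Junction Ramachandran check.**  With only residues *i−1* and *i* in hand,
a residue's own (φ, ψ) pair is not computable (ψ_i needs N of *i+1*).  The
two torsions that depend on the *i−1*/*i* peptide bond are ψ(i−1) and
φ(i); the pair (φ(i), ψ(i−1)) is tested against a coarse allowed mask
(10°-bin boolean grids for general residues, glycine and proline, shipped
as packaged data).  The masks are deliberately permissive — the term exists
to catch geometrically absurd cross-trace junctions, not to validate
conformations.

## Density scoring

Synthetic maps are sums of spherical Gaussians, one per atom, with
element-independent weight equal to the occupancy and width σ derived from
the nominal resolution *d* through B = 79·(d/3)² and σ² = B/(8π²) — a fixed
convention giving B = 79 Å² at 3 Å.  Each atom integrates to its occupancy.
Maps are expanded over all space-group symmetry images so the grid covers
the physical unit cell; optional noise is i.i.d. Gaussian with standard
deviation expressed as a fraction of the noise-free map's σ.

The per-residue score is the standard real-space correlation: Pearson
correlation, over grid points within 2.5 Å of any residue atom, between the
observed map and a model density calculated from the residue plus its
bonded neighbours (positions *i±1* in the same chain), whose peptide atoms
contribute real signal just inside the mask.  Zero-variance windows score 0
by convention so graph weights stay finite; masks under 8 grid points are
flagged unscorable.  CC is exactly invariant under affine rescaling of the
map and a `--cc-mainchain-only` switch restricts both mask and model to
backbone atoms.

## Crystallographic superposition

Symmetry operators come from gemmi's space-group tables.  Allowed origin
shifts are *derived*, not tabulated: a translation **t** is an allowed
origin shift iff `(R − I)t` is a lattice vector for every rotation R of the
group (the translation part of the Euclidean normalizer), searched over a
twelfths-plus-quarters grid; axes fixed by every rotation are polar and
continuous.  Indexing-ambiguity operators are the metric-preserving integer
basis changes of the lattice modulo the point group, enumerated directly
from the cell metric.

Trace-to-trace alignment enumerates `sym_ops × reindex_ops`; for each
candidate the residual translation (origin shift plus lattice part,
including continuous polar components) is recovered in closed form as the
dominant mode of the per-residue fractional-coordinate differences between
same-numbered Cα pairs — rigidly consistent residues share one exact
difference vector, so the mode is robust to deletions, shifts and
mistraces.  The operator maximizing Cα matches within 3.0 Å (below one Cα
step, so register-shifted matches do not count) wins; ties go to lower
RMSD.

Because the map, not any trace, defines the common frame, the reference
trace is first registered onto the map by scoring each candidate operator
by the mean interpolated density at transformed Cα positions, with
continuous polar components scanned at ~1 Å and refined by bounded 1-D
minimization.  Near-ties (symmetry images of a symmetry-expanded map score
identically up to interpolation noise) keep the earliest candidate, i.e.
the identity.  With two or more polar axes the sequential scan could in
principle settle on a local optimum; traces large relative to the cell make
the marginal scans informative in practice.

NCS copies are superposed by sequence-number-guided Kabsch fitting with
iterative rejection of pairs beyond twice the *median* pair distance (at
most 5 cycles).  The median, not the RMSD, is the rejection scale: with a
contaminated fit the least-squares compromise parks outliers at
(1−f)/f times the core distance, which an RMSD-based cut can provably never
reject at one-third contamination.

## Synthetic data generator

The generator emulates the inputs of a consensus run: a ground-truth
polypeptide with idealized geometry (trans peptides, standard bond lengths
and angles, φ/ψ drawn from helix- and strand-like regions in 5–15-residue
runs, self-avoiding at ≥ 3.5 Å between non-near Cα pairs), stub side chains
(Cβ plus one Cγ atom, so "side chain docked" is meaningful), NCS copies
placed by random rigid motions without sub-2 Å clashes, and a unit cell
derived from the content's bounding box with margins giving roughly half
the volume as solvent.  Content is anchored near the origin with unequal
per-axis offsets to stay off special positions.  Degradation applies, in
order: explicit keep-ranges, random deletions, register shifts (relabeled
`seq_num + shift`, collisions dropped), mistraced segments (rigid random
displacement), side-chain stripping, undocked (UNK) conversion, and a
global symmetry + origin-shift displacement so superposition is always
exercised.  Every injected error lands in a JSON manifest, making metric
oracles exact rather than statistical.  Fixed (spec, seed) pairs regenerate
byte-identical files; coordinates serialize at PDB precision.

What the generator does **not** emulate: real scattering factors, solvent
contribution, map distortion from phase error, sequence-dependent side-chain
shapes, and autotracer-specific error correlations.  Passing tests
demonstrate the combinatorial and crystallographic machinery — filtering,
superposition, scoring, path extraction, error correction — not performance
on experimental data.

Named fixtures: `identity` (one perfect trace), `complementary-halves`
(traces with 57% and 39% of side chains docked whose union covers the
target — the second trace models positions 44–100 but carries side chains
only on 62–100, giving the operator search a 14-residue overlap),
`frame-shift` (a 10-residue +4 register error beside a skipped loop, so all
ten relabelings are collision-free), `mistrace` (an 8 Å displaced segment)
and `ncs-2copies`.  The default space groups span polar and non-polar
origin cases: P1, P2₁, P2₁2₁2₁, P4₃2₁2₁.

## Numerical choices and degenerate inputs

- Path-weight ties use an absolute tolerance of 1e-9 before the
  lexicographic tie-break.
- Gap annotation: anchored gaps of length ≤ 14 ("fewer than 15") are
  rebuild candidates; terminal gaps never are.
- Correctness metric: a residue is correct when its Cα is within 1.5 Å of
  the ground truth at the same position — under half a Cα step, so register
  shifts count as wrong.  Models in a different (legitimate) symmetry frame
  are superposed crystallographically before comparison.
- Completeness is reported both as side-chain-docked (`frac_docked`) and
  any-residue (`frac_modeled`) coverage.
- Degenerate CC windows (constant map, < 8 grid points, no atoms) score 0.
- Kabsch fitting refuses fewer than 3 pairs or collinear geometry.
- The filter comparison is strictly `> 0.40`; a flag switches to `≥`.
  Traces below the threshold can still be combined by lowering it — the
  39%-docked complementary fixture requires `--threshold 0.30`.

## Problem sizes

Tests and the acceptance script use 50–100-residue targets, 2–3 traces,
maps at 2.5 Å resolution on ~0.8 Å grids, 1000 random graphs for the solver
cross-check, 50 operator draws per space group and 100 noise seeds for CC
calibration — sizes at which every expected value is exactly computable or
tightly bounded while a full run stays interactive.

## Known limitations

- Sequence-conflict resolution is implicit (the chosen vertex's identity
  wins); no explicit mutation calling.
- Undocked (UNK) fragments are read, carried and written but never
  re-introduced into the consensus.
- Fragment rebuilding and alternate conformations are out of scope; gaps
  are only detected and exported as a work list.
- mmCIF, ligands, waters, anisotropic B-factors and insertion codes are not
  supported; altloc A is kept, others dropped.
- The map registration scan can be slow for P1 cells much larger than the
  trace, and its coordinate-wise polar search is heuristic there.
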