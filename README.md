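# tracefuse

Consensus protein model building from multiple automatically traced models.

Automated model-building programs (ARP/wARP-, RESOLVE-, Buccaneer-style
autotracers) run on the same electron-density map produce *traces* that
differ in completeness and in the errors they make: deleted stretches,
register ("frame") shifts where a correctly placed backbone carries sequence
numbers offset from the truth, and mistraced fragments built into density
that does not belong to them.  `tracefuse` combines any number of such
partial traces into a single consensus model that is more complete and more
accurate than any input.  It is aimed at structural biologists and
method developers working with experimentally phased crystallographic maps,
and at anyone who needs a fully synthetic, downloads-free testbed for
consensus model building.

## Method

1. **Filter.** Traces with ≤ 40% of side chains docked are discarded
   (strictly `> 0.40` by default; the threshold is a parameter).
2. **Superposition.** Independently phased traces may differ from the map
   frame by a space-group symmetry operator, an allowed origin shift
   (continuous along polar axes) and, in some point groups, an indexing
   ambiguity.  The reference trace is registered onto the map by a
   density-driven operator search; every other trace is brought into that
   frame by enumerating `sym_ops x reindex_ops` with the residual
   translation recovered in closed form from same-numbered Cα pairs.
   NCS copies are then superposed onto one reference chain by
   sequence-guided Kabsch fitting with robust outlier rejection.
3. **Graph.** Every docked residue of every trace becomes a vertex in the
   layer of its sequence position *i*; each layer also holds a *dummy* (gap)
   vertex.  Directed edges connect every vertex at *i−1* to every vertex at
   *i*.  The weight of an edge into residue *v* is

   `w = w_cc(1 − CC_v) − w_agree(a_v − 1) + p_ov · o_v + p_rama·[disallowed φ/ψ] + p_ca·max(0, |d(Cα_u,Cα_v) − 3.8| − 0.5)`

   where `CC_v` is the per-residue real-space density correlation, `a_v`
   counts traces that place the same residue at the same spot, and `o_v`
   counts spatially overlapping residues of *different* sequence number
   that fit the density better than `v` does.  Gap edges cost `g_open` once
   and `g_ext` per continued dummy; closing a gap is free.
4. **Path.** The consensus trace is the minimum-weight source→sink path,
   found with Bellman–Ford run from the N- and from the C-terminus (the
   lower-weight result is kept).  Negative weights from agreement rewards
   are safe: the layered graph is acyclic.
5. **Output.** The chosen residues (with per-residue source attribution),
   gap annotations, and a work list of anchored gaps shorter than 15
   residues for an external fragment-rebuilding program.

A synthetic-data module generates idealized ground-truth structures,
degraded traces with exactly known error modes, and matching density maps,
so the whole pipeline is testable without crystallographic data.

## Worked example

Generate the two-trace complementary fixture (57% and 39% of side chains
docked, jointly covering the whole 100-residue target) and fuse it:

```sh
tracefuse fixture --name complementary-halves --seed 7 --out demo/fixture
tracefuse run \
    --trace demo/fixture/trace0.pdb --trace demo/fixture/trace1.pdb \
    --map demo/fixture/map.ccp4 --seq demo/fixture/target.fasta \
    --truth demo/fixture/truth.pdb --threshold 0.30 --out-dir demo/out
```

prints

```json
{
  "frac_correct": 1.0,
  "frac_docked": 0.95,
  "frac_modeled": 1.0,
  "longest_fragment": 100,
  "n_gaps": 0
}
```

Every target position is modeled (`frac_modeled` 1.0) with every residue
within 1.5 Å of its true Cα (`frac_correct` 1.0); 95% of positions carry
side chains — more than either input (0.57 / 0.39) could offer alone.  The
remaining 5% are positions where no input modeled a side chain.  The
threshold is lowered here because the second trace (39% docked) would be
excluded by the default strict `> 0.40` filter.  `demo/out/` also holds the
consensus PDB (with gap and provenance REMARK records), `metrics.json`,
`gaps.txt` and a replayable `run.log`.

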