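# Methods

## Scope and model

`ensitemap` covers the analysis half of ensemble-based druggability mapping:
it consumes conformations (multi-MODEL PDB) and docked probe poses
(probe-PDB dialect) and produces ranked centroids, pocket sites, consensus
sites, viewer scenes and residue reports.  It does **not** run molecular
dynamics, dock probes (FFT sampling, minimisation, rescoring), or compute
energetic site descriptors; poses and ensembles come from files or from the
synthetic generators.

## Rigid-body fitting and RMSD

Superposition is the standard Kabsch SVD solution, unweighted (every
selected atom has weight 1 — the protocols this package follows specify atom
selections, never mass weighting) and restricted to proper rotations: if the
best orthogonal map is a reflection, the sign of the smallest singular
direction is flipped, because molecular mirror images are non-physical.
Degenerate inputs (fewer than 3 atoms, or rank < 2 after centering, i.e.
collinear selections) raise an explicit error rather than returning an
arbitrary rotation.

`fit_then_rmsd(mobile, reference, fit_sel, rmsd_sel)` fits on one selection
and measures on another, the usual trajectory-analysis convention (fit on a
rigid Cα core, measure everywhere).  RMSD after independent pairwise fits is
symmetric but **not** a metric (the triangle inequality can fail), which
matters for the threshold-scan property below.

## Conformational clustering

The greedy neighbour-count algorithm (the "gromos" method of trajectory
clustering tools): among unassigned members, the one with the most
unassigned neighbours (pairwise RMSD ≤ threshold, inclusive, self included)
becomes a centroid; it and its neighbours form a cluster and are removed;
repeat.  Including self makes singleton clusters well-defined.  Ties on
neighbour count go to the lowest member index — the inputs give no other
ordering and determinism is a hard requirement.  Clusters are ranked by
population (descending), ties by lower centroid index.

Two matrix modes are exposed because published protocols are often ambiguous
about the fit/compare interaction:

* `pairwise` (default): every pair independently refitted before the RMSD.
* `prealigned`: one global alignment to the first member, then raw RMSDs.

They differ only when internal motion is large relative to the threshold.

`threshold_scan` reports cluster count versus threshold.  The count is
non-increasing in the threshold for metric (distance-like) matrices — which
pairwise-fitted RMSDs closely approximate — but adversarial non-metric
matrices can violate it; the property tests therefore draw random *point
configurations* rather than raw random symmetric matrices.

## Grid pocket detection

A regular axis-aligned grid (default spacing 0.35 Å) covers the bounding box
of atom centres ± vdW radii plus padding (default 3 Å, enough to contain
every retainable point, since retention reaches at most √2.5 ≈ 1.58 radii
from an atom).  Retention of a grid point requires:

1. the point lies outside every atom's van der Waals sphere (the grid
   *surrounds* the vdW surface), and
2. for the **nearest** atom, d²/r²_vdW < `ratio_max` (default 2.5, strict
   inequality; the boundary case equals-2.5 is eliminated).

"Nearest atom" is one reading of the published ratio criterion ("a protein
receptor atom" is ambiguous); an "any atom" mode is config-exposed.  Neither
reading includes an enclosure/buriedness test — the commercial detector this
emulates additionally eliminates solvent-exposed points with proprietary
logic — so the nearest-atom criterion retains a thin shell over the whole
vdW surface in addition to genuinely sheltered cavity points.  Consequences:
site *counts* are not comparable to commercial output, but site *locations*
are informative, and the transient-pocket analyses in this package test
proximity of site points to a pocket anchor, which is robust to the shell.

Retained points are grouped into connected components under a configurable
grid connectivity (face-6, edge-18 or vertex-26; default 26) via
`scipy.ndimage.label`; components below `min_site_points` (default 15, about
0.6 Å³ at the default spacing — smaller blobs are grid noise) are dropped.
Sites are ordered by point count, ties by lexicographically smaller
centroid.  Volume is exactly point_count·spacing³.

Site descriptors are geometric/compositional only: contacting residues
(any atom within `contact_cutoff`, default 4 Å, of any site point) and the
fraction of them with apolar side chains (ALA, VAL, LEU, ILE, PRO, PHE,
MET, TRP).  A site with no contacts reports fraction 0 with a flag.
Radii come from the Bondi set shipped as a plain-text table (overridable);
unknown elements fall back to a configurable default (1.5 Å) with a warning.

## Probe consensus sites

Probe poses are read from a documented probe-PDB dialect: one residue per
pose, resname = probe type, docking score (lower = better) in the B-factor
column; pose centres are always recomputed as the mean of the pose's atoms.
Per probe type, poses are optionally truncated to the top *k* by score
(default 2,000) and then greedily clustered: the best-scoring unassigned
pose seeds a cluster and collects every unassigned pose within the cutoff
(default 3 Å, inclusive); unscored poses seed in input order.  Cluster
representatives of all probe types are pooled and grouped by the same greedy
rule (seeding priority: larger member count first), giving consensus sites
whose rank is the number of member probe clusters — many probe types
converging on one spot is the hotspot signature.  Tie-breaks: more distinct
probe types, then lexicographically smaller midpoint.  The midpoint is the
unweighted mean of member-cluster centres.  The pooling cutoff reuses 3 Å
and is exposed (`--cs-cutoff`); nothing in the consumed file formats pins
its value.

Note one consequence of the coordinate tie-break: when two sites tie on both
cluster count and type count, their relative rank depends on the coordinate
frame.  All primary keys are frame-invariant.

## Mapping, styling, residue selection

Every ensemble member is aligned to a chosen reference on a fit selection
(default `name CA`); the member's alignment transform is applied to its own
site coordinates (CS midpoints, pocket site points).  Provenance — member
index and centroid rank — rides along.

Styling follows the display convention the package reproduces: the largest
sphere radius equals the number of CS spheres displayed (in Å), shrinking
linearly by 1 Å per CS rank (floored at 0.5 Å so every displayed sphere
remains visible); centroid colours interpolate linearly in RGB from pure red
(rank 1) to pure blue (last rank).  Only the largest radius and the two
colour endpoints are externally fixed; the linear decrement and RGB ramp are
this package's choices, config-exposed.

Residue selection is evaluated in **each member's own frame** (sites belong
to that member's geometry; residue identity is frame-invariant, distances
are not; mapping to the reference is display-only).  A residue enters the
probe set iff, in any member, any of its atoms lies within the cutoff
(default 3 Å) of any CS midpoint; the pocket set is analogous against pocket
site points; "both" is their intersection; all sets are deduplicated across
members.  Distances are measured to CS midpoints, not sphere surfaces — the
midpoint is the only per-CS coordinate the pipeline computes — and the
choice is config-exposed.  The region report groups selected residues by
single-linkage clustering of their mean-atom positions on the reference
(default link cutoff 8 Å, roughly two residue diameters, so residues lining
one pocket merge while distinct surface patches stay separate), naming
regions A, B, C, … by descending size.

Scene output is a line-per-element key-value text file plus a Tcl script of
viewer graphics primitives (spheres, point clouds); both are deterministic
byte-for-byte.  The density-grid export writes one occupancy value per grid
point with a suggested rendering isovalue of 0.5.

## Synthetic fixtures: what they emulate and what they do not

`make_toy_protein` builds a serpentine backbone (N/CA/C/O per residue,
3.8 Å Cα spacing, 5 Å row spacing) — compact enough for fast grids, with
real residue keys and selections.  `make_hinge_ensemble` adds (i) a rigid
rotation of the second domain about a hinge axis per member (default: seven
members, angles 0°/25° split 4/3, emulating a slow two-state clamp motion),
(ii) optional isotropic Gaussian coordinate noise (default 0 Å so every
downstream decision is deterministic; tests that want roughness use
0.05–0.1 Å), and (iii) a planted transient pocket: 3 LEU + 1 SER lining
residues contribute 14 side-chain pseudo-atoms tiling a sphere around an
anchor 6 Å off the protein body, at radius 2.4 Å ("open": the anchor
neighbourhood is outside all spheres with nearest-atom ratio < 2.5, so the
detector retains a cavity) in the declared member subset (default 5 of 7)
and radius 1.1 Å ("closed": the anchor is buried inside the lining vdW
spheres and no retained point comes within 2 Å of it) elsewhere.  The
geometry is chosen so detection is decided by margins of several tenths of
an Å, not by luck.

`make_probe_poses` plants isotropic Gaussian pose clouds with a linear score
law (score = distance of the pose centre from the planted centre), so the
best-scoring representative is provably the pose nearest the planted centre
and midpoint tolerances follow from order statistics.

What the fixtures do **not** model: real backbone geometry and side-chain
rotamers, anharmonic/collective motions beyond one hinge, correlated noise,
solvent, docking-score noise that is not distance-monotone, and pockets
whose opening couples to the hinge state.  Passing tests therefore
demonstrate the correctness of the algorithms and their contracts, not
detection performance on real receptors.

## Numerical choices

* Altloc policy: keep the highest-occupancy conformer; ties prefer altloc
  'A', then blank.  Grid and RMSD stages need single-conformer geometry.
* Coordinates round-trip through PDB at 10⁻³ Å (the format's 3 decimals).
* Rotation validity tolerances: orthogonality and det = +1 within 10⁻⁹.
* All tie-breaks (cluster centroid, site ordering, CS ranking) are total
  orders, so identical inputs give identical outputs on any platform.
* Thresholds are inclusive (≤) for clustering and pose distances; the
  retention ratio is strict (<) — the two conventions that keep boundary
  behaviour fixed and testable.
* Problem sizes in the shipped tests and acceptance script (7-member
  ensembles of ~110 atoms, 10³ grid masks, ≤12-member random matrices,
  50-seed statistical repeats) were chosen so the full verification suite
  runs in seconds on one CPU while every stage is still exercised at its
  default parameters.

## Known limitations

* No enclosure test in retention (see above): absolute site counts and
  volumes include a surface shell.
* Selection grammar covers chain/resseq/name/resname with boolean algebra;
  no distance-based or sequence-motif terms.
* Region naming (A, B, …) is per-run; there is no cross-run region identity.
* mmCIF, protonation modelling and crystallographic symmetry expansion are
  out of scope.
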