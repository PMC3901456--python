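# Methods

`angmut` implements a trajectory-marker protocol for deciding whether a
missense mutation in human angiogenin (ANG) is likely deleterious, and if
so by which loss-of-function mechanism.  ANG is a 123-residue secreted
ribonuclease; its ribonucleolytic activity depends on the catalytic triad
His13/Lys40/His114 and its nuclear import on the nuclear localization
signal (NLS) ²⁹IMRRRGL³⁵, in particular the arginines 31–33.  Missense
mutations that abolish either function are of clinical interest in ALS.
All residue numbering in the package is mature-ANG numbering.

The package does **not** run molecular dynamics.  It consumes trajectories
(multi-model PDB, frame interval in ps supplied out of band, default 1 ps)
produced elsewhere, extracts four markers, and applies a rule-based
classification.  A synthetic-trajectory generator provides controlled
inputs for testing and demonstration.

## The four markers

**Backbone RMSD (stability).**  For every frame, the backbone N/CA/C/O
atoms of all residues are optimally superposed on frame 0 (Kabsch, SVD,
proper rotation enforced) and the RMSD is recorded.  The RMSD of the
returned transform is measured directly on the transformed coordinates
rather than through the `E₀ − 2·tr(S)` identity, which loses precision
near zero.  Point sets with fewer than 3 points or collinear geometry are
rejected (the optimal rotation is not unique there).

**His114 conformational switching (ribonucleolytic marker 1).**  The
side-chain χ1 dihedral (N–CA–CB–CG) of His114 is computed per frame with
the standard signed-dihedral convention and discretized into three rotamer
bins on χ1 mod 360°: `g−` [0°, 120°), `t` [120°, 240°), `g+` [240°, 360°)
(configurable).  The native state is the bin of frame 0; `switch_fraction`
is the fraction of frames outside it.  χ2 (CA–CB–CG–ND1) is reported for
His but does not enter the call — the published protocol judged switching
visually and does not state whether χ2 participated, so the quantitative
stand-in uses χ1 occupancy only.

**Leu115-mediated hydrogen-bond path (ribonucleolytic marker 2).**  Each
frame yields a residue-level graph: nodes are residues; an edge joins two
residues when a donor heavy atom (N/O/S that bears a hydrogen in standard
chemistry; backbone amide N except proline, plus the usual side-chain
donors) of one lies within 3.2 Å (inclusive, configurable) of an acceptor
heavy atom (backbone carbonyl O plus the usual side-chain acceptors) of
the other.  No angle term is applied by default, matching the
distance-only criterion the protocol states; an optional D–H···A angle
filter is available when explicit hydrogens are present.  The minimum
qualifying distance is stored on the edge.

The detector then asks whether a path runs from the mutation site to
His114 **through Leu115 as an interior node**.  The constrained search is
exact: it is solved as a unit-capacity min-cost flow on the node-split
digraph (two node-disjoint shortest legs Leu115→site and Leu115→His114),
so its reachability and path length agree with exhaustive simple-path
enumeration; ties are broken deterministically, preferring smaller residue
numbers during decomposition.  `path_persistence` is the fraction of
frames containing such a path, and the modal path across qualifying frames
is reported.  Branched paths are represented as the distinct simple paths
observed; mediation requires Leu115 interior on at least one.

**NLS SASA and compaction (nuclear-translocation marker).**  Per frame,
the solvent-accessible surface area of R31/R32/R33 is computed with an
in-package Shrake–Rupley implementation: quasi-uniform golden-spiral
sphere points (default 960) on probe-expanded spheres (probe 1.4 Å; vdW
radii C 1.70, N 1.55, O 1.52, S 1.80 Å), heavy atoms only.  The point
lattice is anchored in a molecule-intrinsic principal-axes frame (axis
signs fixed by third moments), which makes the discretized areas exactly
invariant under global rigid motion of the frame.  At 960 points the
result is within 1% of a 4000-point evaluation and within ~2% of an
independent implementation (biotite), which the tests check.  "Local
folding / close packing" is quantified as the joint radius of gyration of
the three arginine side chains (CB…NH2).

## Classification

Means are taken over the final 50% of frames (configurable
`analysis_window`); trajectories are expected to need an equilibration
burn-in, and the published protocol does not state its averaging window.

- **loss of ribonucleolytic activity** ⇔ `switch_fraction ≥ 0.20` AND
  `path_persistence ≥ 0.10`.  The two attributes are always presented
  jointly in the source protocol, hence the conjunction; `ribo_rule = or`
  relaxes it for sensitivity analysis.
- **loss of nuclear translocation** ⇔ relative reduction of window-mean
  total RRR SASA vs wild type ≥ 0.20 AND relative reduction of the RRR
  gyration radius ≥ 0.10.
- **destabilized** ⇔ window-mean mutant RMSD exceeds wild type by more
  than 1.0 Å.
- **deleterious** ⇔ any flag raised.

The numeric thresholds deserve emphasis: the original web protocol
e-mailed its thresholds to users and never printed them, so the defaults
here (0.20 / 0.10 / 0.20 / 0.10 / 1.0 Å) are this package's own declared,
configurable stand-ins, chosen so that a marker must persist for a
non-trivial fraction of a trajectory before it counts.  Likewise "RMSD
comparable to wild type" is made concrete as a 1.0 Å margin.  Every flag
carries an evidence record (statistic, threshold, wild-type baseline).
Both feature sets must be computed under the same configuration;
classification refuses mismatched configs.

## Structure handling and in-silico mutation

A narrow fixed-column PDB dialect is read and written
(ATOM/HETATM/MODEL/ENDMDL/SEQRES/TER/TITLE; altloc blank or "A" kept,
others dropped; other records skipped with a debug log).  Multi-model
files become trajectories after a per-model topology check.  Mutation
preparation strips all HETATM residues (crystallographic waters and the
citrate cofactor in the ANG crystal structure) and replaces the target
side chain from an ideal-geometry template (the chemical component
dictionary bundled with biotite, in its deposited common-rotamer
conformation) superposed on N–CA–CB (N–CA–C when the original is
glycine).  Backbone coordinates are untouched and the wild-type identity
at the site is verified first, which guards against numbering-convention
mistakes.  No energy refinement is attempted: relaxation belongs to
whatever produces the trajectory.

## The synthetic-data generator

`synthdata.generate` emulates only the statistical structure the
detectors read, not physics: no force field, no solvent, no thermostat.
Starting from a base structure it applies, per frame,

1. Gaussian jitter (`noise_sigma`, Å per axis, default 0.05 in presets —
   small relative to the ~1 Å fluctuations of a real folded protein, so
   injected signals are not masked);
2. a progressive per-atom random displacement field reaching
   `drift_amplitude` Å at the last frame (destabilization);
3. compaction of the R31–R33 side chains toward their joint centroid by
   `compaction_factor` (fractional; 0.3 yields a ~29% SASA and 30%
   gyration reduction);
4. an exact His114 χ1 assignment: every frame is set to its native bin
   centre except a seeded random choice of exactly
   `round(switch_fraction_target · n_frames)` frames (never frame 0,
   which defines the native state), which are set to the adjacent bin
   centre;
5. in exactly `round(path_persistence_target · n_frames)` frames, one
   donor–acceptor contact at 3.0 Å per consecutive pair of a named
   residue path, created by displacing a side-chain polar atom of one
   residue to 3.0 Å from a complementary partner atom of the other (no
   atom is moved twice; planning fails loudly when a pair offers no
   movable polar atom).

Because switching and persistence are injected as exact counts, the
detectors must recover them exactly; the drift amplitude is recovered
within 5% (the superposition removes only 6 of ~3N degrees of freedom).
Identical specs (including seed) produce byte-identical trajectory files.

The base structure for presets is a **synthetic** idealized model of
mature ANG: the correct 123-residue sequence built residue-by-residue in
an extended (φ = −120°, ψ = 130°) conformation with ideal-geometry side
chains.  The extended conformation is deliberate: residues distal in
sequence are distal in space, so the only His114-connecting interaction
paths are the injected ones, and the wild-type persistence is exactly 0.
This model is a geometric stand-in for the crystal structure — adequate
for every marker definition, parser, SASA and mutation test, but carrying
no native tertiary contacts; passing tests therefore demonstrate detector
correctness, not behaviour on real MD ensembles.

Presets encode the desk-scale study conditions (100 frames by default):
`wt_like` (noise only), `k17i_like` (switching 0.4 + the
Ile17–Asp15–Ile46–His13–Leu115–Gln117–Asp116–His114 path at 0.4),
`l35p_like` (same switching/persistence, the Leu115 branch of the
Pro35–Lys40–Gln12–His13–…–His114 path, compaction 0.3) and
`destabilized` (3 Å drift).  100 frames keeps a full four-trajectory case
study around half a minute while leaving the counting statistics exact;
the classification logic is identical at any trajectory length.

## Known limitations

- Synthetic trajectories share one topology by construction; real mutant
  trajectories must be supplied already built (the MD step is out of
  scope).
- The H-bond criterion is distance-only by default; atom typing is
  table-driven for the 20 standard residues and ignores protonation
  states (e.g. His is treated as both donor and acceptor at ND1/NE2).
- The rotamer binning is a three-state partition of χ1; slow continuous
  drifts inside one bin are invisible to it.
- Thresholds are not calibrated against experimental mutant panels; they
  parameterize a qualitative protocol, and conclusions about real
  mutations should treat them as such.
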