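# Methods

This note documents the models and procedures trajkit implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices behind each stage.

## Structures, trajectories and selections

A structure is an ordered atom table (serial, name, element, residue,
chain, mass, van der Waals radius) plus an `(n, 3)` coordinate array in
Ångström; a trajectory is a frame stack over one topology with a purely
informational frame period.  PDB input/output (single- and multi-MODEL,
fixed columns) is delegated to biotite; alternate locations keep the
highest-occupancy conformer.  Masses and radii come from element tables
(Bondi radii), with per-call overrides keyed by element and a fallback
keyed by the atom name's leading letters; an atom with neither raises an
error rather than silently defaulting.  Coordinates are Å throughout; no
unit conversion happens anywhere.

Selections are conjunctions of predicates (`chain`, `resid` with ranges
and comma lists, `name`, `resname`, `element`, `all`) joined by `and`.
Conjunction is commutative by construction; resolution returns strictly
increasing atom indices; an empty result is an error unless explicitly
allowed.  Residue numbers are used exactly as found in the input file (the
default helix ranges 408–420/468–475 and 910–918/978–988 follow the
numbering convention of the structures this kind of analysis is usually
run on).

Equilibration discard keeps the trailing production window; the dropped
frame count is recorded in the trajectory metadata.  (A 1500-frame
trajectory with 400 frames discarded mirrors the common 1.5 µs → 1.1 µs
analysis convention.)

## Superposition and flexibility

Superposition is weighted Kabsch: SVD of the weighted cross-covariance
with the determinant correction applied, so a reflection is never
returned.  Fits require ≥3 non-collinear atoms.  RMSD is
√(Σ wᵢ dᵢ² / Σ wᵢ) over the fitted atoms after the transform; mass and
uniform weighting coincide when all masses are equal.

Average structures are computed iteratively: superpose all frames on the
current mean, recompute the mean, repeat until the mean moves less than
`tol` (default 1e-4 Å RMS over the fit atoms, max 100 iterations; failure
raises with the last shift).  The converged average is the reference for
RMSD distributions and RMSF.  One subtlety is worth recording: the final
aligned frame stack is fitted to the *penultimate* mean, and the covariance
analysis stores exactly that alignment target, so re-projecting the
training trajectory reproduces the training coordinates to machine
precision and the projection-variance identity is exact rather than
approximate.

RMSD series fit on one selection and measure on another (required for
ligand-mobility analysis, where frames are fitted on the receptor and the
deviation is measured on the ligand).  Histograms use 0.1 Å bins by default
and are normalized to unit area.  RMSF is the per-atom root-mean-square
deviation about the converged average after per-frame superposition;
residue aggregation is the RMS over the residue's measured atoms.  Note
that superposition absorbs 6 rigid-body degrees of freedom, so for
isotropic noise of scale σ the measured RMSF is σ√3·√((3N−6)/3N) — only at
tens of atoms and above is the textbook σ√3 recovered to a few percent.

Two difference maps compare systems: the per-residue distance between
average structures after superposing one average onto the other on a
chosen fit selection (conventional display scale 0 → 4 Å), and the
per-residue RMSF change (scale −1.2 → +1.2 Å).  Atoms are matched across
systems by (chain, residue id, atom name), so systems differing by a bound
ligand compare over their shared atoms.

## Interface complementarity

Accessible surface area uses deterministic Shrake–Rupley sampling: each
selected atom's sphere is inflated by the probe radius (default 1.4 Å,
water) and covered by a 960-point Fibonacci lattice; a point is accessible
if it lies outside every other occluder's inflated sphere.  The occluder
set defaults to the selection itself — the selection defines the molecular
entity — and can be widened via `context` (used to measure how exposed a
bound ligand remains inside the complex).  Hydrogens are excluded by
default, matching the heavy-atom radii convention.  Per-atom areas sum
exactly to the total; a single sphere reproduces 4π(r+p)² to the quadrature
error of the lattice (<1% at 960 points).

Buried area on complexation is ΔASA = (ASA_A + ASA_B − ASA_AB)/2, with the
parts taken rigidly in their in-complex conformation.  Note the geometric
consequence of probe inflation: two surfaces bury area only when their
separation is below twice the probe radius, so ΔASA vanishes beyond 2.8 Å
of surface separation at the water probe.

The gap volume is defined by an explicit point-classification rule,
integrated on a regular grid (default spacing 0.75 Å): a point p belongs
to the gap region iff it is outside both parts' van der Waals surfaces,
within `max_gap_sphere` (default 5 Å) of both, the local channel admits
the smallest allowed gap sphere (d_A + d_B ≥ 2·`min_gap_sphere`, default
1 Å), and the directions from p to the two nearest part surfaces oppose by
at least 120° — the last clause confines the region to points genuinely
*between* the parts rather than in the lateral shell around them.  This is
a reproducible reimplementation in the spirit of the classical
sphere-filling (SURFNET-style) procedure, not a bit-level replica of it;
the same predicate is integrable by Monte-Carlo sampling, which the test
suite uses as an independent quadrature oracle (agreement within 5% at the
default grid, refinement-stable to 2% on grid halving).

Gap index = gap volume / ΔASA (units Å).  Below a buried-area threshold
(default 1 Å²) the index is reported as undefined instead of dividing by
~0; trajectory series exclude undefined frames from the mean ± sd and
count them.  All surface parameters are echoed into every summary's
metadata.

## Helix axes and angles

The axis of a helical segment is estimated from its Cα trace.  The initial
direction is the normalized sum of cross products of consecutive second
differences of the trace: the second differences of an ideal helix point
radially inward, so each cross product lies exactly along the axis — the
estimate is unbiased even for segments with partial turns, where a
total-least-squares line through (smoothed) points tilts by a couple of
degrees.  The direction is then refined by least-squares fitting a full
helical curve (axis tilt, origin, radius, phase, twist, rise all free) to
the Cα atoms, the maximum-likelihood axis under isotropic coordinate
noise; at 0.3 Å noise on a 13-residue helix the mean axis error is ≈1°.
A winding-free (straight) trace falls back to the principal direction;
fewer than 5 Cα atoms or zero variance is an error.

Directions are signed N→C, so the pair angle arccos(d₁·d₂) lives in
[0, 180°] and distinguishes opening from closing; reversing one segment's
orientation maps θ → 180° − θ.  Per-frame series flag segments whose
perpendicular Cα scatter exceeds 2.5 Å as non-helical (an ideal α-helix
scatters ≈2.3 Å) and exclude them from the summary with a count; a warning
is emitted if any angle comes within 5° of the wrap, where the plain mean
is biased.  Angles can be computed per frame (default) or on average
structures.

## Collective motions

The covariance analysis runs on a configurable selection (default backbone
heavy atoms N, Cα, C) with mass or uniform weighting.  Frames are
superposed on the iteratively converged average over the same selection;
the covariance of the √m-weighted centered coordinates uses 1/n
normalization so the variance of a mode projection equals its eigenvalue
exactly.  Eigenvalues are clipped at zero (tolerance 1e-8) and sorted
descending; eigenvectors are orthonormal rows.

Filtering reconstructs frames as mean + Σ_k c_k(t)·(M^{-1/2} v_k) over a
chosen mode set: all modes reproduce the aligned trajectory to machine
precision, the empty set gives the mean structure, and single-mode
trajectories are the standard way to visualize a collective motion (the
package also supports writing them as multi-model PDB).  The mode report
gives fractional variances and per-residue involvement, defined as the
squared eigenvector weight on the residue's atoms (involvements of one
mode sum to 1).

Because frames are re-superposed, a localized displacement is always
accompanied by a small deterministic rigid-body compensation in the
eigenvector (a single moving atom keeps an exactly rank-1 covariance but
only ~90% of the eigenvector weight on that atom); eigenvalues of a
rigidly transformed trajectory copy agree to within the alignment
approximation (~1%).

## Substates and contacts

Clustering is GROMOS-style neighbor counting on the pairwise-RMSD matrix:
repeatedly take the unassigned frame with the most neighbors within the
cutoff (ties → lowest frame index, making the procedure deterministic),
assign it and its neighbors, remove them.  Pairs are superposed on a fit
selection and measured on a measure selection; the matrix computation is
vectorized with batched 3×3 SVDs.  The default cutoff is 1.5 Å on the
measured selection; a frame cap (default 2000) guards the O(n²) matrix and
the error message instructs striding.  Clusters are reported ordered by
size with dense labels, the medoid frame (minimal summed RMSD within the
cluster) and the cluster-average structure.  In the bundled pipeline the
fit selection is a rigid scaffold (the interface slab) rather than the
whole domain: in the miniature synthetic domain the mobile segment is a
large fraction of the backbone and a whole-domain fit would partially
absorb the displacement being classified.

Contact occupancy supports three criteria, all compared inclusively (≤):
minimum heavy-atom distance; hydrogen bonds (donor–acceptor N/O distance,
default 3.5 Å, plus a D–H…A angle ≥ 120° when hydrogens are present —
without hydrogens the evaluation falls back to distance-only and flags
it); and ion coordination (ion to O/N distance, default 2.6 Å, the Mg–O
convention).  Occupancy is the mean of the per-frame booleans.

Ligand mobility reports two numbers: positional RMSD of the ligand to its
average pose after fitting frames on the receptor (how much the ligand
moves within its site) and internal RMSD after fitting on the ligand
itself (its conformational flexibility), each mean ± sd.

## The synthetic generator

`build_two_domain_system` constructs a schematic two-domain complex:
chains A and B each contribute a planar grid of carbon "filler" atoms
(spacing 4 Å, the simplest geometry whose inter-slab gap is analytically
controllable) and a pair of ideal α-helices (rise 1.5 Å/residue, twist
100°, radius 2.3 Å; backbone N/C stubs placed on the helical curve so
backbone selections resolve) at a configured mutual angle; the slabs face
each other at a configured surface-to-surface separation.  An optional
ring-shaped C/O ligand with two Mg²⁺ ions sits mid-cleft.  The only
sterics is a minimum-distance construction check (1.5 Å, skipping
bonded-range neighbors); there are no energetics.

`generate_trajectory` samples frames as: hinge rotation of one helix
(square-wave schedule with equal dwell over configured angles, rotating
about the slab normal through the helix's N-terminal end) → rigid substate
offset of a target segment driven by a Markov chain → low-rank collective
modes → isotropic Gaussian noise (per-chain overrides).  Mode vectors are
drawn on a configurable support, orthonormalized in the mass-weighted
metric and projected off the rigid-body subspace, so the covariance
analysis should recover the configured variances directly (up to the
isotropic-noise floor ≈ σ²·m̄ per mode).  All randomness flows from one
seeded NumPy generator — identical configurations regenerate bit-identical
output — and the returned ground-truth record (state sequence, mode
coefficients, hinge schedule) suffices to score every downstream recovery
test.

What the generator deliberately does not emulate: real protein geometry
and packing, solvent, force-field correlations between neighboring
residues, anisotropic or state-dependent noise, and kinetics beyond a
first-order Markov chain.  Passing the recovery tests therefore
demonstrates the correctness of the estimators under their stated
statistical assumptions, not the behaviour of the pipeline on real MD
data, where convergence and sampling questions dominate.

### The four-system study

The bundled comparative study mirrors a ligand/partner binding experiment
with four conditions and engineered differences:

| system  | interface gap | helix-pair A | ligand        | noise |
|---------|---------------|--------------|---------------|-------|
| apo     | 2.4 Å         | 26°          | —             | 0.12 Å, 3 substates |
| ligand  | 2.2 Å         | 44°          | 0.25 Å jitter | chain A quieted (0.08 Å) |
| partner | 2.4 Å         | 26°          | —             | chain B quieted (0.08 Å) |
| both    | 2.5 Å         | 44°          | 0.10 Å jitter | chain B target raised (0.20 Å) |

so that ligand binding tightens the interface and opens the helix pair,
partner binding on top of the ligand loosens the interface again, quiets
the ligand (its positional RMSD roughly halves) and raises the target
segment's flexibility — the sign pattern the comparison report is tested
against.  Interface separations sit in the 2.2–2.5 Å range because the
slab contact only buries area below twice the probe radius (see above);
the resulting gap indices span ≈4–10 Å.

## Pipeline and reproducibility

`run_system` validates every referenced selection before any stage runs,
then executes the stages in a fixed order (discard → average/RMSD/RMSF →
interface series → helix angles → substates → contacts/ligand →
covariance analysis); any stage error aborts with the stage name.  Every
table is written as CSV with a JSON summary carrying all parameter values
and an input checksum.  `compare_systems` emits, per pair, the
displacement map, the ΔRMSF map and deltas of every shared scalar summary.
Identical inputs and configuration give bit-identical outputs.

The problem sizes used by the shipped validation runs are the package's
scaled-down study conditions: 200 frames per system (40 discarded) with an
interface stride of 20 in `scripts/acceptance.py`, 150 frames in the
end-to-end test, 5000 frames for eigenvalue recovery, 500 for substate
recovery, 10⁶ Monte-Carlo points for the gap-volume cross-check.

## Known limitations

* ASA quadrature uses a space-fixed lattice, so rotational invariance
  holds only to quadrature noise (≲0.5% at 960 points/atom).
* The gap-region predicate is a geometric operationalization; its absolute
  values are comparable between systems analyzed with the same parameters
  but are not exchangeable with other gap-volume implementations.
* The H-bond criterion requires explicit hydrogens for the angular part;
  heavy-atom-only topologies silently degrade (flagged) to distance-only.
* Pairwise-RMSD clustering is O(n²) in frames; stride long trajectories.
* Angle statistics use the plain mean, appropriate while angles stay away
  from the 0°/180° wrap (a warning covers the rest).
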