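# Methods

## Scope and model

`tmdimer` analyses the dimerization of a pair of membrane-embedded
α-helical transmembrane domains (TMDs) from coordinate trajectories,
and ships a synthetic-trajectory generator so every analysis stage can
be verified against known ground truth at desk scale.  The built-in
systems describe the insulin receptor (IR, residues 940–988) and the
IGF1R (919–967) TMD constructs; all observables operate on backbone
beads (atom name `BB`, one bead per residue) and use nanometres,
degrees, nanoseconds and kcal/mol throughout.  Ångströms appear only at
the PDB file boundary.

### Observables

* **Interhelical distance d_HH** — Euclidean distance between the
  unweighted centroids of the two chains' d_HH residue selections
  (IR: 953–979; IGF1R: 937–959).  Coarse-grained backbone beads have
  uniform mass, so the unweighted centroid *is* the centre of mass.
  The minimum-image convention is applied laterally (x, y) only:
  helices never wrap through the membrane in z.
* **Dimerized state** — frames with d_HH ≤ 1.3 nm, the conventional
  threshold for these receptors.  Detection is a plain threshold with
  no hysteresis: stable dimers in this family show no transient
  dissociation, so smoothing would add a parameter without changing a
  single flag.
* **Helix axis** — principal direction (largest-variance eigenvector)
  of the centred backbone beads of the axis range (IR: 957–979;
  IGF1R: 937–959), sign-fixed N→C.  The principal-axis fit is robust
  to the helix kink and to positional noise, unlike an endpoint
  vector.  The d_HH and axis ranges differ for IR by construction
  (they follow the published analysis conventions) and are kept as two
  independent configurable intervals.
* **Tilt θ** = arccos |axis · ẑ| and **crossing Ω** =
  arccos |axis_A · axis_B|, both folded to [0°, 90°].  Only unsigned
  angles are reported; signed crossing angles (left/right-handed
  packing) are out of scope.
* **RMSF** — per-residue fluctuation after an iterated rigid-body fit
  (Kabsch onto the mean, twice, so the reference is self-consistent).

### Free-energy profiles

Profiles along θ or Ω are plain Boltzmann inversions of the observed
histogram, U(x) = −k_B T ln P(x), with k_B = 0.0019872041 kcal/mol/K
and T = 300 K by default.  Bins are fixed absolute edges
[0°, 2°, …, 90°] so replica profiles always align; 2° is fine enough
to localise a minimum to a few degrees yet keeps ≥ 100 samples per
occupied bin at the default sampling depth.  Each profile is shifted
so its lowest finite value is zero (the shift constant is recoverable
from the stored probabilities); empty bins are marked +∞.  Replica
averaging averages *free energies* bin-wise over bins finite in every
replica and re-shifts.  No Jacobian (sin θ) correction is applied —
the profile is an apparent free energy along the chosen coordinate,
matching how such histograms are conventionally inverted for
transmembrane dimers; a sin θ weight would shift a 30° minimum by
roughly one bin and is deliberately left out.

### Clustering and packing shapes

Dimerized frames are clustered with the greedy neighbour-count
algorithm of Daura et al. over the backbone beads of both chains
jointly (the joint fit is what captures *relative* orientation).  For a
homodimer the two chain labelings are physically equivalent, so every
pairwise RMSD is the smaller of the direct and chain-swapped bead
mappings.  The pairwise matrix is O(n²) and cached; above 5000 frames
the caller must stride (the pipeline does this automatically via
`max_cluster_frames`).  The cluster "centre" is the medoid
(most-neighbours frame); averaged structures (per-bead means after
superposing members onto the medoid) are reported separately.

Shape labels: **X** when Ω > 15° (the published boundary of X-shaped
packing); otherwise the separations of the two chains' N- and
C-terminal core residues decide — **parallel** when
max(s_N, s_C)/min(s_N, s_C) ≤ 1.3, **V** otherwise.  The end-ratio
default of 1.3 is a geometric consequence of this package's
backbone-rod representation: with an axis clearance near 0.9 nm and a
3.3 nm core, a one-end-contact V at Ω ≈ 10° produces end ratios of
~1.4–1.7, while parallel packing stays below ~1.1; 1.3 splits those
populations with margin on both sides.  Both thresholds are explicit
configuration values.

### Surface areas

SASA uses the Shrake–Rupley construction with a deterministic
Fibonacci (golden-spiral) point set — 960 points per bead by default —
bead radius 0.264 nm (a typical coarse-grained bead) and probe radius
0.185 nm.  All three are configurable; none is prescribed by the
conventions this package follows, so the defaults are documented
choices rather than reproductions.  Buried surface area is
BSA = SASA(A) + SASA(B) − SASA(A∪B), *without* a factor ½: the full
accessible area lost on complex formation is reported.  Exactly
coincident beads are merged before evaluation (the union area of
duplicate spheres is otherwise ill-defined at machine precision).
BSA is exactly invariant under translation and invariant under
rotation only up to point-sampling noise (the point set is fixed in
the laboratory frame); at 960 points the residual is below ~2%.

## The synthetic generator

The generator emulates the statistical structure the analyses assume,
not the physics that produces it:

* **Helices are rigid rods** of backbone beads (0.15 nm/residue rise).
  The analysis stages only consume backbone geometry, so side-chain
  beads would add cost without adding verifiable signal.  An optional
  kink (axis direction change at the first kink residue, e.g. IR
  G960) is available in `build_helix`; the shipped presets use
  straight rods so that their labelled frame-0 geometry is exact.
* **Frame 0 realises the preset's initial (d_HH, θ, Ω) exactly**; the
  per-residue flexibility noise (below) starts at frame 1.
* **Diffusive search** — before association each anchor performs a 2-D
  Brownian walk with D = 10 nm²/µs plus a weak adhesion drift
  (0.08 nm/ns closing speed) so that an encounter from 7.2 nm arrives
  within a few thousand 50-ps frames; tilts perform reflected random
  walks in [0°, 90°] and azimuths free random walks.  The drift is an
  emulation accelerant: with it switched off (`approach_drift = 0`)
  the anchors are exactly Brownian, which is how the mean-square
  displacement contract (slope 4Dτ within 20%) is tested.
* **Bound state** — once the anchor distance reaches the association
  radius (1.5 nm), geometry is resampled every frame (memoryless)
  from truncated normals; the stationary distribution is all the PMF
  recovery needs, and no dissociation ever occurs, matching the
  stable-dimer phenomenology.  All normals are truncated at ±3σ,
  which makes "d_HH never exceeds 1.3 nm after association" hold by
  construction whenever mean + 3σ < 1.3 nm.
* **Geometric consistency of θ and Ω** — two axes tilted from the same
  normal satisfy |θ_A − θ_B| ≤ Ω ≤ θ_A + θ_B, so the three values
  cannot be sampled independently.  Sampling order: θ_A from its
  truncated normal, Ω from its truncated normal, then θ_B from its
  truncated normal restricted to the feasible interval.  The marginals
  of θ_A and Ω are therefore *exactly* the preset distributions (the
  quantities the recovery targets measure), θ_B tracks θ_A when Ω is
  small, and every realised value is recorded as ground truth.
* **Placement** — the two axes are realised with a global azimuth that
  random-walks frame to frame; the separation vector combines a
  clearance w along the common perpendicular with an axial contact
  offset t\* (0 = crossing at the centroids, as in X-shaped and
  parallel packing; −3.5 nm for the V preset, putting the apex beyond
  the N-terminal end so the N-ends approach and the C-ends splay).
  w is solved from the sampled d_HH, so the measured distance equals
  the recorded truth exactly.
* **Flexibility noise** — isotropic Gaussian per-bead noise, 0.02 nm
  in the membrane core ramping linearly to 0.12 nm at the termini.
  This reproduces the qualitative core-vs-termini RMSF contrast of
  real trajectories while perturbing core-based axes by < 0.3°.

### Presets

`O1`–`O5` carry the five published initial orientations
(d_HH, θ, Ω) = (7.2, 45, 0), (3.5, 45, 0), (2.4, 45, 45), (3.5, 45, 0),
(3.1, 0, 0) with an X-like bound state.  The shape presets are
calibrated to the reported ranges, not measured from any trajectory:

| preset | tilt mean ± sd (°) | crossing mean ± sd (°) | bound d_HH (nm) | contact offset (nm) |
|---|---|---|---|---|
| `ir_xshape` | 30 ± 5 | 25 ± 10/3 | 1.15 ± 0.04 | 0 |
| `igf1r_vshape` | 10 ± 3 | 10 ± 5/3 | 0.95 ± 0.04 | −3.5 |
| `igf1r_parallel` | 5 ± 2 | 0 ± 2 | 0.90 ± 0.03 | 0 |

The crossing SDs are set so the ±3σ ranges coincide with the reported
mode ranges (X-shaped: 15–35°; IGF1R: < 15°).  The X and parallel
d_HH means sit inside the reported 1–1.3 nm and 0.8–1 nm windows; the
V mean (0.95 nm) sits at the lower edge of its window because
backbone-only rods lack the side-chain girth that holds real V-dimers
slightly further apart.

### What the generator does *not* emulate

Explicit lipids and solvent, force-field energetics, membrane
undulations, correlated bound-state dynamics (geometry is memoryless
frame to frame), dissociation kinetics, and side-chain packing.
Passing tests therefore demonstrate that the *analysis* machinery
recovers known inputs under realistic statistical structure — not that
the generator reproduces receptor biophysics.

## Numerical choices and degenerate inputs

* Kabsch superposition via the standard SVD construction with
  reflection guard (rotation determinant +1); mirror-image
  configurations keep a strictly positive RMSD.
* Ties in the Daura neighbour count and in PMF minima break toward the
  lower frame index / smaller bin centre.
* arccos-based angles lose ~1e-6° of precision near parallel vectors;
  tests tolerate this explicitly.
* Coincident beads: axis fits raise a degenerate-geometry error;
  SASA merges duplicates; `classify_shape` raises when core ends
  coincide.
* GRO files are pre-validated (frame block structure, bead-count
  consistency, coordinate fields) with 1-based line numbers in error
  messages; line-ending dialect and trailing whitespace are
  normalised before fixed-width parsing.  Frame times travel in the
  `t=` field of GRO title lines; PDB carries no times and falls back
  to 50-ps spacing.

## Problem sizes used by the shipped checks

PMF recovery runs 3 replicas × 5000 bound frames (≈ 30 000 tilt
samples); the mixture-recovery check clusters 500 frames
(80% X-shaped / 20% parallel) at a 0.25 nm cutoff; the pipeline tests
use 400–4000 frames per replica.  The 0.25 nm mixture cutoff — rather
than the 0.9 nm production default — is again a consequence of the
backbone-rod representation: smooth rods differing only in (Ω, d_HH)
are separated by ~0.4–0.45 nm pairwise RMSD between packing modes and
~0.1–0.25 nm within a mode, so 0.9 nm (calibrated for full
coarse-grained structures) merges everything, while 0.25 nm separates
the modes with margin.  The production default remains 0.9 nm
throughout the library and CLI.

## Known limitations

* Cluster percentages, BSA magnitudes and tilt ranges of the original
  300 µs simulation campaign are not reproducible from this package:
  those trajectories are not deposited, and the generator makes no
  attempt to mimic their microscopic detail.  Backbone-rod BSA values
  in particular are far below side-chain-resolved values.
* The BSA convention (no ½ factor, 0.264/0.185 nm radii) is a
  documented choice; published BSA figures may use another.
* Signed crossing angles, lipid analyses, per-leaflet properties and
  binary trajectory formats (XTC/TRR/DCD) are out of scope.
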