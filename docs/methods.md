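# Methods

This note records the models, conventions and numerical choices behind
`quasicryst`, and what the synthetic fixtures do and do not establish about
real trajectories.

## Scope and assumptions

The toolkit post-processes trajectories of *quasilinear* molecules — chains
whose long axis is well defined (alkanes, surfactant alkyl tails, lipid
chains). It assumes:

- molecules are whole (they are unwrapped to the image nearest their first
  atom at load time, since trajectory writers often wrap atoms
  independently);
- the box is treated as orthorhombic: for triclinic boxes only the diagonal
  edge lengths are used, with a warning. Imaging and minimum-image RDF
  distances need only edge lengths; full triclinic imaging is out of scope;
- coordinates are in nm, times in ps; angles are radians internally and
  degrees in every output.

Chain positions are 1-based (C1…C16). The defaults anchor the orientation
vector at C3→C14, the long-axis/tilt vector at C3→C13 (parallel to the long
axis of an all-trans chain, and exactly axial in the synthetic zigzag, which
C3→C14 is not), and the plane fit at the mid-chain atom C8. All three are
configurable per residue type, since surfactant tails need not share the
alkane numbering.

## Orientation descriptors and segmentation

Two descriptor modes exist because each fails somewhere:

- **slopes** `B_xy = arctan(Δy/Δx)` (cyclically for yz, zx) live in
  (−π/2, π/2] per component and identify v with −v, but are
  ill-conditioned when the chain vector lies nearly in a coordinate plane
  (a 0/0 ratio); the conventions are: zero denominator with nonzero
  numerator → exactly π/2, 0/0 → 0 (logged).
- **axis angles** `α_i = arccos(v_i/|v|)` are everywhere stable but map
  v → −v to π − α, so vectors are sign-aligned to a common hemisphere
  before use.

Time averaging defaults to **mean-vector** mode: per-frame vectors are
sign-aligned to the molecule's first-frame vector, averaged, and the
descriptor of the mean is taken. Literal arithmetic averaging of per-frame
slopes is available but suffers a wrap artifact (slopes of +89° and −89°
average to 0° although the orientations are 2° apart); the artifact is
unit-tested to document it.

Clustering is DBSCAN on a precomputed wrap-aware metric (per-component
angular distance modulo π for slopes, Euclidean combination). The
`eps_deg` (default 5°) and `min_cluster_size` (default 5) values are
pragmatic defaults, not derived quantities: density clustering is our
concrete realization of "identifying clusters by the ranges of slopes they
span", which admits no unique algorithm. Unclustered molecules form the
disordered pool (id −1). Cluster labels are assigned by descending size,
so they are deterministic and permutation-invariant up to relabelling.

## Periodic-image reconstruction

Slab detection sorts COM coordinates along the rotated z axis (after
aligning the mean chain axis with z) and starts a new slab whenever the gap
between consecutive values exceeds the void threshold. The threshold
defaults to half the median chain length (|C3→C13|), configurable; a
meaningful void must exceed intermolecular spacing but be smaller than a
box edge, and half a chain length sits comfortably between.

Shift multiples follow k = index(reference) − index(slab) with the most
populated slab as reference (ties → lower index), and atoms of slab i are
translated by k_i·L along the chosen axis. Two refinements:

- **Sign consistency.** Slabs are indexed along the *rotated* z axis but
  imaged along an *original* box axis. When the alignment rotation reverses
  the ordering between the two ((R·ê)_z < 0), all k signs are flipped;
  otherwise slabs would be translated away from each other. This reduces to
  the plain convention whenever the orderings agree.
- **Multilayer guard.** Molecules are imaged only if the largest
  COM gap along the sort axis *decreases*; a genuine multilayer structure
  (layers separated by more than the threshold but not created by
  wrapping) is left intact.

With `direction=auto`, all three axes are tried and the one minimizing
(residual gap, bounding-box extent) is kept and logged. The method's
premise is that the wrap direction has a significant component along the
chain axis, so the split shows up in the rotated-z coordinate; a crystallite
wrapped exactly perpendicular to its chains produces no rotated-z void and
is reported as a single slab.

## Eigenplane and tilt

The plane fit mean-centers the mid-atom coordinates and takes the unit
eigenvector of the smallest eigenvalue of the 3×3 second-moment matrix of
the *centered* coordinates; d = N̂·(mean point). The centering is the single
most consequential numerical choice in the package: the second-moment
matrix of raw coordinates only has the plane normal as its smallest
eigenvector when the plane passes through the origin. With centering, the
smallest eigenvalue equals the sum of squared point–plane distances
(least-squares optimality, verified against a brute-force orientation grid
in the tests). The normal sign is fixed deterministically (c ≥ 0, ties
broken by b then a).

Tilt is θ = arccos(|N̂·v̂|) in degrees, folded to [0°, 90°] since both the
normal sign and the chain head–tail direction are arbitrary. Statistics use
the population (N) denominator: the per-frame spatial std measures
molecular mobility within a snapshot; the per-molecule temporal std
measures the ordering of the crystallite over time. The plane is static by
default (fitted to time-averaged mid-atom coordinates over the analysis
window); per-frame refitting is selectable (`per_frame_plane`) for systems
whose plane drifts.

Folding has a statistical consequence worth knowing: near θ = 0 the folded
angle is non-negative, so under *orientational* noise the mean folded tilt
of an untilted crystallite is biased upward by roughly the noise amplitude
(Rayleigh mean). Positional (site) disorder does not trigger the bias
because it leaves chain orientations exact.

## In-plane packing

Key points for tessellation are intersections of each molecule's long-axis
line with the eigenplane, l = (d − N̂·C3)/(N̂·(C13 − C3)); a molecule lying
in the plane (|denominator| < 1e-12) is an error, as the construction
presumes chains crossing the plane. The intersections are mapped to 2D by
one rigid rotation taking N̂ to ẑ, built in axis-angle (Rodrigues) form
about (N̂ × ẑ)/|N̂ × ẑ|. Rotating per-point radius vectors instead would not
be a rigid motion of the point set, so a single plane-normal rotation is
used for all points.

Voronoi cells come from `scipy.spatial.Voronoi`. Neighbors are cells
sharing a ridge longer than 1e-9 nm — cocircular degeneracies (square
lattices) produce zero-length ridges that must not create neighbor pairs,
otherwise interior square-lattice cells would count 8 neighbors instead
of 4. Cells that are unbounded or have a vertex outside the convex hull of
the generators are flagged boundary and excluded from area/neighbor
statistics; crystallites are finite and irregular, so no periodic padding
is appropriate. Nearest-neighbor histograms pool interior-cell distances
with unit weight per frame.

The COM RDF uses minimum-image distances, ideal-gas normalization at the
selection's density in the box volume, bin width 0.01 nm by default, and
r_max ≤ half the smallest box edge (default 0.45×). By construction
∫ g ρ 4πr² dr equals the mean neighbor count within r_max, which the tests
verify against a direct pair count.

## P2 orientation

The inertia tensor about the molecular COM is eigendecomposed; axes are
ordered by *ascending* moment, so P1 (smallest moment) is the long axis —
mass far from an axis means a large moment about it, so the long axis
carries the least. A gyration-tensor mode is provided in which the largest
eigenvalue corresponds to the long axis, for users who prefer that
convention; both yield the same axes for rigid chains. A relative
difference below 1e-9 between the P2/P3 moments flags the axially
symmetric degenerate case.

P2 is a director (its eigenvector sign is arbitrary): in-plane angles are
folded modulo 180°, with angle_x the director angle from +x in [0°, 180°)
and angle_y the same angle measured from +y. The fold is applied to the
vector before `atan2`, making θ(v) = θ(−v) exact. This convention
distinguishes the two herringbone sublattices (35° vs 145°) while removing
the sign ambiguity; signed directions are not tracked across frames.
Vector-field exports anchor every arrow at the molecule's COM in the last
frame, so consecutive frames overlay into a movie of the rotational order.

## Synthetic generator

The generator is the package's ground-truth instrument. All-trans chains
(rise 0.127 nm per carbon, zigzag half-amplitude 0.044 nm — standard
all-trans alkane geometry; both configurable, and the analyses depend only
weakly on them) are planted on a lattice with prescribed area per molecule
(default 0.195 nm², the initial packing used for rotator-phase alkane
lattices), tilted about a chosen azimuth, rotated about their long axes by
a setting pattern (uniform / herringbone on (i+j)-parity sublattices /
random), noised, and rigidly moved. Hexagonal spacing follows
a = √(2A/√3); the distorted-hexagonal mode scales one lattice vector
(default ×1.08) to create two distinct neighbor distances, an R_I-like
deformation for histogram tests.

Noise is split into three channels because they probe different failure
modes:

- `noise_sigma` (nm): rigid per-molecule displacement of the whole chain
  from its site — positional disorder; orientations, tilts and setting
  angles remain exact;
- `angular_noise_deg`: small random rotation of each chain about a random
  in-plane axis — orientational disorder, the channel that spreads
  descriptor clusters and tilt distributions;
- `atom_noise_sigma` (nm): independent per-atom jitter — thermal
  conformational motion, the only channel that perturbs intra-chain
  geometry.

`generate_trajectory` redraws the selected noise channel per frame about a
fixed ideal structure (`noise_kind="site"` or `"atom"`). All randomness
flows through `numpy.random.default_rng(seed)`; identical specs are
bitwise-reproducible.

What the fixtures do **not** emulate: gauche defects and chain flexibility,
correlated thermal motion, surfactant headgroups, water, and genuine
freezing dynamics. Passing the round-trip tests therefore demonstrates the
correctness of the geometry pipeline — not that a particular eps, void
threshold or bin width is optimal for any specific force field or system.

## Problem sizes and determinism

Tests and the acceptance checks run on lattices of 25–100 molecules,
trajectories of 1–100 frames, and RDF baselines of 500 points × 50 frames —
sizes at which every ground-truth recovery is either exact (noiseless:
1e-9) or governed by documented statistical bounds. The full pipeline is
deterministic under a fixed seed: the manifest records a SHA-256 checksum
of every output file, and a rerun with the same config reproduces them
bit-for-bit.

## Known limitations

- Imaging handles one split axis per crystallite (simultaneous multi-axis
  splits are not reconstructed) and orthorhombic imaging vectors only.
- A crystallite wrapped perpendicular to its chain axis yields no
  rotated-z void and is left unreconstructed (reported as one slab).
- Phase assignment (R_I vs R_II vs crystal) remains with the user: the tool
  reports tilt, packing and P2 order parameters, it does not classify.
- Slope descriptors near coordinate planes are ill-conditioned; use
  `mode=axis_angles` there.
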