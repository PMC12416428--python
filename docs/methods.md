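# Methods

This note records the models, conventions and design choices behind
`foam3d`, in the order of the analysis chain.  Axis order is (z, y, x)
everywhere, voxel indexing is zero-based, and in phase maps 1 = liquid,
0 = gas.

## Synthetic foam generator

The generator emulates the statistical structure of tomograms of wet
foams so that every downstream stage can be validated against exact
ground truth at desk scale.

**Packing.**  Sphere centers are placed either by random sequential
addition (uniform candidates, rejected on overlap within
`r_i + r_j + film_thickness`, bounded retries with an explicit error
naming the achievable count) or on a jittered cubic lattice (jitter
amplitude ≤ 1 voxel).  Radii follow a constant or lognormal law.  The
label map is the film-separated Laguerre rasterization: each voxel joins
the seed minimizing the power distance |v − c|² − r², restricted to the
seed's sphere and carved back from the Laguerre cell boundary by half the
film thickness.  Because the power difference between two seeds is linear
in space, the distance of a voxel to the nearest cell bisector is computed
exactly, so films have the prescribed thickness up to rasterization.
Ground-truth volumes and centroids are read off the rasterized label map
itself (hence exactly consistent with it); the ground-truth adjacency
marks pairs whose surfaces are separated by at most `film_thickness + 2.5`
voxels — on generated packings non-contacting pairs are kept well beyond
this, so the criterion is unambiguous.

**Rendering.**  Two plateau intensities, Gaussian blur for the
partial-volume effect of the imaging chain, additive white Gaussian noise
for the detector.  Defaults used in the batch pipeline (levels 50/200,
blur 0.7 voxel, noise 5, i.e. ~3% of contrast) give a clearly bimodal
histogram, matching a well-exposed reconstruction.

**Deformation.**  Sequences apply an affine map x → Ax + t cumulatively,
resampling labels by nearest neighbor (label values preserved exactly).
Bubbles advected outside the box are flagged per frame, never silently
dropped.

**T1 fixture.**  Four equal spheres in a tetrahedral-like arrangement;
the close pair (centers 1.8 R apart, split at the midplane) swaps with the
open pair (2.4 R apart, a 0.4 R liquid gap) between the two frames while
the four diagonal contacts persist.  The constructor verifies the intended
contact sets on the rasterized volumes and fails loudly if the geometry is
ever broken.

**What the generator does not emulate:** Plateau-border geometry and
surface-minimized films, drainage and coarsening dynamics, reconstruction
artifacts (rings, beam hardening, motion blur).  Tests passing on these
synthetic volumes therefore validate the measurement chain — segmentation
topology, tensor algebra, bookkeeping — not the physics of real foams, and
quantitative accuracy on real data still depends on imaging conditions and
segmentation quality.

## Processing chain

* Background removal subtracts a Gaussian low-pass estimate (sigma =
  `scale`, which should exceed the bubble diameter) and restores the
  global mean, so a constant volume is unchanged.
* Phase segmentation uses Otsu's threshold estimated on masked voxels by
  default, or a fixed threshold; `>= threshold` is the high class, and
  which side is liquid is an explicit flag (`liquid_high`, default true
  for aqueous liquid in X-ray absorption contrast).  The liquid fraction
  is known to depend on this choice; it is a recorded config item, not a
  claim of unbiasedness.
* Speckle removal flips connected components smaller than per-phase
  thresholds: gas components first (26-connected), then liquid
  (6-connected).  The operation is idempotent.
* Bubble segmentation is a marker-controlled watershed of the negated
  Euclidean distance transform of the gas phase, with markers at the
  h-maxima of the distance map.  Default h = 2 voxels: small enough to
  separate bubbles whose distance-map saddle is two voxels below the
  peaks, large enough to ignore rasterization-scale maxima.  Labels
  partition the gas phase exactly; regions smaller than `min_volume` are
  merged into their largest neighbor (smallest region first,
  deterministic tie-breaks).
* Edge-bubble removal zeroes labels touching any image face or the
  validity-mask rim, since their volumes and interfaces are truncated.

## Structure

Liquid fraction is a plain voxel count ratio, mask-aware; gridded values
carry per-cell counts, a NaN (never 0) for empty cells, and a flag for
partial edge cells, which are kept.  The global value equals the
count-weighted mean of the cells.

Radius statistics: ⟨R⟩, R₃₂ = ⟨R³⟩/⟨R²⟩ and p₃₂ = R₃₂/⟨R⟩ − 1.  This p₃₂
form is non-negative (power-mean inequality), dimensionless and vanishes
exactly iff the population is monodisperse; it is defined in one place
(`radius_statistics`) so an alternative moment-based definition can be
swapped in if a different convention is required.

Local thickness follows the maximal-inscribed-sphere definition
(Hildebrand–Rüegsegger): thickness(v) = 2r of the largest sphere
B(w, dt(w)) containing v, with dt the Euclidean distance transform.  It
is computed by dilating distance-map level sets in decreasing radius
order with exact-radius ball footprints, which reproduces the definition
exactly (unit-tested against a brute-force per-voxel sphere search).
The cost is acceptable at the volume sizes used here; very large volumes
would need a dedicated approximate algorithm.

## Contacts

Two bubbles are in contact when their regions, each dilated by a
Euclidean ball of `dilation` voxels (default 1), overlap; face-adjacent
regions always qualify.  The criterion is a config item: with dilation d
the detectable liquid gap is about 2d voxels, so d should be matched to
the film thickness (the pipeline default of 2 suits ~1-voxel films).  The
overlap voxels form the labeled film region; a voxel claimed by several
films keeps the first (deterministic pair order) claim.

Films are fitted from the second-moment tensor of their voxel set: the
normal is the eigenvector of the smallest eigenvalue (sign convention:
first nonzero component of (z, y, x) positive), and the in-plane
semi-axes use the uniform-disc calibration a = 2√λ (a filled disc of
radius r has second moment r²/4), giving the planar-film area A = πab.
Contacts with fewer than three voxels or a collinear voxel set are
flagged degenerate with NaN geometry.

## Mechanics

Both strain measures are Hencky (logarithmic) strains about the isotropic
state built from the geometric mean of the eigenvalues, which makes them
exactly traceless and additive under composed volume-preserving
stretches.  Since the shape tensor S = ⟨(r−r̄)(r−r̄)ᵀ⟩ and the texture
tensor M = ⟨llᵀ⟩ are both quadratic in length, the per-axis stretch is
the square root of an eigenvalue ratio and both strains carry the same ½
factor in this representation: U = ½ ln(λ/gm(λ)) in the eigenbasis.  A
sphere stretched by diag(e^ε, e^(−ε/2), e^(−ε/2)) then yields eigenvalues
(ε, −ε/2, −ε/2) for either measure — the recovery that the tests pin
down.  Singular tensors (flat bubbles, coplanar link sets) raise a
dedicated error and are flagged, not fabricated.

The interfacial stress integrates the deviatoric tension dyad over the
bubble interface: σ = (Γ/V) ∮ (Id/3 − n nᵀ) dA.  The sign is the
tension-positive convention — a planar film of area A normal to z
contributes (ΓA/V)·diag(−2/3, +1/3, +1/3) — so an elongated bubble is in
tension along its long axis.  The pressure (isotropic) part is not
measurable from images and is excluded; viscous stresses are out of
scope.  The interface is meshed by marching cubes at the 0.5 level of the
binary bubble region after a 1-voxel Gaussian pre-smoothing.  The
smoothing is a numerical necessity, not cosmetics: normals of a raw
binary iso-surface are quantized along the voxel axes, which inflates the
surface area by ~8% and biases the deviatoric integral by ~12% on a 2:1
ellipsoid; with the pre-smoothing the same integral matches an analytic
surface quadrature to ~1.4%.  Triangle vertices are accumulated in
float64, leaving the trace at machine precision.  Bubbles touching the
image boundary have open interfaces and are rejected with a pointer to
edge-bubble removal.  Resolution dependence is real (it decreases with
bubble radius, as the sphere refinement test shows); a binning study on
one's own data is recommended before comparing absolute stresses across
resolutions.

## Tracking

Candidates for a bubble of frame t are frame-t+1 labels whose centroid
lies within `search_radius` of the predicted position (centroid plus an
optional caller-supplied prior displacement sampled at the centroid) and
whose volume change is within `vol_tol` (default 0.3 — generous against
rasterization jitter, tight against watershed splits/merges).
`search_radius` defaults to the Sauter radius of frame t, a natural
length scale that keeps the match local at moderate frame rates.
Conflicts are resolved greedily in ascending match distance, which is
injective and near-optimal when displacements are small compared with the
inter-bubble spacing; exact distance-and-volume ties are flagged
ambiguous rather than guessed.  A globally optimal assignment solve was
considered and left out: at the intended operating point (displacement
below half the minimal centroid spacing) greedy and optimal coincide, and
greedy keeps the behavior transparent.  Trajectories are transitive
compositions of pairwise matches; a chain ends at the first lost or
ambiguous link, and group trajectories (pairs, T1 quadruplets, clusters)
are the intersections of their members' chains.

## Plasticity

Contact pairs of frame t are translated through the tracking into the
frame-t+1 label space; pairs with a lost member are flagged and excluded.
Lost and new sets are plain set differences of unordered pairs.  A T1 is
emitted only when a lost pair and a new pair select each other uniquely,
both members of each being common neighbors of the other pair; common
neighborhood is evaluated on the union of the two frames' topologies by
default (a neighbor counts if present at either endpoint of the
transition), with strict at-t or at-t1 evaluation available as a config
switch.  Ties and multi-candidate cases — higher-order rearrangements,
tracking dropouts — are reported in a separate table, never as T1s.
Event orientation α is measured in the vertical cylindrical shear plane
(z, rθ): the bar joining the pair centroids is projected onto (e_z,
e_θ(midpoint)) and the angle from the horizontal (azimuthal) direction is
reported in [0°, 180°).  For isotropically oriented bars the distribution
of α is uniform, which the test suite checks by Monte Carlo.

## Fields

Grid averaging is a componentwise arithmetic mean per Cartesian cell with
contributor counts and a `min_count` validity flag.  Coordinate passage
conjugates vectors and tensors with the local orthonormal basis; the
cylindrical azimuth θ is measured from +x toward +y (the convention of
this package — callers must not assume another origin), the spherical
polar angle from +z.  On-axis points get NaN azimuth, flagged rather than
zeroed.  Round trips are identity and eigenvalues are preserved to
machine precision.

## Batch pipeline

One YAML config per experiment: frame range, output root, one block per
stage.  Stage outputs are named deterministically per frame; manifests
record parameters and per-frame status and deliberately contain no
timestamps, so a full run on a fixed config is byte-reproducible (the
determinism test hashes every artifact of two runs).  Completed frames
are skipped unless forced; a missing input frame is a recorded per-frame
failure that does not abort the batch; a malformed config aborts before
any processing.

## Problem sizes

The test suite and the acceptance script run on 27-bubble lattice
packings in 60³–64³ boxes, 4-bubble T1 fixtures in 48³, a ~50-bubble
random packing in 110³, and ellipsoids up to 90 voxels long — sizes
chosen so the full validation chain (including the brute-force oracles
for local thickness, binning and surface quadrature) completes in about a
minute while every geometric quantity is still resolved by at least ~8
voxels per bubble radius, the regime in which rasterization errors stay
within the tolerances asserted in the tests.

## Known limitations

* The contact criterion is dilation-based; watershed-line-based film
  definitions would give slightly different film volumes and areas.
* Film areas assume planar films; curved-film corrections are not
  applied.
* Stress, strain and contact measures all inherit segmentation bias;
  on real tomograms the phase-segmentation method sets the liquid
  fraction scale.
* The tracker is not a global assignment solver and does not model
  coarsening-driven volume drift beyond the volume tolerance.
* Memory: all stages are in-core; terabyte-scale series must be
  processed frame-wise (the batch runner already does) on machines with
  enough RAM per frame.
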