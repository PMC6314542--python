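# Methods

This note records the models implemented in `ernano`, the conventions and
numerical choices behind them, and what the synthetic benchmarks do and do
not establish about real data.

## Coordinate and image conventions

Pixel coordinates are 0-based `(row, col)` indices of pixel centers; the
physical position of pixel (i, j) is ((j+0.5)·p, (i+0.5)·p) nm for pixel
size p (default 18.9 nm, the STED acquisition setting). All filters use
mirror-reflection boundaries so that image borders do not generate dark
edges, which would otherwise seed spurious intensity minima in the hole
detector. Images are photon-count-like: finite, non-negative, integer
after shot noise.

Bleach correction maps each video frame's intensity histogram onto a
reference frame (frame 0 by default, configurable) by monotone empirical
quantile matching — the standard deterministic construction. It is
idempotent up to the quantization of discrete histograms.

## Nanohole segmentation

The chain mirrors a semiautomated live-cell analysis: smooth with a σ =
1 px Gaussian; find candidate hole centers as *regional* minima (plateaus
with no lower 8-neighbor collapse to their centroid) with a 4-px minimum
Euclidean separation, resolved greedily in favor of the deeper minimum;
mask the ER footprint by max-normalizing, median filtering (15×15 px) and
thresholding at 5% of maximum; flood the masked, smoothed image with a
marker-controlled watershed (8-connectivity); then, per selected region,
define hole depth *D* as the mean smoothed intensity of the region's inner
boundary (pixels 8-adjacent to the outside) minus the region minimum, and
take pixels strictly below min + 0.4·*D* as the hole. Raw-image values at
those pixels are carried for downstream quantification.

Choices worth noting:

- The watershed is `skimage.segmentation.watershed`; tie pixels on equal-
  intensity plateaus are assigned by its deterministic flooding order
  (ascending value, then insertion age). On unique-valued images the
  catchment decomposition is unambiguous, and the implementation is
  verified pixel-for-pixel against an independent brute-force priority
  flood in the tests.
- "Edge of the watershed region" is read as the region's own boundary
  pixels (inner boundary), not the exterior ring.
- Ties exactly at the border threshold are excluded (strict `<`).
- Selection is semiautomated: all minima seed the watershed; user seed
  points (CSV or programmatic) pick which regions are analyzed; automatic
  rules reject regions touching the image border, flat regions (D ≤ 0) and
  holes below 3 px (at 18.9 nm/px a 1–2-px "hole" is below any meaningful
  shape measurement), plus an optional manual-rejection list.

## Hole morphometrics

Equivalent diameter d = 2√(A/π) with A = n·p²; symmetry s = √(λ₂/λ₁),
the ratio of pixel-position SDs along minor and major principal axes,
computed from the closed-form eigenvalues of the 2×2 covariance matrix.
Covariance uses population normalization (divide by n): a hole's pixel set
is a complete enumeration, not a sample — so a solid w-px axis has
variance (w²−1)/12. A variance-ratio variant (λ₂/λ₁) is available behind
a flag for comparability; the SD ratio is the default as it matches the
"SD along minor axis over SD along major axis" definition. Degenerate
inputs are flagged rather than raised: collinear sets give s = 0, a single
pixel gives s = NaN.

Group comparisons are the nonparametric route appropriate for these
skewed distributions: `scipy.stats.kruskal` omnibus, then Dunn's pairwise
z-tests on pooled mid-ranks with the usual tie correction, Bonferroni-
adjusted over all pairs (the adjustment scheme is configurable in
principle; Bonferroni is the conservative default). Dunn's test is
implemented in-package and validated against hand-computed rank
arithmetic.

## Tubule diameter fitting

A tubule is an ideal cylinder. Lumen labeling projects to the chord
function P(x) = 2√(a² − x²) (reported diameter = 2a,
inner-leaflet-to-inner-leaflet); surface labeling projects to an annulus
difference 2√(a_o² − x²) − 2√(max(a_i² − x², 0)) with a_i = a_o − shell
(reported diameter = 2a_o, outer-leaflet-to-outer-leaflet). The dye shell
is 4.5 nm for a directly fused protein tag and 17.5 nm when primary plus
secondary antibodies intervene. The membrane itself is treated as
infinitely thin apart from the shell.

The projection is evaluated on a ≤1-nm grid and convolved with a
unit-area 1D Lorentzian of FWHM Γ, truncated at 20·Γ and renormalized
(Lorentzian tails are heavy; truncation leaves ≲2% of the mass, and
renormalization preserves the model integral). The fit scans a (d, Γ)
grid — defaults d ∈ [20, 200] nm step 1, Γ ∈ [20, 100] nm step 0.5, wide
enough to bracket physiological tubules and plausible STED resolutions —
solving amplitude and background *exactly* by linear least squares at each
grid point, which removes two axes from the nested loop. The profile
center is initialized at the intensity-weighted centroid and refined over
a ±2-px sub-grid (0.5-px steps); whether the center should be free is
genuinely open, and this local refinement is robust without adding a grid
axis. Fitting operates on raw counts with unweighted least squares;
background is a fitted parameter rather than pre-subtracted. A fit is
flagged unreliable when its optimum sits on a grid boundary or the
amplitude does not exceed twice the residual noise SD. When Γ is fixed by
the user instead of fitted, per-labeling defaults of 50.9 nm (membrane)
and 45.8 nm (lumen) are provided.

Model profiles for the whole grid are cached as a bank (float32, one bank
resident), so fitting cohorts of profiles with identical grids costs one
construction.

## Image simulator

The generator is the study-conditions oracle: every pipeline stage is
tested against its ground truth.

Geometry: a slab of thickness t = 50 nm; each hole removes a central
cylinder out to the torus equator (the *inner diameter*, the narrowest
point) plus the inner half of a torus with tube radius r = t/2 and
centerline radius R = inner radius + r — the only reading under which the
rim is tangent to both slab faces. Holes sit on a square grid spaced 105
display pixels curved-edge-to-curved-edge, jittered uniformly by ±0.5 px
per axis so holes are never pixel-aligned. The volume is built with 1-nm
axial voxels on a 9×-supersampled lateral grid (2.1-nm subpixels); the
supersampling suppresses aliasing of the sharp rims and the expected image
is resolution-convergent (halving the axial voxel changes it < 0.5% RMS).
The 3D grid is never materialized — per-column luminal voxel counts are
computed in closed form from the torus cross-section.

Imaging: luminal voxels carry intensity α per nm of depth (α = 10 at the
default 1-nm voxel, so a uniform slab interior projects to 500), the
projection is area-averaged to 18.9-nm pixels and convolved with a
radially symmetric 2D Lorentzian kernel K(r) ∝ (r² + γ²)^(−3/2), γ = Γ/2,
truncated at 20·Γ and renormalized. This kernel's line-spread function is
*exactly* the unit-area 1D Lorentzian of FWHM Γ, which ties the simulator
to the profile-fit model: a noiseless simulated tubule profile matches the
1D model to <1% once the model is averaged over the pixel footprint. A
background of 1 is added and shot noise is drawn per pixel from a Poisson
distribution with the expected image as mean, so the default slab interior
expects 501 counts. One RNG seed governs jitter and noise; per-image
sub-seeds are spawned deterministically.

The benchmark sweep is 4 images × 25 holes at each inner diameter in
{30, 50, 75, 100, 125, 150, 200} nm. A caveat on signal levels: with the
axial *sum* projection prescribed here, even 30-nm holes present ~27σ dips
and are essentially always detected, so detection failure rates at small
diameters are not reproduced by this generator — distinguishing
identifiability regimes would require a much lower photon budget (of
order the α value itself rather than α·t). Recovered equivalent diameters
systematically exceed the inner diameter because the 40%-depth contour
lies on the curved rim; what the benchmark establishes is strict rank
agreement with truth and pipeline determinism, not unbiased absolute
diameters.

A sheet-to-tubule intensity-ratio helper inverts the (monotone) relation
between slab thickness and background-subtracted interior intensity,
normalized by a lumen-labeled tubule's peak under identical imaging, via
lookup.

## Hole tracking

Tracks are seeded (a hole the analyst points at) and corrected frame by
frame to the *deepest* local minimum within a 5-px search radius (≈95 nm,
under one hole diameter) of the previous position. Presence requires the
minimum's surround-to-minimum contrast (mean over a 2-px ring outside the
search disk) to reach 20% of the contrast measured at the start frame —
the threshold that separates "disappeared" from shot noise; both radius
and fraction are configurable. Single-frame dropouts are bridged (gap
tolerance 1 frame; a one-frame loss at 70-ms framing is shot-noise-
plausible). Persistence classes partition the cohort: present at both
video ends = persisted; absent at start only = appeared; absent at end
only = disappeared; absent at both ends with an interior run = both. The
classifier encodes presence/absence of a detectable minimum only — a hole
shrinking below resolving power and one genuinely closing are
indistinguishable by construction.

## Curvature budget

All areas are closed-form. A sheet of thickness t is a disk with an
outer-half-torus rim (tube radius r = t/2): flat area 2πR² (both faces to
the rim centerline radius R) plus rim 2π²Rr + 4πr². Each nanohole adds an
inner-half-torus rim 2π²R_h·r − 4πr² (R_h = inner radius + r) and removes
flat area 2πR_h². A tubule adds lateral cylinder area πdL (no end cap);
its junction with the sheet removes rim area equal to the tubule's
cross-section footprint, a second-order term. Total surface area is held
at the bare 5-µm reference disk's value by solving the sheet's rim radius
in closed form (quadratic); conservation is exact by construction and
verified to 10⁻⁹ relative over randomized configurations. Curved area is
reported unsigned: hole rims carry saddle curvature, and positive
curvature with or without orthogonal negative curvature is not
distinguished. The rim and junction conventions are isolated in one
helper each so alternative treatments can be swapped; every tested claim
except the absolute curved-fraction values is insensitive to them.

Consequences: hole_curved_area(50, 100) ≈ 29,157 nm², so ten holes store
the curved area of ≈ 928 nm ≈ 0.93 µm of 100-nm tubule; curved fraction is
monotone in hole count and tubule length; and the constant-curved-fraction
isoclines in the (tubule length, hole count) plane are nearly linear
(R² > 0.999) with slope ≈ −1 / (single-hole equivalent length), as implied
by the budget's affinity in n and L.

## Problem sizes and scope

The shipped analyses use 4×25-hole fields per diameter (2 replicates in
the acceptance tests), 50-profile tubule cohorts, 200-realization Poisson
consistency checks on 64×64 crops, and 1,000 randomized budget
configurations — sizes chosen so each claim is tested at full pipeline
fidelity while the whole suite runs in minutes on a laptop core.

Interfaces are the library functions and the numbered `analysis/` drivers;
the simulator, fitter and geometry model are plain functions, so no
separate command-line layer is provided.

## Limitations

The simulator emulates lateral geometry, Lorentzian blur and shot noise
only: no detector read noise or gain, no axial PSF structure (the axial
dimension is integrated away), no membrane undulations, no motion blur,
and no tubular-matrix or nuclear-envelope geometry. Passing recovery tests
therefore demonstrates correctness of the measurement chain under these
idealized conditions, not accuracy on real acquisitions, where labeling
inhomogeneity and background structure dominate. The tracking module
assumes seeding by an analyst; it does not discover holes. The curvature
model is purely geometric — no bending energies, no helicoidal connectors.
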