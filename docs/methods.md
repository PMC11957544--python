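# Methods

This note documents the models and procedures implemented in
`planaquant`, the parameter choices that matter, and the scope of what
the phantom-based validation demonstrates.

## Geometry and units

A volume is a `VoxelGrid`: a 3D array indexed `(z, y, x)` with voxel
centers at integer indices, per-axis spacing in µm, and the linear
expansion factor of the specimen.  All reported lengths are
expanded-sample µm unless explicitly converted; `to_biological`
divides lengths by the factor, areas by its square, volumes by its
cube.  `effective_resolution(r, f) = r / f` gives the pre-expansion
scale an optical resolution corresponds to: 2×2×5 µm³ optics at 4×
isotropic expansion resolve 0.5×0.5×1.25 µm³ of original tissue.
Physical boxes are half-open `[lower, upper)` and select voxels by
center, so abutting census boxes partition voxels exactly — this
convention is what makes per-region counts add up to the total.

Budget-constrained resampling (used to fit morphometry inputs in
memory) applies one isotropic voxel-count factor
`f = max(1, (bytes/budget)^(1/3))` so aspect ratios, and therefore
length/width/depth ratios, are preserved.

## Denoising

* **Gaussian smoothing** takes sigma in µm and divides by the spacing
  per axis; reflective boundaries.
* **Perona–Malik diffusion** uses the exponential conductance
  `g(d) = exp(-(d/κ)²)` on the six axial neighbour differences in an
  explicit scheme (`λ ≤ 1/6` for 3D stability), written in divergence
  form so total intensity is conserved exactly.  Default
  `κ` = 5% of the dynamic range, 5 iterations (10 for body-mask
  construction, where aggressive interior smoothing is wanted);
  these were interactive checkpoints in the original workflow and are
  config-overridable here.
* **Unsharp masking** is `x + amount·(x - G_σ x)` clipped to the input
  dtype range.
* **Edge enhancement** is a clamped difference of Gaussians.  The
  original workflow used an undisclosed built-in script for this step;
  the DoG band-pass is this package's explicit substitution, chosen as
  the simplest operator that flattens background (DC → 0) and favours
  nucleus-scale blobs over single-voxel noise.

## Structure enhancement

The Hessian at scale σ (in voxels) is computed by Gaussian smoothing
followed by central differences — unlike sampled
derivative-of-Gaussian kernels, finite differences annihilate constant
and affine fields exactly, so flat background cannot masquerade as
curvature.  Eigenvalues are closed-form (trigonometric Cardano,
vectorized; ~10⁻⁶ agreement with LAPACK) and sorted by absolute value,
|λ₁| ≤ |λ₂| ≤ |λ₃|, with γ=2 normalization (multiply by σ²).

* **Ballness** = |λ₁|·|λ₂| / |λ₃| where all three eigenvalues carry
  the polarity-consistent sign (all negative for bright blobs), else 0;
  maximum over the scale sweep, normalized to [0, 1] by the global
  peak.  Normalization is skipped when the peak is below 10⁻³ (on
  [0, 1]-normalized input): a volume containing no blob responds only
  at float-noise level and must not be stretched to full scale.  For a
  Gaussian blob of width s the γ=2-normalized response peaks at
  σ = √(2/3)·s ≈ 0.82 s analytically, which keeps the argmax within
  one unit scale step of s — the property the scale-selection tests
  check for s ∈ {2, 3, 4}.
* **Rodness** is the Frangi vesselness with α = β = 0.5 and
  c = half the maximal Hessian norm, gated on λ₂, λ₃ < 0 (bright
  tubes); the λ₁ eigenvector is the local tube axis.

Scale parameters are in voxels of the processed grid, mirroring the
pixel-unit vocabulary of the published parameter sets (head nuclei
1–6, trunk nuclei 1–3, neuron somata 2–5, fibers 1 only, all step 1).

## Instance segmentation

Thresholding defaults to Otsu on a 256-bin histogram — the
reproducible stand-in for an interactive thresholding checkpoint — and
the value used is always logged.  Spot removal keeps components of
exactly the minimum size; hole filling fills only background components
not connected to the volume border (6-connectivity; spot removal and
labeling use 26).

Watershed runs on the negated Euclidean distance transform restricted
to the mask.  Default markers are the h-minima of that landscape
(depth 1 voxel), plus a seed at the landscape minimum of any connected
component the h-minima missed — every component must own a marker or
it would stay unlabeled.  For *touching* nuclei the distance landscape
is too shallow to carry two minima, so the counting workflow
(`count_nuclei`) instead derives markers from local maxima of the
lightly smoothed **raw intensity** (σ = 1 voxel): a max-composited
stain keeps one intensity peak per nucleus even when boundaries touch.
On 256³ phantoms this splits 100% of pairs placed at 1.5× radius
separation while plain distance-transform markers split under 10%.

Plateau tie-breaks in priority-flood watershed are a convention, not a
correctness property: two valid implementations can assign an
equidistant boundary voxel to either basin.  The flood-correctness
test therefore perturbs each landscape by a deterministic
raster-index epsilon so every priority is unique and the correct
labeling is unique; the production flood then matches an independent
heap-based reimplementation exactly on 100 random instances.

## Morphometry

The body mask pipeline is: optional budget resample → strong diffusion
→ threshold → fill holes → morphological closing → 1-voxel dilation →
largest component.  The closing ball radius defaults to 8 voxels:
it must bridge the gaps between neighbouring nuclei, so the radius has
to exceed about one cell diameter at the working resolution (with
~6 µm nuclear spacing, radius 5 leaves a pitted mask at Dice ≈ 0.93
against a known capsule; radius 8 plus the margin dilation reaches
≥ 0.95).  The dilation compensates for thresholded nuclei ending about
half a cell short of the true body surface.  The closing approximates
the ambient-occlusion surface regularization of the original
workflow — both suppress surface pits; closing is deterministic and
cheap.

Length/width/depth are max–min extents along the mask's inertia
principal axes plus one voxel (voxels are cubes, not points).  These
are straight-line extents, not curved-centerline lengths, and are
labeled as such.  Volume is voxel count × voxel volume.  Surface area
comes from a marching-cubes isosurface at level 0.5 of the mask
smoothed with σ = 0.75 voxel: voxel-face counting overestimates a
sphere's area by ~50%, and σ = 0.75 balances staircase suppression
(sphere area error +0.8% at r = 20) against corner rounding on a cube
(−4%, keeping √SA/∛V within 3% of √6 for sides ≥ ~25 voxels; smaller
cubes lose proportionally more corner area and fall outside that
band — a known limitation).

The brain-lobe angle is defined operationally (the source workflow
never states a formula): project each lobe's landmark cloud (e.g.
octopaminergic-neuron centroids) onto the coronal plane, take each
cloud's first principal axis, and report the angle between the two
axes, folded into [0°, 90°].  Exactly collinear projected clouds are
rejected as degenerate.

## Fiber tracing

**Orientation sampling.** Axes (antipodally identified) are the three
coordinate axes plus a golden-spiral hemisphere set grown until a dense
probe set verifies that every direction lies within the requested
angular step of a sample — deterministic for a given step.  The
published 5° sampling yields ~700 axes.

**Cylinder correlation.** For each sampled orientation a solid-cylinder
template (anti-aliased 1-voxel edge ramp; interior to the outer
radius, cylindrical mask to the mask radius, outside ignored) is
zero-meaned and unit-normed within its mask and correlated with the
image; the local masked mean and variance normalize the score to
[−1, 1] (zero-variance windows are 0 by convention, with a variance
floor scaled to the float32 cancellation magnitude).  FFT products are
cached per volume, so the sweep costs two kernel transforms and three
inverse transforms per orientation.  Voxels whose mask window leaves
the volume are reported as 0 — zero-padded partial windows would fake
structure.  A direct gather-and-dot evaluator (`zncc_at`) provides the
brute-force cross-check used in the tests (agreement ≤ 10⁻⁴).

**Tracing.** Seeds are local correlation maxima above the seed
threshold, visited in descending order; the tracer steps
bidirectionally along the local best orientation with two refinements
that keep it on the ridge: direction momentum (weight 0.5 on the
previous direction, damping the wobble of quantized orientations) and
perpendicular re-centering (snap each landing point to the
best-correlation neighbour sideways of the travel direction).  Stops:
correlation below the continue threshold (default 0.6× seed), per-step
turn above 30°, volume edge, or an already-claimed voxel.  Accepted or
not, a trace claims a 2-voxel-radius tube; claimed voxels can neither
seed nor be traversed, which resolves crossings greedily but
deterministically.  Without momentum and re-centering, traces fragment
(41/50 phantom fibers recovered); with them, 50/50.

**Classification.** Given the body frame (AP, ML, DV; by default the
mask's inertia axes, longest = AP), a fiber within 30° of DV is
dorsoventral; otherwise its projection onto the AP–ML plane is binned
by the angle to AP: longitudinal < 30° ≤ diagonal < 60° ≤ circular.
The 30°/60° boundaries are this package's own — the source names the
classes but never their angular limits.  Censuses count a fiber in a
region if its polyline midpoint falls inside.

**"Angular sampling 5"** is read as 5 degrees (the unit of the
original module); the config key is unit-explicit.  The mask radius
(3) exceeding the outer radius (2.8) is interpreted as a thin
background annulus.  Templates are solid; no inner-radius value was
ever published.

## Statistics

`compare_groups` is the classical pooled-variance (Student) two-sample
two-tailed t-test — pooled, not Welch, matching the named test — with
the conventional star annotation; zero pooled variance with equal
means returns p = 1 by convention.  Note for hand-checking: sample
variances use ddof = 1, so (10,11,12,13) vs (20,21,22,23) gives
|t| = 10.954.

`fit_scaling` fits count–count allometries.  Counts have
multiplicative (constant-CV) errors, so residuals are weighted by 1/x
by default (`weights=None` recovers plain OLS).  The two-segment model
is a **continuous broken-stick** `y = a + bx + c(x−bp)₊` with the
breakpoint chosen by exhaustive grid over observed x values (≥ 5
points per side).  Continuity plus relative weighting is what makes
the breakpoint identifiable: two independent unweighted lines on
log-uniform noisy data mislocate it by up to 40% and "find" breaks in
truly linear data, while the weighted stick recovers a 5×10⁵-cell
breakpoint within ~7% at 5% noise and shows < 15% RSS improvement on
linear data versus > 80% for genuine breaks — hence the
no-breakpoint-supported threshold of 0.5 fractional improvement.

Regeneration time-courses report per-day mean ± SEM; the plateau onset
is the first day from which all subsequent day-to-day slopes of the
mean stay below 10% (configurable) of the maximal earlier slope.  A
constant series plateaus from day 0; strictly linear growth reports no
plateau.  The rule is this package's own operationalization of an
increase-then-plateau description.

## Phantoms: what they emulate, and what they don't

Generators are pure functions of parameters and seed.  SNR is defined
as (object peak − background mean) / background sd; noise is Poisson
photon statistics plus Gaussian read noise calibrated to hit the
target exactly (defaults: 200-photon peak, 20-photon background; SNR
10 for nuclei fields, 5 for fiber fields — representative of cleared,
expanded stains).  Objects are rendered with analytic anti-aliased
coverage because hard voxelization breaks sub-voxel orientation
recovery.  Nuclei are Gaussian-profile spheres (radius 2.5–4 µm,
σ = r/2), max-composited; touching pairs sit at exactly 1.5× radius.
Fibers default to 50 straight cylinders, radius matched to the
standard template, 60–120 µm long, orientations drawn safely inside
their class bins, pairwise separation ≥ 6 voxels, and wholly inside
the matched filter's valid interior (14-voxel margin).  The allometry
generator defaults to a cohort of 99 animals spanning 5×10⁴–2×10⁶
cells with a 10%→5% slope change at 5×10⁵ cells and 5% noise.

Phantoms do **not** model: light-sheet PSF anisotropy and shadowing,
expansion distortion, staining heterogeneity (real muscle antibodies
under-label some fiber classes), curved fibers, nuclei size gradients,
or densely packed tissue where >2 nuclei mutually touch.  Passing the
phantom suite demonstrates the operators are implemented correctly and
the chains are well-calibrated for objects of the stated geometry; it
does not by itself validate biological counts from real volumes, which
still warrant the slice-wise visual review the original workflow
prescribed (label overlays can be exported for that purpose).

## Problem sizes and determinism

The validation suite runs nuclei counting at 256³ with 100 and 500
nuclei, the fiber census at 192³ with 50 fibers (10° sampling for the
census; the published 5° set is exercised on the template self-match),
the noise-control at 96³, and statistics calibrations at 2000
replicates — sizes chosen so the full suite completes in minutes on
one CPU while keeping every criterion at study conditions.  The
acceptance script uses 192³/256³ nuclei runs and a 160³ fiber census.
A single seed fans out to every stage by stable hashing, and repeated
recipe runs are byte-identical.
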