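# Methods

This note records the model behind `tractent`, the parameter choices that
matter, what the synthetic phantoms do and do not emulate, and the numerical
decisions taken where the design was genuinely open.

## Coordinate model

World coordinates are RAS millimetres; voxel indices are 0-based with the
voxel center at the integer index; a 4×4 affine maps voxel index → world mm
(the NIfTI convention). TRK files, whose native frame is voxel-scaled with a
corner origin, are converted to this frame on read and back on write by
nibabel, so both streamline formats present identical world-mm coordinates
to the library. Nearest-voxel lookup is `floor(index + 0.5)` (half-up),
used consistently by the density rasterizer, the fiber scorer and the mask
inclusion test.

## Density and tangent field

The density image assigns to each voxel the total polyline length (mm) of
all streamlines inside it, computed by splitting every segment exactly at
voxel boundaries. Length weighting (rather than point counting) makes the
image independent of the fiber step size; total image mass equals total
in-grid streamline length by construction.

The orientation field is derived from this image, not from diffusion-tensor
eigenvectors: at 2 mm resolution the tensor field is too noisy for 2–10 mm
structures, while the streamlines themselves are sampled ~10× finer than
the voxel. The per-voxel gradient is a spacing-aware central difference
(one-sided at volume borders). A voxel is *degenerate* when its raw
gradient norm is below 1e−3 of the volume maximum — flat background and
plateau interiors carry no orientation.

Optional regularization implements gradient-vector-flow diffusion
(`u ← u + μ ∇²u − |g|²(u − g)`, voxel-unit Laplacian, time step 1, `|g|²`
normalized to max 1). Defaults: 10 iterations, μ = 0.1 (stable for
μ ≤ 1/6); 0 iterations disables it exactly, leaving plain central
differences. The smoothing mildly denoises wall gradients; the pipeline's
behaviour does not hinge on it.

Because the density gradient is normal to a fiber wall, the tangent at a
voxel is recovered as the average of cross products `g_c × g_m` over its
valid 26-neighbors. Fiber orientation is axial (v ≡ −v), so each cross
product is sign-aligned to the running mean before accumulation; the
neighbor order is fixed, making the result deterministic. The tangent is
orthogonal to the central gradient by construction and marked invalid when
the mean cross-product norm falls below 1e−6 (locally parallel gradients —
e.g. a pure planar ramp — define no tangent).

**Known limitation.** Where a bundle *terminates* inside the volume, the
density gradient turns axial and the cross products point along the cap
rim, not the bundle axis. On finite tubes roughly two voxel slices per end
are affected (measured ~88 % axis agreement on a finite tube vs 100 % on a
volume-spanning one). For filtering this is benign — termination zones
genuinely are orientation-incoherent and simply read as high entropy — but
tangent-field accuracy assessments use the volume-spanning tube
(`phantom.straight_tube`), the cylinder idealization with no caps inside.

## Sphere partition and entropy

The orientation histogram bins are the central cones of a recursive zonal
equal-area partition of the unit sphere: a north and south polar cap plus
collar rings cut into equal-longitude sectors, with collar boundaries
adjusted so every region's area is exactly 4π/n (the spherical-cap radius
for k regions is 2·asin(√(k/n))). Region areas are analytic, not
approximated; lookup is O(log n_collars) and deterministic, with boundary
ties resolved to the lower region index.

Defaults: n = 32 bins, matching a 32-direction acquisition. Histograms are
axial by default: each vector is flipped into the hemisphere whose last
nonzero coordinate is non-negative, so v and −v share a bin. Note the
ceiling this implies: axially folded vectors reach only the ~half of the
bins in one hemisphere, so the practical entropy maximum is near
log₂(n/2) rather than log₂(n). Filtering only uses the *ranking* of fiber
scores, which the folding does not disturb; full-sphere binning remains
available (`axial=False`) and attains log₂(n) on uniform directions.

The per-voxel entropy is the plug-in estimator −Σ p log₂ p over the
histogram of all valid tangents in a centered n×n×n cube (clipped at the
borders; voxels with no contributing vector are masked). Neighborhood
sizing follows the nerve diameter: `round(d_mm / mean voxel size)` forced
odd upward and floored at 3 — e.g. 5 voxels for the 7 mm trigeminal nerve
on the 2 mm grid, 3 for the 2 mm lower nerves. The proportionality constant
(one voxel per diameter/voxel-size unit) is the simplest choice consistent
with "neighborhood proportional to diameter"; it keeps the histogram
support within the structure of interest.

The fiber score α is the mean map entropy over the voxels visited by the
fiber's points, nearest-voxel, without deduplicating repeat visits (a
finely sampled fiber thereby weights voxels by dwell length, which is the
natural reading); points on invalid or out-of-grid voxels are skipped, and
a fiber with no usable point receives the max-entropy sentinel so it is
filtered first. Entropy scores rank keep-low; mean-FA scores keep-high;
imported SIFT2-style weights keep-low.

## Filtering and thresholds

`filter_by_fraction` keeps the best `round(f·N)` fibers (half-up rounding —
the percentage semantics do not specify a rule, so one is fixed and
documented), ties broken by ascending fiber id. Kept sets are nested across
fractions and invariant under min–max score normalization, which only
rescales the threshold axis (per-dataset normalization makes optimal
thresholds comparable across datasets).

## Overlap metrics and the sweep

`SD = 2|Z|/(|X|+|Y|)` counts candidate fibers *fully* included in the
reference's discretized mask (inclusion fraction 1.0 by default, exposed as
a parameter since partial inclusion is a legitimate variant); `RSD` swaps
the roles and thereby detects truncation. Both are reported together. The
mask is the exact support of the density image, so a fiber grazing a voxel
for any positive length marks it.

The sweep evaluates SD at keep-percentages 0–100 step 1. Since each
fiber's in-mask status against the fixed reference mask does not change
with the threshold, the curve is computed in one pass from the cumulative
in-mask count along the score ranking — identical to filtering at each
fraction, at 1/100th the cost. `SD_init` is the value at 100 %, `SD_max`
the curve maximum (ties resolve to the largest keep-percentage: equal
quality, more fibers, denser rendering), and `SD_diff = SD_max − SD_init`
is the filtering gain, non-negative because 100 % is in the sweep.

## Phantoms

`make_bundle` sweeps a parametric centerline (straight, arc, or helix
centered in a 40³ × 2 mm grid) with per-fiber in-disk offsets carried along
a parallel-transport frame, per-point Gaussian jitter (default σ = 0.2 mm,
a realistic tracking dispersion), and 0.1 mm sampling — the tracking step
size, well under a tenth of the voxel. Defaults: V-nerve preset (7 mm
diameter), 200 fibers, 60 mm arc. All randomness flows from one seeded
generator per phantom; contaminants draw from a derived sub-seed so adding
them never perturbs the bundle.

Contamination kinds mirror the two spurious-fiber pathologies:

* **false continuations** share the bundle trunk to half its length, then
  turn away by 60° over a 10 mm ramp and fan out to 3× the bundle spread —
  coherent fibers merging into a neighboring structure;
* **disordered** fibers are correlated random walks (persistence 0.9 per
  0.1 mm step ⇒ ~1 mm correlation length, incoherent at the voxel scale)
  confined to a 15 mm sphere beside the bundle — mingling fibers of the
  brainstem type.

Degradation suites map tracking-parameter faults onto their tractogram
effects: a lowered FA cut-off ⇒ proportional disordered contamination; an
enlarged seed region ⇒ proportional false continuations; a translated seed
region ⇒ partial truncation (dropping the true fibers farthest from the
shifted virtual seed) plus contamination. Level 0 regenerates the bundle
with a fresh seed only, emulating the residual variability of probabilistic
tracking (which is why SD_init sits near, not at, 1 even under optimal
conditions).

The FA baseline on phantoms uses a *synthetic* FA-like volume: a smoothed,
normalized fiber-occupancy map rescaled to ~0.15 background / ~0.8 core
plus smooth noise. It reproduces the property that makes FA filtering
punctual — FA is high wherever fibrous tissue is dense, blind to whether
local orientations cohere — without simulating diffusion. What passing
benchmarks therefore shows is that the entropy score exploits contextual
coherence that a density-proxy score cannot; it does not certify behaviour
on tensor-derived FA maps from real acquisitions.

What the phantoms do **not** emulate: partial voluming and acquisition
noise, curvature- and length-constrained tracking, anatomically realistic
neighboring bundles, tumor-displaced anatomy. Absolute SD levels on real
data will differ; the phantom benchmarks validate orderings and gains, not
clinical numbers.

## Problem sizes

The shipped benchmarks use a 40³ grid, 200 true fibers, 100 contaminants
and five seeded phantom instances per condition — a desk-scale setting in
which one full pipeline run (density → tangents → entropy map → α → sweep)
takes a few seconds, chosen so the whole evaluation remains comfortably
interactive while leaving every fiber-to-voxel ratio at the scale the
method assumes.
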