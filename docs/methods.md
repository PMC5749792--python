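# Methods

This note records the model implemented by `georeg`, the parameter choices
and their rationale, the numerical decisions that are easy to get silently
wrong, and what the synthetic fixtures do and do not demonstrate.

## Model and coordinate conventions

The transform family is the planar similarity

    [u]   [s·cos α  −s·sin α  Δu] [u′]
    [v] = [s·sin α   s·cos α  Δv] [v′]
    [1]   [   0         0      1] [1 ]

mapping source coordinates (u′, v′) to target coordinates (u, v). The rigid
form fixes s = 1; the pipeline default estimates s as well, because the scale
filter only coarsely normalizes scale across pyramid levels. All coordinates
are 0-based with x = column, y = row, origin top-left. Keypoints detected on
pyramid level ℓ live in level coordinates and map to full resolution as
x·scale, where scale = factorℓ; the pyramid resamples at exactly
(i·factor, j·factor) so this mapping is bias-free (a resampler that spreads
n output samples over n−1 input intervals would add up to a pixel of
position-dependent error, which matters at the sub-pixel accuracy the
consensus fit reaches).

Images are stored as float64 rasters in [0, 255]. 8-bit inputs round-trip
exactly; float intensities let the star-field generator put its background at
0.25 gray levels, which an integer raster cannot represent.

## Detection

FAST-9 segment test: a pixel is a candidate when ≥ 9 cyclically contiguous of
its 16 radius-3 circle neighbors are *uniformly* brighter than center + ξ or
uniformly darker than center − ξ (ξ default 40, valid range (0, 255)). The
accumulated absolute contrast over the circle is kept as the candidate score
and used only for 3×3 non-maximum suppression; contiguity, not the sum, is
the detection criterion — a sum alone cannot distinguish a corner from a
high-contrast edge crossing the circle twice.

Harris selection: Sobel gradients, structure tensor smoothed by a Gaussian
with σ = 1.5 truncated to a 7×7 window, response det(M) − k·tr(M)² with
k = 0.04, candidates sorted by response descending (ties by (y, x)) and cut
at the per-level budget. Budgets are proportional to level area, 500 total by
default. These constants are the standard operating point for this detector
family; nothing in the pipeline is sensitive to them at the ±50% level.

Orientation: α = atan2(M01, M10) over a radius-15 disc, moments taken with
coordinates relative to the keypoint, y increasing downward. A
point-symmetric patch (both moments zero) gets α = 0 by convention, and −π is
normalized to +π so α ∈ (−π, π].

## Description

256 test pairs are drawn once from an isotropic Gaussian (σ = patch_half/2 =
7.5 px), radially clipped to the disc of radius 12 and rounded to integer
offsets, seed 42. The clip radius leaves room for any steering angle plus the
rounding guard plus the 5×5 box-sum support inside the 31×31 patch, so a
keypoint ≥ 16 px from the border can always be described.

Each bit compares 5×5 box sums (integral image) at the two steered sample
points: bit = 1 iff sum(m) < sum(n), strict, ties → 0. Box integration
rather than single-pixel reads is what makes the descriptor usable at the
noise levels the fixtures model.

Steering rotates the pattern by the keypoint orientation with the matrix
R(α) = [[cos α, −sin α], [sin α, cos α]] applied in the same y-down frame the
orientation is measured in. This is the only direction that tracks content:
rotating the image by φ moves the intensity centroid to α + φ, and the
sample points must follow by exactly R(φ). (The transposed matrix — which
looks equivalent on paper — rotates samples *against* the content and
destroys rotation invariance; the unit tests pin the covariant direction.)
Steered patterns are cached at 30 discrete angles (12°/bin) for determinism
and speed; exact per-angle steering is available via a flag. The residual
quantization error (≤ 6°) costs a few Hamming counts, well inside the ≤ 40/256
rotation tolerance the tests enforce.

A greedy de-correlating selection (`learn_pattern_greedy`) is provided for
users with a training patch corpus: candidates ranked by |mean(bit) − 0.5|
ascending, accepted while the absolute Pearson correlation with every
accepted column stays below 0.2, threshold relaxed in 0.05 steps until the
requested count is reached. The canonical seeded pattern is the default
because it is reproducible without any corpus.

## Scale handling

Pyramid: 4 levels, factor 2, anti-alias Gaussian σ = 0.5·factor before each
resampling. Levels below 32 px are truncated with a warning.

Scale-ratio filter: ratios (query level scale / train level scale) are
histogrammed on log-spaced bins (at most 32, each spanning at least ~5%
relative width; peak ties break toward ratio 1). Matches outside
[peak center − ω, peak center + ω] are rejected (ω default 0.25, the middle
of the recommended 0.20–0.35 band; ω is in absolute ratio units and is
applied to the bin center). The dominant ratio d is the arithmetic mean of
the in-window survivors — a 2-component Gaussian-mixture estimate is
available behind `use_gmm` for bimodal windows, but with one dominant mode
the two coincide and the mean avoids an EM dependency. Finally only
0.6·d ≤ ratio ≤ 1.4·d survives. Ratios on a log axis (not differences) make
the fixed ±ω window symmetric and match the multiplicative 0.6–1.4 band.

## Rough selection

Hamming distance D = popcount(a XOR b) ∈ [0, 256].

Distance window: D̄ = mean distance; ε₁ = (D̄ − D_min)/2, ε₂ = (D_max − D̄)/2
("midpoint" reading of the half-widths); retain (D̄+D_min)/2 ≤ D ≤
(D̄+D_max)/2, inclusive. Degenerate all-equal distances retain everything.
Note the window is a *statistical* filter: one can construct small distance
sets where the match nearest D̄ falls outside it (e.g. {0,4,9,9,11}), so the
tests assert the definitional membership property, not a "nearest is always
kept" folk theorem.

Bidirectional ratio test: nearest/second-nearest ratio < t = 0.65 in both
directions plus mutual-nearest consistency. Ties resolve to the lower index
and an exact tie (ratio 1) is rejected for any t < 1; a side with a single
descriptor has no competitor and passes by convention (the consensus stage
guards downstream). In the pipeline the candidate sets are restricted to
keypoints still in play after the distance window, and surviving pairs are
intersected with the incoming list, so stage outputs are nested.

## Geometric-invariant matching

Each retained keypoint i gets a distance profile D_i: the sorted vector of
Euclidean distances (level-0 pixels) to every other retained keypoint in the
same image. Profiles are invariant under rotation + translation exactly, and
under uniform scaling when normalized by their mean.

Cost: F(i,j) = Σₛ Σₜ exp(−(D_i(s) − D_j(t))²/σ²) with σ = 1 px. σ is a
distance-error tolerance: only near-coincident profile entries contribute, so
F counts (softly) how many inter-point distances the two points agree on.
Corresponding points in two images share most of their distances and collect
one ≈ 1 term each; unrelated points collect only accidental coincidences.
Two deliberate deviations from a literal reading of the printed cost:

* **Kernel sign.** The exponent is negative. A positive exponent grows with
  *disagreement*, is unbounded, and makes any best/runner-up ratio test
  vacuous (the ratio is always ≥ 1). The literal form is kept behind
  `mode="as-printed"` for auditability.
* **σ under normalization.** Normalized profiles have unit mean, so a σ
  expressed in pixels must be mapped into normalized units; the
  implementation divides σ by the geometric mean of the two normalization
  factors. Without this, σ = 1 on unit-mean profiles is as wide as the whole
  profile spread and the cost matrix goes flat. The pipeline nevertheless
  defaults to *raw* profiles (`normalize_profiles=False`): normalization
  couples every entry to the set mean, so a handful of keypoints detected in
  one image but not the other perturbs all normalized entries at once,
  while raw distances degrade only gracefully. After the scale-ratio stage
  the residual inter-image scale is ≈ 1, which is exactly the regime raw
  profiles assume. Normalization stays the default for the standalone
  `distance_profiles` function, where scale invariance is the point.

Acceptance: candidates ranked by F descending; the best j* is accepted iff
every runner-up among ranks 2..K satisfies F(i,j_m) < T·F(i,j*), with
T = 0.8 and K = 2 (the classic second-best test; the printed rule does not
fix K). Accepted pairs are made one-to-one (higher F wins conflicts). The
emitted quality, 1 − runner-up/best, orders matches for progressive sampling.

Before profiling, each side is clustered spatially (greedy, radius 2 px at
level 0, strongest Harris response as representative). This step is
essential, not cosmetic: the same physical corner detected on several pyramid
levels yields near-coincident points whose profiles are mutually
indistinguishable, and the distinctiveness test would reject *all* of them.

Two integration modes with the descriptor pipeline:

* `intersect_geom=True` (default): profiles are built from the
  bidirectional-stage survivors and a match survives iff its representative
  pair was matched geometrically — the geometric stage is a further filter
  and all stage lists are nested.
* `intersect_geom=False` (replace mode, the star-field preset): the
  geometric matcher pairs the *full* described keypoint sets itself.
  Descriptor matching is the weak link in texture-poor scenes, so building
  profiles only from its survivors would starve the one stage that can
  handle them. Stage nesting then holds within the two chains
  initial→scale→window→bidirectional and geometric→consensus.

Cost-matrix evaluation exploits the sorted profiles: entry pairs farther
apart than √746·σ contribute an exact IEEE-754 zero (exp underflow), so a
window search evaluates only the contributing pairs — identical result to
the dense double sum (the tests compare against it), orders of magnitude
cheaper at realistic point counts.

## Robust estimation

`estimate_transform` is the closed-form least-squares similarity/rigid fit
via the centered cross-covariance (SVD with determinant-sign correction, so
only proper rotations are returned; a reflection-only correspondence yields
the best proper rotation with a large reported residual rather than a flip).

`prosac_filter`: matches sorted by quality descending; at iteration k the
prefix size is η = 4 + (k−1) and the sample is 3 uniform draws from the top
η−1 plus the η-th match — the published sample construction, kept although a
rigid fit needs only 2 pairs (over-determined minimal sets are more stable).
Inlier rule ‖M·p − p′‖² ≤ τ_in, default 9 px² (3-px residual). Termination:
inlier fraction > τ_ratio (0.5), or the best inlier count growing by less
than τ_grow (0.1/iteration) over a 10-iteration patience window, or max_iter
(500). The final transform is re-fit on the consensus set and flags are
re-derived under it (iterated to a fixed point, ≤ 3 rounds), so every
reported inlier satisfies the τ_in bound under the reported transform. The
single symbol the source material reuses for the FAST threshold, the inlier
bound and the ratio threshold is split into ξ_fast / τ_in / τ_ratio — one
symbol cannot serve three roles.

`ransac_baseline` shares the model, inlier rule and refit; only the sampling
is uniform. It exists for paired comparisons, not production use.

## Synthetic fixtures

* `synth_texture_pair`: band-limited noise background (Gaussian-filtered
  white noise, σ = 3) plus ~14 random convex polygons — a deliberate corner
  supply. The second frame is the first warped by the ground-truth transform
  (bilinear, zero padding), re-exposed (gain/offset, clipped) and corrupted
  with Gaussian pixel noise. Emulates rotated, re-illuminated, noisy natural
  scenes.
* `synth_starfield_pair`: background at peak_max/dyn_range (0.25 gray levels
  at the default 10³ dynamic range) with 80 Gaussian point spreads
  (σ_PSF = 1.2 px), peak intensities log-spread over the dynamic range,
  centers ≥ 6σ_PSF apart so each star is an isolated local maximum. Emulates
  long-exposure astronomical frames: high dynamic range, no texture.
* `synth_correspondences`: labeled point pairs under a known transform with
  Gaussian noise and a controlled fraction of uniformly misplaced outliers.

All generators are pure functions of their arguments (one `default_rng`
per call); same seed, same bytes. The warp uses the same coordinate
convention as the pipeline — a mismatch here would silently corrupt every
ground-truth evaluation, which is why the round-trip and intensity-mapping
tests exist.

What the fixtures do *not* emulate: non-rigid deformation, parallax,
occlusion, sensor-specific noise (Poisson, fixed-pattern), resolution
differences between the frames, and the appearance statistics of real
medical or remote-sensing imagery. Passing the suite shows the pipeline's
screening logic and estimator behave as designed under the modeled
conditions; it does not certify clinical-grade registration of real data.

## Scenario presets and measured operating points

The default configuration is the textured-scene operating point (ξ = 40,
t = 0.65, σ = 1, T = 0.8, η = 4, ω = 0.25). `starfield_config()` adapts
three knobs to point-source scenes, for stated physical reasons: ξ = 5
(most stars in a 10³ dynamic-range frame sit far below 40 counts of
contrast), one pyramid level (a 1.2-px PSF has no scale-space structure —
it aliases away after a single decimation), σ = 2 px (integer-pixel star
localization puts ~1 px of error on every profile entry), and replace-mode
geometric matching as described above.

Problem sizes used by the test suite and the acceptance script — 256²
fixtures, 500-feature budgets, 10–30 seeds per scenario, 100 constellations —
are the package's chosen desk-scale defaults; a full run of the acceptance
script takes seconds.

Evaluation conventions: a screened match is correct iff the ground-truth
transform maps its source point within tol_px (default 3 px) of its target
point; the matching rate is 100·(screened − mismatches)/screened, rounded
half-up to 2 decimals, 0 when nothing survives. Translation recovery is
compared at the rotation center the fixture defines (the image center): the
raw Δu/Δv parameters are referenced to the image *corner*, where a 0.4°
angle error couples through a ~180-px lever arm into >1 px of apparent
translation error even when the registration error over the content is a
tenth of a pixel.

## Known limitations

* The transform family is similarity-class; affine or nonrigid misalignment
  is out of scope by design.
* Corner localization is integer-pixel (no sub-pixel refinement), bounding
  end-to-end accuracy at roughly 0.1–0.5 px depending on inlier count.
* Replace-mode geometric matching is O(n²) profile pairs with an O(hits)
  kernel per pair; the pipeline caps each side at 250 points
  (`geom_max_points`, strongest responses kept).
* The distance-profile matcher assumes a mostly shared point set between the
  two images; it degrades once fewer than roughly half the points
  correspond, and the distinctiveness test then (correctly) returns few or
  no matches rather than wrong ones.
* With `intersect_geom` off the screened-stage lists are no longer globally
  nested (documented above); diagnostics consumers must use the two chains.
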