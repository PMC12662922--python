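# Methods

## Coordinate and angle conventions

Images are indexed `[row, col]`; a point is `(x, y) = (col, row)` with the
origin at the top-left corner. All in-plane orientations are *axial* angles
in degrees in `[0, 180)`: the chord angle of a contour is
`atan2(dy, dx) mod 180` computed directly in stored coordinates, without
flipping the y axis. Two statistics use different references, both
encapsulated in `angles`: the per-section mean angle is referenced to the
image horizontal, while the polarization statistic (dispersion) re-expresses
each angle as a signed deviation from vertical in `[-90, 90)` before taking
the sample SD (n−1). Any linear statistic on axial data has a fold
somewhere; placing it at horizontal keeps vertically-dominated fields — the
common case in longitudinal sections — far from it, and the arithmetic
section mean emits a warning whenever more than 10% of contour weight lies
within 10° of its 0/180 fold.

Two section-mean estimators are exposed. The default arithmetic
length-weighted mean `Σwᵢαᵢ/Σwᵢ` reproduces the plain weighted average of
the original procedure; the `axial` option takes half the argument of
`Σwᵢ·exp(2iαᵢ)`, which is continuous across the fold and is the estimator of
choice when section means may approach 0/180°. Profiles record which mode
produced them.

## Ridge detection

The detector implements Steger's curvilinear-structure model for bright
lines on a dark background. At scale σ the five Gaussian derivatives are
computed by separable filtering; at each pixel the eigenvector of the
Hessian with the most negative eigenvalue λ₁ gives the line normal **n**,
and the Taylor step `t = −(∇I·n)/(nᵀHn)` locates the subpixel point where
the directional derivative vanishes. A pixel is a line point when that point
falls within ±0.5 px of its centre and λ₁ < 0; the line strength is |λ₁|.
Hysteresis applies the published thresholds (seed ≥ 3.74, extend ≥ 0):
linking starts at the strongest seeds and walks both ways along the local
tangent, choosing among the three forward neighbours the valid point
minimizing subpixel distance plus orientation change, with a 45°-per-step
orientation tolerance. Contours shorter than 2 px are dropped and the 200
longest are kept.

Two numerical guards matter in practice and are deliberate choices:

- **Relative noise floor.** With a lower hysteresis threshold of 0, flat
  background whose eigenvalue is only float noise would be linkable; points
  below 10⁻⁴ of the image's peak response are therefore excluded. The floor
  is relative, preserving intensity-scale invariance of the geometry.
- **1-D structure condition.** Line points must satisfy |λ₂| ≤ 0.25|λ₁|.
  Dome-shaped responses — blob centres and stroke end-caps, where both
  principal curvatures are comparable — and the convex decaying tail just
  past an end-cap otherwise seed short spurious contours or bend contour
  ends around the cap. With the condition, a single Gaussian-profile line
  yields exactly one contour whose worst centerline RMS over widths 2–6 px
  and all orientations is < 0.1 px and whose chord angle errs < 0.5°.

Border pixels within ⌈3σ⌉ cannot seed contours (derivative filters are
unreliable there) but contours may extend into the border zone. Line-width
estimation and junction resolution are out of scope: downstream statistics
use only chord angles and arc lengths.

## Preprocessing

`sd_project` collapses a Z-stack to the per-pixel sample SD (n−1) and
rescales `[0, max]` onto the dtype range; it highlights structure that
varies through depth. `clahe` wraps contrast-limited adaptive histogram
equalization with the common plugin convention as defaults (127-px blocks,
256 bins); the original study names the function without parameters.
`convex_hull_mask` binarizes a reference channel (global Otsu unless a
threshold or callable is given) and returns the filled convex hull with its
vertex polygon; one hull from the reporter channel is applied to both
channels of a field, the stated reading of masking to "labeled tissue".

In the paired-channel analysis the hull *restricts measurements* rather than
zeroing pixels: detection runs on the unmasked images and contours with
fewer than half their points inside the hull are discarded. Zeroing first
would cut fibers at the hull boundary and plant step edges there, both of
which contaminate the dispersion statistic with artifactual short contours.

## Fiber-class analysis

Bernsen's rule with a radius-3 disc: per pixel, the local min/max define a
midgray; contrasted neighbourhoods (max − min ≥ 15, the plugin's default
contrast) assign foreground strictly above midgray, flat neighbourhoods are
assigned wholesale by whether the midgray exceeds the dtype midpoint (the
ImageJ dialect; implementations disagree, so the rule is explicit and
parameterized). Particles are 8-connected components with no size floor.
The class rule is inclusive: area ≤ 25 µm² counts as longitudinal. Class
areas per section are sums of disjoint particle areas — equivalent to the
union ("XOR") of non-overlapping ROIs — and the section statistic is the
longitudinal/transverse ratio, flagged undefined when the transverse area
is zero.

## Orientation profile

Sections are placed at `z = i/(n−1)` on the normalized nerve (uniform
thickness assumed; physical thickness can replace this via metadata).
Sections without a usable angle are dropped with a warning, keeping their
neighbours' z. The fit is ordinary least squares on the raw Vandermonde
basis of degree 7 — on `[0,1]` this is adequately conditioned — and at
least 8 usable sections are required. Critical and inflection points are
real roots of p′ and p″ from the companion-matrix solver, deduplicated at
1e-6; coefficients below 10⁻⁹ of the polynomial's coefficient scale are
treated as zero first, so flat fits report no spurious roots. Inflections
within 5% of either end are discarded (`edge_margin = 0.05`): degree-7
fits of smooth profiles routinely place meaningless p″ roots near the
boundary, and 5% was the smallest margin that suppressed them on smooth
phantoms.

Each surviving inflection is paired with its *nearest* environment
transition (ties toward smaller z) — the weakest assumption consistent with
reporting absolute differences; the pairing is stored so order-respecting
alternatives can be compared. Errors are fractions of nerve length,
reported as percentages. For multi-nerve studies,
`average_inflections_by_rank` aligns inflection lists by rank order before
averaging, the natural correspondence when absolute positions vary between
animals.

## Paired-channel comparison

Both channels are segmented with the same detector parameters. The
correlation is simple linear regression of the astrocyte statistic on the
axon statistic (R² of the fitted line, matching plotted line fits), for
both the SD pairing and the mean-angle pairing; a zero-variance predictor
is flagged undefined. Region comparison is an ordinary one-way ANOVA with
Tukey's HSD over all region pairs; groups need at least 3 values, and
D'Agostino–Pearson normality p-values are reported per group where n ≥ 8
(the test is undefined below that).

## Synthetic phantoms

The generator emulates what the downstream stages consume, not microscopy
physics. Strokes (in-plane fibers) are capsules with Gaussian cross-profile
— the profile for which Steger's model is exact, making subpixel accuracy
analytically checkable — and blobs (longitudinal cross-sections) are
isotropic Gaussians. A shape's footprint is its half-maximum iso-contour,
giving closed-form truth areas: `2Lr + πr²` for a stroke of length L with
`r = σ_w√(2 ln 2)`, and exactly the target area for a blob. Blob areas are
drawn from 5–15 µm², capped at 25 µm² so generator labels and classifier
labels agree by construction (the boundary value is longitudinal, matching
the inclusive cutoff). Axial angles are drawn by sampling a von Mises
variate on the doubled angle and halving — the standard axial
construction; the study never states its angle distribution, and the
doubled-angle von Mises is the canonical axial model. Overlapping shapes
add intensities and clip to the dynamic range.

Default study conditions, chosen once for detector testability rather than
photometric realism: 256×256 px at 0.5 µm/px, 60 fibers per section,
stroke width σ_w = 1 µm, lengths lognormal(ln 18 µm, 0.35), additive
Gaussian noise SD 0.01 of full scale (optional Poisson shot noise at a
1000-count budget), κ = 8 (≈14° axial spread), and — for profile-recovery
studies — 60 sections, 3° of per-section mean-angle jitter emulating
residual placement error, θ(z) = 90° + 30°·sin(4πz) with interior
inflections at z = 0.25, 0.5, 0.75 doubling as environment transitions,
and a longitudinal fraction rising linearly 0.1 → 0.7, the qualitative
proximal-to-chiasm trend. Stroke centres are inset so whole shapes paint
in-frame (truth areas match painted areas to the anti-aliasing tolerance).
Ground-truth inflections of θ are located by a dense finite-difference scan
(Δz = 10⁻⁴) with two guards: grid points landing exactly on a root (second
derivative 0.0) do not mask the sign change, and curvature below the
rounding-noise bound `~10³·ε·max|θ|/Δz²` is treated as identically zero, so
linear profiles report no isolated roots. Boundary roots at z ∈ {0,1} are
excluded, mirroring the edge-effect exclusion downstream.

Channel pairs share a mean angle; channel B draws at κ_b and channel A at
`coupling(κ_b)` for a caller-supplied monotone coupling (validated on a
κ grid). Pair images are 384×384 px at 0.35 µm/px with 50–60 segments of
~12 µm placed by dart throwing with ≥ 8 px segment-to-segment separation:
without separation, side-by-side near-parallel strokes fuse into one
zig-zag contour whose chord angle is biased, inflating the dispersion of
perfectly aligned fields.

What the phantoms do *not* model — and therefore what passing tests do not
establish about real tissue: out-of-focus light and PSF blur, intensity
inhomogeneity of immunolabeling, curved or branching processes, junction
topology, vascular and cell-body structures, and section-to-section
registration error beyond the angle jitter. Results on phantoms bound the
algorithmic error of the chain, not the biological measurement error.

## Problem sizes and tolerances

The test suite and the acceptance script run the studies at desk scale:
8–20 phantom series of 60 sections for profile recovery, 40 channel pairs
for the coupling regression, 6 images per region for the ANOVA, 50 random
images/angle sets for the brute-force oracle comparisons and 100 random
degree-7 polynomials for root-solver equivalence (dense grid Δz = 10⁻⁵,
agreement to 10⁻⁴). Bernsen matches its per-pixel oracle exactly; the
dispersion SD matches a naive loop to 10⁻⁹. Recovered Bernsen footprints
are midgray-threshold footprints, not half-maximum footprints, so recovered
*absolute* areas sit ~10% below analytic truth while rank statistics are
unaffected; the round-trip test allows 15% on total area for this reason.

## Known limitations

- The arithmetic section mean is discontinuous at the axial fold; profiles
  whose true mean wanders near 0/180° should use the axial estimator.
- The contour cap ("maximum = 200") is read as a cap on retained contours,
  longest first; the plugin's own meaning is underdocumented.
- `high_contrast`/`low_contrast` are stored for provenance but inert: the
  explicit hysteresis thresholds govern, since both were published.
- Nearest-transition pairing can map two inflections onto one transition in
  pathological geometries; the stored pairing makes this visible.
- ANOVA pools images without modelling nerve/animal nesting, as in the
  source analysis.
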