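# Methods

## Problem setting

A single-plane (4-chamber) echocardiographic view shows one cross-section of
the left ventricle as a closed endocardial border. Volume estimation from
that border is an inverse problem: every method must assume, or learn,
something about the out-of-plane geometry. This package implements four
estimators under one contract — two geometric (area-length, Simpson's method
of disks) and two learned (quadratic regression and a backpropagation
network on a 16-distance radial descriptor) — together with the agreement
statistics used to compare them against reference volumes, and a synthetic
cohort generator that provides exact ground truth.

## Border model and featurization

A border is an ordered polygon (≥ 16 vertices, mm coordinates, y-up frame)
with an apical vertex and the two mitral-annulus endpoints as landmarks.
Vertex order is normalized to counter-clockwise on construction; landmark
indices are remapped when the input is clockwise. Validity (simple polygon,
positive area, distinct in-range landmarks) is enforced at construction.

The *center of border* used by the radial descriptor is the polygon **area
centroid**, not the vertex mean: manually delineated borders have uneven
vertex spacing, and the area centroid is invariant to it. The descriptor
consists of 16 distances from the centroid to the boundary along rays at
exact 22.5° steps, the first ray aimed at the apex vertex, sweeping
counter-clockwise. Where a ray meets the boundary more than once (small
concavities), the intersection **farthest** from the centroid is used; real
LV borders are near-convex, and the farthest hit is stable under small
concavities. Ray and chord intersections are computed exactly with shapely.

Borders loaded from CSV are densified to at least 256 vertices by
subdividing edges. Densification keeps every original vertex, so the polygon
is unchanged as a point set — it bounds the sampling resolution of
downstream chord/ray measurements without perturbing the geometry. (A pure
arc-length resampler that drops original vertices inscribes a strictly
smaller polygon and measurably biases the disk method; it is deliberately
not used.)

## Volume estimators

**Area-length.** With cavity area `A` (mm², shoelace formula) and long axis
`L` (apex vertex to the midpoint of the mitral chord),
`V = 8A²/(3πL)`, reported in ml (1 ml = 1000 mm³). For a true ellipse this
reduces exactly to the prolate-spheroid volume `πLD²/6` with `D = 4A/(πL)`.

**Simpson's method of disks.** The long axis is cut into `h` equal slices
(default `h = 20`, the usual clinical disk count; configurable). The disk
diameter of slice `i` is the total chord length of the polygon perpendicular
to the long axis through the slice midpoint; multiple chord segments under a
concavity are summed. The volume is `V = (π/4) Σ d_i² (L/h)`. The slice
height `L/h` is required for dimensional consistency even though clinical
shorthand often writes the formula without it. Slices whose plane misses the
polygon (landmark jitter near the apex) contribute zero rather than failing.

**Quadratic regression.** Ordinary least squares on the 33-column design
`[d_i², d_i, 1]`. The fit refuses rank-deficient designs and names the
dependent columns (via pivoted QR) instead of silently regularizing. At
least 33 samples are required.

**Backpropagation network.** A fully connected net `16 → (16 × depth) → 1`
with sigmoid hidden units and a linear output. Defaults: depth 4 (the
benchmark's depth sweep shows test agreement flattening there — deeper nets
only help training agreement), width 16 (the input dimension; the smallest
symmetric choice that trains stably at depth 4). Inputs are z-scored with
statistics of the training split only; the standardization is stored in the
model so prediction is self-contained. Initialization is Glorot-uniform from
a seeded generator; training is full-batch gradient descent **with classical
momentum** (defaults: learning rate 0.2, momentum 0.9, ≤ 30 000 epochs,
stopping when the epoch-to-epoch loss decrease falls below 1e-12) on the
mean-squared error. Momentum is the one departure from plain fixed-step
descent: on deep sigmoid stacks the plain iteration plateaus well short of
convergence (held-out R² ≈ 0.985 on a student–teacher recovery task that
momentum solves to R² ≈ 0.9998), while remaining fully deterministic given
the seed. The output bias is initialized at the training-target mean so the
first iterations fit residuals rather than the mean. Non-finite loss raises
immediately with a pointer to the learning rate. Models serialize to plain
JSON (shapes, weights, standardization, config) for auditability.

**Split protocol.** The benchmark trains on a random half of all frames
(frame-level split, 50 × 40 frames → exactly 1000/1000). Frame-level
splitting leaks cases across the boundary — frames of one heart appear on
both sides — so a case-level mode that keeps whole cycles together is
provided and recommended for generalization claims; the frame-level default
reproduces the benchmark protocol.

## Cardiac function

EDV and ESV are the extremes of the 40-frame cycle volume curve (no ECG
gating is available in a reconstructed fetal cycle; the curve itself
identifies end-diastole and end-systole). `SV = EDV − ESV`,
`EF = SV/EDV`. A flat curve yields SV = EF = 0 with a warning rather than an
error. An optional circular 3-frame median filter damps single-frame
estimator noise before the extremes are picked; it is off by default because
it also clips genuine sharp systolic minima.

## Agreement statistics

CCC is Lin's concordance `2s_xy/(s_x² + s_y² + (μ_x − μ_y)²)` with
population (1/n) moments; its 95% CI uses Lin's Fisher-z asymptotics. ICC is
the two-way random-effects, absolute-agreement, single-measure ICC(A,1)
computed from the two-way ANOVA mean squares, with the McGraw–Wong F-based
CI; the consistency variant ICC(C,1) is available as an option. ICC(A,1) is
the right default here because method-vs-reference comparison is an
absolute-agreement question, and these CI constructions are the common
defaults of clinical statistics packages. Bland-Altman reports the mean
difference (fixed sign convention: method − reference) and
bias ± 1.96·SD(differences) with the sample SD. Tests cross-check ICC
against pingouin and against a from-scratch ANOVA oracle, and CCC against
hand-evaluated values and the |CCC| ≤ |Pearson r| inequality.

## Synthetic cohort

Each case is a solid of revolution: a half-ellipse radius profile `r(u)`
along the long axis with (i) a taper exponent (apex sharpening), (ii)
symmetric low-order axial harmonics that deform the chord profile and break
the ellipse assumption, and (iii) skew harmonics applied with opposite signs
to the two sides, breaking mirror symmetry without changing the chord. The
profile is truncated at 92% of the full axis and closed with a straight
mitral-annulus chord. The **true volume** is the disk integral
`∫(π/4)d(z)²dz` of the chord profile by adaptive quadrature (relative
tolerance 1e-10); tests confirm it against closed forms (spheroid, sphere)
and a 0.05 mm slicewise disc-counting oracle.

Cycles scale the base shape isotropically along a raised-cosine volume curve
(systolic fraction 0.4) affinely mapped so the sampled extremes equal the
requested EDV and ESV exactly; per-frame truths follow from the cube-scaling
law, so SV/EF recovery is exact by construction. Cohort defaults emulate a
normal fetal study population: 50 cases × 40 frames; SV uniform in
[0.23, 1.21] ml and EF uniform in [0.38, 0.85]; long axis 11–20 mm with
diameter ratio 0.45–0.65 and taper 0.9–1.4 (mid-gestation LV dimensions);
profile-harmonic amplitude 0.2 and skew amplitude 0.1.

Delineation error is modelled as iid Gaussian vertex jitter (sd 0.3 mm,
sub-millimetre manual-tracing error at typical ultrasound resolution) added
to 32-vertex traced borders **after** the true volumes are fixed — a
measurement-error model, not a shape change. The 32-vertex density matches a
manual click count and is also a physical constraint of the noise model: iid
jitter on much denser polygons produces self-intersecting scribbles (the
generator redraws the rare invalid polygon, ~2% at these settings).

### What the generator does and does not emulate

Because truth is defined as the disk integral of the visible chord profile,
Simpson's method is **asymptotically unbiased on noise-free shapes by
construction**. This is deliberate: it separates geometric-model mismatch
(which biases the area-length method on tapered/harmonic shapes — on
asymmetric cohorts its per-frame error exceeds Simpson's on essentially
every frame) from delineation-noise robustness. It also means the synthetic
benchmark cannot reproduce the large method separation seen on clinical
data, where the reference volume contains out-of-plane information that no
single-plane method can recover and all geometric assumptions are genuinely
wrong. On the default cohort all four estimators agree with truth at
CCC ≈ 0.998 and the cross-method ranking is asserted only up to a 0.01 CCC
sampling margin (fixed a priori from the CCC confidence-interval width at
n = 1000 test frames). Passing that check shows the stack is wired correctly
and the learned methods are competitive, not that a network beats Simpson on
real hearts. Ultrasound speckle, fetal motion, and non-revolution 3D shape
families are out of scope.

## Numerical and reproducibility choices

* Coordinates mm, volumes ml; fixed conversion 1 ml = 1000 mm³.
* Ray 0 at the apex, counter-clockwise sweep in a y-up frame — a fixed
  convention so feature vectors are comparable across cases.
* Chord measurement at slice midpoints (edges would systematically clip the
  apex slice).
* One global experiment seed fans out to every stochastic stage via stable
  SHA-256 hashing, so stages rerun independently yet reproducibly; rerunning
  a configuration is bit-identical.
* Problem sizes in the shipped tests and the acceptance script (50-case
  benchmark, 1000-sample network training, 10-shape convergence studies) are
  the package's default study conditions; they run in a few minutes on one
  CPU.

## Known limitations

* Frame-level splitting (the benchmark default) overstates generalization;
  use case-level splits for honest out-of-case claims.
* The network's per-frame prediction noise inflates SV (max of a noisy curve
  is biased up, min down) — visible as a small positive SV bias in the
  function-agreement table; the optional median filter reduces it.
* The quadratic model cannot represent the exact cubic scale–volume law;
  over the narrow fetal volume range the approximation error is far below
  the delineation-noise floor.
* Biplane variants (distinct minor axes from a 2-chamber view) are not
  implemented; the stack is single-plane throughout.
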