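# Methods

## Scope and model

`bonecsg` quantifies the cross-sectional geometry of growing long-bone
diaphyses from grayscale voxel volumes.  The analysis chain is:

1. **Segmentation.** The volume (or single section) is binarized at the
   bimodal-histogram minimum threshold: the 256-bin histogram is smoothed
   with a 3-bin running mean until exactly two local maxima remain (plateaus
   count once; iteration cap 10,000 with a fixed-point early exit), and the
   threshold is the lowest minimum-count bin strictly between the modes.
   Bone is `intensity > threshold`.  Only the largest connected component is
   kept (26-connectivity in 3D, 8-connectivity in 2D).  Because a histogram
   valley is invariant under monotone intensity rescaling, no
   brightness/contrast normalization step is needed or performed.
2. **Alignment.** The foreground voxel cloud's largest-variance principal
   axis is mapped to z; a near-isotropic cloud (largest/second eigenvalue
   < 1.05) is rejected as having no unique long axis.  The distal end goes
   to low z — flagged by the caller, or automatically as the end whose
   summed metaphyseal cross-section (outer 15% of length) is wider.
3. **Orientation.** The spin about the long axis is resolved by rotating so
   the major principal axis of the distal-most 5%-of-length slab's summed
   cross-section lies mediolaterally (x); an explicit angle can override.
   Left-side bones are mirrored across x so all specimens share right-side
   handedness.  `standardize()` composes alignment and spin into a single
   nearest-neighbour resample (flips are exact array reversals); the
   separate `align_principal_axes` / `orient_about_long_axis` steps exist
   but cascade two resamples and correspondingly more voxelization noise.
4. **Length and slicing.** Intermetaphyseal length is the foreground
   bounding-box extent along z.  Sections are extracted at fractions of that
   length from the distal end, slice index `z_min + round(f·(n−1))`
   (round-half-away-from-zero, 0-based).
5. **Per-section quantification.** Periosteal contour = hole-filled largest
   component (areas by pixel count; the traced pixel-edge polygon and its
   shoelace area are reported for reference).  Endocortical border = direct
   least-squares conic ellipse fitted to the traced boundary of the cavity
   (the non-bone component containing the section centroid); a degenerate
   fit falls back to the cavity's moment-equivalent ellipse, and a section
   with no enclosed cavity yields MA = 0 with a warning rather than an
   error.  TA = contour pixel area, MA = π·a·b of the fitted ellipse,
   CA = TA − MA (so TA = CA + MA holds by arithmetic).  Second moments are
   computed on the solid (pore-filled) cortex between the two borders by
   pixel summation, including the per-pixel self-moment p⁴/12, which makes
   axis-aligned rectangles exact at any resolution.  θ = ½·atan2(2Ixy,
   Iy−Ix), mapped to (−90°, 90°].
6. **Porosity.** CPA is the area of sub-threshold pixels inside the cortex
   that are *not* 4-connected to the medullary cavity.  The exclusion
   matters because the fitted ellipse never matches the endocortical border
   to the pixel: without it, the sliver of cavity left outside the ellipse
   registers as porosity (~0.05 mm² even on a pore-free section).  The
   porosity index divides by the outline-based CA (pores included in the
   denominator); a bone-only denominator (CA − CPA) is available but
   non-default.  A traced-cavity (non-ellipse) endocortical mode is likewise
   available for sensitivity checks.

### Age estimation

Femur length FL is regressed on age with a cubic by OLS over known-age
individuals (16 of the 20 bundled reference specimens; the four whose ages
were themselves estimated from length are excluded from calibration, and a
stricter documented-only subset can be selected).  Monotonicity is verified
on a 1,000-point grid; the age for an unknown femur is found by bisection,
with a ±5%-of-range slack band beyond which estimation refuses to
extrapolate.  Reported ages are rounded to 0.01 y; full precision is kept
internally.  The regression direction (FL on age, inverted) matches how
such growth curves are drawn; a direct age-on-FL cubic is provided for
sensitivity analysis only.

### Cohort analysis

Ages in [0, 13) y are binned into five locomotor stages at 5/12, 3, 5 and
10 years.  The printed stage definitions leave gaps ("2.9 / 3" years); the
bins here are half-open [low, high) so they are exhaustive and disjoint,
and they reproduce the reference sample's published per-stage counts
(2, 5, 2, 7, 4).  Per-stage box-plot summaries use linearly interpolated
quartiles and Tukey whiskers (last observation within 1.5×IQR of the
quartiles).  No inter-stage hypothesis testing is performed — cohorts of
this size do not support meaningful group comparisons.

Ontogenetic trends are smoothed with LOESS: tricube weights over the span
fraction (default 0.7) of nearest neighbours, local polynomial fit,
evaluated on a 100-point grid, with pointwise 95% intervals from the local
linear-combination variance and a residual-based scale.  The default local
degree is 2, matching R's `loess` (the engine behind `ggplot2::geom_smooth`
and therefore the de facto standard for such plots); this was a deliberate
deviation from an initial local-linear design, because with a 0.7 span a
local line cannot represent an interior maximum near the age-range boundary
at all — its boundary extrapolation of the global decline always exceeds the
interior peak.  Degree 1 remains available and is preferable when the only
question is monotone decline, since a wide-span quadratic adds boundary
wiggle.  The implementation was cross-checked against R's
`stats::loess(span = 0.7, degree = 2)` on identical draws (agreement to a
few parts per thousand; frozen reference values live in the test suite).

## Synthetic phantoms

No raw scans of the study system are publicly deposited, so the generator
is the package's source of ground-truthed inputs.  A phantom diaphysis is a
tapered elliptical annulus: outer semi-axes a(z), b(z) and inner semi-axes
a_i(z), b_i(z) piecewise-linear in z, flared at both metaphyses with a
mid-shaft waist (so the three standard sections differ measurably) and
flared most distally (which the automatic distal-end rule keys on).  All
truth values are closed forms — TA = πab, MA = πa_i b_i,
Ix = π(ab³ − a_i b_i³)/4, Iy = π(ba³ − b_i a_i³)/4 — and truth moments
ignore pores, whose perturbation at ≤10% porosity is far below the
measurement tolerances.

Intracortical pores are circular-cross-section longitudinal canals, 2-6 mm
tall, planted by a per-slice birth–death sweep: canals retire when their
planned span ends or the tapering cortex can no longer contain them
(clearance checked on the slice's Euclidean distance transform), and new
non-overlapping canals are born whenever the planted area falls below
target.  The planted fraction is thereby tracked to ~0.1 percentage points
per slice — well inside the generator's 0.5-point contract — and, just as
importantly, adjacent slices share almost the same pore population, so a
slice extracted after tilt-and-realignment (which may land 1-2 slices away
from its untilted counterpart) sees the same porosity.  Infeasible requests
(pore radius exceeding cortical clearance, saturated packing) raise an
explicit error rather than silently under-planting.

Volumes are 8-bit with bone/background intensities 200/20, additive
Gaussian noise (default sd 5) clipped to [0, 255], mirrored for left-side
specimens and rotated by the requested Euler tilt with nearest-neighbour
resampling.  Nearest-neighbour is used everywhere for resampling: it
preserves the 8-bit value set and the bimodal histogram.  (Trilinear
resampling was tried and rejected — partial-volume edges interact badly
with the valley threshold, and blurred pore interiors drift above it.)

### Ontogenetic cohorts

A cohort draws ages uniformly over the study range (default 0-13 y), sets
femur length from a cubic growth curve (default: the curve fitted to the
bundled reference sample) plus Gaussian noise (default sd 5 mm), and maps
each age to a phantom through three trajectories:

* **medullary index**, gamma-shaped bump over a baseline:
  `m(t) = 0.30 + 0.12·(t/1.5)^k·e^{k(1−t/1.5)}` with k = 1 — rising from a
  thick-cortex neonatal configuration to a peak at 1.5 y (cavity expansion
  in early infancy), then relaxing as the cortex infills;
* **porosity index**, exponential decline
  `q(t) = 0.01 + 0.11·e^{−1.2t}` — high intracortical porosity near birth,
  effectively at its adult plateau by 3-4 y;
* **shape ratio Ix/Iy**, exponential decline from 1.0 (circular) toward an
  adult 0.45 at rate 0.4/y — progressive mediolateral reinforcement, most
  rapid in the first five years.

Per-individual scatter (defaults 0.02, 0.01, 0.03 on the three indices) is
added before the geometry is built.  The inner ellipse is geometrically
similar to the outer one (a_i = ρa, b_i = ρb), which decouples the targets
exactly: medullary index = ρ² and Ix/Iy = (b/a)² at every cross-section
regardless of taper.  Cohort generation is a pure function of (spec, seed);
voxel volumes are realized only on request, since trajectory-level analyses
need only the metadata and closed-form truth.

### What the phantoms do and do not emulate

They reproduce the measurement chain's geometry: tapered periosteal and
endocortical borders, planted porosity, arbitrary initial pose, left/right
handedness, 8-bit noise.  They do not contain trabecular bone, partially
fused epiphyses, scanner artifacts (beam hardening, rings), non-elliptical
endocortical borders, or anisotropic voxels.  Passing tests therefore
demonstrate correctness of the geometric and statistical machinery on
idealized bones, not robustness to every artifact of real micro-CT data;
the optional z-crop covers partially fused ends in real volumes, and the
traced-cavity mode gauges sensitivity to the ellipse idealization.

## Numerical choices and tolerances

* Pixel/voxel centres are 0-indexed coordinates; areas are counts × p²;
  membership tests use pixel centres.
* Nearest-neighbour resampling contributes ≤~2% error to section metrics at
  the resolutions used in the tests; the composed single-resample
  standardization keeps tilted-versus-untilted agreement within 2% at
  0.08 mm voxels (problem sizes in the invariance tests: 45 mm phantoms,
  ~570×210×280 voxels).
* Threshold ties break toward lower intensity; the valley of an
  empty-valley histogram is its lowest interior bin.
* The ellipse fit requires ≥4 cavity pixels; smaller cavities are treated
  as absent (MA = 0).
* LOESS requires ≥8 points and a window of at least degree + 2 neighbours;
  duplicated abscissae filling a window fall back to a weighted mean.

## Known limitations

* The peak age of a bump-shaped trajectory estimated as the argmax of a
  span-0.7 LOESS is a high-variance statistic at desk-scale cohorts: with
  n = 40 ages drawn uniformly over 13 years, the argmax has a standard
  deviation near 0.6 y from the randomness of the age design alone (the
  noise-free limit behaves the same), so individual cohorts frequently miss
  the true peak by more than 0.75 y.  The acceptance suite documents this
  directly; dense cohorts (n = 400) localize the peak reliably.
* The endocortical ellipse is an idealization; strongly scalloped or
  non-elliptical cavities bias MA (the traced-cavity mode exists for
  exactly that check).
* The distal-end heuristic assumes the distal metaphysis is the wider end,
  which holds for femora but is not anatomy-aware; callers can override.
* Only isotropic voxels are supported.
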