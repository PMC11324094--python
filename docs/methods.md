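# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `cucumorph`. It is written for a reader who wants to know
*why* the pipeline behaves as it does, and what passing the test suite does
and does not demonstrate about photographic data.

## Scene model and calibration

A valid frontal scene contains exactly two green objects on a dark
background: one fruit and one rectangular reference card. The excess-green
transform 2G − R − B (clipped to [0, 255]) suppresses the background and any
achromatic clutter; Otsu's threshold on that channel, followed by an opening
(disk radius 3 px) and 3 rounds of single-pixel erosion, removes hairline
bridges and glints, and connected components below 0.1 % of the image area
are dropped as speckle. Because erosion also shrinks the surviving objects —
and would bias both the px/cm calibration and every width measurement — the
cleaned components are morphologically reconstructed under the *opened*
mask, restoring their pre-erosion extent without resurrecting speckle or
thin bridges.

Card and fruit are told apart by **rectangularity** (area over minimum-area
enclosing rectangle area): the card is near 1, a fruit never is. A
rectangularity gap below 0.01 raises an explicit ambiguity error rather than
guessing. The card's physical long side is deliberately *mandatory
configuration* (`card_length_cm`): card sizes vary between imaging setups
and a wrong default silently corrupts every calibrated trait. Synthetic
scenes embed a 3-cm square card.

Perimeters of digitized shapes are measured on a Gaussian-smoothed version
of the marching-squares boundary ring (σ proportional to ring size, clipped
to 1–4 px). Summing the raw ring vertices overestimates the length of a
smooth digitized boundary by ~5 %, which would bias circularity-type traits
(4πS/Lc²) by ~10 %; the σ ∝ size rule keeps the estimate
resolution-equivariant. Real lobes on cross-sections live at wavelengths
far above the smoothing scale and survive intact.

## Centerline

Thinning uses the Zhang–Suen algorithm. The **trunk** is the skeleton path
between the endpoint pair with the longest *geodesic* distance along the
skeleton (8-connected graph, unit/√2 weights); Euclidean endpoint distance
would misrank strongly curved fruits. Both trunk ends are then pruned by the
local medial radius (distance-transform value at the endpoint): thinning a
blunt-ended shape leaves a diagonal corner branch of about that length, and
the extension step rebuilds the true end geometry anyway.

Smoothing follows the reference parameterization: subsample every 5th trunk
pixel, Savitzky–Golay filter with window 3 and polynomial order 1 applied
independently to the row and column sequences. The filtered points are then
regularized by a parametric cubic smoothing spline (residual budget 1 px²
per point) and resampled at 2.5 px arc spacing. The spline step matters
numerically: chord-summing a noisy pixel chain overestimates arc length by
1–3 % at desk-scale resolution (a pure digitization artifact), which would
exceed the accuracy targets for fruit length and curvature; after the
spline, recovered lengths are accurate to a few tenths of a percent.

Extension fits a degree-1 polynomial (arc-length parameterized, both
coordinates — this subsumes the axis-choice question and cannot blow up on
vertical segments) to the terminal 5 points, appends 3 extrapolated points,
and repeats until the polyline crosses the contour; the crossing is refined
by bisection to 0.5 px and snapped to the boundary. Divergence beyond twice
the contour diagonal is an explicit failure.

## Diameter profile and partition

At each centerline point the local tangent is estimated from a **wide
centered secant** (~12 px of arc on each side). This choice is deliberate:
where a thin stalk or stem joins the fruit's blunt shoulder, the true medial
axis makes a short V-shaped excursion; a local finite-difference tangent
rotates with that excursion and produces spuriously oblique chords (we
observed apparent diameters of 1.5× the true width), whereas the symmetric
secant averages the excursion out.

The transverse diameter is the distance between the two nearest contour
intersections of the perpendicular line on either side of the centerline;
positions whose perpendicular misses one side, or whose chord collapses
below 2 px (endpoint tangency), are skipped and flagged. The **clearance**
signal used for neck/tip detection is the shorter perpendicular half-chord.
The all-contour minimum distance is very close to it along tubular regions
but is systematically pulled down near taper shoulders (the thin wall is
"visible" across the corner), which biased detected neck/tip boundaries into
the body by 2–3 % of fruit length; the perpendicular clearance tracks the
local width without that bias.

Partitioning splits the profile at the arc midpoint. On each half, ordered
from the fruit end inward:

* the **neck (tip) boundary** is found by an exhaustive two-class Otsu split
  of the clearance sequence (no histogram binning — the lists are short);
  the boundary index is the low→high class transition with the largest
  adjacent value gap;
* the **stalk (stem) boundary** is the maximum absolute first difference of
  the diameter sequence, searched only before the neck boundary (or within
  the outer 15 % of the half when the clearance has no class structure), so
  body bulges can never be read as a stalk.

Degenerate boundaries (uniform rods) are flagged, never invented; a fruit
with no detectable structure is reported all-body. Orientation is
auto-detected (the neck half has the longer thin-end run, judged against the
global Otsu split of clearances) with a `neck-left`/`neck-right` override.

## Traits

* **Cv** (curvature) has no closed-form definition in the trait list; we use
  centerline arc length over endpoint chord (≥ 1, unitless, 1 = straight),
  the most common bent-fruit index.
* **Er_f**: the ellipse filling rate is computed with the fitted ellipse's
  *semi*-axes, so an elliptical fruit scores ≈ 1; the exported `Ll`/`Ls`
  remain the full moment-equivalent axis lengths.
* **Fd** is the transverse diameter at the arc midpoint of the body segment,
  consistent with the neck/tip diameter ratios that reference the body's
  middle diameter.
* The maximum inscribed circle comes from the interior distance transform;
  the minimum enclosing circle and minimum-area rectangle from exact
  computational-geometry constructions (shapely).
* Neck/tip descriptors: `Dmax` is the widest chord within the segment; the
  angle is subtended by that chord's contour endpoints at the segment's
  distal centerline endpoint; the proportion integrates the diameter profile
  along the arc (a tube-area approximation) distal of the `Dmax` chord.
  Degenerate-segment descriptors are exported as empty cells, never zeros.
* Missing values are NaN internally and empty cells in CSV/XLSX exports.

The trait table has 51 trait columns (the full published parameter list:
34 shape, 5 surface, 5 smoothness, 7 flesh; `Gn`, `Gt`, `Gfr`, `Gtu` are
manual-grade pass-through columns), plus `Lstalk`/`Lstem` and provenance
columns (image, mode, px/cm, version, config hash, error).

## Shape decision tree

Stage 1: circle-filling rate (inscribed-circle area / contour area) strictly
greater than θ₁ = 0.75 → ball. Stage 2: fruits strictly shorter than
L = 10 cm are oval (rate > θ₂ = 0.4) or finger. Stage 3: a six-class model
maps the mask to {rod, cylinder, ellipse, inverted-egg, spindle,
heterotype}; rods and cylinders are long- when Fl strictly exceeds
T = 20 cm, otherwise short-. All equalities fall to the negative branch, as
written. `Fl` here is skeleton arc length, not the bounding-rectangle
length. Without a configured model, stage-3 fruits get an explicit
unclassified result with a reason — never a silent default.

The bundled baseline replaces a trained CNN with a z-scored nearest-centroid
classifier over nine dimensionless descriptors (Dr, Hr_f, Cr_f, Cf_f, Rl_f,
Ar, Dr_f, Cv, Er_f). It is deterministic, order-independent, serializable
to JSON, and exposed as a scikit-learn estimator; any object with
`predict_mask(mask) -> label` can be swapped in.

## Surface and flesh baselines

The three perception tasks are pluggable contracts with classical baselines:

* **Tumors**: multi-scale Laplacian-of-Gaussian blob detection on the
  excess-green channel, restricted to ROI ∩ fruit, with center-distance
  non-maximum suppression (4 px). The ROI is the square at the centerline
  arc midpoint with side equal to the local transverse diameter, clipped to
  the image; density `Td` is count per cm² of the clipped ROI (the clipped
  area is the denominator).
* **Stripes**: within-fruit Otsu on excess-green, lighter class = stripe,
  opened with a radius-1 disk; if the two classes are closer than 20 gray
  levels the fruit counts as unstriped (guards the unimodal case).
  The 5-type taxonomy is rule-based on the recovered mask: proportion
  < 0.01 → *no stripe*; ≥ 90 % of stripe mass within the tip-side 25 % of
  arc → *small stripe at tip*; ≥ 8 components → *fragmented*; median
  component elongation > 4 → *linear*; else *connected*. Components below
  12 px are ignored as segmentation specks. All thresholds are explicit
  configuration.
* **Endocarp**: within-sarcocarp Otsu on luminance, brighter class =
  endocarp, largest component kept and hole-filled; a class gap below 0.05
  flags the endocarp as missing and the flesh traits as absent. Flesh
  geometry is circular-equivalent: Re = √(Se/π), Tm = √((Ss+Se)/π) − Re with
  `Ss` the mesocarp-only area (the printed formula conflates a length with
  an area; the radius-difference reading is the only dimensionally
  consistent one). **Carpels** are counted as the dominant harmonic in
  {2,3,4,5} of the FFT of the endocarp's 1°-sampled radial signature;
  relative amplitude below 5 % of the mean radius is unclassified.

External masks (stripe, endocarp) and models (six-class shape, carpel) can
be supplied to bypass any baseline.

## Synthetic scenes

The generator renders what the pipeline assumes: one fruit plus a 3-cm card
on a dark, lightly noisy background, at a default 30 px/cm (desk-scale
images of roughly 400×700 px, rather than full-camera resolution — all
digitization effects are therefore *harder* than in real photographs).
Frontal fruits sweep a half-width profile along a circular-arc centerline of
exact arc length and arc/chord ratio; the canonical segmented profile has a
thin stalk (0.12× body radius), a thin neck (0.55×) whose C¹ taper into the
body occupies 40 % of the neck and is *centered on the labeled boundary*
(the half-rise convention of edge metrology — the ground-truth boundary is
the 50 % point of the width transition), a constant body, a mirrored tip
taper (0.50×, 45 %), and a thin stem (0.10×). Stalk/stem junctions are
near-steps softened over 0.15 cm: sharp enough to carry the diameter
gradient the partition relies on, smooth enough not to spawn spurious
medial-axis jogs. Five further silhouettes (capsule, ellipse, spindle, egg,
bumpy) populate the six model shape classes with distinct, realistic
parameter ranges.

Tumors are bright-green disks placed by rejection sampling inside the inner
80 % of the midpoint ROI with pairwise separation ≥ 3.5 blob radii (the
regime in which counting should be exact). Stripe patterns (linear bands in
relative lateral coordinates, one connected arc window, scattered
fragments, tip speckle disks) target a requested coverage; the rendered
mask is the ground truth. Cross-sections are lobed disks
r(θ) = R(1 + a sin kθ) (default a = 0.04, k = 10) with a star endocarp of
2–5 arms (default arm amplitude 0.25).

What the generator does **not** emulate: natural lighting and color
variation, shadows, specular glints, soil/blemish texture, camera blur and
lens distortion, overlapping or off-frame objects. Passing the recovery
suite therefore demonstrates the geometry and logic of the pipeline, not
robustness to photographic nuisance factors — the pluggable perception
interfaces exist precisely so learned models can replace the baselines on
real data.

## Problem sizes and accuracy observed in the test suite

The population recovery suite runs 130 seeded segmented fruits (lengths
16–28 cm, diameters 3.2–5 cm, curvature 1.0–1.25), 15 tumor scenes, 12
striped scenes and 20 cross-sections; accuracy is asserted as mean absolute
error within the target and at least 90 % of individual fruits within it
(fruit length and diameter 2 %, curvature 3 %, segment boundaries 3 % of
fruit length, stripe proportion 3 points, tumor and carpel counts exact,
mesocarp+endocarp area conservation 1 %). Decision-tree boundaries are
localized by bisection to 0.005 (filling rates) and 0.05 cm (lengths).

## Known limitations

* One fruit per frontal image; skeletons with loops are errors, not handled.
* The stalk/stem gradient rule needs a width step; fruits whose appendages
  taper smoothly into the body yield flagged-degenerate stalk/stem segments.
* Thinning is not exactly mirror/rotation symmetric, so flipped or rotated
  inputs reproduce traits only to within ~1–2 %.
* `Td` uses the ROI area as denominator; with heavily clipped ROIs near the
  image edge the density refers to the visible ROI only.
* No color constancy or white balancing; the card is used for scale only.
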