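# Methods

## Pipeline model

The pipeline treats head detection as per-pixel color classification
followed by connected-component analysis, and head counting as
per-region shape classification. Both steps are deliberately simple,
fast, and trainable from modest hand annotation.

### Color features and the segmentation tree

Each pixel is embedded in a 9-dimensional color space:
`(r, g, b, H, S, V, L*, a*, b*)`. Channels `r,g,b` are the sRGB values
normalized to [0, 1]; `H,S,V` follow the hexcone model with hue in
[0, 1) (hue 0 by convention for achromatic pixels); `L*,a*,b*` are CIE
L\*a\*b\* under the D65 reference white with the standard sRGB transfer
function, the XYZ matrix being derived from the published sRGB
chromaticities. The decision tree is scale-invariant per feature, so
the channel scalings matter only for model portability; they are fixed
and recorded so serialized models are unambiguous.

The segmentation model is a CART decision tree (Gini impurity,
axis-aligned splits), default `max_depth=12`, `min_samples_leaf=5`.
Depth 12 is enough to carve the color boxes of seven classes with
margin while limiting noise-chasing; the leaf minimum suppresses
single-pixel label noise in scribble annotations. Training samples are
drawn per class with a cap (default 2000 pixels/class) so abundant
background classes cannot dominate the split criterion. No
post-classification smoothing is applied; small spurious components
are instead removed by the region minimum-area filter (below).

### Candidate regions and morphology features

Head-class pixels (green, orange, white heads) are merged and
8-connected components with at least `min_area` pixels (default 20,
about 0.4 cm² at 0.45 cm ground sampling distance — smaller than any
real head) become candidate regions. Eleven features are computed per
region; the definitions that involve a convention are:

* **perimeter** — the number of boundary pixels (region pixels with at
  least one non-region 4-neighbor). This is a pixel-count convention,
  not a weighted contour-length estimate; the convention is stamped
  into counting-model metadata and predictions refuse features
  produced under a different convention.
* **axis lengths / eccentricity** — from the ellipse with the same
  normalized second central moments, with a +1/12 per-pixel variance
  term (the variance of a unit square), so a single pixel has finite
  axes (≈1.155 px) instead of a degenerate ellipse.
* **convex area** — the number of pixels whose centers lie inside or
  on the convex hull of the region's pixel centers (monotone-chain
  hull, inclusive boundary within 1e-7). The boundary convention is
  part of the definition; library hulls using pixel-corner offsets
  would count differently.
* **extent** — area over the region's own bounding-box area (not the
  image area).
* **roundness** — 4π·filled_area / perimeter², clipped to [0, 1]
  (compact regions with short boundary exceed 1 under the pixel-count
  perimeter).

### Count classifier

A support vector machine with quadratic kernel `(γ⟨x,x'⟩ + 1)²`,
`γ = 1/(d·Var)`, box constraint C = 1, one-vs-one multi-class
reduction, on z-scored features. The scaler lives inside the fitted
pipeline, so cross-validation refits it on each training fold and no
information leaks from validation folds. True counts above a cap
(default 5) are pooled into the cap class; regions predicted 0 are
retained in outputs (flagged as false detections) and contribute
nothing to image totals. Assessment uses the six-set protocol:
a seeded uniform partition of image ids into six sets differing in
size by at most one; five sets train with stratified fivefold CV, the
sixth estimates held-out performance.

### Evaluation

Detection: TP and FN are counted in labeled points, FP in detected
regions; this is the only reading under which TP + FN equals the total
number of labeled heads while spurious regions are each penalized
once. Contingencies are pooled over images before ratios
(micro-averaging), so the result is invariant to how images are
batched. Undefined ratios (no detections, no labels) are reported as
NaN with a warning rather than silently zeroed. Counting: R² is the
squared Pearson correlation of per-image (manual, predicted) totals;
because R² alone cannot distinguish a 1:1 relation from a
proportional bias, the OLS slope and intercept are reported alongside.
Detection is evaluated independently of counting: a region predicted 0
by the counter still counts as a detection if it contains a labeled
point.

### Plot extraction

Field layout is a grid of two-row plots (default 5 m plot length,
0.76 m row spacing, 1 m inter-plot gap); plot rectangles are
`row_spacing + margin` wide (margin default 0.76 m, split evenly) —
the cropped plot width is a free choice and is config-exposed. The
world→pixel homography of each frame is a supplied input (produced
upstream by photogrammetry), not computed here. Among all frames
containing a plot, the instance whose quadrilateral centroid is
closest to the geometric image center `((H−1)/2, (W−1)/2)` is chosen
(central pixels carry the least lens and perspective distortion), with
ties broken by smallest image id. Rectification applies the full
perspective transform between the quad and an upright rectangle whose
side lengths are the mean opposite-edge lengths plus one pixel
(corner-to-corner spans), long axis vertical, bilinear resampling;
for near-nadir imagery this coincides closely with a crop-and-rotate.

## Synthetic field generator

The generator exists so that every stage is trainable and testable
without real imagery. It emulates, controllably:

* **background clutter** — an organic patchwork of soil, shadow, dead
  leaves and green leaves (smoothed Gaussian fields, argmax with
  log-weight offsets; default weights 0.35/0.20/0.15/0.30);
* **head diversity** — filled ellipses (semi-major 4–7.5 px, aspect
  0.5–0.85, occasionally 1–2 extra overlapping lobes for the expanded
  tiller/overlap silhouettes) in four color morphs (white, green,
  orange, brown; probabilities 0.25/0.25/0.30/0.20). Brown heads carry
  the orange-head class code, the nearest of the three head classes;
* **merging** — a fraction of heads (default 0.15) is placed within
  about one minor-axis of a neighbor, producing genuine multi-head
  regions for the counter to learn;
* **occlusion** — a fraction of heads (default 0.10) gets a
  leaf-colored blob over its periphery (never the annotated center);
* **illumination** — per-image multiplicative gain in [0.6, 1.2] plus
  a ±6% per-channel color cast, emulating sunny/cloudy variation;
* **sensor noise** — additive Gaussian noise, default SD 1.5 counts.

Pixel colors are drawn iid uniform over per-class HSV boxes. The boxes
were designed jointly with the noise level: hue gaps of ≥ 0.05 between
chromatic classes are several times the hue noise of the dullest class
at the dark end of the gain range; classes whose hues overlap (orange
heads vs soil) are separated by ≥ 0.10 in saturation; white heads are
the only low-saturation class and shadow the only near-black class.
Because colors are iid within a class, every image exhibits the full
within-class diversity, and a segmentation tree trained on a single
image generalizes to any other — under fixed illumination. Under the
default gain range the value/lightness features are *not* separated
across images, so cross-illumination generalization requires training
images spanning the gain range (the reference protocol uses 17).

Per-image head totals default to a negative binomial with mean 100 and
size 10 (CV ≈ 0.33): between-plot head counts in breeding trials vary
widely with genotype, and counting R² is only meaningful against that
between-image variance, not just Poisson noise.

Ground truth (centers, class map, per-head ellipses, per-cluster
counts) is recorded before noise. Everything is deterministic per
seed; dataset files are byte-identical across reruns.

**What the generator does not emulate:** photorealistic texture,
within-class spatial color correlation (real soil varies smoothly;
generated soil is iid speckle), 3D canopy geometry, perspective and
motion blur, radiometric camera response, or the continuous color
gradations between heading stages. Passing the end-to-end thresholds
therefore demonstrates that the pipeline machinery is correct and
well-calibrated under controlled difficulty — not that the same
accuracy would be reached on real fields, where class colors overlap
far more.

### Plot-clipping degradation

`degrade_plot_clipping` emulates imperfect plot segmentation: for a
chosen fraction of heads, a straight boundary line is drawn through
the head near its centroid and the far side is repainted as soil,
while the annotated center is always retained. Detected regions shrink
or fall below the minimum area and vanish; manual totals are
unchanged; per-image counting error grows and R² drops. The reference
experiment clips half the heads of the held-out images — head cut-out
at plot boundaries is the common failure mode for two-row plots — and
measures the R² drop.

## Reference experiment and problem sizes

The reference experiment (`pipeline.run_synthetic_experiment`,
re-computed by `scripts/acceptance.py`) uses 17 scribble-annotated
training images and 52 labeled test images of 448 × 336 px with ~100
heads each — a desk-scale rendition of a field protocol whose frames
are ~1731 × 1154 px with ~300 heads each; head density and head size
in pixels are preserved by scaling both image and head dimensions.
All randomness derives from a single master seed.

## Numerical choices and degenerate inputs

* Center cropping uses floor-division placement: odd margins drop the
  extra row at the bottom, the extra column at the right.
* 16-bit images are reduced to 8 bit by integer right-shift (exact,
  monotone); this matches the common viewer convention.
* Tree leaf ties resolve to the lowest class code (sklearn argmax);
  SVM one-vs-one vote ties resolve to the smallest count class.
* Degenerate training tables (single class, empty) raise typed errors
  rather than fitting trivial models.
* Single-pixel regions are fully defined (see +1/12 moment term;
  roundness clipped at 1).
* Collinear pixel sets get convex area equal to the number of pixel
  centers on the segment.
* An all-background image evaluates to NaN precision with a warning,
  never a silent zero.

## Known limitations

* The counting SVM sees only region shape, not appearance inside the
  region; heavily merged clusters (>3 heads) are pooled at the count
  cap and systematically under-counted.
* Containment-based detection matching cannot credit a detection that
  misses the clicked center pixel even narrowly; there is no
  distance-tolerance matching by design.
* The plot extractor assumes supplied homographies are accurate;
  errors in upstream photogrammetry translate directly into clipped
  plots (see the degradation experiment).
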