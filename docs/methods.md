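# Methods

This note documents the models, parameter choices and limitations behind
`dermatomics`, in the spirit of a methods supplement: what each stage
assumes, which knobs matter, and what the synthetic validation does and
does not demonstrate.

## Tissue detection and slice extraction

Whole-slide images are processed at a working resolution of ~16× below
full resolution (`working_factor`, default 16). If the pyramid has no such
level, the closest level with a *smaller* factor is downsampled with
order-1 interpolation (order 0 for masks), so resampling never upsamples.
Tissue is the logical AND of two Otsu masks: one on the HSV hue channel and
one on the per-pixel RGB minimum. The hue threshold has no intrinsic
polarity, so the side overlapping the non-white pixels more is taken as
tissue and recorded in the mask provenance. The mask is dilated (3×3, 2
iterations), hole-filled, and components under 50,000 working-resolution
pixels are dropped — a scale-dependent cutoff that at 16× corresponds to
roughly 13 mm² of tissue at typical scanner resolutions, i.e. it removes
debris while keeping any plausible biopsy slice. Coordinates are row-major,
0-based, half-open throughout.

## Epidermis segmentation

The color filter excludes a pixel when **any** of these hold (8-bit LAB /
HSV encodings: L scaled to 0–255, A/B offset by +128, H in 0–179 by
default, S/V in 0–255):

| rule | intent |
| --- | --- |
| L < 50 | near-black artifacts |
| L > 140 (abdomen) / 160 (graft) / 200 (buttock) | bright background and pale dermis; site-dependent because abdominal sections stain lighter |
| L < 100 and A < 150 | dark non-pink material |
| H < 110 | hues outside the purple–pink H&E range |
| S < 40 | unsaturated (gray/white) pixels |
| R = G = B | exactly gray pixels |

The hue encoding is selectable (`hue_range_255`) because a 0–255 hue
convention also makes the H < 110 rule meaningful; 0–179 is the default.
Smoothing before filtering is per-channel Gaussian, sigma 2.

Stain separation follows the Macenko construction: OD = −log((I+1)/255),
pixels with all channels below a transparency floor of 0.15 discarded, the
principal 2-D OD plane computed from the **uncentered** second-moment
matrix (stain mixtures are non-negative combinations of two vectors through
the origin, so centering would bias the plane), and the stain vectors taken
at the 1st/99th percentiles of the projection angle. The hematoxylin-like
vector is the one with the larger red-channel OD (hematoxylin looks blue
because it absorbs red). Images whose OD cloud is effectively rank-1 raise
a degeneracy error; the pipeline falls back to canonical published H&E
vectors ([0.65, 0.70, 0.29] / [0.07, 0.99, 0.11], unit-normalized) when
configured to.

The nuclear channel is the OD projection on the hematoxylin vector with
values below 0.2 zeroed, Gaussian-filtered (sigma 2, a choice of ours;
larger sigmas blur adjacent structures together) and Otsu-thresholded.
Refinement applies, in order: 3×3 opening, removal of objects under 64 px,
3×3 opening ×4 iterations, a 10×10 box-mean filter, and a strict local-mean
> 0.5 threshold. The epidermis is precisely the compartment where nuclei
are dense enough to survive this majority vote.

**Resolution floor.** The two opening passes erode 5 px from each side
before regrowing, so structures narrower than ~11 px cannot survive
refinement. This matters for the synthetic validation below: rete ridges at
the 10 px lower edge of the tested width range sit *at* this floor and
occasionally pinch off, while ridges ≥ 20 px wide are always recovered. On
real slides processed at level-1 resolution, ridges are hundreds of pixels
wide and far from the floor.

## Skeleton graph and rete-ridge validation

Components are thinned (`skimage.morphology.thin`); skeleton pixels with
more than 2 neighbors (3×3, 8-connectivity) are junctions, with exactly 1
are endpoints. Adjacent junction pixels merge into a single node at their
centroid — thinning routinely emits 2–3 px junction clusters, and merging
prevents spurious zero-length branches — while endpoints remain individual
pixels. Branch runs adjacent to exactly two nodes become edges weighted by
pixel count; parallel edges collapse to the lighter one. The MST is Kruskal
over edges sorted by (weight, branch id) — a deterministic tie rule — and
the midline is the MST's weighted diameter via the standard double sweep
(farthest vertex from the lowest id, then farthest from that; ties go to
the lower vertex id). Components with midlines under 500 px are rejected
with a logged reason; rejection is per component, so one slice can
contribute both accepted and rejected components.

Ridge validation is a directional filter: for each non-midline MST edge,
the *base* is the node nearer the midline and the *tip* the other end; the
ridge is valid iff the tip is **not strictly closer** to the tissue
boundary than the base. Because the boundary index only contains mask
pixels 8-adjacent to background *inside* the raster (image edges do not
count), the tissue boundary of a full-width section is dominated by the
outer surface, and the rule discards spurs pointing at the surface while
keeping dermis-pointing ridges. Both boundary scopes (whole-tissue and
per-component epidermal) are available; validation defaults to the tissue
boundary, thickness measurements always use the epidermal boundary so that
the ×2 rule returns the band thickness.

## Morphometrics

Thickness at a midline pixel is twice the Euclidean distance to the nearest
epidermal-boundary pixel (k-d tree). Ridge length is branch length + base
centroid to nearest midline pixel + tip centroid to nearest boundary pixel;
base/end thickness apply the ×2 rule at the junction and tip; the dilation
factor is end/base thickness. Aggregates use linear interpolation between
order statistics for percentiles; IQR = p75 − p25. Ridge-free slices emit
missing ridge aggregates (empty CSV cells, not zeros, which would bias
models) with an honest density of 0. All geometry is in pixels; an optional
pixels-per-mm factor converts reported lengths.

Per-feature age trends are ordinary least squares with a Wald t-test on the
slope and a 95% confidence band for the mean response (statsmodels).
Constant features and zero-residual-df fits are flagged as degenerate
rather than raised.

## Age model

Defaults mirror a standard small-cohort protocol: 500 trees, fixed seed 42,
5-fold shuffled cross-validation, per-fold MAE and R² averaged across
folds, then a refit on all rows. Feature importance is mean decrease in
impurity; the reduced model keeps the top-8 predictors (ties broken by
column order) and expands them with degree-2 polynomial features without a
bias column — k linear + k squared + k(k−1)/2 products, 44 columns for
k = 8, with deterministic names (`f`, `f^2`, `a*b` in input order). No
centering or scaling is applied before expansion since forests are
scale-invariant. Cross-validation operates on the rows it is given; the
expected row unit is one row per sample (slice-aggregated means), and
slice-level tables are accepted as-is.

Xenograft scoring averages slice predictions within each (donor, condition)
pair, pivots conditions wide, and reports Pre−Young, Pre−Old and
Young−Old differences; a positive Pre−Young delta means predicted age
dropped after grafting into a young host. Donors missing a condition yield
missing deltas.

## Synthetic phantoms: what they emulate, and what they don't

The H&E phantom is an epidermal band (default 24 px thick) with
trapezoidal, round-tipped ridges (default 6 ridges, 80 px long, 24 px base,
16 px end width) over a pale dermis, rendered by composing hematoxylin and
eosin OD fields (`I = 255·exp(−OD)`) with Gaussian sensor noise (sigma 3).
Nuclei are Poisson-scattered disks (radius 3) covering ~65% of the
epidermis and ~3% of the dermis — the density contrast the nuclear-density
segmentation relies on. The surface is flat by default (undulation
amplitude 0); a sinusoidal undulation is available as a robustness knob but
keeps the default geometry exactly consistent with its recorded truth. The
flanking band on each side of the ridge field (edge margin, default 200 px)
must exceed the ridge length plus band thickness: the midline is a graph
*diameter*, so if ridges out-measure the flanking band the longest path
would descend the outermost ridges instead of spanning the band — the
phantom validator rejects such geometries.

The recovery study grid spans ridge counts {2, 6, 12}, lengths {30, 70,
120} px and base widths {10, 20, 30, 40} px (end width 70% of base). On the
generating masks, valid-ridge counts match the generated counts exactly in
every well-separated cell (spacing ≥ 3× base width). End-to-end from the
rendered images, generated-vs-measured correlations for median ridge
length, base thickness and density exceed r = 0.9, and exact counts hold in
~94% of cells — the exceptions are the 10 px-wide cells at the
morphological resolution floor described above, plus an occasional
segmentation spur that the validation rule cannot distinguish from a true
ridge (the rule set deliberately contains no minimum ridge length).

Feature-table simulation draws ages uniformly on 20–80 years and gives six
informative features linear trends with signs matching an age-stratified
buttock cohort (ridge length, base thickness, end-thickness p75, ITGB4 and
Ki67 declining; dilation factor rising; ridge density deliberately
uninformative, as buttock ridge density is age-stable). Each informative
feature gets Gaussian noise of |slope| × 15 years, i.e. each individually
explains ~57% of age variance — a realistic mid-strength biomarker — and
the table is padded with pure-noise columns to 48 predictors. Xenograft
tables draw post-graft slices at an effective age `pre_age − shift`, so an
ideal model recovers the planted shift; Random Forest regression-to-the-
mean attenuates recovered shifts by roughly 10–20%.

Phantoms are pure functions of (spec, seed). They do not emulate: stain
variation across slides, dermal collagen texture (the phantom dermis is
spectrally flat, which is why working-resolution tissue detection on a
phantom finds mainly the nuclear band — phantoms enter the pipeline at the
slice level with their own tissue mask), folds/tears/pen marks, or
non-linear biomarker–age relationships. Passing the synthetic suite
demonstrates the geometry and statistics of the method, not robustness to
real-world staining artifacts.

## Numerical conventions

- 8-connectivity everywhere (component labeling, skeleton neighborhoods,
  structuring elements 3×3 square).
- Strict inequalities at decision points: local mean > 0.5 for epidermis;
  midline < 500 px rejects; tip strictly closer than base discards a ridge
  (a tie keeps it).
- Percentiles: linear interpolation; std: ddof = 1 (0 for single values).
- Deterministic tie-breaks: MST by (weight, branch id); double-sweep by
  lowest vertex id; importance ties by column order.
- All randomness flows through a single integer seed per generator call.

## Known limitations

- No stain normalization across slides; the stain model is per-slice.
- The midline-as-diameter construction requires the epidermal band to be
  the dominant path; extreme geometries (ridges longer than the band)
  mislead it.
- Ridge validation has no length floor, so segmentation spurs can count as
  ridges; QC overlays make such cases visible for review.
- CD31 region summaries average per-region statistics by default; pooling
  objects before computing statistics is available behind a flag and gives
  different percentile estimates when regions differ in object count.
- Pixel units only; physical calibration must be supplied externally.
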