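# dermatomics

Automated morphometric analysis of human skin histology, built around the
question *"how old does this skin look?"*. The package quantifies the
structural hallmarks of intrinsic epidermal aging — flattening of rete
ridges at the dermal–epidermal junction, loss of basal adhesion (ITGB4)
and proliferation (Ki67), and compaction of papillary microvessels (CD31) —
and combines them into a Random Forest model that predicts skin age from a
histological section. It is aimed at dermatology and aging researchers who
want reproducible, whole-slide-scale measurements instead of manual
field-of-view scoring.

## What it computes

**Epidermis segmentation.** H&E slices are filtered with empirical LAB/HSV
color thresholds, deconvolved into optical-density stain channels with a
PCA-based (Macenko-style) two-stain model

```
OD = -log((I + 1) / I0),     OD = c_H * s_H + c_E * s_E
```

and the hematoxylin concentration `c_H` is turned into a nuclear density
mask; morphological refinement (opening, small-object removal, 4-iteration
opening, 10×10 box mean > 0.5) yields the epidermis mask.

**Skeleton-graph rete-ridge morphometry.** Each epidermal component is
thinned to a skeleton; junction/endpoint pixels become graph vertices and
branch pixel runs become edges weighted by length. On the minimum spanning
tree, the weighted diameter (two-pass Dijkstra sweep) is the epidermal
*midline*; components with midlines under 500 px are rejected. Every other
MST edge is a provisional rete ridge, kept only if its distal tip is not
closer to the outer tissue boundary than its base (a directional filter
that keeps dermis-pointing ridges). Per-slice features include midline
length, thickness profile (2 × nearest-boundary distance), ridge length,
base/end thickness, dilation factor (end/base), count and density, each
with distributional aggregates (mean, std, median, IQR, p5/p25/p75/p95,
range).

**IF quantification.** ITGB4 mean intensity in an annotated basal-epidermis
ROI; Ki67-positive cells per epidermal length and per rete ridge; CD31
object morphometrics (area, eccentricity, solidity, perimeter, axes,
aspect ratio, intensities) and area fraction in the papillary dermis,
averaged across five annotated regions per sample.

**Age model.** A 500-tree Random Forest with 5-fold shuffled CV (seed 42)
over all numeric predictors; the top-8 features by impurity importance are
expanded with degree-2 polynomial features (no bias: 8 linear + 8 squared +
28 pairwise = 44 predictors) and refit. Applied to xenograft cohorts, slice
predictions are averaged per (donor, condition) and differenced into
rejuvenation deltas (Pre−Young, Pre−Old, Young−Old).

**Synthetic phantoms.** Because clinical slides cannot ship with the code,
`dermatomics.synthetic` renders H&E-like slices (epidermal band +
trapezoidal rete ridges + nuclear dots, composed in OD space), IF phantoms
and age-linear feature tables, all with exact ground truth — every stage of
the package is tested against generated geometry.

## Worked example

```bash
python examples/01_he_phantom_pipeline.py
```

```
generated ridges        : 6
measured valid ridges   : 6
midline length          : 1385 px
median ridge length     : 86.5 px (geometry: protrusion 80 + half band 12)
median band thickness   : 21.5 px (generated 24)
ridge density           : 0.00433 ridges/px
```

The pipeline recovers all six generated ridges; the measured ridge length
is the protrusion depth plus half the band thickness because ridges are
measured from the epidermal midline to their distal tip, and the slight
thickness underestimate reflects the morphological refinement eroding the
band margin. `examples/02_if_quantification.py` and
`examples/03_age_model.py` cover the IF markers and the age model (on the
default synthetic cohort the reduced model reaches CV MAE ≈ 5 years,
R² ≈ 0.84, and recovers a planted 15-year xenograft rejuvenation shift to
within a few years).

There is also a thin CLI for shell use:

```bash
dermatomics simulate he --seed 1 --out-dir phantoms
dermatomics run phantoms/he_phantom.png --factor 1 --min-component 20000 --out-dir out
dermatomics model train --features features.csv
```

## Layout

| Module | Role |
| --- | --- |
| `dermatomics.wsi` | pyramid reading, tissue detection, slice extraction |
| `dermatomics.segmentation` | color filter, stain model, epidermis mask |
| `dermatomics.skeleton` | skeleton graph, midline, ridge validation |
| `dermatomics.morphometrics` | features, aggregates, age-trend OLS |
| `dermatomics.ifquant` | ITGB4 / Ki67 / CD31 quantification |
| `dermatomics.model` | Random Forest age models, xenograft deltas |
| `dermatomics.synthetic` | ground-truth phantom generators |
| `dermatomics.pipeline`, `dermatomics.cli` | orchestration and CLI |

See `docs/methods.md` for the underlying model assumptions, parameter
defaults and known limitations.
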