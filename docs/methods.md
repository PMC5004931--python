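# Methods

`renomorph` quantifies chronic renal tubulointerstitial injury on brightfield
whole-slide-image region exports, per anatomic compartment, and relates the
resulting per-case metrics across a cohort. This note records the model
choices, parameters, numerical conventions, and the design of the synthetic
verification substrate, including what it deliberately does not emulate.

## Positive-pixel classification in HSI space

Chromogenic dyes are detected in a hue/saturation/intensity representation:

* **intensity** `I = (R + G + B) / 3` on [0, 255];
* **saturation** `S = 1 − 3·min(R,G,B)/(R+G+B)`, zero exactly when
  `R = G = B` (achromatic — hue undefined);
* **hue** from the polar (Gonzalez–Woods) formula, expressed as a fraction of
  the color circle in [0, 1) with pure red at 0. On this circle aniline blue
  sits near 0.60, PAS magenta near 0.86, Biebrich scarlet near 0.96 and DAB
  brown near 0.05–0.1.

A pixel inside the analysis region is classified, in order:

1. **background** (glass, open lumen) if `I > tissue_intensity_max`
   (default 240);
2. **positive** if its circular hue distance to the profile's
   `hue_center` is ≤ `hue_width` (boundary inclusive), `S ≥ saturation_min`
   (default 0.04) and `I ≤ intensity_weak_upper`;
3. **negative tissue** otherwise.

Positive pixels are binned by intensity: strong `I < 100`, medium
`100 ≤ I < 175`, weak `175 ≤ I ≤ 220`. The bin edges and the saturation
floor are conventional positive-pixel-count defaults; the sources this
package follows tune hue only, so all thresholds stay exposed in
configuration (`StainProfile`, YAML-overridable).

Percent positivity is `100 · positive / (positive + negative)`: glass
background is excluded from the denominator, and a region with no tissue
pixels reports NaN rather than 0.

### Shipped stain profiles

| profile | hue center | hue width | detects |
|---|---|---|---|
| `trichrome_blue` | 0.60 | 0.50 | collagen/fibrosis (aniline blue) |
| `trichrome_red` | 0.96 | 0.20 | epithelial cytoplasm (Biebrich scarlet) |
| `pas` | 0.86 | 0.05 | basement membranes (PAS magenta) |
| `collagen_iii` / `cytokeratin` / `cd34` | 0.10 | 0.50 | DAB chromogen |

The maximum circular hue distance is 0.5, so a width of 0.5 accepts *every*
hue: for those profiles discrimination comes entirely from the saturation
floor and intensity window. One consequence worth stating plainly: on a
two-dye trichrome image the blue profile also counts saturated red pixels.
The synthetic ground truth therefore defines the expected positivity of an
(image, profile) pair from which palette colors satisfy the full predicate,
not from a one-dye-per-profile assumption.

`calibrate_hue` supports re-deriving a profile center from annotated dye
pixels: it takes the *circular* mean of hues (angles averaged as unit
vectors), so dyes straddling the red wrap-around average correctly.

## Compartments and the stripe ruler

Compartment delineation (cortex, outer stripe, inner stripe, other medulla,
excluded regions such as glomeruli) is manual in the underlying workflow, so
the package ingests annotations — integer label PNGs or named polygons —
and never infers anatomy. Polygons are rasterized with pixel-center
semantics and no anti-aliasing: a pixel belongs to a polygon iff its center
lies inside, so an axis-aligned `w × h` rectangle covers exactly `w·h`
pixels. Overlapping polygons of different compartments are an error
(reported with pixel coordinates); the union cortex ∪ medulla minus
exclusions defines the "all tissue" selector used for whole-biopsy metrics.

Stripe width is measured between two boundary polylines: sample points at a
regular arc-length interval (default 20 px) along the first boundary, cast a
ray along the local normal in both directions, record the distance to the
nearest intersection with the second boundary, and report the **median** of
the sampled distances in millimetres. The median was chosen over a single
ruler placement for robustness to annotation jitter; the sample spread
(IQR) is reported alongside. If the boundaries intersect, or more than half
the normals never reach the other boundary, the measurement is refused
rather than extrapolated.

## Per-case metric panel

For each case and each reporting compartment (All / Ctx / Med) the panel
holds: trichrome blue positivity (Tri), trichrome red positivity (RedTri,
an epithelial-cell-mass proxy), PAS positivity (basement-membrane mass),
the derived fibrosis statistic **T-P = Tri% − PAS%** (subtracting
basement-membrane — and often proteinaceous-cast — signal from the
trichrome estimate; negative values are preserved, no cast detector is
applied), collagen III and averaged cytokeratin DAB positivity, microvessel
density and mean vessel area, plus outer/inner stripe widths, optional
visual-assessment scores and creatinine. T-P is computed per compartment
from that compartment's two percentages, not by pixel-set subtraction.
Missing stains propagate as NaN columns, never zeros, and anything derived
from a missing input (T-P without PAS) is NaN too.

## Microvessel detection

CD34 immunohistochemistry rings vessels with DAB while lumens stay clear.
The reconstruction pipeline is: chromogen-positive mask → morphological
closing (disk radius 2 px, sealing gaps in the endothelial ring) → hole
filling (attaching the lumen to its vessel) → 8-connected labelling → area
filter (defaults 10–10,000 µm², whole-profile area including lumen) →
per-component measurement. Components touching an annotated exclusion
(glomerulus, dilated by one pixel) are dropped, mirroring manual glomerular
exclusion. MVD is vessels per µm² of the compartment's analyzable tissue
area (exclusions removed); MVA is the mean whole-profile area, NaN when no
vessel was found.

Wall thickness is estimated as twice the mean Euclidean-distance-transform
value over a component's chromogen pixels. This tracks thin endothelial
walls well (within ~7% at 2 px walls in the verification fields) but is
biased low for thick walls — in the continuum limit it converges to half
the true thickness — so it should be read as a capillary-scale statistic,
not a general wall gauge. Perimeter uses the standard region-property
boundary estimator, which is why the analytic-annulus checks carry a 5–10%
tolerance rather than demanding exactness.

## Cohort statistics

The cohort layer is a model/results pair. `CohortCorrelation` wraps a
per-case metric table; `fit()` produces pairwise-complete Pearson
correlations with two-sided t-test P values and per-pair N. Pairwise
deletion was chosen because per-metric Ns in this kind of panel vary widely
(different stains are available for different cases) and listwise deletion
would discard most of the cohort. Pairs with fewer than `min_n = 3`
complete observations, or involving a constant column, are reported as
undefined. Raw P values are reported by default; a Benjamini–Hochberg
column is available but off by default, matching the uncorrected reporting
convention of the analysis this package follows.

Correlation strength is banded on |r| — negligible < 0.30 ≤ low < 0.50 ≤
moderate < 0.70 ≤ high < 0.90 ≤ very high — with boundaries assigned to the
stronger band (the conventional band endpoints overlap, forcing a tie
rule); the sign is reported separately. Variable clustering for the
correlation color map uses average-linkage agglomeration on distance
`d = 1 − r` (not `1 − |r|`: anti-correlated measures, e.g. epithelial mass
versus fibrosis, should appear distant). The cortex/medulla ranking table
pairs every `Ctx-X` column with its `Med-X` partner (including `Vis-Ctx-X`
visual columns) and sorts by r with band labels.

## Synthetic verification substrate

**Tissue renderer.** A case is a horizontal band layout — cortex, outer
stripe, inner stripe inside a glass margin, glomerular exclusion disks in
the cortex — with one RGB image per stain (trichrome carrying both blue and
red dyes; PAS; collagen III; one or more cytokeratins; CD34 with vessel
annuli). Structures (tubule rings with open lumens, interstitial patches)
are drawn without anti-aliasing, then per-compartment class counts are
*repaired* to `round(fraction × tissue_px)` exactly by flipping randomly
chosen pixels between dye classes and neutral tissue. Exactness is the
contract: the acceptance checks demand equality, not tolerances. The
palette encodes each dye as an RGB direction whose polar hue matches the
corresponding profile center to < 3×10⁻⁵; weak/medium/strong intensity
variants are built by scaling the direction and adding gray, operations
under which that hue is exactly invariant. Vessels are exact annuli
(default outer radius 8–14 px, wall 2 px ≈ 0.5 µm at the default
0.25 µm/px), placed non-touching with clearance exceeding the closing
diameter so detection can never merge them.

What the renderer does **not** emulate: anti-aliased edges, stain
variability and batch effects, out-of-focus regions, hematoxylin
counterstain, proteinaceous casts, CD34 interstitial staining, and
anatomically realistic stripe widths (bands are tens of pixels, not
millimetres — the ruler geometry is verified separately at realistic
scales). Passing the exact-recovery tests therefore demonstrates
correctness of the counting and geometry machinery, not robustness to
histology noise; an optional Gaussian RGB jitter layer exists for
robustness checks and intentionally breaks the exactness contract.

**Cohort simulator.** Per-case metric vectors are multivariate normal with
configurable means, SDs and correlation matrix; defaults reproduce the
published cohort's descriptive statistics and its cortex/medulla
correlation ranking (cross-metric correlations not in that ranking default
to zero, which keeps the default matrix positive semi-definite by
construction; any user matrix is eigenvalue-checked). Draws are clipped to
metric domains ([0, 100] for percentages, [−100, 100] for T-P, non-negative
for MVD/MVA/widths), then per-metric missingness is applied. Clipping
biases moments and attenuates correlations for metrics whose mean sits
within ~2 SD of a boundary (MVD is the worst case at ~1.4 SD); quantitative
recovery checks therefore use metrics with interior means, and the recovery
tolerance (±0.02 at n = 10,000) should not be expected to hold for
boundary-hugging metrics.

## Numerical conventions and edge cases

* Rasters are row-major, 0-based, pixel-center aligned; masks must match
  image shape exactly (mismatch is an error naming both shapes).
* Undefined quantities (empty region, all-background, no vessels, too few
  complete pairs) are NaN, never 0, and NaN propagates through derived
  metrics.
* Hue-window membership is boundary-inclusive; band boundaries go to the
  stronger band; positive-intensity bin edges are half-open as listed above.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning, so every render and simulation is
  bit-reproducible; CLI outputs carry provenance sidecars (config hash,
  seed, version).
* Verification problem sizes: stain-recovery fields are 288×320 px panels
  (20 specs spanning 0–60% target fractions), vessel fields up to 512×560 px
  with 3–30 annuli, cohort recovery at n = 10,000 cases — sizes chosen so
  the full suite runs in well under a minute per module on one CPU.

## Known limitations

* No color deconvolution or stain normalization: overlapping hue windows
  (full-circle widths especially) conflate co-saturated dyes by design.
* The microvessel pipeline is a reconstruction of a proprietary algorithm's
  published outputs, with all parameters exposed; it does not distinguish
  capillaries from arterioles/venules and inherits CD34's interstitial
  staining caveat.
* The wall-thickness estimator is biased low for walls thicker than ~3 px.
* Visual scores and creatinine are ingested as data columns; the package
  does not model them.
* Plain TIFF/PNG region exports only; pyramidal whole-slide containers are
  out of scope.
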