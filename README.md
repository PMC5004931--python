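# renomorph

Whole-slide image morphometry of chronic renal tubulointerstitial injury,
per anatomic compartment, with a cohort-level correlation layer.

Renal biopsies are traditionally scored in the cortex, but the medulla makes
up much of the parenchyma and scars alongside it. `renomorph` reimplements,
as a tested pipeline, the image-analysis workflow used to quantify that
relationship on scanned brightfield slides:

* **Positive-pixel stain quantification** in hue/saturation/intensity
  space. A pixel is positive for a stain when its circular hue distance to
  the stain's hue center is within the profile's hue width, with saturation
  and intensity gates; positives are binned weak/medium/strong by intensity.
  Shipped profiles: trichrome blue (fibrosis, hue 0.60), trichrome red
  (epithelium / Biebrich scarlet, 0.96 ± 0.20), PAS (basement membranes,
  0.86 ± 0.05) and the DAB chromogen (0.10 ± 0.50) for collagen III,
  cytokeratin and CD34 immunohistochemistry.
* **The T-P fibrosis statistic**: trichrome-positive % minus PAS-positive %,
  which subtracts basement-membrane (and often proteinaceous-cast) signal
  from the fibrosis estimate; negative values are preserved.
* **Compartment stratification** — cortex, medullary outer stripe (OS) and
  inner stripe (IS), glomerular exclusions — from manual annotations (label
  PNG or polygons), plus a digital-ruler stripe-width measurement between
  annotated boundaries (median of perpendicular samples, in mm).
* **Microvessel density on CD34**: chromogen rings are closed, hole-filled,
  labelled and measured into per-vessel area/perimeter/wall-thickness and
  region-level MVD (vessels/µm²) and MVA (µm²), honoring glomerular
  exclusion.
* **Cohort statistics**, statsmodels-style: a `CohortCorrelation` model over
  the per-case metric table whose `fit()` returns pairwise-complete Pearson
  r / P / N matrices, strength bands (negligible < 0.30 ≤ low < 0.50 ≤
  moderate < 0.70 ≤ high < 0.90 ≤ very high, boundaries to the upper band),
  average-linkage variable clustering on `1 − r` for the correlation color
  map, and the cortex-vs-medulla ranking table.
* **A synthetic-data module** that renders stained-tissue panels with
  pixel-exact ground truth (no anti-aliasing; class counts repaired to
  exact targets) and simulates cohorts with a specified correlation
  structure — the verification substrate for everything above, since the
  original biopsy cohort is not publicly deposited.

## Worked example

Render a synthetic fibrosis phantom whose cortical blue fraction is 31.7%
and medullary blue fraction 47.0%, quantify it, and simulate a 67-case
cohort:

```python
from renomorph import (default_profiles, quantify_stain, tp_fibrosis,
                       detect_vessels, microvessel_stats, CohortCorrelation)
from renomorph.synthetic import (TissueSpec, render_tissue,
                                 default_cohort_spec, simulate_cohort)

profiles = default_profiles()
fr = {"cortex":       {"tri_blue": 0.317, "pas_pink": 0.161},
      "outer_stripe": {"tri_blue": 0.470, "pas_pink": 0.163},
      "inner_stripe": {"tri_blue": 0.470, "pas_pink": 0.163}}
panel = render_tissue(TissueSpec(seed=42, fractions=fr))

for comp in ("cortex", "medulla"):
    tri = quantify_stain(panel.images["trichrome"],
                         profiles["trichrome_blue"], panel.mask, comp)
    pas = quantify_stain(panel.images["pas"], profiles["pas"], panel.mask, comp)
    print(f"{comp:8s}  Tri% = {tri:5.1f}   PAS% = {pas:5.1f}   "
          f"T-P% = {tp_fibrosis(tri, pas):5.1f}")

vessels = detect_vessels(panel.images["cd34"], profiles["cd34"], panel.mask)
stats = microvessel_stats(vessels, panel.mask, "all")
print(f"vessels = {stats.n_vessels}   MVD = {stats.mvd:.2e} vessels/um^2   "
      f"MVA = {stats.mva:.1f} um^2")

table, truth = simulate_cohort(default_cohort_spec(n_cases=67, seed=42))
results = CohortCorrelation(table).fit()
print(results.rank_compartment_correlations()[["measure", "r", "band"]]
      .head(5).to_string(index=False))
```

prints

```
cortex    Tri% =  31.7   PAS% =  16.1   T-P% =  15.6
medulla   Tri% =  47.0   PAS% =  16.3   T-P% =  30.7
vessels = 10   MVD = 2.03e-03 vessels/um^2   MVA = 24.1 um^2
   measure        r band
       PAS 0.868374 high
     CKAvg 0.827325 high
Vis-PAS-TA 0.824380 high
       T-P 0.795813 high
       MVD 0.775840 high
```

The stain percentages equal the generator's targets *exactly* — the
renderer's no-anti-aliasing contract — and T-P is exactly their difference.
The ten rendered CD34 annuli are all detected; MVD is count over analyzable
tissue area (glomeruli excluded) and MVA the mean whole-profile vessel
area. At n = 67 the recovered cortex/medulla correlations scatter around
their generating values (PAS 0.87, CKAvg 0.85, …) with the sampling noise a
real cohort of that size would show.

The same operations are available from the shell via the `renomorph` CLI
(`render`, `simulate`, `quantify`, `vessels`, `stripes`, `cohort-stats`);
every output carries a provenance sidecar (config hash, seed, version) and
reruns are byte-identical.

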