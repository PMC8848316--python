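# phenograd

Image-based plant shoot phenotyping under **LED light-quality gradients**.

Controlled-environment agriculture increasingly uses LED lighting whose
spectrum can be tuned per crop, but the optimal spectral recipe is
species-specific and must be found experimentally. A light *gradient* set-up
exposes a whole range of red:blue photon-flux ratios in a single growth
cycle: pots sit on a room grid whose columns span a continuous gradient of
red:blue ratio (constant total irradiance), plants are imaged repeatedly
from 6 side angles and from the top, and each phenotypic descriptor is
regressed against the log-transformed ratio measured at each pot position.
`phenograd` implements that analysis end to end for plant scientists and
phenotyping-platform engineers:

* **synthetic** — a generator of complete in-silico gradient experiments
  (layout with species blocks, 5-cluster light map, procedurally rendered
  side/top-view RGB frames) with exact ground-truth masks and programmed,
  possibly transient, descriptor responses — so every downstream stage is
  testable without any external imagery;
* **imaging** — white balance and mm-per-pixel calibration against a
  reference chart, grey-scale (side) / excess-green (top) threshold
  segmentation;
* **descriptors** — the standard morphometric set per pot × day:
  dimensions (HeightMax, WidthMax, AreaMean, top Area, MeanFeret, the
  volume proxy Voxel = √(maxAside · minAside · Atop)), shape factors
  (roundness, solidity, convexity, circularity = 4πA/P², compactness),
  and color statistics/indices (RGB and HSB means on 0–255, HueCv,
  integrated density, GLI = (2G−R−B)/(2G+R+B),
  TGI = [(670−480)(R−G) − (670−550)(R−B)]/−200, and an RGB-regression
  chlorophyll estimate 440 + 7.266·B + 10.873·R − 15.545·G);
* **gradient** — the core statistic: per descriptor × species × day, OLS of
  the descriptor on ln(red:blue), with the **effect size** defined as the
  percentage difference between the regression predictions at the maximal
  and minimal ratios, `100·(ŷ(r_max) − ŷ(r_min))/ŷ(r_min)`, plus Pearson R,
  R², p-value, significance categories (NS / p<0.05 / p<0.01) and the
  effect-size time course;
* **multivariate** — PCA species discrimination over selectable descriptor
  classes and camera views, scored by silhouette on the first two
  components;
* a `phenograd` CLI (`generate` / `process` / `analyze` / `report`) gluing
  the stages into one reproducible run.

## Worked example

Simulate one species (a caulescent morphotype with a programmed transient
height response) on a 36-pot block under a 0.1–10 red:blue gradient, and fit
the gradient regression for maximum plant height at day 14:

```python
from phenograd.synthetic import (LayoutConfig, GradientConfig, build_layout,
    build_light_map, default_morphotypes, simulate_descriptor_table)
from phenograd.gradient import GradientRegression

layout = build_layout(LayoutConfig(species_rows={"caulescent": 3}), seed=1)
light = build_light_map(layout, GradientConfig(), seed=2)
table = simulate_descriptor_table(
    layout, light, {"caulescent": default_morphotypes()["caulescent"]},
    schedule := [14], seed=3)
fit = GradientRegression.from_dataframe(
    table, "side_HeightMax", species="caulescent", day=14).fit()
print(fit.summary())
```

```
Gradient effect-size regression (OLS on ln red:blue ratio)
------------------------------------------------------------
descriptor: side_HeightMax   species: caulescent   day: 14
n pots: 36
slope: 14.529 per ln unit (SE 1.97)
intercept: 220.02
Pearson R: 0.7844   R^2: 0.6152
p-value (slope, two-sided): 1.511e-08   [p<0.01]
prediction at ratio 0.0911: 185.2
prediction at ratio 10.8: 254.57
effect size: 37.45% (95% CI 25.13 .. 49.78)
```

Reading this: across the observed gradient (ratio 0.09 → 10.8), the fitted
line predicts plant height rising from 185 mm to 255 mm — a +37% effect of
red-enriched light on height, highly significant (p < 0.01), with the
programmed +40% response inside the 95% CI. The same fit is repeated for
every descriptor, species and imaging day by
`phenograd.gradient.effect_time_course`, and the full image-based route is:

```bash
phenograd generate --seed 1 --out run/          # render a synthetic run
phenograd process  --run run/ --out run/descriptors.csv
phenograd analyze  --descriptors run/descriptors.csv --out run/analysis/
```

`analyze` writes the effects table (`effects.csv`), PCA scores/loadings per
feature selection, an effect-size heatmap and effect time-course figures.

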