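# epimorph

Epithelial sheet morphometry for segmented flatmount images, with a synthetic
tessellation generator and mixed-effects group comparison.

The retinal pigment epithelium (RPE) is a monolayer whose healthy state is a
near-honeycomb mosaic of hexagonal cells.  Degeneration — for instance in
ciliopathy mouse models — shows up as cells that become larger, more variable
in size, and less hexagonal with age.  `epimorph` quantifies this from
segmented label images (one positive integer label per cell, 0 =
background/membrane): it extracts per-cell polygons, builds the neighbour
graph, computes a panel of shape metrics, and compares genotype/age groups
with the repeated-measures statistics appropriate for cells nested in images
nested in animals.

## The regularity scores

For a cell with perimeter *P*, area *A*, and convex hull perimeter
*P<sub>h</sub>* and area *A<sub>h</sub>*, and the regular *N*-gon identity
*A* = (*N*/4) *s*² cot(π/*N*):

- PSR = (*P*/*P<sub>h</sub>*) · (1 − |1 − *P*/*P*<sub>ref</sub>(*N*, *A*)|),
  where *P*<sub>ref</sub>(*N*, *A*) = *N* √(4*A*/(*N* cot(π/*N*))) is the
  perimeter of the regular *N*-gon of equal area;
- PAR = (*A*/*A<sub>h</sub>*) · (1 − |1 − *A*/*A*<sub>ref</sub>(*N*, *P*)|),
  where *A*<sub>ref</sub>(*N*, *P*) = (*N*/4)(*P*/*N*)² cot(π/*N*) is the
  area of the regular *N*-gon of equal perimeter;
- **polygonality score** = 10 · (PSR + PAR)/2, with *N* the cell's neighbour
  count;
- **hexagonality score** = the same with *N* fixed at 6.

A regular *N*-gon with *N* neighbours scores exactly 10; departures from
regularity lower the score.  The panel also includes area, perimeter,
solidity, maximum/minimum Feret diameter, moment-ellipse eccentricity and
aspect ratio, neighbour count, and the per-image SD of the hexagonality
score.

Group differences in the *mean* of a metric are tested with a linear mixed
model (random intercept per mouse, REML, marginal means); differences in
*variance* with the same model applied to absolute deviations from the group
median (a Brown–Forsythe-style dispersion test).  Both assessments are
Bonferroni–Dunn corrected (factor 2); multi-group contrasts use Tukey's
studentized-range adjustment.

## Worked example

```python
import numpy as np
import epimorph as em

# a disordered synthetic sheet: 480 um field, ~100 um^2 cells
cfg = em.GeneratorConfig(window=(200, 200), target_cell_area=100,
                         jitter_sigma=0.3, seed=2, raster_px_per_um=2.0)
sheet = em.generate_sheet(cfg)
img = em.rasterize(sheet, membrane_px=1)          # label raster with membranes
cells = em.extract_cell_polygons(img)
graph = em.build_adjacency(img, min_shared_px=3)
kept = em.filter_analysis_set(cells, graph)       # drop border cells
metrics = em.measure_cells(kept, graph)
summary = em.summarize_sample(metrics)
print(len(kept), round(summary.stats.loc["hexagonality_score", "mean"], 2),
      round(summary.hexagonality_sd, 2))
```

prints

```
342 6.34 0.85
```

— 342 interior cells were analyzed; their mean hexagonality of 6.34 (on the
0–10 scale, where an undisturbed honeycomb scores 10 and this sheet was
generated with strong seed jitter) and hexagonality SD of 0.85 are exactly
the two readouts that separate disordered mutant sheets from regular
wild-type ones.  Note the raw staircase outlines bias perimeter-based scores
downward; pass `smooth=True` to `extract_cell_polygons` for sub-pixel
outlines when absolute score values matter (see `docs/methods.md`).

The same pipeline runs from the shell:

```sh
epimorph simulate --out sim/ --mice-per-group 4 --jitter-sigma 0.15 --seed 1
epimorph measure sim/*.tif --pixel-size 0.5 --metadata sim/metadata.csv --out metrics.csv
epimorph compare metrics.csv --out results --metrics area,hexagonality_score
```

`compare` writes a results table with the mean and variance test per metric
and age, adjusted p-values, and the significance convention `*` (mean) /
`#` (variance).

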