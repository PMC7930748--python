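# Methods

## Scope and model of the data

`epimorph` analyzes segmented epithelial sheets.  Its unit of data is a 2-D
integer label image: every cell's pixels carry one positive id, background
and membrane are 0.  Segmentation itself (e.g. a border-detection network on
fluorescence flatmounts, plus manual correction) is upstream and out of
scope; damaged tissue regions arrive as a boolean exclusion mask and are
simply removed from the analysis set, mirroring how damaged areas are
excluded from automated flatmount analysis in practice.

Coordinates are x = column, y = row with the origin at the top-left pixel
corner; a pixel (r, c) occupies the half-open square [c, c+1) × [r, r+1).
All outputs are in physical units via `pixel_size` (µm/px).

## Polygon extraction and the staircase convention

Each label is traced into a pixel-boundary ("staircase") polygon, oriented
counter-clockwise.  This makes area bookkeeping exact — the shoelace area of
the traced ring equals pixel count × pixel_size² to machine precision — and
deterministic.  A label split into several 4-connected components, or
enclosing a hole, raises an error: both indicate segmentation failure and
silently merging them would corrupt neighbour counts.

The staircase convention has a known cost: the staircase length of a straight
edge with direction (dx, dy) is |dx| + |dy|, so perimeters are inflated by
10–25% depending on edge orientation (≈ 24% for a regular hexagon's mix of
orientations), and every perimeter-based quantity inherits the bias.  Within
a study this is a common-mode offset and cancels in group comparisons, which
is why raw staircase outlines are the default.

When absolute values matter — e.g. comparing raster measurements against
vector ground truth — `extract_cell_polygons(img, smooth=True)` applies a
sub-pixel smoother: Douglas–Peucker simplification proposes corners; each
sufficiently supported edge is refit by total least squares to boundary
points resampled every half pixel (the staircase oscillates around the true
edge, so the fitted line is unbiased); corners are re-placed at the
intersections of adjacent fitted lines, with short unsupported stubs
(pixel-truncated sharp corners) replaced by the flanking lines' intersection
when that lands nearby.  On Voronoi sheets rasterized at ≈ 50 px per cell
diameter this recovers per-cell hexagonality to within ≈ 0.25 score units of
vector truth; at 20 px/diameter typical (median) errors remain small but
worst-case errors grow, and cells with genuinely sub-pixel features (slivers
in heavily disordered sheets) cannot be recovered at any tolerance — the
validity domain of the concordance checks is therefore moderate disorder and
≥ 30 px per cell diameter.

## Neighbour definition

Two cells are neighbours when at least `min_shared_px` (default 3) pairs of
their pixels face each other across the boundary, either directly 4-adjacent
or separated by exactly one background pixel.  The one-pixel allowance makes
the rule robust to the 1-px membrane skeletons produced by border
segmentation; the 3-pair threshold suppresses corner-touch artefacts.  For
membrane-free rasters where the exact planar-graph structure matters (e.g.
verifying that interior cells average six neighbours, as Euler's relation
requires of any large planar tessellation), `min_shared_px=1` is the right
setting: the default threshold prunes genuinely short cell-cell contacts
(< 3 px of shared boundary) and biases the mean degree low by ≈ 0.3.

Border-touching cells are excluded from metric reporting — their geometry is
truncated — but stay in the adjacency graph, so the neighbour counts of
retained cells are counted against *all* segmented cells.

## The shape metric panel

Per cell: area, perimeter, convex-hull area/perimeter (hull via
`scipy.spatial.ConvexHull`), solidity = A/A_hull, Feret maximum (largest
pairwise hull-vertex distance) and minimum (smallest caliper width over hull
edge orientations; the minimum width of a convex polygon is always attained
flush against an edge), eccentricity and aspect ratio from the
area-normalized second central moments of the polygon (Green's-theorem
closed forms; the moment ellipse is stable for staircase outlines, unlike a
Feret-ratio elongation), neighbour count, and the two regularity scores.

The polygonality score compares the cell against the regular N-gon with N
its neighbour count; the hexagonality score fixes N = 6.  Both use the
regular-N-gon identity A = (N/4) s² cot(π/N) to build the equal-area
reference perimeter and the equal-perimeter reference area; this is the
unique construction under which every regular N-gon scores exactly 10, the
scale the scores are defined on.  Two numerical notes:

- The bracket terms are **not clamped** by default: extremely elongated
  cells can score below 0, and the raw value preserves ordering.
  `clamp_scores=True` floors the PSR/PAR/HSR/HAR ratios at 0.
- The ratios are bounded by 1 only for convex cells.  For concave cells the
  perimeter factor P/P_hull exceeds 1 and PSR can reach P_ref/P_hull (up to
  ≈ 1.29 for N = 3); this is a property of the score's definition, not an
  implementation artefact.  Near-convex epithelial cells are unaffected.

A cell with fewer than three neighbours has no regular-N-gon reference; its
polygonality score is reported as NaN (the hexagonality score is always
defined).

Per-sample summaries use the n−1 SD convention; skewness and kurtosis are
the standardized third/fourth central moments, kurtosis as excess.  The SD
of the hexagonality score is computed per image; aggregation across images
and animals belongs to the statistics layer.

## Synthetic epithelial sheets

The generator emulates the phenotypic axis of interest, not tissue
mechanics.  Seeds sit on a triangular lattice whose spacing d = √(2A/√3)
matches a target cell area A (the Voronoi diagram of the perfect lattice is
the regular-hexagon honeycomb and scores exactly 10); isotropic Gaussian
jitter of SD `jitter_sigma`·d disorders the sheet; `dropout_fraction`
removes seeds, enlarging the surviving cells (the "big cell" phenotype);
optional Lloyd (centroidal) relaxation pulls a jittered sheet back toward
regularity.  Tessellation is by `shapely.voronoi_polygons`, clipped to the
window; the clipped cells tile the window exactly, so summed cell area
equals window area to rounding.  Rasterization labels each pixel centre with
its nearest seed — exact for a Voronoi tessellation — and can paint a 1-px
membrane along label changes; fragments severed by the membrane at acute
corners (or sub-pixel slivers) are absorbed into the background.

Defaults: 250 µm² target cells (realistic for mouse RPE), 400 µm windows,
jitter 0 (the honeycomb reference).  Two knobs have monotone, opposite-sign
effects that the tests verify: mean hexagonality strictly decreases and area
SD strictly increases with jitter.

Cohorts nest images in mice in genotype × age groups.  A per-mouse lognormal
random effect exp(N(0, mouse_sd)) multiplies the target cell area —
animal-to-animal variation is the reason the statistics need a random
intercept — and per-group multipliers scale area, jitter and dropout.  All
randomness derives from one seed through `numpy.random.SeedSequence`
substreams, so cohorts are bit-reproducible.

For calibration and power studies of the statistics the geometry is
irrelevant; `simulate_measurements` draws per-cell values directly from the
hierarchical model (group mean + mouse effect + cell noise), which makes
thousand-replicate Monte Carlo runs affordable.  What those runs do *not*
exercise is everything geometric — segmentation quality, raster
discretization, spatial correlation between neighbouring cells — so they
validate the inference machinery, not the end-to-end pipeline; the
full-geometry cohort tests cover the latter at smaller scale.  Real RPE
flatmounts differ from jittered-lattice Voronoi sheets in ways the generator
does not model (curved membranes, mechanical constraints, spatially
structured damage), so passing tests certify the statistical signatures the
pipeline is meant to detect, not biological realism.

## Group statistics

Cells from one mouse are correlated; treating them as independent is the
classic pseudo-replication error.  Every comparison therefore models a
random intercept per mouse (statsmodels `MixedLM`, REML) and reports
marginal (model-implied) group means.

**Inference is by the containment (between-mouse) convention.**  The
contrast standard error and degrees of freedom (total mice − number of
fixed-effect parameters) come from the spread of per-mouse means around
their group means; the effect estimate is the REML marginal-mean difference.
The alternative — Wald standard errors from the REML fit with cell-level
df — fails exactly where it matters most: in the dispersion test the
between-mouse variance of folded residuals is a tiny fraction of the
cell-level variance, REML estimates it at the zero boundary, and the model
then silently treats thousands of correlated cells as independent (measured
type-I error ≈ 27% at nominal 5% with a 6% animal effect).  Containment
inference restores calibration (≈ 4–5%) at no measurable cost in power in
the regimes tested.  The test suite keeps a regression test showing that a
naive cell-level t-test is badly anti-conservative on the same data.

**Variance test.**  Each observation is transformed to |x − median| with the
median taken per genotype × age group (Brown–Forsythe convention; a `global`
centering option exists, and signed residuals — which test location, not
spread — only for diagnostics), then the mean machinery runs on the
transformed values.  The estimate is the difference in mean absolute
deviation.  One caveat is inherent to group-median folding: strong per-mouse
location effects leak quadratically into the folded values; the containment
SE absorbs this leak because it is a between-mouse phenomenon.

**Multiplicity.**  Each metric × contrast is assessed twice (raw and
folded), so both p-values are doubled and capped at 1 (Bonferroni–Dunn with
family size 2).  Across more than two genotype × age cells, pairwise
contrasts from a joint model are adjusted with the studentized range
(q = √2·|t|, k groups, containment df); with two groups this reduces exactly
to the unadjusted contrast.

**Trends and diagnostics.**  Age trends are OLS slopes of per-mouse summary
means against age with a normal-approximation CI; the direction is the sign
of the slope when the CI excludes 0, else "none".  Normality diagnostics
report per-group skewness, excess kurtosis and normal q-q pairs (Hazen
plotting positions), with a small-sample flag below n = 8.

## Numerical and design choices

- MixedLM optimization: the response is standardized before fitting (the
  quasi-Newton default is unreliable on poorly scaled data, occasionally
  reporting convergence with wrong fixed effects) and a Nelder–Mead refit
  backs it up whenever the fixed effects disagree with their OLS
  counterparts, which coincide with GLS in these balanced designs.
- A mouse-level variance estimated at the zero boundary warns but does not
  fail; containment inference is unaffected.
- Ties/degenerate cases: identical duplicated groups give estimate 0, p = 1;
  fewer than 2 mice per group, fewer than 3 distinct ages for a trend, empty
  label images, and sub-5-px cell rasterization are errors, not silent
  results.
- Monte-Carlo problem sizes in the test suite (e.g. 1000 null replicates at
  4 mice × 120 cells; concordance on one 2000-cell sheet at 5 px/µm) were
  chosen to bound the sampling error of the checked rates (binomial SE
  ≈ 0.7% at 1000 replicates) while keeping the default test run fast.

## Known limitations

- The smoother assumes cells are polygonal with straight edges (true for
  Voronoi sheets, approximately true for epithelia); strongly curved
  membranes would be better served by spline fitting.
- Perimeter-based metrics from unsmoothed rasters carry the staircase bias;
  cross-study comparisons must use one convention consistently.
- The dispersion test detects shifts in mean absolute deviation; it is not a
  variance-ratio estimator.
- The generator does not simulate image noise, point-spread functions, or
  segmentation errors; robustness to those must be established on real
  segmentations.
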