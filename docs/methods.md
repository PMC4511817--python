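# Methods

## Scope and data model

`reefmetrics` operates downstream of photogrammetric reconstruction: its
inputs are a DEM raster and a polygon catalogue of benthic features, both in
a local planar metre coordinate system (reef surveys are laid out with tape
and depth gauge, not a projected CRS; CRS tags in input files are noted and
ignored).  Elevation is up-positive internally; depth-gauge rasters are
negated on load (`depth_mode`), which is an involution.  Rasters are
cell-centre registered: cell `(row, col)` has its centre at
`origin + ((col + ½)·L, −(row + ½)·L)` with `L` the (square) cell size.
Square cells are mandatory because every derivative below assumes one window
spacing.

## Terrain derivatives

Both operators act on the 3×3 window `Z1…Z9` (row-major, `Z5` centre).

**Slope** uses the average-maximum technique (Horn's weighted differences):

    dz/dx = [(Z3 + 2·Z6 + Z9) − (Z1 + 2·Z4 + Z7)] / (8L)
    dz/dy = [(Z1 + 2·Z2 + Z3) − (Z7 + 2·Z8 + Z9)] / (8L)
    tan θ = √((dz/dx)² + (dz/dy)²)

Percent slope is `100·tan θ` (100 % = 45°).  The operator is exact on planar
surfaces, which the property tests exploit.

**Curvature** uses the Zevenbergen–Thorne partial-quartic fit; the five
coefficients that matter are second differences (`D`, `E`, cross term `F`,
in 1/m) and central gradients (`G`, `H`, dimensionless).  Outputs, scaled by
100 as is conventional for GIS curvature tools (hundredths of the z-unit):

    combined = −2(D + E) · 100          convex > 0
    profile  = +2(DG² + EH² + FGH)/(G² + H²) · 100     convex < 0
    planform = −2(DH² + EG² − FGH)/(G² + H²) · 100

Profile curvature follows the direction of maximum slope, planform the
perpendicular direction.  The sign conventions (combined convex-positive,
profile convex-negative) follow the dominant GIS tooling so field tables are
directly comparable; each `MetricRaster` carries its convention string so a
mismatch can never be silent.  On level cells (`G = H = 0`) the slope
direction is undefined and profile/planform are defined as 0 rather than
missing — flat sand would otherwise propagate holes through every summary.
The 3×3 fit reproduces quadratic surfaces exactly, so curvature is
property-tested to 1e-9 relative error against analytic derivatives and an
independent least-squares 9-point fit.

An optional `z_unit_scale` multiplies all three curvature outputs to express
them at a different reference z-unit (sub-centimetre-cell surveys are often
rescaled to the 1 m z-unit of terrestrial studies).  The default is 1 and no
rescaling is ever applied implicitly.

**Border handling.**  The one-cell border and any cell with a masked
neighbour are masked in every derivative raster.  No reflection or padding:
padded derivatives would be fabricated data.

## Surface complexity

A feature's surface complexity is draped 3D area / planimetric 2D area.
Cells belong to a polygon iff their *centre* lies strictly inside (even-odd
rule; centres exactly on a ring belong to no feature) — the same rule the
zonal partition uses, so a cell can never be claimed twice.  Each selected
cell is split into two 3D triangles along its top-left → bottom-right
diagonal; corner elevations are the mean of the (≤ 4) adjacent cell centres.
The fixed diagonal and deterministic corner rule make the drape bit-for-bit
reproducible.  The 2D denominator is the rasterised footprint
`n_cells · L²`, so numerator and denominator live on the same mesh and a
level feature scores exactly 1; the exact vector polygon area is reported
alongside so rasterisation error is auditable.  Known accuracy behaviour:

- exact on planes (a 45° plane gives √2 to 1e-9);
- smooth curved surfaces converge with resolution from below: a hemisphere
  footprint at 100 cells per radius recovers complexity ≈ 1.91 against the
  analytic 2.0 (the near-vertical rim is systematically under-resolved);
- slope discontinuities (e.g. the rim shoulder of a plating disc) are
  smoothed over a ~2-cell band by the corner averaging, biasing the area
  low by a few percent when the discontinuity spans only a few cells.

A DEM is 2.5D: true overhangs (plating *Acropora* canopies) cannot be
represented, and the computed 3D area is that of the drape surface.

## Rugosity

The rugosity index of a transect is path length / chord length of its
elevation profile, ≥ 1 with equality only when level.  Profiles are sampled
on straight lines at a uniform station spacing (default: one cell size,
finer steps add interpolation but no information), elevations by bilinear
interpolation of cell centres.  Straight-line sampling, rather than
cell-to-cell path walks on the raster graph, avoids diagonal-step inflation
and admits closed-form checks (triangle wave → √2 exactly; sine field →
quadrature arc length).  Chord sampling of a smooth curve under-measures arc
length, and refinement is monotone non-decreasing by the triangle
inequality — both property-tested.

The plot-level value averages a transect plan given in fractional
coordinates of the cell-centre extent.  The default plan has six transects:
long-axis lines at 1/3 and 2/3 of the width, short-axis lines at 1/3 and
2/3 of the length, and both corner-to-corner diagonals — covering the
horizontal, vertical and diagonal directions.  Transects crossing nodata are
flagged and excluded; fewer than two usable transects is an error.  The
reported SE is the sample SD of per-transect indices over √n.

## Zonal summaries and percent cover

The annotation catalogue is rasterised once (cell-centre membership; an
overlap is an error naming both features and the cell).  Per-feature
statistics of a metric raster are mean and SE over the feature's unmasked
cells; SE is always sample SD (n−1) over √n and is *missing*, never zero,
when n < 2.

Class-level summaries mirror how per-colony field tables are built:

- surface complexity and slope are summarised **over features** — each
  colony is one replicate;
- curvature is summarised **over cells pooled within the class**,
  reconstructed exactly from per-feature moments via the within+between
  sum-of-squares decomposition (tested against direct cell pooling).  This
  mirrors GIS tooling that yields only class-level curvature statistics;
- percent cover uses exact vector polygon areas clipped to the plot extent
  (resolution-independent); over an exhaustive non-overlapping annotation
  the class covers sum to 100 within rounding.

## Statistics

The comparison stage is one-way fixed-effects ANOVA per metric with Tukey's
HSD post hoc pairs at α = 0.01 (the conventional threshold for these
community comparisons), preceded by a two-response MANOVA (Wilks' lambda,
Rao's F approximation — exact for two responses) to screen the joint
response.  Sums of squares and the q statistic are computed from their
definitions; p-values come from the scipy F and studentized-range
distributions; statsmodels serves as an independent oracle in the tests.
Tukey uses the Tukey–Kramer form for unequal group sizes.

Log transformation: field metrics are often right-skewed, but "transform if
necessary" needs a deterministic rule.  The screen applies a natural log
when the pooled within-group residual |skewness| exceeds 1 (a common
rule-of-thumb boundary for problematic skew), records the decision, and can
be forced either way per metric.  The null calibration (8 groups, n = 30,
2,000 seeded replicates) verifies the ANOVA's type-I error at α = 0.01
within ±0.6 percentage points.

## Synthetic scenes

`make_analytic_surface` samples closed-form surfaces (flat, plane,
paraboloid dome/bowl, hemisphere, sine field, triangle wave) whose
complexity, slope, curvature and rugosity are known exactly; the triangle
wave places its breakpoints on cell centres so profile sampling sees every
segment at full slope.  The annotation polygon is inset one cell so only
interior cells (whose corner interpolation is exact on planes) contribute.

`make_colony_field` emulates a 25 × 6 m survey plot at 0.5 cm cells — the
scale of a sub-centimetre photogrammetric survey — with four colony
morphotypes on a gently undulating matrix (amplitude 4 cm, wavelength 2 m,
split into rock/rubble and sand halves):

| morphotype | shape | defaults | closed-form complexity |
|---|---|---|---|
| mounding | spherical cap | a ∈ [0.15, 0.30] m, h = 0.6a | 2Rh/a², R = (a²+h²)/2h |
| encrusting | cos² bump | h = 0.15a | quadrature (surface of revolution) |
| plating | flat disc, conical rim | h = 0.5a, rim w = 0.1a | [π(a−w)² + π(2a−w)√(w²+h²)]/πa² |
| branching | rectified sine patch | h = 0.06 m, λ = 0.08 m | none |

Default radii give ≥ 30 cells per footprint radius, comfortably above the
≥ 20 cells/radius at which cap recovery is within 2 %.  Plating rims are
steep (slope 5, i.e. 500 % — a stand-in for the near-vertical margins of
plate corals, since a 2.5D drape cannot express true overhangs) and span
only 3–6 cells, so disc recovery is resolution-limited: the package states
a 5 % tolerance for discs from the rim-smoothing argument above, and at
some seeds the smallest discs exceed even that (observed up to ~6 %).  This
is a genuine limitation of drape-based area on under-resolved slope
discontinuities, not of the closed forms, and is asserted as stated rather
than relaxed.  The matrix undulation is ramped smoothly to exactly zero
within 5 cm of every footprint (10 cm cosine ramp) so each colony sits on a
locally flat base and its closed form holds exactly.  Placement is
rejection sampling with a per-colony attempt cap; all randomness flows from
one seeded generator, so (seed, parameters) reproduce scenes bit-for-bit.

What the generator does *not* emulate: photogrammetric reconstruction noise
and holes, texture, overhangs, colony shape irregularity, and spatial
clustering of colonies.  Passing recovery tests therefore validates the
measurement operators on known geometry — they say nothing about
reconstruction error in real surveys, which enters upstream of this
package.

The published class-level community table for the French Frigate Shoals
plot ships with the package (`published.py`) as reference input for
percent-cover arithmetic; the underlying raw per-colony dataset and DEM are
not redistributable, so the statistics stage is validated on synthetic and
hand-computed data, and the corresponding recomputation test documents the
input it would need.

## Problem sizes and numerical choices

The default test and acceptance workloads use the full 25 × 6 m plot at
0.5 cm cells (1200 × 5000 cells) for scene recovery, 2 cm-scale grids for
the analytic oracles, and 2,000 replicates for the null calibration — sizes
chosen so every closed-form comparison is resolution-adequate while the
whole suite completes in well under a minute of compute per stage.
Tie-breaks and degenerate inputs are handled deterministically throughout:
level cells (profile/planform → 0), boundary cell centres (assigned to no
feature), n = 1 features (SE missing), zero-variance ANOVA groups
(degenerate-sample error), singular MANOVA within-matrices (error rather
than pseudo-inverse).
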