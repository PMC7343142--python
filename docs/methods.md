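# Methods

This note documents the models, conventions and numerical choices behind
`beeranges`, and what the synthetic-data tests do and do not establish
about real telemetry data.

## Coordinates and projection

All geometry is planar, in meters. Longitude/latitude input is projected
with a local equirectangular projection about the dataset centroid
(x = R·cos φ₀·Δλ, y = R·Δφ, R = 6 371 008.8 m). For telemetry extents of
a few kilometers this keeps pairwise distances within ~0.5% of
great-circle values; world projections such as Pseudo-Mercator inflate
areas by ~1/cos²(lat) (≈ 37% at 31° S) and are avoided so that hectares
and meters mean what they say. Areas are always reported in hectares.

## Home range (MCP) and shape indices

The MCP is the convex hull of all of a bee's fixes; the "most external"
fixes are exactly the hull vertices, whatever their number. At least 5
fixes are required (the relocation filter), and collinear point sets
raise an error rather than returning a zero-area polygon, because the
shape indices are undefined there. Area comes from the shoelace formula
(via shapely), perimeter from edge lengths, and the hull diameter — the
maximum flight distance — from an all-pairs scan over hull vertices
(point counts are tiny; rotating calipers would be overkill).

Compactness uses the exact constant Kc = P/(2√(πA)); the commonly quoted
multiplier 0.282 is the truncation of 1/(2√π) = 0.2820948…, and using
the exact value preserves the identity Rci·Kc² = 1 to machine precision
(asserted at 1e-9 in tests). Rci = 4πA/P² is bounded by 1
(isoperimetric inequality), reaching 0.785 (= π/4) for a square.

Stage summaries use arithmetic means and sample SDs (n−1 denominator),
which is the convention that reproduces the published stage table from
the published per-bee values.

## Rank tests

`kruskal_wallis` computes H = 12/(N(N+1))·Σ Rᵢ²/nᵢ − 3(N+1) with
midranks. Tie correction (dividing by 1 − Σ(t³−t)/(N³−N)) is **off by
default**: the field study's printed H values (6.94 for MCP areas, 2.44
for homing distances) are reproduced without it, and the area column
contains one tie (0.96/0.96 ha). p-values use the chi-square upper tail
(df = k−1) by default. An exhaustive-permutation p is available for
small problems; enumeration of all C(17,7) = 19 448 two-group
assignments shows the study's printed p-values are permutation
p-values: p = 0.1331 for distances exactly, and p = 0.0068 for areas
when the single tie is ranked by input order (0.0065 with midranks).
Both rank conventions are exposed (`rank_method="average" | "ordinal"`).

`chi2_sf` is the regularized upper incomplete gamma Q(df/2, x/2),
delegated to scipy and cross-checked against numeric quadrature at 1e-8.

## Kernel density

The quartic (biweight) kernel K(u) = (3/π)(1−u²)² on the unit disk is
applied with a fixed radius (default 60 m, configurable) — no bandwidth
selection, matching the fixed-radius estimation the analysis prescribes.
Each point contributes 1/r²·K(d/r), so a point's total mass is 1 and the
raster mass approximates the point count; this conservation law is what
the tests check (within 2% at cellsize = radius/12). A raw-weight mode
(`normalize=False`, CLI `--no-normalize`) reproduces the look of
desktop-GIS heatmap tools that sum unnormalized kernel weights. The grid
origin is snapped to multiples of the cell size, making the surface
exactly translation-equivariant for shifts that are multiples of the
cell. Cell sizes above radius/4 trigger a warning (the Riemann sum gets
crude) but are not fatal. Rasters are written as ESRI ASCII grids:
plain text, diffable, readable by any GIS.

## Habitat selection

Fixes are classified by polygon containment; boundary points take the
first containing feature in file order (a deterministic tie-break), and
points in no polygon count as `unclassified` rather than erroring.
Availability inside a bee's MCP is estimated by uniform rejection
sampling from the hull's bounding box (acceptance is high for convex
polygons; acceptance below 1% raises). Expected counts default to the
mean of 100 null replicates rescaled to the observed total — a
single-draw mode (`replicates=1`) is also exposed, since the original
analysis's replicate count is unstated. The chi-square test runs over
four categories (developed land is excluded — bees were never observed
using it; configurable via `--test-categories`); zero-expectation
categories are dropped with a warning and the df reduced. Per-bee tests
are reported raw, with a Holm-adjusted column alongside (no correction
is applied to the primary p-values, matching per-individual reporting).

Nest substrates are grouped to land-use classes (eucalyptus/pine
plantations and casuarina windbreaks → plantation; citrus → other
fruits; savanna → semi-natural), with percentages over confirmed nests.

## Pollen composition

Flowering stages are assigned from capture dates with day-of-month
weeks (1–7, 8–14, 15–21, 22–end): early = July week 4 + August week 1,
peak = August weeks 2–3, post-peak = August week 4 through September
week 2. The week convention in the original description is ambiguous;
this one is documented and configurable in code. Per-sample percentages
are computed in exact rational arithmetic (counts over total), so focal
species plus the pooled "Others" sum to exactly 100 per sample. The
default focal list is the nine individually reported species; all other
morphotypes pool into "Others".

## Synthetic-data generator

The generator's defaults encode the study conditions: 7 pre-nest and 10
post-nest queens, Poisson(28) fixes each (min 5; the field campaign
averaged 24 before and 31 after), a 2 km × 1.5 km landscape with area
fractions 35% blueberry, 15% plantation (including two 8 m windbreak
strips through the crop), 30% semi-natural, 15% other fruits, 5%
developed. Landscapes are full-height strips, so class area fractions
are exact by construction.

Tracks are unordered Gaussian fix clouds — the MCP/KDE/selection
analyses ignore sequence, so correlated walks would add complexity
without adding testable structure. Pre-nest queens: isotropic SD 140 m
centered in a blueberry field; post-nest queens: anisotropic SD with
geometric mean 55 m and a 3:1 axis ratio, the major axis along a
plantation edge, nests 4 m off that edge (the study reports nests ~3–5 m
from plantation edges, 56% of them in that class). These scales put mean
simulated MCP areas near the reported 22.7 / 3.56 ha stage means.
Habitat affinity is injected by rejection thinning (accept a candidate
fix with probability proportional to its land-use weight) — simple,
seed-stable, and sufficient to create recoverable selection.

Pollen loads are Dirichlet-multinomial: per-stage mean vectors are the
reported stage composition table (nine focal species plus the remainder
spread over 45 morphospecies), and each stage's total concentration is
calibrated by root-finding so the expected richness of a 100-grain load
(inclusion probability E[S] = Σⱼ(1 − P(countⱼ = 0))) matches the
reported per-stage richness means (10.95 / 8.50 / 13.62). The calibrated
totals come out near 9–13, implying heavy overdispersion — consistent
with the large SDs the study reports.

### Power and calibration experiments

Problem sizes were chosen to make the Monte-Carlo checks sharp yet quick:

- **Stage contrast**: 100 replicates of the full 7 + 10 bee campaign
  with a 5-fold ranging-scale contrast; the Kruskal–Wallis test on MCP
  areas rejects in > 90% of replicates.
- **Habitat selection**: the power experiment uses one wide-ranging
  queen (SD 900 m) per replicate on a two-class availability landscape
  with the preferred crop at 25% of the area. That availability mix is
  where a 3:1 preference at ~30 fixes is most informative: the
  noncentrality of the df = 1 chi-square is maximized near preferred-
  class availability of 0.25, and on richer mosaics the test loses power
  both to extra degrees of freedom and to hull feedback (thinning also
  shrinks the MCP toward the preferred class, dragging the availability
  null along with the use distribution). 200 replicates give > 80%
  rejection.
- **Type-I calibration**: 1000 simulations drawing the observed fixes
  uniformly inside a fixed quadrilateral range — exactly the null the
  test assumes — give a rejection rate of 0.05 ± 0.02.
- **Pollen recovery**: 500 simulated loads per stage recover the
  generator's crop-species mean within 3 Monte-Carlo SE.

### What the synthetic tests do not show

The generator emulates unordered fix clouds, crisp polygon boundaries
and independent 100-grain counts. Real telemetry has serially correlated
fixes, GPS error, detection bias near cover, and habitat maps digitized
with boundary uncertainty; pollen counts share observers and reference
libraries. Passing the recovery tests demonstrates that the estimators
are implemented correctly and have the advertised operating
characteristics under their own assumptions — not that those assumptions
hold in any particular field system. The study's own per-bee land-use
proportions and pollen counts were never published, so those table
values are used only as generator parameters, never claimed as
recomputed results; the per-bee summary table (areas, distances,
waypoint counts, nests) is the one packaged ground truth, and its
printed areas are taken as given rather than recomputed from raw fixes
(which were not deposited, and whose original projection is unstated).

## Out of scope

Kernel home-range isopleths (50/95% contours), path statistics (step
lengths, turning angles), bandwidth selection, resource-selection and
step-selection models, and the negative-binomial GLMM of per-class
waypoint counts (a standard mixed-model fit; the pipeline exports the
tidy per-bee per-class table such a model consumes).
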