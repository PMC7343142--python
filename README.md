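# beeranges

Spatio-temporal habitat-use analysis for radio-tracked bumblebee queens
(*Bombus* spp.) in an agricultural mosaic: minimum convex polygon (MCP)
home ranges with shape indices, quartic kernel density surfaces, a
random-point availability null for habitat selection, stage-wise rank
statistics, and pollen-load composition summaries. A synthetic-data
generator produces landscapes, stage-contrasted tracks and pollen loads
with the statistical structure the analysis assumes, so the whole
pipeline can be exercised at desk scale.

The package is aimed at movement ecologists working with small telemetry
datasets (tens of fixes per animal) who want a reproducible, scriptable
version of the classical used-vs-available workflow.

## The methods in brief

**Home range.** Each queen's MCP is the convex hull of her relocation
fixes (at least 5 fixes required). With hull area *A* (m²) and perimeter
*P* (m), two dimensionless shape indices are reported:

- compactness  Kc = P / (2·√(πA)) — 1 for a circle, larger for elongated
  ranges;
- circularity ratio  Rci = 4πA / P² — 1 for a circle, 0.785 for a
  square, below ~0.2 for very elongated shapes.

They satisfy Rci = 1/Kc² exactly. The maximum flight distance is the
hull diameter (farthest pair of fixes).

**Density surface.** A quartic (biweight) kernel
K(u) = (3/π)(1−u²)² for u < 1 is centered on every fix with a fixed
radius (default 60 m); each point contributes unit mass, so the raster
mass approximates the number of fixes.

**Habitat selection.** Fixes are classified against a five-category
land-use map (blueberry, forest plantation, semi-natural, other fruits,
developed). Availability is estimated by scattering the same number of
points uniformly inside the bee's MCP (mean of 100 replicates by
default); observed vs expected counts are compared with a chi-square
goodness-of-fit test over the four categories bees actually use.

**Rank statistics.** Stage contrasts use the Kruskal–Wallis H with
midranks and no tie correction (matching the field study's reported
values); p-values come from the chi-square tail or, for small two-group
problems, exhaustive permutation.

**Pollen.** 100-grain loads are binned into early / peak / post-peak
blueberry-flowering stages by capture date, summarized as mean ± SD
percent per species with the non-focal species pooled as "Others", and
compared across stages per species with Kruskal–Wallis.

## Worked example

The package ships the per-bee summary table of the 17 tracked queens
(waypoint counts, MCP areas, homing distances, nest substrates). The
`report` subcommand reruns the headline statistics:

```sh
$ beeranges report --fixtures table1
Stage summary (mean +- SD):
  before_nest  n=7  area 22.71 (+- 31.68) ha  distance 813.82 (+- 421.77) m
  after_nest   n=10  area 3.55 (+- 4.20) ha  distance 522.71 (+- 350.25) m
  all          n=17  distance 642.58 (+- 396.89) m
MCP area: H = 6.94, p(chi2) = 0.0084
Max distance: H = 2.44, p(chi2) = 0.1184
Area decrease after nesting: 84%
Waypoints: total 473, before 166, after 307
Confirmed nests: 9
  plantation     5 (56%)
  blueberry      2 (22%)
  semi_natural   1 (11%)
  other_fruits   1 (11%)
```

Pre-nest queens ranged over ~6× larger areas than post-nest queens
(H = 6.94: the stage contrast in MCP area is significant), their maximum
homing distances did not differ significantly (H = 2.44), and 5 of the 9
confirmed nests sat against plantation edges or windbreaks.

A fully synthetic run of the same pipeline:

```sh
beeranges simulate --seed 1 --out sim
beeranges homerange --waypoints sim/waypoints.csv --out hr.csv
beeranges kde --waypoints sim/waypoints.csv --out sim
beeranges habitat --waypoints sim/waypoints.csv --landuse sim/landscape.geojson --out sim
beeranges pollen --pollen sim/pollen.csv --out pollen_summary.csv
```

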