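# Methods

This note documents the models, conventions and numerical choices behind
`floragap`, and what the synthetic experiments do and do not demonstrate.

## Units of analysis

The elementary datum is the *unique observation*: a cleaned, name-resolved
record collapsed to one row per (accepted species, coordinate rounded to
`dedup_precision` decimals). The default precision is 4 decimals (~11 m at
the equator) — fine enough that genuinely distinct collection localities
survive, coarse enough that re-entered duplicates of one gathering
collapse. This definition of "unique" is a genuine judgement call (exact
duplicates only, versus rounded coordinates, versus including the source
dataset in the key); it is surfaced in configuration and logs rather than
hidden. Dedup sorts stably on (name, lat, lon, dataset id) and keeps the
first row, so output is independent of input order.

Spatial aggregation uses square cells (default 10 km) on a planar grid
under a spherical Lambert conformal conic projection (closed Snyder forms,
authalic radius 6 370 997 m). Standard parallels bracketing the domain keep
scale error ≪ cell size; the spherical-vs-ellipsoidal datum difference
(~0.3%) is irrelevant for assigning points to 10 km cells. Cells are
half-open `[edge, edge + size)` with a lower-left origin: a point exactly
on a shared edge belongs to the higher-index cell, an unambiguous
convention chosen once. Points are assigned by their own projected
coordinates (raster-style workflow), not by polygon membership.

## Coordinate cleaning

Six documented rules: missing/unparseable coordinates, |lat| > 90 or
|lon| > 180, the (0, 0) artefact, lat exactly equal to lon (column
duplication), outside the supplied country polygon (boundary counts as
inside), and within `radius_km` (default 5 km) of a supplied centroid
list. The last two run only when their reference data are given. A record
failing any enabled rule is removed; the report counts hits per rule
independently, while `kept + removed = input` counts each record once.
Cleaning followed by dedup is idempotent.

## Bioregion map

The analysis-unit raster is built by (biome id, region id) → unit id table
lookup (many-to-one allowed); combinations absent from the table become a
missing sentinel with a logged count. The transformed-areas mask then
overrides masked cells with the reserved unit id 14, treated downstream as
a bioregion in its own right; the override is idempotent. "Total cells" of
a unit means cells carrying that unit id in the map, not a bounding box.

## Completeness and richness

A cell is surveyed with ≥1 record, well-surveyed at threshold T with ≥T
records; T ∈ {10, 25, 50} are the conventional low/moderate/high
thresholds with 25 the headline choice. For the useful-plant subset the
thresholds apply to *useful* record counts, so a cell can be well-surveyed
for all plants but not for useful plants. The share of well-surveyed cells
is reported with two denominators — surveyed cells (primary) and total
cells — because both conventions appear in practice; columns name the
denominator explicitly.

Mean species richness (species/cells ratio) over `all` cells divides the
summed per-cell species counts by every cell of the unit (empty cells
contribute zero), so it is bounded above by the surveyed-cell mean; over
`surveyed`/`well_surveyed` it averages only qualifying cells and is NaN
when none qualify. No richness estimator correcting for effort (Chao,
rarefaction) is applied: raw counts are the object of study here, since
the point is to expose their sampling dependence.

## Use categories

The vocabulary is the closed 10-category scheme (Animal Food,
Environmental Uses, Fuels, Gene Sources, Human Food, Invertebrate Food,
Materials, Medicines, Poisons, Social Uses). A species or record counts
once in each category it holds, so category counts exceed the useful
totals and percentages do not sum to 100; ratios are reported to 2 dp.
The bioregion × use matrix is clustered agglomeratively with average
linkage on Euclidean distances over log10(count + 1) (offset admits
zeros); linkage and metric are configurable, and both raw and
log-transformed inputs are supported since display conventions vary. Ties
follow scipy's deterministic input-order rule; trees are exported as
Newick.

## Survey coverage

Both densities are Gaussian-kernel KDEs evaluated on a 512-point grid
spanning [min − 3h, max + 3h]; h defaults to Silverman's rule
0.9·min(sd, IQR/1.34)·n^(−1/5) (Scott's 1.06·sd·n^(−1/5) optional). The
landscape density uses one climate value per cell of the unit; the effort
density uses the climate value at each record's cell (cell centres, the
native climate resolution — not interpolated to point coordinates), so
cells enter weighted by visitation. The overlap coefficient re-evaluates
both estimates exactly on the union of their grids, renormalises each by
its own trapezoidal integral (the finite window truncates ~1e-4 of kernel
mass), and integrates the pointwise minimum: 1 means identical shapes, 0
disjoint support. It was chosen over a plain KS statistic because it reads
directly as shared probability mass, matching the intuitive
"similar-shaped distributions" criterion for adequate coverage; the KS
distance is emitted alongside. No numeric threshold for "adequate"
coverage is imposed — the statistics are reported, not judged.

## Synthetic study system

The generator emulates the statistical structure of a national occurrence
snapshot on a rectangular landscape:

* **Climate**: ANMT a linear west–east gradient over (5, 28) °C, ANP a
  south–north gradient over (500, 8000) mm/yr — tropical-country-like
  spans — plus Gaussian noise (SD 1 °C / 250 mm), clipped to range.
* **Layers**: biomes are quantile bins of the standardized joint climate
  index (5 classes), regions are 3 contiguous bands, and the overlay table
  merges overflow combinations so 13 units result, with the clustered
  transformed mask (grown patch-by-patch to exactly the target fraction of
  each region, default 15%) adding unit 14.
* **Species**: 2,000 species by default; ~16% useful, matching the
  useful/total ratio of a national flora; use sets drawn per category from
  the national tabulation's marginals (Medicines 0.763 … Invertebrate Food
  0.037), redrawn while empty — note this conditioning inflates each
  realized marginal to p/(1 − Π(1 − p_c)), about +4% relative; ~19.7%
  point endemics, pinned to their single most-suitable cell and one fixed
  locality; Zipf-weighted families over 40 names (family 1 planted as the
  most speciose); product-Gaussian niches in (ANMT, ANP) with breadths
  8–30% of each range inside a circular geographic range.
* **Sampling**: a record draws a cell from the effort surface (uniform, or
  access-biased: weights ∝ exp(−d/λ) from k = 5 random access points with
  λ = 50 km — a road-accessibility stand-in, not an inference target),
  then a species ∝ suitability at that cell, then uniform jitter within
  the cell; planar coordinates map to WGS84 through the conic projection
  so the real cleaning/gridding path is exercised. Verbatim names are
  corrupted at rates 10% synonym / 2% misspelling / 1% unresolvable, and
  non-endemic records additionally at 0.5% (0,0) / 0.5% missing / 0.3%
  out-of-range coordinates; the generator reports exact corruption counts
  so pipeline reports can be checked against ground truth.

All randomness descends from one integer seed through named
`SeedSequence` sub-streams; equal seeds give bit-identical datasets, and
the pipeline's tables are byte-identical across reruns.

What the generator does *not* emulate: real geometry and elevation,
spatial autocorrelation of effort beyond the access-point decay,
phylogenetic structure, temporal sampling trends, and detection
differences among taxa. Passing tests therefore demonstrate correctness of
the accounting and the estimators under known conditions — not that any
particular real dataset is well sampled.

## Problem sizes and validation experiments

The test suite and the acceptance script run at deliberately modest sizes
chosen as sufficient for their statistical checks: landscapes of 15–50
cells per side, pools of 100–2,000 species, 2,500–20,000 records. The
coverage-recovery experiment uses 20 paired simulations at 5,000 records
and a 500-species pool on the default 50×50 landscape; uniform effort
yields median overlap ≈ 0.99 and exceeds the access-biased overlap in
every pair. Published-tabulation arithmetic (percentages, records:species
ratios, per-species means) is recomputed from the printed per-category and
total counts, which function as inputs. The analytic benchmark for the
overlap coefficient is the closed form for two unit-variance Gaussians one
SD apart, 2Φ(−1/2) ≈ 0.6171.

## Known limitations

* The name resolver is table-driven only; no fuzzy matching or live
  taxonomic-backbone queries.
* The cleaning rule set is a documented six-rule subset of what dedicated
  coordinate-cleaning tools offer (no sea/elevation/institution checks).
* The conic projection is spherical; for ellipsoidal-datum work supply a
  custom projection object.
* Effort KDEs treat records as independent; spatially clustered duplicate
  collections inflate effective sample size.
* Mean species richness over all cells is sensitive to unit size and
  should be read alongside the surveyed/well-surveyed means, which is why
  all three extents are always reported.
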