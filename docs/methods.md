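# Methods

## Study design

The pipeline is a cross-sectional spatial accessibility analysis. For each
intensive-care facility it computes the T-minute drive-time service area
on a road network; for each populated census-style block group it derives
an adult-ICU-beds-per-100,000-adults-served ratio from the facilities
whose service areas contain the block-group centroid; block groups are
then classified into four access levels from the ratio distribution, and
adult population is aggregated per level, stratified by race/ethnicity,
urbanization class and region. The default threshold is 60 minutes (the
"golden hour" transport convention); 30- and 90-minute runs form the
sensitivity sweep. The analysis is purely descriptive — the population is
an enumeration, not a sample — so no inferential statistics are attached.

## Travel time and catchment membership

Edges carry drive minutes `60·length_km/speed_kmh`; single-source times
are Dijkstra's algorithm on that weight (networkx). This deliberately
simplifies commercial routing engines: no turn penalties, road capacity,
stoplights or one-way streets. All comparisons in this package are between
quantities computed on the same network, so the simplification is
internally consistent; it does mean isochrones should not be expected to
match any commercial product's.

Catchment membership is evaluated directly as travel time from the
facility's nearest network node to the centroid's nearest network node,
which is equivalent to polygonizing the isochrone and testing centroid
containment but has no polygonization artifacts. Decisions fixed here:

* **Boundary rule** — travel time exactly equal to T counts as inside.
* **Snapping** — off-network points attach to the Euclidean-nearest node,
  ties broken by smallest node id; the snap leg costs zero minutes by
  default. An optional walk speed (km/h) charges both snap legs; it is off
  by default because any particular walk speed would be as arbitrary as
  zero and zero is the simplest defensible choice.
* **Centroids** — the geometric centroid of the polygon is used even when
  it falls outside the polygon; no containment correction.
* **Zero-population block groups** are excluded from catchments,
  classification and every table: there is no population there requiring
  access.

## The bed ratio

The default block-group ratio is the two-step floating catchment area
(2SFCA) form: `R_j = Σ_{i: j∈S(i)} 100000·b_i/P_i` with `P_i` the summed
adult population of facility i's catchment. Two properties recommend it:
it matches the accessibility-GIS lineage this analysis sits in, and it
conserves beds exactly (`Σ_j pop_j·R_j = 100000·Σ_i b_i` over facilities
with `P_i > 0`), giving the test suite an algebraic oracle that any
implementation error breaks. The printed description of the ratio in this
area of the literature is terse enough to admit a second reading — pool
the accessible facilities' beds over the population of the union of their
catchments — which is implemented as `variant="union_pool"` for
sensitivity comparison; the two coincide whenever a single facility covers
everything. The variant used is recorded in every output file and
manifest. Facilities serving zero population have an undefined ratio and
are dropped from sums with a logged warning, never treated as infinite.

## Access levels

Thresholds come from the covered block groups' ratios: sort, drop the top
`ceil(0.01·n)`, and take mean ± 0.5·SD of the remainder. Choices fixed
here:

* The top-1% trim applies to **both** the mean and the SD — trimming one
  moment but not the other would mix estimators incoherently.
* The SD is the unweighted sample standard deviation (ddof = 1) over
  block groups; no population weighting, matching the convention of
  computing "the mean and SD of the block-group bed ratio".
* The AVERAGE band is closed on both sides; published one-decimal band
  edges (e.g. a "19.5 / 19.6" split) are a rounding artifact, so
  classification always compares against unrounded thresholds.
* Trimmed block groups are still classified and counted (they land in
  ABOVE_AVERAGE); only their leverage on the moments is removed.
* With no facilities (or nothing reachable) there is no ratio
  distribution; the pipeline then classifies every populated block group
  as NO_ACCESS and records null thresholds rather than failing.

A distributional sanity check: for symmetric unimodal ratios the ±0.5 SD
band holds `2Φ(0.5)−1 ≈ 38.3%` of block groups, which the suite verifies
on normal draws at n = 10,000 (±5 points).

## Stratified reporting

A block group's entire population inherits its single access level; there
is no within-block-group variation. Stratifiers: race/ethnicity group,
six-level urbanization class, region, and region × race. Row counts sum
exactly to row totals for every stratifier (a partition check in the
suite), and every table's Total row equals the unstratified aggregate.
Race rows are intentionally non-additive across the population: the
Hispanic ethnicity overlaps all racial groups and untabulated
multiracial/other categories exist. Regional summary statistics (median,
IQR, min, max of per-region level percentages) use the linear-interpolation
quartile convention. Percentages are held at full precision and rounded to
one decimal only in reports; fixed-table checks round half away from zero.

## The synthetic region generator

The generator emulates the joint structure the analysis needs: urban
centers with dense block groups and facilities, a sparse uniform rural
periphery, a perturbed-grid road network (local roads at 50 km/h, highway
corridors at 90 km/h along grid paths linking the centers), six
urbanization classes assigned by density quantile, and per-group adult
counts. Defaults: 300×300 km extent, 3 urban centers, 400 block groups
(~1,300 adults each, 2% empty), 12 facilities with 2–20 beds. The bed
range is calibrated so the regional bed density sits near the published
national figure of ~26 ICU beds per 100,000 adults; the extent and
facility count make a sparse region in which roughly a fifth of the
population lies outside all 60-minute catchments — comparable to the most
rural states in published state-level ranges, and deliberately non-trivial
so that coverage, monotonicity and disparity behavior are all exercised.

`disparity_knob ∈ [0,1]` drives the race-composition gradient: block
groups are ranked by distance to the nearest facility (percentile rank
`z`), and the designated minority groups' composition weights scale as
`exp(4·knob·(z−½))` (the majority group mildly opposite). At knob 0
composition is independent of location by construction; at knob 1 the
minority no-access rate exceeds the majority's essentially always, which
is the generator-truth recovery test. The baseline composition shares are
national-census-like; the Hispanic fraction (18%) is drawn independently
of location as an overlapping ethnicity.

All positions are drawn in unit coordinates and scaled by the extent, so
a fixed seed at a growing extent yields geometrically similar regions with
proportionally longer drive times — no-access population is then
non-decreasing in the extent deterministically, which the suite sweeps.

What the generator does **not** emulate: real road topology (loops,
rivers, dead ends), spatially autocorrelated income or insurance
structure, inter-facility capacity differences beyond bed count,
population projections, or any empirical joint distribution of race and
geography — the knob is a modelling convenience, not an estimate. Passing
tests therefore demonstrate the pipeline's correctness and sensitivity,
not any statement about real populations.

## Reference-table fixtures

The published national tables this package's desk checks transcribe are
shipped as plain CSV with a provenance column (table and row). Every
printed percentage is reproducible from its printed numerator and
denominator at one-decimal rounding. One printed inconsistency exists —
the urbanization table's Total-row above-average count exceeds the
race/ethnicity table's by 13,193,807, making that row's counts (and the
urbanization N column) sum past the national adult total — and is recorded
exactly as printed with an expected-mismatch flag; no reconciliation is
attempted.

## Problem sizes and determinism

Tests and the acceptance script use compact regions (150–400 block
groups, 6–12 facilities, 100–196 network nodes) and 20-seed sweeps; the
whole suite runs in a few seconds. All randomness flows through a single
`numpy.random.default_rng(seed)` per generated region; identical
config + seed reproduces every output file byte for byte (region CSVs are
re-read with round-trip float parsing so on-disk and in-memory runs agree
exactly).

## Known limitations

Planar kilometre coordinates only — no geographic CRS handling, by
design; undirected roads; no distance-decay or capacity-constrained
(E2SFCA/gravity) accessibility; no air transport; the four-level
classifier is the only one implemented (quantile/Jenks alternatives are
out of scope). With very few facilities the 2SFCA ratio distribution is a
small set of subset sums and the ±0.5 SD band can fall between its atoms,
leaving the AVERAGE class empty — real analyses with thousands of
facilities do not exhibit this, but tiny demonstrations can.
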