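# Methods

## The accounting model

Every analysis runs on one shared raster frame (`GridSpec`): an abstract
equal-area grid, 0-based and row-major with row 0 at top, carrying a land
mask and per-cell area weights in km². `cell_area` is a scalar by default;
a full per-cell array is the escape hatch for latitude-varying cells, since
the analyses make sense on any grid whose cells carry honest areas. All
areas, shares and means in the package are area-weighted sums over cells,
and percentages are carried on the 0–100 scale throughout.

Cell membership in a polygon is decided by the **center-in-polygon** rule:
a cell belongs to a footprint iff its center lies inside. This is unbiased
as resolution increases and matches binary-mask semantics; any-overlap
membership would systematically inflate areas. Missing data in continuous
layers is NaN and is excluded from every mean and area; undefined results
(empty zones, empty templates) are flagged in output tables, never raised.

## Reserves

Reserve records arrive as tables (id, network BR/PA/OECM, centroid,
terrestrial area, designation year, attributes, optional WKT polygon).
Two exclusion rules apply at load time, each per record and independent of
ordering: a status of `proposed` drops the record, and a designation label
of `MAB` drops a record from the PA/OECM sets (such sites belong in the
biosphere-reserve network; keeping them in both would double count).
Per-rule exclusion counts are logged and returned.

A reserve without a polygon gets an **area-preserving circular buffer**:
a disc centered on its centroid with radius `r = sqrt(A/π)` in map units,
where A is the reported terrestrial area. Buffers are not clipped to land
before rasterization; coverage accounting intersects with the land mask at
counting time. After geometry resolution, buffered and polygon reserves are
treated identically everywhere. Discs use 128 buffer quadrant segments,
keeping the inscribed-polygon area deficit below 2·10⁻⁴ — negligible next
to rasterization error, which itself falls below 5% once a footprint spans
a ~20-cell diameter.

Ecosystem classing assigns each reserve the group of the biome holding the
largest area share of its footprint, with exact ties going to the lowest
biome id (deterministic); the biome→group mapping is a user-supplied table.

## Coverage and thresholds

Coverage of a stratum is the percent of its terrestrial area inside the
network mask; the uplift from recognizing BRs is the percentage-point gain
from replacing PA∪OECM with PA∪OECM∪BR, non-negative by union monotonicity.
Strata are always spatial (zone partitions), not reserve attributes, so the
rates are strictly geometric. Threshold flags use ≥ for both 17% and 30%:
a stratum sitting exactly on a target counts as meeting it.

## Templates, representativeness, overlay

Template shares are `p = area(mask ∩ land)/area(land)`. Derived hotspot
templates take, per continuous layer, the smallest set of highest-valued
land cells whose area reaches one decile of land; cells tying the threshold
value are included (≥), so the realized share can exceed 0.10 under heavy
ties — deterministic and conservative, with the realized share reported.
The quantile is area-weighted, consistent with area-share semantics
elsewhere.

Representativeness compares the percent of a template inside a network
against the network's own land share: the expected coverage under uniform
random placement. This null is exact for the synthetic worlds (verified by
Monte Carlo in the tests at ±0.5 points over 200 placements). The overlay
meta-analysis counts per cell how many of the n templates hit it, reports
land area by count, and, per template, the fraction of its area overlapping
exactly k of the other n−1.

## Rarity weights, CVI, prioritization

Weights are `wᵢ = (1/pᵢ)/Σⱼ(1/pⱼ)`; the sum is exactly 1 up to float
rounding (checked to 1e−12 against arbitrary-precision arithmetic). A zero
share makes a weight undefined: the default policy aborts naming the
template; an explicit `drop` policy excludes it and renormalizes, logged.
Per-cell CVI is the weight sum over hit templates, already in [0, 1]; the
min–max standardization over land cells is applied once (the normalization
is idempotent in the common case where some cell hits no template and some
extreme cell exists, but is applied as a single explicit step regardless).
A degenerate standardization (max = min) maps to all-0 with a loud warning
rather than NaN, so downstream binning still runs.

Province value is the **area-weighted mean** of standardized CVI over the
province's land cells. The aggregation statistic was an open design choice;
the mean is the default and a median is available in config — under
rank-based binning the two differ only when province distributions are
skewed enough to reorder ranks. Using standardized rather than raw CVI is
likewise immaterial to selection, since min–max scaling is monotone and the
bins are rank-based.

Sextile bins are rank-based: ids ranked ascending, rank r of N mapped to
bin ⌈6r/N⌉, ties broken by stable lexicographic id order and logged.
Interpolation-based empirical quantiles were rejected because they differ
from ranking exactly at ties, where they are not deterministic across
implementations. Priorities are provinces with value bin Q5–Q6 and coverage
bin Q1–Q2; the selection is invariant under any monotone transform of
either variable.

## Trends

Habitat quality is consumed as an annual 0–1 raster stack (e.g. from an
InVEST-style model); the package never recomputes it. A reserve's series
starts at `max(first stack year, designation year − 5)` — conservation
activity typically precedes formal designation — and is the area-weighted
mean over footprint cells per year. Aggregation across reserves is an
unweighted mean over reserves reporting that year (each reserve one vote,
matching per-reserve summary statistics); an area-weighted variant is a
parameter. Sub-periods default to 1992–2000 / 2001–2010 / 2011–2020 and are
configurable; each is fitted by OLS of value on year (statsmodels), with a
two-sided t-test on the slope, a 95% CI, and star labels at 0.05/0.01/0.001.
Sub-periods with fewer than 3 points are skipped with a flag; a perfect
zero-residual fit has no defined t-statistic and gets a blank star label.

## The synthetic world generator

The generator emulates the statistical structure of the global accounting
problem, scaled to desk size. Defaults (the package's study conditions):

- Grid 120×120, cell size 1 km, land fraction 0.60 by thresholding
  Gaussian-smoothed noise (correlation length 4 cells) at the exact count.
- 40 contiguous provinces, 5 regions, 6 biomes by seeded region growth
  (multi-source flood fill with randomized propagation order; disconnected
  land attaches to the nearest seed).
- Six templates with target shares BH 0.025, RE 0.30, PD 0.1286, TF 0.1447,
  BC 0.20, IL 0.25 and correlation length 3: the three published magnitudes
  are used as printed, the other three are unpublished and set once to
  plausible values in the 0.20–0.30 range (REs described as the largest,
  ILs next). Masks take the top-valued land cells of smoothed noise until
  the target area is reached, so realized shares land within one cell of
  target.
- Networks: PA 60 reserves (lognormal areas, median 20 km², σ=0.8), OECM 12
  (median 12 km²), BR 25 (median 14 km², σ=0.6), giving a PA+OECM land
  share near 16–17% and a BR share near 5%. BRs target a 0.35 overlap
  fraction with PA∪OECM (the global accounting implies roughly a third of
  BR area is already inside the official network) via rejection-resampling:
  each next center is drawn inside or outside the partner mask according to
  the running overlap tally. A target of exactly 0 enforces disjoint
  footprints and raises if placement keeps failing. 26% of BRs are emitted
  as centroid+area only (the share of BR area lacking true polygons is
  about a quarter), exercising the buffer path. Geometries mix discs and
  irregular star-convex blobs scaled exactly to their sampled area.
- Quality stacks 1992–2020: a static smooth background around 0.75
  (amplitude 0.05) plus, inside each reserve's owned cells, a continuous
  piecewise-linear path whose per-sub-period slopes are drawn
  N(mean, sd) with defaults (+1e−4, −3e−4, −4e−4) ± 5e−4 per year —
  magnitudes matching reported habitat-quality trends — plus i.i.d. N(0,
  0.01²) noise, clipped to [0, 1] (defaults keep the signal far from the
  bounds). Overlapping reserves: cells belong to the first claiming
  reserve, so later overlappers see mixed series; trend-recovery tests use
  disjoint configurations.
- Pressure: smoothed noise min–max scaled to 0–50, the Human-Footprint-like
  range.

All randomness flows from one root seed through fixed named
`SeedSequence(seed, spawn_key=(k,))` substreams, so adding a component
never perturbs the others and a fixed config is byte-identical across runs.
The generator records ground truth (realized shares, network and pairwise
overlap areas, per-reserve rasterized areas and designation years, coverage
percents, true slopes), and a dedicated test re-derives every entry by
brute-force per-cell recount.

What the generator does **not** emulate: realistic biogeography (province
shapes, latitudinal gradients, coastlines), spatial correlation between
templates and networks (real PAs are biased toward remote land),
designation-year trends in placement, and polygon topology pathologies.
Passing tests therefore certify the accounting arithmetic and its
statistical calibration, not that real-world data would yield any
particular coverage or priority set.

## Numerical choices and limitations

- Percent uplifts are clipped at 0 to suppress negative-zero float
  artifacts; union monotonicity guarantees the true value is ≥ 0.
- Problem sizes in tests: grids of 60×60 to 200×200, 20 seeds for coverage
  recounts, 200 placements per null-calibration share, 500 Monte Carlo
  replicates for trend bias/coverage — sizes at which every statistical
  tolerance is comfortably resolvable.
- Raster I/O is ESRI ASCII grid (plain text, single band, 0/1 for masks,
  nodata sentinel −9999); vectors are GeoJSON; tables CSV. There is no CRS
  or reprojection support: all layers must share one frame, and the
  per-cell area array is the hook for non-equal-area grids.
- The CLI's stage commands resume from the on-disk intermediates written by
  `simulate`; zone display names are not round-tripped through ASCII
  rasters (ids are), so stage outputs label zones by id.
- Exit codes: 2 config error, 3 data error, 4 violated internal invariant
  (cross-checks run at pipeline end: overlay counts vs the sum of template
  indicators; land-mask representativeness vs global coverage).
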