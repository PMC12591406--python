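# Methods

This note documents the models and procedures implemented in `orcasoc`,
the defaults they run under, and the reasoning behind the choices that were
genuinely open.

## Sampling units and standardization

The sampling unit is the **daily encounter**: one calendar date × one
photographed group. Multiple same-day reports of the same group are common
in multi-source sighting archives, so `consolidate_daily` processes each
date's records in ascending time order and drops a record whose individual
set is equal to — or a subset of — an already-retained record's set that
day, keeping the earliest reported location. Subset absorption (rather than
exact-duplicate matching only) is our interpretation of "one record per
group per day": a partial re-identification of a group already recorded
adds no association information and would otherwise double-count. Same-day
groups that genuinely differ (neither a subset of the other) are retained
as distinct encounters. Consolidation is idempotent and fully logged: every
dropped record is reachable through the provenance map.

Association analysis then keeps only records where every member was
identified (`all_identified`), and masks individuals seen fewer than
`min_sightings = 3` times. The count threshold is applied in a single pass;
we do not re-threshold iteratively after exclusions, because the criterion
is a flat minimum-resighting rule, not a fixed-point definition.

## Association index

Under the gambit of the group, each daily encounter contributes one joint
sighting to every pair it contains. The simple ratio index is

    SRI_ij = X_ij / (X_ij + Y_i + Y_j) = X_ij / (n_i + n_j − X_ij),

the fraction of either whale's group records in which the two were
together. The second form holds because an individual belongs to at most
one retained group per date, so the "both seen apart on the same day" cell
is structurally zero after consolidation; if upstream data violate that
assumption the matrix builder raises rather than silently folding the
excess. The diagonal is fixed to 1 purely for clustering convenience and
excluded from every statistic.

## Community delineation

* **Linkage**: UPGMA (average linkage) on the dissimilarity `d = 1 − SRI`.
  Average linkage is the standard choice for association indices in this
  literature; `1 − SRI` is the natural bounded transform of an index in
  [0, 1].
* **Fidelity**: the cophenetic correlation coefficient — the Pearson
  correlation over all unordered pairs between `1 − SRI` and the height at
  which the pair merges. We fix the dissimilarity-scale convention; the
  magnitude is unchanged under the affine flip to association scale, and
  the sign is preserved (not clipped) so a pathological tree is visible.
* **Partition**: the weighted Newman modularity
  `Q = Σ_c [w_c/W − (s_c/2W)²]` with `a_ij = SRI` off-diagonal, evaluated
  at every distinct dendrogram merge height plus the all-singletons cut.
  The search is restricted to dendrogram cuts (not free modularity
  optimization) so the partition is always a horizontal cut of the
  reported tree. Ties are broken toward fewer clusters, then toward the
  lower cut height; the full `(height, k, Q)` trace is retained so the
  choice is auditable. Note the ceiling: two balanced communities with no
  cross-weight give exactly Q = 0.5, and k equal communities 1 − 1/k, so
  Q values well above 0.5 necessarily correspond to finer partitions.

## Geospatial derivations

All raster work uses one convention: cell-center registration, 0-based
(row, col), row 0 at the north edge. Rasters are read and written as ESRI
ASCII grids, a plain-text interchange format; coordinates are planar
meters, with a local equirectangular transform for decimal-degree inputs
(adequate at regional extents; the simulator is natively planar).

* **Land/water**: land iff elevation ≥ 1 m. The threshold is applied
  exactly; the boundary value 1 m is land. NaN cells are treated as land
  (with a warning) — conservative for barrier handling.
* **Depth**: nearest-cell sampling of `max(0, −elevation)`; points falling
  on a land cell (GPS jitter near shore) snap to the nearest water cell
  within 3 cells, else error.
* **Distance to shore**: Euclidean distance to the nearest shoreline cell
  (land cells with a water 4-neighbor). Euclidean, not water-path, because
  "nearest shore" is a proximity covariate, not a route.
* **Distance to the shelf break**: a multi-source shortest path over water
  cells only, 8-connectivity with √2 diagonal cost, from all isobath
  source cells (water at/below 200 m depth adjacent to shallower water).
  This is the grid-metric analogue of GIS cost-distance accumulation
  around land barriers; it overestimates true geodesics by at most ~8%
  (the 8-connectivity anisotropy), and is validated in the tests against
  an independent Dijkstra implementation, cell-exact. The signed variant
  is negative inshore of the isobath. Water bodies disconnected from any
  isobath cell get +inf and are excluded from summaries with a warning.
* **Shelf width**: the isobath traced by marching squares on the depth
  field, resampled every 3 km of arc length; each sample's Euclidean
  distance to the nearest shoreline cell is the local width.
* **Effort**: tracklines resampled every 3 km (arc length, start
  included, last sample at the largest multiple of the spacing within the
  track), appended to sighting points, binned into a 5 km fishnet. Totals
  are conserved under fishnet origin shifts.

## MRQAP

The response (SRI) is regressed by OLS, with intercept, on dyadic
predictor matrices over all n(n−1) ordered off-diagonal dyads (the
standard network-regression vectorization; using unordered dyads would
halve the F statistic but leave coefficients unchanged). Habitat
predictors are built from per-individual covariate means as
`−|v_i − v_j|`, z-scored over off-diagonal entries, so a positive
coefficient reads "similar habitat → stronger association". Geographic
proximity enters by default as one combined matrix of minus the
great-circle distance between mean positions (a separate lat/lon pair is
available); a same-matriline indicator predictor is implemented but off by
default. Inference is QAP on the response: each replicate relabels
individuals by a fresh random permutation applied simultaneously to rows
and columns of the response, predictors fixed, and the two-tailed p-value
is `(1 + #{|β*| ≥ |β̂|}) / (1 + n_perm)` — the +1 correction avoids
reporting zero. Collinear designs (condition number > 1e8) fall back to a
pseudo-inverse fit and are flagged in the result.

A caution specific to strongly clustered systems: when one latent factor
(here, the subpopulation split) drives *all* habitat covariates, the
habitat similarity matrices are nearly collinear and the multiple
regression divides the shared signal among them with unstable partial
signs. The multiple fit remains the headline model, but the per-predictor
single-matrix QAP regressions are the stable statement that habitat
similarity predicts association, and the analysis scripts and acceptance
report include both.

## Habitat summaries and envelopes

The unit of analysis is the **identification** (one individual in one
daily encounter), matching how photo-identification studies count habitat
use; summaries report mean, SE = sd/√n, range, and n per community.
Rank-sum comparisons use midranks for ties, exact enumeration of all
C(n+m, n) rank assignments when n + m ≤ 12, and otherwise the normal
approximation with tie-corrected variance and continuity correction. Both
U and the rank-sum W are reported. Two-sided tests throughout, no
multiple-testing correction.

Envelopes are empirical `q = 0.90` quantiles with linear interpolation
between order statistics: the inner community's distance to shore and the
outer community's |signed shelf distance|. Under this interpolation rule
the distinct-value coverage lies in `(q − q/n, q + 1/n]` — within one
order statistic of q on either side, with the lower end attainable (e.g.
n = 444 gives 398.7 → coverage 399/444 = 0.8986). At the identification
level the gambit of the group additionally ties every member of a group to
one location, so coverage can deviate by up to one encounter's
identification weight. The tests assert exactly these attainable bounds.
Envelope zones label water cells inner / outer / overlap / neither; with a
narrowing shelf, overlap appears precisely where the shelf break comes
within (inner + outer) thresholds of the shore.

## The simulator

`orcasoc.synth` generates the study conditions end to end; its defaults
are the conditions under which the pipeline's recovery properties are
claimed.

* **Seascape**: 140 × 150 cells at 500 m; land along the east edge; depth
  rising linearly to 200 m at the per-row shelf-break distance, which
  narrows linearly from 50 km (north) to 12 km (south); 25 m/km slope
  beyond; optional Gaussian canyon incisions pulling the isobath
  shoreward.
* **Population**: 20 matrilines per subpopulation, sizes
  `2 + Binomial(8, 0.25)` (support 2–10, mode and mean 4), plus 10% lone
  roving males — ≈164 whales.
* **Daily fission–fusion**: present units visit a shuffled group list and
  join the first group that accepts them (acceptance `p_w = 0.35` within
  the subpopulation, `p_b = 0.001` across), else found a new group; each
  whale is in exactly one group per day, which is what makes the SRI
  denominator exact. The within rate is deliberately high: it produces the
  dense between-matriline association that makes the two-subpopulation
  cut, rather than the 40-matriline partition, the modularity maximum —
  and groups larger than typical field group sizes, a deliberate trade.
  The cross rate yields ≈1% mixed encounters.
* **Placement and detection**: inner groups draw a distance-to-shore from
  a lognormal with median 2 km (σ_log = 0.6); outer groups a signed
  shelf-break distance from N(0, 5 km); a uniformly random row then
  locates the nearest matching water cell. Detection is 0.12/day for
  groups within 10 km of shore and 0.08/day beyond — heterogeneous effort
  without starving the offshore association graph (sparser offshore
  sampling makes weakly-sampled matrilines split off as spurious
  modularity satellites). 8% of detected groups are reported twice the
  same day to exercise consolidation; 12% of encounters carry a predation
  record drawn from subpopulation-specific prey compositions.
* **Optional visitors**: matrilines present only ~2% of days can be
  enabled (`visitor_fraction`) to exercise the minimum-sightings filter;
  they are off by default because a visitor that barely clears the
  3-sighting filter carries almost no association weight and is split off
  as a satellite community, which is a property of thin data, not of the
  method.

What the simulator does **not** emulate: multi-year demography (births,
deaths, dispersal), day-to-day movement autocorrelation, preferred
companionships within subpopulations, photo-quality heterogeneity, and
tidal-datum or spheroidal-geodesy effects. Passing recovery tests
therefore demonstrate that the chain is correct and well-calibrated under
clean fission–fusion mixing with habitat-segregated communities — not that
it would resolve weaker or hierarchical real-world structure.

## Problem sizes and numerical choices

The default verification runs use the full simulated system (≈160 whales,
365 days, ≈400–450 daily encounters) — small enough for seconds-scale
runs, large enough for stable network statistics. Exactness checks run on
100 random small association instances, 30 random modularity instances,
and five random ≤50×50 barrier grids; QAP calibration uses 500 null
simulations of 30-node systems at 99 permutations. All randomness flows
from explicit integer seeds (numpy `default_rng`); dendrogram ties follow
the linkage algorithm's stable order; every simulator output embeds the
config hash in its JSON artifacts for provenance.

## Known limitations

* Distances are planar; at the ~18° latitude span of a real coastal study
  the equirectangular approximation distorts east–west distances by a few
  percent away from the reference latitude. Real analyses over large
  extents should project per region.
* The grid water-distance metric carries up to ~8% 8-connectivity bias
  relative to true continuous shortest paths.
* The modularity cut is restricted to dendrogram heights; genuinely
  non-nested community structure would require free optimization, which is
  intentionally out of scope.
* GeoTIFF rasters are not read; convert to ESRI ASCII first.
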