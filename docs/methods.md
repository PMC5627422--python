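# Methods

## The procedure

`arealink` addresses the change-of-support problem for a pair of
aggregated databases whose spatial units differ: a *medical* database
recorded on coarse units (level *p*+1) and an *ecological* database on
fine units (level 1), linked only through a chain of ID crosswalks
("transition matrices" `M_1 … M_p`). The procedure never estimates values
on units finer than they were recorded; it aggregates both sides to a
common scale and then measures what that aggregation cost.

**Direction.** Aggregation must run toward the coarser system, so the
database with the larger *median* unit surface area seeds the analysis
IDs. The median (not the mean) is used because administrative unit-area
distributions are strongly right-skewed. An exact tie of medians is
refused rather than broken arbitrarily: the caller must name the base
system explicitly.

**Equivalence situations.** Each matrix is a bipartite graph between two
ID levels. Its connected components are classified by cardinality:
one-to-one, many-to-one (plain aggregation), one-to-many (a fine unit
spans several next-level codes), many-to-many. The census emitted by
`build_mapping_table` reports link counts and percentages per pattern and
per matrix. A one-to-many split needs no special handling downstream: if
the codes reconverge to one coarse unit the composition yields a single
link; if they diverge, the overlap merge (below) fires. The cross-matrix
overlap is reported separately from the four per-matrix patterns; no
claim is made that these five categories correspond one-for-one to any
particular published taxonomy of crosswalk situations.

**Composition and overlap merge.** The chain is composed by path
existence: fine ID *e* links to coarse ID *m* iff a path through every
matrix connects them. IDs that appear as targets of `M_k` but never as
sources of `M_{k+1}` are *dangling*: their paths are dropped from the
linkage but the IDs are listed in the census — real crosswalks have gaps,
and silently losing units would corrupt the validation totals. Coarse
units sharing at least one fine unit are then merged transitively
(union-find) into analysis units. The resulting fine → analysis relation
is a total function on linked fine IDs; this is asserted by tests as the
method's defining invariant, together with idempotence (re-merging changes
nothing) and monotonicity (adding a link can merge but never split units).

Analysis IDs are the sorted member coarse IDs joined with `+`
(`m03+m07`): deterministic, collision-free, and traceable back to the
members without a lookup table.

## Aggregation rules

Count variables admit only a sum; sums over analysis units conserve the
fine-level total exactly (integer arithmetic, no reweighting). Continuous
variables and proportions admit mean, median (even member counts:
midpoint of the two central values, i.e. linear interpolation) and
weighted mean `Σ(vᵢwᵢ)/Σ(wᵢ)`; a zero total weight in a unit is an error
naming the unit, not a NaN. Missing member values are excluded from
mean-like aggregates and logged; for sums the affected analysis unit is
flagged *incomplete* instead of being silently lowered — an undercount in
one database is precisely the signal the validation step exists to
detect, so the aggregation layer must not mask it. Units present in a
table but absent from the mapping are reported, never aggregated.

## Validation statistics

For a variable shared by the two databases (matched by a semantic `tag`
in the variable metadata, ranked by completeness when several match), each
analysis unit contributes `rᵢ = 100·(ecoᵢ − medᵢ)/medᵢ` — the medical
count is the denominator. Units with a zero medical count are excluded
from the quantiles and counted in the report; they still enter the exact
totals. The summary is the median [IQR] of the signed rᵢ, with the
absolute-value version also reported, since either convention is found in
practice; quartiles use linear interpolation between order statistics
(R type 7), which the report documents because IQR endpoints depend on it.

## Spatial quality indices

**Fragmentation.** An analysis unit is fragmented when its dissolved
geometry has more than one connected part. Contiguity is rook-style: two
parts sharing only a corner point are separate fragments, because a
zero-width junction cannot be traversed without leaving the unit. GEOS
polygon unions already return corner-touching parts as separate polygons
of a MultiPolygon, so the part count is the positive-area polygon count
of the dissolved geometry. The index is the fragmented share of all
analysis units, stored at full precision and displayed at 1 decimal.
Fragmentation matters because the area centroid — the usual point
representation of an aggregated unit — can fall outside a discontinuous
unit; `centroid_containment` counts such units (boundary counts as
inside).

**Resolution decline.** The decline index is the ratio of the median unit
size (surface area in km², or inhabitants) of a candidate scale to that
of the finest unit in the initial databases. The report computes the
ratio for the analysis scale and for any configured reference units
(e.g. canton, département medians) against the same initial scale, so the
ratios are directly comparable; smaller means finer resolution. A level
measured against itself gives exactly 1.

**Geometry conventions.** Inputs are assumed already projected to a
planar CRS; areas are planar. The coordinate linear unit is declared
(`km` default, `m` supported) so areas are always reported in km².
Invalid polygons are repaired with GEOS `make_valid` on read; zero-area
geometries are rejected. Dissolve uses exact GEOS unions with no snapping
by default — the synthetic grid geometries are exact, and for real data
any slivers below ~1e-9 of a coordinate unit vanish in the positive-area
part filter.

## The synthetic geography

The generator plants, on a `grid_n × grid_n` lattice of 1 km² cells, a
three-level geography whose every downstream quantity is known:

| parameter | default | meaning |
|---|---|---|
| `grid_n` | 20 | fine units per side (400 cells) |
| `n_codes` | 40 | intermediate, postal-like code regions |
| `n_medical` | 10 | coarse medical units |
| `frac_one_to_one` | 0.10 | codes frozen as single cells (one-to-one links) |
| `frac_split` | 0.05 | cells spanning two codes of the *same* medical unit |
| `overlap_rate` | 0.10 | fraction of medical units sharing a cell with another |
| `fragmentation_rate` | 0.0 | medical units given one relocated, non-adjacent cell |
| `lambda_count` | 30 | Poisson mean events per cell |
| `undercount` | 0.06 | expected fraction of events missing medically |

Code and medical regions are grown from random seeds by
smallest-region-first expansion over edge adjacency, which guarantees
contiguity of every non-planted unit and keeps region sizes balanced, so
the fragmentation ground truth is unambiguous. Splits pick border cells
whose neighbouring code reconverges to the same medical unit (exercising
the split-then-reaggregate case without forcing a merge); overlaps pick
border cells between *different* medical units and are recorded as the
true merge partition. Fragmentation is planted by relocating into the
recipient one donor cell at Chebyshev distance ≥ 2 from the recipient's
territory (no edge or corner contact), subject to the donor unit and
donor code remaining connected — so planted fragments are detected
exactly and edge-contiguous units can never be false positives.

Counts: the ecological side records the true Poisson counts per cell; the
medical side records each cell's events thinned `Binomial(n, 1 −
undercount)` and attributed to the cell's primary medical unit. Thinning
(rather than additive noise) keeps counts integral and non-negative, and
makes the expected per-unit relative difference `u/(1−u)` — at the default
6% undercount, ≈ 6.38%, which the calibration check in the acceptance
script recovers by Monte-Carlo. With `undercount = 0` the two databases
agree exactly at any aggregate scale.

The default sizes (400 cells, 10 medical units, 20 or 50 replicate seeds
for the property checks) are large enough that every equivalence
situation occurs and small enough that the whole suite runs in seconds.

What the generator does *not* emulate: realistic unit shapes and area
skew, spatially correlated event rates, population rasters, and crosswalk
errors other than missing links. Passing tests therefore demonstrate the
correctness of the construction, aggregation and index arithmetic — not
the epidemiological quality of any particular real crosswalk.

## Numerical and design choices

* IDs are opaque strings; leading zeros survive round-trips.
* Parsing is order-invariant: link sets and tables are sets/keyed frames,
  and every writer sorts, so reruns are byte-identical.
* Median-of-areas ties in `choose_direction` raise rather than guess.
* The quartile rule (type 7) and the even-count median rule are fixed and
  documented rather than configurable, to keep reports comparable.
* All randomness flows through one integer seed per run;
  `numpy.random.default_rng` sequences derive the count stream from the
  geography stream so geography and counts can be regenerated
  independently.

## Known limitations

* Probabilistic or population-weighted crosswalks are out of scope by
  design: partial-weight splits are disaggregation.
* Geodesic areas are not computed; inputs must be projected.
* The fragmentation rule is declared (rook) rather than inferred from any
  particular GIS implementation; queen-contiguity counts would be lower.
* Validation is descriptive (median [IQR], totals); no hypothesis testing
  of the differences is performed.
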