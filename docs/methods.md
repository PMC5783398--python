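# Methods

`herdflow` implements the network-analytic toolkit used to describe a
one-year origin–destination (O-D) livestock mobility survey in a Sahelian
setting: network construction from movement records, descriptive topology,
dominant-flow (nodal-region) decomposition, temporal Jaccard dynamics with
period detection, link persistence classes, and QAP network correlation.
Because no such movement database is publicly deposited, the package ships
a first-class synthetic generator whose defaults encode the structure such
a survey year exhibits, with ground-truth labels so every downstream stage
is testable end to end.

## Data model and network construction

A movement record is one observed herd displacement: origin and
destination location ids, month (1–12), species (small ruminants, cattle,
dromedaries), head count, transport mode (foot or truck), and the activity
type at each endpoint (*zone d'élevage* — any livestock-raising place —
market, slaughterhouse, resting area). A movement is *national* when both
endpoints lie in the focal country; the flag is always re-derived from the
gazetteer at ingestion. Cleaning collapses exact full-row duplicates and
excludes records whose endpoints are absent from the gazetteer; both are
counted in a validation report, never silently dropped. Name-level fuzzy
deduplication is out of scope: the gazetteer is assumed pre-cleaned.

The annual network aggregates all records per ordered (origin,
destination) pair; a link exists as soon as one animal moved. *Frequency*
is the number of records on a link and *volume* the summed head count —
the distinction is kept throughout. Monthly snapshots are the same
construction restricted to one month; a link is active in a month iff at
least one animal moved then (no volume floor). Self-loops are dropped with
a warning, and nodes of a filtered network are exactly the endpoints of
surviving links. Networks built from a table retain their contributing
records, so filtered views are exact re-aggregations and chained filters
commute by construction.

## Descriptive topology

Degree and link-volume distributions are summarised as histograms and
fitted with a power law P(x) ∝ x^(−α). The default fit is the
Clauset-style maximum-likelihood estimator with x_min fixed at the minimum
observed value: discrete data use the exact Hurwitz-zeta likelihood
(maximised by bounded scalar search), continuous data the closed form
α = 1 + n / Σ ln(x_i / x_min). A log-log least-squares fit to the
empirical CCDF is provided for comparability with figure-style
regressions; neither method is privileged. Exponents are reported as
positive magnitudes (a figure quoting γ = −1.71 corresponds to α = 1.71).
Goodness is the Kolmogorov–Smirnov distance between empirical and fitted
tail CDFs, evaluated at unique values (the tie-correct form for discrete
data); KS > 0.1 is flagged as a poor fit. Model comparison against
alternative heavy-tailed families is a non-goal.

Clustering (transitivity) and diameter are computed on the undirected
projection, the diameter over the largest weakly connected component —
the only reading under which a single finite diameter coexists with a
directed network that is not strongly connected. Connectivity is reported
both direction-agnostically (`is_connected`: one weak component spans all
nodes) and via largest strong/weak component sizes, so the two senses of
"connected" are never conflated.

Distances are great-circle (haversine, Earth radius 6371.0088 km); the
distance profile bins movements into half-open [lo, hi) bins of 100 km by
destination activity. Flow summary tables report counts, volumes and
percentage shares per grouping cell, with a half-up integer-rounded
variant for reproducing printed tables; full precision is kept internally.
Two counting conventions coexist in such tables — raw records versus
aggregated O-D pairs — and the package exposes both (`n_movements` on
tables, `n_movements` per link on networks) rather than privileging one.

## Dominant flows and nodal regions

Outgoing links carrying at most a threshold fraction (default 20%) of
their origin's outgoing volume are pruned first — the inequality is
strict, so an equal five-way split at exactly 20% loses every link. On the
pruned network, for each node *i* the candidate is its single
largest-outflow destination *j*; the link is dominant iff *j*'s total
in-volume strictly exceeds *i*'s. Volume ties between candidate
destinations are broken toward the destination with larger in-volume,
then lexicographic id order — a deterministic rule where the method's
source is silent. Equality of in-volumes is not dominance.

Dominant links form a forest: out-degree ≤ 1 holds because each node has
one candidate, and acyclicity is structural since in-volume strictly
increases along every dominant link. Dominant nodes are parents with no
dominant outgoing link of their own; their influence areas are the trees
below them. Coverage (nodes, links, volume fraction) is measured against
the unpruned input. Whether dominance should be tested before or after
pruning is genuinely open; the implementation prunes first, matching the
order in which the procedure is usually described, and exposes
`prune=False` so the alternative is one flag away. Multi-level hierarchy
extraction beyond one parent per node is a non-goal.

## Temporal dynamics

For consecutive monthly snapshots the package computes three series: the
plain Jaccard index J = |A∩B| / |A∪B| on node sets and on link sets, and
the weighted index J′ = Σ min(w_A, w_B) / Σ max(w_A, w_B) over the link
union, absent links contributing zero weight. Both-empty arguments give 1
(two empty snapshots are identical; 0/0 is otherwise undefined). J′
reduces to J when all weights are equal, a property the tests assert. The
year is a line, not a cycle: there are 11 consecutive pairs and no
December→January wraparound.

Period detection is contiguity-constrained agglomerative clustering.
Pairwise snapshot dissimilarity is 1 minus a weighted mean of the three
Jaccard indices, with default weights (0, 0, 1) — the weighted index
alone, because the regime break expresses itself most sharply in link
volumes; cluster-pair dissimilarity is the average over cross-cluster
snapshot pairs (average linkage); only adjacent clusters may merge, the
cheapest pair first, leftmost on ties. With `n_periods` unset the cut
falls at the largest jump in the merge-cost sequence, and a jump-free
(homogeneous) year yields a single period. The dissimilarity combination
and stopping rule are declared package choices — the clustering procedure
this follows is under-specified in the literature that uses it — and all
three are parameters.

Links are classified by their count of active months: backbone (12),
frequent (7–11), intermediate (3–6), occasional (1–2). The four class
subnetworks are link-disjoint and their union reproduces the annual
network exactly, volumes included. The activity raster exports the
link × month boolean activity matrix with class annotations.

## QAP network correlation

Two networks are aligned as square weight (or binary) matrices on the
sorted union of their node sets, zero diagonal. The statistic is the
Pearson product-moment correlation over off-diagonal cells; a matrix with
zero off-diagonal variance is an error, not a NaN. Significance comes
from jointly permuting rows and columns of one matrix under uniform
random node relabellings. The p-value uses the add-one convention
p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1): never exactly zero, ties
counted toward rejection — slightly conservative relative to defining p
as the plain fraction of larger correlations, and preferred for
statistical soundness. Weighted and binary modes are both provided
(weighted default; they coincide on unit weights). The default 1000
permutations match standard practice for this test. MRQAP regression and
degree-preserving nulls are non-goals.

## Synthetic generator

The generator emulates the structure of the surveyed year rather than
fitting any real database (which is unavailable). Structure is generated
top-down so ground truth exists by construction:

1. **Locations** (default 73 national + 14 international): national points
   fall in a Mauritania-like bounding box (lon −17…−4.8, lat 14.7…27.3)
   with a southward Beta(1.2, 3.5) latitude skew; international points sit
   across the southern/eastern border, Moroccan ones north. A quarter of
   locations double as markets; every location is a *zone d'élevage*.
2. **Links** (default 150 aggregated O-D pairs): origins uniform;
   destination choice weights preferential attachment on current in-link
   count (offset 0.5), exponential distance decay exp(−d / 150 km) and a
   3× market boost. This yields heavy-tailed in-degrees (hub markets) and
   a modal movement distance in the 100–300 km band by construction, not
   calibration.
3. **Persistence classes** per link with mix (backbone 0.30, frequent
   0.25, intermediate 0.33, occasional 0.12), then active months drawn
   inside each class's defining interval. Occasional links concentrate in
   the Tabaski regime and intermediate links in the routine regime (each
   month lands in the preferred regime with probability 0.8); frequent
   links spread uniformly; backbone links take all twelve months.
4. **Records**: the year has two regimes split at month 9 — routine
   (Jan–Aug) and Tabaski-driven (Sep–Dec). Species mix, truck probability
   (0.07 vs 0.50) and market-destination probability (0.13 vs 0.64) are
   regime-specific. Each active link-month emits 1 + Poisson(1) records,
   guaranteeing the realized active-month set equals the planned one, so
   persistence classes are recoverable exactly. Head counts follow
   species-specific log-normals (μ, σ) = (5.5, 1.0) small ruminants,
   (4.5, 0.8) cattle, (3.5, 0.8) dromedaries, scaled by a monthly volume
   profile peaking April–June with a secondary September bump. Each link
   draws one latent capacity quantile per regime, shared by all its
   records in that regime: link volumes are serially correlated within a
   regime and re-scaled at the regime change, which is what makes the
   break visible to the weighted Jaccard index — mirroring how real O-D
   links carry persistent herd capacities that shift when transhumance
   halts and Tabaski trade begins.

All draws come from one seeded generator; identical (config, seed) pairs
give byte-identical tables. The convenience wrapper decorrelates the
gazetteer and movement sub-seeds through a seed sequence so either half
can be regenerated alone. Ground truth records per-link classes and
active months, the period partition, the highest-in-degree hubs, and the
realized per-regime transport/species shares.

Herd-size distributions, the distance-decay scale, the monthly volume
profile and the market fraction are *not* sourced from any dataset — they
are plausible Sahelian stand-ins chosen once. What passing recovery tests
show is therefore that the methods recover the structure the generator
plants (a two-regime year, heavy tails, class-consistent activity), not
that they would recover the parameters of any particular real survey.
Features of real data the generator does not emulate include reporting
gaps and under-coverage of northern regions, informal border crossings,
village-level name duplication, multi-stop journeys (every movement is a
single O-D displacement), and herd demography. The generator can emit
exact duplicate rows (two indistinguishable movements in the same
link-month); re-ingestion through the cleaning path collapses them, so
record counts may shrink slightly on a write/read round trip while link
structure and active months are unaffected.

## Numerical choices and degenerate inputs

- Power-law fits require ≥ 3 distinct values; the discrete MLE is searched
  on α ∈ (1, 12]; standard error is the asymptotic (α − 1)/√n.
- Probability vectors in the simulation config must sum to 1 within 1e-9.
- Empty networks: valid for component summaries (zeros) and Jaccard
  comparisons (empty vs empty is 1); errors for degree distributions,
  clustering/diameter and flow summaries, where no meaningful value exists.
- Merge-cost gaps below 1e-12 are treated as no jump (single period).
- All orderings (node iteration, tie-breaks, groupbys, exports) are sorted
  or stable, so every result is deterministic given the inputs and seed.

## Problem sizes

Default analyses use the 87-location, 150-link, ~2,300-record year.
Recovery studies run 20 seeds; QAP calibration uses 200 null replicates of
20-node networks at 99 permutations (p-value granularity 0.01, exactly
aligned with the 5% level); power-law recovery uses n = 10,000 samples per
seed. These sizes make every study reproducible on a laptop in seconds to
a couple of minutes while leaving the statistical conclusions stable
across seeds.

## Known limitations

- The nodal-region tie-break and the period-detection dissimilarity/cut
  rules are declared conventions; other defensible choices exist and are
  reachable through parameters.
- The generator's two-regime model has no finer seasonality beyond the
  monthly volume profile, and no multi-year memory.
- `filter_view` on a network requires the network to carry its records;
  networks re-imported from edge lists must be filtered at the table level.
- The QAP null permutes node labels uniformly; degree-preserving null
  models are out of scope.
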