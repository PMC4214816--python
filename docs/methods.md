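# Methods

This note documents the statistical machinery, the defaults, and the
design choices made where the methodology left room for judgement.

## Data model

All analyses run on four aligned tables keyed by sampling point: a
community matrix Y (points × species; abundance counts, dry biomass in g,
or 0/1 presence), an environmental matrix (points × descriptors), UTM
coordinates in metres, and a hierarchy table (point → site → area →
region).  Row order is canonicalised to the hierarchy's point order at
load time.  All-zero community rows (points that caught nothing) are
retained as zero vectors rather than dropped, so the hierarchy stays
aligned; the Hellinger transform maps them to zero vectors and downstream
modules treat them like any other row.  Missing species columns are an
error, never imputed.

## Environmental summarisation

Habitat descriptors measured per quadrant (four per point; litter height
five times) are reduced to one value per point.  Cover descriptors
recorded in the ordinal classes 0–5, 6–25, 26–50, 51–75, 76–95, 96–100 %
are mapped to interval midpoints before any averaging — the only numeric
reading of class data.  Basal area is C²/4π from trunk circumference C.
The central-tendency statistic is gated by a Shapiro–Wilk test: mean when
normality is not rejected, median otherwise.  The gate is applied **per
descriptor across all points**, not per point — four replicates give the
test essentially no power, so a per-point gate would be noise.  Gate
α = 0.05 (configurable).  Constant samples and samples of fewer than
three values pass as "mean" (W is undefined there and mean = median for
constants).  Descriptors measured once per point (altitude, land slope)
pass through unreduced.

## Transformations and detrending

Community matrices are Hellinger-transformed (y′ = √(y/row total)) before
every ordination, making Euclidean distance ecologically meaningful and
damping dominance by abundant species.  Composition analyses apply the
transform to the presence/absence matrix.  A linear spatial trend is
tested by RDA of the transformed matrix on the two centred coordinates,
F = (SS_fit/2)/(SS_res/(n−3)), with p from row permutations of Y; both
coordinates enter the test (df = 2).  Responses are detrended (per-column
OLS residuals on centred easting/northing, an orthogonal projection and
hence idempotent) before spatial eigenfunction analysis, so broad-scale
trend does not leak into every spatial predictor.  Environmental
predictors are standardised (zero mean, unit variance) but never
detrended: detrending is a property of the response model, and removing
trend from predictors would silently change what the fractions mean.

## Additive diversity partition

γ = α + β₁ + β₂ + β₃ for species richness and Shannon entropy in nats
(the natural-log transform of order-1 true diversity, which makes it
additive).  The lowest level is the **site** (α = unweighted mean site
diversity); β₁, β₂, β₃ are the increments to the area, region and pooled
totals.  Point-level partitioning is available behind `base_level=
"point"`, where the extra between-point-within-site increment is folded
into β₁.  Unit diversities pool abundances within units ("pooled
assemblage" convention) rather than averaging per-point entropies; means
across units are unweighted.  No randomisation null model is attached.

## Beta diversity as total variance

With s_ij the deviation of y′_ij from the species mean, SS_Total = Σs²,
BD_Total = SS_Total/(n−1), SCBD_j and LCBD_i the column and row shares.
Both share vectors sum to one and mean SCBD = 1/S identically.  LCBD
significance permutes each **raw** species column independently and
re-applies the Hellinger transform per permutation — permuting the
transformed matrix instead would break the row-sum dependence the
transform induces and distort the null.  p-values use the add-one
convention (k+1)/(nperm+1).  No multiple-testing correction by default
(a Holm option exists on the results object); the significance threshold
is 0.05, configurable.  Spearman correlations (midrank ties, two-sided p)
relate LCBD to per-point richness, abundance and biomass.

## Staggered spatial eigenvectors

Within one block of points, dbMEM/PCNM construction is: Euclidean
distance matrix D; truncation threshold t = longest edge of D's minimum
spanning tree (the smallest threshold keeping the block connected);
D* = D with entries > t replaced by 4t; principal-coordinate
decomposition of the Gower-centred −D*²/2; eigenvectors with positive
eigenvalues (> 1e−9 × the largest) kept, unit-normed, ordered by
decreasing eigenvalue, sign fixed so the first entry of noticeable
magnitude is positive.  This matches the classic PCNM recipe and was
verified against an independent implementation to 1e−9.

For a hierarchical design the blocks are the units one level above each
scale's variation target, and per-block eigenvectors are embedded at the
block's rows with zeros elsewhere ("staggered" matrix), making columns of
different blocks exactly orthogonal:

* **site scale** — one block per site over its points (within-site
  structure);
* **area scale** — one block per area over its points (between-site and
  finer structure within areas);
* **regional scale** — one block per region over its **area centroids**,
  each centroid value inherited by the area's points (between-area
  contrasts within regions).  With 2 areas per region this yields exactly
  one contrast per region.

The site-scale column count depends on within-site geometry: the
generator's 50 m transect layout gives 3 positive eigenvectors per
5-point site (the truncated distance matrix of a transect has rank > 2).
Note that a between-region difference in composition is *not* in the span
of any staggered MEM set (every column is centred within its block);
between-region structure is carried by the linear trend, which is why
detrending is tested before it is applied.

## RDA, permutation tests and variation partitioning

RDA is multivariate least squares of the column-centred Y on predictors
with intercept; R² = SS_fit/SS_total, adjusted by the Ezekiel correction.
Simple tests permute rows of Y; partial tests use reduced-model residual
permutation (permute residuals of Y on the conditioning set W, re-add the
fitted W part, recompute the partial F with residual df based on the
rank of the joint basis).  Joint and conditional fits tolerate
overlapping or nested predictor sets by dropping dependent columns and
using the effective rank (so varpart with E = S correctly returns all
variation as shared); a user-supplied rank-deficient single set remains a
hard error naming the dependent columns.

Two-set variation partitioning reports, on the adjusted scale,
a = adj(E∪S) − adj(S), c = adj(E∪S) − adj(E), b = adj(E) + adj(S) −
adj(E∪S), d = 1 − adj(E∪S); a+b+c+d = 1 by construction and b (and a or
c) may be negative.  Semipartial fractions are obtained **by subtraction
of adjusted R²s**, not by adjusting a partial R² with partial degrees of
freedom — under this convention the pure fraction of one set exceeds its
marginal fit whenever the other set's adjusted R² is negative, which is
the behaviour expected for weak spatial models at fine scales.  The
alternative is available by reading the fits directly.

Forward selection implements the double stopping criterion: a global test
of all candidates gates the procedure (no selection if p > α); candidates
then enter greedily by added R², each gated by its partial permutation
test, and selection stops once the cumulative adjusted R² reaches the
global model's adjusted R².  The candidate that crosses the adjusted-R²
threshold is retained and selection stops *after* it: at that point the
race between cumulative and global adjusted R² is a statistical tie, and
rejecting the crossing variable would drop genuinely informative
predictors about half the time (verified by the planted-predictor
experiments); retention preserves the criterion's purpose — no selection
can explain more than the global model plus one step — while keeping
recovery high.  In the pipeline, environmental selection is run once on
the full dataset and reused at every scale; spatial selection is per
scale, and when the global spatial test fails the **full** spatial model's
statistics are reported (its negative adjusted R² is informative).
Defaults: 999 permutations, α = 0.05.

## Synthetic metacommunities

The generator emulates a nested mainland–island design: 2 regions ×
2 areas × 5 sites × 5 points (100 points), regions 40 km apart, areas
~15 km from their region centre, sites ~1–2 km from their area centre,
points on a 50 m transect with 2.5 m placement jitter (GPS/field error;
it also keeps within-site distances ≥ half the nominal spacing).
Environmental descriptors (20) are a linear coordinate trend plus
region/area/site block effects plus noise, with realized variance
fractions recorded as ground truth.  Scenarios: **sorting** (Gaussian
niche response of each species to the first environmental variable,
breadth 1 sd), **dispersal** (nested species pools: species confined to
one region or area regardless of environment; 10 region-exclusive
species by default, matching a mainland–island split of 5 + 5 with 11
shared), **mixed** (both — the default, mirroring the field system), and
**null** (constant expectation).  Counts are negative-binomial
(dispersion 2; Poisson is the large-dispersion limit) scaled to an
expected total catch of 3 000 individuals; biomass = counts × lognormal
species mass (median 0.05 g, σ = 1) × lognormal measurement jitter
(CV 0.2), mirroring how biomass is obtained by weighing the individuals
caught.  Everything is bit-reproducible for a given seed.

What the generator does **not** emulate: temporal dynamics, source–sink
mass effects beyond pool masking, species interactions, and the
irregular, terrain-constrained geometry of real sites.  Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability of planted structure, not field realism.

## Problem sizes and numerical choices

The test suite and the acceptance script use these problem sizes, chosen
to make the Monte-Carlo bands tight enough to be meaningful while the
whole suite stays fast: 500 null replicates at nperm = 99 for
permutation-test calibration (binomial ±2 pp band at α = 0.05), 200
replicates for the trend test, 100 for the LCBD test, 20 replicates for
planted-predictor recovery, 50 per scenario for process recovery.
Degenerate inputs: constant community matrices are an error ("no beta
diversity"); coincident points within a spatial block are an error;
collinear or constant coordinates cannot be detrended and error;
conditional sums of squares below 1e−12 of the total are clamped to
exactly zero so that an X nested in its conditioning set yields F = 0 and
p = 1 rather than noise-driven p-values.  Eigenvectors are re-centred
after decomposition (floating error otherwise scales with km-sized
coordinates) and MST ties are irrelevant to the truncation threshold
(all minimum spanning trees share one edge-weight multiset).

## Known limitations

* The area-scale block geometry (points vs site centroids as embedded
  units) is a genuine design fork; the point-based construction is
  implemented, so MEM numbering at that scale need not match outputs of
  other staggered-matrix implementations.
* Shannon partitioning uses pooled assemblages; an abundance-weighted or
  per-point-averaged convention would give slightly different β values
  in unbalanced designs.
* Reported semipartial fractions are subtraction-based (see above);
  testwise-adjusted conventions will differ whenever predictor sets are
  far from orthogonal.
* The LCBD column-permutation null tests random, independent species
  placement; it is not a test against spatially autocorrelated nulls.
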