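# Methods

`spscan` detects Simpson's paradox — the reversal of an association's
direction when data are split into (or pooled over) subgroups — in two
data regimes: stratified 2×2 count tables, and bivariate continuous data
where the subgroups may be latent.

## Stratified 2×2 tables

A stratum is a 2×2 table of two groups (rows) by success/failure
(columns). Amalgamation sums strata cell-wise; it conserves every cell
total exactly. The association sign in a table is the sign of the
difference in success proportions, `p1 − p2`, evaluated exactly through
the integer cross-product `n11·n22 − n12·n21` so count tables never
produce floating-point ties.

Independence within a table is tested with the Pearson chi-square
statistic on 1 degree of freedom. For 2×2 tables the Yates continuity
correction (subtract 0.5 from `|O − E|`, floored at 0, before squaring)
is applied by default and can be disabled (`--no-yates`). The corrected
statistic is never larger than the raw one.

The conditional-independence scan tests the amalgamated table and every
stratum, then classifies:

- **full reversal** — the aggregate sign is nonzero and *every* testable
  stratum's sign opposes it;
- **partial** — at least one but not all strata oppose a nonzero
  aggregate sign;
- **none** — otherwise.

Classification uses signs only; a separate `significant_reversal` flag
additionally requires the aggregate test and every opposing stratum's
test to reach the chosen α (default 0.05). Strata with a zero row or
column margin are undefined for the test; they are excluded from the
vote and listed as untestable rather than failing the scan — a
robustness choice for sparse real tables.

`pooled_rate` exposes the same phenomenon for simple success/trial
records: the pooled rate is the trials-weighted mean of per-stratum
rates, so a unit can lead in every stratum yet trail overall whenever
the strata sizes differ enough.

## Bivariate regression and the heteroscedasticity screen

All fits are ordinary least squares of y on x with an intercept
(closed-form; n ≥ 3 and non-constant x required). The fit reports slope,
intercept, slope standard error, Pearson r with n−2 degrees of freedom,
and the slope t-test p-value.

Pooled data containing subgroups with different slopes often shows
residual variance that grows along x, so a Breusch–Pagan test is offered
as a cheap warning marker: squared residuals are regressed on x and the
LM statistic referred to χ²(1). The default is the studentized (Koenker)
form `n·R²`, robust to non-normal errors; the original normality-based
scaling is available behind a flag. The screen is one-directional:
equal-mean clusters with opposite slopes are heteroscedasticity-free yet
still reverse, which is exactly why the pipeline below does not rely on
it.

## Mixture clustering and model selection

Latent subgroups are modeled as a K-component Gaussian mixture with
unconstrained full covariance per component (one family, not the full
catalogue of constrained parameterizations; a shared-covariance flag is
provided). EM details:

- **Initialization**: `restarts` (default 10) k-means-seeded starts;
  the start with the best final log-likelihood wins.
- **Convergence**: successive log-likelihood gain < `tol` (default
  1e-6, absolute), capped at `max_iter` = 500 iterations.
- **Regularization**: each M-step covariance receives a ridge
  `1e-6·(trace/d)·I`, preventing singular collapse onto tight clusters.
- **Monotonicity guard**: EM is monotone by construction, so the
  per-iteration log-likelihood trajectory is retained and any decrease
  beyond 1e-8 raises an error instead of returning a silently broken
  fit.
- K = 1 is computed in closed form (sample mean, ML covariance).

Model selection minimizes `BIC(K) = −2·loglik + p·ln(n)` with
`p = (K−1) + Kd + K·d(d+1)/2` over K = 1..`k_max` (default 5), ties
toward smaller K. The same machinery runs on d-dimensional external
covariate blocks (`cluster_features`), whose labels then act as a
manifest grouping of the (x, y) sample.

Known behavior of BIC selection: the chosen K tends to grow with sample
size and under non-Gaussian clusters; every report carries a fixed
caveat to that effect, and the homogeneous-null tests quantify the false
alarm rate only under the generator's Gaussian conditions.

## The three-stage detection pipeline

1. **Cluster**: latent (mixture on the (x, y) plane), manifest (supplied
   group labels, or subject ids for repeated-measures data), or
   feature-based (mixture on covariates).
2. **Regress**: OLS in the pooled sample and in every cluster with at
   least `min_cluster_size` (default 10) observations; smaller clusters
   are reported as skipped.
3. **Compare**: each cluster's slope is referred to a *size-matched
   permutation null* — `B` (default 1000) slopes of uniformly random
   subsets of exactly the cluster's size, drawn without replacement from
   the full sample. The two-sided p-value is

       p = (1 + #{b*: |b* − β_group| ≥ |β_cluster − β_group|}) / (B + 1),

   with the add-one keeping p ≥ 1/(B+1). A significant cluster yields
   the deviation warning; if its slope sign additionally opposes a
   nonzero group slope sign, the sign-reversal warning is emitted
   instead (one warning line per significant cluster). Warning strings
   are fixed templates rendered byte-for-byte; clusters are numbered
   1..K by descending size.

The size-matched-subset null was a genuinely open design point: it
directly encodes both constraints the comparison must respect — a
cluster is a dependent subset of the full dataset, and clusters of
different sizes must face size-appropriate reference distributions. An
alternative (scaling by analytic standard errors) would ignore the
dependency; permuting labels within clusters would not size-correct.
The subset scheme is the simplest mechanism satisfying both and is
calibrated: on random splits of homogeneous data the rejection rate at
α = 0.05 sits at the nominal level (checked over 500 replications).
Subsets need only two points with distinct x to define a slope, so
subset sizes from 2 are accepted; draws with constant x are redrawn and
counted. The compared statistic is the raw OLS slope; r is reported but
not tested.

All randomness — k-means restarts, permutation draws, per-cluster
sub-seeds — derives from one mandatory integer seed via a seed sequence,
so reports are bit-identical across runs at a fixed seed.

## Synthetic archetypes

The generator emulates the canonical reversal layouts as Gaussian
clusters in arbitrary units. Each unit (cluster or subject) has a
centroid; centroids are spaced `separation` noise-SDs apart (default 8)
along a diagonal with slope sign `group_slope_sign`; within a unit,
x ~ N(centroid_x, 1.2) and y = centroid_y + `within_slope`·(x −
centroid_x) + N(0, `noise_sd`). Archetypes: `two_cluster` (default 2 ×
100 points), `k_cluster` (3 units), `within_person` (10 subjects × 20
observations with subject ids), `orthogonal` (equal-mean units with
slopes ±|within_slope|), `homogeneous` (single unit, the null control).

Gaussian within-unit x is a deliberate choice: it makes each unit an
elliptical cluster — the shape the mixture model assumes and the
classical scatterplots depict — and makes the homogeneous null exactly
one bivariate Gaussian. With uniform x each unit is a stripe that BIC
legitimately describes with several Gaussian pieces, which measures
model misspecification rather than subgroup structure.

What the generator does *not* emulate: heavy tails, outliers, unequal
cluster sizes or noise levels, nonlinear within-unit trends, and
measurement error in x. Passing tests therefore demonstrate correct
behavior under idealized elliptical-cluster conditions, not robustness
on arbitrary real data.

## Random-table prevalence study

How often does full reversal arise by chance? A random 2×2×2 table is 8
cell probabilities drawn from the symmetric Dirichlet (concentration 1 =
uniform on the simplex), split into two strata. A draw counts as a full
reversal when both strata's association signs are strictly opposite to a
strictly nonzero amalgamated sign (ties, a measure-zero event, count as
no reversal). Under the uniform distribution the prevalence is 1/60 ≈
1.67%; the Monte-Carlo estimator reports the fraction with its binomial
standard error and is consistent with 1/60 within 3 SE at 10⁶ draws
(about two seconds, processed in constant-memory chunks). Probability
tables, not sampled integer tables, are classified — the 1/60 value is a
distribution-level statement.

## Numerical conventions and edge cases

- Association signs on tables: exact cross-product comparison, never
  float subtraction of proportions.
- Degenerate inputs raise typed errors: zero-margin tables
  (`DegenerateMarginError`), constant x or n < 3
  (`DataError`/`InsufficientDataError`), perfect fits for the
  Breusch–Pagan test, non-finite inputs to clustering.
- Posterior ties in hard assignment go to the lowest component index.
- BIC ties go to smaller K.
- JSON reports carry full double precision; the text view rounds to
  2 decimal places.

## Problem sizes used in the validation suite

Calibration and recovery checks run at the generator defaults above:
100-seed loops for warning emission and K recovery, 500 replications for
the type-I rate of the permutation comparison, 10⁶ draws for the
prevalence study, and exhaustive subset enumeration on n ≤ 7 fixtures as
the permutation oracle.

## Known limitations

- One covariance family; no factor-mixture or latent-profile models.
- The heteroscedasticity screen's printed-value behavior on real
  datasets depends on which Breusch–Pagan variant is chosen.
- No causal adjudication: the scan flags structure, it cannot decide
  whether conditioning on it is licit — that requires background
  knowledge about the third variable, and every report says so.
- K×M tables beyond 2×2 strata, Mantel–Haenszel pooling, and exact
  tests are out of scope.
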