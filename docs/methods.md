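# Methods

`reefrestore` implements a quantitative audit of global coral-reef
restoration as a reproducible pipeline.  This note documents the models
and procedures, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, the numerical
choices, and the known limitations.

## The problem and the data model

Reef localities are 0.5° × 0.5° grid cells.  Each cell carries:

* **gravity** — an accessibility/pressure index (population of nearby
  settlements divided by squared travel time, summed within 500 km);
  dimensionless, heavy-tailed.
* **remoteness** — log-transformed travel time (minutes) to the nearest
  large human settlement.
* **cumulative impact** (mean and 2003–2013-style trend) — summed
  standardized intensity of 14 anthropogenic and climatic stressors.
* **coral richness** — local coral species count.
* **alert history** — annual counts of severe bleaching-alert events
  (NOAA-style level I: daily heat stress > 1 °C with DHW 4–8 °C-weeks;
  level II: DHW ≥ 8 °C-weeks) for 1986–2021.
* **projected DHW** — annual maximum degree-heating-weeks for
  2015–2100 under an intermediate (SSP2-4.5-style) warming pathway.

Restoration actions are records with a locality, a year, four technique
flags (coral gardening, direct transplantation, artificial reefs,
larval enhancement), the number of coral genera used, a monitoring
duration (months), and the observed percent survival of monitored
colonies.

## Stage 1 — where restoration happens

A boosted-regression-tree classifier predicts the binary restored flag
from gravity, remoteness, impact mean/trend, coral richness, and the
mean and ordinary-least-squares trend of severe-alert counts in the
five years preceding a reference year.  For restored localities the
reference year is the (earliest) restoration year; for non-restored
localities it defaults to the median restoration year of the record set
(configurable) — the choice matters little because alert climatology is
stationary in the generator.

Because restoration status is spatially autocorrelated, each replicate
runs on a spatially independent subset: greedy thinning that visits
localities in a seeded random order and keeps one only if it is
strictly more than 150 km (haversine, Earth radius 6,371 km) from every
locality already kept, validated with join-count statistics on a
distance-band neighbour graph (band = 2 × the thinning threshold by
default).  Subsets in which any same-class join count departs from the
random-labelling expectation at α = 0.05 are discarded and redrawn.

Each accepted subset is split 80/20 stratified by class; training
observations are weighted inversely to their class prevalence
(normalized to mean 1) so the rare restored class is not swamped.  The
tree ensemble uses bernoulli deviance, row subsampling at the bag
fraction, depth-limited trees and shrinkage; the tree count is chosen
by minimizing mean out-of-fold deviance along the staged ensemble over
a grid (50–10,000 in steps of ten by default; ties go to the smallest
count).  Test-set probabilities are thresholded at the value in
{0.001, …, 0.900} maximizing the true skill statistic
(TSS = sensitivity + specificity − 1; smallest threshold on ties), and
the replicate reports TSS and false-positive/negative rates.
Aggregates are means ± s.d. over replicates (1,000 by default; scaled
runs use fewer).  A full-data model with the reference
parameterization (learning rate 0.001, bag fraction 0.5, tree
complexity 3) supplies relative influence (improvement-based
importance, normalized to 100%) and partial-dependence curves.

Partial dependence clamps one variable to each grid value and averages
predictions over the training rows.  The grid is placed at empirical
quantiles (including the observed extremes) rather than equal spacing:
for heavy-tailed covariates such as gravity an equally spaced grid puts
almost all its points in the data-sparse tail, where tree ensembles are
flat and noisy.

## Stage 2 — is short-term success predictable?

Observed survival is standardized against the survival expected at the
same monitoring time from a calibrated decay curve

    S_e(t) = a + (100 − a)·exp(−k·t),   S_e(0) = 100,

reflecting high early post-transplant mortality that declines as
colonies grow; the asymptote a keeps S_e bounded away from zero at long
monitoring times (monitoring ranges over 0.8–144 months, and an
asymptote-free curve would make the success statistic explode at the
long end).  The standardized success statistic is

    S_r = ln(1 + 100 − (S_e − S_o)/S_e · 100) = ln(1 + 100·S_o/S_e),

so S_r = 0 for total mortality and S_r = ln 101 ≈ 4.6151 when observed
equals expected.  Observed survival above 100% (fragmentation,
overgrowth) is allowed up to a configurable cap (default 120%).

The default curve is fitted by least squares to a **synthetic stand-in
calibration point set** shipped as package data
(`data/synthetic_decay_calibration.csv`, generated from a = 20%,
k = 0.08 month⁻¹ with small jitter).  Real-data analyses must supply
their own empirical calibration points; the fitting routine accepts any
(months, survival) table with ≥ 3 points.

The success model regresses S_r on the four technique flags, number of
genera, gravity, remoteness, impact mean/trend, coral richness and the
severe-alert event counts in the five years before and after the
restoration (the restoration year itself belongs to the pre window;
the post window is strictly after — an unambiguous partition).  Each
replicate deduplicates sites at a 1 km thinning threshold, screens the
subset with Moran's I under inverse-distance weights (retained when
P > 0.05), splits 80/20, fits a squared-error boosted-tree model
(reference parameterization: learning rate 0.001, bag fraction 0.7,
tree complexity 5) and scores the squared Pearson correlation of
predicted versus observed S_r on the test split.  When the mean
cross-validated R² falls below 0.05 the variable-importance report is
suppressed with an explanatory message, because importance rankings
from a model with no predictive skill are misleading; the comparison is
strict (< 0.05), so a mean of exactly 0.05 is reported.

## Stage 3 — thermal exposure

Past exposure distinguishes event-years (years with ≥ 1 event at the
given severity or worse — used for "exposed at least once" fractions)
from event counts (multiplicity kept — used for mean-events
statistics).  The restored-versus-control comparison is rolling: for
each target year, localities restored in the five preceding years are
"restored" and all others are controls, so the two groups partition the
locality set every year; yearly exposed fractions are aggregated in
5-year bins labelled by the upper boundary (1990 = 1986–1990), with
mean ± s.d. over the member years and undefined years (empty restored
group) excluded and counted.  The per-locality post-restoration window
excludes the restoration year (consistent with the success model's
window partition) and is clipped to data coverage.

Future exposure reduces each locality's annual-max DHW series
(2015–2100) to the number of years at or **above** 20 °C-weeks — an
inclusive comparison, tested at the boundary — and the first such year.
Twenty °C-weeks is used as a mass-mortality proxy (near-complete
mortality of > 80% of corals expected).  Group summaries (restored vs
other) report the fraction with ≥ 1 exceedance and the mean ± s.d. of
counts and first years.

## Cost extrapolation

Total cost is per-hectare cost × area, linear through the origin, for
low/median/high per-hectare bounds per technique.  Published
per-hectare estimates (Bayraktarov et al. 2016, PLoS ONE) span
~US$6,000 to US$143 million.  Restoring 10% of the ~11,700 km² of reef
degraded over 2009–2018 means 117,000 ha (1 km² = 100 ha), giving
~US$16.7 trillion at the upper bound and ~US$3.3 billion at the bundled
coral-gardening median (US$28,200/ha).  The per-technique table is a
**synthetic stand-in** anchored to those grand bounds
(`data/synthetic_cost_schemes.csv`): editable package data, not an
authoritative cost survey.  Taxonomic coverage is the per-record ratio
of genera used to local coral richness, averaged and reported as a
percentage, with zero-richness localities excluded and logged.

## Spatial statistics

Join-count statistics and Moran's I use the classical randomization
(non-free sampling) moments of Cliff & Ord: labels are held fixed and
permuted over positions.  For join counts the same-class count of each
class is compared with its permutation expectation and variance (edge
count, shared-vertex edge pairs and disjoint edge pairs weighted by
falling-factorial label-draw probabilities); a pooled cross-class row
is reported as well, and acceptance in the subset sampler is keyed to
the same-class rows.  P-values are two-sided normal approximations;
both tests also expose Monte-Carlo permutation p-values, which the test
suite uses as independent oracles.  On small neighbour graphs the join
count is visibly discrete, so analytic and permutation p-values are
compared on the mid-p scale (half weight on ties); agreement is typically
within 0.05.  Single-class labellings return a flagged degenerate
result rather than an error.  Moran's I row-standardizes the weight
matrix (isolated rows stay zero) and uses the standard randomization
variance with the kurtosis correction.

## The synthetic-data generator

The generator produces worlds with known, configurable structure:

* **Grid**: unique 0.5° cells sampled within a latitude band (default
  ±32°, the reef belt).  Covariates: gravity log-normal (heavy-tailed),
  remoteness truncated normal on log-minutes, impact mean gamma, impact
  trend normal, richness Poisson (mean 250).
* **Restoration status**: Bernoulli draws from a logistic model whose
  linear predictor combines standardized covariates (planted
  coefficients: gravity +1.2, remoteness −0.8, impact mean +0.5,
  richness −0.3 by default) and a spatially autocorrelated Gaussian
  random field with exponential covariance over great-circle distance
  (default range 300 km, s.d. 1) — the simplest mechanism giving
  tunable label clustering for the join-count machinery to detect.  The
  intercept is solved numerically so the expected prevalence matches
  the configured restored fraction (default 6.5%, ≈ 250 restored of
  3,900, mirroring the global audit's proportions).
* **Records**: one or more per restored locality; monitoring durations
  log-normal, clipped to 0.8–144 months; observed survival is the decay
  expectation times exp(technique effects + N(0, σ)) with σ = 0.35 by
  default, capped at 120% (multiplicative log-normal noise keeps
  survival positive and right-skewed; the cap keeps S_r finite).
* **Alert histories**: independent Poisson event counts per year
  (level I rate 0.20/yr, level II 0.07/yr).
* **DHW projections**: baseline (2 °C-weeks) + per-locality linear
  warming trend (mean 0.30, s.d. 0.08 °C-weeks yr⁻¹) + N(0, 1.5) noise,
  truncated at zero.  Under these defaults ~90% of localities cross
  20 °C-weeks by 2100 with first exceedance around 2070 and ~24
  exceedance years — the qualitative regime of intermediate-pathway
  projections.

The covariate distributions are pragmatic choices (the empirical
distributions of gravity/remoteness/impact are not published as
parametric forms); what the generator guarantees is the *structure* the
analyses assume — covariate-driven, spatially clustered site selection;
decay-curve-consistent survival; stationary alert climatology; trending
DHW.  It does **not** emulate coastline geometry, spatially correlated
climate fields (alerts and DHW noise are independent across
localities), reporting biases in monitoring databases, or per-stressor
impact layers (one cumulative impact mean + trend stands in for the 12
impact variables of real analyses; a per-stressor option is a
documented extension point).  Passing tests therefore demonstrate that
the *methods* behave correctly on data with the assumed structure, not
that real restoration data satisfy those assumptions.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning, so identical configurations
reproduce identical tables bit for bit.

## Numerical choices

* Bernoulli deviance: −2·Σ w·[y·log p + (1−y)·log(1−p)], probabilities
  clipped to [10⁻¹², 1−10⁻¹²].
* Tree-count ties → smallest count; TSS-threshold ties → smallest
  threshold; both deterministic.
* Thinning keeps a pair only at strictly greater than the threshold
  distance; the iteration order is the seeded random permutation (no
  distance-based tie-breaking is needed).
* The decay-curve fit is bounded least squares (k ≥ 0, 0 ≤ a < 100);
  an all-100% point set short-circuits to the no-mortality limit k = 0.
* Degenerate inputs fail loudly (empty locality tables, single-class
  responses, constant values for Moran's I, zero-variance features in
  the collinearity screen are flagged as undefined rather than crashing).

## Problem sizes for tests and benchmarks

The reference experiments in `reefrestore.benchmarks` (used by the
acceptance tests and `scripts/acceptance.py`) scale the analyses so a
full run takes minutes on one core, as the package's own choice of
benchmark size: null calibration uses a 4,000-cell balanced grid with
12 replicates, thinning just above the grid spacing (60 km, so test
splits stay large while rethinning attempts still vary) and a reduced
tree grid (50–300, learning rate 0.01);
planted-truth recovery uses 1,200 cells, 12% restored, 50 replicate
subsets; type-I calibration uses 500 simulated null datasets for each
spatial test.  Replicate counts and tree grids revert to the full
defaults (1,000 replicates, 50–10,000 trees, learning rate 0.001) when
the corresponding analysis configs are used unchanged.

## Known limitations

* The default decay curve and the per-technique cost table are labelled
  synthetic stand-ins; headline conclusions about real reefs require
  the real calibration curve and cost survey.
* The TSS threshold is optimized on the evaluation split (mirroring the
  audited procedure), which inflates skill estimates when test sets are
  small; the null-calibration benchmark quantifies this optimism and
  keeps it below 0.05 TSS at its problem size.
* Join-count p-values are normal approximations of a discrete statistic
  and are conservative/liberal by up to a few percent on small graphs;
  the permutation option is available where that matters.
* The generator's alert and DHW series are independent across
  localities, so spatial uncertainty in group-level exposure summaries
  is understated relative to real, spatially coherent climate fields.
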