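# Methods

This note records the models, estimators and numerical choices behind
`asna`, and what the synthetic generators do and do not emulate.

## Data model

The observation substrate is the group-by-individual (GBI) matrix: one
binary row per observed group, one column per individual, with per-row
metadata (sampling period, optional timestamp and location). Under the
gambit of the group, all members of an observed group are associating at
that moment. Every derived matrix and attribute table is aligned to a single
immutable registry of individual labels (first-seen order by default,
overridable by an explicit roster); all outputs are keyed by label, never by
bare index. Self-edges are unused: nonzero diagonals in inputs are zeroed
with a warning.

## Association indices

Sampling units default to *period unions*: all group rows sharing a period
label form one unit, and a dyad is "together" in the unit if it shared at
least one group. The alternative `per-row` mode treats each group record as
its own unit (appropriate for instantaneous group records). From the tallies
x, y_AB, y_A, y_B the simple ratio index is x/(x+y_AB+y_A+y_B) and the
half-weight index x/(x+y_AB+(y_A+y_B)/2); HWI ≥ SRI always, with equality
when no solo sightings occur. Dyads with a zero denominator (one member
never identified) are stored as weight 0 and flagged in a boolean mask so
that statistics can include or exclude them explicitly — both conventions
are used in practice and they change the CV, so the choice is surfaced
rather than hidden.

Generalized affiliation indices regress the association data on structural
predictor matrices and keep the residuals. The default family is binomial
(x successes of d trials, deviance residuals), since association counts are
bounded counts; identity-link least squares is available for precomputed
edge values. Predictors that are constant across dyads are absorbed by the
intercept; genuinely collinear predictor sets are rejected with the
offending names.

Thresholding (binarize or prune above a cut) uses a strictly-greater
comparison, and always logs a warning: removing weak edges inflates both
error types and is recommended only for display.

## Metrics

Degree counts nonzero edges, strength sums weights (equal on 0/1 networks).
Weighted betweenness converts weight w to distance 1/w (stronger edge =
shorter path); the transform is configurable since no canonical weighted
path length exists for association data. Eigenvector centrality is the
principal eigenvector of the weight matrix, computed per connected component
(with a warning when disconnected) and scaled to max 1; PageRank sums to 1.
Transitivity is the standard global clustering coefficient
3·triangles/connected-triples; a literal closed-over-open triad ratio (not
bounded by 1) is exposed as an alternative. Weighted assortativity is the
edge-weight-weighted Pearson correlation of endpoint values (numeric) or
Newman's coefficient on the weighted mixing matrix (categorical). Community
detection wraps igraph's leading-eigenvector modularity algorithm, the
method most commonly applied to animal social networks.

## Null models

Node-label permutations shuffle one attribute column, preserving the value
multiset — a weak null that assumes the observed network is the true one.

Data-stream permutations randomize the observations themselves: a
checkerboard swap picks two group rows in the same stratum and two
individuals with pattern [[1,0],[0,1]] and flips it, conserving exactly
every group size, every individual's sighting count, every stratum total,
and (when strata include the period) the per-period identification
patterns — hence also both association-index denominators. Strata are the
cross-product of the named metadata keys (period × location by default for
the simulation studies); a named key with no data collapses to a single
stratum with a warning, so constraints are always opt-in. Proposals without
a valid checkerboard are resampled without being counted; 10⁶ consecutive
rejections raise a constraint-saturation error.

The chain is sequential, so successive replicates are serially correlated.
`PermutationConfig` defaults to recording after every swap following a
1000-swap burn-in (the classic sequential design). For calibrated p-values
the statistic must decorrelate between records: on the simulation-study
data (40 individuals × 100 periods, ~3800 memberships) the lag-1
autocorrelation of a model coefficient is still ≈0.8 at 100-swap spacing,
so the simulation-study analyses here use burn_in=2000 and
swaps_per_step=1000. A numba-compiled kernel (`asna/_fastswap.py`) makes
this cheap (~1 µs per swap) and is verified against the pure-Python sampler
and against from-scratch tallies; a pure-Python path remains as fallback.

## Hypothesis tests

All permutation p-values follow the proportion-of-extremes rule
(#extreme/n); an add-one variant ((1+#)/(1+n)), the exact Monte Carlo
convention, is available as a flag and used in the calibration-sensitive
acceptance analyses. Tails default to upper for the CV and coefficient
tests; two-sided compares absolute values.

*CV test.* The coefficient of variation (population sd / mean) of the dyadic
index values is compared with its distribution over data-stream-randomized
data sets; small p means more preferred/avoided structure than random. The
observed and null-mean CV are reported together as the effect size.

*Permutation-corrected coefficients.* A Gaussian linear model with optional
single random intercept is fitted by profiled REML (`asna/lmm.py`): the
variance ratio λ = σ²_u/σ²_e is profiled with per-group Sherman–Morrison
blocks, making one refit cost O(k p²) plus a 1-D bounded minimization. The
fitter matches statsmodels MixedLM (REML) to ~4 decimals on the same data
(asserted in tests) and degrades to OLS when λ̂ hits zero. For each
randomized data set the network, metric and model are recomputed and the
focal coefficient recorded. The naive model t-statistic is reported
alongside: under class-dependent detection bias it is grossly inflated while
the permutation p stays near its nominal level, because the swaps preserve
each class's observation deficit. A caveat worth knowing: because margin-
preserving swaps cannot reproduce between-dataset variance arising from
individual heterogeneity (e.g. chance correlations between an attribute and
gregariousness expressed through group sizes), the test retains a small
type-I inflation (measured ≈6–7% at α=0.05 under the detection-bias null
here). This is a property of the method, not of the implementation.

*Mantel / MRQAP.* Mantel correlates corresponding off-diagonal elements
(Pearson or Spearman) with rows+columns of the second matrix permuted
jointly; exhaustive enumeration is available for small matrices. MRQAP uses
double-semi-partialling: the focal predictor is residualized on the others,
the residual matrix is node-relabel-permuted and substituted back, and the
focal coefficient re-estimated; partial correlations are the effect sizes.

*Lagged association rate.* g(τ) sums, over ordered period pairs a lag τ
apart, dyads together at both times, divided by dyads together at the first
time whose members were both identified at the second — the conditional
probability that an association survives a lag. Lag bins are user-specified
(log-spaced default); empty bins are masked. The random-grouping baseline is
(mean group size − 1)/(N − 1).

*Precision.* Bootstrap intervals resample sampling periods with replacement
(each draw is a distinct unit) and take percentile intervals of the
recomputed metric; degenerate resamples are redrawn and counted. Split-half
repeatability builds networks from disjoint period subsets (odd–even or
first–second) and reports the Spearman correlation of node metrics.

## Sampling power

True dyadic association probabilities are modelled as gamma with mean 0.05
and CV S (gamma is non-negative and parameterizes the CV directly); values
above 1 are clipped, and a combination forcing >10% of the mass to clip is
rejected. Each dyad is sampled binomially over d = H/mean units so the mean
identification (joint-observation) count is H, edges estimated by simple
ratio, and the Pearson correlation r between true and estimated edges
averaged over replicates. This simulation matches the closed form
r² = S²H/(1+S²H) to within ~0.01 over moderate (S, H), so
`required_sampling_effort` inverts the closed form:
H = r²/(S²(1−r²)), giving ≈44 identifications per dyad for a weakly
differentiated population (S=0.2) at r=0.8, ≈4.9 at S=0.6, and ≈0.018 at
S=10.

## Synthetic populations

The two-area generator draws per-individual gregariousness g ~ Poisson(λ)
with λ = 2 (area 1) and 3 (area 2), allocates sex with
P(male) = logistic(6·(g − ḡ)) (steep, so maleness closely tracks
above-average gregariousness; slope 0 makes sex independent for null
scenarios), and in each of 100 sampling periods creates independent dyadic
events with probability 0.02·(g_i + g_j) within areas and zero across areas
(mean dyadic probability ≈0.1). Groups are the connected components of each
period's event graph, one GBI row per component tagged with its area.
Animals with no events in a period are treated as unobserved (no singleton
rows) in the simulation-study pipelines: field gambit-of-the-group sampling
cannot record unseen solitary animals, and this choice also lets the
permutation null retain the gregariousness signal carried by sighting
frequencies. Detection bias thins observations per class (females 0.7,
males 1.0 by default): an undetected animal loses its events for that
period, which is what depresses observed female indices through the
solo-sighting denominator terms.

What these generators do *not* emulate: spatial movement or home ranges,
temporal autocorrelation of group membership across periods (each period is
independent), observer effort variation across periods, and within-group
interaction structure. Tests passing on these data therefore demonstrate the
statistical machinery (conservation, calibration, power under the stated
effect), not robustness to every field-data pathology.

Problem sizes in the test suite (simulation-study properties: 100 and 500
fresh-seed runs at 200 recorded permutations per run; oracle suites on all
996 connected graphs of ≤7 nodes; power simulations with 150–200
replicates) were chosen to make the stochastic properties sharp enough to
assert while keeping the default run lightweight.

## Known limitations

- Only single random intercepts are supported in model formulas (no random
  slopes, no crossed factors); Gaussian response only.
- The dyadic data-stream permutation swaps receivers within strata and so
  conserves in/out totals, but multi-edges may momentarily collapse when
  tallied per period.
- MRQAP relies on node relabeling (no data-stream variant), matching its
  standard formulation.
- The CV test and coefficient test inherit the sequential chain's serial
  correlation; use generous thinning (see above) when p-values near the
  threshold matter.
- Network comparison across studies/populations is deliberately out of
  scope.
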