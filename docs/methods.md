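# Methods

## The world model

An election is a weighted threshold function.  An `ElectoralMap` lists
voting units (states) with positive integer electoral-vote weights and a
victory threshold; the focal candidate wins the presidency in a world iff
the vote total of the units they win reaches the threshold.  With the
default *majority* constructor the threshold is the smallest strict
majority (270 of 538 on the real map), so an exact 269–269 tie counts as a
loss for the focal candidate; a different rule can be had by passing an
explicit threshold.  Congressional-district splits (Maine, Nebraska) are
not modeled specially: the data model is unit-based, so district units can
be listed as separate units if a file provides them, but the bundled 2020
map is winner-take-all states plus DC — the rated stimuli are whole states,
and with winner-take-all coding the focal candidate still totals 306 votes.

A `WorldEnsemble` is an `n_sims × n_units` binary outcome matrix with
nonnegative per-simulation weights (normalized to sum to 1; uniform by
default).  The presidency vector is derived from the threshold rule and
cached; the outcome and weight arrays are frozen so the cache cannot go
stale.  All moments are population moments under the weights — for binary
variables `σ_S = sqrt(p(1−p))` exactly, and at tens of thousands of
simulations the sample/population distinction is far below every tolerance
used here.

## Measures

**CESM.**  For simulation `i` and focal unit `j`, the twin world resamples
`S_ij` from Bernoulli(`Pr(S_j)`) holding all other units fixed.  When the
twin's value differs, the pair contributes `ΔP/ΔS`; because the threshold
rule is monotone this ratio always equals the interventional contrast
`D_i = P(force S=1) − P(force S=0) ∈ {0,1}`, which is how the implementation
vectorizes it.  The score is the weighted mean ratio over changed pairs
times `σ_S/σ_P`.  Two evaluation modes are provided, because the sampled
form is the procedure described while its expectation is what the sampling
converges on: `cesm` draws one twin per simulation from a seeded generator;
`cesm_exhaustive` weights both twin values by `Pr(S)`/`Pr(¬S)` and is the
deterministic default for scoring and testing.  Pairs with `ΔS = 0` are
excluded from the average (the denominator is the weight of changed pairs).
If `σ_S = 0` or `σ_P = 0` the score is 0 by convention: a never-varying
factor has no effect size.  On ensembles whose unit columns are mutually
independent under the weights, `cesm_exhaustive` equals the weighted
Pearson correlation of `S` with `P` exactly; the suite asserts this at
1e-10 on enumerated product ensembles.  A delta-method standard error
(`cesm_mc_se`) linearizes the ratio estimator and is used to standardize
sampled-vs-exact deviations in tests.

**Necessity and sufficiency.**  Necessity is evaluated in the actual world:
the outcome occurred and flipping the focal unit alone undoes it (on the
2020 map only California is necessary).  Sufficiency restricts to
simulations where both the unit and the presidency were lost and returns
the weighted fraction in which forcing the unit would have won the
presidency; with fewer than `min_sims = 10` qualifying simulations
(unweighted count, matching the published exclusion rule) the measure is
undefined and propagates NA.  The combined score is
`w_nec·1{necessary} + Pr(S)·sufficiency` with `w_nec = 1`.  The exact
combination rule is genuinely open — the components are described but their
combination is not fixed in the main sources — so the rule is a config knob
whose setting is recorded in the score table's metadata rather than
hard-coded silently.

**Pivotality.**  Distance `k` is the minimal number of *other* units whose
actual outcomes must flip so that the focal-candidate vote total excluding
the focal unit lands in `[threshold − votes_j, threshold − 1]`.  This is a
0/1-knapsack reachability problem: each other unit contributes `−votes`
(won) or `+votes` (lost) at cost 1, and a dynamic program over vote totals
`0..total_votes` tracks minimal flip counts, processing units one at a time
so no unit flips twice.  Ties in flip count need no tie-breaking (only the
count matters).  Strength is `1/(1+k)`; if no flip set can make the unit
pivotal (possible on contrived maps) the result is NA.  An exhaustive
subset-search oracle backs the DP in tests on maps up to 15 units.

**Contrast measures.**  Observational Delta-P conditions on the unit's
outcome and is NA when a stratum has zero weight.  The interventional
variant averages `D_i` over all simulations and is always defined; it
coincides with the probability of necessity and sufficiency for this
monotone system, and with the observational contrast exactly when the unit
is independent of the rest of the ensemble.  Power-PC divides Delta-P by
`1 − P(P=1|S=0)` and is NA when that base rate is 1.

`score_all` evaluates the requested measures for every unit the focal
candidate won in the supplied actual world and returns a unit × measure
table with NA only where a measure's own precondition fails.

## Synthetic data

**Forecast generator.**  A one-factor latent-probit model: unit `j` has
prior mean margin `μ_j`; simulation `i` draws a shared national shock
`η_i ~ N(0, σ_nat)` and independent unit shocks `ε_ij ~ N(0, σ_unit)`, and
the unit is won iff `μ_j + η_i + ε_ij > 0`.  Marginal win probabilities are
the probit `Φ(μ_j/√(σ_nat²+σ_unit²))` (so `from_win_probs` inverts exactly),
and the shared shock induces the positive cross-state correlation that
separates the interventional from the observational contrasts.  This is
deliberately the simplest generator with the two features the measures are
sensitive to — heterogeneous win probabilities and correlated outcomes —
and it does not attempt poll aggregation, demographic similarity clusters,
or fat-tailed national error, so passing tests speak to the measures'
behavior under realistic marginals and nationalized correlation, not to any
particular forecaster's machinery.

The bundled preset uses the 2020 winner-take-all map with realistic final
pre-election Democratic win probabilities (safe states at 0.01/0.99,
battlegrounds in between, e.g. Georgia 0.58) and `σ_nat = 1.5, σ_unit = 1`.
The shock ratio gives a latent between-state correlation of ≈ 0.69,
consistent with how strongly nationalized the 2020 forecast errors were;
with a weaker shared factor the presidency becomes a near-additive function
of many independent states and every measure degenerates toward
vote-weighting, which is not the regime of interest.  Under the preset the
focal candidate wins about 86% of simulated worlds.

**Rating generator.**  Ratings are
`clip(round(intercept + slope·z(score) + a_p + offset_g + e_pj), 0, 10)`
with participant effect `a_p ~ N(0, 1.0)` and residual
`e_pj ~ N(0, 2.5)`.  Defaults: intercept 4.59 and slope 1.8 place the
state-mean profile in the observed human range; the group mixture is
158/207 focal-candidate voters (offset 0), 29/207 opponent voters (offset
−1.71, mostly not believing the outcome legitimate) and 20/207 others
(offset −0.8), so group mean levels differ while the cross-state ranking is
untouched.  The residual SD was set once with `calibrate_residual_sd`
(bisection against simulated per-participant correlations, discretization
included) so the median per-participant score–rating correlation lands near
.55 — the individual-level fidelity the pipeline is meant to operate at.
Clipping compresses extreme raters, so the realized group mean difference
(≈1.4) is somewhat below the injected offset; the generator reproduces the
qualitative signature (large level shift, near-perfect between-group
ranking correlation ≈ .97), which is what the subgroup-invariance analysis
consumes.

## Comparison statistics

Pearson correlations throughout (Spearman available behind a flag, never
the default); pairwise-complete NA handling for correlations and listwise
for regressions, with the used `n` (hence `df = n − 2`) always reported so
the df bookkeeping under NA-dropping is visible.  State-mean CIs use the t
distribution (small subgroup n).  Group mean comparisons use Welch's
unequal-variance t-test.  Regressions z-score outcome and predictors before
OLS, so coefficients are standardized betas.

The paired permutation test compares two models against the same human
means with statistic `T = |r_A| − |r_B|`; the null swaps, independently per
unit, which model contributed which prediction, and the two-sided p is
`(1 + #{|T_perm| ≥ |T_obs|})/(1 + n_perm)`.  Predictions are z-scored
before swapping: the observed statistic is unchanged (Pearson r is
scale-invariant), but raw swaps between models on different scales inject
outliers into the hybrid vectors and inflate the null spread to the point
of absurd conservatism.  The scheme is a standard paired construction and
is declared in the result metadata rather than asserted to match any
particular published variant.  Calibration is checked empirically: under
exchangeable predictors the rejection rate at α = .05 stays within
[0.02, 0.10] over 200 replicates.

## Problem sizes and numerical choices

Scoring is vectorized (`O(n_sims × n_units)` per measure), so the default
analyses use 20,000-world ensembles and the regression pattern analysis
50,000, matching the scale of real forecast simulation sets.  Oracle tests
enumerate product ensembles up to 2¹² worlds where independence holds
exactly; Monte-Carlo checks tile small ensembles to ≥ 4,000 twin pairs so
standardized deviations are near-normal, and assert the profile a
standard-normal z-sample must satisfy (all |z| < 5, at most a couple beyond
3 in 200 draws) rather than a per-case hard 3σ cut, which a correct
estimator would fail ~40% of the time.  Vote-share binarization is strict
(`share > 0.5` is a win; exactly 0.5 is not) so file reading is pinned and
reproducible.  Every stochastic stage takes a seed; pipeline stages derive
per-stage seeds from the run seed via `SeedSequence.spawn`.

## Limitations

The generator's worlds are exchangeable draws with a single shared factor —
no regional blocs, no similarity weighting of counterfactuals toward the
actual outcome, no turnout/vote-share detail below the binary win.  The NSM
combination rule and the permutation scheme are declared package choices
among defensible variants.  Real-file readers cover wide vote-share CSV,
binary CSV, and the simmed-maps JSON layout; other forecast export formats
need a dialect of their own.  All model-vs-human results shipped here are
computed against *synthetic* ratings generated from a known measure — they
demonstrate pipeline correctness and recoverability, not any new empirical
claim about human judgment.
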