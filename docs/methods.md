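# Methods

## Decision problem and model

A risk prediction model for a binary outcome is to be used, or not, in a
target population.  At risk threshold `z` the decision maker compares three
strategies — treat no one, treat those with predicted risk ≥ `z`, treat
everyone — by net benefit in net true-positive units,

    NB(0) = 0
    NB(1) = θ_p θ_se − (1 − θ_p)(1 − θ_sp) ω
    NB(2) = θ_p − (1 − θ_p) ω,          ω = z / (1 − z),

where θ = (θ_p, θ_se, θ_sp) is the outcome prevalence and the model's
sensitivity and specificity at `z` in that population.  `z` must lie
strictly in (0, 1) (validated at construction, never clamped), risks
exactly equal to `z` are classified positive, and all internal values are
in true-positive units; the false-positive reporting unit is the exact
transform `(1 − z) / z` applied at output time.

Uncertainty about θ is summarized by a posterior given current data `d`.
The package computes

* `ENB_current = max_i E[NB(i, θ) | d]` — the value of deciding now;
* `EVPI = E[max_i NB(i, θ) | d] − ENB_current`;
* `EVSI(N) = E_D[max_i E[NB(i, θ) | d, D]] − ENB_current`, where `D` is a
  future validation sample of size `N` drawn from the posterior predictive.

Modeling assumptions shared by all algorithms: a single homogeneous target
population; `d` and `D` are random samples from it; a fixed, known
threshold (a list of thresholds is handled by independent runs); binary
outcomes without missingness or censoring.  Survival outcomes,
multicenter heterogeneity and model updating are out of scope.

## Estimators

All three algorithms are single-loop Monte Carlo schemes that share the
same accounting: per iteration they record the three "true" NBs at a truth
draw θ\*, the maximum of those (for ENB_truth), and the true NB of the
strategy that wins *after* the simulated future sample (for ENB_sample).
`ENB_current` is the max over strategies of the *averaged* per-draw NBs
rather than the NB at a point estimate: the two terms of each VoI
difference then share their Monte Carlo noise, which tightens the estimate
and prevents small negative EVPI/EVSI values.  VoI estimates are computed
as means of the per-iteration *paired differences* (scored NB minus the
current-best strategy's NB at the same θ\*); when every draw is visited
this is algebraically identical to differencing the two ENB averages, and
under random subsampling of truths it stays unbiased where the unpaired
difference would add noise from comparing different averages.

**Conjugate beta-binomial** (`nbvoi.beta_binomial`).  Current information
is three independent betas; future confusion counts are generated
hierarchically (events ~ Binomial(N, θ_p\*), TP ~ Binomial(events, θ_se\*),
TN ~ Binomial(non-events, θ_sp\*)), and the post-study decision uses the
closed-form posterior means, e.g. `θ_p+ = (α_p + N_+) / (α_p + β_p + N)`.
These update formulas are tested to agree exactly with the means of the
conjugate posterior-update routine.  `N = 0` is handled as an identity:
no data leaves the decision unchanged, so EVSI is exactly 0.  Fully
vectorized; 10^6 draws take ~2 s.

**Two-level bootstrap** (`nbvoi.bootstrap`).  Current information is an
individual-level pilot sample.  Bayesian weights are Dirichlet(1,…,1)
(normalized exponentials); the ordinary multinomial bootstrap is available
behind the same interface.  At a fixed threshold every record is fully
described by its confusion cell, so the implementation aggregates weights
into four cell masses and draws the future sample as a multinomial over
cells with the weights as probabilities — algebraically identical to
record-level resampling from the weighted population.  The pooled data
`d + D` use unit weights (the literal pooling of existing and future
records); the post-study decision is its unweighted plug-in.  Replicates
with zero weighted events keep a well-defined NB because the undefined
sensitivity multiplies a zero mass; such draws are counted in the
diagnostics.  Samples containing only one outcome class are rejected with
a pointer to the conjugate algorithm with informative priors.

Note on the two weighting schemes: Dirichlet and multinomial weights have
cell-mass variances `p(1−p)/(n+1)` vs `p(1−p)/n` and differ in
discreteness, so their VoI estimates agree only to O(1/n) — about 10% on
the 500-record fixture — not within pure Monte Carlo error.  The Bayesian
scheme is the default and the one with an exact conjugate equivalent.

**Likelihood reweighting** (`nbvoi.general`).  Current information is an
arbitrary (M, 3) matrix of posterior draws.  The updated posterior after a
simulated future sample is represented by importance weights over the
draws, proportional to the factorized binomial likelihood; weights are
computed in log space via a feature-matrix product (binomial coefficients
cancel under normalization) with log-sum-exp normalization.  Exact zeros
(θ components of 0 or 1 with a required success) use a finite log-zero
stand-in of −10^6 so that `0 · log 0` contributes nothing while any
required impossible success underflows the weight to exactly zero; an
iteration where every draw is impossible is flagged degenerate, excluded,
and the run fails if more than 1% of iterations degenerate.  The outer
loop visits every draw when M ≤ 20,000 (configurable), otherwise samples
truths at random with a configurable iteration count.  Per-iteration
effective sample sizes `1/Σw²` are summarized (min/median) so users can
detect weight degeneracy.

The finite draw set adds error *beyond* the reported MCSE (which is
conditional on the draws): with the case-study posteriors, run-to-run CV
across independent draw sets is ≈18% at M = 100 and ≈2% at M = 10^5.
Users bringing MCMC output should check the ESS diagnostics and prefer
M ≥ 10^4.

## Monte Carlo error

MCSEs are computed by batch means (100 contiguous batches) on the paired
per-iteration differences, so the positive correlation between the ENB
terms is reflected.  Reported MCSEs are conditional on any fixed inputs
(the posterior draw set in the reweighting algorithm); tests that compare
algorithms account for between-run variability by replication.

## Reproducibility and seeding

Every routine takes one integer seed.  Substreams are keyed by value, not
call order: the θ\* stream depends only on the seed, and the future-data
stream on (seed, N).  Consequently EVSI curves across an N grid share
common random numbers in θ (so estimated curves are monotone up to
residual noise), repeated N values give identical results, and a single
`evsi` call equals the corresponding grid entry.

## Synthetic data

The generator draws predicted risks as expit of a normal on the logit
scale (location −2.9, scale 1.1 by default, giving an implied prevalence
of ≈0.08, typical of short-term post-infarction mortality) and outcomes
from a logistic calibration map of the risks (intercept 0, slope 1 by
default, i.e. a calibrated model).  It emulates the marginal risk
distribution and calibration of a validation sample; it does not emulate
covariate structure, clustering, missingness, or measurement error, so
passing tests demonstrate correctness of the VoI computations under clean
sampling, not robustness to those real-data features.  The fixed
500-record fixture reproduces the pilot-sample contract exactly (43
events; TP/FN/TN/FP = 41/2/147/310 at z = 0.02); its individual risk
values are arbitrary fixed constants and only those counts are
contractual.

## Numerical choices and defaults

* Argmax ties over strategies break to the lowest index (the less
  interventionist strategy), making runs deterministic.
* Default simulation sizes: 10^6 iterations for the conjugate and
  bootstrap algorithms (MC error well below the third significant figure
  of case-study-scale VoI values); default flat Beta(1,1) priors for the
  conjugate update.  Test and example runs use 10^4–4·10^5 iterations to
  keep the suite fast; the acceptance checks use the full 10^6.
* Plug-in estimates from counts with no events (or no non-events) are
  rejected on the strict plug-in path (`ConfusionCounts.to_theta`);
  decision curves and bootstrap internals use cell proportions directly,
  which stay well-defined.
* Binomial conventions: zero-trial draws and pmfs are handled without
  special-casing (`Binomial(0, p) = 0`, `pmf(0; 0, p) = 1`).
* Percentile bootstrap CIs for incremental NB use the ordinary bootstrap
  with `NB_model − max(NB_none, NB_all)` recomputed per resample.

## Known limitations

* The bootstrap algorithm requires individual-level data and both outcome
  classes present; extreme thresholds with near-empty cells are better
  served by the conjugate algorithm with weakly informative priors.
* The reweighting algorithm's accuracy is bounded by the supplied draw
  set; importance weights cannot extrapolate outside its support.
* Population scaling treats the decision count per period as fixed and
  known; no uncertainty in it is propagated.
* No missing-data imputation hooks, survival outcomes, or correlated-prior
  conjugate updating.
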