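# nbvoi

Value-of-information analysis for external validation of clinical risk
prediction models.

## The problem

Before a risk prediction model is used in a new population it is validated
in a sample from that population, and its clinical utility is summarized by
**net benefit (NB)**: at a risk threshold *z* (treat when predicted risk ≥
*z*), a strategy's NB in net true-positive units is

    NB = p_tp − ω · p_fp,        ω = z / (1 − z),

where ω is the number of false positives whose harm offsets the benefit of
one true positive.  Writing θ = (θ_p, θ_se, θ_sp) for outcome prevalence and
the model's sensitivity and specificity at *z*,

    NB(treat none) = 0
    NB(use model)  = θ_p·θ_se − (1 − θ_p)(1 − θ_sp)·ω
    NB(treat all)  = θ_p − (1 − θ_p)·ω.

A finite validation sample leaves θ uncertain, so the strategy with the
highest *expected* NB may not be the one with the highest *true* NB.
Decision theory prices that risk:

* **EVPI** = E[max_i NB(i, θ)] − max_i E[NB(i, θ)] — the expected NB gain
  from fully resolving uncertainty (an infinite validation study);
* **EVSI(N)** = E_D[max_i E[NB(i, θ) | D]] − max_i E[NB(i, θ)] — the
  expected gain from first observing a future validation sample *D* of size
  *N*, then deciding.

EVSI rises from 0 at N = 0 to EVPI as N → ∞; scaled by the number of times
the decision is made per year it expresses the return, in true positives
gained (or false positives averted) per year, on running a validation study
of a given size.  The package is for biostatisticians and study planners
who want a value-based, rather than purely inferential, sample-size
rationale for external validation studies.

## Algorithms

Three Monte Carlo estimators of EVPI/EVSI are provided, for three shapes of
"current information" about θ:

| algorithm | current information | module |
|---|---|---|
| beta-binomial (conjugate, fast) | independent Beta distributions on θ_p, θ_se, θ_sp | `nbvoi.beta_binomial` |
| two-level bootstrap | an individual-level pilot sample (risk, outcome) | `nbvoi.bootstrap` |
| likelihood reweighting | arbitrary joint posterior draws of θ (e.g. MCMC) | `nbvoi.general` |

For binary outcomes the Bayesian bootstrap (Dirichlet(1,…,1) record
weights) is equivalent to the conjugate algorithm under the
Dirichlet(n_tp, n_fn, n_tn, n_fp) posterior — the package's primary
cross-validation.  Shared plumbing (NB calculus, decision curves,
percentile-bootstrap CIs for incremental NB, population scaling) lives in
`nbvoi.nb`, and a deterministic 500-record fixture plus a logit-normal
sample generator in `nbvoi.synthetic`.

## Worked example

Current information: a 500-record pilot validation sample with 43 events;
at z = 0.02 the confusion counts are TP=41, FN=2, TN=147, FP=310.  With
flat Beta(1,1) priors this gives θ_p ~ Beta(44,458), θ_se ~ Beta(42,3),
θ_sp ~ Beta(148,311).

```python
from nbvoi import (ConfusionCounts, PopulationScale, Threshold,
                   evsi, posterior_from_counts, scale_to_population)

post = posterior_from_counts(ConfusionCounts(41, 2, 147, 310))
thr = Threshold(0.02)
run = evsi(post, thr, n_future=1000, n_sim=10**6, seed=1)
print(f"EVPI            {run.evpi:.5f}")
print(f"EVSI(N=1000)    {run.evsi:.5f}")
tp = PopulationScale(800_000, "true_positive")
fp = PopulationScale(800_000, "false_positive")
print(f"population EVSI {scale_to_population(run.evsi, thr, tp):.0f} TP/yr "
      f"= {scale_to_population(run.evsi, thr, fp):.0f} FP averted/yr")
```

prints

```
EVPI            0.00126
EVSI(N=1000)    0.00101
population EVSI 808 TP/yr = 39571 FP averted/yr
```

Read: uncertainty about the model's performance costs at most 0.00126 net
true positives per decision (EVPI); a 1,000-subject validation study would
recover 0.00101 of that.  If the decision recurs 800,000 times a year, that
study is worth about 808 true positives gained — equivalently some 39,600
false positives averted — per year, and (via `evsi_curve`) studies beyond
N ≈ 4,000 add little.

The same analysis from the shell:

```sh
nbvoi beta-binomial --counts 41 2 147 310 -z 0.02 -N 1000 \
    --n-sim 1000000 --seed 1 --population 800000 --out results/case
```

`nbvoi bootstrap` and `nbvoi general` run the other two algorithms from a
sample CSV (`risk,outcome`) or a posterior-draw CSV
(`prevalence,sensitivity,specificity`); `nbvoi sample --fixture` emits the
built-in pilot sample; `nbvoi decision-curve` and `nbvoi inb-ci` cover the
descriptive side.

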