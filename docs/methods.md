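# Methods

## Generative model

A change-point process over T steps is defined by a hazard specification
(h, refractory): position 0 starts an epoch; afterwards each step is a
change-point with probability h unless it falls within the refractory window
(a fixed number of steps after the previous change during which the hazard
is forced to zero; 0 everywhere except the behavioral task, which uses 3).
At every change-point the generative parameter is redrawn from the
conjugate prior — including the very first epoch, which uses the same prior
(the natural symmetric choice).  Observations are i.i.d. within epochs.

Three conjugate families are supported, parameterized throughout by the
accumulated sufficient statistic χ and pseudo-count ν so that the posterior
mean statistic is always χ/ν and one observation is a Delta-rule update with
rate 1/ν:

| family | tracked parameter | u(x) | prior | predictive |
|---|---|---|---|---|
| bernoulli | rate θ | x | Beta(χ₀, ν₀−χ₀) | Bernoulli(χ/ν) |
| gaussian_mean (known sd σ) | mean | x | N(χ₀/ν₀, σ²/ν₀) | N(χ/ν, σ²(1+1/ν)) |
| gaussian_scale (known mean) | sd | (x−μ)² | Gamma(ν₀/2, χ₀/2) on precision | Student-t(ν), scale √(χ/ν) |

A Gaussian mean prior (μ_p, σ_p) maps to ν₀ = σ²/σ_p², χ₀ = ν₀μ_p
(round-trip tested).  The Gaussian-scale point estimate of the sd is
√(χ/ν), the consistent root-mean-square estimate whose square follows the
Delta rule; alternatives (e.g. the posterior mean of σ) differ only at small
ν.  All densities are evaluated in log space.

The behavioral task generator emulates the number-prediction experiment:
blocks of 200 trials with block-wise constant noise sd cycling through
{5, 10}, means uniform on [40, 260] redrawn at hazard 0.1 with a 3-trial
refractory period, and samples redrawn until they land in [0, 300] (safety
cap 10⁴ retries).  Benchmarks LB (mean |x_t − x_{t−1}|) and HB
(mean |θ_{t−1} − x_t|) summarize the attainable error range; the monetary
payout mapping between them is not modelled.

What the generator does **not** emulate: drifting (as opposed to jumping)
parameters, run-length-dependent hazards, serial dependence within epochs,
and — for the synthetic subjects — any human departure from the candidate
model class beyond i.i.d. Gaussian decision noise.  Passing tests therefore
certify the inference machinery under its own generative assumptions, not
behavioral conclusions about real subjects.

## Full model

State: a weight vector over run-lengths r = 0..R_max plus per-run-length
statistic means μ_r = χ_r/ν_r with ν_r = ν₀ + r fixed.  One step computes
every node's log predictive of x, forms growth messages ((1−h) · weight ·
predictive into r+1) and change messages (h, pooled into r = 0, whose
statistics are the prior), and renormalizes with log-sum-exp.  Storing the
mean rather than χ makes the update μ_{r+1} ← μ_r + (u(x) − μ_r)/(ν₀+r+1),
algebraically identical and convenient at the truncation boundary.

Two bookkeeping choices worth stating:

* **Hazard placement.**  After a step the weight vector is already the
  hazard-propagated distribution for the upcoming interval — the r = 0
  weight equals h exactly.  The predictive for the next observation is then
  the plain node mixture; applying the change-point transition a second time
  inside prediction would double-count the hazard.  Correctness is pinned by
  a brute-force oracle that enumerates all 2^(T−1) change-point
  configurations: posterior and prediction agree to better than 1e-10.
* **Truncation.**  Growth mass from both R_max−1 and R_max lands at R_max
  (the truncated prior self-transitions), and their statistic means are
  merged as a convex combination weighted by the two incoming messages.
  This preserves normalization and the ν_r = ν₀ + r invariant; it is exact
  whenever R_max ≥ T and negligible otherwise once R_max is several times
  the typical epoch length (predictions shift < 1e-6 in tests).

Degenerate inputs (an observation with zero likelihood under every node)
raise a diagnostic numerical error rather than silently renormalizing.

## Reduced model

N nodes with strictly increasing positive run-lengths, each a Delta rule on
the mean statistic with fixed rate α_i = 1/(l_i + ν₀).  Folding the prior
pseudo-count into the node makes one node with rate 1/(l+ν₀) *exactly* a
fixed-rate Delta rule initialized at the prior mean, and recovers α = 1/l as
ν₀ → 0.  Rates are capped at 1 (a node with l + ν₀ < 1 cannot forget faster
than total replacement).  Node likelihoods use the family predictive with
effective count ν₀ + l_i and statistic χ = μ_i(ν₀ + l_i).

The transition prior routes all change mass to node 1; for spacing
s_i = l_{i+1} − l_i ≥ 1 the advance probability 1/s_i matches the unit mean
run-length growth of the exact filter, while for s_i < 1 the advance
probability saturates at 1 and the growth is under-matched (the closest
achievable).  The last node self-transitions.  Weight updates multiply each
node's weight by its predictive likelihood, push the result through the
transition matrix, and renormalize; this ordering makes the two-node case
agree with an independently hand-coded recursion to 1e-12.

Initial weights put all mass on node 1: change-points route there, so it is
the natural start-of-epoch node.  Initial means sit at the prior mean.

## Error analysis

The error E is the mean over time and replicate sequences of
(prediction_t − θ_t)², where prediction_t is formed from x_{<t} — i.e. the
one-step-ahead estimate is scored against the parameter of the trial it
predicts.  The relative error divides by the **prior variance of the
tracked parameter**, which is the error of an observer that always predicts
the prior mean; the zero-learning limit then has relative error 1 exactly.
(The prior *data* variance is the other candidate normalizer, but it is
inconsistent with that limit for Gaussian data, so it is not used.)

Estimates are Monte Carlo — replicate sequences are simulated, the reduced
model is run on each, and per-replicate means give a standard error — in
place of any closed-form moment expansion; the stationary one-node Gaussian
case, where the closed form α²σ²/(2α − α²) is elementary, is used as a
check (with a burn-in so the transient from the prior initialization does
not bias the comparison against the stationary value).

Node optimization works on learning rates (the natural bounded axis),
mapped to run-lengths via l = 1/α − ν₀, with the upper bound intersected
with α < 1/ν₀ so run-lengths stay positive.  The simulated sequences are
fixed by the seed (common random numbers), making the objective
deterministic and smooth; ≥ 3 Nelder-Mead starts (default 8) guard against
the multiple local minima that appear with 3 nodes at low hazard.  Default
problem sizes (T = 1000, 20 replicates) put the Monte-Carlo standard error
of the relative error near 0.01–0.02, well below the effects examined.

## Behavioral fitting

Candidate models: full (hazard + noise), 1-node (rate + noise), 2- and
3-node (hazard + rates + noise).  Models larger than 3 nodes are excluded:
in recovery analyses they are not separable from the 3-node model.  The
single-adaptive-rate alternative model from the experimental literature is
out of scope here.

A synthetic subject reports the model prediction plus i.i.d. Gaussian
decision noise σ_n, clipped to the task bounds.  The likelihood of reports
is an *untruncated* Gaussian around the model prediction (the clip almost
never binds for realistic σ_n; the bias is negligible away from the
bounds).  Model predictions condition only on the observed numbers — the
subject's own reports never feed back into model state.  The task's uniform
mean prior is represented inside the candidate models by its
moment-matched Gaussian (mean 150, sd 220/√12).

Fitting profiles σ_n out in closed form (its MLE is the residual RMS), so
the search is 1-dimensional for the full and 1-node models (deterministic
grid scan plus bounded polish) and 2–4-dimensional for the multi-node
models (multi-start Nelder-Mead with deterministic restart seeds, sorted
and gap-separated learning rates).  Evidence is BIC, −2 logL + k log n,
with log evidence ≈ −BIC/2.  Group comparison uses variational
Dirichlet-multinomial random-effects selection; exceedance probabilities
come from 10⁵ Dirichlet draws.  A fast scalar implementation of the reduced
model's Gaussian block runs inside the likelihood loop; it is asserted
equal to the reference implementation to 1e-10.

Confusion matrices simulate subjects from each model with parameters drawn
around group-mean fit values typical of human subjects on this task
(spread set to half the between-subject sd, clipped away from degenerate
corners: a 2-node subject with
two equal rates, or a rate pinned at 1, *is* behaviourally a 1-node
subject, so such draws would make the recovery question ill-posed).
Simulated subjects run 1000 trials — the scale of the real experiment —
because BIC cannot separate realistic 1- and 2-node subjects on much
shorter sequences; the reduced scale is taken on the subject count instead.
Recovery *correlation* tests draw parameters from wide uniform ranges with
enforced rate separation (≥ 0.25–0.35) and decision noise between 2 and 6:
close rates sit on a likelihood ridge where they trade off against the
hazard (refits reach higher likelihood than the generating parameters), so
sampling them would measure that ridge, not recovery quality.

## Problem sizes and determinism

Test and script problem sizes are chosen so Monte-Carlo standard errors sit
well below the effects being checked while the whole suite stays desk-scale:
20 × 1000 trials for tracking errors, 30 subjects × 400 trials for parameter
recovery, 8 subjects per generating model for confusion matrices.  Every
stochastic component takes an explicit seed; a master seed spawns
per-purpose substreams, so identical invocations are bit-reproducible.

## Known limitations

* Hazards are constant; run-length- or time-dependent hazards are not
  modelled.
* Families are scalar with one unknown parameter; unknown mean *and*
  variance, or multivariate data, are out of scope.
* Node run-lengths are fixed during inference (no online adaptation).
* The fitting stack is validated on synthetic subjects only; no human data
  ship with the package.
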