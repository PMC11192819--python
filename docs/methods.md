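# Methods

## The generative task model

`memval.task` simulates the number-sequence / free-recall / willingness-to-pay
experiment trial by trial.

**Sequences.** Each sequence's distribution mean is an integer drawn uniformly
from {40, …, 70}; the seven stimulus values are drawn independently, with
replacement, from the integers within ±29 of that mean. Every sequence
distribution therefore spans exactly 58 GC, every stimulus is a two-digit
value in [11, 99], and the sequence's true value is the arithmetic mean of the
seven values. Stimuli are integers and duplicates within a sequence are
permitted (nothing in the task precludes them).

**Recall.** Free recall is simulated position-wise: position `i` is recalled
independently with probability `p_recall[i]`; when evaluation precedes recall
(ER order) the last two positions are multiplied by an attenuation factor,
emulating the loss of recency under delayed recall. Intrusions are Poisson
with a per-trial mean, drawn uniformly from the sequence's generating range
*excluding* presented values, so that correctness scoring of synthetic data is
unambiguous. Output order is randomised and capped (default 8 items,
standing in for the task's bounded response window). Defaults —
`p_recall = (0.75, 0.60, 0.50, 0.45, 0.45, 0.55, 0.70)`, ER attenuation 0.6,
intrusion rate 0.3 — produce the qualitative serial-position shape of
seven-item lists: extended primacy, a recency bump over the last two
positions, and reduced recency under ER.

**Bids and the auction.** Bids are generated from one of the candidate
evaluation models plus a participant intercept `u_j ~ N(0, τ)` and Gaussian
trial noise, clipped to the response range [0, 100] (the small bias this
introduces at extreme means is accepted and irrelevant at the default
parameters, where bids sit mid-scale). Default generating slopes are the
fitted values reported for this paradigm (recalled 0.541, presented 0.936,
both (0.41, 0.54)); the TD generator uses slope 0.9 and α = 0.6 (no fitted
values are available for it); intercepts `b0` are set per model so that mean
bids sit near 55 GC; `τ = σ = 3` GC give the strong-signal regime the
recovery experiment presumes. The selling price is continuous `U(40, 70)`
(the range of sequence means) so the bid-equals-price tie has measure zero;
ties resolve as a purchase. For a true value strictly inside (40, 70),
expected earnings are uniquely maximised at bid = true value; at the
boundary the optimum is attained but not unique (all bids below 40 forgo
every purchase equally).

**What the generator does not emulate.** Reaction times, the 15-s recall
clock, output-order dynamics (lag-CRP structure), serial-position-dependent
intrusion rates, and any dependence of bids on recall *order*. Passing tests
therefore show that the pipeline recovers what it assumes — they say nothing
about whether real participants obey these regressions.

## Trial-level predictors

The presented predictor is the mean of the seven values; the recalled
predictor is the mean of *all* reported values, intrusions and duplicate
reports included, and is missing when nothing was recalled. The TD value
starts at the first presented value (`V0 = x1`; this avoids an arbitrary
anchor and yields clean α = 0 / α = 1 limits — the first / last item;
a mid-scale anchor can be substituted by passing a value sequence with a
prepended anchor) and updates by `V ← V + α (x_t − V)`, which equals the
exponential-weight sum `w1 = (1−α)^6`, `w_t = α (1−α)^{7−t}`.

For model comparison all candidate models are fitted to the **same trial
set**: trials with an empty recall set, where the recalled predictor is
undefined, are dropped for every model, because marginal likelihoods are
comparable only on common data.

## Hierarchical fits

All single-strategy models share the structure
`y_ij ~ N(b0 + u_j + Σ β_k x_ijk, σ)`, `u_j ~ N(0, τ)`, with priors
`β ~ N(1, 0.5)` per slope, `b0 ~ N(0, 10)`, `τ ~ half-t(3, 0, 10)`,
`σ ~ half-t(3, 0, 10)`, `α ~ U(0, 1)`. The residual-σ prior mirrors the
stated group-level prior (a fixed prior keeps the marginal likelihood
well-defined and reproducible, in contrast to data-dependent defaults); the
two-slope model applies the same `N(1, 0.5)` prior to each slope. Both
choices are configurable through `PriorConfig`.

Because the intercepts enter linearly with Gaussian noise, they are
marginalised analytically: per participant the bids are jointly Gaussian with
compound-symmetry covariance `σ²I + τ²11ᵀ`, evaluated via the rank-one
Woodbury identities in O(n) per likelihood call. The sampler therefore only
explores the 4–6 population-level parameters — (b0, slopes, log τ, log σ,
logit α) in an unconstrained parametrisation with the appropriate Jacobians —
using an affine-invariant ensemble sampler (24 walkers, vectorised likelihood),
one independent ensemble per chain, initialised near a Nelder–Mead posterior
mode. Default settings are 1000 warm-up steps and 4000 retained draws per
chain with four chains (5000/10,000 for the TD model, whose predictor is
recomputed inside the sampler from the raw stimulus matrix as a function of
α). Posterior draws of the `u_j` are recovered exactly from their conjugate
Gaussian conditional given each retained draw. Convergence is summarised by
the maximum rank-normalised split R-hat across the sampled parameters, with
1.05 as the acceptance bound; comparisons refuse non-converged fits unless
forced.

For development-scale work and the simulation studies the package uses
documented reduced presets (`McmcConfig.desk()`: 300 warm-up steps, 1500
retained draws, 2 chains); the full-size settings are the defaults.

## Marginal likelihood and Bayes factors

The log marginal likelihood is estimated by iterative optimal bridge sampling
in the unconstrained space: a Gaussian proposal is moment-matched to half of
the posterior draws, the other half enters the bridge identity, and the
normalising constant is iterated to a 1e-10 fixed point on the log scale.
The reported Monte-Carlo error uses the standard relative-MSE approximation
with the posterior-side term inflated by the draws' effective sample size.
Against a conjugate closed form (known-variance normal mean) the estimator is
accurate to well under 0.1 nats at default draw counts. Model ranking selects
the highest marginal likelihood; Bayes factors are `exp(Δ log ML)` with
Wagenmakers-style verbal labels. Differences of a few nats should be read
against the reported bridge errors; the regimes this package targets produce
differences of tens to hundreds of nats.

The JZS t-test Bayes factor integrates the Cauchy(0, r) effect-size prior in
its scale-mixture form (inverse-gamma(1/2, r²/2) on the prior variance g) by
adaptive quadrature on the log-g axis, with the central-t null density
factored out for numerical headroom; r defaults to √2⁄2.

## The strategy mixture

The mixture likelihood for trial `i` of participant `j` is
`Σ_c θ_jc N(y_ij; b0 + u_j + η_c(x_i), σ)` over components c ∈ {recalled,
presented, both}, each with its own slope(s) under the `N(1, 0.5)` prior;
`θ_j ~ Dirichlet(1, 1, 1)`. The intercept `b0`, participant effects `u_j`
and residual σ are shared across components — separate σ would let
components soak up variance through noise differences rather than through
their predictors, and population-level shared slopes are the simplest
structure consistent with reporting a single estimate per component.

Inference is Gibbs sampling: component indicators and θ_j have exact
categorical/Dirichlet conditionals; slopes, b0 and u_j are conjugate
Gaussians; σ and τ are updated by univariate slice sampling under their
half-t priors. Indicators are sampled rather than marginalised (the joint
posterior is identical); per-trial component posteriors are nevertheless
reported Rao-Blackwellised, i.e. the conditional categorical probabilities
averaged over retained sweeps. Participants are classified by the argmax of
the posterior-mean θ_j, with exact ties resolved conservatively to "both".
Fits report max R-hat over the shared continuous parameters and flag
component starvation (a component explaining under 0.5% of trials).

**Identifiability caveat.** The "both" component nests each single-predictor
component: on data generated purely from the presented model, the both-slopes
adapt to (≈0, ≈β_presented) and the two components explain every trial
equally well, so θ_j mass splits between them and no procedure can push
θ_presented above ~0.5. Classification is therefore validated on mixed
populations, where the both-component's shared slopes are anchored by the
genuinely-both participants and mimicry is broken; there the classifier
recovers ≥80% of participants. For a pure-vertex sanity check,
`theta_fixed` pins the weights at a simplex vertex, which collapses the
mixture onto one component regression; its marginal likelihood then matches
an independently run single-model fit.

## Model recovery

`run_recovery` simulates experiments from each of the recalled, presented and
TD generators (default 33 participants × 32 trials at the strong-signal
parameters above), fits all three candidates to every dataset, and awards
each replicate to the highest marginal likelihood. A fit missing the R-hat
bound is retried once with a fresh seed and otherwise recorded as a no-win
failure. The desk preset (10 replicates per generator, reduced chains)
finishes in minutes on one CPU and yields a pure or near-pure diagonal; the
full preset (50 replicates, default chains) reproduces the perfect-diagonal
design. The winning margins in this regime are tens to hundreds of nats, far
above bridge-sampling error, and decay monotonically as the generating σ
grows. The entire experiment is a pure function of its seed.

## Descriptives and exclusions

A trial counts as completed when both its bid and its recall report are
present. Participants are excluded for completing under 80% of the 32
trials, for averaging under one correctly recalled item per attempted recall
trial, or for completing under 80% of the evaluation trials; participants
with any bid outside [0, 100] are flagged and removed from evaluation
analyses only. All filters are computed from the raw table, so the result is
independent of application order. The joint model-comparison subset keeps
only participants with all 32 trials completed. One file-format limitation:
the CSV round trip cannot distinguish "recall not administered" from
"attempted, zero items recalled" (both are empty fields and read back as an
empty recall set); in-memory tables can carry the distinction as missing
values.

Recall is scored by exact integer match, with duplicated presented values
handled by greedy earliest-position matching and unmatched reports counted as
intrusions (report counts are conserved: correct + intrusions = reports).
Serial-position curves average per-participant position accuracies over
attempted recall trials; within-subject error bars centre each participant's
position profile on the grand mean and apply the Morey correction
`√(K/(K−1))`, K = 7. WTP accuracy is the per-participant RMSE of bids
against sequence true values, optionally split by task order.

## Known limitations

* The ensemble sampler is well-suited to the low-dimensional marginalised
  posteriors used here but would not scale to sampling the random intercepts
  directly; the analytic marginalisation is load-bearing.
* Marginal likelihoods depend on the documented priors; changing
  `PriorConfig` changes Bayes factors, not just posteriors.
* Bid clipping to [0, 100] is ignored in the fitted likelihoods (as in the
  original regressions); at generating parameters that push bids against the
  bounds the models are misspecified and σ estimates inflate.
* Value-based recall scoring is ambiguous when a sequence repeats a value;
  the greedy rule is deterministic but other conventions would shift
  position-level accuracies slightly.
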