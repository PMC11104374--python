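# Methods

## The model

`hgflearn` implements a trial-by-trial model of social advice-taking under
volatility. An agent predicts a binary lottery outcome on each of ~170
trials using two information sources: a non-social cue (a pie chart showing
outcome probabilities) and the binary recommendation of an adviser whose
helpfulness changes over time. Learning about the adviser is modelled with
a 3-level binary Hierarchical Gaussian Filter (HGF):

* level 1 — advice accuracy on the current trial, `x1 ∈ {0, 1}`;
* level 2 — the adviser's fidelity, an unbounded tendency `x2` linked to
  level 1 through the unit sigmoid;
* level 3 — the log-volatility `x3` of the adviser's intentions, which
  modulates the level-2 random-walk variance through
  `v2 = exp(kappa2 * x3 + omega2)`.

Beliefs are Gaussian, `N(mu_i, sigma_i)`, and updated once per trial with
precision-weighted prediction errors: `Δmu_i ∝ (pihat_{i-1} / pi_i) *
delta_{i-1}`. The exact one-step updates are documented in
`hgflearn.perceptual` and verified trial-by-trial against an independent
literal transcription in the test suite.

Two perceptual variants form the hypothesis space:

* **Standard HGF (HI)** — `x3` is a pure random walk.
* **Mean-reverting HGF (HII)** — `x3` additionally drifts toward an
  equilibrium `m3` at rate `phi3` (a discrete-time Ornstein-Uhlenbeck
  process). `m3` above the initial volatility belief `mu3_0` formalizes an
  agent that comes to perceive the environment as *increasingly volatile*,
  producing larger precision-weighted updates at every level and more
  susceptibility to noisy stretches of input; `m3 < mu3_0` produces the
  opposite, increasingly rigid learning.

The response model maps beliefs to choices: the integrated belief
`b = zeta * muhat1 + (1 - zeta) * c` blends the predicted advice accuracy
with the advice-congruent cue probability `c`, and the probability of going
with the advice is `p = b^beta / (b^beta + (1-b)^beta)` with inverse
temperature `beta = nu * exp(-muhat3)`. Decisions are therefore
exploitative when the environment is perceived as stable and exploratory
when it is perceived as volatile; `nu > 0` is volatility-independent
decision noise (larger = less noise). The additive noise term of the
temperature is interpreted on the estimation (log) scale, i.e.
`beta = nu * e^{-muhat3}`: with the canonical prior mean `nu = 48` this
yields usable temperatures (`beta ≈ 18` at `muhat3 = 1`), whereas a native
additive term of 48 would make choices astronomically deterministic.

Control models CI and CII freeze all perceptual parameters at
input-optimized ("Bayes optimal") values — obtained by maximizing the
one-step-ahead predictive likelihood of the input stream alone — and
estimate only `zeta` and `nu`. They formalize the null hypothesis that
behavioral variation is purely a matter of response style.

## Parameters, priors, estimation

Free parameters (native space → estimation space): `kappa2` (logit),
`omega2` (identity), `mu2_0` (identity), `mu3_0` (identity), `m3`
(identity; HII only), `zeta` (logit), `nu` (log) — 6 free for HI, 7 for
HII, 2 for CI/CII. Fixed: `theta = 0.5`, `sigma2_0 = sigma3_0 = 1`,
`phi3 = 0.1`. Prior means are native-space values (`kappa2 = 0.5`,
`omega2 = -2`, `mu2_0 = 0`, `mu3_0 = 1`, `m3 = 1`, `zeta = 0.5`,
`nu = 48`); prior variances apply in estimation space (all 1, except
`omega2`: 4), matching the convention of the reference HGF toolbox.

Subject-level fitting is MAP estimation in estimation space with an
L-BFGS-B multistart (default 5 starts: the prior mean plus seeded unit
Gaussian perturbations; gradient tolerance 1e-6). Parameter vectors whose
trajectory produces a non-positive posterior precision are rejected — the
objective is treated as -inf, never clamped, because silent clamping biases
estimates. Because this creates a cliff in the objective, the optimizer
records the best visited iterate and uses it if a line search ends on the
wrong side. Log model evidence is the Laplace approximation at the MAP
(central-difference Hessian; non-positive-definite Hessians are projected
to the nearest positive-definite matrix and flagged). The Laplace evidence
plays the role a variational free energy plays in other implementations;
group-level selection only consumes evidence differences.

Group-level inference is random-effects Bayesian model selection: a
variational Dirichlet scheme (`alpha0 = 1`) yields model frequencies and
per-subject attributions; exceedance probabilities are computed exactly for
two models (regularized incomplete beta function) and by Monte Carlo
otherwise (default 1e6 samples, seeded); the Bayesian omnibus risk
`BOR = 1/(1 + exp(F1 - F0))` compares the RFX free energy against the
equal-frequency null, and protected exceedance probabilities are
`phi = XP * (1 - BOR) + BOR / K`.

## Synthetic task and cohorts

The default schedule has 170 trials: a stable phase (trials 1–67, advice
accuracy 0.85), rapid reversal blocks (68–119, alternating 0.9/0.1 in
13-trial blocks), a noisy stretch (120–136, accuracy 0.55), and further
reversals (137–170, 11/11/12-trial blocks). The only quotable anchors are
the phase boundary after trial 67, reversals over 68–119 and the noisy
stretch 120–136; the block subdivision within the reversal segments is
this package's choice and fully configurable.

Cue handling: the pie chart concerns the *lottery outcome*, not the advice,
and the adviser agrees with the cue-favoured option only about half the
time. The advice-congruent cue probability `c` used by the response model
is therefore a configured level (`{0.55, 0.65, 0.75, 0.85}`) or its
complement, each with probability 1/2. This choice makes simulated
advice-taking rates (~0.78 stable / ~0.56 volatile) resemble empirically
reported behavior; drawing `c` only above 0.5 would saturate advice-taking
near 1.

Latent generative states are not simulated; the schedule's per-trial advice
accuracy plays their role, which is sufficient for recovery studies that
only need input streams with the assumed statistical structure.

Cohorts draw each subject's generative parameters in estimation space
around the prior means. The default spread is 1.0 prior standard
deviations (i.e. draws from the prior itself); recovery studies widen `m3`
(sd 2) so that both volatility-overestimating and stability-biased agents
occur. Parameter draws whose own trajectory the filter rejects are
redrawn — they lie outside the model's support. "FEP-like" groups
(first-episode-psychosis-like) use elevated drift equilibrium (`m3` mean 3,
sd 1) with reduced coupling (`kappa2` mean 0.3), the parameter profile that
characterizes patient groups; reduced coupling is also what keeps strongly
positive `m3` inside the filter's validity region. Each synthetic subject
receives its own input realization by default (`share_inputs` switches to
one shared stream per cohort, closer to the experimental situation in
which every participant faced the same prerecorded adviser; the two
settings give indistinguishable recovery results).

## Recovery diagnostics

*Model recovery*: for each seed and generating model, simulate a cohort,
fit every candidate model to every subject, run RFX-BMS, and average
protected exceedance probabilities across seeds into a confusion matrix.
The full-scale design enumerates 4 models × 56 subjects × 20 seeds = 4,480
simulations; the default here is the scaled-down 20 subjects × 5 seeds.

*Parameter recovery*: simulate and re-fit the same model; report per
parameter the Pearson correlation between simulated and recovered values
(computed in estimation space, where Pearson r is not distorted by bounded
supports) and Cohen's `f² = r²/(1-r²)`, with `f² ≥ 0.35` as the
large-effect criterion. *Identifiability*: pairwise correlations between
estimated parameters across subjects, flagging `|r| > 0.6`.

At the scaled sizes, `m3`, `omega2`, `zeta` and `mu2_0` reach the
large-effect criterion in every seed, while `kappa2` and `mu3_0` recover
poorly — the same parameters that are reported as weakly recoverable in
empirical applications of this model family.

## Known limitations

* Distinguishing HI from HII on 170 binary choices is intrinsically hard
  when generative parameters are drawn from the prior: the mean-reverting
  filter closely mimics typical standard-HGF volatility trajectories, so
  per-subject evidence differences on standard-HGF data are ~0.5 nats and
  sometimes favour the drift model. The omnibus-risk protection converts
  that inconsistency into non-trivial off-diagonal confusion mass for the
  standard-HGF row; the mean-reverting row, generated with FEP-like
  parameters, is recovered much more decisively.
* The Laplace evidence and a variational free energy can differ by small
  constants; all selection results here are internally consistent but not
  numerically interchangeable with other toolboxes.
* The synthetic generator emulates the task's statistical structure, not
  its psychology: no reaction times, no engagement drift, no
  session-specific cue sequences. Passing recovery tests therefore
  demonstrates internal consistency of the pipeline under the assumed
  generative conditions, not that empirical data meet those conditions.
* The AR1 variant evaluates the level-2 variance inflation `v2` at the
  previous posterior volatility `mu3^(k-1)`, not at the drifted prediction;
  this follows the reference implementation's convention.
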