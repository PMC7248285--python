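# Methods

## The task and the modelling question

In the gaze–emotion categorisation paradigm an observer sees a face morphed
between neutral and either anger or fear (7 intensity steps per emotion),
shown with direct or averted gaze, and must answer "anger" or "fear".
Combinations that signal self-relevant threat — anger with direct gaze, fear
with averted gaze — are called *Threat+*; the alternate pairings are
*Threat−*. Observers categorise Threat+ faces more accurately, and two
mechanisms can produce that advantage:

* a **perceptual sensitivity** change — gaze sharpens the perceptual read-out
  of threat-congruent emotions, so the psychometric slope is steeper for
  Threat+ stimuli; or
* a **decision bias** — gaze shifts the response criterion towards the
  threat-congruent answer (anger for direct gaze, fear for averted gaze),
  which asymmetrises responses even to neutral faces that carry no emotion
  evidence at all.

This package implements both as signal-detection-style probit choice models,
fits them per subject by maximum likelihood, and asks at the group level
which mechanism better explains the data.

## Choice models

Evidence on each trial is coded on a signed axis
`u = ±(morph_level / n_levels)`, positive for anger, negative for fear, 0 for
neutral. Linear coding of morph level is a documented default: any strictly
monotone recoding would be admissible, and the slope parameter absorbs an
overall scale. The probability of answering "anger" is

    P(anger) = Φ(w_eff · u + b_eff)

with Φ the standard normal CDF (probit link — the natural choice under the
signal-detection framing of the task, where a logistic link would behave
near-identically). The models differ only in which term gaze modulates:

| model | free parameters | w_eff | b_eff |
|---|---|---|---|
| M1 sensitivity | `w_plus, w_minus, b` | `w_plus` on Threat+, `w_minus` on Threat−, their mean on neutral | `b` |
| M2 bias | `w, b_direct, b_averted` | `w` | `b_direct` / `b_averted` by gaze |
| M3 combined | `w_plus, w_minus, b_direct, b_averted` | as M1 | as M2 |

Slopes are unitless sensitivities (≥ 0); criteria are in the same standard
normal units, positive values biasing towards "anger". M1 with equal slopes
and M2 with equal criteria collapse to the same two-parameter model, which
the tests exploit as an exact likelihood identity.

There is no lapse-rate parameter — adding one would break the equal
parameter count that makes raw likelihoods comparable between M1 and M2.
Instead every trial probability is floored into `[1e-6, 1 − 1e-6]`, which
keeps the log-likelihood finite when a saturated model meets a contrary
response. Neutral trials are included in the likelihood: they are exactly
where the bias model is identified, and under M1 they constrain only the
criterion (u = 0 makes the neutral slope moot).

## Maximum-likelihood fitting

Per subject and model, the negative log-likelihood is minimised by L-BFGS-B
with an analytic gradient, restarted from a deterministic Cartesian grid of
start points (slopes {0.1, 1, 3} × criteria {−1, 0, 1}; 27 starts for the
3-parameter models, 81 for M3). Bounds are `w ∈ [0, 20]`,
`b ∈ [−5, 5]` — generous for a task whose evidence axis spans [−1, 1].
Ties between equally good optima are broken by the first-found start in
fixed grid order, so identical inputs always reproduce identical fits.
Degenerate data (e.g. a subject answering "anger" throughout) do not raise:
the optimum then sits on a parameter bound and the fit is flagged
`at_bound`. The likelihood of these models is smooth and, in the (slope ×
criterion) blocks into which it separates, effectively unimodal; the test
suite verifies the optimiser against a dense 0.01-step grid search that
exploits that separability exactly.

## Model evidence and group-level selection

Model evidence per subject is the maximised log-likelihood, unpenalised:
M1 and M2 have the same number of parameters, so complexity correction
cancels. For comparisons involving the 4-parameter M3, a BIC-penalised
evidence `LL − (k/2) ln n` is available alongside the raw value
(`evidence_matrix(..., penalty="bic")`), since nothing forces one convention
for unequal counts; both are reported rather than silently choosing.

*Fixed-effects* comparison assumes one mechanism for everyone: the group
log₁₀ Bayes factor is `Σ_subjects (LL_A − LL_B) / ln 10`.

*Random-effects* Bayesian model selection treats the governing model as a
random effect across subjects and estimates a Dirichlet posterior over model
frequencies by the variational scheme of Stephan et al. (2009): iterate

    u_nk ∝ exp(LL_nk + ψ(α_k) − ψ(Σ_j α_j)),   α_k = α₀ + Σ_n u_nk

until `max |Δα| < 1e-6` (flat prior α₀ = 1, at most 10 000 iterations;
non-convergence is flagged, not raised). The summary statistic is the
exceedance probability p_exc — the posterior probability that a model is the
most frequent in the population. For two models it is computed exactly via
the regularised incomplete beta function, `p_exc(1) = P(r₁ > ½)` under
`Beta(α₁, α₂)`; for three or more, by seeded Monte-Carlo Dirichlet sampling
(10⁶ draws by default).

One property of this scheme is easy to misread: a subject whose evidence is
identical under both models is *not* split 50/50 at the fixed point — the
digamma weights assign them in proportion to the estimated prevalence, so
expected frequencies stay essentially unchanged (the Dirichlet mass still
grows by one). The tests assert this actual fixed-point behaviour.

## Behavioural statistics

Accuracy is defined over emotion trials only; neutral faces have no correct
answer and score as undefined. The inclusion rule retains a subject iff
overall emotion-trial accuracy is **at least** 60% — the boundary is
inclusive, mirroring the wording of the criterion it implements.

The Threat+/Threat− contrast averages cell accuracies (emotion × gaze ×
morph level) with equal weight and is tested with a paired t; Cohen's d uses
the within-subject convention, mean difference over the SD of differences.
The focal gaze × emotion interaction is tested exactly rather than through
an omnibus ANOVA: for a 2×2 within-subject layout, the repeated-measures
interaction F equals t² of a one-sample t on the per-subject difference of
differences `(A_direct − A_averted) − (F_direct − F_averted)`, with
df (1, n−1). The difference of differences is algebraically twice the
Threat+ − Threat− contrast, a relation the tests check. If every subject has
exactly additive cells the difference variance is zero and the t statistic
is undefined; this raises rather than returning 0/0.

The neutral-face fingerprint — the anger-response rate to neutral faces
under direct vs averted gaze — separates the two mechanisms behaviourally:
only a gaze-conditioned criterion produces a rate difference there. Pooled
rates are compared with Fisher's exact test.

## Trial schedules

Schedules present every stimulus of the grid exactly once, in `n_blocks`
equal blocks exactly balanced for emotion, gaze, gender and morph level.
Balance is enforced constructively: stimuli are stratified by the *joint*
emotion × morph × gaze × gender combination, each stratum shuffled and dealt
round-robin to blocks, then each block shuffled. This guarantees every
marginal balance exactly, at the cost of requiring each joint stratum count
(= identities per gender, for this grid) to be divisible by the block count;
infeasible requests raise `BalanceError` rather than approximating. The
default 20-identity / 5-block design satisfies it (10 per gender, 2 per
block per stratum). Left/right averted gaze is collapsed to a single
"averted" level — no analysis distinguishes the sides. The anger/fear hand
mapping alternates with subject parity and is schedule metadata only.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the images: each simulated observer draws parameters from a group-level
normal (truncated at zero for slopes; sd = 0 plants the mean exactly) and
responds Bernoulli in the model's choice probability over a freshly
shuffled balanced 600-trial schedule. Default groups are 21 "control"
observers under M1 (`w⁺ = 1.2, w⁻ = 0.9, b = 0`, sds 0.2) and 15 "patient"
observers under M2 (`w = 1.0, b_direct = +0.3, b_averted = −0.3`, sds 0.2)
— plausible magnitudes chosen so both mechanisms are detectable at 600
trials per subject; they are configuration, not empirical claims. One
master seed spawns independent per-subject substreams keyed on (group,
subject) indices, so cohorts are byte-reproducible and subjects independent.

What the generator does **not** emulate: reaction times, lapses or
attentional drift across blocks, identity-specific difficulty, perceptual
calibration error in the morphs, or any symptom-level structure. Passing
recovery tests therefore show that the pipeline is correct and
well-conditioned under its own assumptions — not that real data meet them.

## Problem sizes and numerical tolerances

Recovery checks run the full default cohort (36 subjects × 600 trials, both
models fitted per subject — about 2 000 optimisations, a few seconds in
total) at a fixed conventional seed (0). Likelihood values are verified
against per-trial summation at 1e-10; optimiser results against the dense
grid oracle within 1e-3 nats; closed-form exceedance against 10⁶-draw
sampling within 3 standard errors.

## Known limitations

* Discrimination of M1 from M2 on M1-generated data is intrinsically modest
  at 600 trials when the two slopes differ by only 0.3: with small cohorts,
  individual seeds can fail to reach a decisive exceedance probability.
  M2-generated data separate far more strongly (the neutral-face bias cannot
  be mimicked by M1).
* Parameter-recovery correlations are attenuated by per-subject estimation
  noise (slope SE ≈ 0.12 at 600 trials against a between-subject sd of 0.2),
  capping expected r near 0.85 for slopes under the default configuration.
* No hierarchical (shrinkage) fitting, no Bayesian posteriors over
  parameters, no protected exceedance probabilities, and no family-level
  inference — per-subject ML plus group-level BMS only.
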