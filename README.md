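# threatgaze

Signal-detection modelling of how gaze direction shapes facial-emotion
categorisation. Written for researchers in psychophysics and computational
psychiatry who study the anger/fear categorisation paradigm: morphed
emotional faces (7 intensity levels per emotion) shown with direct or
averted gaze, where threat-congruent combinations — anger with direct gaze,
fear with averted gaze ("Threat+") — are categorised more accurately than
the alternate pairings ("Threat−").

The package answers the mechanistic question behind that advantage. On each
trial the probability of an "anger" response is modelled as

    P(anger) = Φ(w·u + b)

with `u ∈ [−1, 1]` the signed morph evidence (positive anger, negative fear,
0 neutral) and Φ the standard normal CDF. Two competing 3-parameter models
differ in what gaze modulates:

* **M1 — perceptual sensitivity:** the slope splits by threat congruence
  (`w⁺` for Threat+, `w⁻` for Threat−), one criterion `b`;
* **M2 — decision bias:** one slope `w`, but the criterion splits by gaze
  (`b_direct`, `b_averted`), biasing even neutral-face responses;

plus a 4-parameter combined model **M3**. Each subject's models are fitted
by bounded multi-start maximum likelihood; groups are compared with a
fixed-effects log₁₀ Bayes factor and random-effects Bayesian model
selection (variational Dirichlet scheme, summarised by the exceedance
probability p_exc). Because no raw participant data are deposited for this
paradigm, the package ships a synthetic-cohort generator with known ground
truth, so the full inferential chain — design, simulation, fitting,
selection, behavioural contrasts — is testable end to end.

## Worked example

`examples/04_cohort_recovery.py` simulates the default cohort — 21
"control" observers generated under the sensitivity model and 15 "patient"
observers under the bias model, 600 balanced trials each — then fits both
models to every subject and runs the group-level comparison:

```
simulated 36 subjects, 21600 trials

controls (generated under M1):
  p_exc(M1) = 0.9935   log10 BF(M1 vs M2) = +5.24
  w+ > w-:  t(20) = 3.26, p = 0.0020, d = 0.711

patients (generated under M2):
  p_exc(M2) = 0.9997   log10 BF(M2 vs M1) = +20.27
  b_direct > b_averted:  t(14) = 9.93, p = 5.115e-08, d = 2.563
```

Each group's generative mechanism wins its model comparison (p_exc is the
posterior probability that the model is the more frequent one in the
population; the positive log₁₀ Bayes factor agrees under the
all-subjects-alike assumption), and the recovered parameters reproduce the
group-defining asymmetries: a steeper Threat+ slope in controls, an
anger-ward criterion under direct gaze in patients. The other examples walk
through schedule building, single-subject fitting, model selection, and the
behavioural contrasts — including the neutral-face fingerprint that only a
decision bias produces.

A thin CLI mirrors the pipeline for shell use:

```bash
threatgaze simulate --seed 3 --out trials.csv --truth truth.csv
threatgaze fit --data trials.csv --model M1 --model M2 --out fits.csv
threatgaze bms --fits fits.csv --models M1,M2 --out bms.json
threatgaze report --data trials.csv --out report.json
```

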