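"""Simulate one observer and recover their parameters by maximum likelihood.

The bias-model observer answers "anger" with probability Phi(w*u + b_gaze):
a criterion shifted towards "anger" under direct gaze and towards "fear"
under averted gaze, visible even on neutral faces (u = 0).
"""

import numpy as np

import threatgaze as tg
from threatgaze.simulate import simulate_trials

truth = tg.ObserverParameters("M2", w=1.0, b_direct=0.4, b_averted=-0.4)

# choice probabilities on neutral faces expose the bias directly
for gaze in ("direct", "averted"):
    s = tg.StimulusCondition(1, "female", "neutral", 0, gaze)
    print(f"P(anger | neutral, {gaze} gaze) = {tg.p_choose_anger(truth, s):.4f}")

grid = tg.enumerate_stimuli(20, 7)
schedule = tg.build_schedule(grid, 5, seed=7)
trials = simulate_trials(truth, schedule, np.random.default_rng(7))

fit = tg.fit_ml(trials, "M2", subject_id="demo")
print(f"\nfitted over {fit.n_trials} trials "
      f"(log-likelihood {fit.log_likelihood:.1f} nats):")
for name, value in fit.parameters.as_dict().items():
    print(f"  {name:10s} true {getattr(truth, name):+.2f}   "
          f"fitted {value:+.3f}")
# Fitted values land close to the planted ones; estimation noise at 600
# trials is roughly +/-0.1 on each parameter.
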