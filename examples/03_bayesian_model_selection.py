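"""Compare the sensitivity and bias models at the group level.

Simulates a small cohort generated by the decision-bias model, fits both
candidate models to every subject, and runs the fixed-effects Bayes factor
and random-effects BMS.  The exceedance probability p_exc is the posterior
probability that the named model is the more frequent one in the population.
"""

import threatgaze as tg
from threatgaze import selection
from threatgaze.simulate import DEFAULT_PATIENT, GroupConfig, generate_cohort

group = GroupConfig("demo", 12, "M2", DEFAULT_PATIENT.means, DEFAULT_PATIENT.sds)
cohort = generate_cohort([group], master_seed=11)

fits = tg.fit_cohort(cohort.trials, ("M1", "M2"))
ev = selection.evidence_matrix(fits)

ffx = selection.ffx_bayes_factor(ev, "M2", "M1")
print(f"fixed effects: log10 BF(M2 vs M1) = "
      f"{ffx.log10_group_bayes_factor:+.2f} -> winner {ffx.winning_model}")

bms = selection.rfx_bms(ev)
for model, freq, pexc in zip(bms.model_ids, bms.expected_frequencies,
                             bms.exceedance_probabilities):
    print(f"random effects: {model}  expected frequency {freq:.3f}  "
          f"p_exc {pexc:.3f}")
# Data were generated under M2 (a gaze-conditioned criterion shift), and
# both statistics point at M2: a positive log10 Bayes factor and an
# exceedance probability near 1.  The sensitivity model cannot mimic the
# bias signature on neutral faces, which is what drives the separation.
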