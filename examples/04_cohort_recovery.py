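"""Full two-group recovery: the study's inferential logic on synthetic data.

Controls are generated by the perceptual-sensitivity model (steeper slope
for Threat+ faces), patients by the decision-bias model (criterion shifted
by gaze).  Fitting both models per subject and running random-effects BMS
per group should re-select each group's generative mechanism, and the
recovered parameters should show the group-defining contrasts.
"""

import threatgaze as tg
from threatgaze import behavior, selection
from threatgaze.simulate import generate_cohort

cohort = generate_cohort(master_seed=0)  # 21 controls + 15 patients
print(f"simulated {cohort.trials['subject'].nunique()} subjects, "
      f"{len(cohort.trials)} trials")

for label, model, other in (("control", "M1", "M2"), ("patient", "M2", "M1")):
    fits = tg.fit_cohort(cohort.group_trials(label), ("M1", "M2"))
    ev = selection.evidence_matrix(fits)
    bms = selection.rfx_bms(ev)
    ffx = selection.ffx_bayes_factor(ev, model, other)
    print(f"\n{label}s (generated under {model}):")
    print(f"  p_exc({model}) = {bms.p_exc(model):.4f}   "
          f"log10 BF({model} vs {other}) = {ffx.log10_group_bayes_factor:+.2f}")

    fitted = tg.fits_to_frame(
        [f for f in fits if f.model_id == model]
    ).set_index("subject")
    if model == "M1":
        res = behavior.paired_t(fitted["w_plus"], fitted["w_minus"], tail="one")
        print(f"  w+ > w-:  t({res.df}) = {res.statistic:.2f}, "
              f"p = {res.p_value:.4f}, d = {res.cohen_d:.3f}")
    else:
        res = behavior.paired_t(fitted["b_direct"], fitted["b_averted"], tail="one")
        print(f"  b_direct > b_averted:  t({res.df}) = {res.statistic:.2f}, "
              f"p = {res.p_value:.4g}, d = {res.cohen_d:.3f}")
# Each group's own mechanism wins its model comparison, and the recovered
# parameters reproduce the group-defining asymmetry.
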