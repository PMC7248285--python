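"""Build the full stimulus grid and a balanced trial schedule.

20 identities x (7 morph levels x 2 emotions x 2 gaze directions + 2 neutral
faces) = 600 stimuli, presented once each across 5 blocks of 120 trials with
every block exactly balanced for emotion, gaze, gender and morph level.
"""

import threatgaze as tg

grid = tg.enumerate_stimuli(n_identities=20, n_levels=7)
print(f"stimulus grid: {len(grid)} conditions "
      f"({len(grid) // 20} per identity)")

schedule = tg.build_schedule(grid, n_blocks=5, seed=42, subject_index=0)
print(f"schedule: {len(schedule)} trials in {schedule.n_blocks} blocks, "
      f"anger hand = {schedule.response_mapping['anger']}")

per_block = schedule.trials.groupby(["block", "emotion"]).size().unstack()
print("\nemotion counts per block (identical rows = exact balance):")
print(per_block.to_string())
# 56 anger + 56 fear + 8 neutral per block: the balance the task demands so
# that no block over-represents any stimulus class.
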