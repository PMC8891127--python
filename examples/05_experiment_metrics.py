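"""Build the 6x6x3 classification schedule and score simulated listeners.

The testing phase presents 6 parameter combinations (blocks, Latin-square
counterbalanced) x 6 patterns x 3 repetitions = 108 trials per
participant.  A uniform-random responder pins down the 6-AFC chance
level; an ideal responder checks the scoring path end to end.
"""

import pandas as pd

from sts_sonify import accuracy_percent, build_schedule, confusion_matrix, f_score, simulate_responses

sched = build_schedule(participant=0, seed=0)
print(f"one participant: {len(sched)} trials "
      f"({sched['block'].nunique()} blocks)")

all_scheds = pd.concat(
    [build_schedule(participant=i, seed=0) for i in range(25)],
    ignore_index=True)
print(f"25 participants: {len(all_scheds)} response records")

uniform = simulate_responses(all_scheds, "uniform", seed=1)
print(f"uniform-random responder accuracy: {accuracy_percent(uniform):.2f}% "
      "(chance = 16.67%)")

ideal = simulate_responses(all_scheds, "ideal")
cm = confusion_matrix(ideal)
print(f"ideal responder accuracy: {accuracy_percent(ideal):.2f}%, "
      f"F(P4) = {f_score(cm, 'P4')[2]:.2f}")
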