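"""Build working-memory task trials and continuous input streams.

Generates Match-First trials (respond "yes" iff the last cue equals the
first), concatenates them into a separator-delimited stream, and shows the
reward values delivered at decision timesteps under both reward schemes.
"""

import numpy as np

from wmrnn import TaskSpec, build_stream, reward, sample_trial
from wmrnn.taskgen import Trial

spec = TaskSpec(task="match_first", set_size=5, trial_size=4, encoding="scalar")
rng = np.random.default_rng(0)

trials = [sample_trial(spec, rng) for _ in range(3)]
for t in trials:
    print(f"cues {t.cues}  lead={t.lead_cue} test={t.test_cue}  -> {t.label}")

stream = build_stream(trials, spec)
print("\nscalar stream (0 = separator / blank screen):")
print("-".join(str(int(c)) for c in stream.cue_ids))
print("decision timesteps:", stream.decision_steps.tolist())

# rewards: +5 correct / -5 incorrect; the recency scheme pays +3 and +1 for
# "yes" on the two near-miss no-match patterns instead of -5
xaxa = Trial(cues=(2, 1, 3, 1), label="no_match")
xxaa = Trial(cues=(2, 3, 1, 1), label="no_match")
print("\nreward('yes' to a match trial):         ",
      reward(Trial((1, 2, 3, 1), "match"), "yes"))
print("reward('yes' to 2-1-3-1, original):     ", reward(xaxa, "yes"))
print("reward('yes' to 2-1-3-1, recency):      ", reward(xaxa, "yes", "recency"))
print("reward('yes' to 2-3-1-1, recency):      ", reward(xxaa, "yes", "recency"))
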