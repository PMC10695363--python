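"""State-space geometry of a trained agent: sorting directions and clusters.

Trains one agent to moderate proficiency, records hidden states after the
first three cues of each correct test trial, embeds them with PCA, and
measures (i) the cue-sorting directions and their angles and (ii) the
pairwise distances between lead-cue cluster centroids.  Aligned sorting
directions (small theta_12) put particular cue-history clusters close
together — overlap there produces the "recency-like" error pattern.
"""

import numpy as np

from wmrnn import TaskSpec, TrainConfig, evaluate, train
from wmrnn import geometry
from wmrnn.behavior import match_error_profile

spec = TaskSpec()
checkpoints = train(spec, 25, TrainConfig(checkpoint_episodes=(0, 20_000)), seed=3)
log = evaluate(checkpoints[20_000], spec, n_test=5_000, seed=30, record_states=True)
print(f"performance at 20k episodes: {log.performance:.3f}")

states = geometry.collect_states(log, after_cue=3, filter="correct")
geo = geometry.sorting_geometry(states)
print(f"top-3 PC variance: {geo.variance_top3:.1%}")
print("sorting-direction angles (deg):",
      {k: round(v, 1) for k, v in geo.angles.items()})

values, D = geometry.intercluster_distances(
    geo.embedding, states.labels["cue1"].to_numpy()
)
print("\nlead-cue centroid distances (PC units):")
print(np.round(D, 2))

prof = match_error_profile(log, spec)
r, p, _ = geometry.distance_error_correlation(values, D, prof)
print(f"\ndistance vs paired match-error rate: Pearson r = {r:+.2f} (p = {p:.3g})")
print("closer clusters -> more confusions between their cue sequences.")
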