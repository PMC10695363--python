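"""Original vs recency-based reward shaping, with matched seeds.

The recency scheme pays +3 / +1 for "yes" on the two near-miss no-match
patterns (X-A-X-A / X-X-A-A) instead of -5.  This example trains small
matched-seed cohorts under both schemes and prints the per-checkpoint mean
performance and SPC slope.  Note the shaping trap this scheme creates under
balanced trial sampling: a constant-"yes" policy earns +1.31 per trial on
average, so agents can stall at chance accuracy before escaping — see
docs/methods.md for the analysis.
"""

from wmrnn import TaskSpec
from wmrnn.experiments import GridConfig, aggregate, compare_reward_schemes

cfg = GridConfig(
    spec=TaskSpec(),
    sizes=(25,),
    checkpoints=(0, 6_000, 12_000),
    replicates=3,
    master_seed=5,
    n_test=2_000,
)
table = compare_reward_schemes(cfg)
for scheme, sub in table.groupby("scheme"):
    print(f"\n{scheme} reward scheme:")
    agg = aggregate(sub, by=("n_ep",))
    print(agg[["n_ep", "performance_mean", "performance_sem",
               "slope_mean", "slope_sem"]].round(3).to_string(index=False))
print("\nmatched seeds: replicate k shares its initialisation and trial")
print("stream across the two schemes, so differences are scheme effects.")
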