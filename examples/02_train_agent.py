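"""Train a small LSTM agent with advantage actor-critic and watch it learn.

A 25-unit agent learns Match-First (set size 5) by trial and error: +5/-5
rewards only, gradient updates every 3 trials, discount gamma = 0.  Test
performance is the fraction of correctly answered trials with actions
sampled from the learned policy.  A few thousand episodes lift the agent
off chance; tens of thousands are needed for high proficiency.
"""

from wmrnn import TaskSpec, TrainConfig, evaluate, train

spec = TaskSpec()
config = TrainConfig(checkpoint_episodes=(0, 2_000, 5_000, 10_000))

checkpoints = train(spec, n_units=25, config=config, seed=7)

print(f"{'episodes':>10} {'performance':>12} {'yes-rate':>9}")
for n_ep, params in sorted(checkpoints.items()):
    log = evaluate(params, spec, n_test=2_000, seed=100 + n_ep)
    print(f"{n_ep:>10} {log.performance:>12.3f} {log.responses.mean():>9.3f}")
print("\nperformance ~0.5 at 0 episodes is chance; the agent improves as the")
print("policy learns to compare the final cue against the stored lead cue.")
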