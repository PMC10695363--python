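# wmrnn

Recurrent agents trained by reinforcement learning on working-memory
match-to-sample tasks, with the behavioral and state-space analyses needed
to characterise *how* they solve them.

Monkeys and humans performing delayed match-to-sample tasks can reach
similar accuracy with apparently different strategies: error patterns that
look *recency-based* (yes-responses driven by how recently the probe cue
was last seen) versus *target-selective* (elevated yes-rate only when the
task-relevant cue matches).  `wmrnn` provides a complete simulation
testbed for studying this distinction in small LSTM agents: task
generation, actor-critic training, serial-position-curve behavioral
analysis, and PCA-based cluster geometry of hidden states.  Trained agents
progress from random responding through a recency-like phase to target
selectivity — and the recency-like phase turns out to be a signature of
partially-separated hidden-state clusters, not of a recency rule.

The package is aimed at computational-neuroscience researchers who want a
small, fully inspectable model of strategy formation under reinforcement
learning, with every analysis re-derivable from logged agent behavior.

## The model

The agent is a single-layer LSTM (`n` units; the focal model has 25) with
the standard gated update

    f_t = σ(W_xf x_t + W_hf h_{t-1} + b_f)        (forget gate)
    i_t = σ(W_xi x_t + W_hi h_{t-1} + b_i)        (input gate)
    o_t = σ(W_xo x_t + W_ho h_{t-1} + b_o)        (output gate)
    c_t = f_t ∘ c_{t-1} + i_t ∘ tanh(W_xc x_t + W_hc h_{t-1} + b_c)
    h_t = o_t ∘ tanh(c_t)

and two linear readouts of `h_t`: a softmax policy π over {yes, no} and a
value estimate V.  Input is `[cue, one-hot(a_{t-1}), r_{t-1}]`.  Training
is advantage actor-critic: with advantage `δ_t = R_t − V(s_t)` and
discount γ = 0 (so `R_t = r_t`), Adam (lr 1e-3) descends

    L = Σ_t [ −log π(a_t|s_t) δ_t + (β_v/2) δ_t² − β_H H(π_t) ],

β_v = β_H = 0.05, updating every 3 trials with the hidden state carried
across trials.  Rewards are +5/−5 at the decision timestep (an optional
recency-shaping scheme pays +3/+1 for "yes" on the two near-miss no-match
patterns).  Behavior is summarised by the **serial position curve** (SPC):
yes-rate versus the recency position at which the test cue last appeared,
with a two-point linear fit whose *slope* indexes recency-like responding
and whose *residual* (hit rate minus the extrapolated fit) indexes target
selectivity.  Hidden-state geometry is summarised by PCA cluster
centroids, cue *sorting directions* and their angles, and intercluster
distances.

## Worked example

Scripted agents illustrate what the SPC metrics measure
(`python examples/03_serial_position_curves.py`):

```
 target-selective: yes-rates {-3: 1.00, -2: 0.00, -1: 0.00}
                   slope=+0.000  residual=+1.000  performance=1.000
          recency: yes-rates {-3: 0.85, -2: 0.54, -1: 0.35}
                   slope=-0.183  residual=+0.133  performance=0.819
```

The selective agent says yes only at the target position (-3, where the
lead cue sits): residual 1, slope 0.  The recency agent's yes-rate decays
with distance from the target: negative slope, small residual — the two
phenotypes the slope/residual pair separates.

Training a real agent (`python examples/02_train_agent.py`) shows the
learning progression; `examples/04_state_space_geometry.py` trains one
agent to the intermediate stage and prints its sorting-direction angles,
lead-cue centroid distances, and the negative distance–error correlation
that explains the recency-like error pattern as cluster overlap.  The
other examples cover trial/stream construction and the reward-scheme
comparison.

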