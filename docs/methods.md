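# Methods

`wmrnn` simulates how a small gated recurrent network learns delayed
match-to-sample working-memory tasks by reinforcement, and provides the two
analysis families used to characterise what the network has learned: serial
position curves of its yes/no behavior, and the principal-component
geometry of its hidden-state clusters.

## Tasks and trial generation

Three tasks share one trial grammar: a sequence of cues (integers in
`[1, set_size]`) followed by a yes/no decision at the final cue.

| task | trial size | "match" means |
|---|---|---|
| same_different | 2 | cue 2 equals cue 1 |
| match_first | 4 or 8 | last cue equals the first (lead) cue |
| match_any | 4 or 8 | last cue equals any earlier cue in the trial |

Cues are encoded either as a single scalar (`cue 3 -> [3.]`, a
similarity-based code in which numerically close cues produce similar
inputs) or as one-hot vectors (all cues equidistant).  Trials are separated
by one blank timestep (zero input); a stream therefore looks like
`0-3-1-5-2-0-2-4-3-2-0` for two scalar-encoded 4-cue trials.

**Match fraction.**  The task definition does not fix the match/no-match
base rate.  The generator draws the label first (default probability 0.5)
and then samples cues consistent with it.  Balanced classes make chance
performance 50% and keep both hit and false-alarm rates informative at
every training stage; the fraction is configurable.  Distractor cues (the
positions between lead and test in match_first) are sampled uniformly from
cues other than the lead, and may repeat each other or the test cue — this
is what creates the near-miss no-match patterns X-A-X-A (test cue repeated
at position 2) and X-X-A-A (repeated at position 3) that the error
analyses depend on.

**Rewards.**  +5 for a correct decision, -5 for an incorrect one, 0 at all
other timesteps.  The recency-based shaping scheme (match_first, 4-cue
trials only) replaces -5 with +3 for "yes" to X-A-X-A and +1 for "yes" to
X-X-A-A, leaving all other rewards unchanged.

## Agent

The agent is a single-layer LSTM with `n` units (default grids span 5–500;
the focal model has 25), using the standard forget/input/output-gated cell
update with sigmoid gates and tanh nonlinearities, plus two independent
linear readouts of the output `h_t`: a 2-logit softmax policy over
{yes, no} and a scalar state-value estimate.  The input at each timestep
is `[encoded cue, one-hot(previous action), previous reward]`
(dimension `cue_dim + 3`); at a stream start the trailing slots are zero.

Initialisation: gate and readout weights are uniform with fan-in scaling
(`U(-1/sqrt(fan_in), 1/sqrt(fan_in))`), all biases zero (including the
forget gate), `h = c = 0`.  A forget-gate bias of 1.0 was evaluated and
rejected: it slows learning enough to miss the intermediate-stage
performance levels this package reproduces.

The forward pass, backpropagation through time, and the Adam optimizer are
implemented directly in NumPy; the analytic gradients are verified against
central finite differences in the test suite (1e-5 relative agreement).

## Training

Advantage actor-critic.  Over each update segment the loss

    L = sum_t [ -log pi(a_t|s_t) * delta_t + (beta_v/2) * delta_t^2
                - beta_H * H(pi_t) ]

is minimised by Adam (learning rate 1e-3, default moment decays 0.9/0.999,
eps 1e-8), where `delta_t = R_t - V(s_t)` is the advantage (treated as a
constant in the policy term) and `R_t` the discounted return with
`gamma = 0`, so `R_t = r_t`: actions before the decision timestep have no
bearing on the outcome, and non-decision timesteps contribute only through
the value and entropy terms (their policy terms vanish as `V -> 0` there).
`beta_v = beta_H = 0.05`.  Updates occur every 3 trials; the hidden state
is carried across trials and across segments, with gradients truncated at
segment boundaries.  The loss sums over all timesteps of the segment (a
decision-timesteps-only variant is available as a config switch but trains
unreliably and is not used).  Segments are shortened where necessary so
parameter snapshots land exactly on the checkpoint grid, by default
{0, 5, 10, 20, 30, 40, 50} x 10^3 episodes (one episode = one trial).

Evaluation freezes the parameters and runs fresh trials with actions
sampled from the policy (not argmax — response *rates* are the object of
study), feeding actions and rewards back as inputs, and optionally
recording the hidden state after each cue.  One master seed fans out into
separate initialisation / trial / action streams per run; the run seed is
independent of the reward scheme so scheme comparisons use matched seeds.

## Behavioral analyses

**Serial position curve (SPC).**  Trials are binned by the within-trial
recency position of the most recent earlier occurrence of the test cue
(for 4-cue trials: -1, -2, -3; a separate "no-prior" bin holds trials
whose test cue is new, excluded from fits).  The yes-rate per bin is the
curve; the yes-rate at the target position (-3 for match_first, where the
lead cue sits) is the hit rate.  A least-squares line over the two usable
positions adjacent to the target gives the *slope*; the *residual* is
`hit_rate - fit(target_position)`.  Random behavior: slope ~ 0, residual
~ 0.  Recency-like behavior: negative slope (yes-rate rises toward the
target side), small residual.  Target-selective behavior: slope ~ 0,
residual -> 1.  Empty bins propagate as NaN with counts, never imputed;
fits with |slope| > 1 rate/position are flagged, not dropped.

**Match-error profiles.**  Among erroneous "yes" responses in each
near-miss category (X-A-X-A, X-X-A-A) and for each target cue A, the share
attributable to each lead-cue identity is reported against the parity
baseline `100/(set_size-1)%` that a pure recency strategy predicts.  For
the distance–error analyses, each unordered cue pair (i, j) is assigned
the mean of its two directed X-A-X-A yes-error rates (j-i-X-i and
i-j-X-j); when the two disagree, averaging is the declared convention.

**Replicate statistics.**  Means with SEM over independently trained
networks; one-sample and paired one-sided t-tests on replicate-level
summaries (slopes, angles).  Zero-variance inputs are flagged degenerate.

## State-space geometry

Hidden states recorded at a fixed within-trial point (after cue 3 for
sorting directions and intercluster distances; after the final cue for
solution-map analyses) on the filter named per analysis (correct trials by
default; correct-after-correct for trajectory collection) are embedded with
mean-centred PCA (top 3 components).  PCA is fitted per checkpoint, never
pooled across checkpoints.

*Sorting direction* for cue position k: the total-least-squares line (first
principal axis) through the centroids of the embedded states grouped by
the cue shown at position k, oriented by increasing cue value; directions
2 and 3 are computed within the sub-cloud whose first cue is 1.  Total
least squares is used because a least-squares line through 3-D points is
direction-symmetric.  Angles between directions are reported on the
oriented vectors in [0, 180] degrees for the scalar encoding (cue order is
meaningful there); one-hot runs have no cue order, so their angles fold to
[0, 90] via a mode flag.  *Intercluster distances* are Euclidean distances
between lead-cue centroids in top-3 PC space, in arbitrary PC-score units
(no normalisation across networks).

## Reproduction arms and problem sizes

`wmrnn.reproduction` re-derives the headline quantities from scratch:
10 independently seeded 25-unit replicates per arm (scalar/original,
recency-reward to 12k, one-hot to 20k), 5000 test episodes per checkpoint,
and a reduced grid (sizes {10, 25, 50} x checkpoints {0, 10, 20, 50}k x 3
seeds) for the residual–performance correlation.  The full published-scale
grid (sizes to 500 units, 8 task variants) is reachable through
`GridConfig` but is not part of the default suite.

## Findings the implementation reproduces, and two it does not

The qualitative learning progression reproduces robustly: agents move from
random responding through a recency-like phase (significantly negative
mean SPC slope at intermediate checkpoints) to target selectivity
(residual > 0.5, slope ~ 0 by 50k), with ~77% mean performance at 20k and
>90% at 50k; match errors concentrate on cue-adjacent leads (lead-2 share
of X-1-X-1 errors ~3x parity, lead-5 near zero), refuting a true recency
strategy; one-hot networks show idiosyncratic per-network error profiles
whose intercluster distances correlate negatively with paired match-error
rates (9 of 10 replicates at the default seed; the exception is an
undertrained network, and the replicate mean is strongly negative); the
within-replicate increase of theta_12 from 20k to 50k is significant
(paired one-sided p ~ 1e-3); and the SPC residual tracks performance
across the size x experience grid at r > 0.9.  The target-cue-stratified
recency contrast (edge targets 1 and 5 more recency-like than middle
targets) is directionally present but reaches significance only for
target 5 at 10 replicates.

Two quantitative results deviate, and are left visible rather than tuned
away:

1. **Recency-reward acceleration.**  Under balanced trial sampling
   (match fraction 0.5) the recency shaping scheme makes the constant-yes
   policy a positive-expected-value attractor: EV(always yes) =
   0.5(+5) + 0.5(3/16·3 + 3/16·1 − 10/16·5) = **+1.31 per trial**, while
   EV(always no) = 0.  The value head learns this baseline, advantages at
   the attractor shrink toward zero, and agents stall at ~50% accuracy
   until exploration tips them out (typically 15–25k episodes) — the
   shaping *delays* rather than accelerates learning here.  Lowering the
   match fraction only moves the trap (at 0.35 the constant-no policy
   becomes the positive-EV attractor; under this scheme some constant
   policy always has positive EV).  Performance at the 12k recency
   checkpoint therefore sits near chance instead of ~72%.
2. **Sorting-angle magnitudes at fixed checkpoints.**  theta_12 is small
   (~38–50 deg) in replicates still inside the recency-like phase and grows
   with training — the mechanism the angle is meant to index — but our
   replicates traverse that phase at individually different times, so at
   the fixed 20k checkpoint the replicate mean is inflated by networks
   already past the phase, and by 50k the second-cue code's component
   along the first-cue axis has shrunk to ~0 with arbitrary (but stable,
   verified at 30k-episode sampling depth) sign, pushing oriented angles
   past orthogonality.  Mean theta_12 at the 20k/50k checkpoints therefore
   overshoots the reference values, while the paired within-replicate
   *increase* of theta_12 from 20k to 50k — the directional claim — holds.

## What the generator does and does not emulate

The generator reproduces the trial grammar, encodings, and reward
contingencies of the behavioral protocol; it does not model stimulus
rendering, psychophysical timing, shaping protocols, or subjects' prior
experience.  Passing tests therefore speak to the learning dynamics and
state-space geometry of the model class under this grammar, not to any
property of biological subjects.

## Numerical notes

Float64 throughout.  Softmax is computed with max-subtraction; policy
probabilities are clipped at 1e-12 inside logs.  Training aborts with a
diagnostic on non-finite loss.  PCA of rank-deficient state sets returns
the available components and the caller sees the shorter variance vector.
Degenerate geometry inputs (coincident centroids, zero vectors, constant
distances or error rates) raise or flag rather than returning silent
values.  Checkpoints are single-file `.npz` containers with a JSON
metadata record; reload is bit-exact.
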