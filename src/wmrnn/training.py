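"""Advantage actor-critic (A2C) training and evaluation of the LSTM agent.

The agent interacts with a continuous trial stream (leading separator, then
the trial's cues; the decision is scored at the final cue).  Training
minimises, by Adam gradient descent with backpropagation through time over
3-trial segments, the composite loss

    L = sum_t [ -log pi(a_t) * delta_t  +  (beta_v / 2) * delta_t^2
                - beta_H * H(pi_t) ]

where delta_t = R_t - V(s_t) is the advantage, R_t the discounted return
(R_t = r_t when gamma = 0, the default: actions before the decision step
have no bearing on the outcome), and H the policy entropy.  delta is
treated as a constant in the policy term; the value term's gradient is
-beta_v * delta * dV/dtheta.  The recurrent state is carried across trials
and across update segments (gradients are truncated at segment boundaries).

All gradients are computed analytically (see ``segment_grads``); the
finite-difference oracle in the test suite checks them against numerical
differentiation of ``segment_loss``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .lstm import (
    ACTIONS,
    AgentParams,
    init_params,
    input_dim_for,
    sigmoid,
)
from .taskgen import TaskSpec, reward as trial_reward, sample_trial

DEFAULT_CHECKPOINTS = (0, 5_000, 10_000, 20_000, 30_000, 40_000, 50_000)


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the A2C training loop.

    Defaults follow the simulation protocol: beta_v = beta_H = 0.05,
    Adam with learning rate 1e-3, gamma = 0, a gradient update every
    3 trials, checkpoints on the {0, 5, 10, 20, 30, 40, 50} x 10^3 grid,
    and 5000 test episodes per checkpoint.
    """

    beta_v: float = 0.05
    beta_h: float = 0.05
    learning_rate: float = 1e-3
    gamma: float = 0.0
    update_every: int = 3
    checkpoint_episodes: tuple[int, ...] = DEFAULT_CHECKPOINTS
    n_test: int = 5000
    loss_timesteps: str = "all"  # or "decision": score decision steps only
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.beta_v < 0 or self.beta_h < 0:
            raise ValueError("beta_v and beta_h must be >= 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.loss_timesteps not in ("all", "decision"):
            raise ValueError("loss_timesteps must be 'all' or 'decision'")


def discounted_return(
    rewards: Sequence[float], terminal_value: float = 0.0, gamma: float = 0.0
) -> np.ndarray:
    """Discounted returns R_t = sum_i gamma^i r_{t+i} + gamma^k V(s_{t+k}).

    ``terminal_value`` is the bootstrap value at the state following the
    last reward.  With gamma = 0 this reduces to R_t = r_t.
    """
    rewards = np.asarray(rewards, dtype=float)
    out = np.empty_like(rewards)
    acc = float(terminal_value)
    for t in range(len(rewards) - 1, -1, -1):
        acc = rewards[t] + gamma * acc
        out[t] = acc
    return out


@dataclass
class StepRecord:
    """Per-timestep record of one agent-environment interaction."""

    t: int
    x: np.ndarray
    pi: np.ndarray
    V: float
    action: int
    reward: float
    is_decision: bool
    h: np.ndarray | None = None
    logits: np.ndarray | None = None


@dataclass
class LossComponents:
    policy: float
    value: float
    entropy: float

    @property
    def total(self) -> float:
        return self.policy + self.value + self.entropy


def a2c_loss(segment: Sequence[StepRecord], config: TrainConfig) -> LossComponents:
    """Loss components over a recorded segment (analysis-side computation).

    Returns are recomputed from the recorded rewards per trial (a decision
    timestep ends each episodic unit), so the segment must cover an integer
    number of trials.
    """
    if not segment[-1].is_decision:
        raise ValueError("segment must end at a decision timestep")
    rewards = np.array([r.reward for r in segment])
    returns = np.empty(len(segment))
    start = 0
    for t, rec in enumerate(segment):
        if rec.is_decision:
            returns[start : t + 1] = discounted_return(
                rewards[start : t + 1], 0.0, config.gamma
            )
            start = t + 1
    pol = val = ent = 0.0
    for rec, R in zip(segment, returns):
        if config.loss_timesteps == "decision" and not rec.is_decision:
            continue
        delta = R - rec.V
        pol += -np.log(rec.pi[rec.action]) * delta
        val += 0.5 * config.beta_v * delta**2
        p = np.clip(rec.pi, 1e-12, None)
        ent += -config.beta_h * float(-(p * np.log(p)).sum())
    return LossComponents(policy=float(pol), value=float(val), entropy=float(ent))


# ---------------------------------------------------------------------------
# segment-level loss and analytic gradients (the BPTT core)
# ---------------------------------------------------------------------------


def _forward_segment(params: AgentParams, xs: np.ndarray, h0, c0):
    """Run the LSTM over a segment, returning all per-step caches."""
    T = xs.shape[0]
    n, D = params.n, params.input_dim
    xh = np.empty((T, D + n))
    f = np.empty((T, n))
    i = np.empty((T, n))
    o = np.empty((T, n))
    g = np.empty((T, n))
    cs = np.empty((T + 1, n))
    tanh_c = np.empty((T, n))
    hs = np.empty((T + 1, n))
    hs[0] = h0
    cs[0] = c0
    W, b = params.W, params.b
    for t in range(T):
        xh[t, :D] = xs[t]
        xh[t, D:] = hs[t]
        z = xh[t] @ W + b
        gates = sigmoid(z[: 3 * n])
        f[t] = gates[:n]
        i[t] = gates[n : 2 * n]
        o[t] = gates[2 * n :]
        g[t] = np.tanh(z[3 * n :])
        cs[t + 1] = f[t] * cs[t] + i[t] * g[t]
        tanh_c[t] = np.tanh(cs[t + 1])
        hs[t + 1] = o[t] * tanh_c[t]
    logits = hs[1:] @ params.W_pi + params.b_pi
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    pis = e / e.sum(axis=1, keepdims=True)
    Vs = hs[1:] @ params.W_v + params._bv_arr[0]
    return dict(xh=xh, f=f, i=i, o=o, g=g, cs=cs, tanh_c=tanh_c, hs=hs,
                logits=logits, pis=pis, Vs=Vs)


def segment_loss(
    params: AgentParams,
    xs: np.ndarray,
    actions: np.ndarray,
    returns: np.ndarray,
    h0: np.ndarray,
    c0: np.ndarray,
    config: TrainConfig,
    mask: np.ndarray | None = None,
    policy_weights: np.ndarray | None = None,
) -> float:
    """Scalar segment loss as a pure function of the parameters.

    ``policy_weights`` fixes the advantage multipliers of the policy term
    (delta is treated as a constant there); pass the delta values computed
    at the reference parameters when differentiating numerically.  When
    omitted, the current delta values are used.
    """
    cache = _forward_segment(params, xs, h0, c0)
    pis, Vs = cache["pis"], cache["Vs"]
    deltas = returns - Vs
    w = deltas if policy_weights is None else np.asarray(policy_weights)
    if mask is None:
        mask = np.ones(len(xs))
    logp = np.log(pis[np.arange(len(xs)), actions])
    p = np.clip(pis, 1e-12, None)
    H = -(p * np.log(p)).sum(axis=1)
    pol = -(mask * logp * w).sum()
    val = 0.5 * config.beta_v * (mask * deltas**2).sum()
    ent = -config.beta_h * (mask * H).sum()
    return float(pol + val + ent)


def segment_grads(
    params: AgentParams,
    xs: np.ndarray,
    actions: np.ndarray,
    returns: np.ndarray,
    h0: np.ndarray,
    c0: np.ndarray,
    config: TrainConfig,
    mask: np.ndarray | None = None,
    cache: dict | None = None,
):
    """Analytic gradients of ``segment_loss`` w.r.t. all parameters.

    Returns (loss components, list of gradient arrays in ``params.arrays()``
    order, final (h, c)).
    """
    T = xs.shape[0]
    n, D = params.n, params.input_dim
    if cache is None:
        cache = _forward_segment(params, xs, h0, c0)
    xh, f, i, o, g = cache["xh"], cache["f"], cache["i"], cache["o"], cache["g"]
    cs, tanh_c, hs = cache["cs"], cache["tanh_c"], cache["hs"]
    pis, Vs = cache["pis"], cache["Vs"]
    if mask is None:
        mask = np.ones(T)

    deltas = returns - Vs
    idx = np.arange(T)
    logpi = np.log(np.clip(pis, 1e-12, None))
    H = -(pis * logpi).sum(axis=1)

    pol = -(mask * logpi[idx, actions] * deltas).sum()
    val = 0.5 * config.beta_v * (mask * deltas**2).sum()
    ent = -config.beta_h * (mask * H).sum()
    components = LossComponents(policy=float(pol), value=float(val), entropy=float(ent))

    # heads: d loss / d logits and d loss / d V, all vectorised
    onehot = np.zeros((T, 2))
    onehot[idx, actions] = 1.0
    dlogits = (pis - onehot) * deltas[:, None]  # from -log pi(a) * delta
    dlogits += config.beta_h * pis * (logpi + H[:, None])  # from -beta_h * H
    dlogits *= mask[:, None]
    dV = -config.beta_v * deltas * mask

    gW_pi = hs[1:].T @ dlogits
    gb_pi = dlogits.sum(axis=0)
    gW_v = hs[1:].T @ dV
    gb_v = np.array([dV.sum()])
    dh_base = dlogits @ params.W_pi.T + dV[:, None] * params.W_v

    # backward through time
    dz = np.empty((T, 4 * n))
    dh_next = np.zeros(n)
    dc_next = np.zeros(n)
    WT = params.W.T
    for t in range(T - 1, -1, -1):
        dh = dh_base[t] + dh_next
        do = dh * tanh_c[t]
        dc = dh * o[t] * (1.0 - tanh_c[t] ** 2) + dc_next
        dz[t, :n] = dc * cs[t] * f[t] * (1.0 - f[t])
        dz[t, n : 2 * n] = dc * g[t] * i[t] * (1.0 - i[t])
        dz[t, 2 * n : 3 * n] = do * o[t] * (1.0 - o[t])
        dz[t, 3 * n :] = dc * i[t] * (1.0 - g[t] ** 2)
        dxh = dz[t] @ WT
        dh_next = dxh[D:]
        dc_next = dc * f[t]

    gW = xh.T @ dz
    gb = dz.sum(axis=0)
    final = (hs[T].copy(), cs[T].copy())
    return components, [gW, gb, gW_pi, gb_pi, gW_v, gb_v], final


class AdamOptimizer:
    """Standard Adam (bias-corrected first/second moments)."""

    def __init__(self, arrays: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.arrays = arrays
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for a, gr, m, v in zip(self.arrays, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * gr
            v *= b2
            v += (1.0 - b2) * gr * gr
            a -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _segment_returns(rewards: np.ndarray, decision: np.ndarray, gamma: float) -> np.ndarray:
    """Per-trial discounted returns over a segment (a decision ends a trial)."""
    if gamma == 0.0:
        return rewards.copy()
    out = np.empty_like(rewards)
    start = 0
    for t in range(len(rewards)):
        if decision[t]:
            out[start : t + 1] = discounted_return(rewards[start : t + 1], 0.0, gamma)
            start = t + 1
    return out


def train(
    spec: TaskSpec,
    n_units: int,
    config: TrainConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    callback: Callable[[int, float], None] | None = None,
) -> dict[int, AgentParams]:
    """Train one agent; return parameter snapshots keyed by episode count.

    One master seed fans out into three independent streams (parameter
    initialisation, trial sampling, action sampling), so agents built from
    the same seed are bit-identical and follow identical trajectories.
    """
    config = config or TrainConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_rng, task_rng, act_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    D = input_dim_for(spec.cue_dim)
    params = init_params(n_units, D, init_rng, meta={"task": spec.task})
    n = n_units
    checkpoints: dict[int, AgentParams] = {}
    grid = sorted(set(config.checkpoint_episodes))
    n_total = max(grid) if grid else 0
    if 0 in grid:
        checkpoints[0] = params.copy()

    opt = AdamOptimizer(
        params.arrays(), config.learning_rate,
        config.adam_beta1, config.adam_beta2, config.adam_eps,
    )
    L = spec.trial_size
    steps_per_trial = L + 1  # leading separator + cues
    Tseg = config.update_every * steps_per_trial

    # encoded cue lookup: row c is the encoding of cue id c (0 = blank)
    from .taskgen import encode_cue

    cue_table = np.stack([encode_cue(c, spec) for c in range(spec.set_size + 1)])
    cue_dim = spec.cue_dim

    h = np.zeros(n)
    c = np.zeros(n)
    prev_action: int | None = None
    prev_reward = 0.0
    episodes_done = 0

    xs = np.empty((Tseg, D))
    actions = np.empty(Tseg, dtype=int)
    rewards = np.empty(Tseg)
    decision = np.zeros(Tseg, dtype=bool)
    W, b = params.W, params.b  # live views; Adam updates in place
    W_pi, b_pi, W_v = params.W_pi, params.b_pi, params.W_v

    pending = [ep for ep in grid if ep > 0]
    while episodes_done < n_total:
        n_trials = min(config.update_every, n_total - episodes_done)
        if pending:
            # shorten the segment so snapshots land exactly on grid values
            n_trials = min(n_trials, pending[0] - episodes_done)
        T = n_trials * steps_per_trial
        h0, c0 = h.copy(), c.copy()
        t = 0
        for _ in range(n_trials):
            trial = sample_trial(spec, task_rng)
            step_cues = (0,) + trial.cues
            for j, cue in enumerate(step_cues):
                xs[t, :cue_dim] = cue_table[cue]
                xs[t, cue_dim] = 1.0 if prev_action == 0 else 0.0
                xs[t, cue_dim + 1] = 1.0 if prev_action == 1 else 0.0
                xs[t, cue_dim + 2] = prev_reward
                z = np.concatenate([xs[t], h]) @ W + b
                gates = sigmoid(z[: 3 * n])
                cc = gates[:n] * c + gates[n : 2 * n] * np.tanh(z[3 * n :])
                h = gates[2 * n :] * np.tanh(cc)
                c = cc
                logits = h @ W_pi + b_pi
                m = logits[0] if logits[0] > logits[1] else logits[1]
                e0, e1 = np.exp(logits[0] - m), np.exp(logits[1] - m)
                p_yes = e0 / (e0 + e1)
                a = 0 if act_rng.random() < p_yes else 1
                is_dec = j == L
                if is_dec:
                    r = trial_reward(trial, ACTIONS[a], spec.reward_scheme)
                else:
                    r = 0.0
                actions[t] = a
                rewards[t] = r
                decision[t] = is_dec
                prev_action, prev_reward = a, r
                t += 1

        returns = _segment_returns(rewards[:T], decision[:T], config.gamma)
        mask = decision[:T].astype(float) if config.loss_timesteps == "decision" else None
        components, grads, (h, c) = segment_grads(
            params, xs[:T], actions[:T], returns, h0, c0, config, mask=mask
        )
        if not np.isfinite(components.total):
            raise TrainingDiverged(
                f"non-finite loss at episode {episodes_done}: {components}"
            )
        opt.step(grads)
        episodes_done += n_trials
        if callback is not None:
            callback(episodes_done, components.total)
        while pending and episodes_done >= pending[0]:
            checkpoints[pending.pop(0)] = params.copy()

    for ep, p in checkpoints.items():
        p.meta.update(n_ep=ep)
    return checkpoints


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EpisodeLog:
    """Outcome of a frozen-parameter test run.

    Per-trial arrays (length ``n_test``): cue sequences, match labels,
    yes responses, correctness, previous-trial correctness, decision
    rewards.  ``states[k, j]`` is the hidden output h after cue ``j+1`` of
    trial ``k`` (present when recorded).  ``step_pi``/``step_V`` hold the
    per-timestep policy and value along each trial (separator + cues).
    """

    spec: TaskSpec
    cues: np.ndarray
    labels: np.ndarray      # True = match
    responses: np.ndarray   # True = yes
    correct: np.ndarray
    prev_correct: np.ndarray
    rewards: np.ndarray
    states: np.ndarray | None = None
    step_pi: np.ndarray | None = None
    step_V: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return len(self.cues)

    @property
    def performance(self) -> float:
        """Fraction of correct trials."""
        return float(self.correct.mean())

    def trial_table(self) -> "pd.DataFrame":
        import pandas as pd

        L = self.spec.trial_size
        out = pd.DataFrame(
            {f"cue{j + 1}": self.cues[:, j] for j in range(L)}
        )
        out["label"] = np.where(self.labels, "match", "no_match")
        out["response"] = np.where(self.responses, "yes", "no")
        out["correct"] = self.correct
        out["prev_correct"] = self.prev_correct
        out["reward"] = self.rewards
        return out


def evaluate(
    params: AgentParams,
    spec: TaskSpec,
    n_test: int = 5000,
    record_states: bool = False,
    record_steps: bool = False,
    seed: int | np.random.SeedSequence = 0,
    policy: Callable | None = None,
) -> EpisodeLog:
    """Run ``n_test`` trials with frozen parameters, sampling actions from pi.

    ``policy`` optionally overrides the agent's policy: a callable
    ``(trial, step_index, pi) -> action index`` used to script behaviours
    (e.g. an always-yes or oracle agent) while keeping the environment loop
    identical.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    task_rng, act_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    n, D = params.n, params.input_dim
    if D != input_dim_for(spec.cue_dim):
        raise ValueError(
            f"checkpoint input dim {D} incompatible with encoding "
            f"(expected {input_dim_for(spec.cue_dim)})"
        )
    L = spec.trial_size
    from .taskgen import encode_cue

    cue_table = np.stack([encode_cue(c, spec) for c in range(spec.set_size + 1)])
    cue_dim = spec.cue_dim

    cues = np.empty((n_test, L), dtype=int)
    labels = np.empty(n_test, dtype=bool)
    responses = np.empty(n_test, dtype=bool)
    correct = np.empty(n_test, dtype=bool)
    prev_correct = np.empty(n_test, dtype=bool)
    rewards = np.empty(n_test)
    states = np.empty((n_test, L, n)) if record_states else None
    step_pi = np.empty((n_test, L + 1, 2)) if record_steps else None
    step_V = np.empty((n_test, L + 1)) if record_steps else None

    W, b = params.W, params.b
    W_pi, b_pi, W_v = params.W_pi, params.b_pi, params.W_v
    bv = params._bv_arr[0]
    h = np.zeros(n)
    c = np.zeros(n)
    prev_action: int | None = None
    prev_reward = 0.0
    was_correct = False
    x = np.empty(D)

    for k in range(n_test):
        trial = sample_trial(spec, task_rng)
        cues[k] = trial.cues
        labels[k] = trial.label == "match"
        prev_correct[k] = was_correct if k > 0 else False
        step_cues = (0,) + trial.cues
        for j, cue in enumerate(step_cues):
            x[:cue_dim] = cue_table[cue]
            x[cue_dim] = 1.0 if prev_action == 0 else 0.0
            x[cue_dim + 1] = 1.0 if prev_action == 1 else 0.0
            x[cue_dim + 2] = prev_reward
            z = np.concatenate([x, h]) @ W + b
            gates = sigmoid(z[: 3 * n])
            cc = gates[:n] * c + gates[n : 2 * n] * np.tanh(z[3 * n :])
            h = gates[2 * n :] * np.tanh(cc)
            c = cc
            logits = h @ W_pi + b_pi
            m = logits[0] if logits[0] > logits[1] else logits[1]
            e0, e1 = np.exp(logits[0] - m), np.exp(logits[1] - m)
            p_yes = e0 / (e0 + e1)
            if policy is None:
                a = 0 if act_rng.random() < p_yes else 1
            else:
                a = int(policy(trial, j, np.array([p_yes, 1.0 - p_yes])))
            if record_steps:
                step_pi[k, j] = (p_yes, 1.0 - p_yes)
                step_V[k, j] = h @ W_v + bv
            if j > 0 and record_states:
                states[k, j - 1] = h
            if j == L:
                r = trial_reward(trial, ACTIONS[a], spec.reward_scheme)
                responses[k] = a == 0
                correct[k] = (a == 0) == labels[k]
                rewards[k] = r
                was_correct = bool(correct[k])
            else:
                r = 0.0
            prev_action, prev_reward = a, r

    return EpisodeLog(
        spec=spec,
        cues=cues,
        labels=labels,
        responses=responses,
        correct=correct,
        prev_correct=prev_correct,
        rewards=rewards,
        states=states,
        step_pi=step_pi,
        step_V=step_V,
    )
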