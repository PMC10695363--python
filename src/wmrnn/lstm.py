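"""Gated recurrent agent: LSTM dynamics plus linear policy/value readouts.

The recurrent state update is the standard forget/input/output-gated cell,

    f_t = sigmoid(W_xf x_t + W_hf h_{t-1} + b_f)
    i_t = sigmoid(W_xi x_t + W_hi h_{t-1} + b_i)
    o_t = sigmoid(W_xo x_t + W_ho h_{t-1} + b_o)
    c_t = f_t * c_{t-1} + i_t * tanh(W_xc x_t + W_hc h_{t-1} + b_c)
    h_t = o_t * tanh(c_t)

with elementwise (*) gating.  Two independent linear heads read the output
h_t: a 2-logit policy head (softmax over {yes, no}) and a scalar value head.

The input vector at each timestep is the concatenation
``[encoded cue, one-hot(previous action), previous reward]``; at the start
of a stream the action and reward slots are zero.

Weights are stored as one stacked matrix ``W`` of shape
``(input_dim + n, 4n)`` with gate blocks ordered (f, i, o, c); named views
(``W_xf`` etc.) are exposed as properties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

ACTIONS = ("yes", "no")
ACTION_INDEX = {"yes": 0, "no": 1}


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class AgentParams:
    """All trainable parameters of one agent.

    W      : (input_dim + n, 4n) stacked gate weights, blocks (f, i, o, c);
             the first ``input_dim`` rows are the input weights W_x*, the
             remaining ``n`` rows the recurrent weights W_h*.
    b      : (4n,) gate biases, same block order.
    W_pi   : (n, 2) policy-head weights; b_pi: (2,).
    W_v    : (n,)  value-head weights;  b_v: scalar.
    """

    n: int
    input_dim: int
    W: np.ndarray
    b: np.ndarray
    W_pi: np.ndarray
    b_pi: np.ndarray
    W_v: np.ndarray
    b_v: float
    meta: dict = field(default_factory=dict)

    def _block(self, which: str, gate: str) -> np.ndarray:
        g = "fioc".index(gate)
        rows = slice(0, self.input_dim) if which == "x" else slice(self.input_dim, None)
        return self.W[rows, g * self.n : (g + 1) * self.n]

    # named views onto the stacked weight matrix
    @property
    def W_xf(self):
        return self._block("x", "f")

    @property
    def W_hf(self):
        return self._block("h", "f")

    @property
    def W_xi(self):
        return self._block("x", "i")

    @property
    def W_hi(self):
        return self._block("h", "i")

    @property
    def W_xo(self):
        return self._block("x", "o")

    @property
    def W_ho(self):
        return self._block("h", "o")

    @property
    def W_xc(self):
        return self._block("x", "c")

    @property
    def W_hc(self):
        return self._block("h", "c")

    def bias(self, gate: str) -> np.ndarray:
        g = "fioc".index(gate)
        return self.b[g * self.n : (g + 1) * self.n]

    def arrays(self) -> list[np.ndarray]:
        """The six trainable arrays, in a fixed order (b_v as 1-element)."""
        return [self.W, self.b, self.W_pi, self.b_pi, self.W_v, self._bv_arr]

    def __post_init__(self) -> None:
        self._bv_arr = np.atleast_1d(np.asarray(self.b_v, dtype=float))
        self.b_v = self._bv_arr  # keep scalar head bias as a mutable view

    def copy(self) -> "AgentParams":
        return AgentParams(
            n=self.n,
            input_dim=self.input_dim,
            W=self.W.copy(),
            b=self.b.copy(),
            W_pi=self.W_pi.copy(),
            b_pi=self.b_pi.copy(),
            W_v=self.W_v.copy(),
            b_v=float(self._bv_arr[0]),
            meta=dict(self.meta),
        )


@dataclass
class AgentState:
    """Recurrent state: output vector h and cell state c, both length n."""

    h: np.ndarray
    c: np.ndarray

    def copy(self) -> "AgentState":
        return AgentState(self.h.copy(), self.c.copy())


@dataclass
class PolicyValue:
    """Policy distribution over {yes, no}, value estimate, raw logits."""

    pi: np.ndarray
    V: float
    logits: np.ndarray


def init_params(
    n: int, input_dim: int, rng: np.random.Generator, meta: dict | None = None
) -> AgentParams:
    """Uniform fan-in-scaled weight initialization, zero biases.

    Gate weights are drawn U(-k, k) with k = 1/sqrt(input_dim + n); head
    weights with k = 1/sqrt(n).  All biases (including the forget gate) are
    zero, and the initial h = c = 0.
    """
    k = 1.0 / np.sqrt(input_dim + n)
    kh = 1.0 / np.sqrt(n)
    return AgentParams(
        n=n,
        input_dim=input_dim,
        W=rng.uniform(-k, k, size=(input_dim + n, 4 * n)),
        b=np.zeros(4 * n),
        W_pi=rng.uniform(-kh, kh, size=(n, 2)),
        b_pi=np.zeros(2),
        W_v=rng.uniform(-kh, kh, size=n),
        b_v=0.0,
        meta=meta or {},
    )


def initial_state(n: int) -> AgentState:
    return AgentState(h=np.zeros(n), c=np.zeros(n))


def lstm_step(
    params: AgentParams, state: AgentState, x: np.ndarray
) -> tuple[AgentState, np.ndarray]:
    """One recurrent update; returns the new state and its output h_t."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.input_dim,):
        raise ValueError(f"input shape {x.shape} != ({params.input_dim},)")
    n = params.n
    z = np.concatenate([x, state.h]) @ params.W + params.b
    gates = sigmoid(z[: 3 * n])
    f, i, o = gates[:n], gates[n : 2 * n], gates[2 * n :]
    g = np.tanh(z[3 * n :])
    c = f * state.c + i * g
    h = o * np.tanh(c)
    return AgentState(h=h, c=c), h


def policy_value(params: AgentParams, h: np.ndarray) -> PolicyValue:
    """Linear policy and value readouts of the LSTM output."""
    logits = h @ params.W_pi + params.b_pi
    shifted = logits - logits.max()
    e = np.exp(shifted)
    pi = e / e.sum()
    V = float(h @ params.W_v + params._bv_arr[0])
    return PolicyValue(pi=pi, V=V, logits=logits)


def build_input(
    cue_vec: np.ndarray, prev_action: str | int | None, prev_reward: float
) -> np.ndarray:
    """Compose the agent input ``[cue, one-hot(a_{t-1}), r_{t-1}]``.

    ``prev_action=None`` (stream start) leaves the action slots zero.
    """
    act = np.zeros(2)
    if prev_action is not None:
        idx = ACTION_INDEX[prev_action] if isinstance(prev_action, str) else int(prev_action)
        act[idx] = 1.0
    return np.concatenate([np.asarray(cue_vec, dtype=float), act, [float(prev_reward)]])


def input_dim_for(cue_dim: int) -> int:
    """Agent input dimension for a given encoded-cue length."""
    return cue_dim + 2 + 1


def save_checkpoint(path, params: AgentParams) -> None:
    """Write all parameter arrays plus metadata to a single .npz file."""
    np.savez(
        path,
        W=params.W,
        b=params.b,
        W_pi=params.W_pi,
        b_pi=params.b_pi,
        W_v=params.W_v,
        b_v=params._bv_arr,
        meta=np.array(json.dumps({"n": params.n, "input_dim": params.input_dim, **params.meta})),
    )


def load_checkpoint(path) -> AgentParams:
    """Bit-exact reload of a saved checkpoint."""
    with np.load(path) as data:
        meta = json.loads(str(data["meta"]))
        return AgentParams(
            n=int(meta.pop("n")),
            input_dim=int(meta.pop("input_dim")),
            W=data["W"],
            b=data["b"],
            W_pi=data["W_pi"],
            b_pi=data["b_pi"],
            W_v=data["W_v"],
            b_v=float(data["b_v"][0]),
            meta=meta,
        )
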