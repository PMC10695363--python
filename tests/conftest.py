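import numpy as np
import pytest

from wmrnn import TaskSpec
from wmrnn.lstm import init_params, input_dim_for


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mf_spec():
    """Match-First, set size 5, trial size 4, scalar encoding."""
    return TaskSpec()


@pytest.fixture
def tiny_params(rng, mf_spec):
    """A small random agent compatible with the scalar Match-First task."""
    return init_params(3, input_dim_for(mf_spec.cue_dim), rng)


def scripted_policy(kind: str, seed: int = 0, rates: dict | None = None):
    """Scripted action rules for evaluation-loop tests.

    kind:
      "always_yes"  — yes at every timestep
      "oracle"      — yes iff the trial is a match (perfect agent)
      "selective"   — yes iff lead cue equals test cue (target-selective)
      "recency"     — at the decision step, yes with a probability given by
                      ``rates[recency position]``; no otherwise
    """
    prng = np.random.default_rng(seed)

    def policy(trial, step_index, pi):
        L = len(trial.cues)
        if kind == "always_yes":
            return 0
        if step_index < L:  # non-decision steps: arbitrary fixed action
            return 1
        if kind == "oracle":
            return 0 if trial.label == "match" else 1
        if kind == "selective":
            return 0 if trial.cues[0] == trial.cues[-1] else 1
        if kind == "recency":
            test = trial.cues[-1]
            pos = 0
            for k in range(1, L):
                if trial.cues[L - 1 - k] == test:
                    pos = -k
                    break
            p = rates.get(pos, 0.0)
            return 0 if prng.random() < p else 1
        raise ValueError(kind)

    return policy
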