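"""Trial generation for the Wittig-style working-memory tasks.

Three tasks are supported, each a sequence of cues followed by a yes/no
("match" / "no match") decision at the final cue:

* ``same_different`` — two cues; match iff they are equal.
* ``match_first``    — 4 or 8 cues; match iff the last cue equals the first
  (the *lead* cue).  Intervening cues are task-irrelevant *distractors*.
* ``match_any``      — 4 or 8 cues; match iff the last cue equals any
  earlier cue in the trial.

Cues are integers in ``[1, set_size]`` and can be encoded either as a single
scalar (a similarity-based code: cue 3 -> [3.]) or as a one-hot vector.
Timesteps with no cue (trial separators) are encoded as zero.

Trials are concatenated into continuous streams of the form
``sep, cues_1, sep, cues_2, ..., sep`` — e.g. two match-first trials
[3,1,5,2] and [2,4,3,2] under scalar encoding give the cue-id sequence
0-3-1-5-2-0-2-4-3-2-0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

TASKS = ("same_different", "match_first", "match_any")
ENCODINGS = ("scalar", "one_hot")
REWARD_SCHEMES = ("original", "recency")

#: reward values delivered at the decision timestep
REWARD_CORRECT = 5.0
REWARD_INCORRECT = -5.0
#: recency-scheme rewards for "yes" on the two near-miss no-match patterns
REWARD_XAXA = 3.0
REWARD_XXAA = 1.0


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent task specification."""


@dataclass(frozen=True)
class TaskSpec:
    """Full specification of one task variant.

    Parameters
    ----------
    task : {"same_different", "match_first", "match_any"}
    set_size : int
        Number of distinct cue types (>= 2).
    trial_size : int
        Cues per trial; must be 2 for same_different, >= 2 otherwise.
    encoding : {"scalar", "one_hot"}
    reward_scheme : {"original", "recency"}
        The recency scheme is only defined for match_first with trial size 4.
    match_fraction : float
        Probability that a sampled trial is a match trial.  The base rate is
        not pinned down by the task definition; balanced classes (0.5) are
        the default.
    """

    task: str = "match_first"
    set_size: int = 5
    trial_size: int = 4
    encoding: str = "scalar"
    reward_scheme: str = "original"
    match_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ConfigurationError(f"unknown task {self.task!r}")
        if self.encoding not in ENCODINGS:
            raise ConfigurationError(f"unknown encoding {self.encoding!r}")
        if self.reward_scheme not in REWARD_SCHEMES:
            raise ConfigurationError(f"unknown reward scheme {self.reward_scheme!r}")
        if self.set_size < 2:
            raise ConfigurationError("set_size must be >= 2")
        if self.trial_size < 2:
            raise ConfigurationError("trial_size must be >= 2")
        if self.task == "same_different" and self.trial_size != 2:
            raise ConfigurationError("same_different requires trial_size 2")
        if self.task == "match_first" and self.trial_size < 3:
            raise ConfigurationError("match_first requires trial_size >= 3")
        if not 0.0 <= self.match_fraction <= 1.0:
            raise ConfigurationError("match_fraction must lie in [0, 1]")
        if self.reward_scheme == "recency":
            if self.task != "match_first" or self.trial_size != 4:
                raise ConfigurationError(
                    "recency reward scheme is defined only for match_first "
                    "with trial_size 4"
                )

    @property
    def cue_dim(self) -> int:
        """Length of one encoded cue vector."""
        return 1 if self.encoding == "scalar" else self.set_size

    @property
    def target_position(self) -> int:
        """Recency position of the target cue (match_first / same_different)."""
        return -(self.trial_size - 1)


def rule_label(cues: Sequence[int], task: str) -> str:
    """Ground-truth label ("match" / "no_match") of a cue sequence."""
    cues = list(cues)
    if task == "same_different":
        return "match" if cues[0] == cues[1] else "no_match"
    if task == "match_first":
        return "match" if cues[0] == cues[-1] else "no_match"
    if task == "match_any":
        return "match" if cues[-1] in cues[:-1] else "no_match"
    raise ConfigurationError(f"unknown task {task!r}")


@dataclass(frozen=True)
class Trial:
    """One trial: an ordered cue sequence plus its ground-truth label."""

    cues: tuple[int, ...]
    label: str

    @property
    def lead_cue(self) -> int:
        return self.cues[0]

    @property
    def test_cue(self) -> int:
        return self.cues[-1]

    def target_positions(self, task: str) -> tuple[int, ...]:
        """1-based positions compared against the test cue under ``task``."""
        if task in ("same_different", "match_first"):
            return (1,)
        return tuple(range(1, len(self.cues)))


def sample_trial(
    spec: TaskSpec,
    rng: np.random.Generator,
    force_label: str | None = None,
    lead: int | None = None,
) -> Trial:
    """Draw one trial.

    The label is drawn first (Bernoulli(match_fraction), unless forced) and
    cues are then sampled consistent with it, so the requested match fraction
    holds by construction.  For match_first, distractor cues are sampled
    uniformly from cues other than the lead cue; they may repeat each other
    or the test cue.
    """
    S, L = spec.set_size, spec.trial_size
    if force_label is None:
        label = "match" if rng.random() < spec.match_fraction else "no_match"
    else:
        if force_label not in ("match", "no_match"):
            raise ConfigurationError(f"bad label {force_label!r}")
        label = force_label

    if spec.task == "same_different":
        c1 = lead if lead is not None else int(rng.integers(1, S + 1))
        if label == "match":
            cues = (c1, c1)
        else:
            c2 = _uniform_excluding(rng, S, {c1})
            cues = (c1, c2)
    elif spec.task == "match_first":
        c1 = lead if lead is not None else int(rng.integers(1, S + 1))
        distractors = tuple(_uniform_excluding(rng, S, {c1}) for _ in range(L - 2))
        last = c1 if label == "match" else _uniform_excluding(rng, S, {c1})
        cues = (c1,) + distractors + (last,)
    else:  # match_any
        while True:
            first = lead if lead is not None else int(rng.integers(1, S + 1))
            earlier = (first,) + tuple(
                int(rng.integers(1, S + 1)) for _ in range(L - 2)
            )
            if label == "match":
                last = int(rng.choice(np.asarray(earlier)))
                cues = earlier + (last,)
                break
            avoid = set(earlier)
            if len(avoid) >= S:  # all cue types already shown; resample
                if lead is not None and S == 1:
                    raise ConfigurationError("cannot build no_match trial")
                continue
            last = _uniform_excluding(rng, S, avoid)
            cues = earlier + (last,)
            break

    assert rule_label(cues, spec.task) == label
    return Trial(cues=cues, label=label)


def _uniform_excluding(rng: np.random.Generator, set_size: int, avoid: set) -> int:
    """Uniform draw from [1, set_size] excluding ``avoid`` (rejection-free)."""
    allowed = [c for c in range(1, set_size + 1) if c not in avoid]
    if not allowed:
        raise ConfigurationError("no cue satisfies the exclusion constraint")
    return int(allowed[rng.integers(0, len(allowed))])


def encode_cue(cue_id: int | None, spec: TaskSpec) -> np.ndarray:
    """Encode a cue id (or 0/None for a blank timestep) as an input vector."""
    cue = 0 if cue_id is None else int(cue_id)
    if not 0 <= cue <= spec.set_size:
        raise ValueError(f"cue id {cue} outside [0, {spec.set_size}]")
    if spec.encoding == "scalar":
        return np.array([float(cue)])
    vec = np.zeros(spec.set_size)
    if cue > 0:
        vec[cue - 1] = 1.0
    return vec


@dataclass
class TrialStream:
    """Trials concatenated into a continuous timestep stream.

    ``cue_ids[t]`` is 0 on separator timesteps; ``inputs[t]`` is the encoded
    cue; ``decision_steps`` are the indices of each trial's last cue.
    """

    cue_ids: np.ndarray
    inputs: np.ndarray
    decision_steps: np.ndarray
    trials: list[Trial]
    spec: TaskSpec = field(repr=False)

    def __len__(self) -> int:
        return len(self.cue_ids)

    def to_frame(self) -> pd.DataFrame:
        """Plain-table view (timestep, trial index, cue id, is_decision)."""
        L = self.spec.trial_size
        trial_index = np.full(len(self), -1)
        for k in range(len(self.trials)):
            start = k * (L + 1) + 1
            trial_index[start : start + L] = k
        is_decision = np.zeros(len(self), dtype=bool)
        is_decision[self.decision_steps] = True
        return pd.DataFrame(
            {
                "timestep": np.arange(len(self)),
                "trial_index": trial_index,
                "cue_id": self.cue_ids,
                "is_decision": is_decision,
            }
        )


def build_stream(trials: Sequence[Trial], spec: TaskSpec) -> TrialStream:
    """Concatenate trials as ``sep, cues_1, sep, cues_2, ..., sep``."""
    if len(trials) == 0:
        raise ValueError("cannot build a stream from an empty trial list")
    L = spec.trial_size
    ids = [0]
    decision_steps = []
    for trial in trials:
        if len(trial.cues) != L:
            raise ValueError("trial length inconsistent with spec")
        ids.extend(trial.cues)
        decision_steps.append(len(ids) - 1)
        ids.append(0)
    cue_ids = np.asarray(ids)
    inputs = np.stack([encode_cue(c, spec) for c in cue_ids])
    return TrialStream(
        cue_ids=cue_ids,
        inputs=inputs,
        decision_steps=np.asarray(decision_steps),
        trials=list(trials),
        spec=spec,
    )


def parse_stream(cue_ids: Sequence[int], spec: TaskSpec) -> list[Trial]:
    """Recover the trial list from a stream's cue-id sequence."""
    ids = list(cue_ids)
    L = spec.trial_size
    if ids[0] != 0 or ids[-1] != 0:
        raise ValueError("stream must start and end with a separator")
    n, rem = divmod(len(ids) - 1, L + 1)
    if rem != 0:
        raise ValueError("stream length inconsistent with trial size")
    trials = []
    for k in range(n):
        chunk = ids[k * (L + 1) + 1 : k * (L + 1) + 1 + L]
        if 0 in chunk or ids[(k + 1) * (L + 1)] != 0:
            raise ValueError("separator pattern violated")
        cues = tuple(int(c) for c in chunk)
        trials.append(Trial(cues=cues, label=rule_label(cues, spec.task)))
    return trials


def is_xaxa(cues: Sequence[int]) -> bool:
    """True for X-A-X-A patterns: test cue repeated only at position 2."""
    c1, c2, c3, c4 = cues
    return c2 == c4 and c1 != c4 and c3 != c4


def is_xxaa(cues: Sequence[int]) -> bool:
    """True for X-X-A-A patterns: test cue repeated only at position 3."""
    c1, c2, c3, c4 = cues
    return c3 == c4 and c1 != c4 and c2 != c4


def reward(trial: Trial, response: str, scheme: str = "original") -> float:
    """Reward delivered at the trial's decision timestep.

    Original scheme: +5 for a correct response, -5 otherwise.  Recency
    scheme (match_first, trial size 4): a "yes" to an X-A-X-A no-match trial
    earns +3 and a "yes" to X-X-A-A earns +1; everything else is unchanged.
    """
    if response not in ("yes", "no"):
        raise ValueError(f"bad response {response!r}")
    if scheme not in REWARD_SCHEMES:
        raise ConfigurationError(f"unknown reward scheme {scheme!r}")
    correct = (response == "yes") == (trial.label == "match")
    if scheme == "recency" and response == "yes" and trial.label == "no_match":
        if len(trial.cues) != 4:
            raise ConfigurationError("recency scheme requires trial size 4")
        if is_xaxa(trial.cues):
            return REWARD_XAXA
        if is_xxaa(trial.cues):
            return REWARD_XXAA
    return REWARD_CORRECT if correct else REWARD_INCORRECT
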