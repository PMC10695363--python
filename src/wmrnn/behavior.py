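"""Behavioral analyses: serial position curves, linear fits, error profiles.

A *serial position curve* (SPC) sorts trials by how recently the test cue
(the final cue of a trial) was last presented within the trial and reports
the "yes" response rate at each recency position.  For a 4-cue trial the
within-trial positions are -1 (test cue repeated the immediately preceding
cue), -2, and -3; -3 is the *target* position for Match-First (the lead
cue), so the yes-rate there is the hit rate.  Trials whose test cue never
appeared earlier in the trial fall into a separate "no-prior" bin and are
excluded from fits.

The SPC is summarised by a least-squares line over the two positions
adjacent to the target; its *slope* signals recency-like behavior (negative
for Match-First) and its *residual* — observed hit rate minus the line
extrapolated to the target position — measures target selectivity (1 for a
pure target-selective agent, ~0 for random or pure recency behavior).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .taskgen import TaskSpec, is_xaxa, is_xxaa
from .training import EpisodeLog

NO_PRIOR = 0  # bin code for "test cue not previously seen in the trial"


def performance(log: EpisodeLog) -> float:
    """Fraction of correct trials."""
    return log.performance


def recency_positions(cues: np.ndarray) -> np.ndarray:
    """Within-trial recency position of the test cue for each trial.

    Position -k means the most recent earlier occurrence of the test cue
    was k steps before the final cue; 0 (NO_PRIOR) if it never occurred.
    """
    cues = np.asarray(cues)
    L = cues.shape[1]
    pos = np.zeros(len(cues), dtype=int)
    test = cues[:, -1]
    for k in range(1, L):  # nearest first: column L-1-k
        hit = (cues[:, L - 1 - k] == test) & (pos == 0)
        pos[hit] = -k
    return pos


@dataclass
class SerialPositionCurve:
    """Yes-rate per recency position, with counts and the target position."""

    positions: np.ndarray          # e.g. [-3, -2, -1]
    yes_rate: np.ndarray           # NaN where a bin is empty
    counts: np.ndarray
    target_position: int
    no_prior_rate: float = np.nan
    no_prior_count: int = 0
    stratum: int | None = None

    @property
    def hit_rate(self) -> float:
        """Yes-rate at the target position."""
        return float(self.yes_rate[self.positions == self.target_position][0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "yes_rate": self.yes_rate, "n": self.counts}
        )


def serial_position_curve(
    log: EpisodeLog, spec: TaskSpec | None = None, stratify: int | None = None
) -> SerialPositionCurve:
    """Bin trials by test-cue recency and measure the yes-rate per bin.

    ``stratify`` restricts the curve to trials whose test cue equals the
    given cue id.  Empty bins yield NaN rates (never silently zero).
    """
    spec = spec or log.spec
    L = spec.trial_size
    pos = recency_positions(log.cues)
    yes = log.responses
    keep = np.ones(len(pos), dtype=bool)
    if stratify is not None:
        keep = log.cues[:, -1] == stratify
    positions = np.arange(-(L - 1), 0)
    rates = np.full(len(positions), np.nan)
    counts = np.zeros(len(positions), dtype=int)
    for i, p in enumerate(positions):
        m = keep & (pos == p)
        counts[i] = m.sum()
        if counts[i]:
            rates[i] = yes[m].mean()
    m0 = keep & (pos == NO_PRIOR)
    return SerialPositionCurve(
        positions=positions,
        yes_rate=rates,
        counts=counts,
        target_position=spec.target_position,
        no_prior_rate=float(yes[m0].mean()) if m0.any() else np.nan,
        no_prior_count=int(m0.sum()),
        stratum=stratify,
    )


@dataclass
class SPCFit:
    """Least-squares line over SPC positions, and its target-point residual."""

    slope: float
    intercept: float
    residual: float
    positions_used: tuple[int, ...]
    extreme: bool = False  # flagged when the fitted slope is implausibly steep


def fit_spc(
    curve: SerialPositionCurve,
    positions_used: tuple[int, ...] | None = None,
    extreme_slope: float = 1.0,
) -> SPCFit:
    """Fit the SPC and extrapolate to the target position.

    By default the two usable positions nearest the target are fit (for a
    4-cue trial: -2 and -1).  residual = hit_rate - fit(target_position).
    Fits with |slope| above ``extreme_slope`` (rate per position) are
    flagged, not dropped.
    """
    if positions_used is None:
        usable = [
            int(p)
            for p, r in zip(curve.positions, curve.yes_rate)
            if p != curve.target_position and np.isfinite(r)
        ]
        usable.sort(key=lambda p: abs(p - curve.target_position))
        positions_used = tuple(sorted(usable[:2]))
    if len(positions_used) < 2:
        raise ValueError("need at least two usable positions for the fit")
    ps = np.asarray(positions_used, dtype=float)
    rs = np.array(
        [curve.yes_rate[curve.positions == p][0] for p in positions_used]
    )
    if not np.all(np.isfinite(rs)):
        raise ValueError(f"undefined yes-rate among positions {positions_used}")
    slope, intercept = np.polyfit(ps, rs, 1)
    resid = curve.hit_rate - (slope * curve.target_position + intercept)
    return SPCFit(
        slope=float(slope),
        intercept=float(intercept),
        residual=float(resid),
        positions_used=tuple(int(p) for p in positions_used),
        extreme=abs(slope) > extreme_slope,
    )


# ---------------------------------------------------------------------------
# match-error profiles (Match-First, 4-cue trials)
# ---------------------------------------------------------------------------


@dataclass
class ErrorProfile:
    """Lead-cue breakdown of erroneous "yes" responses, per target cue.

    ``table`` holds one row per (target cue A, lead cue, category) with the
    error count, trial count, yes-error rate, and the percentage share of
    that category's errors for target A.  Categories are the two near-miss
    no-match patterns "X-A-X-A" (test cue repeated at position 2) and
    "X-X-A-A" (repeated at position 3).  ``parity`` is the share a pure
    recency strategy would predict for every lead cue.
    """

    table: pd.DataFrame
    parity: float
    set_size: int

    def share(self, target: int, lead: int, category: str) -> float:
        t = self.table
        row = t[(t.target_cue == target) & (t.lead_cue == lead) & (t.category == category)]
        return float(row["percent"].iloc[0])

    def category_errors(self, target: int, category: str) -> int:
        t = self.table
        rows = t[(t.target_cue == target) & (t.category == category)]
        return int(rows["n_errors"].sum())


def match_error_profile(log: EpisodeLog, spec: TaskSpec | None = None) -> ErrorProfile:
    """Breakdown of match errors by lead-cue identity (Match-First, 4 cues).

    For each target cue A, erroneous "yes" responses on X-A-X-A and X-X-A-A
    no-match trials are attributed to their lead cue; the percentage share
    within each category is reported next to the parity baseline
    100/(set_size-1)%.  Categories with zero errors get NaN shares (flagged
    by the n_errors column), never an imputed value.
    """
    spec = spec or log.spec
    if spec.task != "match_first" or spec.trial_size != 4:
        raise ValueError("error profiles are defined for match_first, trial size 4")
    S = spec.set_size
    cues = log.cues
    yes = log.responses
    xaxa = np.array([is_xaxa(c) for c in cues])
    xxaa = np.array([is_xxaa(c) for c in cues])
    rows = []
    for A in range(1, S + 1):
        tgt = cues[:, -1] == A
        for category, cat_mask in (("X-A-X-A", xaxa), ("X-X-A-A", xxaa)):
            in_cat = tgt & cat_mask
            total_errors = int((in_cat & yes).sum())
            for lead in range(1, S + 1):
                if lead == A:
                    continue
                m = in_cat & (cues[:, 0] == lead)
                n_err = int((m & yes).sum())
                n_tr = int(m.sum())
                rows.append(
                    {
                        "target_cue": A,
                        "lead_cue": lead,
                        "category": category,
                        "n_errors": n_err,
                        "n_trials": n_tr,
                        "yes_rate": n_err / n_tr if n_tr else np.nan,
                        "percent": 100.0 * n_err / total_errors
                        if total_errors
                        else np.nan,
                    }
                )
    return ErrorProfile(
        table=pd.DataFrame(rows), parity=100.0 / (S - 1), set_size=S
    )


def pairwise_error_rates(profile: ErrorProfile) -> pd.DataFrame:
    """Mean directed X-A-X-A yes-error rate for each unordered cue pair.

    Pair (i, j) combines the yes-rates of j-i-X-i and i-j-X-j trials
    (lead j / target i and lead i / target j), averaged.
    """
    t = profile.table
    xaxa = t[t.category == "X-A-X-A"].set_index(["target_cue", "lead_cue"])
    rows = []
    for i in range(1, profile.set_size + 1):
        for j in range(i + 1, profile.set_size + 1):
            r_ij = xaxa.loc[(i, j), "yes_rate"]
            r_ji = xaxa.loc[(j, i), "yes_rate"]
            rows.append({"cue_i": i, "cue_j": j, "error_rate": (r_ij + r_ji) / 2.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# replicate-level significance tests
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    n: int
    degenerate: bool = False


def replicate_tests(
    values,
    kind: str = "one_sample_t",
    popmean: float = 0.0,
    alternative: str = "two-sided",
    paired_with=None,
) -> TestResult:
    """t-tests over replicate-level summaries (slopes, angles, ...).

    ``one_sample_t`` tests the replicate values against ``popmean``;
    ``paired_one_sided_t`` tests ``paired_with`` - ``values`` > 0 by default
    (alternative applies to the differences).  Zero-variance inputs are
    flagged as degenerate with NaN statistics.
    """
    values = np.asarray(values, dtype=float)
    if kind == "one_sample_t":
        if len(values) < 2:
            raise ValueError("need >= 2 replicates")
        if np.allclose(values, values[0]):
            return TestResult(np.nan, np.nan, len(values), degenerate=True)
        res = stats.ttest_1samp(values, popmean, alternative=alternative)
    elif kind == "paired_one_sided_t":
        other = np.asarray(paired_with, dtype=float)
        if other.shape != values.shape:
            raise ValueError("paired test requires equal-length replicate sets")
        diffs = other - values
        if np.allclose(diffs, diffs[0] if len(diffs) else 0.0):
            return TestResult(np.nan, np.nan, len(values), degenerate=True)
        res = stats.ttest_rel(other, values, alternative="greater")
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return TestResult(float(res.statistic), float(res.pvalue), len(values))


def spc_summary(log: EpisodeLog, spec: TaskSpec | None = None) -> dict:
    """Convenience bundle: performance, SPC, fit slope/residual, hit rate."""
    curve = serial_position_curve(log, spec)
    fit = fit_spc(curve)
    return {
        "performance": log.performance,
        "hit_rate": curve.hit_rate,
        "slope": fit.slope,
        "residual": fit.residual,
        "curve": curve,
        "fit": fit,
    }
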