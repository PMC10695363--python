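"""State-space geometry of the trained agent's hidden activity.

Hidden states recorded at a fixed point within each trial (e.g. after the
first three cues) are embedded with PCA; label-conditioned centroids in the
top-3 PC space yield

* *sorting directions* — the total-least-squares line through the centroids
  of states grouped by the cue shown at a given within-trial position,
  oriented by increasing cue value; the angles between successive sorting
  directions (theta_12, theta_23, theta_13) quantify how orthogonally the
  network separates cue history, and
* *intercluster distances* — pairwise Euclidean distances between lead-cue
  centroids, whose inverse relation to pairwise match-error rates shows
  that "recency-like" errors are really cluster-overlap errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA

from .behavior import ErrorProfile, pairwise_error_rates
from .training import EpisodeLog

FILTERS = ("all", "correct", "correct_after_correct")


@dataclass
class StateMatrix:
    """Hidden states (rows = trials) with the aligned per-trial label table."""

    X: np.ndarray
    labels: pd.DataFrame  # columns cue1..cueL, label, correct, prev_correct
    after_cue: int

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]


def collect_states(
    log: EpisodeLog, after_cue: int, filter: str = "correct"
) -> StateMatrix:
    """Extract the hidden state after cue ``after_cue`` (1-based) per trial.

    ``filter`` keeps all trials, correct trials, or correct trials that
    follow a correct trial.
    """
    if log.states is None:
        raise ValueError("log was recorded without hidden states")
    L = log.spec.trial_size
    if not 1 <= after_cue <= L:
        raise ValueError(f"after_cue must be in [1, {L}]")
    if filter not in FILTERS:
        raise ValueError(f"unknown filter {filter!r}")
    keep = np.ones(log.n_trials, dtype=bool)
    if filter in ("correct", "correct_after_correct"):
        keep &= log.correct
    if filter == "correct_after_correct":
        keep &= log.prev_correct
    if keep.sum() < 2:
        raise ValueError(f"filter {filter!r} leaves fewer than 2 trials")
    labels = pd.DataFrame(
        {f"cue{j + 1}": log.cues[keep, j] for j in range(L)}
    )
    labels["label"] = np.where(log.labels[keep], "match", "no_match")
    labels["correct"] = log.correct[keep]
    labels["prev_correct"] = log.prev_correct[keep]
    return StateMatrix(X=log.states[keep, after_cue - 1], labels=labels, after_cue=after_cue)


def save_state_matrix(path, sm: StateMatrix, **key) -> None:
    """Persist a StateMatrix to a single .npz file.

    ``key`` holds identifying metadata (e.g. seed, n_ep, filter) stored
    alongside ``after_cue``; the label table is stored column-wise.
    """
    cols = {}
    for c in sm.labels.columns:
        arr = sm.labels[c].to_numpy()
        if arr.dtype == object:  # string labels: store as fixed-width unicode
            arr = arr.astype("U")
        cols[f"label_{c}"] = arr
    np.savez(path, X=sm.X, after_cue=sm.after_cue,
             key=np.array(json.dumps(key)), **cols)


def load_state_matrix(path) -> tuple[StateMatrix, dict]:
    """Reload a persisted StateMatrix and its identifying metadata."""
    with np.load(path) as data:
        labels = pd.DataFrame(
            {k[len("label_"):]: data[k] for k in data.files if k.startswith("label_")}
        )
        sm = StateMatrix(
            X=data["X"], labels=labels, after_cue=int(data["after_cue"])
        )
        return sm, json.loads(str(data["key"]))


def pca_embed(states: StateMatrix | np.ndarray, k: int = 3):
    """Mean-centred PCA; returns (scores, variance fractions).

    If the data have rank < k, the available components are returned (the
    caller sees this in the length of the variance-fraction vector).
    """
    X = states.X if isinstance(states, StateMatrix) else np.asarray(states)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    k_eff = min(k, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k_eff)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_.copy()


def centroids_by_label(embedding: np.ndarray, labels: np.ndarray):
    """Per-label mean points, labels sorted ascending."""
    labels = np.asarray(labels)
    values = np.unique(labels)
    cents = np.stack([embedding[labels == v].mean(axis=0) for v in values])
    return values, cents


def sorting_direction(
    embedding: np.ndarray,
    labels: np.ndarray,
    restrict: np.ndarray | None = None,
) -> np.ndarray:
    """Unit vector along the TLS line through label-conditioned centroids.

    The line is the first principal axis of the centroid set (a least-squares
    line through points is direction-symmetric, so total least squares is
    the natural fit); the sign is oriented by increasing cue value.
    ``restrict`` optionally masks the rows used (e.g. first cue == 1 when
    computing the second and third sorting directions).
    """
    if restrict is not None:
        embedding = embedding[restrict]
        labels = np.asarray(labels)[restrict]
    values, cents = centroids_by_label(embedding, labels)
    if len(values) < 2:
        raise ValueError("need >= 2 labels with >= 1 point each")
    centred = cents - cents.mean(axis=0)
    if np.allclose(centred, 0.0):
        raise ValueError("all centroids coincide; sorting direction undefined")
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    # orient along increasing cue value
    if direction @ (cents[-1] - cents[0]) < 0:
        direction = -direction
    return direction / np.linalg.norm(direction)


def angle_between(u: np.ndarray, v: np.ndarray, fold: bool = False) -> float:
    """Angle between two directions in degrees, in [0, 180].

    ``fold=True`` folds to [0, 90] for runs where cue order is meaningless
    (one-hot encodings have no orientation convention).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("angle with a zero vector is undefined")
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    ang = float(np.degrees(np.arccos(cosang)))
    return min(ang, 180.0 - ang) if fold else ang


@dataclass
class ClusterGeometry:
    """Bundle of geometry summaries for one recorded state set."""

    embedding: np.ndarray
    variance_fractions: np.ndarray
    directions: dict[int, np.ndarray]
    angles: dict[str, float]
    centroid_labels: np.ndarray | None = None
    distance_matrix: np.ndarray | None = None

    @property
    def variance_top3(self) -> float:
        return float(self.variance_fractions[:3].sum())


def sorting_geometry(
    states: StateMatrix, k: int = 3, reference_cue: int = 1, fold: bool = False
) -> ClusterGeometry:
    """PCA embedding plus the three cue-position sorting directions.

    Direction 1 groups states by the first cue over all rows; directions
    2 and 3 group by the second/third cue within the subset whose first cue
    is ``reference_cue``.
    """
    scores, var = pca_embed(states, k)
    lab = states.labels
    d1 = sorting_direction(scores, lab["cue1"].to_numpy())
    ref = lab["cue1"].to_numpy() == reference_cue
    d2 = sorting_direction(scores, lab["cue2"].to_numpy(), restrict=ref)
    d3 = sorting_direction(scores, lab["cue3"].to_numpy(), restrict=ref)
    angles = {
        "theta_12": angle_between(d1, d2, fold=fold),
        "theta_23": angle_between(d2, d3, fold=fold),
        "theta_13": angle_between(d1, d3, fold=fold),
    }
    return ClusterGeometry(
        embedding=scores,
        variance_fractions=var,
        directions={1: d1, 2: d2, 3: d3},
        angles=angles,
    )


def intercluster_distances(
    embedding: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Euclidean distances between per-label centroids.

    Returns (sorted label values, symmetric distance matrix with zero
    diagonal), in arbitrary PC-score units.
    """
    values, cents = centroids_by_label(embedding, labels)
    if len(values) < 2:
        raise ValueError("need >= 2 labels")
    return values, squareform(pdist(cents))


def distance_error_correlation(
    label_values: np.ndarray,
    distances: np.ndarray,
    profile: ErrorProfile,
):
    """Pearson correlation between centroid distances and match-error rates.

    Each unordered lead-cue pair (i, j) is matched with the mean of the two
    directed X-A-X-A error yes-rates (j-i-X-i and i-j-X-j).  Degenerate
    inputs (constant distances or rates) return NaN with a flag.
    """
    rates = pairwise_error_rates(profile).set_index(["cue_i", "cue_j"])["error_rate"]
    ds, es = [], []
    for a in range(len(label_values)):
        for b_ in range(a + 1, len(label_values)):
            i, j = int(label_values[a]), int(label_values[b_])
            key = (min(i, j), max(i, j))
            if key in rates.index and np.isfinite(rates.loc[key]):
                ds.append(distances[a, b_])
                es.append(float(rates.loc[key]))
    ds, es = np.asarray(ds), np.asarray(es)
    if len(ds) < 3:
        raise ValueError("need >= 3 valid pairs")
    if np.allclose(ds, ds[0]) or np.allclose(es, es[0]):
        return np.nan, np.nan, True
    r, p = stats.pearsonr(ds, es)
    return float(r), float(p), False


def cluster_separation(embedding: np.ndarray, labels: np.ndarray) -> float:
    """Silhouette-style separation of label-conditioned clusters.

    Mean over labels of (nearest-other-centroid distance) / (mean in-cluster
    distance to own centroid); higher is better separated.
    """
    values, cents = centroids_by_label(embedding, labels)
    spreads = np.array(
        [
            np.linalg.norm(embedding[labels == v] - cents[k], axis=1).mean()
            for k, v in enumerate(values)
        ]
    )
    D = squareform(pdist(cents))
    np.fill_diagonal(D, np.inf)
    nearest = D.min(axis=1)
    return float((nearest / np.maximum(spreads, 1e-12)).mean())
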