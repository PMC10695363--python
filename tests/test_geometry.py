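"""PCA embedding, sorting directions, angles, intercluster distances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wmrnn import TaskSpec
from wmrnn.behavior import match_error_profile
from wmrnn.geometry import (
    angle_between,
    centroids_by_label,
    cluster_separation,
    collect_states,
    distance_error_correlation,
    intercluster_distances,
    pca_embed,
    sorting_direction,
)
from wmrnn.training import evaluate
from conftest import scripted_policy


@pytest.fixture
def recorded_log(mf_spec, tiny_params):
    return evaluate(tiny_params, mf_spec, n_test=400, seed=21, record_states=True)


class TestCollectStates:
    def test_correct_filter_row_count(self, recorded_log):
        sm = collect_states(recorded_log, after_cue=4, filter="correct")
        assert sm.n_trials == recorded_log.correct.sum()
        assert len(sm.labels) == sm.n_trials

    def test_after_cue_four_is_final_pre_response_state(self, recorded_log):
        sm = collect_states(recorded_log, after_cue=4, filter="all")
        np.testing.assert_array_equal(sm.X, recorded_log.states[:, 3])

    def test_correct_after_correct_is_subset_of_correct(self, recorded_log):
        a = collect_states(recorded_log, 3, "correct")
        b = collect_states(recorded_log, 3, "correct_after_correct")
        assert b.n_trials <= a.n_trials
        assert b.labels["correct"].all() and b.labels["prev_correct"].all()

    def test_missing_states_rejected(self, mf_spec, tiny_params):
        log = evaluate(tiny_params, mf_spec, n_test=50, seed=1)
        with pytest.raises(ValueError):
            collect_states(log, 3)


class TestStateMatrixIO:
    def test_round_trip_preserves_states_labels_and_key(self, recorded_log, tmp_path):
        from wmrnn.geometry import load_state_matrix, save_state_matrix

        sm = collect_states(recorded_log, after_cue=3, filter="correct")
        path = tmp_path / "states.npz"
        save_state_matrix(path, sm, seed=4, n_ep=20000, filter="correct")
        loaded, key = load_state_matrix(path)
        np.testing.assert_array_equal(loaded.X, sm.X)
        assert loaded.after_cue == 3
        assert key == {"seed": 4, "n_ep": 20000, "filter": "correct"}
        assert loaded.labels["cue1"].tolist() == sm.labels["cue1"].tolist()


class TestPCA:
    def test_planar_data_explained_by_two_components(self, rng):
        basis = rng.normal(size=(2, 25))
        coords = rng.normal(size=(200, 2))
        X = coords @ basis + rng.normal(size=25)  # offset plane in 25-dim
        scores, var = pca_embed(X, k=3)
        assert var[:2].sum() == pytest.approx(1.0)

    def test_variance_fractions_match_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(100, 8)) @ rng.normal(size=(8, 8))
        _, var = pca_embed(X, k=3)
        C = np.cov(X - X.mean(axis=0), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(var, eig[:3] / eig.sum(), rtol=1e-8)

    def test_row_duplication_preserves_embedding_up_to_sign(self, rng):
        X = rng.normal(size=(50, 6))
        s1, v1 = pca_embed(X, 3)
        s2, v2 = pca_embed(np.vstack([X, X]), 3)
        np.testing.assert_allclose(v1, v2, atol=1e-10)
        for j in range(3):
            col = s2[:50, j]
            assert np.allclose(col, s1[:, j]) or np.allclose(col, -s1[:, j])


class TestSortingDirection:
    def test_collinear_centroids_recover_axis(self):
        pts = np.array([[c, 0.0, 0.0] for c in (1, 2, 3, 4, 5)])
        labels = np.array([1, 2, 3, 4, 5])
        d = sorting_direction(pts, labels)
        np.testing.assert_allclose(d, [1, 0, 0], atol=1e-12)

    def test_noisy_collinear_centroids_within_two_degrees(self, rng):
        labels = np.repeat([1, 2, 3, 4, 5], 50)
        X = np.zeros((250, 3))
        X[:, 0] = labels + rng.normal(scale=0.01, size=250)
        X[:, 1:] = rng.normal(scale=0.01, size=(250, 2))
        d = sorting_direction(X, labels)
        assert angle_between(d, np.array([1.0, 0, 0])) < 2.0

    def test_reversed_cue_order_negates_direction(self):
        pts = np.array([[c, c * 0.5, 0.0] for c in (1, 2, 3)])
        d_fwd = sorting_direction(pts, np.array([1, 2, 3]))
        d_rev = sorting_direction(pts, np.array([3, 2, 1]))
        np.testing.assert_allclose(d_fwd, -d_rev, atol=1e-12)

    def test_coincident_centroids_rejected(self):
        pts = np.ones((10, 3))
        with pytest.raises(ValueError):
            sorting_direction(pts, np.repeat([1, 2], 5))


class TestAngles:
    def test_unit_axes_orthogonal(self):
        e1, e2 = np.eye(3)[0], np.eye(3)[1]
        assert angle_between(e1, e2) == pytest.approx(90.0)
        assert angle_between(e1, e1) == pytest.approx(0.0)
        assert angle_between(e1, -e1) == pytest.approx(180.0)

    def test_rotation_constructed_pair_recovers_angle(self, rng):
        for _ in range(20):
            theta = rng.uniform(1, 179)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            # rotate u by theta within the plane spanned by (u, helper)
            helper = rng.normal(size=3)
            helper -= helper @ u * u
            helper /= np.linalg.norm(helper)
            v = np.cos(np.radians(theta)) * u + np.sin(np.radians(theta)) * helper
            assert angle_between(u, v) == pytest.approx(theta, abs=1e-6)

    def test_folded_mode_caps_at_90(self):
        e1 = np.eye(3)[0]
        assert angle_between(e1, -e1, fold=True) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angle_between(np.zeros(3), np.ones(3))


class TestDistances:
    def test_three_four_five_triangle(self):
        emb = np.array([[0, 0, 0.0]] * 5 + [[3, 4, 0.0]] * 5)
        labels = np.repeat([1, 2], 5)
        values, D = intercluster_distances(emb, labels)
        assert values.tolist() == [1, 2]
        assert D[0, 1] == pytest.approx(5.0)

    def test_symmetry_zero_diagonal_and_loop_oracle(self, rng):
        emb = rng.normal(size=(120, 3))
        labels = rng.integers(1, 6, 120)
        values, D = intercluster_distances(emb, labels)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)
        _, cents = centroids_by_label(emb, labels)
        for a in range(len(values)):
            for b in range(len(values)):
                ref = np.sqrt(((cents[a] - cents[b]) ** 2).sum())
                assert D[a, b] == pytest.approx(ref)


class TestDistanceErrorCorrelation:
    def _profile_with_rates(self, rate_of_pair):
        """Synthetic log: X-A-X-A yes-rate for pair (i,j) set by callable."""
        cues, resp = [], []
        for i in range(1, 6):
            for j in range(1, 6):
                if i == j:
                    continue
                # 20 j-i-X-i trials; X chosen != i, != j to stay in category
                other = next(c for c in range(1, 6) if c not in (i, j))
                n_yes = int(round(20 * rate_of_pair(i, j)))
                for k in range(20):
                    cues.append((j, i, other, i))
                    resp.append(k < n_yes)
        from test_behavior import make_log

        return match_error_profile(make_log(cues, resp))

    def test_perfect_inverse_relation_gives_minus_one(self):
        labels = np.arange(1, 6)
        cents = np.array([[v * 1.0, 0, 0] for v in labels])
        D = np.abs(cents[:, 0][:, None] - cents[:, 0][None, :])
        prof = self._profile_with_rates(lambda i, j: 1.0 - abs(i - j) / 5.0)
        r, p, degenerate = distance_error_correlation(labels, D, prof)
        assert not degenerate
        assert r == pytest.approx(-1.0)

    def test_constant_rates_flagged_degenerate(self):
        labels = np.arange(1, 6)
        D = np.abs(labels[:, None] - labels[None, :]).astype(float)
        prof = self._profile_with_rates(lambda i, j: 0.5)
        r, p, degenerate = distance_error_correlation(labels, D, prof)
        assert degenerate and np.isnan(r)

    def test_hand_table_matches_direct_pearson_formula(self, rng):
        labels = np.arange(1, 6)
        cents = rng.normal(size=(5, 3))
        D = np.sqrt(((cents[:, None] - cents[None]) ** 2).sum(-1))
        prof = self._profile_with_rates(
            lambda i, j: 0.05 * ((i * 7 + j * 3) % 11) / 11 + 0.1
        )
        r, p, _ = distance_error_correlation(labels, D, prof)
        from wmrnn.behavior import pairwise_error_rates

        rates = pairwise_error_rates(prof)
        ds = [D[i - 1, j - 1] for i, j in zip(rates.cue_i, rates.cue_j)]
        ref_r, ref_p = stats.pearsonr(ds, rates.error_rate)
        assert r == pytest.approx(ref_r)
        assert p == pytest.approx(ref_p)


class TestClusterSeparation:
    def test_separated_clusters_score_higher_than_mixed(self, rng):
        labels = np.repeat([1, 2, 3], 40)
        tight = rng.normal(scale=0.1, size=(120, 3)) + labels[:, None] * 3.0
        loose = rng.normal(scale=2.0, size=(120, 3)) + labels[:, None] * 0.3
        assert cluster_separation(tight, labels) > cluster_separation(loose, labels)
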