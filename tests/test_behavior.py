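"""Serial position curves, linear fits, error profiles, replicate tests."""

import numpy as np
import pytest
from scipy import stats

from wmrnn import TaskSpec
from wmrnn.behavior import (
    ErrorProfile,
    SerialPositionCurve,
    fit_spc,
    match_error_profile,
    pairwise_error_rates,
    recency_positions,
    replicate_tests,
    serial_position_curve,
)
from wmrnn.training import EpisodeLog, evaluate
from conftest import scripted_policy


def make_log(cues, responses, spec=None):
    """Hand-built EpisodeLog from explicit cue rows and yes/no responses."""
    spec = spec or TaskSpec()
    cues = np.asarray(cues)
    responses = np.asarray(responses, dtype=bool)
    labels = cues[:, 0] == cues[:, -1]
    correct = responses == labels
    prev = np.concatenate([[False], correct[:-1]])
    return EpisodeLog(
        spec=spec, cues=cues, labels=labels, responses=responses,
        correct=correct, prev_correct=prev,
        rewards=np.where(correct, 5.0, -5.0),
    )


class TestRecencyPositions:
    @pytest.mark.parametrize(
        "cues,pos",
        [
            ((1, 2, 3, 1), -3),   # target match: lead = test
            ((2, 1, 3, 1), -2),   # X-A-X-A
            ((2, 3, 1, 1), -1),   # X-X-A-A
            ((2, 1, 1, 1), -1),   # most recent occurrence wins
            ((2, 3, 4, 5), 0),    # never seen before
        ],
    )
    def test_positions_by_most_recent_occurrence(self, cues, pos):
        assert recency_positions(np.array([cues]))[0] == pos


class TestSerialPositionCurve:
    def test_hand_counted_six_trial_log(self):
        # two -3 trials (1 yes), two -2 trials (2 yes), one -1, one no-prior
        log = make_log(
            cues=[(1, 2, 3, 1), (2, 3, 4, 2), (2, 1, 3, 1), (3, 1, 4, 1),
                  (2, 3, 1, 1), (2, 3, 4, 5)],
            responses=[True, False, True, True, False, True],
        )
        c = serial_position_curve(log)
        assert c.positions.tolist() == [-3, -2, -1]
        np.testing.assert_allclose(c.yes_rate, [0.5, 1.0, 0.0])
        assert c.counts.tolist() == [2, 2, 1]
        assert c.no_prior_count == 1 and c.no_prior_rate == 1.0
        assert c.hit_rate == 0.5

    def test_empty_bin_is_nan_not_zero(self):
        log = make_log(cues=[(1, 2, 3, 1)], responses=[True])
        c = serial_position_curve(log)
        assert np.isnan(c.yes_rate[c.positions == -1][0])

    def test_selective_agent_yes_only_at_target(self, mf_spec, tiny_params):
        log = evaluate(tiny_params, mf_spec, n_test=2000, seed=5,
                       policy=scripted_policy("selective"))
        c = serial_position_curve(log)
        np.testing.assert_allclose(c.yes_rate, [1.0, 0.0, 0.0])
        fit = fit_spc(c)
        assert fit.slope == pytest.approx(0.0)
        assert fit.residual == pytest.approx(1.0)

    def test_recency_agent_rates_recovered_within_binomial_ci(self, mf_spec, tiny_params):
        rates = {-3: 0.9, -2: 0.55, -1: 0.35, 0: 0.1}
        log = evaluate(tiny_params, mf_spec, n_test=5000, seed=6,
                       policy=scripted_policy("recency", seed=7, rates=rates))
        c = serial_position_curve(log)
        for pos, n, got in zip(c.positions, c.counts, c.yes_rate):
            p = rates[pos]
            half = 2.576 * np.sqrt(p * (1 - p) / n)
            assert abs(got - p) < half
        assert fit_spc(c).slope < 0  # imposed negative-going profile

    def test_stratified_curve_restricts_to_target_cue(self, mf_spec, tiny_params):
        log = evaluate(tiny_params, mf_spec, n_test=2000, seed=8)
        c_all = serial_position_curve(log)
        c1 = serial_position_curve(log, stratify=1)
        assert c1.counts.sum() < c_all.counts.sum()
        assert (log.cues[:, -1] == 1).sum() == c1.counts.sum() + c1.no_prior_count

    def test_performance_reconstructed_from_curve_and_composition(self, mf_spec, tiny_params):
        """performance == hit-weighted and false-alarm-weighted mixture."""
        log = evaluate(tiny_params, mf_spec, n_test=3000, seed=10)
        c = serial_position_curve(log)
        n_match = c.counts[0]
        n_nm = c.counts[1] + c.counts[2] + c.no_prior_count
        fa = (c.yes_rate[1] * c.counts[1] + c.yes_rate[2] * c.counts[2]
              + c.no_prior_rate * c.no_prior_count) / n_nm
        expected = (n_match * c.hit_rate + n_nm * (1 - fa)) / (n_match + n_nm)
        assert log.performance == pytest.approx(expected, abs=1e-12)


class TestFit:
    def test_two_point_example(self):
        c = SerialPositionCurve(
            positions=np.array([-3, -2, -1]),
            yes_rate=np.array([0.9, 0.3, 0.2]),
            counts=np.array([10, 10, 10]),
            target_position=-3,
        )
        fit = fit_spc(c)
        assert fit.positions_used == (-2, -1)
        assert fit.slope == pytest.approx(-0.1)
        assert fit.residual == pytest.approx(0.5)

    def test_flat_curve_residual(self):
        c = SerialPositionCurve(
            positions=np.array([-3, -2, -1]),
            yes_rate=np.array([0.9, 0.1, 0.1]),
            counts=np.array([10, 10, 10]),
            target_position=-3,
        )
        fit = fit_spc(c)
        assert fit.slope == pytest.approx(0.0)
        assert fit.residual == pytest.approx(0.8)

    def test_insufficient_positions_rejected(self):
        c = SerialPositionCurve(
            positions=np.array([-3, -2, -1]),
            yes_rate=np.array([0.9, np.nan, 0.1]),
            counts=np.array([10, 0, 10]),
            target_position=-3,
        )
        with pytest.raises(ValueError):
            fit_spc(c, positions_used=(-2, -1))

    def test_extreme_slope_flagged_not_dropped(self):
        c = SerialPositionCurve(
            positions=np.array([-3, -2, -1]),
            yes_rate=np.array([0.5, 1.0, 0.0]),
            counts=np.array([5, 5, 5]),
            target_position=-3,
        )
        fit = fit_spc(c, extreme_slope=0.5)
        assert fit.extreme


class TestErrorProfile:
    def test_only_lead2_errors_gives_100_percent_share(self):
        log = make_log(
            cues=[(2, 1, 3, 1)] * 4 + [(3, 1, 4, 1)] * 4,
            responses=[True] * 4 + [False] * 4,
        )
        prof = match_error_profile(log)
        assert prof.share(1, 2, "X-A-X-A") == 100.0
        assert prof.share(1, 3, "X-A-X-A") == 0.0
        assert prof.parity == pytest.approx(25.0)

    def test_uniform_errors_approach_parity(self, mf_spec, tiny_params):
        # an agent that says yes to every X-A-X-A trial: shares follow the
        # lead-cue composition, which is uniform over the three non-target leads
        log = evaluate(tiny_params, mf_spec, n_test=6000, seed=11,
                       policy=scripted_policy("always_yes"))
        prof = match_error_profile(log)
        shares = [prof.share(1, lead, "X-A-X-A") for lead in (2, 3, 4, 5)]
        # each of the four leads should sit near the 25% parity line
        for s in shares:
            assert abs(s - 25.0) < 10.0

    def test_matches_brute_force_count_oracle(self, mf_spec, tiny_params):
        log = evaluate(tiny_params, mf_spec, n_test=3000, seed=12)
        prof = match_error_profile(log)
        cues, yes = log.cues, log.responses
        for _, row in prof.table.iterrows():
            A, lead = row.target_cue, row.lead_cue
            n_err = 0
            n_tr = 0
            for c, y in zip(cues, yes):
                c1, c2, c3, c4 = c
                if c4 != A or c1 != lead:
                    continue
                if row.category == "X-A-X-A" and (c2 != A or c3 == A or c1 == A):
                    continue
                if row.category == "X-X-A-A" and (c3 != A or c2 == A or c1 == A):
                    continue
                n_tr += 1
                n_err += bool(y)
            assert row.n_trials == n_tr and row.n_errors == n_err

    def test_zero_error_category_flagged_nan(self):
        log = make_log(cues=[(2, 1, 3, 1)] * 3, responses=[False] * 3)
        prof = match_error_profile(log)
        assert np.isnan(prof.share(1, 2, "X-A-X-A"))
        assert prof.category_errors(1, "X-A-X-A") == 0

    def test_pairwise_rates_average_both_directions(self):
        log = make_log(
            cues=[(2, 1, 3, 1)] * 2 + [(1, 2, 3, 2)] * 2,
            responses=[True, False, True, True],
        )
        rates = pairwise_error_rates(match_error_profile(log))
        r12 = rates[(rates.cue_i == 1) & (rates.cue_j == 2)].error_rate.iloc[0]
        assert r12 == pytest.approx((0.5 + 1.0) / 2)


class TestReplicateTests:
    def test_symmetric_values_give_zero_t(self):
        res = replicate_tests([-2.0, -1.0, 1.0, 2.0], "one_sample_t")
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        vals = [1.2, 0.8, 1.5, 0.9, 1.1]
        res = replicate_tests(vals, "one_sample_t")
        x = np.asarray(vals)
        t_ref = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        assert res.statistic == pytest.approx(t_ref)
        assert res.pvalue == pytest.approx(
            stats.t.sf(abs(t_ref), len(x) - 1) * 2
        )

    def test_paired_identical_samples_flagged_degenerate(self):
        res = replicate_tests([1.0, 2.0, 3.0], "paired_one_sided_t",
                              paired_with=[1.0, 2.0, 3.0])
        assert res.degenerate and np.isnan(res.statistic)

    def test_paired_one_sided_direction(self):
        res = replicate_tests([1.0, 2.0, 3.0], "paired_one_sided_t",
                              paired_with=[2.0, 3.5, 4.0])
        assert res.pvalue < 0.05
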