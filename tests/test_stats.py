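import math

import numpy as np
import pytest

from larvaction import stats as lst
from larvaction.actions import ActionSequence
from larvaction.kinematics import DT, SpineTrack
from larvaction.synth import gen_point_clouds


def _seq(labels, onset=60.0, t0=0.0, larva_id=""):
    labels = np.asarray(labels, dtype=object)
    return ActionSequence(times=t0 + DT * np.arange(labels.size), labels=labels,
                          stimulus_onset=onset, larva_id=larva_id)


class TestActionProbabilities:
    def _cohort(self, n_hunch, n_total, steps=700):
        seqs = []
        for i in range(n_total):
            labels = ["crawl"] * steps
            if i < n_hunch:
                labels[602:608] = ["hunch"] * 6
            seqs.append(_seq(labels, larva_id=str(i)))
        return seqs

    def test_cumulative_fraction(self):
        res = lst.action_probabilities(self._cohort(4, 10), "hunch")
        assert res.value == pytest.approx(0.4)
        assert res.n_qualifying == 10

    def test_larva_lost_mid_window_excluded(self):
        seqs = self._cohort(4, 10)
        seqs.append(_seq(["crawl"] * 620, larva_id="lost"))  # ends at 62 s
        res = lst.action_probabilities(seqs, "hunch")
        assert res.n_qualifying == 10

    def test_identical_pre_post_occupancy_corrects_to_zero(self):
        labels = (["crawl", "head_cast"] * 500)[:950]
        res = lst.action_probabilities([_seq(labels)], "head_cast",
                                       mode="corrected_mean")
        assert res.value == pytest.approx(0.0, abs=0.01)

    def test_empty_qualifying_set_is_an_error(self):
        with pytest.raises(ValueError, match="window"):
            lst.action_probabilities([_seq(["crawl"] * 100)], "hunch")


class TestChiAndTheta:
    def test_chi_difference(self):
        c = lst.GroupWindowCounts(5, 10, 2, 10)
        assert lst.chi_estimator(c) == pytest.approx(0.3)

    def test_chi_bounds(self):
        assert lst.chi_estimator(lst.GroupWindowCounts(0, 5, 5, 5)) == -1.0
        assert lst.chi_estimator(lst.GroupWindowCounts(3, 6, 3, 6)) == 0.0

    def test_theta_difference_and_antisymmetry(self):
        t = lst.GroupWindowCounts(5, 10, 2, 10)
        c = lst.GroupWindowCounts(3, 10, 2, 10)
        assert lst.theta_statistic(t, c) == pytest.approx(0.2)
        assert lst.theta_statistic(c, t) == pytest.approx(-0.2)
        assert lst.theta_statistic(t, t) == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            lst.GroupWindowCounts(6, 5, 0, 5)


class TestThetaTest:
    def test_identical_groups_give_p_one(self):
        g = lst.GroupWindowCounts(20, 50, 10, 50)
        res = lst.theta_test(g, g, n_sim=500, seed=0)
        assert res["p_value"] == 1.0

    def test_seed_determinism(self):
        t = lst.GroupWindowCounts(30, 50, 10, 50)
        c = lst.GroupWindowCounts(15, 50, 10, 50)
        r1 = lst.theta_test(t, c, n_sim=500, seed=42)
        r2 = lst.theta_test(t, c, n_sim=500, seed=42)
        assert r1["p_value"] == r2["p_value"]
        np.testing.assert_array_equal(r1["null_sample"], r2["null_sample"])

    def test_clear_effect_is_significant(self):
        t = lst.GroupWindowCounts(45, 100, 20, 100)
        c = lst.GroupWindowCounts(20, 100, 20, 100)
        res = lst.theta_test(t, c, n_sim=1000, seed=0)
        assert res["p_value"] < 0.05

    def test_small_n_sim_rejected(self):
        g = lst.GroupWindowCounts(5, 10, 2, 10)
        with pytest.raises(ValueError, match="n_sim"):
            lst.theta_test(g, g, n_sim=50)

    def test_literal_scheme_runs_and_reports(self):
        t = lst.GroupWindowCounts(30, 50, 10, 50)
        c = lst.GroupWindowCounts(15, 50, 10, 50)
        res = lst.theta_test(t, c, n_sim=200, seed=1, scheme="literal")
        assert res["scheme"] == "literal"
        assert 0 < res["p_value"] <= 1


class TestTransitionMatrix:
    def test_scripted_transitions_land_in_right_cells(self):
        labels = ["crawl"] * 600 + ["hunch"] * 5 + ["head_cast"] * 10 + ["crawl"] * 85
        tc = lst.transition_matrix([_seq(labels)] * 60, window=2.0)
        assert tc.counts.loc["crawl", "hunch"] == 60
        assert tc.counts.loc["hunch", "head_cast"] == 60
        # head_cast -> crawl at 61.5 s also lands in the 2 s window
        assert tc.n_transitions == 180

    def test_constant_cohort_has_empty_matrix_and_fallback(self):
        tc = lst.transition_matrix([_seq(["crawl"] * 700)] * 5, window=2.0)
        assert tc.n_transitions == 0
        assert tc.fallback_used and tc.window == 10.0

    def test_low_count_engages_fallback_window(self):
        labels = ["crawl"] * 600 + ["hunch"] * 5 + ["crawl"] * 95
        tc = lst.transition_matrix([_seq(labels)] * 49, window=2.0)  # 98 < 100
        assert tc.fallback_used
        assert tc.window == 10.0


class TestGLR:
    def test_equal_proportions_give_zero(self):
        z, p = lst.glr_transition_test(10, 20, 10, 20)
        assert z == 0.0 and p == 1.0

    def test_matches_direct_loglikelihood_evaluation(self):
        def oracle(n_m, N_m, n_0, N_0):
            def ll(n, N, q):
                if q in (0.0, 1.0):
                    return 0.0 if n in (0, N) and (q == n / N) else -math.inf
                return n * math.log(q) + (N - n) * math.log(1 - q)
            pi = (n_m + n_0) / (N_m + N_0)
            return -2 * ((ll(n_m, N_m, pi) + ll(n_0, N_0, pi))
                         - (ll(n_m, N_m, n_m / N_m) + ll(n_0, N_0, n_0 / N_0)))

        z, _ = lst.glr_transition_test(15, 20, 5, 20)
        assert z == pytest.approx(oracle(15, 20, 5, 20), abs=1e-10)

    def test_group_swap_symmetry(self):
        z1, _ = lst.glr_transition_test(15, 20, 5, 20)
        z2, _ = lst.glr_transition_test(5, 20, 15, 20)
        assert z1 == pytest.approx(z2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            lst.glr_transition_test(0, 0, 5, 20)


class TestSegmentWindowVectors:
    def _track(self, t0=55.0, t1=70.0, static=True):
        n = int(round((t1 - t0) / DT)) + 1
        t = t0 + DT * np.arange(n)
        spine = np.zeros((n, 11, 2))
        for i in range(11):
            spine[:, i, 0] = -0.4 * i
        if not static:
            spine[:, :, 0] += 0.01 * np.arange(n)[:, None]
        return SpineTrack("a", t, spine, regular=True)

    def test_five_vectors_of_length_200(self):
        vecs = lst.segment_window_vectors(self._track())
        assert len(vecs) == 5
        assert all(v.shape == (200,) for v in vecs)

    def test_static_larva_gives_identical_vectors(self):
        vecs = lst.segment_window_vectors(self._track(static=True))
        for v in vecs[1:]:
            np.testing.assert_allclose(v, vecs[0])

    def test_truncated_track_skips_late_centers(self):
        vecs = lst.segment_window_vectors(self._track(t1=64.0))
        assert 0 < len(vecs) < 5


class TestMMD:
    def test_identical_samples_give_nonpositive_estimate(self):
        X, _ = gen_point_clouds(20, 5, 0.0, seed=0)
        assert lst.mmd_statistic(X, X) <= 1e-12

    def test_three_point_toy_matches_hand_summation(self):
        X = np.array([[0.0], [1.0], [2.0]])
        Y = np.array([[0.5], [1.5], [3.0]])
        s = 2.0
        k = lambda a, b: math.exp(-((a - b) ** 2) / (2 * s * s))
        sx = sum(k(a[0], b[0]) for i, a in enumerate(X) for j, b in enumerate(X)
                 if i != j) / 6
        sy = sum(k(a[0], b[0]) for i, a in enumerate(Y) for j, b in enumerate(Y)
                 if i != j) / 6
        sxy = sum(k(a[0], b[0]) for a in X for b in Y) / 9
        assert lst.mmd_statistic(X, Y) == pytest.approx(sx + sy - 2 * sxy, abs=1e-12)

    def test_estimate_grows_with_mean_shift(self):
        vals = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            X, Y = gen_point_clouds(200, 5, shift, seed=3)
            vals.append(lst.mmd_statistic(X, Y))
        assert vals == sorted(vals)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lst.mmd_statistic(np.zeros((5, 3)), np.zeros((5, 4)))

    def test_permutation_test_determinism_and_bonferroni(self):
        X, Y = gen_point_clouds(40, 5, 1.0, seed=1)
        r1 = lst.mmd_permutation_test(X, Y, B=200, seed=9, bonferroni_m=45)
        r2 = lst.mmd_permutation_test(X, Y, B=200, seed=9, bonferroni_m=45)
        assert r1["p_value"] == r2["p_value"]
        assert r1["p_adjusted"] == pytest.approx(min(1.0, 45 * r1["p_value"]))

    def test_small_b_rejected(self):
        X, Y = gen_point_clouds(10, 3, 0.0, seed=0)
        with pytest.raises(ValueError, match="B"):
            lst.mmd_permutation_test(X, Y, B=50)


class TestFluorescence:
    def _trace(self, amp, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 15, 0.1)
        F = 1.0 + rng.normal(0, noise, t.size)
        F[(t >= 5) & (t < 10)] += amp
        return lst.FluorescenceTrace(t, F, (0.0, 5.0), (5.0, 10.0))

    def test_flat_trace_fails(self):
        res = lst.dff_metrics(self._trace(0.0))
        assert res["stimulus_mean"] == pytest.approx(0.0)
        assert res["failed"]

    def test_quarter_response_passes(self):
        res = lst.dff_metrics(self._trace(0.25))
        assert res["stimulus_mean"] == pytest.approx(0.25, abs=1e-9)
        assert not res["failed"]

    def test_cohort_failure_rate_counts_threshold(self):
        traces = [self._trace(a) for a in (0.05, 0.2, 0.3, 0.08, 0.5)]
        assert lst.cohort_failure_rate(traces) == pytest.approx(2 / 5)

    def test_nonpositive_baseline_rejected(self):
        t = np.arange(0, 15, 0.1)
        trace = lst.FluorescenceTrace(t, np.zeros(t.size), (0, 5), (5, 10))
        with pytest.raises(ValueError, match="baseline"):
            lst.dff_metrics(trace)


class TestPreferenceIndex:
    @pytest.mark.parametrize("Ns,Na,Ntot,expected", [
        (20, 0, 20, 1.0), (8, 8, 20, 0.0), (6, 10, 20, -0.2),
    ])
    def test_examples(self, Ns, Na, Ntot, expected):
        assert lst.preference_index(Ns, Na, Ntot) == pytest.approx(expected)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            lst.preference_index(5, 5, 0)
        with pytest.raises(ValueError):
            lst.preference_index(15, 10, 20)
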