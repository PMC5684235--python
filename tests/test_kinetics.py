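"""Tests of the transition-matrix rate estimator and its corrections."""

import numpy as np
import pytest

import if2fret as f
import if2fret.kinetics as kin
from conftest import make_path, noiseless_config

F_, B_ = 0, 1


def counts_dict(cm):
    n = cm.counts
    return {"FF": n[0, 0], "FB": n[0, 1], "BF": n[1, 0], "BB": n[1, 1]}


def simulate_observed_paths(config, n, seed):
    """Ground-truth apparent-label paths (ideal detector, HMM bypassed)."""
    root = np.random.SeedSequence(seed)
    truths = [f.simulate_state_path(config, np.random.default_rng(s), f"t{i}")
              for i, s in enumerate(root.spawn(n))]
    return kin.paths_from_truth(truths, config.frame_time, config.n_frames,
                                observed=True)


class TestCounting:
    def test_enumerated_example_no_exclusion(self):
        cm = f.count_transitions([make_path([0, 0, 1, 1, 0])])
        assert counts_dict(cm) == {"FF": 1, "FB": 1, "BB": 1, "BF": 1}

    def test_exclusion_with_entry_kept_matches_enumeration(self):
        cm = f.count_transitions([make_path([0, 0, 1, 1, 0])],
                                 exclude_final_free_dwell=True,
                                 keep_entry_transition=True)
        assert counts_dict(cm) == {"FF": 1, "FB": 1, "BB": 1, "BF": 1}
        cm = f.count_transitions([make_path([0, 1, 1, 0, 0, 0])],
                                 exclude_final_free_dwell=True,
                                 keep_entry_transition=True)
        assert counts_dict(cm) == {"FF": 0, "FB": 1, "BB": 1, "BF": 1}

    def test_exclusion_default_drops_whole_final_dwell(self):
        """The default convention removes the final free dwell including
        the bound->free transition entering it."""
        cm = f.count_transitions([make_path([0, 1, 1, 0, 0, 0])],
                                 exclude_final_free_dwell=True)
        assert counts_dict(cm) == {"FF": 0, "FB": 1, "BB": 1, "BF": 0}

    def test_path_ending_bound_unaffected_by_exclusion(self):
        for flag in (False, True):
            cm = f.count_transitions([make_path([0, 1, 1])],
                                     exclude_final_free_dwell=flag)
            assert counts_dict(cm) == {"FF": 0, "FB": 1, "BB": 1, "BF": 0}

    def test_all_free_path_fully_excluded(self):
        cm = f.count_transitions([make_path([0, 0, 0, 0])],
                                 exclude_final_free_dwell=True)
        assert cm.counts.sum() == 0

    def test_short_paths_contribute_nothing(self):
        cm = f.count_transitions([make_path([0]), make_path([])])
        assert cm.counts.sum() == 0

    def test_additive_over_disjoint_subsets(self, rng):
        paths = [make_path(rng.integers(0, 2, 40)) for _ in range(10)]
        whole = f.count_transitions(paths, exclude_final_free_dwell=True)
        parts = (f.count_transitions(paths[:4], exclude_final_free_dwell=True)
                 + f.count_transitions(paths[4:], exclude_final_free_dwell=True))
        np.testing.assert_array_equal(whole.counts, parts.counts)


class TestProbabilitiesAndRates:
    def test_row_normalization_arithmetic(self):
        cm = f.CountingMatrix(np.array([[99, 1], [4, 96]]))
        tm = f.transition_probabilities(cm, 0.1)
        assert tm.probs[F_, F_] == pytest.approx(0.99)
        assert tm.probs[B_, B_] == pytest.approx(0.96)
        np.testing.assert_allclose(tm.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_row_flagged_undefined(self):
        tm = f.transition_probabilities(f.CountingMatrix(np.array([[5, 5],
                                                                   [0, 0]])), 0.1)
        assert tm.row_defined[F_] and not tm.row_defined[B_]
        k_a, k_d = f.rates_from_probabilities(tm, 0.025)
        assert np.isfinite(k_a) and np.isnan(k_d)

    def test_rate_equations_closed_form(self):
        probs = np.array([[np.exp(-0.05 * 0.1), 1 - np.exp(-0.05 * 0.1)],
                          [1 - np.exp(-0.041 * 0.1), np.exp(-0.041 * 0.1)]])
        tm = f.TransitionMatrix(probs, 0.1, np.array([True, True]))
        k_a, k_d = f.rates_from_probabilities(tm, 0.025)
        assert k_d == pytest.approx(0.041, abs=1e-12)
        assert k_a == pytest.approx(0.05 / 0.025, abs=1e-12)

    def test_published_arithmetic_example(self):
        probs = np.array([[0.995, 0.005], [0.005, 0.995]])
        tm = f.TransitionMatrix(probs, 0.1, np.array([True, True]))
        k_a, _ = f.rates_from_probabilities(tm, 0.025)
        assert k_a == pytest.approx(-np.log(0.995) / 0.0025, rel=1e-12)
        assert k_a == pytest.approx(2.005, abs=0.001)

    def test_unit_staying_probability_gives_zero_rates(self):
        tm = f.TransitionMatrix(np.eye(2), 0.1, np.array([True, True]))
        assert f.rates_from_probabilities(tm, 0.025) == (0.0, 0.0)

    def test_rejects_nonpositive_concentration(self):
        tm = f.TransitionMatrix(np.eye(2), 0.1, np.array([True, True]))
        with pytest.raises(ValueError):
            f.rates_from_probabilities(tm, 0.0)


class TestReplicateAggregation:
    def test_mean_and_se_arithmetic(self):
        vals = [0.040, 0.041, 0.042]
        mean, se = kin._mean_se(vals)
        assert mean == pytest.approx(0.041)
        assert se == pytest.approx(np.std(vals, ddof=1) / np.sqrt(3))
        assert se == pytest.approx(0.000577, abs=1e-6)

    def test_single_replicate_has_no_se(self):
        mean, se = kin._mean_se([0.04])
        assert mean == 0.04 and se is None

    def test_kd_identity_exact_per_replicate(self, rng):
        reps = [[make_path(rng.integers(0, 2, 300)) for _ in range(5)]
                for _ in range(3)]
        est = f.estimate_condition(reps, 0.025, 0.1)
        for k_a, k_d, kd in zip(est.k_a_replicates, est.k_d_replicates,
                                est.kd_nM_replicates):
            assert kd * k_a == pytest.approx(k_d * 1000.0, rel=1e-12)

    def test_kd_unit_conversion(self):
        # k_d/k_a in µM, reported in nM: 0.041/2.0 -> 20.5 nM
        assert 1000 * 0.041 / 2.0 == pytest.approx(20.5)


class TestPaddingPlan:
    def test_correction_factor_formula(self):
        obs = [make_path([0, 1, 0])] * 3 + [make_path([0, 0, 0])] * 7
        ref = [make_path([0, 1, 0])] * 9 + [make_path([0, 0, 0])] * 1
        plan = f.plan_cy3_padding(obs, ref)
        assert plan.percent_capable == pytest.approx(90.0)
        assert plan.percent_observed == pytest.approx(30.0)
        assert plan.correction_factor == pytest.approx(2.0)
        assert plan.n_simulated == round(3 * 2.0)
        assert plan.length_frames == 3

    def test_equal_fractions_mean_no_padding(self):
        obs = [make_path([0, 1, 0])] * 5
        plan = f.plan_cy3_padding(obs, obs)
        assert plan.correction_factor == 0.0 and plan.n_simulated == 0

    def test_zero_observed_fraction_is_an_error(self):
        obs = [make_path([0, 0, 0])] * 5
        ref = [make_path([0, 1, 0])] * 5
        with pytest.raises(ValueError, match="binding event"):
            f.plan_cy3_padding(obs, ref)

    def test_padding_paths_are_all_free(self):
        plan = kin.PaddingPlan(90.0, 30.0, 2.0, 3, 6, 50)
        pads = kin.make_padding_paths(plan, 0.1)
        assert len(pads) == 6
        assert all(not p.macro.any() and p.n_frames == 50 for p in pads)


class TestEstimatorProperties:
    def test_consistency_on_ground_truth_paths_without_bleaching(self):
        """With no photobleaching and no exclusion, rates recovered from
        ground-truth labels match the generating values within 3 SE."""
        config = noiseless_config(n_frames=1800)
        k_as, k_ds = [], []
        for seed in range(3):
            paths = simulate_observed_paths(config, 60, 1000 + seed)
            k_a, k_d, _ = kin.estimate_replicate(paths, 0.025, 0.1)
            k_as.append(k_a)
            k_ds.append(k_d)
        for vals, truth in ((k_as, 2.0), (k_ds, 0.041)):
            se = np.std(vals, ddof=1) / np.sqrt(3)
            assert abs(np.mean(vals) - truth) < 3 * se

    def test_cy5_bleach_bias_reduced_by_final_dwell_exclusion(self):
        """With acceptor bleaching at k_d/4, the uncorrected k_d exceeds
        the generating value and the exclusion shrinks the bias by at
        least half."""
        config = noiseless_config(n_frames=1800, kb_cy5=0.041 / 4,
                                  kb_cy3=0.005)
        paths = simulate_observed_paths(config, 500, 2024)
        _, kd_unc, _ = kin.estimate_replicate(paths, 0.025, 0.1)
        _, kd_cor, _ = kin.estimate_replicate(paths, 0.025, 0.1,
                                              exclude_final_free_dwell=True)
        truth = 0.041
        assert kd_unc > truth
        assert abs(kd_cor - truth) < 0.5 * abs(kd_unc - truth)

    def test_keep_entry_convention_retains_spurious_exits(self):
        """Keeping the entering transition leaves the fake bleach exits in
        the counting, so it cannot reduce the k_d bias the way the default
        convention does."""
        config = noiseless_config(n_frames=1800, kb_cy5=0.01, kb_cy3=0.005)
        paths = simulate_observed_paths(config, 300, 2025)
        _, kd_keep, _ = kin.estimate_replicate(
            paths, 0.025, 0.1, exclude_final_free_dwell=True,
            keep_entry_transition=True)
        _, kd_drop, _ = kin.estimate_replicate(
            paths, 0.025, 0.1, exclude_final_free_dwell=True)
        assert kd_keep > kd_drop
        assert abs(kd_drop - 0.041) < abs(kd_keep - 0.041)

    def test_cy3_padding_reduces_rare_event_bias(self):
        """Rare binders with short donor lifetimes: dropping event-free
        traces inflates k_a; padding with zero-FRET traces brings it back
        within 3 replicate SE of the generating value."""
        truth_ka = 0.4
        sub = [f.Substate(mean=0.7, width=0.0, weight=1.0)]
        cfg_obs = noiseless_config(k_a=truth_ka, k_d=0.1, substates=sub,
                                   n_frames=1800, kb_cy3=0.01)
        cfg_ref = noiseless_config(k_a=2.0, k_d=0.1, substates=sub,
                                   n_frames=1800, kb_cy3=0.01)
        unc_reps, cor_reps, plans = [], [], []
        for r in range(3):
            obs_all = simulate_observed_paths(cfg_obs, 80, 3000 + r)
            ref_all = simulate_observed_paths(cfg_ref, 80, 4000 + r)
            selected = [p for p in obs_all if p.macro.any()]
            plans.append(f.plan_cy3_padding(obs_all, ref_all))
            unc_reps.append(selected)
            cor_reps.append(selected)
        est_unc = f.estimate_condition(unc_reps, 0.025, 0.1)
        est_cor = f.estimate_condition(cor_reps, 0.025, 0.1,
                                       padding_plans=plans)
        assert est_unc.k_a > truth_ka
        assert abs(est_cor.k_a - truth_ka) < 3 * est_cor.k_a_se
        assert abs(est_cor.k_a - truth_ka) < abs(est_unc.k_a - truth_ka)
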