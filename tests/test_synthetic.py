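"""Generator contracts: determinism, covariance structure, trial counts,
noise monotonicity and ground-truth linkage."""

import numpy as np
import pytest

from restvs.networks import NETWORKS
from restvs.rest_fc import fc_matrix
from restvs.synthetic import (
    CohortConfig,
    GroundTruth,
    TrialTiming,
    link_targets,
    make_cohort,
    make_mid_design,
    make_rest_cov,
    make_roi_set,
    required_volumes,
    simulate_rest_ts,
    simulate_task_ts,
)
from restvs.task_glm import build_design_matrix, fit_glm


class TestRoiSet:
    def test_one_roi_per_network_gets_all_labels(self):
        rs = make_roi_set(9, networks={lab: 1 for lab in NETWORKS}, seed=0)
        assert sorted(rs.network_labels) == sorted(NETWORKS)

    def test_deterministic_for_fixed_seed(self):
        a = make_roi_set(40, seed=7)
        b = make_roi_set(40, seed=7)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        np.testing.assert_array_equal(a.network_labels, b.network_labels)

    def test_edge_feature_count(self):
        assert make_roi_set(40, seed=0).n_edges == 40 * 39 // 2 == 780

    def test_too_few_rois_rejected(self):
        with pytest.raises(ValueError):
            make_roi_set(1)

    def test_labels_contiguous_by_network(self):
        rs = make_roi_set(40, seed=3)
        labs = list(rs.network_labels)
        seen = [labs[0]]
        for lab in labs[1:]:
            if lab != seen[-1]:
                assert lab not in seen  # a network never reappears
                seen.append(lab)


class TestRestCov:
    def test_block_pattern_two_networks(self):
        labels = np.array(["DM", "DM", "VI", "VI"])
        R = make_rest_cov(labels, within_net_r=0.5, between_net_r=0.0)
        expected = np.array([
            [1.0, 0.5, 0.0, 0.0],
            [0.5, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.5],
            [0.0, 0.0, 0.5, 1.0],
        ])
        np.testing.assert_allclose(R, expected)

    def test_zero_correlations_give_identity(self):
        rs = make_roi_set(12, seed=0)
        np.testing.assert_allclose(make_rest_cov(rs, 0.0, 0.0), np.eye(12))

    def test_default_block_matrix_positive_definite(self):
        rs = make_roi_set(40, seed=0)
        R = make_rest_cov(rs, 0.5, 0.1)
        assert np.linalg.eigvalsh(R).min() > 0

    def test_invalid_ordering_rejected(self):
        rs = make_roi_set(6, seed=0)
        with pytest.raises(ValueError):
            make_rest_cov(rs, within_net_r=0.1, between_net_r=0.5)


class TestRestSimulation:
    def test_identical_seed_identical_series(self):
        R = make_rest_cov(make_roi_set(10, seed=0), 0.4, 0.1)
        a = simulate_rest_ts(R, 60, 2.0, seed=5)
        b = simulate_rest_ts(R, 60, 2.0, seed=5)
        np.testing.assert_array_equal(a.ts, b.ts)
        np.testing.assert_array_equal(a.motion, b.motion)

    def test_identity_cov_yields_null_correlations(self):
        sim = simulate_rest_ts(np.eye(10), 5000, 2.0, ar_coef=0.0, seed=1)
        C = fc_matrix(sim.clean).r
        off = C[np.triu_indices(10, 1)]
        assert np.mean(np.abs(off)) < 0.05

    def test_ar_filter_preserves_spatial_covariance(self):
        # AR(1) with variance-normalised innovations keeps the stationary
        # spatial correlation equal to the input covariance
        labels = np.array(["DM"] * 4 + ["VI"] * 4)
        R = make_rest_cov(labels, 0.5, 0.0)
        sim = simulate_rest_ts(R, 8000, 2.0, ar_coef=0.5, seed=2)
        C = fc_matrix(sim.clean).r
        within = [C[i, j] for i in range(4) for j in range(i + 1, 4)]
        assert abs(np.mean(within) - 0.5) < 0.03

    def test_preconditions(self):
        with pytest.raises(ValueError):
            simulate_rest_ts(np.eye(3), 10, 2.0)
        with pytest.raises(ValueError):
            simulate_rest_ts(np.eye(3), 50, 2.0, ar_coef=1.0)

    def test_confounds_recorded_and_low_rank(self):
        sim = simulate_rest_ts(np.eye(6), 80, 2.0, seed=3)
        assert sim.motion.shape == (80, 6)
        assert np.linalg.matrix_rank(sim.wm_signals) == 2
        assert set(sim.mixing) == {"motion", "wm", "csf"}


class TestMidDesign:
    def test_two_run_trial_counts(self):
        d = make_mid_design("two_run_gain_loss", seed=1)
        conds = [c for _, _, c in d.events]
        # per session (2 runs): anticipation events for 40 gain + 40 loss
        # trials per run, 10 neutral cues per run
        n_gain = sum(c.startswith("ant_gain") for c in conds)
        n_loss = sum(c.startswith("ant_loss") for c in conds)
        n_neut = conds.count("neutral_cue")
        assert (n_gain, n_loss, n_neut) == (80, 80, 20)
        assert len(d.run_boundaries) == 2

    def test_one_run_trial_counts(self):
        d = make_mid_design("one_run_gain", seed=1)
        conds = [c for _, _, c in d.events]
        assert sum(c.startswith("ant_gain") for c in conds) == 62
        assert conds.count("neutral_cue") == 18
        assert d.run_boundaries == [0]

    def test_hit_rate_calibrated(self):
        hits = misses = 0
        for seed in range(125):  # 125 x 80 = 10,000 trials
            d = make_mid_design("one_run_gain", seed=seed)
            for _, _, c in d.events:
                if c.endswith("_hit"):
                    hits += 1
                elif c.endswith("_miss"):
                    misses += 1
        rate = hits / (hits + misses)
        assert abs(rate - 0.66) < 0.015

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            make_mid_design("three_run", seed=0)

    def test_anticipation_duration_spans_cue_to_target(self):
        t = TrialTiming()
        d = make_mid_design("two_run_gain_loss", seed=0, timing=t)
        durs = [dur for _, dur, c in d.events if c.startswith("ant_")]
        assert min(durs) >= t.cue_s + t.ant_min_s - 1e-9
        assert max(durs) <= t.cue_s + t.ant_max_s + 1e-9


class TestTaskSimulation:
    def test_noiseless_glm_refit_recovers_betas(self):
        d = make_mid_design("one_run_gain", seed=4)
        T = required_volumes(d, 2.0)
        rng = np.random.default_rng(0)
        betas = {lab: float(rng.normal()) for lab in d.condition_labels}
        Y = simulate_task_ts(d, betas, 2.0, T, noise_sd=0.0)
        X, labels = build_design_matrix(d, 2.0, T)
        glm = fit_glm(Y, X, labels)
        for lab in d.condition_labels:
            assert abs(float(glm.betas[lab][0]) - betas[lab]) < 1e-6

    def test_zero_betas_zero_noise_flat_series(self):
        d = make_mid_design("one_run_gain", seed=4)
        T = required_volumes(d, 2.0)
        Y = simulate_task_ts(d, {lab: 0.0 for lab in d.condition_labels},
                             2.0, T, noise_sd=0.0)
        assert np.abs(Y).max() == 0.0

    def test_beta_recovery_degrades_with_noise(self):
        d = make_mid_design("one_run_gain", seed=4)
        T = required_volumes(d, 2.0)
        betas = {lab: 1.0 for lab in d.condition_labels}
        X, labels = build_design_matrix(d, 2.0, T)
        rmse = {}
        for sd in (0.1, 1.0):
            errs = []
            for rep in range(5):
                Y = simulate_task_ts(d, betas, 2.0, T, noise_sd=sd, seed=rep)
                glm = fit_glm(Y, X, labels)
                errs += [float(glm.betas[lab][0]) - 1.0 for lab in d.condition_labels]
            rmse[sd] = np.sqrt(np.mean(np.square(errs)))
        assert rmse[1.0] > rmse[0.1]

    def test_onset_beyond_scan_rejected(self):
        d = make_mid_design("one_run_gain", seed=4)
        with pytest.raises(ValueError):
            simulate_task_ts(d, {lab: 0.0 for lab in d.condition_labels},
                             2.0, 10, noise_sd=0.0)


class TestLinkTargets:
    def _gt(self, d, weights, noise=0.0):
        return GroundTruth(true_edge_weights=weights, noise_sd_target=noise,
                           rest_cov={}, true_task_betas={})

    def test_one_hot_weight_reads_off_edge(self, rng):
        F = rng.standard_normal((7, 10))
        w = np.zeros(10)
        w[3] = 1.0
        out = link_targets(F, self._gt(10, {"sensitivity": w}))
        np.testing.assert_allclose(out["sensitivity"], F[:, 3])

    def test_length_mismatch_rejected(self, rng):
        F = rng.standard_normal((5, 9))
        with pytest.raises(ValueError):
            link_targets(F, self._gt(9, {"maximal": np.zeros(10)}))

    def test_zero_weights_targets_pure_noise(self, rng):
        F = rng.standard_normal((200, 6))
        out = link_targets(F, self._gt(6, {"average": np.zeros(6)}, noise=1.0), seed=0)
        y = out["average"]
        assert abs(y.mean()) < 0.25 and abs(y.std() - 1.0) < 0.25

    def test_measures_positively_correlated(self, small_cohort):
        gt = small_cohort.ground_truth
        s = np.array([sub.targets_true.sensitivity for sub in small_cohort.subjects])
        m = np.array([sub.targets_true.maximal for sub in small_cohort.subjects])
        assert np.corrcoef(s, m)[0, 1] > 0


class TestCohort:
    def test_cohort_sizes_and_schemes(self, small_cohort):
        labs = small_cohort.cohort_labels
        assert [int((labs == c).sum()) for c in (1, 2, 3)] == [5, 5, 5]
        schemes = {s.cohort: s.design.scheme for s in small_cohort.subjects}
        assert schemes[1] == schemes[3] == "two_run_gain_loss"
        assert schemes[2] == "one_run_gain"

    def test_bit_identical_for_same_seed(self):
        from tests.conftest import SMALL_CONFIG
        a = make_cohort(SMALL_CONFIG, seed=5)
        b = make_cohort(SMALL_CONFIG, seed=5)
        np.testing.assert_array_equal(a.subjects[0].rest_ts, b.subjects[0].rest_ts)
        np.testing.assert_array_equal(a.subjects[-1].task_ts, b.subjects[-1].task_ts)
        np.testing.assert_array_equal(a.ground_truth.fc_features,
                                      b.ground_truth.fc_features)

    def test_oracle_r_decreases_with_target_noise(self):
        # prediction ceiling (true-weight predictor) falls monotonically in
        # target noise
        from tests.conftest import SMALL_CONFIG
        oracle = []
        for noise in (0.0, 0.5, 1.0, 2.0):
            cfg = CohortConfig(**{**SMALL_CONFIG.__dict__,
                                  "noise_sd_target": noise,
                                  "simulate_task": False})
            coh = make_cohort(cfg, seed=21)
            gt = coh.ground_truth
            y = np.array([s.targets_true.sensitivity for s in coh.subjects])
            yhat = gt.fc_features @ gt.true_edge_weights["sensitivity"]
            oracle.append(np.corrcoef(y, yhat)[0, 1])
        assert all(a > b for a, b in zip(oracle, oracle[1:])), oracle
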