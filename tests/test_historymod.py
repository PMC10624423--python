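"""History-modulation index, trial-shuffle null, and onset detection."""

import numpy as np
import pytest
from scipy import stats

from trialhist import SynthConfig, synthdata
from trialhist.historymod import (
    detect_onset,
    learning_modulation,
    modulation_trace,
    onset_threshold_correlation,
    shuffle_null,
    trialtime_modulation,
)
from trialhist.imaging import STIM_WINDOW, window_average


class TestModulationTrace:
    def test_identical_groups_give_zero(self, rng):
        g = rng.standard_normal((10, 40))
        assert np.allclose(modulation_trace(g, g.copy()), 0.0)

    def test_constant_offset_recovered(self, rng):
        g = rng.standard_normal((10, 40))
        assert np.allclose(modulation_trace(g + 0.05, g), 0.05)

    def test_matches_independent_means(self, rng):
        a, b = rng.standard_normal((12, 30)), rng.standard_normal((8, 30))
        expected = np.array([a[:, f].mean() - b[:, f].mean() for f in range(30)])
        assert np.allclose(modulation_trace(a, b), expected, atol=1e-12)

    def test_antisymmetric_under_group_swap(self, rng):
        a, b = rng.standard_normal((7, 20)), rng.standard_normal((9, 20))
        assert np.allclose(modulation_trace(a, b), -modulation_trace(b, a), atol=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            modulation_trace(np.empty((0, 10)), np.zeros((3, 10)))


class TestShuffleNull:
    def test_exchangeable_groups_center_on_zero(self, rng):
        a, b = rng.standard_normal((25, 20)), rng.standard_normal((25, 20))
        nm, ns = shuffle_null(a, b, n_iter=1000, seed=0)
        assert np.all(np.abs(nm) < 3.5 * ns / np.sqrt(1000) + 1e-12)

    def test_null_sd_matches_analytic_mean_difference(self, rng):
        """SD of a mean difference of sigma-Gaussians is sigma*sqrt(1/nA+1/nB)."""
        sigma, n_a, n_b = 2.0, 40, 25
        a = rng.normal(0, sigma, size=(n_a, 10))
        b = rng.normal(0, sigma, size=(n_b, 10))
        _, ns = shuffle_null(a, b, n_iter=2000, seed=1)
        expected = sigma * np.sqrt(1 / n_a + 1 / n_b)
        assert np.all(np.abs(ns - expected) / expected < 0.15)

    def test_deterministic_given_seed(self, rng):
        a, b = rng.standard_normal((10, 15)), rng.standard_normal((12, 15))
        r1 = shuffle_null(a, b, n_iter=200, seed=42)
        r2 = shuffle_null(a, b, n_iter=200, seed=42)
        assert np.array_equal(r1[0], r2[0]) and np.array_equal(r1[1], r2[1])

    def test_batching_does_not_change_result(self, rng):
        a, b = rng.standard_normal((10, 5)), rng.standard_normal((10, 5))
        r1 = shuffle_null(a, b, n_iter=500, seed=3, batch=7)
        r2 = shuffle_null(a, b, n_iter=500, seed=3, batch=500)
        assert np.allclose(r1[0], r2[0], atol=1e-12)

    def test_too_few_iterations_rejected(self, rng):
        with pytest.raises(ValueError, match="n_iter"):
            shuffle_null(np.zeros((3, 4)), np.zeros((3, 4)), n_iter=1)


class TestDetectOnset:
    def test_zero_delta_never_crosses(self):
        n = np.zeros(50)
        assert detect_onset(n, n, np.ones(50)) is None

    def test_large_step_found_at_its_index(self):
        sd = np.ones(50)
        delta = np.zeros(50)
        delta[10:] = 5.0
        assert detect_onset(delta, np.zeros(50), sd) == 10
        assert detect_onset(delta, np.zeros(50), sd, min_consecutive=3) == 10

    def test_single_frame_blip_filtered_by_persistence(self):
        delta = np.zeros(50)
        delta[10] = 5.0
        sd = np.ones(50)
        assert detect_onset(delta, np.zeros(50), sd) == 10
        assert detect_onset(delta, np.zeros(50), sd, min_consecutive=2) is None

    def test_two_sided_detects_negative_crossing(self):
        delta = np.zeros(50)
        delta[20:] = -5.0
        sd = np.ones(50)
        assert detect_onset(delta, np.zeros(50), sd) is None
        assert detect_onset(delta, np.zeros(50), sd, two_sided=True) == 20

    def test_zero_sd_with_nonzero_delta_rejected(self):
        sd = np.ones(50)
        sd[5] = 0.0
        delta = np.full(50, 0.1)
        with pytest.raises(ValueError, match="zero"):
            detect_onset(delta, np.zeros(50), sd)


@pytest.fixture(scope="module")
def synth_session():
    cfg = SynthConfig(
        n_trials=900, n_sessions=3, learn_b=300, learn_c=80,
        history_onset_learning=350, history_effect=0.04, noise_sd=0.03,
        contamination_amp=0.0, seed=11,
    )
    table = synthdata.simulate_behavior(cfg)
    tensor, _, truth = synthdata.simulate_session_tensor(table, cfg)
    return cfg, table, tensor, truth


class TestTrialtimeModulation:
    def test_expert_onset_falls_in_stim_window(self, synth_session):
        """The BC history effect is injected in the stim window; the detected
        onset (relative to texture stop) must land there."""
        cfg, table, tensor, _ = synth_session
        res = trialtime_modulation(tensor, table, area="BC", session_id="day03", seed=0)
        assert res.onset_time_s is not None
        assert -0.2 <= res.onset_time_s < 0.2

    def test_rl_pre_window_onset_precedes_bc(self, synth_session):
        cfg, table, tensor, _ = synth_session
        bc = trialtime_modulation(tensor, table, area="BC", session_id="day03", seed=0)
        rl = trialtime_modulation(tensor, table, area="RL", session_id="day03", seed=1)
        assert rl.onset_time_s is not None
        assert rl.onset_time_s < bc.onset_time_s

    def test_naive_phase_reports_no_onset(self, synth_session):
        cfg, table, tensor, _ = synth_session
        res = trialtime_modulation(tensor, table, area="BC", session_id="day01", seed=2)
        assert res.onset_time_s is None

    def test_min_trial_rule_enforced(self, synth_session):
        cfg, table, tensor, _ = synth_session
        with pytest.raises(ValueError, match="too few"):
            trialtime_modulation(
                tensor, table, area="BC", session_id="day03", min_trials=10_000
            )


class TestLearningModulation:
    def test_onset_tracks_injected_switch_on(self, synth_session):
        cfg, table, tensor, _ = synth_session
        res = learning_modulation(tensor, table, threshold=300.0, area="BC", seed=0)
        assert res.onset_trial is not None
        # detection at bin granularity: the bin holding the switch-on trial
        # (only partially dosed) or the one right after it
        onset_bin = int(np.searchsorted(res.bin_centers, res.onset_trial))
        injected_bin = int((cfg.history_onset_learning - 1) // res.bin_size)
        assert onset_bin - injected_bin in (0, 1)
        # relative axis anchored at the threshold's bin center
        thr_bin = np.flatnonzero(res.bin_centers_rel == 0.0)
        assert res.bin_centers[thr_bin[0]] == pytest.approx(250.5)

    def test_no_effect_gives_no_onset(self):
        cfg = SynthConfig(
            n_trials=900, n_sessions=3, learn_b=300, history_onset_learning=350,
            history_effect=0.0, contamination_amp=0.0, seed=21,
        )
        table = synthdata.simulate_behavior(cfg)
        tensor, _, _ = synthdata.simulate_session_tensor(table, cfg)
        res = learning_modulation(tensor, table, threshold=300.0, area="BC", seed=0)
        assert res.onset_trial is None

    def test_single_bin_equals_windowed_trace_delta(self, synth_session):
        """With all trials in one bin the learning-dimension modulation equals
        the window average of the trial-time modulation."""
        cfg, table, tensor, _ = synth_session
        res = learning_modulation(
            tensor, table, threshold=300.0, area="BC", bin_size=len(table), seed=0
        )
        tt = trialtime_modulation(tensor, table, area="BC", seed=0)
        stim = STIM_WINDOW.frame_mask(tensor.time_s)
        assert res.delta[0] == pytest.approx(tt.delta[stim].mean(), abs=1e-12)


class TestOnsetThresholdCorrelation:
    def test_monotone_coupling_gives_unit_rho(self):
        thr = np.array([800, 1200, 1500, 2000, 2600.0])
        rho, p, excl = onset_threshold_correlation(thr + 300, thr)
        assert rho == pytest.approx(1.0)
        assert excl == 0

    def test_reversed_ranks_give_minus_one(self):
        thr = np.array([1.0, 2.0, 3.0, 4.0])
        rho, _, _ = onset_threshold_correlation(thr[::-1], thr)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_formula_with_ties(self, rng):
        onsets = rng.integers(0, 5, size=10).astype(float)
        thr = rng.integers(0, 5, size=10).astype(float)
        rho, _, _ = onset_threshold_correlation(onsets, thr)
        # oracle: Pearson correlation of midranks
        r_o = stats.rankdata(onsets)
        r_t = stats.rankdata(thr)
        expected = np.corrcoef(r_o, r_t)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_missing_onsets_excluded_and_counted(self):
        rho, _, excl = onset_threshold_correlation(
            [100.0, None, 300.0, 400.0], [1, 2, 3, 4]
        )
        assert excl == 1
        assert rho == pytest.approx(1.0)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            onset_threshold_correlation([1.0, None, None], [1, 2, 3])
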