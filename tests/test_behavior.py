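"""Outcome typing, history pairing, d' curves, sigmoid thresholds, phases."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from trialhist import behavior
from trialhist.behavior import (
    LearningCurve,
    assign_phases,
    bin_learning_curve,
    classify_outcome,
    compute_dprime,
    fit_sigmoid,
    history_conditioned_behavior,
    learning_threshold,
    pair_history,
    sigmoid,
)

from conftest import table_from_outcomes


@pytest.mark.parametrize(
    "texture,licked,expected",
    [
        ("go", True, "Hit"),
        ("go", False, "Miss"),
        ("nogo", True, "FA"),
        ("nogo", False, "CR"),
    ],
)
def test_classify_outcome_mapping(texture, licked, expected):
    assert classify_outcome(texture, licked) == expected


def test_classify_outcome_rejects_unknown_texture():
    with pytest.raises(ValueError, match="unknown texture"):
        classify_outcome("rough", True)


class TestPairHistory:
    def test_single_session_enumeration(self):
        t = table_from_outcomes(["CR", "Hit", "Hit"])
        counts = pair_history(t)["pair"].value_counts()
        assert counts.to_dict() == {"CR-Hit": 1, "Hit-Hit": 1}

    def test_session_boundary_pair_excluded(self):
        t = table_from_outcomes(["Hit", "Hit", "Hit"], session_ids=["a", "b", "b"])
        counts = pair_history(t)["pair"].value_counts()
        assert counts.to_dict() == {"Hit-Hit": 1}

    def test_matches_bruteforce_scan(self, random_table):
        """Pair counts equal an explicit consecutive-outcome scan."""
        pairs = pair_history(random_table)
        # independent oracle: loop over consecutive rows
        expected = {}
        rows = random_table.sort_values("trial_index").to_dict("records")
        for prev, curr in zip(rows, rows[1:]):
            if prev["session_id"] != curr["session_id"]:
                continue
            key = f"{prev['outcome']}-{curr['outcome']}"
            expected[key] = expected.get(key, 0) + 1
        assert pairs["pair"].value_counts().to_dict() == expected
        n_sessions = random_table["session_id"].nunique()
        assert len(pairs) == len(random_table) - n_sessions

    def test_invariant_to_session_relabeling(self, random_table):
        relabeled = random_table.assign(
            session_id=random_table["session_id"].map({"day01": "X", "day02": "Y"})
        )
        a = pair_history(random_table).drop(columns="curr_trial_index")
        b = pair_history(relabeled).drop(columns="curr_trial_index")
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_trial_index_rejected(self):
        t = table_from_outcomes(["Hit", "Hit"])
        t.loc[1, "trial_index"] = 1
        with pytest.raises(ValueError, match="duplicate"):
            pair_history(t)


class TestDprime:
    def test_symmetric_rates_give_zero(self):
        assert compute_dprime(25, 25, 25, 25) == pytest.approx(0.0)

    def test_matches_probit_oracle(self):
        # hit rate .84, FA rate .16 -> d' = 2 * Phi^-1(.84)
        assert compute_dprime(42, 8, 8, 42) == pytest.approx(2 * norm.ppf(0.84), abs=1e-12)

    def test_perfect_performance_clipped(self):
        # rates 0 and 1 clipped to 1/(2N) with N=50 -> 2 * Phi^-1(.99)
        assert compute_dprime(50, 0, 0, 50) == pytest.approx(2 * norm.ppf(0.99), abs=1e-12)

    def test_monotone_in_hits_and_fas(self):
        base = compute_dprime(30, 20, 20, 30)
        assert compute_dprime(31, 19, 20, 30) > base
        assert compute_dprime(30, 20, 21, 29) < base

    @pytest.mark.parametrize("counts", [(0, 0, 10, 10), (10, 10, 0, 0)])
    def test_missing_class_rejected(self, counts):
        with pytest.raises(ValueError, match="undefined"):
            compute_dprime(*counts)


class TestLearningCurve:
    def test_blocks_with_known_counts(self):
        """Three 100-trial blocks with counts (42,8,8,42) each give the probit d'."""
        block = ["Hit"] * 42 + ["Miss"] * 8 + ["FA"] * 8 + ["CR"] * 42
        t = table_from_outcomes(block * 3)
        curve = bin_learning_curve(t, bin_size=100)
        assert curve.dprime == pytest.approx([2 * norm.ppf(0.84)] * 3, abs=1e-12)
        assert curve.bin_centers == pytest.approx([50.5, 150.5, 250.5])

    def test_go_only_bins_flagged_missing(self):
        t = table_from_outcomes(["Hit"] * 200)
        curve = bin_learning_curve(t, bin_size=100)
        assert curve.missing.all()
        assert np.isnan(curve.dprime).all()

    def test_trailing_partial_bin_dropped(self):
        block = ["Hit", "CR"] * 50
        t = table_from_outcomes(block * 2 + ["Hit"] * 30)
        curve = bin_learning_curve(t, bin_size=100)
        assert len(curve.dprime) == 2


def _curve_from_sigmoid(a, b, c, centers, noise=0.0, rng=None):
    y = sigmoid(centers, a, b, c)
    if noise:
        y = y + rng.normal(0, noise, size=len(centers))
    return LearningCurve(bin_size=100, bin_centers=centers, dprime=y)


class TestSigmoidFit:
    centers = np.arange(50.0, 3000.0, 100.0)

    def test_noiseless_recovery(self):
        fit = fit_sigmoid(_curve_from_sigmoid(3.0, 1000.0, 150.0, self.centers))
        assert fit.a == pytest.approx(3.0, rel=1e-3)
        assert fit.b == pytest.approx(1000.0, rel=1e-3)
        assert fit.c == pytest.approx(150.0, rel=1e-3)
        assert not fit.degenerate

    def test_flat_curve_flagged_degenerate(self):
        curve = LearningCurve(bin_size=100, bin_centers=self.centers,
                              dprime=np.zeros_like(self.centers))
        fit = fit_sigmoid(curve)
        assert fit.degenerate
        with pytest.raises(ValueError, match="degenerate"):
            learning_threshold(fit)

    def test_scale_equivariance_in_trial_axis(self):
        fit1 = fit_sigmoid(_curve_from_sigmoid(2.5, 800.0, 120.0, self.centers))
        fit2 = fit_sigmoid(_curve_from_sigmoid(2.5, 1600.0, 240.0, 2 * self.centers))
        assert learning_threshold(fit2) == pytest.approx(2 * learning_threshold(fit1), rel=1e-3)

    def test_threshold_is_half_amplitude_point(self):
        """The returned threshold solves s(t) = a/2 (independent root finder)."""
        fit = fit_sigmoid(
            _curve_from_sigmoid(3.0, 1000.0, 150.0, self.centers, noise=0.1,
                                rng=np.random.default_rng(3))
        )
        root = brentq(lambda t: fit.predict(t) - fit.a / 2.0, 50.0, 2950.0)
        assert learning_threshold(fit) == pytest.approx(root, abs=1e-6)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_sigmoid(_curve_from_sigmoid(3.0, 1000.0, 150.0, self.centers[:3]))


class TestAssignPhases:
    @staticmethod
    def _cohort_table():
        # 5 sessions x 600 trials, rich in CR-Hit and Hit-Hit pairs
        outcomes = ["CR", "Hit", "Hit"] * 1000
        sess = [f"day{1 + i // 600}" for i in range(3000)]
        return table_from_outcomes(outcomes, session_ids=sess)

    def test_threshold_maps_to_third_session(self):
        phases = assign_phases(self._cohort_table(), threshold=1500)
        assert phases.learning == "day3"
        assert phases.expert == "day5"
        assert phases.naive == "day1"
        assert not phases.overlapping

    def test_threshold_in_last_session_flagged_overlapping(self):
        phases = assign_phases(self._cohort_table(), threshold=2900)
        assert phases.learning == phases.expert == "day5"
        assert phases.overlapping

    def test_threshold_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            assign_phases(self._cohort_table(), threshold=5000)


class TestHistoryConditionedBehavior:
    def test_fa_probability_matches_bruteforce(self, random_table):
        rep = history_conditioned_behavior(random_table)
        # oracle: stratified counting over consecutive rows
        rows = random_table.sort_values("trial_index").to_dict("records")
        for prev_kind in ("Hit", "CR"):
            nogo = fa = 0
            for prev, curr in zip(rows, rows[1:]):
                if prev["session_id"] != curr["session_id"]:
                    continue
                if prev["outcome"] == prev_kind and curr["texture"] == "nogo":
                    nogo += 1
                    fa += curr["licked"]
            got = rep["fa_by_predecessor"][prev_kind]
            assert got["n"] == nogo
            assert got["p_fa"] == pytest.approx(fa / nogo)

    def test_empty_stratum_flagged_missing(self):
        t = table_from_outcomes(["CR", "Hit"] * 100)
        rep = history_conditioned_behavior(t, predecessors=("Miss", "CR"))
        assert "Miss" in rep["missing"]
        assert rep["curves"]["Miss"] is None
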