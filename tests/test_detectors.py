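import numpy as np
import pytest

from tolsense.config import DetectorConfig, PipelineConfig
from tolsense.detectors import (
    FeatureError,
    ModelStateError,
    TransferFeatures,
    TransferModel,
    candidate_transfers,
    classify_transfer,
    default_transfer_model,
    detect_active,
    detect_lying,
    detect_transfers,
    detect_walking,
    normalized_xcorr_peak,
    threshold_classify_transfer,
    transfer_features,
    transfer_template,
)
from tolsense.signals import compute_derived
from tolsense.synthetic import build_script, make_profile, synthesize
from tolsense.training import make_transfer_training_set

RATE = 50.0


def _runs_oracle(mask):
    """Brute-force run extraction over a boolean sample sequence."""
    runs, start = [], None
    for i, v in enumerate(list(mask) + [False]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    return runs


class TestActive:
    def test_all_below_threshold(self):
        out = detect_active(np.full(500, 0.001), RATE, 0.03)
        assert out.intervals == []

    def test_single_run_length(self):
        x = np.zeros(2000)
        x[500:1000] = 0.1
        out = detect_active(x, RATE, 0.03, min_bout_s=1.0, merge_gap_s=0.5)
        assert len(out) == 1
        s, e = out.intervals[0]
        assert e - s == pytest.approx(10.0, abs=0.1)

    def test_two_runs_beyond_merge_gap(self):
        x = np.zeros(3000)
        x[100:400] = 0.1
        x[1000:1300] = 0.1   # 12 s gap > merge_gap
        out = detect_active(x, RATE, 0.03, min_bout_s=1.0, merge_gap_s=2.0)
        oracle = _runs_oracle(x >= 0.03)
        assert len(out) == len(oracle) == 2
        for (s, e), (i0, i1) in zip(out.intervals, oracle):
            assert s == pytest.approx(i0 / RATE) and e == pytest.approx(i1 / RATE)

    def test_gap_merging(self):
        x = np.zeros(2000)
        x[100:400] = 0.1
        x[450:700] = 0.1     # 1 s gap <= merge_gap
        out = detect_active(x, RATE, 0.03, min_bout_s=1.0, merge_gap_s=2.0)
        assert len(out) == 1

    def test_idempotent_on_own_indicator(self):
        rng = np.random.default_rng(5)
        x = np.abs(rng.normal(0, 0.05, 4000))
        first = detect_active(x, RATE, 0.03)
        indicator = np.zeros_like(x)
        for s, e in first.intervals:
            indicator[int(s * RATE):int(e * RATE)] = 1.0
        second = detect_active(indicator, RATE, 0.5,
                               min_bout_s=0.0, merge_gap_s=0.0)
        assert [(round(a, 2), round(b, 2)) for a, b in second.intervals] == \
               [(round(a, 2), round(b, 2)) for a, b in first.intervals]


class TestWalking:
    def _peak_train(self, n_peaks, period_s, amp=0.4):
        t = np.arange(int((n_peaks * period_s + 4) * RATE)) / RATE
        x = np.ones_like(t)
        for k in range(n_peaks):
            centre = 2.0 + k * period_s
            x += amp * np.exp(-0.5 * ((t - centre) / 0.06) ** 2)
        return x

    def test_flat_signal_no_walking(self):
        out = detect_walking(np.ones(2000), RATE)
        assert out.intervals == []

    def test_ten_peaks_one_bout(self):
        x = self._peak_train(10, 0.5)
        out = detect_walking(x, RATE)
        assert len(out) == 1
        assert out.attributes[0]["step_count"] == 10

    def test_single_peak_is_not_walking(self):
        x = self._peak_train(1, 0.5)
        assert detect_walking(x, RATE).intervals == []

    def test_two_peaks_minimum(self):
        x = self._peak_train(2, 0.5)
        out = detect_walking(x, RATE)
        assert len(out) == 1 and out.attributes[0]["step_count"] == 2

    def test_peaks_slower_than_cadence_range_rejected(self):
        x = self._peak_train(5, 2.0)   # 2 s intervals > 1.4 s maximum
        assert detect_walking(x, RATE).intervals == []


class TestLying:
    def test_upright_no_lying(self):
        assert detect_lying(np.zeros(3000), RATE).intervals == []

    def test_sustained_tilt_detected(self):
        x = np.zeros(3000)
        x[500:2000] = 85.0   # 30 s beyond the 60 deg threshold
        out = detect_lying(x, RATE, 60.0, 10.0)
        assert len(out) == 1
        s, e = out.intervals[0]
        assert (s, e) == (pytest.approx(10.0), pytest.approx(40.0))

    def test_short_tilt_below_min_duration(self):
        x = np.zeros(3000)
        x[500:650] = 85.0    # 3 s only
        assert detect_lying(x, RATE, 60.0, 10.0).intervals == []


class TestTransferFeatures:
    def test_self_correlation_is_one(self):
        t = transfer_template()
        pad = np.concatenate([np.zeros(50), t, np.zeros(50)])
        assert normalized_xcorr_peak(pad, t) == pytest.approx(1.0, abs=1e-6)

    def test_inverted_transient_correlates_negatively(self):
        t = transfer_template()
        pad = np.concatenate([np.zeros(50), -t, np.zeros(50)])
        assert normalized_xcorr_peak(pad, t) == pytest.approx(-1.0, abs=1e-6)

    def test_flat_window_zero_correlation(self):
        assert normalized_xcorr_peak(np.zeros(300), transfer_template()) == 0.0

    def test_window_too_short(self):
        with pytest.raises(FeatureError):
            normalized_xcorr_peak(np.zeros(10), transfer_template())

    def test_feature_invariants_enforced(self):
        with pytest.raises(FeatureError):
            TransferFeatures(1.5, 0.0, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(FeatureError):
            TransferFeatures(0.5, -1.0, 0.0, 0.0, 0.0, 0.0)

    def test_stand_up_altitude_delta(self, transfer_scene, nonfrail_profile):
        script, rec, derived = transfer_scene
        centre = 30.0 + nonfrail_profile.transfer_duration_s / 2
        f = transfer_features((centre - 2, centre + 2), derived)
        assert f.altitude_delta_m == pytest.approx(
            nonfrail_profile.seat_height_m, abs=0.12)
        assert f.template_xcorr > 0.5


class TestCandidates:
    def test_quiet_sitting_no_candidates(self, nonfrail_profile):
        script = build_script([("sitting", 60.0)])
        rec, _ = synthesize(script, nonfrail_profile, 0.0, seed=1)
        derived = compute_derived(rec)
        assert candidate_transfers(derived) == []

    def test_stand_up_yields_window_containing_event(self, transfer_scene,
                                                     nonfrail_profile):
        script, rec, derived = transfer_scene
        wins = candidate_transfers(derived)
        centre = 30.0 + nonfrail_profile.transfer_duration_s / 2
        assert any(w0 <= centre <= w1 for w0, w1 in wins)

    def test_two_transients_two_windows(self, transfer_scene):
        _, rec, derived = transfer_scene
        wins = candidate_transfers(derived)
        assert len(wins) == 2

    def test_walking_on_level_ground_not_proposed(self, nonfrail_profile):
        script = build_script([("standing", 10.0), ("walking", 30.0),
                               ("standing", 10.0)])
        rec, _ = synthesize(script, nonfrail_profile, 0.0, seed=2)
        wins = candidate_transfers(compute_derived(rec))
        assert wins == []


class TestTransferClassifier:
    def test_untrained_model_raises(self):
        with pytest.raises(ModelStateError):
            TransferModel().predict(np.zeros((1, 6)))

    def test_json_round_trip(self):
        m = default_transfer_model()
        back = TransferModel.from_json(m.to_json())
        X = np.random.default_rng(0).normal(size=(5, 6))
        assert list(back.predict(X)) == list(m.predict(X))

    def test_clean_stand_up_classified(self, transfer_scene, nonfrail_profile):
        script, rec, derived = transfer_scene
        td = nonfrail_profile.transfer_duration_s
        up = transfer_features((30 + td / 2 - 2, 30 + td / 2 + 2), derived)
        down = transfer_features((50 + td / 2 - 2, 50 + td / 2 + 2), derived)
        assert classify_transfer(up) == "sit_to_stand"
        assert classify_transfer(down) == "stand_to_sit"

    def test_all_zero_features_rejected(self):
        f = TransferFeatures(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        assert classify_transfer(f) == "none"

    def test_threshold_fallback_agrees_on_clean_transfers(self, transfer_scene,
                                                          nonfrail_profile):
        script, rec, derived = transfer_scene
        td = nonfrail_profile.transfer_duration_s
        up = transfer_features((30 + td / 2 - 2, 30 + td / 2 + 2), derived)
        assert threshold_classify_transfer(up) == "sit_to_stand"

    def test_held_out_accuracy(self):
        """The packaged model generalises to a freshly drawn synthetic set."""
        model = default_transfer_model()
        X, y = make_transfer_training_set(n_draws=16, seed=424242)
        acc = float(np.mean(model.predict(X) == y))
        assert acc >= 0.95

    def test_detect_transfers_end_to_end(self, transfer_scene):
        _, rec, derived = transfer_scene
        sts, stst = detect_transfers(derived)
        assert len(sts) == 1 and len(stst) == 1
        assert 29.0 < sts.intervals[0][0] < 33.0
        assert 49.0 < stst.intervals[0][0] < 53.0
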