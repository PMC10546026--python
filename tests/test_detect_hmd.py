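"""Unit and property tests of the HMD (refresh-peak-train) detection."""

import numpy as np
import pytest

from clet import (
    DetectionParams,
    PeakSet,
    PhotodiodeRecording,
    detect_onsets_hmd,
    detect_onsets_led,
    find_all_peaks,
    small_peak_mask,
)
from clet._types import BLACK_LABEL, WHITE_LABEL

from _oracles import brute_small_peak_runs


def _rec(samples, fs=500.0):
    return PhotodiodeRecording(samples=np.asarray(samples, dtype=float), fs=fs)


def _peak_train(heights, spacing=6, floor=0.0):
    """Single-sample peaks of the given heights on a flat floor."""
    n = spacing * (len(heights) + 1) + 1
    samples = np.full(n, floor)
    idx = spacing * (1 + np.arange(len(heights)))
    samples[idx] = heights
    return samples, idx


class TestFindAllPeaks:
    @pytest.mark.parametrize(
        "samples, indices, heights",
        [
            ([0, 1, 0, 2, 0], [1, 3], [1, 2]),
            ([0, 1, 2, 3, 4], [], []),  # monotone ramp
            ([4, 3, 2, 1, 0], [], []),
            ([0, 5, 5, 0, 3, 0], [1, 4], [5, 3]),  # plateau counts at first sample
        ],
    )
    def test_examples(self, samples, indices, heights):
        peaks = find_all_peaks(_rec(samples) if len(samples) >= 3 else samples)
        assert peaks.indices.tolist() == indices
        assert peaks.heights.tolist() == heights

    def test_too_short(self):
        with pytest.raises(ValueError, match="3 samples"):
            find_all_peaks(np.array([1.0, 2.0]))

    def test_synthetic_peak_train_count_and_heights(self):
        heights = np.linspace(1000, 2000, 90)
        samples, idx = _peak_train(heights)
        peaks = find_all_peaks(_rec(samples))
        assert peaks.indices.tolist() == idx.tolist()
        np.testing.assert_array_equal(peaks.heights, heights)

    def test_hmd_simulation_peak_spacing(self, hmd_run):
        config, recording, _, _ = hmd_run
        peaks = find_all_peaks(recording)
        spacing = int(round(config.fs / config.refresh_hz))
        gaps = np.diff(peaks.indices)
        # the train is quantised to the sample grid; re-phasing at stimulus
        # boundaries may stretch individual gaps but never below the grid
        assert gaps.min() >= 2
        assert np.median(gaps) == spacing


class TestSmallPeakMask:
    def test_all_small_peaks_marked(self):
        samples, idx = _peak_train(np.full(20, 5000.0))
        peaks = find_all_peaks(_rec(samples))
        mask = small_peak_mask(peaks, len(samples), thd2=8000, run_window=11)
        assert np.flatnonzero(mask).tolist() == idx.tolist()

    def test_alternating_heights_never_qualify(self):
        heights = np.tile([5000.0, 200000.0], 20)
        samples, _ = _peak_train(heights)
        peaks = find_all_peaks(_rec(samples))
        mask = small_peak_mask(peaks, len(samples), thd2=8000, run_window=11)
        assert not mask.any()

    def test_threshold_is_strict(self):
        samples, _ = _peak_train(np.full(15, 8000.0))
        peaks = find_all_peaks(_rec(samples))
        mask = small_peak_mask(peaks, len(samples), thd2=8000, run_window=11)
        assert not mask.any()  # heights == ThD2 are not "below"

    def test_fewer_peaks_than_window_warns(self):
        samples, _ = _peak_train(np.full(5, 100.0))
        peaks = find_all_peaks(_rec(samples))
        with pytest.warns(UserWarning, match="fewer than the run window"):
            mask = small_peak_mask(peaks, len(samples), thd2=8000, run_window=11)
        assert not mask.any()

    def test_zero_at_every_non_peak_sample(self, hmd_run):
        config, recording, _, _ = hmd_run
        peaks = find_all_peaks(recording)
        mask = small_peak_mask(peaks, recording.n_samples, thd2=8000)
        non_peak = np.setdiff1d(np.arange(recording.n_samples), peaks.indices)
        assert not mask[non_peak].any()

    def test_matches_brute_force_runs(self, rng):
        for _ in range(50):
            heights = rng.choice([3000.0, 5000.0, 50000.0], size=int(rng.integers(11, 120)))
            samples, idx = _peak_train(heights)
            peaks = find_all_peaks(_rec(samples))
            mask = small_peak_mask(peaks, len(samples), thd2=8000, run_window=11)
            expect = idx[brute_small_peak_runs(heights, 8000, 11)]
            assert np.flatnonzero(mask).tolist() == list(expect)

    def test_literal_rule_agrees_on_homogeneous_runs(self, rng):
        """On traces whose 11-peak windows are homogeneous (all-small or
        all-large blocks of length >= 11), the printed 4-position check and
        the all-of-window rule mark identical peaks."""
        for _ in range(20):
            blocks = []
            for _b in range(int(rng.integers(2, 6))):
                level = 5000.0 if rng.random() < 0.5 else 50000.0
                blocks.append(np.full(int(rng.integers(11, 30)), level))
            heights = np.concatenate(blocks)
            samples, _ = _peak_train(heights)
            peaks = find_all_peaks(_rec(samples))
            a = small_peak_mask(peaks, len(samples), 8000, 11, rule="all")
            b = small_peak_mask(peaks, len(samples), 8000, 11, rule="literal")
            assert np.array_equal(a, b)

    def test_literal_rule_is_looser_on_mixed_windows(self):
        # positions 0,1,2,10 small but 3..9 large: literal marks, all does not
        heights = np.concatenate(
            [[5000.0] * 3, [50000.0] * 7, [5000.0] * 11]
        )
        samples, _ = _peak_train(heights)
        peaks = find_all_peaks(_rec(samples))
        strict = small_peak_mask(peaks, len(samples), 8000, 11, rule="all")
        literal = small_peak_mask(peaks, len(samples), 8000, 11, rule="literal")
        assert literal.sum() > strict.sum()


class TestDetectOnsetsHmd:
    def test_recovers_injected_onsets(self, hmd_run):
        config, recording, markers, truth = hmd_run
        params = config.default_detection_params()
        refresh_period = 1.0 / config.refresh_hz
        for stimulus, label in (("white", WHITE_LABEL), ("black", BLACK_LABEL)):
            onsets = detect_onsets_hmd(recording, params, stimulus)
            true_onsets = truth.select(label)["onset_s"].to_numpy()
            assert len(onsets) == len(true_onsets)
            # the generator phase-locks the train to each onset, so recovery
            # is sample-exact; a free-running train would add <= one refresh
            # period for black stimuli
            np.testing.assert_allclose(
                onsets.onset_times_s, true_onsets, atol=1.0 / recording.fs
            )

    def test_white_path_identical_to_led_pipeline(self, hmd_run):
        config, recording, _, _ = hmd_run
        params = config.default_detection_params()
        hmd = detect_onsets_hmd(recording, params, "white")
        led = detect_onsets_led(recording, params, "white")
        np.testing.assert_array_equal(hmd.onset_samples, led.onset_samples)

    def test_black_detection_delay_constant_for_free_running_train(self):
        """With a free-running 6-sample-grid train, the black onset lands on
        the first refresh peak at/after the true onset: a bounded, constant
        systematic delay (regression value: < one refresh period)."""
        fs, sp = 500.0, 6
        n = 6000
        samples = np.zeros(n)
        idx = np.arange(sp, n - 1, sp)
        samples[idx] = 100000.0  # neutral train
        onset_sample = 2003  # not on the peak grid
        black = idx[(idx >= onset_sample) & (idx < onset_sample + 150)]
        samples[black] = 5000.0
        rec = _rec(samples, fs)
        params = DetectionParams(thd1=180000, thd2=8000, mode="hmd")
        onsets = detect_onsets_hmd(rec, params, "black")
        assert onsets.onset_samples.tolist() == [black[0]]
        delay = black[0] - onset_sample
        assert 0 <= delay < sp

    def test_neutral_train_detects_nothing(self):
        samples, _ = _peak_train(np.full(600, 100000.0))
        rec = _rec(samples)
        params = DetectionParams(thd1=180000, thd2=8000, mode="hmd")
        with pytest.warns(UserWarning):
            assert len(detect_onsets_hmd(rec, params, "white")) == 0
        with pytest.warns(UserWarning):
            assert len(detect_onsets_hmd(rec, params, "black")) == 0

    def test_peakset_invariants(self):
        with pytest.raises(ValueError, match="increasing"):
            PeakSet(indices=np.array([3, 2]), heights=np.array([1.0, 2.0]))
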