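import numpy as np
import pytest

from songseg.audio_io import Recording
from songseg.pulse_detect import NoiseEstimate, PulseCandidate
from songseg.sine_detect import (
    SineTrain,
    detect_sine_trains,
    mask_pulses,
    sine_carrier_track,
)

FS = 10_000
NOISE = NoiseEstimate(sigma=0.05, window_s=1.0, quantile=0.1, n_windows_used=1)


def sine_recording(intervals, rng, freq=150.0, amplitude=0.25, duration_s=10.0,
                   noise_sd=0.05, chirp_to=None):
    x = rng.normal(0, noise_sd, int(duration_s * FS))
    for a, b in intervals:
        tt = np.arange(int(a * FS), int(b * FS)) / FS
        f = freq
        if chirp_to is not None:
            f = freq + (chirp_to - freq) * (tt - a) / (b - a)
        phase = 2 * np.pi * np.cumsum(np.broadcast_to(f, tt.shape)) / FS
        x[int(a * FS) : int(b * FS)] += amplitude * np.sin(phase)
    return Recording(x, FS)


def fake_pulse(t):
    return PulseCandidate(
        center_time_s=t, peak_amplitude=1.0, best_scale_freq_hz=220.0,
        window=np.ones(201),
    )


class TestMasking:
    def test_no_pulses_identity(self, rng):
        rec = Recording(rng.normal(0, 0.05, FS), FS)
        masked = mask_pulses(rec, [])
        np.testing.assert_array_equal(masked.recording.samples, rec.samples)
        assert masked.valid.all()

    def test_pulse_window_zeroed(self, rng):
        rec = Recording(rng.normal(0, 0.05, 2 * FS), FS)
        masked = mask_pulses(rec, [fake_pulse(1.0)], window_s=0.010)
        lo, hi = int(0.99 * FS), int(1.01 * FS)
        assert np.all(masked.recording.samples[lo + 1 : hi] == 0)
        assert not masked.valid[lo + 1 : hi].any()
        assert masked.valid[: lo - 1].all()

    def test_masking_pulse_free_input_leaves_sine_detection_unchanged(self, rng):
        rec = sine_recording([(2.0, 5.0)], rng)
        unmasked = detect_sine_trains(mask_pulses(rec, []), NOISE)
        masked = detect_sine_trains(mask_pulses(rec, []), NOISE)
        assert len(unmasked) == len(masked)
        for a, b in zip(unmasked, masked):
            assert a.start_s == b.start_s and a.stop_s == b.stop_s


class TestDetection:
    def test_single_train_coverage_and_frequency(self, rng):
        rec = sine_recording([(3.0, 5.0)], rng)  # SNR 5 in amplitude units
        trains = detect_sine_trains(mask_pulses(rec, []), NOISE)
        assert len(trains) == 1
        tr = trains[0]
        overlap = min(tr.stop_s, 5.0) - max(tr.start_s, 3.0)
        assert overlap >= 0.95 * 2.0
        assert tr.mean_freq_hz == pytest.approx(150.0, abs=2.0)

    def test_false_alarms_on_pure_noise(self, rng):
        total = 0.0
        for _ in range(10):
            rec = Recording(rng.normal(0, 0.05, 10 * FS), FS)
            trains = detect_sine_trains(mask_pulses(rec, []), NOISE)
            total += sum(t.length_s for t in trains)
        assert total / 10 < 0.05  # seconds of false sine per 10 s recording

    def test_gap_splits_trains(self, rng):
        rec = sine_recording([(1.0, 3.0), (4.0, 6.0)], rng)
        trains = detect_sine_trains(mask_pulses(rec, []), NOISE)
        assert len(trains) == 2

    def test_ftest_criterion_also_detects(self, rng):
        rec = sine_recording([(3.0, 5.0)], rng)
        trains = detect_sine_trains(mask_pulses(rec, []), NOISE, criterion="ftest")
        assert len(trains) >= 1
        assert sum(t.length_s for t in trains) >= 1.5

    def test_frame_longer_than_recording(self, rng):
        rec = Recording(rng.normal(0, 0.05, 100), FS)
        with pytest.raises(ValueError):
            detect_sine_trains(mask_pulses(rec, []), NOISE)

    def test_length_cull_monotone(self, rng):
        rec = sine_recording([(1.0, 1.4), (3.0, 3.2), (5.0, 8.0)], rng)
        masked = mask_pulses(rec, [])
        counts, totals = [], []
        for min_frames in [2, 3, 6, 12]:
            trains = detect_sine_trains(masked, NOISE, min_len_frames=min_frames)
            counts.append(len(trains))
            totals.append(sum(t.length_s for t in trains))
        assert counts == sorted(counts, reverse=True)
        assert totals == sorted(totals, reverse=True)

    def test_masking_reduces_false_sine_inside_pulse_trains(self, synth60, seg60):
        _, rec, truth, _ = synth60
        res = seg60
        masked = mask_pulses(rec, res.final_pulses)
        unmasked = mask_pulses(rec, [])
        pulse_ivs = [
            (tr["start_s"], tr["stop_s"]) for tr in truth.pulse_trains
        ]

        def sine_in_pulse_trains(trains):
            tot = 0.0
            for t in trains:
                for a, b in pulse_ivs:
                    tot += max(0.0, min(t.stop_s, b) - max(t.start_s, a))
            return tot

        with_mask = sine_in_pulse_trains(detect_sine_trains(masked, res.noise))
        without = sine_in_pulse_trains(detect_sine_trains(unmasked, res.noise))
        assert with_mask <= without

    def test_zero_bridge_oversplits_but_preserves_total(self, synth60, seg60):
        # masked pulses inside sine trains plus no bridging across masked
        # frames force the over-splitting bias: more, shorter trains than
        # truth while total sine time stays within 10%
        _, rec, truth, _ = synth60
        res = seg60
        mid_train_pulses = [
            fake_pulse((a + b) / 2 + off)
            for a, b in truth.sine_trains
            if b - a > 1.0
            for off in (-0.035, 0.0, 0.035)
        ]
        masked = mask_pulses(rec, res.final_pulses + mid_train_pulses)
        trains = detect_sine_trains(masked, res.noise, bridge_frames=0)
        true_lengths = [b - a for a, b in truth.sine_trains]
        det_lengths = [t.length_s for t in trains]
        assert len(trains) >= len(truth.sine_trains)
        assert np.mean(det_lengths) <= np.mean(true_lengths)
        assert sum(det_lengths) == pytest.approx(sum(true_lengths), rel=0.10)


class TestCarrierTrack:
    def test_constant_train_track(self, rng):
        rec = sine_recording([(2.0, 2.5)], rng, noise_sd=0.01)
        trains = detect_sine_trains(mask_pulses(rec, []), NOISE)
        assert len(trains) == 1
        track = sine_carrier_track(trains[0])
        assert 8 <= len(track) <= 12
        for _, f in track:
            assert f == pytest.approx(150.0, abs=2.0)

    def test_chirp_track_recovers_endpoints(self, rng):
        rec = sine_recording([(2.0, 3.0)], rng, freq=140.0, chirp_to=160.0,
                             noise_sd=0.01)
        trains = detect_sine_trains(mask_pulses(rec, []), NOISE)
        assert len(trains) == 1
        freqs = [f for _, f in sine_carrier_track(trains[0])]
        assert freqs[0] == pytest.approx(140.0, abs=3.0)
        assert freqs[-1] == pytest.approx(160.0, abs=3.0)
        # broadly monotone increasing
        assert np.mean(np.diff(freqs) > -1.0) > 0.8

    def test_single_bin_train(self):
        tr = SineTrain(start_s=1.0, stop_s=1.05, bin_freqs_hz=[150.0])
        track = sine_carrier_track(tr)
        assert track == [(1.025, 150.0)]
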