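"""Unit and property tests for the chrominance rPPG signal chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rppgstress as r
from rppgstress.chrom_rppg import (bandpass, design_bandpass, iter_windows,
                                   process_window, window_length_frames)
from rppgstress.errors import (DegenerateSignalError, InputError)


class TestFaceDetection:
    def test_uniform_frame_has_no_face(self):
        frame = np.full((120, 160, 3), 128, dtype=np.uint8)
        assert r.detect_face(frame) is None

    def test_injected_detector_passthrough(self):
        frame = np.zeros((200, 200, 3), dtype=np.uint8)
        box = r.detect_face(frame, detector=lambda f: (10, 10, 110, 110))
        assert box == (10, 10, 110, 110)

    def test_pretrained_cascade_finds_real_face(self):
        # the astronaut portrait's face occupies roughly rows 70-160,
        # columns 170-260 of the 512x512 image
        from skimage.data import astronaut
        box = r.detect_face(astronaut())
        assert box is not None
        truth = (170, 70, 260, 160)
        x0 = max(box[0], truth[0]); y0 = max(box[1], truth[1])
        x1 = min(box[2], truth[2]); y1 = min(box[3], truth[3])
        inter = max(0, x1 - x0) * max(0, y1 - y0)
        area = lambda b: (b[2] - b[0]) * (b[3] - b[1])
        iou = inter / (area(box) + area(truth) - inter)
        assert iou > 0.3

    def test_malformed_frame_rejected(self):
        with pytest.raises(InputError):
            r.detect_face(np.zeros((10, 10)), detector=lambda f: None)


class TestCheekGeometry:
    def test_fractional_offsets(self):
        pair = r.extract_cheek_rois((0, 0, 100, 100), (200, 200))
        assert pair.left == (15, 45, 35, 70)
        assert pair.right == (65, 45, 85, 70)

    def test_clipping_at_frame_edge_keeps_roi_nonempty(self):
        pair = r.extract_cheek_rois((120, 50, 230, 160), (200, 200))
        x0, y0, x1, y1 = pair.right
        assert x1 == 200 and x1 > x0 and y1 > y0

    def test_mirror_symmetry(self):
        fw = 300
        pair = r.extract_cheek_rois((40, 20, 140, 120), (200, fw))
        flipped = r.extract_cheek_rois((fw - 140, 20, fw - 40, 120),
                                       (200, fw))
        def reflect(b):
            return (fw - b[2], b[1], fw - b[0], b[3])
        assert reflect(pair.left) == flipped.right
        assert reflect(pair.right) == flipped.left

    def test_zero_area_box_rejected(self):
        with pytest.raises(InputError):
            r.extract_cheek_rois((10, 10, 10, 50), (100, 100))


class TestMeanRGB:
    @pytest.mark.parametrize("value", [(120, 80, 60), (0, 255, 7)])
    def test_constant_frame(self, value):
        frame = np.empty((20, 30, 3), dtype=np.uint8)
        frame[..., :] = value
        assert r.mean_rgb(frame, (5, 5, 15, 15)) == pytest.approx(value)

    def test_two_pixel_average(self):
        frame = np.zeros((1, 2, 3), dtype=np.uint8)
        frame[0, 1] = 255
        assert r.mean_rgb(frame, (0, 0, 2, 1)) == pytest.approx(
            (127.5, 127.5, 127.5))

    def test_checkerboard(self):
        frame = np.zeros((4, 4, 3), dtype=np.uint8)
        frame[::2, ::2, 0] = 100
        frame[1::2, 1::2, 0] = 100
        frame[::2, 1::2, 0] = 200
        frame[1::2, ::2, 0] = 200
        assert r.mean_rgb(frame, (0, 0, 4, 4)) == pytest.approx(
            (150.0, 0.0, 0.0))

    def test_empty_roi_rejected(self):
        with pytest.raises(InputError):
            r.mean_rgb(np.zeros((5, 5, 3), dtype=np.uint8), (2, 2, 2, 4))


class TestNormalization:
    def test_constant_trace_maps_to_ones(self):
        trace = np.tile([80.0, 100.0, 120.0], (50, 1))
        assert np.allclose(r.normalize_segment(trace), 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        trace = 100 + rng.normal(0, 3, (40, 3))
        doubled = trace.copy()
        doubled[:, 0] *= 2
        np.testing.assert_allclose(r.normalize_segment(trace),
                                   r.normalize_segment(doubled))

    def test_arithmetic(self):
        trace = np.array([[90.0, 100.0, 50.0], [110.0, 100.0, 150.0]])
        out = r.normalize_segment(trace)
        np.testing.assert_allclose(
            out, [[0.9, 1.0, 0.5], [1.1, 1.0, 1.5]])

    def test_output_means_are_one(self):
        rng = np.random.default_rng(1)
        out = r.normalize_segment(120 + rng.normal(0, 5, (33, 3)))
        np.testing.assert_allclose(out.mean(axis=0), 1.0, atol=1e-9)

    def test_zero_mean_channel_rejected(self):
        trace = np.ones((10, 3))
        trace[:, 2] = 0.0
        with pytest.raises(DegenerateSignalError):
            r.normalize_segment(trace)


class TestChromTransform:
    @pytest.mark.parametrize("rgb, expected", [
        ((1.0, 1.0, 1.0), (1.0, 1.0)),
        ((1.02, 0.99, 1.00), (1.08, 1.02)),
        ((0.0, 0.0, 0.0), (0.0, 0.0)),
    ])
    def test_pointwise_values(self, rgb, expected):
        xs, ys = r.chrom_transform(*[np.array([c]) for c in rgb])
        assert xs[0] == pytest.approx(expected[0])
        assert ys[0] == pytest.approx(expected[1])

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_agrees_with_elementwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Rn, Gn, Bn = rng.normal(1, 0.05, (3, 64))
        xs, ys = r.chrom_transform(Rn, Gn, Bn)
        for i in range(64):
            assert abs(xs[i] - (3 * Rn[i] - 2 * Gn[i])) < 1e-12
            assert abs(ys[i] - (1.5 * Rn[i] + Gn[i] - 1.5 * Bn[i])) < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            r.chrom_transform(np.ones(3), np.ones(4), np.ones(3))


class TestBandpass:
    def test_dc_rejection(self):
        out = r.bandpass(np.full(120, 7.5), 30)
        assert np.max(np.abs(out[20:-20])) < 1e-6

    def test_passband_amplitude_preserved(self):
        t = np.arange(300) / 30.0
        x = np.sin(2 * np.pi * 1.2 * t)
        y = r.bandpass(x, 30)
        gain = np.sqrt(np.mean(y[60:-60] ** 2) / np.mean(x[60:-60] ** 2))
        assert 0.8 < gain < 1.2

    def test_stopband_attenuated(self):
        t = np.arange(600) / 30.0
        x = np.sin(2 * np.pi * 0.2 * t)
        y = r.bandpass(x, 30)
        gain = np.sqrt(np.mean(y[90:-90] ** 2) / np.mean(x[90:-90] ** 2))
        assert gain < 0.2

    def test_short_signal_rejected(self):
        with pytest.raises(InputError):
            r.bandpass(np.ones(10), 30)

    def test_filter_fits_subsegment(self):
        assert design_bandpass(30).size <= 33


class TestAlphaCombine:
    def test_self_cancellation(self):
        s = np.sin(np.linspace(0, 10, 99))
        alpha, sf = r.alpha_combine(s, s)
        assert alpha == pytest.approx(1.0)
        assert np.allclose(sf, 0.0)

    def test_proportional_signals_cancel(self):
        s = np.cos(np.linspace(0, 7, 80))
        alpha, sf = r.alpha_combine(2 * s, s)
        assert alpha == pytest.approx(2.0)
        assert np.allclose(sf, 0.0)

    def test_quadrature_keeps_frequency(self):
        # 75 samples = exactly 3 cycles of 1.2 Hz at 30 fps, so the two
        # quadrature components have identical sample variance
        t = np.arange(75) / 30.0
        alpha, sf = r.alpha_combine(np.sin(2 * np.pi * 1.2 * t),
                                    np.cos(2 * np.pi * 1.2 * t))
        assert alpha == pytest.approx(1.0, abs=1e-6)
        freqs = np.fft.rfftfreq(1024, 1 / 30.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(sf, 1024)))]
        assert peak == pytest.approx(1.2, abs=30.0 / 1024)

    def test_constant_y_rejected(self):
        with pytest.raises(DegenerateSignalError):
            r.alpha_combine(np.sin(np.arange(50.0)), np.ones(50))


class TestOverlapAddPulse:
    def test_constant_window_gives_silence(self):
        trace = np.tile([150.0, 100.0, 80.0], (99, 1))
        sf = r.overlap_add_pulse(trace, 30)
        assert sf.shape == (99,)
        assert np.max(np.abs(sf)) < 1e-9

    def test_planted_modulation_frequency_survives(self):
        t = np.arange(99) / 30.0
        mod = 1 + 0.02 * np.sin(2 * np.pi * 1.5 * t)
        trace = np.stack([150 * (1 + 0.5 * (mod - 1)),
                          100 * mod,
                          80 * (1 + 0.4 * (mod - 1))], axis=1)
        sf = r.overlap_add_pulse(trace, 30)
        freqs = np.fft.rfftfreq(1024, 1 / 30.0)
        band = (freqs >= 0.67) & (freqs <= 3.67)
        peak = freqs[band][np.argmax(np.abs(np.fft.rfft(sf, 1024))[band])]
        assert peak == pytest.approx(1.5, abs=0.15)

    def test_output_length_contract(self):
        for fps in (20, 25, 30):
            n = window_length_frames(fps)
            trace = 100 + np.zeros((n, 3))
            assert r.overlap_add_pulse(trace, fps).size == n


class TestHRFromSpectrum:
    @pytest.mark.parametrize("hz, bpm", [(1.2, 72.0), (2.0, 120.0)])
    def test_pure_tone(self, hz, bpm):
        t = np.arange(99) / 30.0
        est = r.hr_from_spectrum(np.sin(2 * np.pi * hz * t), 30)
        assert est == pytest.approx(bpm, abs=3.0)

    def test_silent_window_gives_sentinel(self):
        assert r.hr_from_spectrum(np.zeros(99), 30) == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(InputError):
            r.hr_from_spectrum(np.array([1.0, np.nan]), 30)


class TestProcessVideo:
    def test_one_minute_yields_18_values_per_cheek(self):
        video = r.make_synthetic_video(duration_s=60, fps=30, pulse_bpm=80,
                                       frame_height=60, frame_width=80,
                                       seed=4)
        roi = r.extract_cheek_rois(video.face_box, (60, 80))
        left, right = r.process_video(video, roi_pair=roi)
        assert left.values.size == 18
        assert right.values.size == 18

    def test_window_count_floor(self, small_video):
        video, roi = small_video
        frames = video.to_array()
        exact = r.ArrayVideo(frames[:99], 30.0)
        left, _ = r.process_video(exact, roi_pair=roi)
        assert left.values.size == 1
        short = r.ArrayVideo(frames[:96], 30.0)   # 3.2 s
        left, _ = r.process_video(short, roi_pair=roi)
        assert left.values.size == 0

    def test_nonzero_estimates_inside_band(self, small_video):
        video, roi = small_video
        left, right = r.process_video(video, roi_pair=roi)
        for series in (left, right):
            nz = series.values[series.values != 0]
            assert np.all((nz >= 40) & (nz <= 220))

    def test_no_face_windows_emit_sentinel(self, small_video):
        video, _ = small_video
        left, right = r.process_video(video, detector=lambda f: None)
        assert np.all(left.values == 0) and np.all(right.values == 0)

    def test_pixel_scale_invariance(self, small_video):
        # the normalization contract, checked in float arithmetic
        # (uint8 re-quantization would bury a 1% pulse at c = 0.25)
        video, roi = small_video
        frames = video.to_array().astype(float)
        base, _ = r.process_video(r.ArrayVideo(frames, 30.0), roi_pair=roi)
        scaled, _ = r.process_video(r.ArrayVideo(frames * 0.25, 30.0),
                                    roi_pair=roi)
        one_bin = 60.0 * 30.0 / 1024
        np.testing.assert_allclose(scaled.values, base.values,
                                   atol=one_bin)

    def test_low_fps_rejected(self):
        with pytest.raises(InputError):
            r.process_video(r.ArrayVideo(np.zeros((40, 8, 8, 3),
                                                  dtype=np.uint8), 15.0))

    @pytest.mark.parametrize("bpm", [60, 72, 100, 150])
    def test_planted_pulse_recovered(self, bpm):
        video = r.make_synthetic_video(duration_s=20, fps=30,
                                       pulse_bpm=bpm, frame_height=60,
                                       frame_width=80, seed=bpm)
        roi = r.extract_cheek_rois(video.face_box, (60, 80))
        left, right = r.process_video(video, roi_pair=roi)
        est = np.concatenate([left.values, right.values])
        assert np.mean(np.abs(est - bpm) <= 5.0) >= 0.9
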