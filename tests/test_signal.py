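"""Landmark-to-trace conversion, filtering, blink detection, normalization."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blinkpipe.protocol import HabParams, build_habituation_session, build_ppi_session
from blinkpipe.signal import (
    BlinkEvent,
    EyelidTrace,
    EyeLandmarkIndex,
    LandmarkStream,
    compute_eyelid_openness,
    detect_spontaneous_blinks,
    filter_trace,
    normalize_session,
    resample_uniform,
    segment_trials,
)
from blinkpipe.simulate import (
    DEFAULT_EYE,
    ParticipantModel,
    blink_kernel,
    render_landmarks,
    simulate_session,
)

FS = 60.0
DT = 1000.0 / FS


def stream_from_eye_coords(rows):
    """Frames with explicit eye-landmark coordinates, other landmarks at 0."""
    n = len(rows)
    pts = np.zeros((n, 77, 2))
    for i, (uy, ly, cx) in enumerate(rows):
        for j, k in enumerate(DEFAULT_EYE.upper_lid):
            pts[i, k] = (40 + 14 * j, uy[j])
        for j, k in enumerate(DEFAULT_EYE.lower_lid):
            pts[i, k] = (40 + 14 * j, ly[j])
        for j, k in enumerate(DEFAULT_EYE.corners):
            pts[i, k] = (cx[j], 50.0)
    t = np.arange(n) * DT
    bbox = np.tile([0.0, 0.0, 100.0, 100.0], (n, 1))
    return LandmarkStream(t, pts, bbox)


class TestOpenness:
    def test_hand_computed_ratio(self):
        # upper lids y=(40,40), lower y=(60,60), corners x=(30,70):
        # openness = (120 - 80) / (2*40) = 0.5; a closed frame gives 0,
        # so in closure orientation: open frame 0, closed frame 0.5
        stream = stream_from_eye_coords(
            [((40, 40), (60, 60), (30, 70)), ((50, 50), (50, 50), (30, 70))]
        )
        trace = compute_eyelid_openness(stream, DEFAULT_EYE)
        assert trace.stage == "raw"
        np.testing.assert_allclose(trace.closure, [0.0, 0.5])

    def test_scale_invariance_under_camera_zoom(self):
        rows = [((40, 42), (58, 61), (30, 70)), ((45, 47), (55, 56), (30, 70))]
        s1 = stream_from_eye_coords(rows)
        s2 = LandmarkStream(
            s1.timestamps_ms, s1.points * 2.0, s1.bbox * 2.0
        )
        t1 = compute_eyelid_openness(s1, DEFAULT_EYE)
        t2 = compute_eyelid_openness(s2, DEFAULT_EYE)
        np.testing.assert_allclose(t1.closure, t2.closure, atol=1e-12)

    def test_degenerate_corner_frames_interpolated_or_fatal(self):
        rows = [((40, 40), (60, 60), (30, 70))] * 12
        rows[5] = ((10, 10), (90, 90), (50, 50))  # zero corner distance
        trace = compute_eyelid_openness(stream_from_eye_coords(rows), DEFAULT_EYE)
        np.testing.assert_allclose(trace.closure, np.zeros(12), atol=1e-12)
        bad = [((40, 40), (60, 60), (50, 50))] * 4 + [((40, 40), (60, 60), (30, 70))]
        with pytest.raises(ValueError, match="degenerate"):
            compute_eyelid_openness(stream_from_eye_coords(bad), DEFAULT_EYE)

    def test_eye_index_validation(self):
        with pytest.raises(ValueError):
            EyeLandmarkIndex((1, 1), (2, 3), (4, 5))
        with pytest.raises(ValueError):
            EyeLandmarkIndex((1, 2), (3, 4), (5, 99))


class TestResample:
    def test_identity_on_uniform_grid(self):
        t = np.arange(100) * DT
        c = np.sin(t / 200.0)
        out = resample_uniform(EyelidTrace(t, c, FS, "raw"), FS)
        np.testing.assert_allclose(out.closure, c, atol=1e-12)

    def test_two_point_linear_interpolation(self):
        tr = EyelidTrace([0.0, 100.0], [0.0, 1.0], 10.0, "raw")
        out = resample_uniform(tr, 50.0)  # 20 ms steps
        np.testing.assert_allclose(out.closure, [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])

    def test_jittered_sinusoid_recovery(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 5000, DT) + rng.uniform(-4, 4, size=300)
        t = np.sort(t)
        tr = EyelidTrace(t, np.sin(2 * np.pi * 2.0 * t / 1000.0), FS, "raw")
        out = resample_uniform(tr, FS)
        expected = np.sin(2 * np.pi * 2.0 * out.t_ms / 1000.0)
        assert np.max(np.abs(out.closure - expected)) < 0.05

    def test_non_monotonic_rejected(self):
        with pytest.raises(ValueError):
            resample_uniform(EyelidTrace([0.0, 10.0, 10.0], [0, 1, 2], 60, "raw"), 60)


class TestFilter:
    def test_dc_gain_is_one(self):
        tr = EyelidTrace(np.arange(200) * DT, np.full(200, 0.37), FS, "raw")
        out = filter_trace(tr)
        np.testing.assert_allclose(out.closure, 0.37, atol=1e-9)
        assert out.stage == "filtered"

    def test_zero_phase_keeps_symmetric_peak_position(self):
        t = np.arange(400) * DT
        c = np.exp(-0.5 * ((t - t[200]) / 100.0) ** 2)
        out = filter_trace(EyelidTrace(t, c, FS, "raw"))
        assert abs(int(np.argmax(out.closure)) - 200) <= 0

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(1)
        c = rng.standard_normal(2000)
        out = filter_trace(EyelidTrace(np.arange(2000) * DT, c, FS, "raw"))
        assert out.closure.var() < c.var()

    @settings(max_examples=20, deadline=None)
    @given(a=st.floats(-5, 5, allow_nan=False))
    def test_linearity(self, a):
        rng = np.random.default_rng(2)
        c = rng.standard_normal(500)
        tr = lambda x: filter_trace(EyelidTrace(np.arange(500) * DT, x, FS, "raw"))
        np.testing.assert_allclose(
            tr(a * c).closure, a * tr(c).closure, atol=1e-9
        )

    def test_requires_uniform_grid(self):
        rng = np.random.default_rng(4)
        t = np.sort(np.cumsum(np.full(100, DT)) + rng.uniform(-2, 2, 100))
        with pytest.raises(ValueError, match="uniform"):
            filter_trace(EyelidTrace(t, np.zeros(100), FS, "raw"))


class TestBlinkDetection:
    def _trace_with_blinks(self, onsets_ms, amp=1.0, n=3000):
        t = np.arange(n) * DT
        c = np.zeros(n)
        for o in onsets_ms:
            c += blink_kernel(t - o, amp, 50, 50)
        return EyelidTrace(t, c, FS, "filtered")

    def test_flat_baseline_yields_nothing(self):
        tr = self._trace_with_blinks([])
        assert detect_spontaneous_blinks(tr, [(0, 5000)]) == []

    def test_single_injected_blink_recovered(self):
        tr = self._trace_with_blinks([10_000.0], amp=0.8)
        events = detect_spontaneous_blinks(tr, [(9_500.0, 10_500.0)])
        assert len(events) == 1
        assert abs(events[0].peak_time_ms - 10_050.0) <= DT
        assert events[0].onset_time_ms <= events[0].peak_time_ms
        assert events[0].peak_amplitude == pytest.approx(0.8, abs=1e-6)

    def test_two_blinks_600ms_apart(self):
        tr = self._trace_with_blinks([10_000.0, 10_600.0])
        events = detect_spontaneous_blinks(tr, [(9_800.0, 11_000.0)])
        assert len(events) == 2

    def test_peak_outside_window_ignored(self):
        tr = self._trace_with_blinks([10_000.0])
        assert detect_spontaneous_blinks(tr, [(0.0, 9_000.0)]) == []


class TestSegmentation:
    def test_ppi_segment_count_conserved(self):
        protocol = build_ppi_session(seed=2)
        stream, gt = simulate_session(protocol, ParticipantModel(), seed=2)
        trace = compute_eyelid_openness(stream, DEFAULT_EYE)
        segs = segment_trials(trace, protocol, gt.trial_onsets_abs_ms)
        assert len(segs) == 55
        assert sum(s.missing for s in segs) == 0

    def test_incomplete_baseline_marks_trial_missing(self):
        protocol = build_habituation_session(HabParams(n_trials=2), seed=0)
        t = np.arange(int(30_000 / DT)) * DT
        trace = EyelidTrace(t, np.zeros_like(t), FS, "filtered")
        segs = segment_trials(trace, protocol, {0: 100.0, 1: 20_000.0})
        assert segs[0].missing and not segs[1].missing
        assert len(segs) == 2

    def test_time_axis_zeroed_at_first_stimulus(self):
        protocol = build_habituation_session(HabParams(n_trials=1), seed=0)
        t = np.arange(int(30_000 / DT)) * DT
        trace = EyelidTrace(t, np.zeros_like(t), FS, "filtered")
        onset = 600 * DT  # grid-aligned
        segs = segment_trials(trace, protocol, {0: onset})
        assert 0.0 in segs[0].t_ms
        assert segs[0].t_ms[0] >= -500.0 and segs[0].t_ms[-1] <= 3800.0


class TestNormalization:
    def _session(self, baseline_level=0.2, blink_amp=1.0):
        protocol = build_habituation_session(HabParams(n_trials=2), seed=0)
        t = np.arange(int(60_000 / DT)) * DT
        c = np.full_like(t, baseline_level)
        onsets = {0: 25_000.0, 1: 55_000.0}
        c += blink_kernel(t - 24_700.0, blink_amp, 50, 50)  # baseline blink
        c += blink_kernel(t - 25_100.0, 0.6, 50, 50)  # evoked response
        trace = EyelidTrace(t, c, FS, "filtered")
        segs = segment_trials(trace, protocol, onsets)
        blinks = detect_spontaneous_blinks(
            trace, [(o - 500.0, o) for o in onsets.values()]
        )
        return segs, blinks

    def test_anchors_baseline_zero_blink_one(self):
        segs, blinks = self._session()
        out, info = normalize_session(segs, blinks)
        assert not info.fallback_used
        assert info.blink_reference_amplitude == pytest.approx(1.0, abs=1e-6)
        s = out[0]
        base = s.closure[(s.t_ms >= -500) & (s.t_ms < -400)]
        np.testing.assert_allclose(base, 0.0, atol=1e-9)
        assert s.closure.max() == pytest.approx(1.0, abs=1e-6)

    def test_affine_invariance(self):
        segs, blinks = self._session()
        out1, _ = normalize_session(segs, blinks)
        scaled = [
            dataclasses.replace(s, closure=3.0 * s.closure + 0.7) for s in segs
        ]
        sblinks = [
            BlinkEvent(b.peak_time_ms, 3.0 * b.peak_amplitude + 0.7, b.onset_time_ms)
            for b in blinks
        ]
        out2, _ = normalize_session(scaled, sblinks)
        for a, b in zip(out1, out2):
            np.testing.assert_allclose(a.closure, b.closure, atol=1e-9)

    def test_idempotence_with_own_anchors(self):
        segs, blinks = self._session()
        out1, info1 = normalize_session(segs, blinks)
        nblinks = [
            BlinkEvent(
                b.peak_time_ms,
                (b.peak_amplitude - 0.2) / info1.blink_reference_amplitude,
                b.onset_time_ms,
            )
            for b in blinks
        ]
        out2, info2 = normalize_session(out1, nblinks)
        assert info2.blink_reference_amplitude == pytest.approx(1.0, abs=1e-9)
        for a, b in zip(out1, out2):
            np.testing.assert_allclose(a.closure, b.closure, atol=1e-9)

    def test_fallback_uses_max_evoked_closure(self):
        segs, _ = self._session()
        out, info = normalize_session(segs, [])
        assert info.fallback_used and info.n_spontaneous_blinks_used == 0
        # the largest stimulus-evoked closure (the 0.6 kernel) becomes 1
        evoked = max(s.closure[s.t_ms >= 0].max() for s in out)
        assert evoked == pytest.approx(1.0, abs=1e-6)

    def test_render_extract_round_trip_is_affine_exact(self):
        rng = np.random.default_rng(3)
        closure = np.clip(
            np.cumsum(rng.standard_normal(600)) * 0.01 + 0.3, 0.0, 1.0
        )
        stream = render_landmarks(closure)
        trace = compute_eyelid_openness(stream, DEFAULT_EYE)
        # recover affine map and compare
        A = np.vstack([closure, np.ones_like(closure)]).T
        coef, *_ = np.linalg.lstsq(A, trace.closure, rcond=None)
        fit = A @ coef
        assert np.max(np.abs(fit - trace.closure)) < 1e-6
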