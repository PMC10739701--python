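"""From facial-landmark streams to normalized per-trial eyelid traces.

The processing chain mirrors how camera-based eyeblink systems treat eyelid
kinematics:

1. ``compute_eyelid_openness`` — collapse the six eye landmarks (two upper-lid
   points, two lower-lid points, two corners) of each frame into a single
   scale-invariant openness ratio, returned in *closure* orientation (larger
   value = more closed);
2. ``resample_uniform`` — linear interpolation onto a uniform grid (camera
   timestamps jitter);
3. ``filter_trace`` — zero-phase (forward-backward) low-pass Butterworth;
4. ``detect_spontaneous_blinks`` — full blinks inside the 500 ms pre-stimulus
   baseline windows, which anchor the normalization;
5. ``normalize_session`` / ``segment_trials`` — per-trial baseline at 0, the
   median spontaneous-blink peak at 1, segments re-zeroed to the first
   stimulus onset of each trial.

The normalized scale therefore reads 0 = eye fully open, 1 = full blink.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import signal as _sps

from .protocol import EbcParams, HabParams, PpiParams, SessionProtocol

__all__ = [
    "LandmarkStream",
    "EyeLandmarkIndex",
    "EyelidTrace",
    "BlinkEvent",
    "NormalizationInfo",
    "TrialSegment",
    "compute_eyelid_openness",
    "resample_uniform",
    "filter_trace",
    "detect_spontaneous_blinks",
    "segment_trials",
    "normalize_session",
    "analysis_window_end_ms",
    "BASELINE_MS",
]

N_LANDMARKS = 77
BASELINE_MS = 500.0  # pre-stimulus baseline window length
_UNIFORM_TOL_MS = 1e-3  # grid spacing constant to within 1 microsecond


@dataclass
class LandmarkStream:
    """Per-frame facial geometry: timestamps, 77 (x, y) points, bounding box."""

    timestamps_ms: np.ndarray  # (n,)
    points: np.ndarray  # (n, 77, 2) image pixels
    bbox: np.ndarray  # (n, 4) x, y, width, height
    orientation: Optional[np.ndarray] = None  # (n, 3) device attitude

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        self.bbox = np.asarray(self.bbox, dtype=float)
        n = self.timestamps_ms.shape[0]
        if self.points.shape != (n, N_LANDMARKS, 2):
            raise ValueError(
                f"points must have shape ({n}, {N_LANDMARKS}, 2), "
                f"got {self.points.shape}"
            )
        if self.bbox.shape != (n, 4):
            raise ValueError(f"bbox must have shape ({n}, 4)")
        if np.any(self.bbox[:, 2:] <= 0):
            raise ValueError("bbox width/height must be positive")
        if n > 1 and np.any(np.diff(self.timestamps_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.timestamps_ms.shape[0])


@dataclass(frozen=True)
class EyeLandmarkIndex:
    """Which of the 77 landmarks are the six eye points.

    The landmark model's index assignment is a deployment detail, so the map
    is configuration. ``corners`` is ordered (temporal, nasal).
    """

    upper_lid: tuple[int, int]
    lower_lid: tuple[int, int]
    corners: tuple[int, int]

    def __post_init__(self) -> None:
        idx = [*self.upper_lid, *self.lower_lid, *self.corners]
        if len(set(idx)) != 6 or any(not 0 <= i < N_LANDMARKS for i in idx):
            raise ValueError("need 6 distinct landmark indices below 77")


@dataclass
class EyelidTrace:
    t_ms: np.ndarray
    closure: np.ndarray
    fs_hz: float
    stage: str  # raw | filtered | normalized

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.closure = np.asarray(self.closure, dtype=float)
        if self.t_ms.shape != self.closure.shape:
            raise ValueError("t_ms and closure must have equal length")

    def is_uniform(self) -> bool:
        d = np.diff(self.t_ms)
        return d.size == 0 or float(np.ptp(d)) <= _UNIFORM_TOL_MS


@dataclass(frozen=True)
class BlinkEvent:
    peak_time_ms: float
    peak_amplitude: float  # pre-normalization closure units
    onset_time_ms: float

    def __post_init__(self) -> None:
        if self.onset_time_ms > self.peak_time_ms:
            raise ValueError("onset must not follow the peak")


@dataclass
class NormalizationInfo:
    blink_reference_amplitude: float
    baseline_offset_per_trial: dict[int, float]
    n_spontaneous_blinks_used: int
    fallback_used: bool
    n_clipped_samples: int = 0


@dataclass
class TrialSegment:
    """One trial's snippet, time-zeroed at its first stimulus onset."""

    trial_index: int
    trial_type: str
    t_ms: np.ndarray  # relative, includes >= 500 ms pre-stimulus
    closure: np.ndarray
    stimulus_onsets: dict[str, tuple[float, ...]]  # label -> relative onsets
    onset_abs_ms: float  # absolute time of the 0 of t_ms
    stage: str = "filtered"
    missing: bool = False


# ---------------------------------------------------------------------------


def compute_eyelid_openness(
    stream: LandmarkStream,
    eye: EyeLandmarkIndex,
    max_invalid_fraction: float = 0.10,
) -> EyelidTrace:
    """Collapse the six eye landmarks into a closure series (stage ``raw``).

    Per frame, with coordinates taken relative to the face bounding box and
    the image convention that y grows downward::

        openness = (sum(y_lower) - sum(y_upper)) / (2 * |x_temporal - x_nasal|)

    i.e. the mean lid gap scaled by the inter-corner distance, which makes the
    value invariant to camera zoom and in-plane translation. The returned
    series is ``closure = max(openness) - openness`` so that larger values
    mean a more closed eye; the arbitrary additive constant is removed later
    by baseline normalization.

    Frames with a degenerate (zero-width) corner distance are interpolated
    from their neighbours; more than ``max_invalid_fraction`` such frames is a
    hard error.
    """
    rel = stream.points - stream.bbox[:, None, :2]
    y_upper = rel[:, list(eye.upper_lid), 1].sum(axis=1)
    y_lower = rel[:, list(eye.lower_lid), 1].sum(axis=1)
    x_t = rel[:, eye.corners[0], 0]
    x_n = rel[:, eye.corners[1], 0]
    denom = 2.0 * np.abs(x_t - x_n)
    invalid = denom < 1e-9
    frac = float(invalid.mean()) if invalid.size else 0.0
    if frac > max_invalid_fraction:
        raise ValueError(
            f"{frac:.0%} of frames have a degenerate eye-corner distance "
            f"(limit {max_invalid_fraction:.0%})"
        )
    openness = np.empty_like(denom)
    ok = ~invalid
    openness[ok] = (y_lower[ok] - y_upper[ok]) / denom[ok]
    if invalid.any():
        if not ok.any():
            raise ValueError("no valid frames")
        openness[invalid] = np.interp(
            stream.timestamps_ms[invalid],
            stream.timestamps_ms[ok],
            openness[ok],
        )
    closure = openness.max() - openness
    dt = np.diff(stream.timestamps_ms)
    fs = 1000.0 / float(np.median(dt)) if dt.size else 60.0
    return EyelidTrace(stream.timestamps_ms.copy(), closure, fs, "raw")


def resample_uniform(trace: EyelidTrace, fs_hz: float) -> EyelidTrace:
    """Linearly interpolate onto a uniform grid spanning the original range."""
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    if trace.t_ms.size < 2:
        raise ValueError("need at least 2 samples to resample")
    if np.any(np.diff(trace.t_ms) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    step = 1000.0 / fs_hz
    t0, t1 = float(trace.t_ms[0]), float(trace.t_ms[-1])
    n = int(np.floor((t1 - t0) / step)) + 1  # no extrapolation past t1
    grid = t0 + step * np.arange(n)
    closure = np.interp(grid, trace.t_ms, trace.closure)
    return EyelidTrace(grid, closure, fs_hz, trace.stage)


def filter_trace(
    trace: EyelidTrace, cutoff_hz: float = 50.0, order: int = 2
) -> EyelidTrace:
    """Zero-phase low-pass Butterworth filtering (stage ``filtered``).

    The filter is applied in the forward and reverse directions, giving zero
    phase shift and doubling the effective order. The effective cutoff is
    clamped to ``0.45 * fs``: a cutoff at or above Nyquist is undefined, and
    at 60 Hz video the nominal 50 Hz configuration value therefore acts as
    "remove only near-Nyquist noise" (effective 27 Hz).
    """
    if not trace.is_uniform():
        raise ValueError("filter_trace requires a uniform time grid")
    eff = min(cutoff_hz, 0.45 * trace.fs_hz)
    b, a = _sps.butter(order, eff, btype="low", fs=trace.fs_hz)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if trace.closure.size <= padlen:
        raise ValueError(
            f"trace too short to filter ({trace.closure.size} <= {padlen})"
        )
    out = _sps.filtfilt(b, a, trace.closure)
    return EyelidTrace(trace.t_ms.copy(), out, trace.fs_hz, "filtered")


def effective_cutoff_hz(cutoff_hz: float, fs_hz: float) -> float:
    """The cutoff actually applied by :func:`filter_trace`."""
    return min(cutoff_hz, 0.45 * fs_hz)


def detect_spontaneous_blinks(
    trace: EyelidTrace,
    baseline_windows: Sequence[tuple[float, float]],
    min_prominence_fraction: float = 0.5,
    min_separation_ms: float = 200.0,
    min_width_ms: float = 60.0,
) -> list[BlinkEvent]:
    """Find full spontaneous blinks inside the pre-stimulus baseline windows.

    Peaks must have prominence of at least ``min_prominence_fraction`` of the
    stream's robust closure range (95th - 5th percentile), a half-prominence
    width of at least ``min_width_ms`` (a full blink occupies well over
    100 ms, which separates it from narrow sensor-noise bumps), and mutual
    separation of at least ``min_separation_ms``. Only peaks whose apex falls
    inside one of the windows are returned, sorted by time.
    """
    c = trace.closure
    if c.size < 3:
        return []
    robust = float(np.percentile(c, 95) - np.percentile(c, 5))
    if robust <= 0:
        # sparse activity on a clean trace: fall back to the full range
        robust = float(np.ptp(c))
    if robust <= 0:
        return []
    # noise floor: full blinks are tens of sigma above sensor noise, while
    # chance noise excursions stay below ~6 sigma even over long streams
    sigma = 1.4826 * float(np.median(np.abs(c - np.median(c))))
    prominence = max(min_prominence_fraction * robust, 8.0 * sigma)
    distance = max(1, int(round(min_separation_ms * trace.fs_hz / 1000.0)))
    width = min_width_ms * trace.fs_hz / 1000.0
    peaks, props = _sps.find_peaks(
        c,
        prominence=prominence,
        distance=distance,
        width=width,
        rel_height=0.5,
    )
    events: list[BlinkEvent] = []
    t = trace.t_ms
    for p, lb in zip(peaks, props["left_bases"]):
        tp = float(t[p])
        if any(lo <= tp <= hi for lo, hi in baseline_windows):
            events.append(BlinkEvent(tp, float(c[p]), float(t[lb])))
    events.sort(key=lambda e: e.peak_time_ms)
    return events


# ---------------------------------------------------------------------------
# trial segmentation and normalization


def analysis_window_end_ms(protocol: SessionProtocol, trial_type: str) -> float:
    """End of a trial's analysis window, relative to its first stimulus onset.

    EBC: nominal US offset + 500 ms; PPI: pulse onset + 800 ms; habituation:
    last pulse onset + 800 ms.
    """
    p = protocol.params
    if protocol.paradigm == "ebc":
        return p.isi_ms + p.us_duration_ms + 500.0
    if protocol.paradigm == "ppi":
        lead = p.prepulse_lead_ms if trial_type.startswith("prepulse") else 0.0
        return lead + 800.0
    if protocol.paradigm == "hab":
        return (p.pulses_per_train - 1) * p.inter_onset_ms + 800.0
    raise ValueError(f"unknown paradigm {protocol.paradigm!r}")


def segment_trials(
    trace: EyelidTrace,
    protocol: SessionProtocol,
    absolute_onsets: Mapping[int, float],
    baseline_ms: float = BASELINE_MS,
    stimulus_offset_ms: float = 0.0,
) -> list[TrialSegment]:
    """Cut one snippet per trial, re-zeroed to its first stimulus onset.

    ``absolute_onsets`` maps trial index to the absolute stream time of the
    trial's clock zero. ``stimulus_offset_ms`` is a constant added to every
    stimulus onset (e.g. a measured Bluetooth audio latency). A trial whose
    window exceeds the trace bounds is returned flagged ``missing`` rather
    than raising, so ``len(segments) == protocol.n_trials`` always.
    """
    t = trace.t_ms
    segments: list[TrialSegment] = []
    for trial in protocol.trials:
        t0 = float(absolute_onsets[trial.index]) + stimulus_offset_ms
        ref_abs = t0 + trial.first_onset_ms
        onsets: dict[str, list[float]] = {}
        for e in trial.events:
            onsets.setdefault(e.label, []).append(
                t0 + e.onset_ms - ref_abs
            )
        onset_map = {k: tuple(v) for k, v in onsets.items()}
        end = analysis_window_end_ms(protocol, trial.trial_type)
        lo, hi = ref_abs - baseline_ms, ref_abs + end
        if t.size == 0 or lo < t[0] or hi > t[-1]:
            segments.append(
                TrialSegment(
                    trial.index,
                    trial.trial_type,
                    np.empty(0),
                    np.empty(0),
                    onset_map,
                    ref_abs,
                    trace.stage,
                    missing=True,
                )
            )
            continue
        mask = (t >= lo) & (t <= hi)
        segments.append(
            TrialSegment(
                trial.index,
                trial.trial_type,
                t[mask] - ref_abs,
                trace.closure[mask].copy(),
                onset_map,
                ref_abs,
                trace.stage,
            )
        )
    return segments


_BLINK_EXCLUDE_PRE_MS = 150.0
_BLINK_EXCLUDE_POST_MS = 300.0


def _baseline_offset(
    seg: TrialSegment,
    baseline_ms: float,
    blink_peaks_abs: Sequence[float] = (),
) -> float:
    """Median of the pre-stimulus baseline, excluding detected blink spans.

    A full blink can occupy most of a 500 ms window, which would drag even a
    median off the true resting level; samples within [peak - 150 ms,
    peak + 300 ms] of any detected spontaneous blink are therefore masked out
    first (falling back to the plain median if nothing remains).
    """
    t_abs = seg.t_ms + seg.onset_abs_ms
    mask = (seg.t_ms >= -baseline_ms) & (seg.t_ms < 0)
    if not mask.any():
        raise ValueError(f"trial {seg.trial_index}: no baseline samples")
    clean = mask.copy()
    for pk in blink_peaks_abs:
        clean &= ~(
            (t_abs >= pk - _BLINK_EXCLUDE_PRE_MS)
            & (t_abs <= pk + _BLINK_EXCLUDE_POST_MS)
        )
    if clean.any():
        return float(np.median(seg.closure[clean]))
    return float(np.median(seg.closure[mask]))


def normalize_session(
    segments: Sequence[TrialSegment],
    blinks: Sequence[BlinkEvent],
    baseline_ms: float = BASELINE_MS,
    clip: tuple[float, float] = (-0.5, 1.5),
) -> tuple[list[TrialSegment], NormalizationInfo]:
    """Anchor the session scale: baseline at 0, spontaneous full blink at 1.

    Each trial's 500 ms pre-stimulus baseline median is subtracted (median:
    robust to a blink inside the window). All trials are then divided by the
    session blink reference — the median of the baseline-corrected spontaneous
    blink peak amplitudes. When no spontaneous blink was detected, the largest
    stimulus-evoked closure in the session is used instead and
    ``fallback_used`` is set. Output is clipped to ``clip`` (artifact guard);
    clipped samples are counted.
    """
    scored = [s for s in segments if not s.missing]
    if not scored:
        raise ValueError("session has no usable trials")
    peaks = [ev.peak_time_ms for ev in blinks]
    offsets = {
        s.trial_index: _baseline_offset(s, baseline_ms, peaks) for s in scored
    }
    median_offset = float(np.median(list(offsets.values())))

    corrected: list[float] = []
    for ev in blinks:
        off = median_offset
        for s in scored:
            if s.onset_abs_ms - baseline_ms <= ev.peak_time_ms < s.onset_abs_ms:
                off = offsets[s.trial_index]
                break
        corrected.append(ev.peak_amplitude - off)
    corrected = [a for a in corrected if a > 0]

    fallback = not corrected
    if fallback:
        evoked = [
            float(np.max(s.closure[s.t_ms >= 0])) - offsets[s.trial_index]
            for s in scored
            if np.any(s.t_ms >= 0)
        ]
        reference = max(evoked) if evoked else 0.0
    else:
        reference = float(np.median(corrected))
    if reference <= 0:
        raise ValueError("blink reference amplitude must be positive")

    n_clipped = 0
    out: list[TrialSegment] = []
    for s in segments:
        if s.missing:
            out.append(replace(s, stage="normalized"))
            continue
        c = (s.closure - offsets[s.trial_index]) / reference
        n_clipped += int(np.sum((c < clip[0]) | (c > clip[1])))
        out.append(
            replace(
                s,
                closure=np.clip(c, clip[0], clip[1]),
                stage="normalized",
            )
        )
    info = NormalizationInfo(
        blink_reference_amplitude=reference,
        baseline_offset_per_trial=offsets,
        n_spontaneous_blinks_used=len(corrected),
        fallback_used=fallback,
        n_clipped_samples=n_clipped,
    )
    return out, info
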