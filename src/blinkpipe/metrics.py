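"""Trial- and session-level scoring of the normalized eyelid traces.

Conditioned-response (CR) scoring follows the anticipatory-window convention
of delay eyeblink conditioning: only eyelid movement between 60 ms after CS
onset and the (nominal) US is conditioned; earlier deflections are reflexive
alpha responses and are excluded. A CR is an eyelid movement larger than a
fixed 0.15 threshold on the normalized scale whose peak lies inside the
window. Startle responses are scored in a 60-330 ms window after pulse onset
(video measures the movement, which lags the muscle activity EMG would see);
the direct response to a prepulse is scored in a 60-180 ms window after the
prepulse.

Session-level startle amplitudes use a two-pass procedure: first the mean
peak time of significant startle responses across all trials is found, then
each trial contributes its closure value at that common time. Prepulse
inhibition is expressed as ``100 * (1 - prepulse_trial / pulse_only)`` and
habituation as the analogous percent drop from the first to the last pulse of
the train.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .protocol import SessionProtocol
from .signal import TrialSegment

__all__ = [
    "ScoringParams",
    "CRMetrics",
    "StartleMetrics",
    "SessionSummary",
    "score_cr",
    "summarize_cr_session",
    "score_startle",
    "score_train",
    "ppi_session_summary",
    "ppi_percent",
    "habituation_summary",
    "score_session",
]

CS_BEARING = ("cs_only", "paired")


@dataclass(frozen=True)
class ScoringParams:
    cr_threshold: float = 0.15
    cr_window_start_ms: float = 60.0  # after CS onset
    us_duration_ms: float = 50.0  # closes the CS-only window at nominal US offset
    startle_window_ms: tuple[float, float] = (60.0, 330.0)  # after pulse onset
    prepulse_window_ms: tuple[float, float] = (60.0, 180.0)  # after prepulse onset
    onset_criterion: float = 0.05  # fraction of the normalized scale
    onset_sustain_frames: int = 3
    nominal_peak_ms: float = 150.0  # used when no startle is significant

    def __post_init__(self) -> None:
        if not 0 < self.cr_threshold < 1:
            raise ValueError("cr_threshold must lie in (0, 1)")
        for w in (self.startle_window_ms, self.prepulse_window_ms):
            if w[0] >= w[1]:
                raise ValueError("response windows must be (start, end)")


@dataclass
class CRMetrics:
    trial_index: int
    trial_type: str
    cr_amplitude: float = float("nan")
    is_cr: bool = False
    latency_onset_ms: Optional[float] = None
    latency_peak_ms: Optional[float] = None  # CS-only trials only
    window_ms: tuple[float, float] = (float("nan"), float("nan"))
    missing: bool = False


@dataclass
class StartleMetrics:
    trial_index: int
    trial_type: str
    peak_amplitude: float = float("nan")
    peak_time_ms: float = float("nan")  # relative to pulse onset
    significant: bool = False
    amplitude_at_mean_peak: float = float("nan")  # filled by the summary pass
    prepulse_response_amplitude: Optional[float] = None
    pulse_position: Optional[int] = None  # 1-based within a train
    pulse_onset_ms: float = 0.0  # relative to segment time zero
    missing: bool = False
    segment: Optional[TrialSegment] = field(
        default=None, repr=False, compare=False
    )


@dataclass
class SessionSummary:
    paradigm: str
    session_index: int
    n_trials_scored: int
    n_missing: int
    cr_percentage: Optional[float] = None
    mean_cr_amplitude: Optional[float] = None
    mean_latency_onset_ms: Optional[float] = None
    mean_latency_peak_ms: Optional[float] = None
    mean_peak_time_ms: Optional[float] = None
    per_type_amplitudes: Optional[dict[str, float]] = None
    ppi_percent_per_level: Optional[dict[str, float]] = None
    per_pulse_amplitudes: Optional[dict[int, float]] = None
    habituation_percent: Optional[float] = None
    flagged: bool = False


# ---------------------------------------------------------------------------
# eyeblink conditioning


def _sustained_onset(
    t: np.ndarray, c: np.ndarray, level: float, sustain: int
) -> Optional[float]:
    above = c >= level
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= sustain:
            return float(t[i - sustain + 1])
    return None


def score_cr(
    segment: TrialSegment,
    isi_ms: float,
    params: ScoringParams = ScoringParams(),
) -> CRMetrics:
    """Score one CS-bearing trial for a conditioned response.

    The window runs from CS onset + 60 ms to the US onset for paired trials
    (only the pre-US interval is anticipatory) and to the *nominal* US offset
    (CS onset + ISI + US duration) for CS-only trials, where no US truncates
    the response. ``is_cr`` additionally requires the window maximum not to
    sit on the window's first sample, which excludes the decaying tail of a
    pre-window alpha response.
    """
    if segment.trial_type not in CS_BEARING:
        raise ValueError(f"cannot CR-score trial type {segment.trial_type!r}")
    if segment.missing:
        return CRMetrics(segment.trial_index, segment.trial_type, missing=True)
    cs = segment.stimulus_onsets["CS"][0]
    w_start = cs + params.cr_window_start_ms
    if segment.trial_type == "paired":
        w_end = segment.stimulus_onsets["US"][0]
    else:
        w_end = cs + isi_ms + params.us_duration_ms
    mask = (segment.t_ms >= w_start) & (segment.t_ms <= w_end)
    if not mask.any():
        return CRMetrics(
            segment.trial_index,
            segment.trial_type,
            window_ms=(w_start, w_end),
            missing=True,
        )
    t, c = segment.t_ms[mask], segment.closure[mask]
    k = int(np.argmax(c))
    amp = float(c[k])
    is_cr = amp > params.cr_threshold and k > 0
    onset = _sustained_onset(
        t, c, params.onset_criterion, params.onset_sustain_frames
    )
    return CRMetrics(
        trial_index=segment.trial_index,
        trial_type=segment.trial_type,
        cr_amplitude=amp,
        is_cr=is_cr,
        latency_onset_ms=None if onset is None else onset - cs,
        latency_peak_ms=(
            float(t[k] - cs) if segment.trial_type == "cs_only" else None
        ),
        window_ms=(w_start, w_end),
    )


def summarize_cr_session(
    metrics: Sequence[CRMetrics], protocol: SessionProtocol
) -> SessionSummary:
    """Session summary over CS-bearing trials (US-only trials are excluded).

    The CR percentage and mean CR amplitude pool paired and CS-only trials;
    the latency to peak averages CS-only CR trials only, since only those show
    the full kinetic profile.
    """
    scored = [m for m in metrics if not m.missing]
    if not scored:
        raise ValueError("no scored trials to summarize")
    n_cr = sum(m.is_cr for m in scored)
    onsets = [m.latency_onset_ms for m in scored if m.latency_onset_ms is not None]
    peaks = [
        m.latency_peak_ms
        for m in scored
        if m.trial_type == "cs_only" and m.is_cr and m.latency_peak_ms is not None
    ]
    return SessionSummary(
        paradigm="ebc",
        session_index=protocol.session_index,
        n_trials_scored=len(scored),
        n_missing=len(metrics) - len(scored),
        cr_percentage=100.0 * n_cr / len(scored),
        mean_cr_amplitude=float(np.mean([m.cr_amplitude for m in scored])),
        mean_latency_onset_ms=float(np.mean(onsets)) if onsets else None,
        mean_latency_peak_ms=float(np.mean(peaks)) if peaks else None,
    )


# ---------------------------------------------------------------------------
# startle / PPI / habituation


def _window_peak(
    segment: TrialSegment, onset: float, window: tuple[float, float]
) -> tuple[float, float]:
    mask = (segment.t_ms >= onset + window[0]) & (
        segment.t_ms <= onset + window[1]
    )
    if not mask.any():
        return float("nan"), float("nan")
    t, c = segment.t_ms[mask], segment.closure[mask]
    k = int(np.argmax(c))
    return float(c[k]), float(t[k] - onset)


def score_startle(
    segment: TrialSegment,
    params: ScoringParams = ScoringParams(),
    pulse_onset_ms: Optional[float] = None,
    pulse_position: Optional[int] = None,
) -> StartleMetrics:
    """Score one pulse of a PPI or habituation trial.

    The peak is sought 60-330 ms after pulse onset; a response is significant
    when its peak exceeds the (shared) 0.15 threshold. In prepulse trials the
    direct response to the prepulse is additionally the maximum 60-180 ms
    after the prepulse.
    """
    if segment.missing:
        return StartleMetrics(
            segment.trial_index, segment.trial_type, missing=True
        )
    if pulse_onset_ms is None:
        pulse_onset_ms = segment.stimulus_onsets["pulse"][0]
    amp, pt = _window_peak(segment, pulse_onset_ms, params.startle_window_ms)
    pp_amp = None
    if "prepulse" in segment.stimulus_onsets:
        pp_onset = segment.stimulus_onsets["prepulse"][0]
        pp_amp, _ = _window_peak(segment, pp_onset, params.prepulse_window_ms)
    return StartleMetrics(
        trial_index=segment.trial_index,
        trial_type=segment.trial_type,
        peak_amplitude=amp,
        peak_time_ms=pt,
        significant=bool(amp > params.cr_threshold),
        prepulse_response_amplitude=pp_amp,
        pulse_position=pulse_position,
        pulse_onset_ms=pulse_onset_ms,
        segment=segment,
    )


def score_train(
    segment: TrialSegment, params: ScoringParams = ScoringParams()
) -> list[StartleMetrics]:
    """Score every pulse of a habituation train as its own startle response."""
    if segment.missing:
        return [
            StartleMetrics(segment.trial_index, segment.trial_type, missing=True)
        ]
    onsets = segment.stimulus_onsets["pulse"]
    return [
        score_startle(segment, params, pulse_onset_ms=o, pulse_position=k + 1)
        for k, o in enumerate(onsets)
    ]


def _amplitude_at(segment: TrialSegment, t: float) -> float:
    return float(np.interp(t, segment.t_ms, segment.closure))


def _mean_peak_time(
    metrics: Sequence[StartleMetrics], params: ScoringParams
) -> tuple[float, bool]:
    sig = [m.peak_time_ms for m in metrics if not m.missing and m.significant]
    if sig:
        return float(np.mean(sig)), False
    return params.nominal_peak_ms, True


def _fill_amplitude_at_mean_peak(
    metrics: Sequence[StartleMetrics], t_mean: float
) -> None:
    for m in metrics:
        if m.missing or m.segment is None:
            continue
        m.amplitude_at_mean_peak = _amplitude_at(
            m.segment, m.pulse_onset_ms + t_mean
        )


def ppi_percent(pulse_amp: float, prepulse_trial_amp: float) -> float:
    """Percent inhibition of the startle by the prepulse (negative =
    facilitation): ``100 * (1 - prepulse_trial_amp / pulse_amp)``."""
    if pulse_amp <= 0:
        raise ValueError("pulse amplitude must be positive")
    return 100.0 * (1.0 - prepulse_trial_amp / pulse_amp)


def ppi_session_summary(
    metrics: Sequence[StartleMetrics],
    params: ScoringParams = ScoringParams(),
    session_index: int = 0,
) -> SessionSummary:
    """Two-pass PPI summary.

    Pass 1 finds the mean peak time of significant startle responses across
    all trials; pass 2 reads every trial's closure at that common
    pulse-referenced time. Per-type means and percent inhibition per prepulse
    level follow. With no significant startle in the session the summary is
    flagged and amplitudes are read at the nominal peak time.
    """
    t_mean, flagged = _mean_peak_time(metrics, params)
    _fill_amplitude_at_mean_peak(metrics, t_mean)
    scored = [m for m in metrics if not m.missing]
    types = sorted({m.trial_type for m in scored})
    per_type = {
        tt: float(
            np.mean([m.amplitude_at_mean_peak for m in scored if m.trial_type == tt])
        )
        for tt in types
    }
    ppi_levels = None
    pulse_amp = per_type.get("pulse_only")
    if pulse_amp is not None and pulse_amp > 0:
        ppi_levels = {
            tt: ppi_percent(pulse_amp, amp)
            for tt, amp in per_type.items()
            if tt.startswith("prepulse_pulse")
        }
    return SessionSummary(
        paradigm="ppi",
        session_index=session_index,
        n_trials_scored=len(scored),
        n_missing=len(metrics) - len(scored),
        mean_peak_time_ms=t_mean,
        per_type_amplitudes=per_type,
        ppi_percent_per_level=ppi_levels,
        flagged=flagged,
    )


def habituation_summary(
    metrics: Sequence[StartleMetrics],
    params: ScoringParams = ScoringParams(),
    session_index: int = 0,
) -> SessionSummary:
    """Within-train habituation summary.

    ``per_pulse_amplitudes[k]`` is the mean amplitude-at-mean-peak for pulse
    position k across trains; the habituation percent is the drop from the
    first to the last pulse, ``100 * (1 - last / first)``.
    """
    t_mean, flagged = _mean_peak_time(metrics, params)
    _fill_amplitude_at_mean_peak(metrics, t_mean)
    scored = [m for m in metrics if not m.missing and m.pulse_position]
    positions = sorted({m.pulse_position for m in scored})
    per_pulse = {
        k: float(
            np.mean(
                [m.amplitude_at_mean_peak for m in scored if m.pulse_position == k]
            )
        )
        for k in positions
    }
    hab_pct = None
    if positions:
        first, last = per_pulse[positions[0]], per_pulse[positions[-1]]
        if first > 0:
            hab_pct = 100.0 * (1.0 - last / first)
        else:
            flagged = True
    n_trials = len({m.trial_index for m in scored})
    n_missing = len({m.trial_index for m in metrics if m.missing})
    return SessionSummary(
        paradigm="hab",
        session_index=session_index,
        n_trials_scored=n_trials,
        n_missing=n_missing,
        mean_peak_time_ms=t_mean,
        per_pulse_amplitudes=per_pulse,
        habituation_percent=hab_pct,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# orchestration


def score_session(
    segments: Sequence[TrialSegment],
    protocol: SessionProtocol,
    params: ScoringParams = ScoringParams(),
) -> tuple[list, SessionSummary]:
    """Score all trials of a session and summarize, dispatched by paradigm.

    Returns ``(per_trial_metrics, session_summary)``. For EBC, US-only trials
    carry no CS and are not scored.
    """
    if protocol.paradigm == "ebc":
        isi = protocol.params.isi_ms
        cr = [
            score_cr(s, isi, params)
            for s in segments
            if s.trial_type in CS_BEARING
        ]
        return cr, summarize_cr_session(cr, protocol)
    if protocol.paradigm == "ppi":
        sm = [score_startle(s, params) for s in segments]
        return sm, ppi_session_summary(sm, params, protocol.session_index)
    if protocol.paradigm == "hab":
        sm = [m for s in segments for m in score_train(s, params)]
        return sm, habituation_summary(sm, params, protocol.session_index)
    raise ValueError(f"unknown paradigm {protocol.paradigm!r}")
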