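"""Generative virtual participant for end-to-end pipeline testing.

The simulator turns any :class:`~blinkpipe.protocol.SessionProtocol` into a
60 Hz facial-landmark stream plus a ground-truth record, so that every stage
of the pipeline — extraction, filtering, normalization, segmentation,
scoring — can be exercised without external data and checked against known
generative parameters.

The behavioural phenomenology covered:

* reflexive blinks to the US and to startle pulses, with realistic latency
  and asymmetric closure/re-opening kinetics (gamma-shaped kernel);
* prepulse inhibition: the pulse response in prepulse trials is scaled by a
  per-intensity inhibition fraction, and sufficiently loud prepulses evoke a
  small direct response of their own;
* within-train startle habituation: pulse k is scaled by a multiplicative
  retention factor per preceding pulse;
* conditioned-response acquisition: CRs appear with probability following an
  exponential-saturation learning curve over cumulative paired trials, with
  peak timing tracking the interstimulus interval (and re-adapting after an
  ISI switch with the same dynamics);
* spontaneous full blinks as a Poisson process, restricted to times where
  their kernel cannot intrude into stimulus/response windows — this blink
  suppression around stimuli keeps the ground truth exactly recoverable at
  zero noise;
* white Gaussian pixel noise on every landmark coordinate.

The learning model is a test harness constrained to reproduce the measured
group phenomenology, not a mechanistic claim about the cerebellum.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .protocol import SessionProtocol
from .signal import (
    BASELINE_MS,
    EyeLandmarkIndex,
    LandmarkStream,
    N_LANDMARKS,
    analysis_window_end_ms,
)

__all__ = [
    "DEFAULT_EYE",
    "ParticipantModel",
    "GroundTruth",
    "TrialTruth",
    "blink_kernel",
    "face_template",
    "render_landmarks",
    "simulate_session",
]

FS_HZ = 60.0

# A fixed eye-landmark assignment for simulated faces (the landmark model's
# real index map is deployment configuration; any six indices work).
DEFAULT_EYE = EyeLandmarkIndex(upper_lid=(37, 38), lower_lid=(40, 41), corners=(36, 39))

# template eye geometry (pixels, bbox-relative): lid gap 20 px, corners 40 px
# apart, so fully open openness = (2*60 - 2*40) / (2*40) = 0.5
_EYE_OPEN = {
    36: (30.0, 50.0),  # temporal corner
    37: (43.0, 40.0),  # upper lid
    38: (57.0, 40.0),
    39: (70.0, 50.0),  # nasal corner
    40: (43.0, 60.0),  # lower lid
    41: (57.0, 60.0),
}
_LID_TRAVEL = 10.0  # px each lid moves to meet at y=50 when closure = 1
_BBOX = (12.0, 8.0, 100.0, 120.0)


def face_template() -> np.ndarray:
    """Canonical 77-point face, bbox-relative pixels. Deterministic."""
    pts = np.zeros((N_LANDMARKS, 2))
    # face outline: an ellipse through the remaining indices
    theta = np.linspace(0.0, 2.0 * np.pi, N_LANDMARKS, endpoint=False)
    pts[:, 0] = 50.0 + 45.0 * np.cos(theta)
    pts[:, 1] = 60.0 + 55.0 * np.sin(theta)
    for k, xy in _EYE_OPEN.items():
        pts[k] = xy
    return pts


def blink_kernel(
    t_ms: np.ndarray | float,
    amplitude: float,
    rise_ms: float,
    decay_ms: float,
) -> np.ndarray | float:
    """Gamma-shaped unimodal closure pulse with exact compact support.

    Zero for t <= 0 and for t >= ``rise_ms + 5 * decay_ms``, peak exactly
    ``amplitude`` at ``t = rise_ms``. The shape parameter is
    ``rise_ms / decay_ms``, giving the fast-close / slower-reopen asymmetry
    of a blink. The underlying gamma shape is truncated at the support end
    and rescaled so the peak value is preserved; the hard support boundary is
    what lets a blink provably not contaminate a later response window.
    """
    if rise_ms <= 0 or decay_ms <= 0:
        raise ValueError("rise_ms and decay_ms must be positive")
    t = np.asarray(t_ms, dtype=float)
    m = rise_ms / decay_ms
    x_end = (rise_ms + 5.0 * decay_ms) / rise_ms
    g_end = np.power(x_end, m) * np.exp(m * (1.0 - x_end))
    with np.errstate(invalid="ignore"):
        x = np.where(t > 0, t / rise_ms, 0.0)
        g = np.power(x, m) * np.exp(m * (1.0 - x))
    k = amplitude * np.clip(g - g_end, 0.0, None) / (1.0 - g_end)
    k = np.where((t > 0) & (x < x_end), k, 0.0)
    return k if k.ndim else float(k)


def kernel_support_ms(rise_ms: float, decay_ms: float) -> float:
    """Length of a blink kernel's (exact) support."""
    return rise_ms + 5.0 * decay_ms


@dataclass(frozen=True)
class ParticipantModel:
    """Generative parameters of the virtual subject.

    Amplitudes are in normalized eyelid units (spontaneous full blink = 1).
    Defaults are round numbers producing group-level behaviour in the range
    reported for neurotypical adults on this class of paradigm: a ~0.35
    startle to a 105 dB pulse, ~60-70 % inhibition by the strongest prepulse,
    a ~0.4 fifth/first-pulse habituation ratio, and a CR rate saturating
    near 60 % after six 40-paired-trial sessions.
    """

    ur_amplitude: float = 0.8  # blink evoked by the (composite) US
    startle_gain_per_db: float = 0.027  # amplitude per dB above threshold
    startle_threshold_db: float = 92.0
    startle_latency_ms: float = 110.0
    startle_latency_sd_ms: float = 15.0
    habituation_factor: float = 0.8  # per-pulse multiplicative retention
    ppi_inhibition: tuple[tuple[float, float], ...] = (
        (65.0, 0.60),
        (75.0, 0.62),
        (83.0, 0.66),
        (93.0, 0.70),
    )
    cr_asymptote_prob: float = 0.6
    cr_learning_rate: float = 0.012  # per cumulative paired trial
    cr_amplitude_asymptote: float = 0.6
    cr_peak_offset_ms: float = 50.0  # CR peak target = ISI + this offset
    cr_timing_jitter_sd_ms: float = 30.0
    cr_prior_isi_ms: Optional[float] = None  # ISI trained before this session
    cr_rise_ms: float = 250.0
    cr_decay_ms: float = 100.0
    spontaneous_blink_rate_hz: float = 0.3
    spontaneous_blink_amp_sd: float = 0.05
    noise_sd_px: float = 0.5
    blink_rise_ms: float = 50.0  # reflexive blinks; 3 frames at 60 Hz
    blink_decay_ms: float = 50.0

    def __post_init__(self) -> None:
        for name in ("cr_asymptote_prob", "habituation_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(not 0.0 <= f <= 1.0 for _, f in self.ppi_inhibition):
            raise ValueError("ppi_inhibition fractions must lie in [0, 1]")
        if self.spontaneous_blink_rate_hz < 0 or self.noise_sd_px < 0:
            raise ValueError("rates and noise levels must be >= 0")

    def noiseless(self) -> "ParticipantModel":
        """Copy with every stochastic nuisance source switched off."""
        return replace(
            self,
            startle_latency_sd_ms=0.0,
            cr_timing_jitter_sd_ms=0.0,
            spontaneous_blink_amp_sd=0.0,
            noise_sd_px=0.0,
        )

    def inhibition_for(self, db: float) -> float:
        pairs = dict(self.ppi_inhibition)
        if db in pairs:
            return pairs[db]
        key = min(pairs, key=lambda k: abs(k - db))
        return pairs[key]

    def startle_amplitude(self, db: Optional[float]) -> float:
        if db is None:
            return 0.0
        return self.startle_gain_per_db * max(0.0, db - self.startle_threshold_db)


@dataclass
class TrialTruth:
    trial_index: int
    trial_type: str
    cr_emitted: bool = False
    cr_peak_time_ms: Optional[float] = None  # realized, relative to CS onset
    cr_amplitude: Optional[float] = None
    startles: list[dict] = field(default_factory=list)
    blink_times_ms: list[float] = field(default_factory=list)  # absolute


@dataclass
class GroundTruth:
    seed: int
    fs_hz: float
    trial_onsets_abs_ms: dict[int, float]  # trial index -> trial clock zero
    trials: list[TrialTruth]
    spontaneous: list[tuple[float, float]]  # (absolute peak time, amplitude)

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o

        return json.dumps(enc(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            seed=raw["seed"],
            fs_hz=raw["fs_hz"],
            trial_onsets_abs_ms={int(k): v for k, v in raw["trial_onsets_abs_ms"].items()},
            trials=[TrialTruth(**t) for t in raw["trials"]],
            spontaneous=[tuple(x) for x in raw["spontaneous"]],
        )


# ---------------------------------------------------------------------------


def render_landmarks(
    closure: np.ndarray,
    fs_hz: float = FS_HZ,
    template: Optional[np.ndarray] = None,
    eye: EyeLandmarkIndex = DEFAULT_EYE,
    noise_sd_px: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    t0_ms: float = 0.0,
) -> LandmarkStream:
    """Render a closure series to a landmark stream (inverse of extraction).

    Lid y-coordinates move linearly between the template's open and closed
    configurations (lids meet at closure = 1); the other 71 landmarks and the
    bounding box stay fixed. Extraction of the output recovers the input
    closure up to the affine ambiguity that normalization removes.
    """
    closure = np.asarray(closure, dtype=float)
    n = closure.shape[0]
    if template is None:
        template = face_template()
    pts = np.broadcast_to(template, (n, N_LANDMARKS, 2)).copy()
    for k in eye.upper_lid:
        pts[:, k, 1] = template[k, 1] + _LID_TRAVEL * closure
    for k in eye.lower_lid:
        pts[:, k, 1] = template[k, 1] - _LID_TRAVEL * closure
    bbox = np.tile(np.asarray(_BBOX), (n, 1))
    pts = pts + bbox[:, None, :2]  # template is bbox-relative
    if noise_sd_px > 0:
        if rng is None:
            rng = np.random.default_rng()
        pts = pts + rng.normal(0.0, noise_sd_px, size=pts.shape)
    t = t0_ms + np.arange(n) * (1000.0 / fs_hz)
    return LandmarkStream(t, pts, bbox)


def _add_kernel(
    closure: np.ndarray,
    fs_hz: float,
    onset_ms: float,
    amplitude: float,
    rise_ms: float,
    decay_ms: float,
) -> float:
    """Add a blink kernel with its onset snapped to the frame grid.

    Returns the snapped onset time. With the default 60 Hz grid and rise
    times that are whole numbers of frames, the kernel peak lands exactly on
    a sample, which is what makes zero-noise amplitude recovery exact.
    """
    dt = 1000.0 / fs_hz
    i0 = int(round(onset_ms / dt))
    n_sup = int(math.ceil((rise_ms + 5.0 * decay_ms) / dt)) + 1
    i1 = min(i0 + n_sup, closure.shape[0])
    if i1 <= max(i0, 0):
        return i0 * dt
    j0 = max(i0, 0)
    t_loc = (np.arange(j0, i1) - i0) * dt
    closure[j0:i1] += blink_kernel(t_loc, amplitude, rise_ms, decay_ms)
    return i0 * dt


def simulate_session(
    protocol: SessionProtocol,
    model: ParticipantModel = ParticipantModel(),
    history: int = 0,
    seed: int = 0,
    fs_hz: float = FS_HZ,
) -> tuple[LandmarkStream, GroundTruth]:
    """Simulate one session: landmark stream + ground truth.

    ``history`` is the number of paired CS-US trials the virtual participant
    experienced before this session; the CR learning curve continues from
    there. Identical ``(protocol, model, history, seed)`` produce an
    identical stream.
    """
    rng = np.random.default_rng(seed)
    dt = 1000.0 / fs_hz
    support = kernel_support_ms(model.blink_rise_ms, model.blink_decay_ms)

    # absolute trial clocks; spontaneous blinks may not *start* inside a
    # stimulus/analysis span, and (via the support margin applied at each
    # gap's right edge below) must have fully reopened before the next
    # stimulus — so they populate the pre-stimulus baselines but provably
    # never reach into a scoring window
    cursor = 500.0
    onsets_abs: dict[int, float] = {}
    windows: list[tuple[float, float]] = []  # spontaneous-blink exclusion
    for trial in protocol.trials:
        cursor += trial.iti_before_ms
        onsets_abs[trial.index] = cursor
        end = analysis_window_end_ms(protocol, trial.trial_type)
        # blinks may run until 50 ms past the first stimulus onset: every
        # scoring window starts at stimulus + 60 ms, so this is still safe
        windows.append(
            (
                cursor + trial.first_onset_ms + 50.0,
                cursor + trial.first_onset_ms + end + 50.0,
            )
        )
        cursor += trial.last_offset_ms
    total_ms = cursor + analysis_window_end_ms(
        protocol, protocol.trials[-1].trial_type if protocol.trials else "paired"
    ) + 1000.0
    n = int(math.ceil(total_ms / dt)) + 1
    closure = np.zeros(n)

    truths: list[TrialTruth] = []
    n_paired = history  # cumulative paired trials, for the learning curve
    n_paired_session = 0  # paired trials under this session's ISI

    def reflexive(stim_abs_ms: float, amplitude: float) -> tuple[float, float]:
        """Add a stimulus-evoked blink; returns (latency, amplitude)."""
        lat = model.startle_latency_ms + model.startle_latency_sd_ms * rng.standard_normal()
        lat = max(lat, model.blink_rise_ms + dt)
        onset = stim_abs_ms + lat - model.blink_rise_ms
        snapped = _add_kernel(
            closure, fs_hz, onset, amplitude,
            model.blink_rise_ms, model.blink_decay_ms,
        )
        peak_abs = snapped + model.blink_rise_ms
        return peak_abs - stim_abs_ms, amplitude

    for trial in protocol.trials:
        t0 = onsets_abs[trial.index]
        truth = TrialTruth(trial.index, trial.trial_type)

        if protocol.paradigm == "ebc":
            cs = next((e for e in trial.events if e.label == "CS"), None)
            us = next((e for e in trial.events if e.label == "US"), None)
            if cs is not None:
                p = model.cr_asymptote_prob * (
                    1.0 - math.exp(-model.cr_learning_rate * n_paired)
                )
                emit = rng.random() < p
                if emit:
                    isi_cur = (
                        us.onset_ms - cs.onset_ms
                        if us is not None
                        else protocol.params.isi_ms
                    )
                    if model.cr_prior_isi_ms is None:
                        isi_eff = isi_cur
                    else:  # timing re-adapts to a new ISI with learning dynamics
                        isi_eff = model.cr_prior_isi_ms + (
                            isi_cur - model.cr_prior_isi_ms
                        ) * (1.0 - math.exp(-model.cr_learning_rate * n_paired_session))
                    amp = model.cr_amplitude_asymptote * (
                        1.0 - math.exp(-model.cr_learning_rate * n_paired)
                    )
                    peak_rel = (
                        isi_eff
                        + model.cr_peak_offset_ms
                        + model.cr_timing_jitter_sd_ms * rng.standard_normal()
                    )
                    peak_rel = max(peak_rel, model.cr_rise_ms / 2.0)
                    snapped = _add_kernel(
                        closure, fs_hz,
                        t0 + cs.onset_ms + peak_rel - model.cr_rise_ms,
                        amp, model.cr_rise_ms, model.cr_decay_ms,
                    )
                    truth.cr_emitted = True
                    truth.cr_peak_time_ms = (
                        snapped + model.cr_rise_ms - (t0 + cs.onset_ms)
                    )
                    truth.cr_amplitude = amp
            if us is not None:
                lat, amp = reflexive(t0 + us.onset_ms, model.ur_amplitude)
                truth.startles.append(
                    {
                        "label": "US",
                        "position": 1,
                        "onset_rel_ms": us.onset_ms,
                        "latency_ms": lat,
                        "amplitude": amp,
                    }
                )
            if trial.trial_type == "paired":
                n_paired += 1
                n_paired_session += 1

        elif protocol.paradigm == "ppi":
            prepulse = next(
                (e for e in trial.events if e.label == "prepulse"), None
            )
            inhibition = 0.0
            if prepulse is not None:
                inhibition = model.inhibition_for(prepulse.intensity_db)
                pp_amp = model.startle_amplitude(prepulse.intensity_db)
                if pp_amp > 0:
                    lat, amp = reflexive(t0 + prepulse.onset_ms, pp_amp)
                    truth.startles.append(
                        {
                            "label": "prepulse",
                            "position": 0,
                            "onset_rel_ms": prepulse.onset_ms,
                            "latency_ms": lat,
                            "amplitude": amp,
                        }
                    )
            for e in trial.events:
                if e.label != "pulse":
                    continue
                amp = model.startle_amplitude(e.intensity_db) * (1.0 - inhibition)
                if amp <= 0:
                    continue
                lat, amp = reflexive(t0 + e.onset_ms, amp)
                truth.startles.append(
                    {
                        "label": "pulse",
                        "position": 1,
                        "onset_rel_ms": e.onset_ms,
                        "latency_ms": lat,
                        "amplitude": amp,
                    }
                )

        elif protocol.paradigm == "hab":
            pulses = [e for e in trial.events if e.label == "pulse"]
            for k, e in enumerate(pulses):
                amp = model.startle_amplitude(e.intensity_db) * (
                    model.habituation_factor**k
                )
                if amp <= 0:
                    continue
                lat, amp = reflexive(t0 + e.onset_ms, amp)
                truth.startles.append(
                    {
                        "label": "pulse",
                        "position": k + 1,
                        "onset_rel_ms": e.onset_ms,
                        "latency_ms": lat,
                        "amplitude": amp,
                    }
                )
        truths.append(truth)

    # spontaneous blinks: Poisson process outside the stimulus/response zones
    spont: list[tuple[float, float]] = []
    if model.spontaneous_blink_rate_hz > 0:
        edges = [0.0]
        for lo, hi in sorted(windows):
            edges.extend((lo, hi))
        edges.append(total_ms - support)
        for lo, hi in zip(edges[0::2], edges[1::2]):
            hi = hi - support
            if hi <= lo:
                continue
            k = rng.poisson(model.spontaneous_blink_rate_hz * (hi - lo) / 1000.0)
            for t_on in np.sort(rng.uniform(lo, hi, size=k)):
                amp = 1.0 + model.spontaneous_blink_amp_sd * rng.standard_normal()
                amp = max(amp, 0.2)
                snapped = _add_kernel(
                    closure, fs_hz, float(t_on), amp,
                    model.blink_rise_ms, model.blink_decay_ms,
                )
                spont.append((snapped + model.blink_rise_ms, amp))
        # attribute baseline-window blinks to their trial's truth record
        for peak, _ in spont:
            for trial in protocol.trials:
                ref = onsets_abs[trial.index] + trial.first_onset_ms
                if ref - BASELINE_MS <= peak < ref:
                    truths[trial.index].blink_times_ms.append(peak)

    stream = render_landmarks(
        closure,
        fs_hz=fs_hz,
        noise_sd_px=model.noise_sd_px,
        rng=rng,
    )
    gt = GroundTruth(
        seed=seed,
        fs_hz=fs_hz,
        trial_onsets_abs_ms=onsets_abs,
        trials=truths,
        spontaneous=spont,
    )
    return stream, gt
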