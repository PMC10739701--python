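"""Stimulus-schedule generation for the three paradigms.

Three trial-based paradigms are supported:

* delay eyeblink conditioning (EBC): a visual conditioned stimulus (CS, a dot
  on the screen) overlapping and co-terminating with a loud white-noise +
  screen-flash unconditioned stimulus (US);
* prepulse inhibition of acoustic startle (PPI): a 105 dB startle pulse,
  optionally preceded 120 ms earlier by a weaker prepulse;
* startle habituation: trains of five 105 dB pulses at a fixed 750 ms
  onset-to-onset interval.

All schedules are millisecond-resolved, seeded, and fully deterministic:
identical ``(params, seed)`` produce byte-identical serialized sessions.
Times inside a trial are relative to the trial's clock zero (the first
stimulus onset is at 0 by construction); the inter-trial interval is attached
to the trial it precedes (``iti_before_ms``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "StimulusEvent",
    "TrialSpec",
    "EbcParams",
    "PpiParams",
    "HabParams",
    "SessionProtocol",
    "build_ebc_session",
    "build_ppi_session",
    "build_habituation_session",
    "validate_session",
    "session_to_json",
    "session_from_json",
]

_MODALITIES = ("auditory", "visual", "composite")
_DB_RANGE = (40.0, 120.0)

# canonical trial-type tags for the four default prepulse intensities,
# expressed as the conventional percent-of-startle labels
_PREPULSE_PCT_TAGS = (5, 10, 25, 50)


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus within a trial, timed relative to the trial clock zero."""

    label: str  # CS | US | pulse | prepulse
    modality: str  # auditory | visual | composite
    onset_ms: float
    duration_ms: float
    intensity_db: Optional[float] = None  # auditory/composite only

    def __post_init__(self) -> None:
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be > 0")
        if self.onset_ms < 0:
            raise ValueError("onset_ms must be >= 0")
        if self.intensity_db is not None and not (
            _DB_RANGE[0] <= self.intensity_db <= _DB_RANGE[1]
        ):
            raise ValueError(
                f"intensity_db {self.intensity_db} outside {_DB_RANGE}"
            )

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass(frozen=True)
class TrialSpec:
    index: int
    trial_type: str
    events: tuple[StimulusEvent, ...]
    iti_before_ms: float
    block_index: int

    @property
    def first_onset_ms(self) -> float:
        return min(e.onset_ms for e in self.events) if self.events else 0.0

    @property
    def last_offset_ms(self) -> float:
        return max(e.offset_ms for e in self.events) if self.events else 0.0


@dataclass(frozen=True)
class EbcParams:
    """Eyeblink-conditioning session parameters (delay paradigm).

    ``isi_ms`` is the CS-onset-to-US-onset interval; delay trials co-terminate,
    so ``cs_duration_ms == isi_ms + us_duration_ms``.
    """

    cs_duration_ms: float = 450.0
    probe_cs_duration_ms: float = 100.0
    long_cs_duration_ms: float = 750.0
    us_duration_ms: float = 50.0
    us_db: float = 105.0
    isi_ms: float = 400.0
    long_isi_ms: float = 700.0
    iti_range_ms: tuple[float, float] = (7000.0, 20000.0)
    n_blocks: int = 5
    per_block: tuple[tuple[str, int], ...] = (
        ("cs_only", 1),
        ("us_only", 1),
        ("paired", 8),
    )

    def __post_init__(self) -> None:
        if self.isi_ms + self.us_duration_ms != self.cs_duration_ms:
            raise ValueError(
                "delay-trial identity violated: isi + us_duration != cs_duration"
            )
        if self.long_isi_ms + self.us_duration_ms != self.long_cs_duration_ms:
            raise ValueError(
                "delay-trial identity violated for the long-ISI regime"
            )
        if any(n <= 0 for _, n in self.per_block):
            raise ValueError("per-block trial counts must be positive")
        if self.iti_range_ms[0] > self.iti_range_ms[1]:
            raise ValueError("iti_range_ms must be (low, high)")


@dataclass(frozen=True)
class PpiParams:
    pulse_db: float = 105.0
    pulse_duration_ms: float = 50.0
    prepulse_duration_ms: float = 50.0
    prepulse_dbs: tuple[float, ...] = (65.0, 75.0, 83.0, 93.0)
    prepulse_lead_ms: float = 120.0
    n_habituation: int = 5
    n_blocks: int = 10
    iti_range_ms: tuple[float, float] = (10000.0, 25000.0)

    def __post_init__(self) -> None:
        dbs = self.prepulse_dbs
        if any(b >= self.pulse_db for b in dbs):
            raise ValueError("every prepulse intensity must be below the pulse")
        if any(b2 <= b1 for b1, b2 in zip(dbs, dbs[1:])):
            raise ValueError("prepulse_dbs must be strictly increasing")
        if self.prepulse_lead_ms <= 0:
            raise ValueError("prepulse_lead_ms must be > 0")


@dataclass(frozen=True)
class HabParams:
    n_trials: int = 10
    pulses_per_train: int = 5
    pulse_db: float = 105.0
    pulse_duration_ms: float = 50.0
    inter_onset_ms: float = 750.0
    iti_range_ms: tuple[float, float] = (20000.0, 40000.0)

    def __post_init__(self) -> None:
        if self.pulses_per_train < 2:
            raise ValueError("pulses_per_train must be >= 2")
        if self.inter_onset_ms <= self.pulse_duration_ms:
            raise ValueError("inter_onset_ms must exceed pulse_duration_ms")


Params = Union[EbcParams, PpiParams, HabParams]


@dataclass(frozen=True)
class SessionProtocol:
    paradigm: str  # ebc | ppi | hab
    session_index: int
    trials: tuple[TrialSpec, ...]
    seed: int
    params: Params

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _draw_iti(rng: np.random.Generator, lo: float, hi: float) -> float:
    # uniform-continuous over the stated range, rounded to 1 ms
    return float(round(rng.uniform(lo, hi)))


def prepulse_trial_type(params: PpiParams, db: float) -> str:
    """Trial-type tag for a prepulse intensity.

    The four default intensities carry the conventional percent-of-startle
    labels (5/10/25/50); any other configuration is tagged by its dB value.
    """
    dbs = params.prepulse_dbs
    if len(dbs) == len(_PREPULSE_PCT_TAGS):
        return f"prepulse_pulse_{_PREPULSE_PCT_TAGS[dbs.index(db)]}"
    return f"prepulse_pulse_{db:g}db"


def _ebc_events(
    trial_type: str, params: EbcParams, session_index: int
) -> tuple[StimulusEvent, ...]:
    long_regime = session_index >= 8
    isi = params.long_isi_ms if long_regime else params.isi_ms
    cs_dur = params.long_cs_duration_ms if long_regime else params.cs_duration_ms
    us = StimulusEvent(
        "US", "composite", isi, params.us_duration_ms, params.us_db
    )
    if trial_type == "us_only":
        return (
            StimulusEvent(
                "US", "composite", 0.0, params.us_duration_ms, params.us_db
            ),
        )
    if trial_type == "cs_only":
        # session 7: the short probe CS, never reinforced
        dur = params.probe_cs_duration_ms if session_index == 7 else cs_dur
        return (StimulusEvent("CS", "visual", 0.0, dur),)
    if trial_type == "paired":
        return (StimulusEvent("CS", "visual", 0.0, cs_dur), us)
    raise ValueError(f"unknown EBC trial type {trial_type!r}")


def build_ebc_session(
    session_index: int, params: EbcParams = EbcParams(), seed: int = 0
) -> SessionProtocol:
    """Build one eyeblink-conditioning session (sessions 0-9).

    Sessions 0-6 use the 450 ms CS / 400 ms ISI; session 7 is identical except
    that CS-only trials carry the 100 ms probe CS; sessions 8-9 use the 750 ms
    CS / 700 ms ISI. Each block holds the configured trial mix (default
    1 CS-only + 1 US-only + 8 paired), placed by a seeded permutation; ITIs
    are drawn uniformly from ``iti_range_ms``.
    """
    if not 0 <= session_index <= 9:
        raise ValueError("session_index must be in 0..9")
    rng = np.random.default_rng(seed)
    # record the resolved timing regime on the params carried by the session
    if session_index >= 8:
        params = replace(
            params,
            isi_ms=params.long_isi_ms,
            cs_duration_ms=params.long_cs_duration_ms,
        )
    trials: list[TrialSpec] = []
    for block in range(params.n_blocks):
        block_types = [t for t, n in params.per_block for _ in range(n)]
        order = rng.permutation(len(block_types))
        for k in order:
            ttype = block_types[k]
            trials.append(
                TrialSpec(
                    index=len(trials),
                    trial_type=ttype,
                    events=_ebc_events(ttype, params, session_index),
                    iti_before_ms=_draw_iti(rng, *params.iti_range_ms),
                    block_index=block,
                )
            )
    return SessionProtocol("ebc", session_index, tuple(trials), seed, params)


def build_ppi_session(
    params: PpiParams = PpiParams(), seed: int = 0, session_index: int = 0
) -> SessionProtocol:
    """Build one prepulse-inhibition session.

    Five habituation trials (soft bursts, letting the participant settle)
    precede ``n_blocks`` blocks each holding one pulse-only trial plus one
    trial per prepulse intensity, seeded-permuted within the block. In every
    prepulse trial the prepulse leads the pulse by ``prepulse_lead_ms``.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    for k in range(params.n_habituation):
        # soft bursts of various intensities: cycle through the prepulse levels
        db = params.prepulse_dbs[k % len(params.prepulse_dbs)]
        trials.append(
            TrialSpec(
                index=len(trials),
                trial_type="ppi_habituation",
                events=(
                    StimulusEvent(
                        "pulse", "auditory", 0.0, params.pulse_duration_ms, db
                    ),
                ),
                iti_before_ms=_draw_iti(rng, *params.iti_range_ms),
                block_index=-1,
            )
        )
    for block in range(params.n_blocks):
        block_dbs: list[Optional[float]] = [None] + list(params.prepulse_dbs)
        order = rng.permutation(len(block_dbs))
        for k in order:
            db = block_dbs[k]
            if db is None:
                ttype = "pulse_only"
                events = (
                    StimulusEvent(
                        "pulse",
                        "auditory",
                        0.0,
                        params.pulse_duration_ms,
                        params.pulse_db,
                    ),
                )
            else:
                ttype = prepulse_trial_type(params, db)
                events = (
                    StimulusEvent(
                        "prepulse",
                        "auditory",
                        0.0,
                        params.prepulse_duration_ms,
                        db,
                    ),
                    StimulusEvent(
                        "pulse",
                        "auditory",
                        params.prepulse_lead_ms,
                        params.pulse_duration_ms,
                        params.pulse_db,
                    ),
                )
            trials.append(
                TrialSpec(
                    index=len(trials),
                    trial_type=ttype,
                    events=events,
                    iti_before_ms=_draw_iti(rng, *params.iti_range_ms),
                    block_index=block,
                )
            )
    return SessionProtocol("ppi", session_index, tuple(trials), seed, params)


def build_habituation_session(
    params: HabParams = HabParams(), seed: int = 0, session_index: int = 0
) -> SessionProtocol:
    """Build one startle-habituation session of fixed-interval pulse trains."""
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    for k in range(params.n_trials):
        events = tuple(
            StimulusEvent(
                "pulse",
                "auditory",
                j * params.inter_onset_ms,
                params.pulse_duration_ms,
                params.pulse_db,
            )
            for j in range(params.pulses_per_train)
        )
        trials.append(
            TrialSpec(
                index=k,
                trial_type="pulse_train",
                events=events,
                iti_before_ms=_draw_iti(rng, *params.iti_range_ms),
                block_index=0,
            )
        )
    return SessionProtocol("hab", session_index, tuple(trials), seed, params)


# ---------------------------------------------------------------------------
# validation


def _check_composition(protocol: SessionProtocol) -> list[str]:
    out: list[str] = []
    p = protocol.params
    from collections import Counter

    counts = Counter(t.trial_type for t in protocol.trials)
    if protocol.paradigm == "ebc":
        expected = {t: n * p.n_blocks for t, n in p.per_block}
    elif protocol.paradigm == "ppi":
        expected = {"pulse_only": p.n_blocks}
        for db in p.prepulse_dbs:
            expected[prepulse_trial_type(p, db)] = p.n_blocks
        if p.n_habituation:
            expected["ppi_habituation"] = p.n_habituation
    else:
        expected = {"pulse_train": p.n_trials}
    if dict(counts) != {k: v for k, v in expected.items() if v}:
        out.append(
            f"session: trial-type composition {dict(counts)} != expected {expected}"
        )
    return out


def validate_session(protocol: SessionProtocol) -> list[str]:
    """Check every schedule invariant; violations are returned, not raised.

    Each violation string names the trial index (or 'session') and the rule.
    """
    out: list[str] = []
    p = protocol.params
    lo, hi = p.iti_range_ms
    for i, trial in enumerate(protocol.trials):
        if trial.index != i:
            out.append(f"trial {trial.index}: indices not contiguous from 0")
        if not lo <= trial.iti_before_ms <= hi:
            out.append(
                f"trial {trial.index}: iti_before_ms {trial.iti_before_ms} "
                f"outside iti_range_ms [{lo}, {hi}]"
            )
        labels = {}
        for e in trial.events:
            if e.duration_ms <= 0 or e.onset_ms < 0:
                out.append(f"trial {trial.index}: malformed event {e.label}")
            labels.setdefault((e.label, e.modality), []).append(e)
        if trial.trial_type == "paired":
            cs = next((e for e in trial.events if e.label == "CS"), None)
            us = next((e for e in trial.events if e.label == "US"), None)
            if cs is None or us is None:
                out.append(f"trial {trial.index}: paired trial missing CS or US")
            elif abs(cs.offset_ms - us.offset_ms) > 1e-9:
                out.append(
                    f"trial {trial.index}: CS and US must co-terminate "
                    f"(CS offset {cs.offset_ms}, US offset {us.offset_ms})"
                )
        if trial.trial_type.startswith("prepulse_pulse"):
            pp = next((e for e in trial.events if e.label == "prepulse"), None)
            pu = next((e for e in trial.events if e.label == "pulse"), None)
            if pp is None or pu is None:
                out.append(f"trial {trial.index}: prepulse trial missing event")
            else:
                if abs((pu.onset_ms - pp.onset_ms) - p.prepulse_lead_ms) > 1e-9:
                    out.append(
                        f"trial {trial.index}: prepulse lead "
                        f"{pu.onset_ms - pp.onset_ms} != {p.prepulse_lead_ms}"
                    )
                if pp.intensity_db is not None and pp.intensity_db >= pu.intensity_db:
                    out.append(
                        f"trial {trial.index}: prepulse not softer than pulse"
                    )
        if trial.trial_type == "pulse_train":
            onsets = [e.onset_ms for e in trial.events]
            gaps = np.diff(onsets)
            if len(onsets) != p.pulses_per_train:
                out.append(
                    f"trial {trial.index}: {len(onsets)} pulses != "
                    f"{p.pulses_per_train}"
                )
            if gaps.size and not np.allclose(gaps, p.inter_onset_ms):
                out.append(
                    f"trial {trial.index}: pulse spacing {gaps.tolist()} != "
                    f"{p.inter_onset_ms} ms"
                )
    out.extend(_check_composition(protocol))
    return out


# ---------------------------------------------------------------------------
# JSON round trip

_PARAM_TYPES = {"ebc": EbcParams, "ppi": PpiParams, "hab": HabParams}


def session_to_json(protocol: SessionProtocol) -> str:
    def as_dict(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {
                f.name: as_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            }
        if isinstance(obj, (tuple, list)):
            return [as_dict(x) for x in obj]
        return obj

    return json.dumps(as_dict(protocol), indent=None, sort_keys=True)


def session_from_json(text: str) -> SessionProtocol:
    raw = json.loads(text)
    ptype = _PARAM_TYPES[raw["paradigm"]]

    def tup(x):
        return tuple(tuple(v) if isinstance(v, list) else v for v in x)

    params_raw = dict(raw["params"])
    for k, v in params_raw.items():
        if isinstance(v, list):
            params_raw[k] = tup(v)
    params = ptype(**params_raw)
    trials = tuple(
        TrialSpec(
            index=t["index"],
            trial_type=t["trial_type"],
            events=tuple(StimulusEvent(**e) for e in t["events"]),
            iti_before_ms=t["iti_before_ms"],
            block_index=t["block_index"],
        )
        for t in raw["trials"]
    )
    return SessionProtocol(
        raw["paradigm"], raw["session_index"], trials, raw["seed"], params
    )
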