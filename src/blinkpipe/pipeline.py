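"""Configuration and the end-to-end pipeline.

``process_stream`` composes the library stages (extract -> [resample] ->
filter -> segment -> detect spontaneous blinks -> normalize -> score) on one
session; ``run_pipeline`` drives it from a validated :class:`RunConfig`,
optionally simulating the input, and writes every artifact together with a
manifest (inputs, seed, version, effective parameters including the clamped
filter cutoff) sufficient to regenerate it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .io import (
    read_landmark_stream,
    write_landmark_stream,
    write_protocol,
    write_trace,
)
from .metrics import ScoringParams, SessionSummary, score_session
from .protocol import (
    EbcParams,
    HabParams,
    PpiParams,
    SessionProtocol,
    build_ebc_session,
    build_habituation_session,
    build_ppi_session,
    validate_session,
)
from .signal import (
    BASELINE_MS,
    BlinkEvent,
    EyelidTrace,
    EyeLandmarkIndex,
    LandmarkStream,
    NormalizationInfo,
    TrialSegment,
    compute_eyelid_openness,
    detect_spontaneous_blinks,
    effective_cutoff_hz,
    filter_trace,
    normalize_session,
    resample_uniform,
    segment_trials,
)
from .simulate import DEFAULT_EYE, ParticipantModel, simulate_session
from .stats import export_tidy

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "process_stream",
           "run_pipeline", "build_protocol"]

log = logging.getLogger("blinkpipe")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    paradigm: Literal["ebc", "ppi", "hab"] = "ebc"
    sessions: list[int] = Field(default_factory=lambda: [1])
    seed: int = 0
    subject_id: str = "sim"
    out_dir: Path = Path("blinkpipe_out")
    simulate: bool = True
    input_path: Optional[Path] = None  # landmark stream when simulate=False
    onsets_path: Optional[Path] = None  # JSON trial index -> absolute ms
    params: dict = Field(default_factory=dict)  # paradigm param overrides
    scoring: dict = Field(default_factory=dict)
    model: dict = Field(default_factory=dict)  # simulator overrides
    eye: Optional[dict] = None  # eye landmark index map
    apply_filter: bool = True
    filter_cutoff_hz: float = 50.0
    filter_order: int = 2
    bluetooth_offset_ms: float = 0.0
    write_landmarks: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text)
            if path.suffix == ".json"
            else yaml.safe_load(text)
        )
        return cls(**(data or {}))

    def eye_index(self) -> EyeLandmarkIndex:
        if self.eye is None:
            return DEFAULT_EYE
        return EyeLandmarkIndex(
            upper_lid=tuple(self.eye["upper_lid"]),
            lower_lid=tuple(self.eye["lower_lid"]),
            corners=tuple(self.eye["corners"]),
        )

    def scoring_params(self) -> ScoringParams:
        d = dict(self.scoring)
        for k in ("startle_window_ms", "prepulse_window_ms"):
            if k in d:
                d[k] = tuple(d[k])
        return ScoringParams(**d)

    def participant_model(self) -> ParticipantModel:
        d = dict(self.model)
        if "ppi_inhibition" in d:
            d["ppi_inhibition"] = tuple(
                (float(k), float(v)) for k, v in dict(d["ppi_inhibition"]).items()
            )
        return ParticipantModel(**d)


def build_protocol(
    paradigm: str, session_index: int, seed: int, overrides: Mapping = ()
) -> SessionProtocol:
    overrides = dict(overrides)
    for k, v in overrides.items():
        if isinstance(v, list):
            overrides[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
    if paradigm == "ebc":
        return build_ebc_session(session_index, EbcParams(**overrides), seed)
    if paradigm == "ppi":
        return build_ppi_session(PpiParams(**overrides), seed, session_index)
    if paradigm == "hab":
        return build_habituation_session(HabParams(**overrides), seed, session_index)
    raise PipelineError("config", f"unknown paradigm {paradigm!r}")


@dataclass
class PipelineResult:
    protocol: SessionProtocol
    trace: EyelidTrace  # session trace at the stage fed to segmentation
    segments: list[TrialSegment]  # normalized
    blinks: list[BlinkEvent]
    norm_info: NormalizationInfo
    metrics: list
    summary: SessionSummary


def process_stream(
    stream: LandmarkStream,
    protocol: SessionProtocol,
    absolute_onsets: Mapping[int, float],
    eye: EyeLandmarkIndex = DEFAULT_EYE,
    scoring: ScoringParams = ScoringParams(),
    apply_filter: bool = True,
    filter_cutoff_hz: float = 50.0,
    filter_order: int = 2,
    bluetooth_offset_ms: float = 0.0,
) -> PipelineResult:
    """Run extraction through scoring on one session's landmark stream."""
    try:
        trace = compute_eyelid_openness(stream, eye)
    except ValueError as exc:
        raise PipelineError("extract", str(exc)) from exc
    if not trace.is_uniform():
        trace = resample_uniform(trace, trace.fs_hz)
    if apply_filter:
        try:
            trace = filter_trace(trace, filter_cutoff_hz, filter_order)
        except ValueError as exc:
            raise PipelineError("filter", str(exc)) from exc
    segments = segment_trials(
        trace, protocol, absolute_onsets, stimulus_offset_ms=bluetooth_offset_ms
    )
    windows = [
        (s.onset_abs_ms - BASELINE_MS, s.onset_abs_ms)
        for s in segments
        if not s.missing
    ]
    blinks = detect_spontaneous_blinks(trace, windows)
    try:
        normalized, info = normalize_session(segments, blinks)
    except ValueError as exc:
        raise PipelineError("normalize", str(exc)) from exc
    try:
        metrics, summary = score_session(normalized, protocol, scoring)
    except ValueError as exc:
        raise PipelineError("score", str(exc)) from exc
    return PipelineResult(
        protocol, trace, normalized, blinks, info, metrics, summary
    )


def _summary_row(subject: str, s: SessionSummary) -> dict:
    row = {"subject": subject}
    for f in dataclasses.fields(s):
        v = getattr(s, f.name)
        row[f.name] = json.dumps(v) if isinstance(v, dict) else v
    return row


def run_pipeline(config: RunConfig) -> list[SessionSummary]:
    """Execute the configured run and write all exports plus a manifest."""
    import pandas as pd

    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scoring = config.scoring_params()
    eye = config.eye_index()
    summaries: list[SessionSummary] = []
    summary_rows = []
    effective: dict = {}

    for session in config.sessions:
        seed = config.seed + session
        protocol = build_protocol(config.paradigm, session, seed, config.params)
        bad = validate_session(protocol)
        if bad:
            raise PipelineError("protocol", "; ".join(bad))
        if config.simulate:
            model = config.participant_model()
            history = (
                sum(n for t, n in protocol.params.per_block if t == "paired")
                * protocol.params.n_blocks
                * max(0, session - 1)
                if config.paradigm == "ebc"
                else 0
            )
            stream, gt = simulate_session(protocol, model, history, seed)
            onsets = gt.trial_onsets_abs_ms
            (out / f"{config.subject_id}_{config.paradigm}_s{session}_truth.json").write_text(
                gt.to_json()
            )
            if config.write_landmarks:
                write_landmark_stream(
                    stream,
                    out / f"{config.subject_id}_{config.paradigm}_s{session}_landmarks.csv",
                )
        else:
            if config.input_path is None or config.onsets_path is None:
                raise PipelineError(
                    "config", "simulate=false requires input_path and onsets_path"
                )
            try:
                stream = read_landmark_stream(config.input_path)
            except (OSError, ValueError) as exc:
                raise PipelineError("extract", str(exc)) from exc
            onsets = {
                int(k): float(v)
                for k, v in json.loads(Path(config.onsets_path).read_text()).items()
            }
        result = process_stream(
            stream,
            protocol,
            onsets,
            eye=eye,
            scoring=scoring,
            apply_filter=config.apply_filter,
            filter_cutoff_hz=config.filter_cutoff_hz,
            filter_order=config.filter_order,
            bluetooth_offset_ms=config.bluetooth_offset_ms,
        )
        tag = f"{config.subject_id}_{config.paradigm}_s{session}"
        write_protocol(protocol, out / f"{tag}_protocol.json")
        write_trace(result.trace, out / f"{tag}_trace.csv")
        export_tidy(
            result.metrics, config.subject_id, session, out / f"{tag}_trials.csv"
        )
        summaries.append(result.summary)
        summary_rows.append(_summary_row(config.subject_id, result.summary))
        effective[f"session_{session}"] = {
            "seed": seed,
            "n_trials": protocol.n_trials,
            "blink_reference": result.norm_info.blink_reference_amplitude,
            "normalization_fallback": result.norm_info.fallback_used,
        }
        log.info("session %s scored: %s", session, result.summary)

    pd.DataFrame(summary_rows).to_csv(
        out / f"{config.subject_id}_{config.paradigm}_summary.csv", index=False
    )
    manifest = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "effective": {
            "filter_cutoff_hz_configured": config.filter_cutoff_hz,
            "filter_cutoff_hz_applied": effective_cutoff_hz(
                config.filter_cutoff_hz, 60.0
            ),
            "scoring": dataclasses.asdict(scoring),
            "sessions": effective,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return summaries
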