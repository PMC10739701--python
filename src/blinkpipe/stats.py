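"""Group-level aggregation: learning curves, 95% CIs, tidy exports.

Group means are means of subject-level values (each subject contributes one
value per session), with a t-distribution 95% confidence interval on the
between-subject standard deviation. Model fitting (e.g. a mixed model with
session as fixed and subject as random effect) is downstream of this package;
``export_tidy`` writes the long-format per-trial table such a model consumes.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .metrics import CRMetrics, SessionSummary, StartleMetrics

__all__ = [
    "extract_outcome",
    "summaries_to_frame",
    "learning_curve_table",
    "export_tidy",
    "read_tidy",
]


def extract_outcome(summary: SessionSummary, outcome: str) -> Optional[float]:
    """Read a scalar outcome off a summary.

    ``outcome`` is a field name, optionally with a dict key appended after a
    colon, e.g. ``"cr_percentage"`` or ``"ppi_percent_per_level:prepulse_pulse_50"``
    or ``"per_pulse_amplitudes:1"``.
    """
    field, _, key = outcome.partition(":")
    value = getattr(summary, field)
    if key and value is not None:
        try:
            return value[key]
        except KeyError:
            return value[int(key)]
    return value


def summaries_to_frame(
    summaries: dict[str, Sequence[SessionSummary]], outcomes: Sequence[str]
) -> pd.DataFrame:
    """Tidy frame with one row per subject x session, one column per outcome."""
    rows = []
    for subject, seq in summaries.items():
        for s in seq:
            row = {"subject": subject, "session_index": s.session_index}
            for o in outcomes:
                row[o] = extract_outcome(s, o)
            rows.append(row)
    return pd.DataFrame(rows)


def learning_curve_table(
    summaries: dict[str, Sequence[SessionSummary]] | pd.DataFrame,
    outcome: str,
) -> pd.DataFrame:
    """Per-session group mean and 95% CI of one outcome across subjects.

    A session observed in a single subject yields a degenerate CI equal to
    the mean and is flagged in the ``degenerate`` column.
    """
    if isinstance(summaries, dict):
        df = summaries_to_frame(summaries, [outcome])
    else:
        df = summaries
    if df.empty:
        raise ValueError("no summaries to aggregate")
    rows = []
    for session, grp in df.groupby("session_index"):
        vals = grp[outcome].dropna().to_numpy(dtype=float)
        n = vals.size
        if n == 0:
            continue
        mean = float(vals.mean())
        if n > 1:
            half = float(
                _stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
            )
        else:
            half = 0.0
        rows.append(
            {
                "session_index": session,
                "n_subjects": n,
                "group_mean": mean,
                "ci95_low": mean - half,
                "ci95_high": mean + half,
                "degenerate": n == 1,
            }
        )
    return pd.DataFrame(rows).sort_values("session_index", ignore_index=True)


_EXPORT_ORDER = [
    "subject",
    "session_index",
    "trial_index",
    "trial_type",
    "pulse_position",
    "cr_amplitude",
    "is_cr",
    "latency_onset_ms",
    "latency_peak_ms",
    "peak_amplitude",
    "peak_time_ms",
    "significant",
    "amplitude_at_mean_peak",
    "prepulse_response_amplitude",
    "missing",
]


def export_tidy(
    metrics: Sequence[CRMetrics | StartleMetrics],
    subject: str,
    session_index: int,
    path=None,
) -> pd.DataFrame:
    """One row per scored trial (or per pulse of a train), mixed-model-ready.

    Missing trials appear as rows with NA markers rather than being dropped,
    so the table is complete with respect to the protocol.
    """
    rows = []
    for m in metrics:
        d = {
            f.name: getattr(m, f.name)
            for f in dataclasses.fields(m)
            if f.name != "segment"
        }
        d.pop("window_ms", None)
        d.pop("pulse_onset_ms", None)
        d["subject"] = subject
        d["session_index"] = session_index
        rows.append(d)
    df = pd.DataFrame(rows)
    cols = [c for c in _EXPORT_ORDER if c in df.columns] + [
        c for c in df.columns if c not in _EXPORT_ORDER
    ]
    df = df[cols]
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_tidy(path) -> pd.DataFrame:
    return pd.read_csv(path)
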