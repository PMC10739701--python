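import numpy as np
import pytest

from blinkpipe.signal import TrialSegment


@pytest.fixture
def make_segment():
    """Build a synthetic normalized trial segment on a 1 ms grid."""

    def _make(
        trial_type="cs_only",
        onsets=None,
        t_start=-500.0,
        t_end=1000.0,
        closure=None,
        peaks=(),
        trial_index=0,
        onset_abs_ms=10_000.0,
    ):
        t = np.arange(t_start, t_end + 0.5, 1.0)
        c = np.zeros_like(t) if closure is None else np.asarray(closure, float)
        for when, amp, half_width in peaks:
            c = c + amp * np.exp(-0.5 * ((t - when) / half_width) ** 2)
        if onsets is None:
            onsets = {"CS": (0.0,)}
        return TrialSegment(
            trial_index=trial_index,
            trial_type=trial_type,
            t_ms=t,
            closure=c,
            stimulus_onsets={k: tuple(v) for k, v in onsets.items()},
            onset_abs_ms=onset_abs_ms,
            stage="normalized",
        )

    return _make
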