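"""Trial scoring rules and session summaries on constructed traces."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blinkpipe.metrics import (
    CRMetrics,
    ScoringParams,
    habituation_summary,
    ppi_percent,
    ppi_session_summary,
    score_cr,
    score_startle,
    score_train,
    summarize_cr_session,
)
from blinkpipe.protocol import build_ebc_session

P = ScoringParams()


class TestScoreCR:
    def test_clear_cr_in_window(self, make_segment):
        seg = make_segment("cs_only", peaks=[(390.0, 0.35, 40.0)])
        m = score_cr(seg, isi_ms=400.0)
        assert m.is_cr
        assert m.cr_amplitude == pytest.approx(0.35, abs=1e-3)
        assert m.latency_peak_ms == pytest.approx(390.0, abs=1.0)
        assert m.window_ms == (60.0, 450.0)

    def test_subthreshold_movement_is_not_a_cr(self, make_segment):
        seg = make_segment("cs_only", peaks=[(300.0, 0.10, 40.0)])
        m = score_cr(seg, isi_ms=400.0)
        assert not m.is_cr
        assert m.cr_amplitude == pytest.approx(0.10, abs=1e-3)

    def test_alpha_response_before_window_excluded(self, make_segment):
        # a large reflexive deflection peaking 30 ms after CS onset that has
        # decayed by 60 ms must not count, however big its peak
        seg = make_segment("cs_only", peaks=[(30.0, 0.5, 10.0)])
        m = score_cr(seg, isi_ms=400.0)
        assert not m.is_cr
        assert m.cr_amplitude < 0.05

    def test_paired_window_ends_at_us_onset(self, make_segment):
        seg = make_segment(
            "paired",
            onsets={"CS": (0.0,), "US": (400.0,)},
            peaks=[(500.0, 0.9, 30.0)],  # the UR, after the US: out of window
        )
        m = score_cr(seg, isi_ms=400.0)
        assert m.window_ms == (60.0, 400.0)
        assert m.latency_peak_ms is None  # peak latency is CS-only-only
        assert m.cr_amplitude < 0.9

    def test_onset_latency_from_sustained_crossing(self, make_segment):
        t = np.arange(-500.0, 1001.0)
        c = np.where(t >= 200.0, 0.4, 0.0)
        seg = make_segment("cs_only", closure=c, t_start=-500, t_end=1000)
        m = score_cr(seg, isi_ms=400.0)
        assert m.latency_onset_ms == pytest.approx(200.0, abs=2.0)

    def test_translation_equivariance(self, make_segment):
        seg1 = make_segment("cs_only", peaks=[(390.0, 0.35, 40.0)])
        seg2 = dataclasses.replace(
            seg1,
            t_ms=seg1.t_ms + 250.0,
            stimulus_onsets={"CS": (250.0,)},
        )
        m1, m2 = score_cr(seg1, 400.0), score_cr(seg2, 400.0)
        assert m1.is_cr == m2.is_cr
        assert m1.cr_amplitude == pytest.approx(m2.cr_amplitude, abs=1e-12)
        assert m1.latency_peak_ms == pytest.approx(m2.latency_peak_ms, abs=1e-9)

    def test_wrong_trial_type_rejected(self, make_segment):
        seg = make_segment("us_only", onsets={"US": (0.0,)})
        with pytest.raises(ValueError):
            score_cr(seg, 400.0)


class TestSummarizeCR:
    def _metrics(self, n, n_cr):
        out = []
        for i in range(n):
            out.append(
                CRMetrics(
                    trial_index=i,
                    trial_type="cs_only" if i % 9 == 0 else "paired",
                    cr_amplitude=0.4 if i < n_cr else 0.05,
                    is_cr=i < n_cr,
                )
            )
        return out

    def test_percentage_is_cr_fraction(self):
        protocol = build_ebc_session(1, seed=0)
        s = summarize_cr_session(self._metrics(45, 27), protocol)
        assert s.cr_percentage == pytest.approx(60.0)
        assert s.n_trials_scored == 45

    def test_no_crs_gives_zero(self):
        protocol = build_ebc_session(1, seed=0)
        assert summarize_cr_session(self._metrics(45, 0), protocol).cr_percentage == 0.0

    @settings(max_examples=30, deadline=None)
    @given(flags=st.lists(st.booleans(), min_size=1, max_size=60))
    def test_matches_brute_force_count(self, flags):
        metrics = [
            CRMetrics(i, "paired", cr_amplitude=0.3, is_cr=f)
            for i, f in enumerate(flags)
        ]
        protocol = build_ebc_session(1, seed=0)
        s = summarize_cr_session(metrics, protocol)
        assert s.cr_percentage == pytest.approx(
            100.0 * sum(flags) / len(flags)
        )


class TestScoreStartle:
    def test_peak_inside_window(self, make_segment):
        seg = make_segment(
            "pulse_only", onsets={"pulse": (0.0,)}, peaks=[(150.0, 0.4, 30.0)]
        )
        m = score_startle(seg)
        assert m.significant
        assert m.peak_time_ms == pytest.approx(150.0, abs=1.0)
        assert m.peak_amplitude == pytest.approx(0.4, abs=1e-3)

    def test_flat_segment_not_significant(self, make_segment):
        seg = make_segment("pulse_only", onsets={"pulse": (0.0,)})
        m = score_startle(seg)
        assert not m.significant
        assert m.peak_amplitude == pytest.approx(0.0, abs=1e-9)

    def test_window_bounds_exclude_outside_peaks(self, make_segment):
        # responses at 40 ms and 400 ms post-pulse fall outside 60-330 ms
        seg = make_segment(
            "pulse_only",
            onsets={"pulse": (0.0,)},
            peaks=[(40.0, 0.5, 8.0), (400.0, 0.5, 8.0)],
        )
        m = score_startle(seg)
        assert m.peak_amplitude < 0.15 and not m.significant

    def test_prepulse_response_window(self, make_segment):
        seg = make_segment(
            "prepulse_pulse_50",
            onsets={"prepulse": (0.0,), "pulse": (120.0,)},
            peaks=[(100.0, 0.1, 15.0), (230.0, 0.2, 20.0)],
        )
        m = score_startle(seg)
        # prepulse window is 60-180 ms after the prepulse
        assert m.prepulse_response_amplitude == pytest.approx(0.1, abs=5e-3)
        # pulse window is referenced to pulse onset
        assert m.peak_time_ms == pytest.approx(110.0, abs=1.0)


class TestPpiPercent:
    def test_printed_worked_example(self):
        assert ppi_percent(0.35, 0.10) == pytest.approx(
            100 - (0.10 / 0.35) * 100
        )

    @pytest.mark.parametrize("a", [0.1, 0.35, 1.0])
    def test_limits(self, a):
        assert ppi_percent(a, a) == pytest.approx(0.0)
        assert ppi_percent(a, 0.0) == pytest.approx(100.0)

    def test_facilitation_is_negative(self):
        assert ppi_percent(0.2, 0.3) < 0

    def test_requires_positive_pulse_amplitude(self):
        with pytest.raises(ValueError):
            ppi_percent(0.0, 0.1)

    @settings(max_examples=50, deadline=None)
    @given(
        p=st.floats(0.01, 2.0, allow_nan=False),
        q=st.floats(0.0, 2.0, allow_nan=False),
    )
    def test_algebraic_identity(self, p, q):
        assert ppi_percent(p, q) + 100.0 * q / p == pytest.approx(100.0)


class TestPpiSummary:
    def test_mean_peak_time_over_significant(self, make_segment):
        segs = [
            make_segment("pulse_only", onsets={"pulse": (0.0,)},
                         peaks=[(140.0, 0.4, 25.0)], trial_index=0),
            make_segment("pulse_only", onsets={"pulse": (0.0,)},
                         peaks=[(160.0, 0.4, 25.0)], trial_index=1),
        ]
        metrics = [score_startle(s) for s in segs]
        summary = ppi_session_summary(metrics)
        assert summary.mean_peak_time_ms == pytest.approx(150.0, abs=1.0)

    def test_identical_traces_give_zero_ppi(self, make_segment):
        segs = []
        for i, tt in enumerate(
            ["pulse_only", "prepulse_pulse_5", "prepulse_pulse_50"]
        ):
            onsets = (
                {"pulse": (0.0,)}
                if tt == "pulse_only"
                else {"prepulse": (0.0,), "pulse": (120.0,)}
            )
            pulse = onsets["pulse"][0]
            segs.append(
                make_segment(
                    tt, onsets=onsets, peaks=[(pulse + 150.0, 0.4, 25.0)],
                    trial_index=i,
                )
            )
        summary = ppi_session_summary([score_startle(s) for s in segs])
        vals = set(round(v, 9) for v in summary.per_type_amplitudes.values())
        assert len(vals) == 1
        for v in summary.ppi_percent_per_level.values():
            assert v == pytest.approx(0.0, abs=1e-6)

    def test_no_significant_startles_flagged(self, make_segment):
        segs = [
            make_segment("pulse_only", onsets={"pulse": (0.0,)}, trial_index=i)
            for i in range(3)
        ]
        summary = ppi_session_summary([score_startle(s) for s in segs])
        assert summary.flagged
        assert summary.mean_peak_time_ms == P.nominal_peak_ms


class TestHabituationSummary:
    def _train_segment(self, idx, amps, peak=150.0):
        t = np.arange(-500.0, 3801.0)
        c = np.zeros_like(t)
        onsets = tuple(750.0 * k for k in range(len(amps)))
        for o, a in zip(onsets, amps):
            c += a * np.exp(-0.5 * ((t - o - peak) / 30.0) ** 2)
        from blinkpipe.signal import TrialSegment

        return TrialSegment(idx, "pulse_train", t, c, {"pulse": onsets},
                            10_000.0, "normalized")

    def test_group_percent_from_printed_values(self):
        segs = [self._train_segment(i, [0.30, 0.24, 0.18, 0.15, 0.13])
                for i in range(4)]
        metrics = [m for s in segs for m in score_train(s)]
        summary = habituation_summary(metrics)
        assert summary.per_pulse_amplitudes[1] == pytest.approx(0.30, abs=0.01)
        assert summary.per_pulse_amplitudes[5] == pytest.approx(0.13, abs=0.01)
        # 100 * (1 - 0.13/0.30) = 56.7
        assert summary.habituation_percent == pytest.approx(56.7, abs=1.0)

    def test_constant_response_gives_zero_percent(self):
        segs = [self._train_segment(i, [0.3] * 5) for i in range(3)]
        metrics = [m for s in segs for m in score_train(s)]
        assert habituation_summary(metrics).habituation_percent == pytest.approx(
            0.0, abs=1e-6
        )

    def test_geometric_decay_is_monotone(self):
        amps = [0.35 * 0.7**k for k in range(5)]
        segs = [self._train_segment(i, amps) for i in range(3)]
        metrics = [m for s in segs for m in score_train(s)]
        per_pulse = habituation_summary(metrics).per_pulse_amplitudes
        vals = [per_pulse[k] for k in sorted(per_pulse)]
        assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_each_pulse_scored_in_own_window(self):
        seg = self._train_segment(0, [0.4, 0.3, 0.2, 0.15, 0.1])
        metrics = score_train(seg)
        assert [m.pulse_position for m in metrics] == [1, 2, 3, 4, 5]
        for m, expected in zip(metrics, [0.4, 0.3, 0.2, 0.15, 0.1]):
            assert m.peak_amplitude == pytest.approx(expected, abs=0.01)
            assert 60 <= m.peak_time_ms <= 330
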