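# blinkpipe

Offline, testable analysis of smartphone-based neurometric testing:
**delay eyeblink conditioning (EBC)**, **prepulse inhibition of acoustic
startle (PPI)** and **startle habituation**, measured from facial-landmark
streams recorded by a front-facing camera at a nominal 60 Hz.

The package is for researchers who have per-frame facial-landmark exports
(77 (x, y) points plus a face bounding box per frame) and need the full
measurement chain: millisecond-resolved stimulus schedules, eyelid-trace
extraction, trial scoring and group summaries. A built-in virtual
participant generates ground-truthed landmark streams for every paradigm, so
the whole pipeline runs and is tested with no external data.

## The measurement model

**Eyelid trace.** Per frame, with coordinates taken relative to the face
bounding box and six eye landmarks (two upper-lid points *u₁, u₂*, two
lower-lid points *l₁, l₂*, two corners *c₁, c₂*):

```
openness = (y_l1 + y_l2 − y_u1 − y_u2) / (2 · |x_c1 − x_c2|)
```

a scale-invariant lid-gap ratio. The series (in closure orientation) is
low-pass filtered with a zero-phase (forward–backward) Butterworth filter
(configured cutoff 50 Hz, clamped to 0.45·fs — 27 Hz at 60 Hz video) and
normalized per session so that the pre-stimulus baseline sits at 0 and the
median **spontaneous full blink** captured in the 500 ms pre-stimulus
baseline windows sits at 1.

**Scoring.**

* *EBC* — a conditioned response (CR) is an eyelid movement > 0.15 on the
  normalized scale whose peak falls between 60 ms after CS onset and the US
  (US onset for paired trials, nominal US offset for CS-only trials);
  shorter-latency deflections are reflexive alpha responses and are
  excluded. Sessions report CR%, mean CR amplitude, latency to onset, and
  latency to peak (CS-only trials only).
* *PPI / habituation* — startle responses are scored 60–330 ms after pulse
  onset; the direct prepulse response 60–180 ms after the prepulse. Session
  amplitudes use the two-pass rule: find the mean peak time T of significant
  startles over all trials, then read every trial's closure at T. Percent
  inhibition is `100 · (1 − prepulse_trial / pulse_only)`; habituation
  percent is the analogous first-to-last-pulse drop within 5-pulse trains.

**Default protocols** (all seeded and deterministic): EBC sessions of 50
trials in 5 blocks of {1 CS-only, 1 US-only, 8 paired}, 450 ms CS, 50 ms
105 dB US, 400 ms ISI (700 ms in the late ISI-switch sessions, 100 ms probe
CS in the probe session); PPI sessions of 55 trials (5 settling trials, then
10 blocks of one pulse-only plus 65/75/83/93 dB prepulse trials, 120 ms
lead); habituation sessions of 10 five-pulse trains at 750 ms spacing.

## Worked example

```python
from blinkpipe.protocol import build_ppi_session
from blinkpipe.simulate import ParticipantModel, simulate_session
from blinkpipe.pipeline import process_stream

protocol = build_ppi_session(seed=7)                      # 55 trials
stream, truth = simulate_session(protocol, ParticipantModel(), seed=7)
result = process_stream(stream, protocol, truth.trial_onsets_abs_ms)
s = result.summary
print(f"trials scored: {s.n_trials_scored}, mean startle peak: {s.mean_peak_time_ms:.1f} ms")
print(f"pulse-only amplitude: {s.per_type_amplitudes['pulse_only']:.3f}")
for level, v in sorted(s.ppi_percent_per_level.items()):
    print(f"{level}: {v:.1f}% inhibition")
```

prints

```
trials scored: 55, mean startle peak: 114.2 ms
pulse-only amplitude: 0.319
prepulse_pulse_10: 56.9% inhibition
prepulse_pulse_25: 66.9% inhibition
prepulse_pulse_5: 56.4% inhibition
prepulse_pulse_50: 66.6% inhibition
```

The virtual participant startles at ~0.35 of a full blink to the 105 dB
pulse about 110 ms after pulse onset; prepulses inhibit the startle by a
per-intensity fraction (0.70 generative at 93 dB, recovered here as ~67%
from one 55-trial session). `truth` carries the generative record for every
trial, which is how the test suite checks parameter recovery.

There is also a thin CLI (`blinkpipe simulate | extract | score | report |
run`); `blinkpipe run --config cfg.yaml` executes simulate → extract →
filter → normalize → segment → score → report and writes tidy per-trial
CSVs, session summaries and a manifest.

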