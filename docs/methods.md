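# Methods

## Scope and data model

`blinkpipe` measures three trial-based reflex paradigms from facial-landmark
time series: delay eyeblink conditioning (EBC), prepulse inhibition of
acoustic startle (PPI) and startle habituation. The input is a
`LandmarkStream`: per-frame timestamp, 77 image-pixel (x, y) landmarks and a
face bounding box, nominally 60 Hz. Stimulus delivery, landmark detection
and environment monitoring happen upstream (on the recording device) and are
out of scope; the package consumes their output and a millisecond-resolved
`SessionProtocol` describing what was presented when.

## Protocol generation

Schedules are generated per session from parameter records
(`EbcParams` / `PpiParams` / `HabParams`) and a seed, and are fully
deterministic given both. "Semi-random" trial placement within a block is a
uniform seeded permutation — no adjacency constraints are imposed because
none are defined. Inter-trial intervals are uniform-continuous over the
paradigm's range ([7, 20] s EBC, [10, 25] s PPI, [20, 40] s habituation),
rounded to 1 ms, and attached to the trial they precede.

Timing identities enforced by construction and by `validate_session`:

* delay trials co-terminate: `isi_ms + us_duration_ms == cs_duration_ms`
  (450 = 400 + 50 for the standard regime, 750 = 700 + 50 after the ISI
  switch in sessions 8–9);
* the probe session (7) replaces the CS in CS-only trials with a 100 ms
  probe CS that is never reinforced; US-only and paired trials are
  unchanged;
* every prepulse leads its pulse by exactly 120 ms;
* habituation trains use a fixed 750 ms onset-to-onset interval (the
  printed value; the nominal 1.33 Hz reading differs by <2 ms, under one
  frame at 60 Hz).

Prepulse trial types carry the conventional percent-of-startle tags
(5/10/25/50%) for the default intensity list [65, 75, 83, 93] dB; the dB
values are authoritative and no dB↔percent conversion is computed, since the
tag pairs are not consistent with standard 20·log10 amplitude arithmetic.

## Signal chain

1. **Openness/closure extraction.** With bbox-relative coordinates and the
   image convention that y grows downward,
   `openness = (Σ y_lower − Σ y_upper) / (2 · |x_temporal − x_nasal|)` — an
   eye-aspect-ratio-style quantity: the mean of the two lid gaps scaled by
   the inter-corner distance, invariant to zoom and translation. The series
   is returned in closure orientation (larger = more closed) by subtracting
   from its maximum; the additive constant is irrelevant after baseline
   normalization. Frames with a degenerate corner distance are interpolated
   from neighbours; above 10% such frames the stream is rejected. Which six
   of the 77 landmarks form the eye, and which eye is scored, is deployment
   configuration (`EyeLandmarkIndex`), not something the pipeline can infer.
2. **Resampling.** Camera timestamps jitter; traces are linearly
   interpolated onto a uniform grid before filtering (no extrapolation).
3. **Filtering.** Zero-phase low-pass Butterworth (`filtfilt`), order 2
   (doubled by the forward–backward pass; the order is a convention choice —
   blink kinematics live below ~10 Hz). The configured cutoff is 50 Hz for
   provenance, but a cutoff at or above Nyquist is undefined, so the applied
   cutoff is clamped to 0.45·fs: 27 Hz at 60 Hz video. Both values are
   recorded in the run manifest. A constant stream passes unchanged (DC gain
   1) and symmetric pulses keep their peak sample (zero phase).
4. **Spontaneous-blink detection.** Full blinks are the normalization
   reference and are sought in the 500 ms pre-stimulus baseline windows.
   Peaks must have prominence ≥ 50% of the stream's robust closure range
   (95th − 5th percentile; full range if that is degenerate on a sparse
   clean trace), *and* half-prominence width ≥ 60 ms, *and* prominence above
   8× the scaled-MAD noise estimate of the trace, with ≥ 200 ms separation.
   The width and noise-floor guards exist because on realistic streams the
   percentile range alone can fall to the sensor-noise scale (blinks occupy
   only a few percent of samples), and narrow noise bumps would then
   masquerade as blinks; both guards are no-ops on clean traces.
5. **Normalization.** Per trial, the median of the 500 ms pre-stimulus
   baseline is subtracted — computed excluding ±(150/300) ms spans around
   detected blink peaks, since a full blink can occupy most of a 500 ms
   window and would drag even a median off the resting level. All trials
   are then divided by the session blink reference: the median
   baseline-corrected spontaneous-blink peak (median, for robustness to
   partial blinks; the aggregator is a package choice). The result reads
   0 = fully open, 1 = full blink. If a session yields no usable
   spontaneous blink the reference falls back to the maximum
   stimulus-evoked closure and the output is flagged (`fallback_used`);
   ratio-based measures (percent inhibition, habituation percent) are
   unaffected by the resulting scale change, absolute amplitudes are not.
   Output is clipped to [−0.5, 1.5] with clipped samples counted.
6. **Segmentation.** One snippet per trial, spanning 500 ms before the
   first stimulus onset to the paradigm's window end (EBC: nominal US offset
   + 500 ms; PPI: pulse onset + 800 ms; habituation: last pulse onset +
   800 ms), re-zeroed at the first stimulus onset. Trials whose window
   exceeds the trace are flagged missing, never dropped, so segment count
   always equals protocol trial count. A constant stimulus-onset offset
   (e.g. a measured Bluetooth audio latency) can be applied; default 0 ms.

## Scoring rules

* **CR window**: CS onset + 60 ms to the US onset on paired trials (only
  the pre-US interval is anticipatory) and to the *nominal* US offset
  (CS + ISI + 50 ms) on CS-only trials, where no US truncates the response.
  This reconciles the amplitude window definition with the
  anticipatory-only restriction; both bounds are configurable.
* **CR criterion**: amplitude (window maximum) > 0.15 on the normalized
  scale with the argmax interior to the window; a maximum on the window's
  first sample is the decaying tail of a pre-window alpha response and does
  not count. CR amplitude is reported for every scored trial regardless of
  the criterion; CR% is the fraction of CS-bearing trials (paired +
  CS-only; US-only trials are excluded, 45 of 50 per default session)
  meeting it. Latency to onset is the first crossing of 0.05 sustained for
  3 frames after the window start; latency to peak is reported for CS-only
  trials only, and averaged over CR trials.
* **Startle**: peak in [pulse + 60, pulse + 330] ms (video measures lid
  movement, which lags the muscle activity EMG would register, hence the
  longer-than-EMG window); significant when the peak exceeds the same 0.15
  threshold used for CRs (one threshold across paradigms; no separate
  criterion is defined for startle significance). Prepulse responses:
  maximum in [prepulse + 60, prepulse + 180] ms.
* **Two-pass session amplitudes**: T = mean peak time of significant
  startles across all trials; every trial then contributes its closure at
  pulse onset + T (linear interpolation between samples). With no
  significant startle the summary is flagged and T falls back to a nominal
  150 ms. Percent inhibition per level uses the pulse-only mean as
  denominator; habituation reports per-pulse-position means and
  `100·(1 − last/first)`.

## The virtual participant

`simulate_session` turns any protocol into a landmark stream plus a
ground-truth record. All responses are gamma-shaped closure kernels
`k(t) ∝ (t/t_rise)^m · exp(m(1 − t/t_rise))`, `m = rise/decay`, truncated to
exact compact support `[0, rise + 5·decay]` and rescaled to preserve the
peak. The hard support boundary is what makes the zero-noise recovery
invariant provable: a baseline blink cannot reach any scoring window.
Reflexive blinks use rise 50 ms / decay 50 ms (a brisk ~300 ms blink; the
rise is exactly 3 frames at 60 Hz, so snapped-to-grid onsets put the peak
on a sample and zero-noise amplitude recovery is exact to float precision);
CRs use rise 250 ms / decay 100 ms (gradual anticipatory closure).

Generative model, defaults, and what they emulate:

| parameter | default | rationale |
|---|---|---|
| `ur_amplitude` | 0.8 | the composite noise+flash US evokes a strong, occasionally partial blink |
| `startle_gain_per_db`, `startle_threshold_db` | 0.027 /dB above 92 dB | 105 dB pulse → 0.35 of a full blink; only the 93 dB prepulse evokes a small (~0.03) direct response |
| `startle_latency_ms` (sd) | 110 (15) | video peak latency inside the 60–330 ms window |
| `habituation_factor` | 0.8 | per-pulse retention; pulse5/pulse1 = 0.8⁴ ≈ 0.41 |
| `ppi_inhibition` | 0.60/0.62/0.66/0.70 at 65/75/83/93 dB | strong sensorimotor gating, ~2/3 suppression |
| `cr_asymptote_prob`, `cr_learning_rate` | 0.6, 0.012/trial | exponential-saturation acquisition reaching ~56–60% CRs after six 40-paired-trial sessions |
| `cr_amplitude_asymptote` | 0.6 | session-6 mean CR amplitude ~0.3 across CR and non-CR trials |
| `cr_peak_offset_ms` (jitter sd) | 50 (30) | CR peaks at the nominal US offset, i.e. the end of the anticipatory window |
| `cr_prior_isi_ms` | none | set to 400 when simulating post-ISI-switch sessions: peak timing re-adapts to the new US onset with the same learning dynamics |
| `spontaneous_blink_rate_hz` | 0.3 | ~18 blinks/min, typical for screen viewing |
| `noise_sd_px` | 0.5 | white Gaussian landmark-coordinate noise; ≈0.013 closure units after extraction |

The acquisition curve is an exponential-saturation learning model over
cumulative paired trials (continued across sessions via the `history`
argument). It is a test harness calibrated to the observed group
phenomenology, not a mechanistic claim.

Spontaneous blinks are a Poisson process restricted to times where the
blink's entire kernel ends by 50 ms after a trial's first stimulus onset
(all scoring windows start at +60 ms) and does not overlap any analysis
window. This blink suppression around stimuli is what keeps the ground
truth exactly recoverable at zero noise; its cost is a near-zero baseline
false-CR rate, whereas human baselines show a few percent "CRs" from
blink tails entering the window. Rendering moves only the four lid
landmarks (linearly between the template's open and closed configurations,
lids meeting at closure 1); the other 71 landmarks and the bounding box are
static, so extraction inverts rendering exactly up to an affine map that
normalization removes.

## What the simulator does and does not show

Passing recovery tests show the *pipeline* is correct and unbiased under
the generative model: landmark noise, timestamp grids, baseline blinks,
response overlap and per-session normalization. They do not establish
performance under real-world conditions the generator omits: head motion
and pose change, landmark-model biases and dropouts, lighting artifacts,
gaze-dependent lid position, non-Poisson blink bursts, blink suppression or
rebound around stimuli in real participants, and between-subject kinematic
variability (defaults are round numbers, not fitted to any dataset).

Known quantitative consequences of the design:

* Habituation sessions have only 10 baseline windows, so ~half of simulated
  sessions contain no spontaneous baseline blink and normalize via the
  evoked-maximum fallback; their absolute amplitudes are inflated (the
  first pulse's startle becomes ≈1) while habituation percent and the
  pulse5/pulse1 ratio are unaffected. EBC and PPI sessions (50–55 windows)
  almost always find blinks.
* On paired trials the CR peak (at the nominal US offset) lies beyond the
  scoring window's end at US onset, so paired-trial CR amplitudes are
  window-truncated (~6% at default timing); this mirrors the anticipatory
  window definition, and CS-only trials measure the full kinetic profile.

## Numerical choices and degenerate inputs

* Uniform-grid tolerance: 1 µs of spacing spread; filtering refuses
  non-uniform grids and traces shorter than the filter padding.
* Zero corner distance → frame interpolated; >10% such frames → error.
* Normalization requires a positive blink reference and at least one
  usable trial; sessions failing that raise a stage-named pipeline error.
* Tie-breaks: window maxima use the first argmax sample (`np.argmax`);
  prepulse-level summary means follow trial-type tags.
* All ITIs are whole milliseconds; event times within trials are exact
  integers by construction; segment time axes inherit the camera grid.
* Seeds: every stochastic component (schedule ITIs and permutations,
  simulator draws) is driven by an explicit integer seed;
  identical inputs give byte-identical outputs.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` simulate full-size sessions
(50/55/10 trials with the default ITI ranges, ~8–17 min of 60 Hz video
each). Recovery properties use 20 seeds per paradigm (20 virtual subjects ×
6 EBC sessions for the acquisition curve); the acceptance script uses a
6-subject cohort for its headline numbers, a size at which group means are
stable to a few percent while the whole script completes in well under a
minute.
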