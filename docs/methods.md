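# Methods

## Measurement model

A trial is a commanded stimulus train (per-modality pulses, each a command
time and a requested duration) rendered into a uniformly sampled
multi-channel trace, emulating what an oscilloscope records from a phone's
audio jack, a phototransistor on its display, and a piezo disk on its case.
Defaults follow the measurement setting the profiles were derived from:
10 000-Hz sampling over a window of −125…+125 ms around the commanded onset
(time 0), in arbitrary volt-equivalent units with unit pulse amplitude.
Longer stimulus trains need a wider window, passed explicitly; a pulse that
would leave the window is an error rather than a truncation.

Per channel the simulator applies, in order:

- **auditory** — onset at `command + onset_delay`; physical duration exactly
  the commanded one; the burst is a 1-kHz cosine (the standard pure-tone
  stimulus; phase locked to the onset so the first and last samples of an
  integer-millisecond burst carry full amplitude). When a commanded pair's
  gap is at or below `shortest_isi_ms` (14 ms = the spacing rule at the
  7-ms minimum duration), the realized gap is overshot by
  `shortest_isi_overshoot_ms` (+2 ms in both shipped profiles).
- **visual** — onsets snap forward to the display frame grid and durations
  to whole frames (`frame_period_ms` = 16.67 ms at 60 Hz, minimum one
  frame). Per nominal duration, `frame_miss_prob` gives the probability of a
  ±1-frame error, sign equiprobable, never below one frame. Pixel
  transitions are raised-cosine ramps of `transition_ms` (≈5 ms on the
  Xiaomi, ≈1 ms on the Samsung).
- **tactile** — onset lag, `max(commanded, min_duration_ms)` (30 ms on both
  devices) plus `duration_inflation_ms` (26 ms on the Samsung, whose 100-ms
  command therefore exceeds 125 ms). Commanded pairs with gaps below
  `merge_below_isi_ms` fuse into one wave of `merged_wave_duration_ms`
  (125 ms); the Samsung profile merges every pair, the Xiaomi none.

Gaussian baseline noise (default SD 1 % of pulse amplitude) is added to
every channel; the shipped traces are visibly low-noise recordings and the
exact SNR is not a measured quantity, so 1 % is a package choice. Every
stochastic element (frame-miss draws, noise) is driven by one explicit seed
per trial; sessions derive trial seeds as `session_seed + trial_index`.
Ground-truth physical intervals are stored in `Trace.meta["injected"]` for
closed-loop testing.

### The frame grid anchor

A phone's vsync phase relative to the software command is unobservable from
the profile, so the frame grid is anchored with a boundary at the first
visual pulse's `command + onset_delay` (plus an optional `frame_phase_ms`).
This reproduces the measured onset-delay table exactly for the first flash
while still quantizing subsequent flashes; sequential visual ISIs therefore
show the realistic frame-rounded variability.

### Edge convention (why detection is unbiased)

Pulses are active on the *closed* interval [onset, offset] and transitions
are ramps *centred* on the nominal edge time. Physically this is a
measure-zero convention, but it makes the half-amplitude crossing of the
rendered waveform — and, for instantaneous edges, the first/last active
sample — sit exactly at the nominal edge. With the detector's
first/last-sample-at-threshold rule, durations and gaps are then recovered
without the one-sample (−0.1 ms per duration, +0.1 ms per gap) bias an
open-interval convention would force.

## Detection pipeline

1. **Smoothing.** Auditory/tactile: Savitzky–Golay, window 11 samples
   (1.1 ms), polynomial order 3 — "low degree" with a window short enough
   not to blur 1-ms transitions. Visual: zero-phase (forward–backward)
   Butterworth low-pass of order 4 with passband edge 0.1·π rad/sample
   (500 Hz at 10 kHz); zero-phase filtering preserves edge positions.
2. **Baseline band.** From the 50 ms before the command: centre = median
   (mean selectable; the median resists pre-stimulus glitches) ± `k` = 2
   sample SDs.
3. **Event membership.** A sample belongs to an event when its deviation
   from the baseline centre reaches
   `max(k·SD, amplitude_floor_frac × plateau)`, ties counting as exceeding
   (with 1e-6 relative tolerance, which also absorbs ~1e-8 zero-phase filter
   overshoot). The plateau (ON level) is estimated two-pass as the median of
   samples in the upper half of the excursion range, which is insensitive to
   how much of the window the stimulus occupies. The half-amplitude floor
   (default fraction 0.5) exists because the ±2 SD band collapses to zero
   width on noiseless traces and, more importantly, because the
   half-amplitude crossing is the unbiased edge estimator under any
   symmetric smoother — a near-baseline cutoff reads ramped edges
   systematically early. A channel whose plateau estimate is below 10
   baseline SDs is reported as event-free rather than thresholded into
   noise runs.
4. **Runs → events.** Supra-threshold runs closer than
   `min_event_separation_ms` = 2 ms merge (this also glues the intra-cycle
   dips of the rectified audio carrier); onset = first sample of the run,
   offset = last, duration = offset − onset; single-sample runs carry no
   duration and are dropped.

**Audio is rectified and thresholded raw by default** (`rectify_audio=True`,
`smooth_audio=False`). Smoothing the rectified 1-kHz carrier leaves ±10 %
plateau ripple whose half-amplitude crossing is ambiguous at sample
precision; the raw rectified burst is high-SNR and sample-exact. The
smoothed-audio path remains available as a parameter. For noiseless bursts
whose duration is not a whole number of carrier periods, the offset can read
early by up to half a period (0.5 ms at 1 kHz); the standard durations
(7–100 ms) are all integer periods.

**Changepoint segmentation** (for transition-ramp characterization) is an
exact dynamic program minimising within-segment squared error about segment
means — equivalent to exhaustive search, verified against brute-force
enumeration in tests. `auto` segment count minimises
`SSE(k) + penalty·(k−1)` over k = 1…10 with
`penalty = 3·σ̂²·log n`, σ̂ the MAD-of-first-differences noise scale; the
constant 3 (slightly stiffer than BIC's 2) resists over-segmenting ramps.
On a constant signal every partition is equivalent: the function returns
valid boundaries and emits a `UserWarning` marking them low-confidence.

## Metrics conventions

- Accuracy = session median duration; precision = sample SD (ddof 1) and
  mean absolute deviation about the median.
- ISI = offset→next-onset gap (the silent interval, matching the commanded
  spacing convention); onset→onset is available and every report row
  records which convention it used.
- Frame-miss = fraction of trials whose duration deviates from the
  session's modal duration by one frame period ±25 %. The modal duration is
  located by the median, valid while misses stay below 50 %.
- Trials with merged/missing/extra events are counted per session and
  excluded from duration statistics — never silently dropped.
- Simultaneity deltas are onsets minus the minimum onset; exactly one
  modality reads 0.

## Behavioural statistics

Per-participant proportions of correct flash-count reports in three groups
(single flash on the phone, illusion condition on the phone, illusion
condition on the PC rig) enter a tie-corrected Kruskal–Wallis H with
χ²(k−1) p. Post-hocs are paired Dunn tests on the pooled ranks,

    z = (R̄_second − R̄_first) / sqrt((N(N+1)/12 − ΣT/(12(N−1)))·(1/n₁+1/n₂)),

two-sided normal p multiplied by the family size (3) and capped at 1. Tie
correction is on by default and switchable, since proportions over 20 trials
are heavily tied. The sign convention (second minus first) makes a
higher-performing first group yield negative z. With all pooled values
identical, H is reported as 0 with p = 1 (no rank information).

The synthetic observer is a per-condition Bernoulli "report two"
probability — a fission rate for the illusion condition, lapse rates
elsewhere. It models no temporal sensitivity, no learning and no
inter-participant correlation; tests that pass with it show the analysis
chain is correct, not that the illusion occurs in people.

## Problem sizes

Sessions default to 100 trials, the standard validation session length.
The shipped acceptance computation uses 10 000 trials per visual duration
(40 000 per device) so the pooled frame-miss percentage carries a binomial
SD below 0.15 percentage points, and single noiseless trials for the
deterministic quantities (delay tables, audio-gap overshoot, fused-wave
duration). The test suite uses 100–4 000-trial sessions with 3-binomial-SD
tolerances.

## Known limitations

- The Xiaomi vibrator's failure to start at commanded gaps below 60 ms is
  not modelled (the profile schema only carries merge parameters); commanded
  sub-minimum tactile pairs instead overlap after duration flooring and are
  flagged as merged by detection.
- The Samsung per-duration split of the 12.75 % visual miss rate is not a
  measured quantity; the profile applies it uniformly across durations.
- Audio latency is a fixed per-device onset delay; driver jitter, buffer
  underruns and thermal drift are out of scope.
- Detection on a channel containing only noise (no commanded pulse) returns
  no events via the plateau-SNR guard; a real near-threshold stimulus
  (amplitude within ~10 baseline SDs) would likewise be reported absent.
- The behavioural module analyses response tables; it does not fit
  psychometric functions or model tactile-induced illusion variants.
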