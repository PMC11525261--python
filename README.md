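# stimtime

Timing validation for smartphone-based psychophysics, as a desk-scale
toolkit.

Psychophysical experiments need stimuli whose onset, offset and duration are
accurate to milliseconds. When the stimulus device is a phone rather than a
lab rig, each channel — speaker, display, vibration motor — adds its own
command-to-physical latency and fidelity pathologies: displays quantize every
flash to the refresh period (16.7 ms at 60 Hz) and occasionally drop or add a
frame, vibrators have a minimum producible pulse and may fuse closely spaced
pulses into one long wave, and the shortest audio inter-stimulus intervals
come out a couple of milliseconds long. `stimtime` packages the whole
measurement methodology around those behaviours:

- **device simulator** — renders the multi-channel "oscilloscope" trace a
  profiled phone would produce for any commanded stimulus train (10-kHz
  sampling, ±125-ms window). Two measured phone profiles ship with the
  package (`xiaomi_mi_a2`, `samsung_a40`).
- **trace analysis** — Savitzky–Golay / zero-phase low-pass smoothing, a
  baseline-±2 SD cutoff, onset/offset event extraction
  (duration = offset − onset), and exact least-squares changepoint
  segmentation for transition ramps.
- **timing metrics** — per-session accuracy (median duration), precision
  (SD and mean absolute deviation), ISI measurement, frame-miss rates, and
  cross-modal onset deltas.
- **scheduling** — the ISI spacing rule (ISI = 2 × duration), the
  delay-compensation schedule `command(m) = max_delay − delay(m)` that makes
  physical onsets coincide, and the double-flash-illusion session design.
- **behavioural statistics** — proportions correct, tie-corrected
  Kruskal–Wallis `H`, and paired Dunn post-hoc `z` with Bonferroni
  correction, plus a Bernoulli observer for end-to-end tests.

## Worked example

Measure a phone's cross-modal onset asynchrony and cancel it:

```python
from stimtime import (Pulse, StimulusSpec, compensate, detect_events,
                      load_packaged_profile, simulate_trial,
                      simultaneity_deltas)

profile = load_packaged_profile("samsung_a40")

# command all three channels at t = 0 and measure the physical onsets
spec = StimulusSpec({m: [Pulse(0, 50)] for m in ("auditory", "visual", "tactile")})
trace = simulate_trial(spec, profile, seed=0)
events = {m: detect_events(trace, m)[0] for m in trace.channels}
print(dict(simultaneity_deltas(events)))
# {'auditory': 0.0, 'tactile': 28.1, 'visual': 20.0}

# command the slow channels early by their measured delays
sched = compensate(profile.delay_table())
print(sched.command_times_ms)
# {'auditory': 28.0, 'tactile': 0.0, 'visual': 8.0}
spec2 = StimulusSpec({m: [Pulse(t, 50)] for m, t in sched.command_times_ms.items()})
trace2 = simulate_trial(spec2, profile, seed=0)
events2 = {m: detect_events(trace2, m)[0] for m in trace2.channels}
print(dict(simultaneity_deltas(events2)))
# {'auditory': 0.0, 'tactile': 0.1, 'visual': 0.1}
```

The uncompensated deltas are this device's latency signature (tactile
+28 ms, visual +20 ms behind audio); after compensation the residual
asynchrony is at the one-sample (0.1 ms) level.

The same pipeline is scriptable from the shell:

```bash
stimtime validate --profile xiaomi_mi_a2 --n 100 --seed 1 --out report/
stimtime schedule --profile samsung_a40 --out sched.yaml
stimtime dfi-design --reps 20 --seed 1 --out trials.csv
stimtime dfi-stats --responses responses.csv --out stats.json
```

`validate` simulates full 100-trial sessions for every duration × modality
in the plan, analyses them, and writes duration/ISI/simultaneity tables plus
a bar chart (median ± MAD). It exits 0 on a clean report and 2 when any
session contains merged or missing stimuli — e.g. the `samsung_a40`
vibrator, which fuses every sequential tactile pair into a single ~125-ms
wave.

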