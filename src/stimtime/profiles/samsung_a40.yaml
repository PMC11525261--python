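# Samsung A40 stimulus-channel profile (measured device behaviour).
# The vibrator is pathological: single pulses come out ~26 ms too long
# (a 100-ms command exceeds 125 ms) and ANY commanded pair of pulses fuses
# into one wave of about 125 ms.  The per-duration split of the 12.75 %
# visual one-frame miss rate was not measured; it is applied uniformly.
name: samsung_a40
modalities:
  auditory:
    onset_delay_ms: 0.0
    carrier_hz: 1000.0
    transition_ms: 0.0
    shortest_isi_ms: 14.0
    shortest_isi_overshoot_ms: 2.0
    noise_sd: 0.01
  visual:
    onset_delay_ms: 20.0
    frame_period_ms: 16.666666666666668
    transition_ms: 1.0          # fast, near-square transitions
    frame_miss_prob:
      17: 0.1275
      30: 0.1275
      50: 0.1275
      100: 0.1275
    noise_sd: 0.01
  tactile:
    onset_delay_ms: 28.0
    min_duration_ms: 30.0
    transition_ms: 1.0
    duration_inflation_ms: 26.0
    merge_below_isi_ms: 10000.0   # every sequential pair fuses
    merged_wave_duration_ms: 125.0
    noise_sd: 0.01
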