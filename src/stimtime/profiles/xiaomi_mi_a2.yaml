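# Xiaomi Mi A2 stimulus-channel profile (measured device behaviour).
# Onset delays are relative to the auditory channel, the fastest one.
# Visual frame-miss probabilities are per nominal duration (ms): one-frame
# errors are more frequent for the two shortest durations.
name: xiaomi_mi_a2
modalities:
  auditory:
    onset_delay_ms: 0.0
    carrier_hz: 1000.0
    transition_ms: 0.0
    shortest_isi_ms: 14.0
    shortest_isi_overshoot_ms: 2.0
    noise_sd: 0.01
  visual:
    onset_delay_ms: 30.0
    frame_period_ms: 16.666666666666668
    transition_ms: 5.0          # slow pixel transitions, up to ~5 ms
    frame_miss_prob:
      17: 0.125
      30: 0.125
      50: 0.04
      100: 0.04
    noise_sd: 0.01
  tactile:
    onset_delay_ms: 5.0
    min_duration_ms: 30.0       # vibrator cannot produce shorter pulses
    transition_ms: 1.0
    duration_inflation_ms: 0.0
    merge_below_isi_ms: 0.0     # no merge pathology on this device
    noise_sd: 0.01
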