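# 28-day culture, scratched and allowed to heal for 7 days.
# The repopulated (healed) lane carries immature cells with roughly half the
# spontaneous responsiveness of the mature surroundings.
name: 28d7d
kind: calcium
description: >
  Mature (28-day) monolayer whose scratch lane has been repopulated during a
  7-day healing period; reduced spontaneous responsiveness inside the healed
  wound relative to the non-wounded control areas.
monolayer:
  field_size: [384, 384]
  pixel_size_um: 1.0
  cell_radius_um: 7.0
  packing: 2.5
  jitter_sd_um: 1.5
kinetics:
  frame_rate: 2.0
  n_frames: 600
  baseline_mean: 1000.0
  baseline_cv: 0.1
  bleach_fraction: 0.15
  noise_sd: 20.0
  background: 100.0
  transient_amplitude: 1.5
  transient_amplitude_sd: 0.05
  transient_rise_s: 4.0
  transient_decay_s: 15.0
  event_window_s: [25.0, 255.0]
  mean_extra_events: 0.7
  min_event_gap_s: 20.0
responsive_fraction_by_zone:
  wound: 0.197
  area1: 0.387
  area2: 0.387
  area3: 0.387
  beyond: 0.387
  control: 0.387
responsive_fraction_sd_by_zone:
  wound: 0.023
  area1: 0.010
  area2: 0.010
  area3: 0.010
  beyond: 0.010
  control: 0.010
wound:
  kind: healed
  lane_width_um: 100.0
  lane_center_frac: 0.5
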