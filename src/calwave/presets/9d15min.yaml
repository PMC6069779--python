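# 9-day culture, freshly scratched (imaged 15 min after wounding).
# Cells directly adjacent to the fresh wound edge show elevated spontaneous
# activity; the injected per-zone responsive fractions are the condition
# means, with sample-to-sample dispersion drawn once per recording.
name: 9d15min
kind: calcium
description: >
  Immature (9-day) monolayer with a fresh denuded scratch lane; elevated
  spontaneous responsiveness in the first 50 um band next to the wound.
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
  wound: 0.0
  area1: 0.332
  area2: 0.153
  area3: 0.153
  beyond: 0.153
  control: 0.153
responsive_fraction_sd_by_zone:
  wound: 0.0
  area1: 0.032
  area2: 0.022
  area3: 0.022
  beyond: 0.022
  control: 0.022
wound:
  kind: fresh
  lane_width_um: 100.0
  lane_center_frac: 0.5
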