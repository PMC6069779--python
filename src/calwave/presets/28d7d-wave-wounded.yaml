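# Mechanical stimulation inside the healed lane of a 28-day + 7-day sample:
# the immature healed area supports a wide-spreading intercellular wave.
# Spontaneous transients are kept at a low incidence and their window starts
# well after the wave has finished: wave spreading and spontaneous activity
# were assessed in separate recordings, and this keeps the injected wave
# membership unambiguous in the ground truth.
name: 28d7d-wave-wounded
kind: wave
description: >
  Induced intercellular calcium wave in the healed wound area of a mature
  culture; wide spread (condition mean 79 participating cells).
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
  event_window_s: [60.0, 255.0]
  mean_extra_events: 0.7
  min_event_gap_s: 20.0
responsive_fraction_by_zone:
  control: 0.05
responsive_fraction_sd_by_zone:
  control: 0.0
wave:
  mean_cells: 79
  rel_sd: 0.05
  speed_um_s: 12.0
  amplitude: 1.6
  stim_time_s: 40.0
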