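# Scratch-wound closure of an immature (9-day) culture: full linear closure
# in 20 h at 1 h time-lapse sampling.
name: healing-9d
kind: healing
description: >
  Linear closure of a 100-px scratch lane in 20 hours, sampled hourly.
healing:
  closure_time_h: 20
  frame_interval_h: 1.0
  field_size: [384, 384]
  lane_width_px: 100
  profile: linear
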