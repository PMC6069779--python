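# Scratch-wound closure of a mature (28-day) culture: 2.5-fold slower than
# the immature condition, full linear closure in 49 h at 1 h sampling.
name: healing-28d
kind: healing
description: >
  Linear closure of a 100-px scratch lane in 49 hours, sampled hourly.
healing:
  closure_time_h: 49
  frame_interval_h: 1.0
  field_size: [384, 384]
  lane_width_px: 100
  profile: linear
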