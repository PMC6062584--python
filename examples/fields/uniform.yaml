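a0: 1000.0
a1x: 0.0
a1y: 0.0
plate_half_width: 11.5
source_direction:
- 1.0
- 0.0
theta_deg: 40.0
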