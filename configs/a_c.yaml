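use_men: true
use_bafe: false
use_embfpn: true
use_scau: false
num_classes: 11
input_size:
- 640
- 640
width_mult: 0.25
reg_max: 16
men_n_units: 1
men_scales:
- - 3
  - 6
  - 9
  - 12
- - 3
  - 6
  - 9
  - 12
- - 3
  - 6
  - 9
  - 12
- - 3
  - 6
  - 9
  - 12
bafe_mid: 0
bafe_heads: 4
bafe_window: 3
neck_width: 0
mscm_expansion: 1.0
mscm_n_blocks: 2
scau_s: 1
scau_g: 4
seed: 0
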