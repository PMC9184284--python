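# BSA diffusing in Channel I (100 x 27 nm^2), diffusion-only imaging at
# 200 fps and 0.005% relative noise.  12 independent scenes are pooled.
channel:
  name: I
species:
  - name: BSA
    mw_kda: 66.0
    rs_nm: 3.5
plan:
  n_frames: 500
  n_scenes: 12
infer:
  field: mw_kda
seed: 42
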