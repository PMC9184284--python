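# Flow-mode mixture in SLB-passivated Channel V (225 x 200 nm^2):
# lipoprotein-scale particles plus larger extracellular vesicles, both
# flushed through the channel by a slow pressure-driven flow.  The
# population field of interest is the hydrodynamic radius.
channel:
  name: V
species:
  - name: lipoprotein
    mw_kda: 2000.0
    rs_nm: 12.0
    drift_velocity: 20000.0   # nm/s
  - name: EV
    mw_kda: 30000.0
    rs_nm: 40.0
    drift_velocity: 20000.0
plan:
  n_frames: 400
  n_scenes: 8
infer:
  field: rs_nm
seed: 7
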