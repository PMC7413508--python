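# Homogeneous cylindrical phantom: one right cylinder (height = diameter)
# uniformly filled with 177Lu solution. Volumes in ml, concentrations in
# MBq/ml at scan time, lengths in mm.
name: cylindrical
nuclide: Lu-177
scan_time_h: 1.0
container:
  name: phantom
  kind: cylinder
  volume_ml: 5640.0
  concentration_mbq_per_ml: 0.25
  center_mm: [0.0, 0.0, 0.0]
inserts: []
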