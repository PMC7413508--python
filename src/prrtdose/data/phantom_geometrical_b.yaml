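# Geometrical phantom, second insert configuration: torus, pear-shaped and
# tubular inserts at a common activity concentration in a cold background.
name: geometrical_b
nuclide: Lu-177
scan_time_h: 1.0
container:
  name: background
  kind: cylinder
  volume_ml: 6713.0
  concentration_mbq_per_ml: 0.0
  center_mm: [0.0, 0.0, 0.0]
inserts:
  - name: To17b
    kind: torus
    volume_ml: 2.8
    concentration_mbq_per_ml: 1.53
    center_mm: [60.0, 0.0, 0.0]
  - name: P38
    kind: pear
    volume_ml: 29.2
    concentration_mbq_per_ml: 1.53
    center_mm: [30.0, 52.0, 0.0]
  - name: P39a
    kind: pear
    volume_ml: 30.1
    concentration_mbq_per_ml: 1.53
    center_mm: [-30.0, 52.0, 0.0]
  - name: P39b
    kind: pear
    volume_ml: 31.2
    concentration_mbq_per_ml: 1.53
    center_mm: [-60.0, 0.0, 0.0]
  - name: Tu38a
    kind: tube
    volume_ml: 28.6
    concentration_mbq_per_ml: 1.53
    center_mm: [-30.0, -52.0, 0.0]
  - name: Tu38b
    kind: tube
    volume_ml: 28.8
    concentration_mbq_per_ml: 1.53
    center_mm: [30.0, -52.0, 0.0]
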