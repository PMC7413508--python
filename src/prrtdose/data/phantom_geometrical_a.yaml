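# Geometrical phantom, first insert configuration: toroidal and ellipsoidal
# inserts at a common activity concentration in a cold water background.
# Insert names encode shape + equivalent sphere diameter (mm).
name: geometrical_a
nuclide: Lu-177
scan_time_h: 1.0
container:
  name: background
  kind: cylinder
  volume_ml: 6713.0
  concentration_mbq_per_ml: 0.0
  center_mm: [0.0, 0.0, 0.0]
inserts:
  - name: To17a
    kind: torus
    volume_ml: 2.8
    concentration_mbq_per_ml: 1.53
    center_mm: [55.0, 0.0, 0.0]
  - name: To26
    kind: torus
    volume_ml: 9.7
    concentration_mbq_per_ml: 1.53
    center_mm: [17.0, 52.3, 0.0]
  - name: E20
    kind: ellipsoid
    volume_ml: 4.1
    concentration_mbq_per_ml: 1.53
    center_mm: [-44.5, 32.3, 0.0]
  - name: E30
    kind: ellipsoid
    volume_ml: 14.8
    concentration_mbq_per_ml: 1.53
    center_mm: [-44.5, -32.3, 0.0]
  - name: E38
    kind: ellipsoid
    volume_ml: 28.5
    concentration_mbq_per_ml: 1.53
    center_mm: [17.0, -52.3, 0.0]
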