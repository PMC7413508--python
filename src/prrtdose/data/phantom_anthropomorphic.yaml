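# Anthropomorphic phantom: organ-shaped inserts at clinically realistic
# activity concentrations over a warm (0.03 MBq/ml) background. Organ shapes
# are idealised as ellipsoids (semi-axis aspect via semi_axes_mm, rescaled
# uniformly so the analytic volume matches volume_ml); the dummy lesion is a
# sphere. Placements are non-overlapping, not anatomical.
name: anthropomorphic
nuclide: Lu-177
scan_time_h: 1.0
container:
  name: background
  kind: cylinder
  volume_ml: 11600.0
  concentration_mbq_per_ml: 0.03
  center_mm: [0.0, 0.0, 0.0]
inserts:
  - name: Lesion
    kind: sphere
    volume_ml: 2.0
    concentration_mbq_per_ml: 8.34
    center_mm: [0.0, -75.0, -15.0]
  - name: Pancreas
    kind: ellipsoid
    volume_ml: 92.0
    concentration_mbq_per_ml: 0.99
    center_mm: [0.0, -75.0, -60.0]
    parameters:
      semi_axes_mm: [22.2, 44.4, 22.2]
  - name: Left kidney
    kind: ellipsoid
    volume_ml: 142.0
    concentration_mbq_per_ml: 0.81
    center_mm: [-50.0, 0.0, -60.0]
    parameters:
      semi_axes_mm: [25.7, 25.7, 51.4]
  - name: Right kidney
    kind: ellipsoid
    volume_ml: 142.0
    concentration_mbq_per_ml: 0.82
    center_mm: [50.0, 0.0, -60.0]
    parameters:
      semi_axes_mm: [25.7, 25.7, 51.4]
  - name: Spleen
    kind: ellipsoid
    volume_ml: 156.0
    concentration_mbq_per_ml: 1.10
    center_mm: [0.0, 75.0, -60.0]
    parameters:
      semi_axes_mm: [26.6, 26.6, 53.1]
  - name: Liver
    kind: ellipsoid
    volume_ml: 1470.0
    concentration_mbq_per_ml: 0.53
    center_mm: [0.0, 0.0, 60.0]
    parameters:
      semi_axes_mm: [95.0, 72.0, 51.0]
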