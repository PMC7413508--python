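# prrtdose

Internal dosimetry for ¹⁷⁷Lu peptide receptor radionuclide therapy (PRRT),
built for medical physicists comparing **organ-level MIRD dosimetry**
(reference-phantom S factors, sphere model for lesions) against
**voxel-level dose kernel convolution**, with the method-agreement
statistics that such comparisons are reported with.

Both engines implement the MIRD schema `D = Ã · S`: the time-integrated
activity Ã (MBq·s, the number of decays in a region) multiplied by an
S factor (Gy per decay). At organ level,
`D_t = Σ_s Ã_s S(t←s)` with `m_ref/m_true` rescaling of the electron self
dose; at voxel level, `D_i = Σ_j Ã_j k(i−j)` with a voxel S-value kernel
`k`, evaluated by zero-padded FFT convolution with optional masking of the
activity outside the VOI before convolution. Ã comes from trapezoidal
integration of the organ or voxel time–activity curve between the first and
last scan, with an analytic `A/λ` tail using the fitted effective or the
physical half-life (¹⁷⁷Lu: 6.647 d). Method agreement uses Lin's
concordance correlation coefficient
`ρ_c = 2s_xy/(s_x² + s_y² + (x̄−ȳ)²)`, Bland–Altman limits of agreement
(mean ± 1.96 SD of percentage differences), and signed relative differences
`100·(a−b)/b`. A renal BED module
(`BED = D[1 + T_rep/(T_rep+T_eff)·D/(α/β)]`) covers the kidney
dose-limiting prescription logic (46 Gy cumulative BED, 28 Gy with risk
factors).

Because clinical SPECT series are not distributable, the package includes a
first-class synthetic stage: voxel phantoms (homogeneous cylinder;
torus/ellipsoid/pear/tube inserts; anthropomorphic organs) rasterized from
analytic shapes solved to exact target volumes, SPECT-like PSF blur and
Poisson noise, and patient-like organ time–activity curves on the clinical
1/4/24/44/72 h schedule.

## Worked example

Run the geometrical-insert phantom study — rasterize, paint 1.53 MBq/ml
into the inserts, integrate TIA (single scan, physical tail), dose with
both engines, compare:

```python
import prrtdose as p

report = p.run_phantom_study(p.StudyConfig(recipe="geometrical_a",
                                           grid_spacing_mm=2.0))
print(report.summary)
```

```
    region  target_volume_ml  organ_dose_gy  voxel_mean_gy  rel_diff_voxel_vs_organ_pct
     To17a             2.800         29.856         28.071                       -5.978
      To26             9.700         29.856         28.897                       -3.214
       E20             4.100         29.856         29.055                       -2.683
       E30            14.800         29.856         29.598                       -0.863
       E38            28.500         29.856         29.809                       -0.158
```

Every insert holds the same activity concentration, so the organ-level
(sphere-model, local-deposition) dose is identical for all of them; the
voxel engine loses beta energy across each surface, so its mean dose falls
short by an amount that grows with surface-to-volume ratio — worst for the
small tori, negligible for the largest ellipsoid. This is the geometric
mechanism behind organ-level methods reading systematically higher than
voxel-level methods, especially for small, non-spherical regions.

The same statistics applied to the packaged per-patient reference tables:

```python
b = p.load_reference_tables()["sample_b"]
x, y = b.complete_pairs("VoxelMed", "RAYDOSE", "kidneys")
p.lin_ccc(x, y)                      # 0.982 over 20 patients
s = p.compare_methods(b, "VoxelMed", "RAYDOSE", grouping="pooled")["pooled"]
# n=59 pairs, mean -8.1%, limits of agreement [-24.3, 8.0]%
```

i.e. the convolution engine reads on average 8% lower than the Monte Carlo
engine across all organ–patient pairs, with high concordance.

A CLI mirrors the library: `prrtdose phantom-gen`, `tia`, `dose-voxel`,
`dose-organ`, `bed`, `compare`, `run-study`, `reproduce` (see
`prrtdose --help`).

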