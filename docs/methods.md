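# Methods

`prrtdose` implements and cross-checks the two dose-calculation strategies in
routine use for ¹⁷⁷Lu peptide receptor radionuclide therapy (PRRT) —
organ-level MIRD dosimetry with reference S factors, and voxel-level dose
kernel convolution — together with the agreement statistics used to compare
dosimetry methods, and a synthetic-phantom stage that makes the whole chain
testable without clinical images.

## The dosimetric model

Both engines are instances of the MIRD schema: absorbed dose equals
time-integrated activity (TIA, Ã, the number of decays in a source region)
times an S factor (dose per decay).

**Organ level.** `organ_dose` computes
`D_target = Σ_source Ã_source · S(target ← source)` from a user-supplied
S-factor table with reference organ masses. The self-dose term is rescaled
by `m_ref / m_true` (inverse-mass scaling of the electron-dominated self
dose for ¹⁷⁷Lu); photon cross terms are left at reference-phantom values.
`sphere_dose` covers lesions and phantom inserts with a unit-density sphere:
by default the full non-penetrating energy Δ_np = 0.147 MeV/decay is
absorbed locally (absorbed fraction φ = 1, photons escape), optionally
modulated by a `(mass, φ)` table interpolated in log–log space. Reference
S-factor sets for commercial organ-level programs are proprietary, so the
module is table-driven; none of the packaged statistics depend on absolute
organ S factors.

**Voxel level.** `convolve_dose` evaluates the discrete voxel sum
`D_i = Σ_j Ã_j k(i−j)` by zero-padded FFT multiplication (`fftconvolve`,
linear convolution — wrap-around is impossible by construction); a
direct-sum oracle in the tests pins the FFT path to 1e-9 relative. The
engine supports the "mask before convolution" behaviour that distinguishes
mask-based convolution codes from full-field transport: zeroing Ã outside
the VOI removes cross-irradiation from neighbouring sources, which is why
mask-based results can only be ≤ full-field results voxelwise.

**Kernels.** Published ¹⁷⁷Lu voxel S-value matrices can be loaded from CSV
(`load_kernel_csv`, with optional inversion-symmetry completion and strict
validation). Since no specific matrix is canonical, `build_parametric_kernel`
provides a physically scaled default: the non-penetrating energy is split
between a purely local term and an isotropic Gaussian beta spread
(default σ = 0.6 mm, the mean beta path length in water), and the photon
share of the emitted energy (default 18.3%, i.e. 0.033 of 0.180 MeV/decay)
falls off as `exp(−μr)/4πr²` with μ = 0.012/mm (~200 keV photons in water).
Each term is normalised so the energy deposited inside the kernel support
equals its share; truncation is recorded in `energy_retained_j`, which the
energy-conservation audit uses (1 MBq·s = 1e6 decays throughout). Kernels
are never resampled: their spacing must match the dose grid within 1%
(anisotropic voxels are supported by building the kernel on the same
spacing). The agreement statistics packaged here are deliberately
independent of the absolute kernel values.

**Engine equivalence.** With a purely local kernel
(`local_fraction = 1, photon_fraction = 0`) and uniform activity, the voxel
mean dose equals the sphere-model dose on the same rasterized volume to
numerical precision — the cross-check wired into both the test suite and
`run_phantom_study`. With any energy-conserving spread kernel the voxel
mean falls below the φ = 1 organ value (edge leakage only removes energy
from the VOI), reproducing the systematic organ-level-high direction, and
the deficit grows with the surface-to-volume ratio of the region — largest
for a torus, then elongated solids, smallest for a sphere.

## Time-integrated activity

`integrate_tia` follows the clinical convolution-workflow convention:
trapezoid between the first and last acquisition, then an analytic tail
`A(t_N)/λ` using either the fitted effective decay rate or the physical
constant (¹⁷⁷Lu T½ = 6.647 d = 159.528 h, stored in `data/nuclides.yaml`).
For the interval between injection and the first scan no published
convention exists; the default head term is a triangle from (0, 0) to
(t₁, A₁) — injection at t = 0 implies zero initial organ activity — with
`constant` and `none` selectable. Single-scan (phantom) curves use
Ã = A/λ_phys with no head term.

Fitting is deterministic: rate seeds come from log-linear regression on the
terminal samples (no random restarts), two-point curves use the closed
form, and the bi-exponential fit leaves amplitude signs free so an uptake
phase fits naturally; failed or non-decaying fits are flagged and fall back
to the mono-exponential. Per-voxel maps use the *organ* terminal rate for
their tails (per-voxel rate fits are noise-dominated); `organwise` mode
instead integrates the organ curve and redistributes Ã proportionally to
the time-averaged voxel activity, conserving the organ total by
construction.

## Renal BED

`renal_bed` applies the linear-quadratic model with exponentially decaying
dose rate: `BED = D[1 + T_rep/(T_rep + T_eff) · D/(α/β)]` per cycle, summed
over cycles, with cycle-specific parameters supported (a fixed population
T_eff or per-cycle fitted values both work). Defaults α/β = 2.6 Gy and
T_rep = 2.8 h are literature values for kidney, kept in an editable config,
not fitted here. Cumulative limits: 46 Gy BED, or 28 Gy with renal risk
factors.

## Agreement statistics

`lin_ccc` uses Lin's original estimator with population (1/n) moments:
`ρ_c = 2s_xy / (s_x² + s_y² + (x̄−ȳ)²)`. Confidence intervals use the
Fisher z transform with Lin's asymptotic variance (reported for context).
`relative_difference` fixes the convention 100·(a−b)/b with b the reference
method. `bland_altman` reports mean ± 1.96 SD limits of agreement on
percentage (of reference or of pair mean) or absolute differences. All
statistics delete missing pairs pairwise; missing doses are NaN-flagged,
never zero-filled. Pooled summaries are computed over all organ–patient
pairs, which makes the pooled mean the pair-count-weighted mean of the
per-organ means (a tested invariant).

## Synthetic data

The phantom generator emulates the three physical phantom classes used to
benchmark dosimetry software: a homogeneous 5640 ml cylinder at 0.25
MBq/ml; a 6713 ml cylinder with toroidal/ellipsoidal/pear/tubular inserts
(2.8–31.2 ml) at 1.53 MBq/ml in cold water; and an anthropomorphic phantom
(organ inserts at 0.53–8.34 MBq/ml over a 0.03 MBq/ml background). Shapes
are solved from target volume with fixed aspect ratios, since only volumes
and equivalent diameters of the physical inserts are documented: torus
major:minor radius 3:1; tube length:diameter 4:1; cylinder height =
diameter; ellipsoid default semi-axes 2:1:1 (overridable per recipe); pear
as the union of two spheres with radius ratio 1.6:1 and center separation
1.3× the body radius (chosen so the neck protrudes and the surface-to-volume
ratio exceeds the equal-volume ellipsoid's, as a pear shape should). Only
the volume and the qualitative shape class influence any packaged result.

Rasterization uses voxel-center world coordinates (0-based indices,
`world = origin + (index+0.5)·spacing`) and includes a voxel when at least
half of its supersampled points (default 3³) fall inside the analytic
surface; odd supersampling avoids the tie-inclusion bias of even grids.
Rasterized volumes converge to the analytic volume as spacing shrinks
(tested at 4/2/1 mm). Default test grids are 2 mm isotropic, finer than the
clinical 4.8 mm reconstruction so the geometry effects stay resolvable on
small study volumes.

`simulate_spect` is a degradation stand-in, not a projector: an isotropic
Gaussian PSF (activity-conserving up to boundary truncation) plus optional
Poisson resampling of voxel counts at a configurable counts-per-MBq
calibration. It reproduces partial-volume recovery loss (recovery
coefficient < 1 for small objects) but none of the attenuation, scatter,
reconstruction-iteration or registration artefacts of real SPECT; passing
tests therefore validate the dosimetry chain, not quantitative SPECT
imaging.

`simulate_patient_tacs` draws per-organ curves
`A(t) = A₀(e^(−λ_w t) − e^(−λ_u t))` on the clinical 1/4/24/44/72 h
schedule. Defaults (kidneys 150 MBq peak scale, T_eff,washout 55 h; liver
250 MBq, 65 h; spleen 100 MBq, 70 h; uptake half-times 1–1.5 h) represent a
~4.4 GBq ¹⁷⁷Lu-DOTATOC administration with effective half-lives in the
clinically reported range; inter-patient variability is log-normal with
unit mean (CV 0.3 on amplitudes, 0.2 on rates). The washout rate is floored
at the physical decay constant.

## Reference-study tables and what is (not) reproducible

`prrtdose.data` packages transcriptions of the published per-patient mean
organ doses (Gy/GBq) of a 50-patient sample (two methods) and a 20-patient
sample (four methods, including the convolution engine re-run with the
Monte Carlo code's effective half-life), plus the per-region phantom mean
doses, with SHA-256 checksums. `reproduce_reference_study` recomputes Lin's
CCCs, pooled percentage differences and per-insert relative differences
from these tables and flags each against the published value.

Two published Sample A CCCs (spleen 0.85, kidneys 0.55) are *not*
recoverable from the printed per-patient table, which yields 0.970 and
0.937 under any moment convention; the original computation evidently used
unrounded or differently scaled underlying data, and the same table is
internally inconsistent with the published direction of the Sample A mean
difference. The reproduction report keeps these rows flagged as failing
rather than substituting the published numbers. The absolute phantom doses
are likewise not reproducible from first principles here (they depend on
unpublished reconstructed images and S-value matrices); only their printed
values and the qualitative geometry ordering are used.

## Numerical choices and limitations

- FFT convolution in float64; round-off negatives (≲1e-16 of the maximum)
  are clipped to zero after convolution.
- DVHs use 256 uniform bins from 0 to the VOI maximum, edges inclusive on
  the left; V(0) = 1 by definition.
- Negative fitted activities are clamped to zero for integration with a
  logged warning; degenerate fits fall back deterministically.
- Overlapping recipe shapes resolve last-listed-wins (inserts are listed
  after their container).
- No kernel resampling, no DICOM-RT export, no Monte Carlo transport, no
  image registration, no partial-volume correction (configuration hook
  only); SPECT projection/reconstruction is out of scope.
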