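"""Synthetic voxel phantoms and patient-like time-activity curves.

This module builds the test-bench inputs for the dosimetry engines:

* analytic shapes (sphere, cylinder, ellipsoid, torus, pear, tube)
  rasterized onto voxel grids with a supersampled inclusion rule,
* activity painting per labelled region (MBq/ml),
* a SPECT-like degradation stage (Gaussian PSF blur + optional Poisson
  count noise) emulating the partial-volume behaviour of reconstructed
  emission images — the acquisition/reconstruction chain itself is not
  modelled,
* simulated organ time-activity curves with uptake-washout kinetics and
  log-normal inter-patient variability, sampled on the clinical
  1/4/24/44/72 h post-injection schedule.

Shapes are parameterized by target volume: free dimensions are solved from
fixed aspect ratios (torus major:minor radius 3:1, tube length:diameter 4:1,
cylinder height = diameter, pear = two fused spheres with radius ratio
1.6:1) so the analytic volume equals the requested volume exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage

from .nuclides import get_nuclide
from .tia import TimeActivityCurve

logger = logging.getLogger(__name__)

GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: pear = union of two spheres, larger:smaller radius ratio and the
#: center separation as a fraction of the larger radius (see ShapeSpec).
PEAR_RADIUS_RATIO = 1.6
PEAR_SEPARATION = 1.3
TORUS_ASPECT = 3.0       # major radius / minor radius
TUBE_LENGTH_TO_DIAMETER = 4.0

SHAPE_KINDS = ("sphere", "cylinder", "ellipsoid", "torus", "pear", "tube")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice.

    World coordinates are voxel-center based: ``world = origin +
    (index + 0.5) * spacing`` with 0-based indices.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]  # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(d * s for d, s in zip(self.dims, self.spacing))

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.dims[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = [o + 0.5 * s for o, s in zip(self.origin, self.spacing)]
        return aff

    @classmethod
    def centered(cls, extent_mm: Sequence[float],
                 spacing: float | Sequence[float]) -> "VoxelGrid":
        """Grid covering ``extent_mm`` symmetrically around the world origin."""
        sp = (spacing,) * 3 if np.isscalar(spacing) else tuple(spacing)
        dims = tuple(int(math.ceil(e / s)) for e, s in zip(extent_mm, sp))
        origin = tuple(-d * s / 2.0 for d, s in zip(dims, sp))
        return cls(dims=dims, spacing=tuple(float(s) for s in sp), origin=origin)


@dataclass
class VoiMask:
    """Integer label volume; 0 is background, labels are exclusive."""

    grid: VoxelGrid
    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != tuple(self.grid.dims):
            raise ValueError("label array shape does not match grid dims")
        present = set(np.unique(self.labels).tolist())
        for lab in self.label_names:
            if lab != 0 and lab not in present:
                raise ValueError(f"named label {lab} missing from array")

    def label_for(self, name: str) -> int:
        for lab, nm in self.label_names.items():
            if nm == name:
                return lab
        raise KeyError(f"no label named {name!r}")

    def voxel_count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def volume_ml(self, label: int) -> float:
        return self.voxel_count(label) * self.grid.voxel_volume_ml

    def surface_to_volume(self, label: int) -> float:
        """Exposed-face surface area / volume (1/mm), by face counting."""
        m = self.labels == label
        if not m.any():
            raise ValueError(f"label {label} is empty")
        area = 0.0
        sx, sy, sz = self.grid.spacing
        face = {0: sy * sz, 1: sx * sz, 2: sx * sy}
        for ax in range(3):
            pad = np.pad(m, [(1, 1) if a == ax else (0, 0) for a in range(3)])
            diff = np.diff(pad.astype(np.int8), axis=ax)
            area += np.count_nonzero(diff) * face[ax]
        return area / (self.voxel_count(label) * self.grid.voxel_volume_mm3)


@dataclass
class ActivityImage:
    """3D activity-concentration image (MBq/ml) at a known acquisition time."""

    grid: VoxelGrid
    concentration: np.ndarray
    time_post_injection_h: float = 0.0
    nuclide: str = "Lu-177"

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.concentration.shape != tuple(self.grid.dims):
            raise ValueError("concentration shape does not match grid dims")
        if np.any(self.concentration < 0):
            raise ValueError("negative activity concentration")
        if not np.all(np.isfinite(self.concentration)):
            raise ValueError("non-finite activity concentration")

    @property
    def total_activity_mbq(self) -> float:
        return float(self.concentration.sum() * self.grid.voxel_volume_ml)


@dataclass(frozen=True)
class ShapeSpec:
    """Analytic shape with its free dimensions solved from target volume."""

    kind: str
    target_volume_ml: float
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = ""
    parameters: dict | None = None

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.target_volume_ml <= 0:
            raise ValueError("target_volume_ml must be > 0")

    @property
    def equivalent_diameter_mm(self) -> float:
        """Diameter of the equal-volume sphere, (6V/pi)^(1/3)."""
        v_mm3 = self.target_volume_ml * 1000.0
        return (6.0 * v_mm3 / math.pi) ** (1.0 / 3.0)

    def solved(self) -> dict:
        """Solve shape dimensions (mm) so the analytic volume matches."""
        v = self.target_volume_ml * 1000.0  # mm^3
        p = dict(self.parameters or {})
        kind = self.kind
        if kind == "sphere":
            return {"radius": (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)}
        if kind == "cylinder":
            if "radius" in p and "height" in p:
                return {"radius": float(p["radius"]), "height": float(p["height"])}
            # height = diameter unless both given
            r = (v / (2.0 * math.pi)) ** (1.0 / 3.0)
            return {"radius": r, "height": 2.0 * r}
        if kind == "ellipsoid":
            if "semi_axes_mm" in p:
                a, b, c = (float(x) for x in p["semi_axes_mm"])
            else:
                a, b, c = 2.0, 1.0, 1.0  # prolate default, long axis x
            scale = (v / (4.0 / 3.0 * math.pi * a * b * c)) ** (1.0 / 3.0)
            return {"semi_axes": (a * scale, b * scale, c * scale)}
        if kind == "torus":
            aspect = float(p.get("aspect", TORUS_ASPECT))
            if aspect <= 1.0:
                raise ValueError("torus aspect (R/r) must exceed 1")
            # V = 2 pi^2 R r^2 with R = aspect * r
            r = (v / (2.0 * math.pi**2 * aspect)) ** (1.0 / 3.0)
            return {"major_radius": aspect * r, "minor_radius": r}
        if kind == "tube":
            ratio = float(p.get("length_to_diameter", TUBE_LENGTH_TO_DIAMETER))
            # V = pi r^2 L, L = 2 r ratio
            r = (v / (2.0 * math.pi * ratio)) ** (1.0 / 3.0)
            return {"radius": r, "length": 2.0 * r * ratio}
        if kind == "pear":
            ratio = float(p.get("radius_ratio", PEAR_RADIUS_RATIO))
            sep = float(p.get("separation", PEAR_SEPARATION))
            unit = _sphere_union_volume(1.0, 1.0 / ratio, sep)
            s = (v / unit) ** (1.0 / 3.0)
            return {"r_body": s, "r_neck": s / ratio, "separation": sep * s}
        raise AssertionError(kind)

    def bounding_radius_mm(self) -> float:
        d = self.solved()
        if self.kind == "sphere":
            return d["radius"]
        if self.kind == "cylinder":
            return math.hypot(d["radius"], d["height"] / 2.0)
        if self.kind == "ellipsoid":
            return max(d["semi_axes"])
        if self.kind == "torus":
            return math.hypot(d["major_radius"] + d["minor_radius"],
                              d["minor_radius"])
        if self.kind == "tube":
            return math.hypot(d["radius"], d["length"] / 2.0)
        if self.kind == "pear":
            return max(d["r_body"], d["separation"] + d["r_neck"])
        raise AssertionError(self.kind)

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Inside test in shape-local coordinates (center subtracted)."""
        d = self.solved()
        if self.kind == "sphere":
            return x * x + y * y + z * z <= d["radius"] ** 2
        if self.kind in ("cylinder", "tube"):
            r = d["radius"]
            half = (d["height"] if self.kind == "cylinder" else d["length"]) / 2.0
            return (x * x + y * y <= r * r) & (np.abs(z) <= half)
        if self.kind == "ellipsoid":
            a, b, c = d["semi_axes"]
            return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
        if self.kind == "torus":
            big, small = d["major_radius"], d["minor_radius"]
            rho = np.sqrt(x * x + y * y)
            return (rho - big) ** 2 + z * z <= small**2
        if self.kind == "pear":
            in_body = x * x + y * y + z * z <= d["r_body"] ** 2
            dz = z - d["separation"]
            in_neck = x * x + y * y + dz * dz <= d["r_neck"] ** 2
            return in_body | in_neck
        raise AssertionError(self.kind)


def _sphere_union_volume(r1: float, r2: float, dist: float) -> float:
    """Volume of the union of two spheres with center distance ``dist``."""
    v1 = 4.0 / 3.0 * math.pi * r1**3
    v2 = 4.0 / 3.0 * math.pi * r2**3
    if dist >= r1 + r2:
        return v1 + v2
    if dist <= abs(r1 - r2):
        return max(v1, v2)
    lens = (math.pi * (r1 + r2 - dist) ** 2
            * (dist**2 + 2.0 * dist * (r1 + r2) - 3.0 * (r1 - r2) ** 2)
            / (12.0 * dist))
    return v1 + v2 - lens


# ---------------------------------------------------------------------------
# rasterization and painting
# ---------------------------------------------------------------------------

def rasterize_shape(spec: ShapeSpec, grid: VoxelGrid,
                    supersample: int = 3) -> VoiMask:
    """Rasterize one shape to a binary mask (label 1).

    A voxel is included when at least half of its ``supersample**3``
    sub-points lie inside the analytic surface (center rule for
    ``supersample=1``). Raises if the shape does not fit inside the grid.
    """
    labels = np.zeros(grid.dims, dtype=np.int16)
    _rasterize_into(spec, grid, labels, 1, int(supersample))
    name = spec.name or spec.kind
    return VoiMask(grid=grid, labels=labels, label_names={1: name})


def rasterize_phantom(specs: Sequence[ShapeSpec], grid: VoxelGrid,
                      supersample: int = 3) -> VoiMask:
    """Rasterize several shapes into one exclusive label volume.

    Shapes are painted in order and later shapes overwrite earlier labels
    (inserts are listed after the container they sit in). Labels are
    1..len(specs) in input order.
    """
    labels = np.zeros(grid.dims, dtype=np.int16)
    names: dict[int, str] = {}
    for i, spec in enumerate(specs, start=1):
        sub = np.zeros(grid.dims, dtype=np.int16)
        _rasterize_into(spec, grid, sub, i, int(supersample))
        clash = (labels > 0) & (sub > 0)
        if clash.any():
            logger.debug("shape %s overwrites %d voxels of earlier labels",
                         spec.name or spec.kind, int(clash.sum()))
        labels[sub > 0] = i
        names[i] = spec.name or f"{spec.kind}_{i}"
    return VoiMask(grid=grid, labels=labels, label_names=names)


def _rasterize_into(spec: ShapeSpec, grid: VoxelGrid, labels: np.ndarray,
                    label: int, supersample: int) -> None:
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    rad = spec.bounding_radius_mm()
    lo_w = [c - rad for c in spec.center_mm]
    hi_w = [c + rad for c in spec.center_mm]
    for ax in range(3):
        if (lo_w[ax] < grid.origin[ax]
                or hi_w[ax] > grid.origin[ax] + grid.extent_mm[ax]):
            raise ValueError(
                f"shape {spec.name or spec.kind} exceeds grid bounds on "
                f"axis {ax}: [{lo_w[ax]:.1f}, {hi_w[ax]:.1f}] mm")
    # index bounding box
    lo = [max(0, int((lo_w[ax] - grid.origin[ax]) / grid.spacing[ax]) - 1)
          for ax in range(3)]
    hi = [min(grid.dims[ax],
              int((hi_w[ax] - grid.origin[ax]) / grid.spacing[ax]) + 2)
          for ax in range(3)]
    axes = [grid.axis_centers(ax)[lo[ax]:hi[ax]] - spec.center_mm[ax]
            for ax in range(3)]
    s = supersample
    offs = [(np.arange(s) + 0.5) / s - 0.5 for _ in range(3)]
    counts = np.zeros([len(a) for a in axes], dtype=np.int32)
    for ox in offs[0] * grid.spacing[0]:
        for oy in offs[1] * grid.spacing[1]:
            for oz in offs[2] * grid.spacing[2]:
                counts += spec.contains(
                    (axes[0] + ox)[:, None, None],
                    (axes[1] + oy)[None, :, None],
                    (axes[2] + oz)[None, None, :])
    inside = counts * 2 >= s**3  # at least half the sub-points
    view = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    view[inside] = label


def paint_activity(mask: VoiMask,
                   per_label_concentration: Mapping[int | str, float],
                   background: float = 0.0,
                   time_post_injection_h: float = 0.0,
                   nuclide: str = "Lu-177") -> ActivityImage:
    """Assign an activity concentration (MBq/ml) to each labelled region."""
    if background < 0:
        raise ValueError("background concentration must be >= 0")
    conc = np.full(mask.grid.dims, float(background))
    for key, c in per_label_concentration.items():
        if c < 0:
            raise ValueError(f"negative concentration for label {key!r}")
        lab = mask.label_for(key) if isinstance(key, str) else int(key)
        if lab not in mask.label_names and lab != 0:
            raise KeyError(f"unknown label {key!r}")
        conc[mask.labels == lab] = float(c)
    return ActivityImage(grid=mask.grid, concentration=conc,
                         time_post_injection_h=time_post_injection_h,
                         nuclide=nuclide)


# ---------------------------------------------------------------------------
# SPECT-like degradation
# ---------------------------------------------------------------------------

def simulate_spect(image: ActivityImage, psf_fwhm_mm: float,
                   noise_seed: int | None = None,
                   counts_per_mbq: float = 200.0) -> ActivityImage:
    """Blur with an isotropic Gaussian PSF and optionally add Poisson noise.

    The blur conserves total activity up to boundary truncation; noise
    resamples voxel counts at ``counts_per_mbq`` counts per MBq of voxel
    activity (a detector-calibration stand-in), then converts back to
    concentration. ``psf_fwhm_mm = 0`` with no seed returns the input
    unchanged.
    """
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be >= 0")
    conc = image.concentration
    if psf_fwhm_mm > 0:
        sigma_vox = [psf_fwhm_mm * GAUSS_FWHM_TO_SIGMA / s
                     for s in image.grid.spacing]
        conc = ndimage.gaussian_filter(conc, sigma=sigma_vox, mode="constant")
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        mean_counts = conc * image.grid.voxel_volume_ml * counts_per_mbq
        conc = rng.poisson(mean_counts).astype(float) / (
            image.grid.voxel_volume_ml * counts_per_mbq)
    return ActivityImage(grid=image.grid, concentration=conc,
                         time_post_injection_h=image.time_post_injection_h,
                         nuclide=image.nuclide)


# ---------------------------------------------------------------------------
# patient time-activity curves
# ---------------------------------------------------------------------------

#: clinical acquisition schedule, hours post injection
DEFAULT_SCHEDULE_H = (1.0, 4.0, 24.0, 44.0, 72.0)

#: uptake-washout kinetics A(t) = A0 (exp(-lw t) - exp(-lu t)) per organ:
#: peak-scale amplitude (MBq), effective washout half-life (h, includes
#: physical decay), uptake half-life (h). Amplitudes reflect a ~4.4 GBq
#: 177Lu-DOTATOC administration with a few percent organ uptake.
DEFAULT_KINETICS: dict[str, dict[str, float]] = {
    "kidneys": {"a0_mbq": 150.0, "t_washout_h": 55.0, "t_uptake_h": 1.0},
    "liver": {"a0_mbq": 250.0, "t_washout_h": 65.0, "t_uptake_h": 1.5},
    "spleen": {"a0_mbq": 100.0, "t_washout_h": 70.0, "t_uptake_h": 1.0},
}


def simulate_patient_tacs(n_patients: int,
                          organs: Sequence[str] | None = None,
                          schedule_h: Sequence[float] = DEFAULT_SCHEDULE_H,
                          kinetics: Mapping[str, Mapping[str, float]] | None = None,
                          amplitude_cv: float = 0.3,
                          rate_cv: float = 0.2,
                          seed: int = 0,
                          nuclide: str = "Lu-177",
                          ) -> dict[int, dict[str, TimeActivityCurve]]:
    """Simulate per-organ time-activity samples for a patient cohort.

    Each organ follows ``A(t) = A0 (exp(-lw t) - exp(-lu t))`` with
    log-normal inter-patient variation of ``A0`` and of both rate constants
    (coefficients of variation ``amplitude_cv`` and ``rate_cv``; zero gives
    an identical cohort). The washout rate is floored at the physical decay
    constant — biological clearance can only speed washout up.
    Returns ``{patient_index: {organ: TimeActivityCurve}}``.
    """
    times = np.asarray(schedule_h, dtype=float)
    if times.ndim != 1 or len(times) < 1:
        raise ValueError("schedule must be a non-empty 1D sequence")
    if np.any(times <= 0) or np.any(np.diff(times) <= 0):
        raise ValueError("schedule times must be strictly increasing and > 0")
    kin = dict(kinetics or DEFAULT_KINETICS)
    organs = list(organs) if organs is not None else list(kin)
    lam_phys = get_nuclide(nuclide).decay_constant_per_h
    rng = np.random.default_rng(seed)
    out: dict[int, dict[str, TimeActivityCurve]] = {}
    for p in range(n_patients):
        out[p] = {}
        for organ in organs:
            k = kin[organ]
            a0 = k["a0_mbq"] * _lognormal_factor(rng, amplitude_cv)
            lw = math.log(2.0) / k["t_washout_h"] * _lognormal_factor(rng, rate_cv)
            lu = math.log(2.0) / k["t_uptake_h"] * _lognormal_factor(rng, rate_cv)
            lw = max(lw, lam_phys)
            if lu <= lw:
                lu = 10.0 * lw
            act = a0 * (np.exp(-lw * times) - np.exp(-lu * times))
            out[p][organ] = TimeActivityCurve(
                region_id=f"patient{p:03d}/{organ}",
                times_h=times, activities_mbq=np.maximum(act, 0.0),
                nuclide=nuclide)
    return out


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean log-normal multiplier with coefficient of variation cv."""
    if cv == 0.0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


# ---------------------------------------------------------------------------
# recipes and I/O
# ---------------------------------------------------------------------------

def load_phantom_recipe(path: str | Path) -> dict:
    """Load a phantom recipe YAML and build its shape specs.

    Returns a dict with keys ``name``, ``nuclide``, ``scan_time_h``,
    ``specs`` (container first, then inserts, in label order 1..N) and
    ``concentrations`` (region name -> MBq/ml).
    """
    raw = yaml.safe_load(Path(path).read_text())
    specs: list[ShapeSpec] = []
    conc: dict[str, float] = {}
    for entry in [raw["container"], *raw.get("inserts", [])]:
        spec = ShapeSpec(kind=entry["kind"],
                         target_volume_ml=float(entry["volume_ml"]),
                         center_mm=tuple(entry.get("center_mm", (0, 0, 0))),
                         name=entry["name"],
                         parameters=entry.get("parameters"))
        specs.append(spec)
        conc[entry["name"]] = float(entry["concentration_mbq_per_ml"])
    return {"name": raw["name"], "nuclide": raw.get("nuclide", "Lu-177"),
            "scan_time_h": float(raw.get("scan_time_h", 1.0)),
            "specs": specs, "concentrations": conc}


def write_nifti(path: str | Path, grid: VoxelGrid, array: np.ndarray) -> None:
    """Write a 3D array on a grid as NIfTI (float data, integer labels kept)."""
    arr = np.asarray(array)
    dtype = np.int16 if np.issubdtype(arr.dtype, np.integer) else np.float32
    img = nib.Nifti1Image(arr.astype(dtype), grid.affine())
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[VoxelGrid, np.ndarray]:
    """Read a NIfTI volume back to (grid, array)."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) - 0.5 * spacing[i] for i in range(3))
    grid = VoxelGrid(dims=arr.shape, spacing=spacing, origin=origin)
    return grid, arr
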