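"""Time-integrated activity (TIA): curve fitting and integration.

Converts time-activity samples into the number of decays Ã (MBq·s) that
drives every MIRD-style dose estimate. The integration rule follows the
dose-kernel-convolution workflow: trapezoid between the first and the last
acquisition, analytic extrapolation beyond (effective half-life from a fit,
or the physical half-life), and a configurable head term before the first
scan (the injection-to-first-scan interval, for which no single convention
exists — default is a triangle from (0, 0) to (t1, A1)).

Voxel-level maps either integrate each voxel's own samples (with the
organ-level terminal rate for the tail, which is robust to voxel noise) or
integrate the whole-organ curve and redistribute Ã proportionally to the
time-averaged voxel activity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .nuclides import get_nuclide

if TYPE_CHECKING:  # pragma: no cover
    from .phantoms import ActivityImage, VoiMask, VoxelGrid

logger = logging.getLogger(__name__)

HEAD_MODES = ("triangle", "constant", "none")
TAIL_MODES = ("effective", "physical")


@dataclass
class TimeActivityCurve:
    """Activity samples A(t) for one region (times in h, activity in MBq)."""

    region_id: str
    times_h: np.ndarray
    activities_mbq: np.ndarray
    nuclide: str = "Lu-177"

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.activities_mbq = np.asarray(self.activities_mbq, dtype=float)
        if self.times_h.ndim != 1 or len(self.times_h) < 1:
            raise ValueError("need at least one (time, activity) sample")
        if len(self.times_h) != len(self.activities_mbq):
            raise ValueError("times and activities differ in length")
        if np.any(self.times_h <= 0) or np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing and > 0")
        if np.any(self.activities_mbq < 0):
            raise ValueError("activities must be >= 0")

    def __len__(self) -> int:
        return len(self.times_h)


@dataclass
class DecayModel:
    """Sum-of-exponentials fit A(t) = sum_i a_i exp(-l_i t).

    Rates in 1/h, positive; amplitudes may be negative (uptake phase).
    The terminal (smallest) positive-amplitude rate defines the effective
    half-life.
    """

    kind: str  # 'monoexp' | 'biexp' | 'linear_uptake_monoexp'
    amplitudes_mbq: tuple[float, ...]
    rates_per_h: tuple[float, ...]
    non_decaying: bool = False
    fell_back: bool = False

    def __post_init__(self) -> None:
        if len(self.amplitudes_mbq) != len(self.rates_per_h):
            raise ValueError("amplitudes and rates differ in length")

    @property
    def terminal_rate_per_h(self) -> float:
        """Slowest rate among components with positive amplitude."""
        pos = [r for a, r in zip(self.amplitudes_mbq, self.rates_per_h) if a > 0]
        return min(pos) if pos else min(self.rates_per_h)

    @property
    def t_eff_h(self) -> float:
        return math.log(2.0) / self.terminal_rate_per_h

    def __call__(self, t_h: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_h, dtype=float)
        out = sum(a * np.exp(-r * t)
                  for a, r in zip(self.amplitudes_mbq, self.rates_per_h))
        return out


@dataclass
class TIAResult:
    """Ã split into head (0->t1), trapezoid (t1->tN) and tail (tN->inf)."""

    region_id: str
    tia_mbq_s: float
    head_mbq_s: float
    trapezoid_mbq_s: float
    tail_mbq_s: float
    tail_mode: str
    head_mode: str

    def __post_init__(self) -> None:
        parts = self.head_mbq_s + self.trapezoid_mbq_s + self.tail_mbq_s
        if not math.isclose(self.tia_mbq_s, parts, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("tia must equal head + trapezoid + tail")


@dataclass
class TIAMap:
    """Per-voxel time-integrated activity (MBq·s) on a grid."""

    grid: "VoxelGrid"
    tia: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tia = np.asarray(self.tia, dtype=float)
        if self.tia.shape != tuple(self.grid.dims):
            raise ValueError("tia shape does not match grid dims")
        if np.any(self.tia < 0) or not np.all(np.isfinite(self.tia)):
            raise ValueError("tia must be finite and >= 0")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _loglinear_rate(times: np.ndarray, act: np.ndarray) -> tuple[float, float]:
    """Log-linear regression seed (amplitude, rate) from positive samples."""
    pos = act > 0
    if pos.sum() < 2:
        return float(act.max(initial=1.0)), 0.01
    slope, intercept = np.polyfit(times[pos], np.log(act[pos]), 1)
    return float(np.exp(intercept)), float(-slope)


def fit_monoexp(curve: TimeActivityCurve) -> DecayModel:
    """Least-squares mono-exponential fit A0 exp(-lambda t).

    A non-decaying dataset (fitted lambda <= 0) is returned flagged with the
    physical decay rate substituted, so callers can decide how to proceed.
    """
    t, a = curve.times_h, curve.activities_mbq
    if len(t) < 2 or np.count_nonzero(a > 0) < 2:
        raise ValueError("mono-exponential fit needs >= 2 positive samples")
    a0_seed, lam_seed = _loglinear_rate(t, a)
    if len(t) == 2 and np.all(a > 0):
        # exact two-point solution
        lam = math.log(a[0] / a[1]) / (t[1] - t[0])
        a0 = a[0] * math.exp(lam * t[0])
    else:
        try:
            popt, _ = curve_fit(
                lambda tt, a0, lam: a0 * np.exp(-lam * tt), t, a,
                p0=[a0_seed, max(lam_seed, 1e-6)], maxfev=10000)
            a0, lam = float(popt[0]), float(popt[1])
        except RuntimeError:
            a0, lam = a0_seed, lam_seed
    if lam <= 0:
        lam_phys = get_nuclide(curve.nuclide).decay_constant_per_h
        logger.warning("non-decaying fit for %s (lambda=%.3g/h); flagged",
                       curve.region_id, lam)
        return DecayModel("monoexp", (a0,), (lam_phys,), non_decaying=True)
    return DecayModel("monoexp", (a0,), (lam,))


def fit_biexp(curve: TimeActivityCurve) -> DecayModel:
    """Least-squares bi-exponential fit a1 exp(-l1 t) + a2 exp(-l2 t).

    Amplitude signs are unconstrained so an uptake phase (negative fast
    component) can be represented. Falls back to the mono-exponential fit,
    flagged, when the optimisation fails or degenerates.
    """
    t, a = curve.times_h, curve.activities_mbq
    if len(t) < 4:
        raise ValueError("bi-exponential fit needs >= 4 samples")
    # seed slow component from the terminal half of the samples
    half = len(t) // 2
    a_slow, l_slow = _loglinear_rate(t[half:], a[half:])
    l_slow = max(l_slow, 1e-4)
    resid0 = a[0] - a_slow * math.exp(-l_slow * t[0])
    p0 = [a_slow, l_slow, resid0, 10.0 * l_slow]

    def model(tt, a1, l1, a2, l2):
        return a1 * np.exp(-l1 * tt) + a2 * np.exp(-l2 * tt)

    try:
        popt, _ = curve_fit(
            model, t, a, p0=p0,
            bounds=([-np.inf, 1e-7, -np.inf, 1e-7],
                    [np.inf, np.inf, np.inf, np.inf]),
            maxfev=20000)
        a1, l1, a2, l2 = (float(v) for v in popt)
    except (RuntimeError, ValueError):
        mono = fit_monoexp(curve)
        logger.warning("bi-exponential fit failed for %s; mono fallback",
                       curve.region_id)
        return DecayModel("biexp", mono.amplitudes_mbq, mono.rates_per_h,
                          non_decaying=mono.non_decaying, fell_back=True)
    # order components slow-first for readability
    if l1 > l2:
        a1, l1, a2, l2 = a2, l2, a1, l1
    model_out = DecayModel("biexp", (a1, a2), (l1, l2))
    if model_out.terminal_rate_per_h <= 0 or not np.isfinite([a1, l1, a2, l2]).all():
        mono = fit_monoexp(curve)
        return DecayModel("biexp", mono.amplitudes_mbq, mono.rates_per_h,
                          non_decaying=mono.non_decaying, fell_back=True)
    return model_out


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate_tia(curve: TimeActivityCurve,
                  tail_mode: str = "physical",
                  head_mode: str = "triangle",
                  model: DecayModel | None = None) -> TIAResult:
    """Integrate a TAC to Ã (MBq·s): head + trapezoid + analytic tail.

    ``tail_mode='effective'`` requires a fitted model with a positive
    terminal rate; ``'physical'`` uses the nuclide decay constant. A
    single-sample curve is only allowed with ``head_mode='none'`` and the
    physical tail (the single-scan phantom convention: Ã = A/lambda).
    """
    if head_mode not in HEAD_MODES:
        raise ValueError(f"head_mode must be one of {HEAD_MODES}")
    if tail_mode not in TAIL_MODES:
        raise ValueError(f"tail_mode must be one of {TAIL_MODES}")
    t, a = curve.times_h, curve.activities_mbq
    if len(t) == 1 and not (head_mode == "none" and tail_mode == "physical"):
        raise ValueError("single-sample curve requires head_mode='none' "
                         "and tail_mode='physical'")
    lam_tail_h = _tail_rate_per_h(curve, tail_mode, model)
    t_s = t * 3600.0
    head = {"triangle": 0.5 * t_s[0] * a[0],
            "constant": t_s[0] * a[0],
            "none": 0.0}[head_mode]
    trap = float(np.trapezoid(a, t_s)) if len(t) > 1 else 0.0
    tail = float(a[-1]) / (lam_tail_h / 3600.0)
    return TIAResult(region_id=curve.region_id,
                     tia_mbq_s=head + trap + tail, head_mbq_s=head,
                     trapezoid_mbq_s=trap, tail_mbq_s=tail,
                     tail_mode=tail_mode, head_mode=head_mode)


def _tail_rate_per_h(curve: TimeActivityCurve, tail_mode: str,
                     model: DecayModel | None) -> float:
    if tail_mode == "physical":
        return get_nuclide(curve.nuclide).decay_constant_per_h
    if model is None:
        raise ValueError("tail_mode='effective' requires a fitted model")
    lam = model.terminal_rate_per_h
    if lam <= 0 or model.non_decaying:
        raise ValueError("effective tail requires a decaying terminal rate")
    return lam


def voxel_tia_map(image_series: Sequence["ActivityImage"],
                  mask: "VoiMask",
                  mode: str = "voxelwise",
                  tail_mode: str = "physical",
                  head_mode: str = "triangle",
                  labels: Sequence[int] | None = None) -> TIAMap:
    """Build a per-voxel Ã map from a registered activity time series.

    ``mode='voxelwise'`` integrates each voxel's own samples, using the
    whole-organ terminal rate for the tail; ``mode='organwise'`` integrates
    the organ curve and redistributes Ã across the organ's voxels
    proportionally to their time-averaged activity, so the organ total is
    conserved by construction. Regions are processed per mask label
    (including background label 0 if it carries activity).
    """
    if mode not in ("voxelwise", "organwise"):
        raise ValueError("mode must be 'voxelwise' or 'organwise'")
    if not image_series:
        raise ValueError("need at least one activity image")
    grid = image_series[0].grid
    for img in image_series:
        if img.grid != grid:
            raise ValueError("all images must share one grid")
    if tuple(grid.dims) != tuple(mask.grid.dims):
        raise ValueError("mask grid does not match image grid")
    order = np.argsort([img.time_post_injection_h for img in image_series])
    series = [image_series[i] for i in order]
    times = np.array([img.time_post_injection_h for img in series])
    conc = np.stack([img.concentration for img in series])  # [T, nx, ny, nz]
    vox_ml = grid.voxel_volume_ml
    nuclide = series[0].nuclide
    single = len(series) == 1
    if single:
        head_mode = "none"
        if times[0] <= 0:
            # A/lambda tail is independent of the scan time
            times = np.array([1.0])
    tia_arr = np.zeros(grid.dims)
    use_labels = (list(labels) if labels is not None
                  else [int(v) for v in np.unique(mask.labels)])
    for lab in use_labels:
        sel = mask.labels == lab
        if not sel.any():
            continue
        act_vox = conc[:, sel] * vox_ml  # [T, n_vox] MBq
        organ_act = act_vox.sum(axis=1)
        if lab == 0 and not np.any(organ_act > 0):
            continue
        organ_curve = TimeActivityCurve(
            region_id=mask.label_names.get(lab, f"label{lab}"),
            times_h=times, activities_mbq=organ_act, nuclide=nuclide)
        model = (fit_monoexp(organ_curve)
                 if tail_mode == "effective" and not single else None)
        lam_tail_s = _tail_rate_per_h(
            organ_curve, "physical" if single else tail_mode, model) / 3600.0
        t_s = times * 3600.0
        if mode == "voxelwise" or single:
            head = {"triangle": 0.5 * t_s[0] * act_vox[0],
                    "constant": t_s[0] * act_vox[0],
                    "none": 0.0}[head_mode]
            trap = (np.trapezoid(act_vox, t_s, axis=0)
                    if len(t_s) > 1 else 0.0)
            tia_arr[sel] = head + trap + act_vox[-1] / lam_tail_s
        else:
            res = integrate_tia(organ_curve, tail_mode=tail_mode,
                                head_mode=head_mode, model=model)
            weights = (np.trapezoid(act_vox, t_s, axis=0)
                       if len(t_s) > 1 else act_vox[0])
            total = weights.sum()
            if total <= 0:
                continue
            tia_arr[sel] = res.tia_mbq_s * weights / total
    return TIAMap(grid=grid, tia=tia_arr,
                  provenance={"mode": mode, "tail_mode": tail_mode,
                              "head_mode": head_mode})
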