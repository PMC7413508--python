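"""Voxel dose engine: kernels, convolution, DVH, statistics."""

import numpy as np
import pytest

from prrtdose import (ShapeSpec, VoxelGrid, build_parametric_kernel,
                      compute_dvh, convolve_dose, dose_stats, get_nuclide,
                      load_kernel_csv, paint_activity, rasterize_shape,
                      save_kernel_csv, simulate_spect, sphere_dose,
                      voxel_tia_map)
from prrtdose.nuclides import DECAYS_PER_MBQ_S
from prrtdose.tia import TIAMap
from prrtdose.voxeldose import DoseKernel, DoseMap

LU177 = get_nuclide("Lu-177")


def direct_convolution(tia: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Brute-force shifted-accumulate oracle for the voxel MIRD sum."""
    out = np.zeros_like(tia)
    rad = [s // 2 for s in kernel.shape]
    for di in range(-rad[0], rad[0] + 1):
        for dj in range(-rad[1], rad[1] + 1):
            for dk in range(-rad[2], rad[2] + 1):
                v = kernel[di + rad[0], dj + rad[1], dk + rad[2]]
                if v == 0.0:
                    continue
                src = [slice(max(0, -d), min(n, n - d))
                       for d, n in zip((di, dj, dk), tia.shape)]
                dst = [slice(max(0, d), min(n, n + d))
                       for d, n in zip((di, dj, dk), tia.shape)]
                out[tuple(dst)] += v * tia[tuple(src)]
    return out


def tia_map_of(arr: np.ndarray, spacing: float = 2.0) -> TIAMap:
    grid = VoxelGrid(dims=arr.shape, spacing=(spacing,) * 3)
    return TIAMap(grid=grid, tia=arr)


class TestParametricKernel:
    def test_pure_local_kernel_central_value_hand_arithmetic(self):
        # 0.147 MeV/decay deposited in a 4.8 mm cube of water
        kernel = build_parametric_kernel(
            4.8, components={"local_fraction": 1.0, "photon_fraction": 0.0},
            radius_voxels=1)
        mass_kg = 4.8**3 * 1e-6
        expected = 0.147 * 1.602176634e-13 * 1e6 / mass_kg
        center = kernel.values[1, 1, 1]
        assert center == pytest.approx(expected, rel=1e-12)
        assert center == pytest.approx(2.13e-4, rel=2e-3)
        assert np.count_nonzero(kernel.values) == 1
        assert kernel.energy_retained_j == pytest.approx(
            LU177.electron_energy_j)

    def test_no_photons_means_compact_beta_support(self):
        kernel = build_parametric_kernel(
            2.0, components={"photon_fraction": 0.0, "beta_range_mm": 0.6},
            radius_voxels=5)
        nz = np.argwhere(kernel.values > kernel.values.max() * 1e-12)
        assert np.abs(nz - 5).max() <= 2  # within ~3 sigma of the beta range

    def test_energy_retained_monotone_in_radius(self):
        prev = 0.0
        for radius in (1, 2, 4, 6):
            k = build_parametric_kernel(2.0, radius_voxels=radius)
            assert k.energy_retained_j >= prev - 1e-18
            prev = k.energy_retained_j

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            build_parametric_kernel(2.0, components={"local_fraction": 1.4})

    def test_kernel_invariants(self):
        k = build_parametric_kernel(2.0, radius_voxels=3)
        assert k.is_symmetric()
        center = tuple(n // 2 for n in k.values.shape)
        assert k.values[center] == k.values.max()
        # energy audit: sum(S) * m * = retained energy per MBq.s
        assert k.values.sum() * k.voxel_mass_kg == pytest.approx(
            k.energy_retained_j * DECAYS_PER_MBQ_S, rel=1e-12)


class TestKernelCsv:
    def test_round_trip_is_bit_exact(self, tmp_path):
        kernel = build_parametric_kernel(2.0, radius_voxels=2)
        path = tmp_path / "k.csv"
        save_kernel_csv(kernel, path)
        back = load_kernel_csv(path)
        assert np.array_equal(back.values, kernel.values)
        assert back.spacing_mm == kernel.spacing_mm
        assert back.energy_retained_j == kernel.energy_retained_j

    def test_single_row_is_local_deposition(self, tmp_path):
        path = tmp_path / "k.csv"
        path.write_text("# spacing_mm: 4.8 4.8 4.8\n"
                        "di,dj,dk,s_value\n0,0,0,2.13e-4\n")
        k = load_kernel_csv(path)
        assert k.values.shape == (1, 1, 1)
        assert k.values[0, 0, 0] == 2.13e-4

    def test_asymmetric_table_without_flag_rejected(self, tmp_path):
        path = tmp_path / "k.csv"
        path.write_text("# spacing_mm: 2 2 2\ndi,dj,dk,s_value\n"
                        "0,0,0,1.0\n1,0,0,0.5\n")
        with pytest.raises(ValueError, match="symmetric"):
            load_kernel_csv(path)

    def test_symmetric_flag_completes_half_table(self, tmp_path):
        path = tmp_path / "k.csv"
        path.write_text("# spacing_mm: 2 2 2\n# symmetric: true\n"
                        "di,dj,dk,s_value\n0,0,0,1.0\n1,0,0,0.5\n")
        k = load_kernel_csv(path)
        assert k.values[0, 1, 1] == k.values[2, 1, 1] == 0.5

    def test_missing_center_rejected(self, tmp_path):
        path = tmp_path / "k.csv"
        path.write_text("# spacing_mm: 2 2 2\ndi,dj,dk,s_value\n1,0,0,0.5\n")
        with pytest.raises(ValueError, match="center"):
            load_kernel_csv(path)


class TestConvolution:
    def test_delta_kernel_is_elementwise_product(self, rng):
        tia = rng.random((10, 11, 12)) * 1e4
        s0 = 2.5e-4
        kernel = DoseKernel(values=np.full((1, 1, 1), s0),
                            spacing_mm=(2.0, 2.0, 2.0))
        dose = convolve_dose(tia_map_of(tia), kernel)
        assert np.allclose(dose.dose, tia * s0, rtol=1e-12)

    def test_fft_matches_direct_sum_oracle(self, rng):
        kernel = build_parametric_kernel(2.0, radius_voxels=2)
        for shape in ((8, 8, 8), (16, 12, 9), (24, 24, 24)):
            tia = rng.random(shape) * 1e5
            dose = convolve_dose(tia_map_of(tia), kernel)
            oracle = direct_convolution(tia, kernel.values)
            assert np.allclose(dose.dose, oracle, rtol=1e-9, atol=0.0)

    def test_energy_conservation_with_padding(self, rng):
        kernel = build_parametric_kernel(2.0, radius_voxels=3)
        tia = np.zeros((20, 20, 20))
        tia[6:14, 6:14, 6:14] = rng.random((8, 8, 8)) * 1e5
        dose = convolve_dose(tia_map_of(tia), kernel)
        vox_mass = kernel.voxel_mass_kg
        energy_dep = dose.dose.sum() * vox_mass
        energy_src = tia.sum() * DECAYS_PER_MBQ_S * kernel.energy_retained_j
        assert energy_dep == pytest.approx(energy_src, rel=1e-6)

    def test_dose_linear_in_tia(self, rng):
        kernel = build_parametric_kernel(2.0, radius_voxels=2)
        tia = rng.random((12, 12, 12)) * 1e4
        d1 = convolve_dose(tia_map_of(tia), kernel).dose
        d3 = convolve_dose(tia_map_of(3.0 * tia), kernel).dose
        assert np.allclose(d3, 3.0 * d1, rtol=1e-12)

    def test_spacing_mismatch_rejected(self):
        kernel = build_parametric_kernel(4.8, radius_voxels=1)
        with pytest.raises(ValueError, match="spacing"):
            convolve_dose(tia_map_of(np.ones((5, 5, 5)), spacing=2.0), kernel)

    def test_torus_loses_more_than_equal_volume_ellipsoid(self, spread_kernel):
        means = {}
        for kind in ("torus", "ellipsoid"):
            spec = ShapeSpec(kind=kind, target_volume_ml=9.7, name=kind)
            grid = VoxelGrid.centered(
                [2 * spec.bounding_radius_mm() + 40] * 3, 2.0)
            mask = rasterize_shape(spec, grid)
            img = paint_activity(mask, {kind: 1.53})
            tmap = voxel_tia_map([img], mask, tail_mode="physical")
            dose = convolve_dose(tmap, spread_kernel, mask=mask,
                                 mask_mode="mask_before")
            means[kind] = dose_stats(dose, mask, 1)["mean_gy"]
        assert means["torus"] < means["ellipsoid"]

    def test_mask_before_never_exceeds_full_field(self, spread_kernel):
        spec = ShapeSpec(kind="sphere", target_volume_ml=4.0, name="s")
        grid = VoxelGrid.centered([60] * 3, 2.0)
        mask = rasterize_shape(spec, grid)
        img = paint_activity(mask, {"s": 1.0}, background=0.1)
        tmap = voxel_tia_map([img], mask, tail_mode="physical")
        masked = convolve_dose(tmap, spread_kernel, mask=mask,
                               mask_mode="mask_before")
        full = convolve_dose(tmap, spread_kernel, mask_mode="full_field")
        assert np.all(masked.dose <= full.dose + 1e-12)
        assert masked.dose.sum() < full.dose.sum()


class TestDvhAndStats:
    def make_dose(self, values):
        arr = np.asarray(values, dtype=float)
        grid = VoxelGrid(dims=arr.shape, spacing=(2.0, 2.0, 2.0))
        from prrtdose.phantoms import VoiMask
        mask = VoiMask(grid=grid, labels=np.ones(arr.shape, dtype=int),
                       label_names={1: "voi"})
        return DoseMap(grid=grid, dose=arr), mask

    def test_uniform_dose_is_step_function(self):
        dose, mask = self.make_dose(np.full((4, 4, 4), 5.0))
        dvh = compute_dvh(dose, mask, 1, n_bins=10)
        assert dvh.volume_at(0.0) == 1.0
        assert dvh.volume_at(4.99) == 1.0
        assert dvh.cumulative_fraction[-1] == 1.0  # top edge == the dose

    def test_two_level_dose_half_volume_at_midpoint(self):
        arr = np.ones((4, 4, 4))
        arr[:2] = 3.0
        dose, mask = self.make_dose(arr)
        dvh = compute_dvh(dose, mask, 1, n_bins=64)
        assert dvh.volume_at(2.0) == pytest.approx(0.5, abs=0.02)

    def test_mean_recovered_from_dvh_integral(self, rng):
        arr = rng.random((6, 6, 6)) * 10
        dose, mask = self.make_dose(arr)
        dvh = compute_dvh(dose, mask, 1, n_bins=512)
        mean_from_dvh = np.trapezoid(dvh.cumulative_fraction,
                                     dvh.dose_edges_gy)
        assert mean_from_dvh == pytest.approx(arr.mean(), rel=0.01)

    def test_stats_uniform_and_simple_mean(self):
        dose, mask = self.make_dose(np.full((3, 3, 3), 2.0))
        s = dose_stats(dose, mask, 1)
        assert s["sd_gy"] == 0.0 and s["cv_pct"] == 0.0
        arr = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        dose, mask = self.make_dose(arr)
        assert dose_stats(dose, mask, 1)["mean_gy"] == pytest.approx(2.0)

    def test_empty_voi_rejected(self):
        dose, mask = self.make_dose(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            dose_stats(dose, mask, 7)

    def test_blur_increases_cv_of_uniform_cylinder(self):
        spec = ShapeSpec(kind="cylinder", target_volume_ml=30.0, name="c")
        grid = VoxelGrid.centered([80] * 3, 2.0)
        mask = rasterize_shape(spec, grid)
        img = paint_activity(mask, {"c": 1.0})
        blurred = simulate_spect(img, 8.0)
        kernel = build_parametric_kernel(
            2.0, components={"local_fraction": 1.0, "photon_fraction": 0.0},
            radius_voxels=1)
        cvs = {}
        for tag, image in [("sharp", img), ("blurred", blurred)]:
            tmap = voxel_tia_map([image], mask, tail_mode="physical")
            dose = convolve_dose(tmap, kernel)
            cvs[tag] = dose_stats(dose, mask, 1)["cv_pct"]
        assert cvs["sharp"] == pytest.approx(0.0, abs=1e-9)
        assert cvs["blurred"] > 1.0


class TestEngineEquivalence:
    def test_local_kernel_uniform_voi_matches_sphere_model(self, delta_kernel):
        spec = ShapeSpec(kind="sphere", target_volume_ml=8.0, name="s")
        grid = VoxelGrid.centered([50] * 3, 2.0)
        mask = rasterize_shape(spec, grid)
        img = paint_activity(mask, {"s": 2.0})
        tmap = voxel_tia_map([img], mask, tail_mode="physical")
        dose = convolve_dose(tmap, delta_kernel, mask=mask,
                             mask_mode="mask_before")
        stats = dose_stats(dose, mask, 1)
        organ = sphere_dose(float(tmap.tia[mask.labels == 1].sum()),
                            stats["volume_ml"])
        assert stats["mean_gy"] == pytest.approx(organ, rel=1e-9)

    def test_sphere_model_bounds_voxel_mean_for_spread_kernel(
            self, spread_kernel):
        spec = ShapeSpec(kind="sphere", target_volume_ml=8.0, name="s")
        grid = VoxelGrid.centered([80] * 3, 2.0)
        mask = rasterize_shape(spec, grid)
        img = paint_activity(mask, {"s": 2.0})
        tmap = voxel_tia_map([img], mask, tail_mode="physical")
        dose = convolve_dose(tmap, spread_kernel, mask=mask,
                             mask_mode="mask_before")
        stats = dose_stats(dose, mask, 1)
        organ = sphere_dose(float(tmap.tia[mask.labels == 1].sum()),
                            stats["volume_ml"])
        assert organ >= stats["mean_gy"]
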