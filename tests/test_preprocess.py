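"""Calibration, segmentation, spectrum extraction, band trimming, lab assay."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import leafspec as ls
from leafspec.preprocess import (CalibrationError, LabAssay,
                                 SegmentationError, lab_k_percent)
from leafspec.simulate import HyperCube


def _toy_cube(band_image, centers=(795.0, 800.0, 805.0)):
    """A tiny reflectance cube with the same image in every band."""
    img = np.asarray(band_image, dtype=float)
    values = np.repeat(img[:, :, None], len(centers), axis=2)
    return HyperCube(values=values, grid=ls.WavelengthGrid(np.array(centers)),
                     units="reflectance", panel_region=None,
                     background_region=None)


class TestCalibration:
    def test_panel_maps_to_panel_reflectance(self, noiseless_scene):
        cfg, cube, _, _ = noiseless_scene
        refl = ls.calibrate_reflectance(cube,
                                        panel_reflectance=cfg.panel_reflectance)
        panel_vals = refl.values[cube.panel_region]
        assert np.allclose(panel_vals, cfg.panel_reflectance, atol=1e-12)

    def test_global_gain_invariance(self, noiseless_scene):
        cfg, cube, _, _ = noiseless_scene
        doubled = HyperCube(values=cube.values * 2.0, grid=cube.grid,
                            units="dn", panel_region=cube.panel_region,
                            background_region=cube.background_region)
        r1 = ls.calibrate_reflectance(cube, dark_level=0.0,
                                      panel_reflectance=cfg.panel_reflectance)
        r2 = ls.calibrate_reflectance(doubled, dark_level=0.0,
                                      panel_reflectance=cfg.panel_reflectance)
        assert np.allclose(r1.values, r2.values, atol=1e-12)

    def test_noiseless_leaf_recovers_reflectance_model(self, noiseless_scene):
        cfg, cube, mask, _ = noiseless_scene
        refl = ls.calibrate_reflectance(cube, dark_level=cfg.dark_current,
                                        panel_reflectance=cfg.panel_reflectance)
        expected = ls.reflectance_model(1.2, cube.grid, cfg)
        assert np.allclose(refl.values[mask], expected[None, :], atol=1e-12)

    def test_dead_panel_band_reported(self, noiseless_scene):
        _, cube, _, _ = noiseless_scene
        broken = cube.values.copy()
        broken[cube.panel_region, 3] = 0.0
        bad = HyperCube(values=broken, grid=cube.grid, units="dn",
                        panel_region=cube.panel_region,
                        background_region=cube.background_region)
        with pytest.raises(CalibrationError, match="band 3"):
            ls.calibrate_reflectance(bad, dark_level=200.0)


class TestSegmentation:
    def test_threshold_boundary_values(self):
        img = np.full((8, 8), 0.20)
        img[2:6, 2:6] = 0.28
        mask = ls.segment_leaf(_toy_cube(img))
        assert mask[3, 3] and not mask[0, 0]
        assert mask.sum() == 16

    def test_all_background_raises(self):
        with pytest.raises(SegmentationError):
            ls.segment_leaf(_toy_cube(np.full((8, 8), 0.20)))

    def test_largest_component_kept(self):
        img = np.full((10, 10), 0.1)
        img[1:3, 1:3] = 0.5  # 4-pixel speck
        img[4:9, 4:9] = 0.5  # 25-pixel leaf
        mask = ls.segment_leaf(_toy_cube(img))
        assert mask.sum() == 25 and not mask[1, 1]

    def test_recovers_ground_truth_mask(self, default_scene):
        cfg, cube, truth_mask, _ = default_scene
        refl = ls.calibrate_reflectance(cube,
                                        panel_reflectance=cfg.panel_reflectance)
        mask = ls.segment_leaf(ls.trim_bands(refl))
        jaccard = (mask & truth_mask).sum() / (mask | truth_mask).sum()
        assert jaccard >= 0.95


class TestMeanSpectrum:
    def test_constant_and_single_pixel(self):
        cube = _toy_cube(np.full((4, 4), 0.3))
        mask = np.zeros((4, 4), bool)
        mask[1, 2] = True
        assert np.allclose(ls.mean_spectrum(cube, mask), 0.3)
        cube.values[1, 2, :] = [0.1, 0.2, 0.3]
        assert np.allclose(ls.mean_spectrum(cube, mask), [0.1, 0.2, 0.3])

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 1, size=(6, 5, 4))
        cube = HyperCube(values=values,
                         grid=ls.WavelengthGrid(np.arange(4, dtype=float)),
                         units="reflectance", panel_region=None,
                         background_region=None)
        mask = rng.random((6, 5)) > 0.5
        expected = np.zeros(4)
        count = 0
        for r in range(6):
            for c in range(5):
                if mask[r, c]:
                    expected += values[r, c]
                    count += 1
        assert np.allclose(ls.mean_spectrum(cube, mask), expected / count,
                           atol=1e-12)

    def test_shape_mismatch_rejected(self):
        cube = _toy_cube(np.full((4, 4), 0.3))
        with pytest.raises(ValueError):
            ls.mean_spectrum(cube, np.ones((3, 3), bool))


class TestTrimBands:
    def test_default_window_keeps_106_bands(self, default_grid):
        trimmed = ls.trim_bands(default_grid)
        assert len(trimmed) == 106
        assert trimmed.centers[0] >= 400 and trimmed.centers[-1] <= 950

    def test_boundary_inclusion(self):
        g = ls.WavelengthGrid(np.array([399.0, 400.0, 950.0, 951.0]))
        # uniform-spacing check is per-grid; build via spectrum pair interface
        spec = np.array([1.0, 2.0, 3.0, 4.0])
        _, trimmed = ls.trim_bands((spec, g))
        assert np.allclose(trimmed.centers, [400.0, 950.0])

    def test_single_exact_center(self, default_grid):
        c = default_grid.centers[50]
        trimmed = ls.trim_bands(default_grid, c, c)
        assert len(trimmed) == 1 and trimmed.centers[0] == c

    def test_idempotent(self, default_grid):
        once = ls.trim_bands(default_grid)
        twice = ls.trim_bands(once)
        assert np.array_equal(once.centers, twice.centers)

    def test_empty_window_rejected(self, default_grid):
        with pytest.raises(ValueError):
            ls.trim_bands(default_grid, 100.0, 200.0)


class TestLabAssay:
    @pytest.mark.parametrize("rho,v,ts,m,expected", [
        (0.0, 100, 10, 0.5, 0.0),
        (50.0, 100, 10, 0.5, 10.0),
        (25.0, 50, 4, 1.0, 0.5),
    ])
    def test_hand_computed_values(self, rho, v, ts, m, expected):
        assert lab_k_percent(LabAssay(rho, v, ts, m)) == pytest.approx(expected)

    @given(rho=st.floats(0.1, 100), m=st.floats(0.1, 5), c=st.floats(1.5, 4))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_rho_and_inverse_mass(self, rho, m, c):
        base = lab_k_percent(LabAssay(rho, 100, 10, m))
        assert lab_k_percent(LabAssay(c * rho, 100, 10, m)) == pytest.approx(
            c * base)
        assert lab_k_percent(LabAssay(rho, 100, 10, c * m)) == pytest.approx(
            base / c)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            LabAssay(50, 100, 10, 0.0)
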