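"""Masked GLCM texture, color moments and image-feature screening."""

import numpy as np
import pandas as pd
import pytest

import leafspec as ls
from leafspec.features import (PairCountError, correlation_pvalues,
                               glcm_matrix, glcm_stats)

from conftest import brute_force_glcm, brute_force_glcm_stats


class TestGlcmMatrix:
    def test_two_by_two_hand_enumeration(self):
        img = np.array([[0, 1], [0, 1]], dtype=np.uint8)
        P = glcm_matrix(img, np.ones((2, 2), bool), 0, levels=2)
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == P[1, 1] == 0

    def test_constant_region_is_diagonal_delta(self):
        img = np.full((5, 5), 7, dtype=np.uint8)
        P = glcm_matrix(img, np.ones((5, 5), bool), 45, levels=16)
        assert P[7, 7] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_l_shaped_mask_matches_brute_force(self, angle):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 8, size=(6, 6)).astype(np.uint8)
        mask = np.zeros((6, 6), bool)
        mask[:, :2] = True
        mask[4:, :] = True  # L shape
        P = glcm_matrix(img, mask, angle, levels=8)
        assert np.allclose(P, brute_force_glcm(img, mask, angle, levels=8),
                           atol=1e-15)

    def test_no_valid_pair_raises(self):
        img = np.zeros((3, 3), dtype=np.uint8)
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = mask[2, 2] = True  # no neighbors at distance 1
        with pytest.raises(PairCountError):
            glcm_matrix(img, mask, 0)

    def test_random_masked_images_match_enumeration(self):
        """Randomized oracle equivalence for the matrix and its statistics."""
        rng = np.random.default_rng(99)
        for _ in range(25):
            h, w = rng.integers(3, 17, size=2)
            img = rng.integers(0, 12, size=(h, w)).astype(np.uint8)
            mask = rng.random((h, w)) > 0.3
            angle = int(rng.choice([0, 45, 90, 135]))
            try:
                P = glcm_matrix(img, mask, angle, levels=12)
            except PairCountError:
                continue
            expected = brute_force_glcm(img, mask, angle, levels=12)
            assert np.allclose(P, expected, atol=1e-12)
            s = glcm_stats(P)
            e = brute_force_glcm_stats(P)
            for name in ("ENE", "ENT", "CON", "COR", "MEA", "VAR"):
                assert getattr(s, name) == pytest.approx(e[name], abs=1e-12)


class TestGlcmStats:
    def test_single_entry_delta(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        s = glcm_stats(P)
        assert s.ENE == 1.0 and s.ENT == 0.0 and s.CON == 0.0
        assert s.degenerate and s.COR == 0.0

    def test_two_entry_hand_values(self):
        P = np.zeros((2, 2))
        P[0, 1] = P[1, 0] = 0.5
        s = glcm_stats(P)
        assert s.ENE == pytest.approx(0.5)
        assert s.ENT == pytest.approx(np.log(2))
        assert s.CON == pytest.approx(1.0)
        assert s.COR == pytest.approx(-1.0)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            glcm_stats(np.ones((3, 3)))


class TestTextureFeatures:
    def test_exactly_24_named_features(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        feats = ls.texture_features(img, np.ones((12, 12), bool), 641.0)
        assert len(feats) == 24
        assert "641 nm-CON-135°" in feats.index
        assert "641 nm-MEA (CON)" in feats.index
        assert "641 nm-VAR (COR)" in feats.index
        assert feats.index.is_unique

    def test_constant_region_limits(self):
        img = np.full((10, 10), 100, dtype=np.uint8)
        feats = ls.texture_features(img, np.ones((10, 10), bool))
        for a in (0, 45, 90, 135):
            assert feats[f"CON-{a}°"] == 0.0
            assert feats[f"ENE-{a}°"] == 1.0

    def test_rotation_maps_0_onto_90(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 64, size=(9, 9)).astype(np.uint8)
        mask = rng.random((9, 9)) > 0.2
        f = ls.texture_features(img, mask, levels=64)
        fr = ls.texture_features(np.rot90(img), np.rot90(mask), levels=64)
        for stat in ("ENE", "ENT", "CON", "COR"):
            assert fr[f"{stat}-90°"] == pytest.approx(f[f"{stat}-0°"],
                                                      abs=1e-12)


class TestColorMoments:
    def test_constant_image(self):
        img = np.full((4, 4), 37, dtype=np.uint8)
        m = ls.color_moments(img, np.ones((4, 4), bool))
        assert (m.MEA, m.VAR, m.SKE) == (37.0, 0.0, 0.0)

    def test_hand_computed_two_values(self):
        img = np.array([[0, 2]], dtype=np.uint8)
        m = ls.color_moments(img, np.ones((1, 2), bool))
        assert m.MEA == pytest.approx(1.0)
        assert m.VAR == pytest.approx(1.0)
        assert m.SKE == pytest.approx(0.0)

    def test_hand_computed_skewed_values(self):
        img = np.array([[0, 0, 3]], dtype=np.uint8)
        m = ls.color_moments(img, np.ones((1, 3), bool))
        assert m.MEA == pytest.approx(1.0)
        assert m.VAR == pytest.approx(np.sqrt(2.0))
        assert m.SKE == pytest.approx(np.cbrt(2.0))

    def test_matches_direct_mean_and_population_std(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, size=(15, 15)).astype(np.uint8)
        mask = rng.random((15, 15)) > 0.4
        m = ls.color_moments(img, mask)
        vals = img[mask].astype(float)
        assert m.MEA == pytest.approx(vals.mean(), abs=1e-12)
        assert m.VAR == pytest.approx(vals.std(), abs=1e-12)

    def test_named_color_features(self):
        img = np.full((4, 4), 10, dtype=np.uint8)
        feats = ls.color_features(img, np.ones((4, 4), bool), 532.0)
        assert list(feats.index) == ["532 nm-MEA", "532 nm-VAR", "532 nm-SKE"]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ls.color_moments(np.zeros((3, 3), np.uint8),
                             np.zeros((3, 3), bool))


class TestScreening:
    def test_perfect_correlate_survives(self):
        rng = np.random.default_rng(4)
        k = rng.uniform(0.5, 2.5, 40)
        table = pd.DataFrame({
            "perfect": k,
            "noise1": rng.normal(size=40),
            "noise2": rng.normal(size=40),
            "noise3": rng.normal(size=40),
        })
        res = ls.screen_image_features(table, k, seed=0)
        assert 0 in res.selected_indices  # the "perfect" column

    def test_null_type_one_error_rate(self):
        """~5% of pure-noise features pass the p < 0.05 gate."""
        rates = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            k = rng.uniform(0.5, 2.5, 60)
            table = pd.DataFrame(rng.normal(size=(60, 400)))
            _, p = correlation_pvalues(table, k)
            rates.append((p < 0.05).mean())
        assert 0.03 <= np.mean(rates) <= 0.07

    def test_no_survivors_degrades_to_empty_selection(self):
        rng = np.random.default_rng(5)
        k = np.linspace(0.5, 2.5, 20)
        table = pd.DataFrame(np.ones((20, 5)))  # constant features
        res = ls.screen_image_features(table, k, seed=0)
        assert res.selected_indices.size == 0
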