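"""Mosaicking stages: distortion, equalization, registration, blending, stitching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from plantarkit import mosaic, phantom
from plantarkit.core import (
    CoverageError,
    DegenerateContrastError,
    RegistrationError,
    StitchError,
)


class TestUndistort:
    def test_identity_camera_returns_pixels_unchanged(self, rng):
        img = rng.uniform(0, 255, (40, 50))
        tile = mosaic.RawTile(img, "UL", mosaic.CameraModel())
        out = mosaic.undistort(tile)
        assert np.array_equal(out.pixels, img)

    def test_forward_formula_at_half_radius(self):
        # r_d = r_u (1 + k1 r_u^2): 0.5 * (1 + 0.1 * 0.25) = 0.5125
        r_u = mosaic.invert_radial(np.array([0.5125]), k1=0.1, k2=0.0)
        assert r_u[0] == pytest.approx(0.5, abs=1e-9)

    def test_dot_grid_round_trip_displacement(self):
        # forward-distort a dot grid, undistort, re-detect the dot centroids
        img = np.zeros((220, 220))
        step = 10
        centers = [(r, c) for r in range(30, 200, step * 2)
                   for c in range(30, 200, step * 2)]
        rr, cc = np.mgrid[0:220, 0:220].astype(float)
        for r0, c0 in centers:
            img = np.maximum(img, 200 * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / 4.0))
        captured = mosaic.radial_distort_image(img, k1=0.05)
        restored = mosaic.undistort(
            mosaic.RawTile(captured, "UL", mosaic.CameraModel(k1=0.05))).pixels
        disp = []
        for r0, c0 in centers:
            win = restored[r0 - 4:r0 + 5, c0 - 4:c0 + 5]
            total = win.sum()
            wr, wc = np.mgrid[-4:5, -4:5]
            disp.append(np.hypot((wr * win).sum() / total, (wc * win).sum() / total))
        assert np.mean(disp) < 0.5

    def test_non_invertible_model_rejected(self):
        with pytest.raises(mosaic.DistortionModelError):
            mosaic.invert_radial(np.array([0.5]), k1=-0.5, k2=0.0)


class TestEqualize:
    def test_identical_images_unchanged(self, rng):
        a = rng.uniform(0, 200, (20, 20))
        _, b2, off = mosaic.equalize_intensity(a, a.copy())
        assert off == 0.0
        assert np.allclose(b2, a)
        a2, b2 = mosaic.equalize_contrast(a, a.copy())
        assert np.allclose(a2, b2)

    def test_constant_offset_recovered(self):
        a = np.full((5, 5), 100.0)
        b = np.full((5, 5), 120.0)
        _, b2, off = mosaic.equalize_intensity(a, b)
        assert off == -20.0
        assert np.all(b2 == 100.0)

    def test_shifted_image_means_match(self, rng):
        a = rng.uniform(20, 200, (30, 30))
        b = a + 17.0
        _, b2, off = mosaic.equalize_intensity(a, b, level_range=(0, 255))
        assert off == pytest.approx(-17.0)
        assert b2.mean() == pytest.approx(a.mean())

    def test_contrast_union_range(self):
        a = np.linspace(0, 200, 64).reshape(8, 8)
        b = np.linspace(50, 150, 64).reshape(8, 8)
        a2, b2 = mosaic.equalize_contrast(a, b)
        for im in (a2, b2):
            assert im.min() == pytest.approx(0.0)
            assert im.max() == pytest.approx(200.0)

    def test_affine_related_images_coincide_after_stretch(self, rng):
        a = rng.uniform(10, 240, (25, 25))
        b = 0.5 * a + 30.0
        a2, b2 = mosaic.equalize_contrast(a, b)
        assert np.abs(a2 - b2).max() < 1.0

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateContrastError):
            mosaic.equalize_contrast(np.full((4, 4), 7.0), np.eye(4))


class TestEstimateTransform:
    def test_identity_for_identical_landmarks(self, rng):
        pts = rng.uniform(0, 100, (5, 2))
        t = mosaic.estimate_transform(np.stack([pts, pts], axis=1))
        assert t.scale == pytest.approx(1.0)
        assert t.rotation_deg == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(t.translation_rc, (0, 0), atol=1e-9)
        assert t.residual < 1e-9

    def test_pure_translation(self, rng):
        pts = rng.uniform(0, 100, (4, 2))
        moved = pts + np.array([5.0, -3.0])
        t = mosaic.estimate_transform(np.stack([moved, pts], axis=1))
        assert np.allclose(t.translation_rc, (5.0, -3.0), atol=1e-9)
        assert t.scale == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.9, 1.1), rot=st.floats(-15.0, 15.0),
           tr=st.floats(-20.0, 20.0), tc=st.floats(-20.0, 20.0),
           seed=st.integers(0, 1000))
    def test_random_similarity_recovery(self, scale, rot, tr, tc, seed):
        pts = np.random.default_rng(seed).uniform(0, 200, (5, 2))
        t_true = mosaic.PlanarTransform.from_params(scale, rot, (tr, tc))
        moved = t_true.apply_rc(pts)
        t = mosaic.estimate_transform(np.stack([moved, pts], axis=1))
        assert t.scale == pytest.approx(scale, abs=1e-6)
        assert t.rotation_deg == pytest.approx(rot, abs=1e-6)
        assert np.allclose(t.translation_rc, (tr, tc), atol=1e-6)

    def test_noisy_recovery_within_statistical_bound(self):
        # translation error of the LS fit is ~ sigma / sqrt(n) per component
        sigma, n = 0.5, 30
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = rng.uniform(0, 300, (n, 2))
            t_true = mosaic.PlanarTransform.from_params(1.0, 5.0, (8.0, -3.0))
            moved = t_true.apply_rc(pts) + rng.normal(0, sigma, (n, 2))
            t = mosaic.estimate_transform(np.stack([moved, pts], axis=1))
            err = np.abs(np.array(t.translation_rc) - np.array([8.0, -3.0]))
            assert np.all(err < 3 * sigma)  # loose 3-sigma envelope

    def test_degenerate_landmarks_rejected(self):
        one = np.array([[(1.0, 2.0), (1.0, 2.0)]])
        with pytest.raises(RegistrationError):
            mosaic.estimate_transform(one)
        same = np.array([[(1.0, 2.0), (3.0, 3.0)], [(5.0, 6.0), (3.0, 3.0)]])
        with pytest.raises(RegistrationError):
            mosaic.estimate_transform(same)


class TestBlend:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(n=st.integers(2, 300), s=st.floats(0.05, 50.0))
    def test_partition_of_unity(self, n, s):
        w = mosaic.hyperbolic_weights(n, steepness=s)
        assert np.abs(w.Hl + w.Hr - 1.0).max() < 1e-12
        assert np.all(np.diff(w.Hl) <= 0)  # Hl monotone non-increasing

    def test_stitch_identical_images_is_idempotent(self, rng):
        img = rng.uniform(0, 255, (30, 40))
        out = mosaic.stitch(img, img, mosaic.PlanarTransform.identity())
        assert np.allclose(out, img)

    def test_constant_ramp_across_overlap(self):
        base = np.zeros((40, 20))
        moving = np.full((40, 20), 100.0)
        t = mosaic.PlanarTransform.from_params(translation_rc=(30.0, 0.0))
        out = mosaic.stitch(base, moving, t)
        seam_col = out[:, 10]
        assert np.all(np.diff(seam_col) >= -1e-9)  # monotone ramp
        w = mosaic.hyperbolic_weights(10)
        max_inc = np.abs(np.diff(w.Hr)).max()
        assert np.abs(np.diff(seam_col[30:40])).max() <= 100 * max_inc + 1e-9

    def test_partition_keeps_constant_images_constant(self):
        c = np.full((30, 30), 55.0)
        t = mosaic.PlanarTransform.from_params(translation_rc=(12.0, 0.0))
        out = mosaic.stitch(c, c.copy(), t)
        assert np.allclose(out, 55.0)

    def test_zero_overlap_raises(self):
        t = mosaic.PlanarTransform.from_params(translation_rc=(100.0, 0.0))
        with pytest.raises(StitchError):
            mosaic.stitch(np.zeros((10, 10)), np.zeros((10, 10)), t)


class TestMosaicFour:
    @staticmethod
    def _landmark_sets(landmarks):
        return {p: phantom.landmark_pairs(landmarks, p)
                for p in ("UL-LL", "UR-LR", "L-R")}

    def test_identity_cameras_round_trip_exactly(self, platform_scene):
        tiles, landmarks, dotted = phantom.split_into_tiles(
            platform_scene, overlap_px=16, n_landmarks=4, seed=3)
        full = mosaic.mosaic_four(list(tiles.values()), self._landmark_sets(landmarks))
        assert full.data.shape == dotted.data.shape
        assert np.abs(full.data - dotted.data).max() < 1e-9

    def test_distorted_tiles_reconstruct_within_tolerance(self, distorted_tile_set):
        tiles, landmarks, dotted = distorted_tile_set
        full = mosaic.mosaic_four(list(tiles.values()), self._landmark_sets(landmarks))
        err = np.abs(full.data - dotted.data)
        assert err.mean() < 2.0
        H2, W2 = dotted.shape[0] // 2, dotted.shape[1] // 2
        col_grad = np.abs(np.diff(full.data, axis=1))[:, W2 - 17:W2 + 17]
        assert col_grad.mean(axis=0).max() < 3.0
        row_grad = np.abs(np.diff(full.data, axis=0))[H2 - 17:H2 + 17, :]
        assert row_grad.mean(axis=1).max() < 3.0

    def test_shuffled_tile_ids_rejected(self, distorted_tile_set):
        tiles, landmarks, _ = distorted_tile_set
        bad = [mosaic.RawTile(t.pixels, "UL", t.camera) for t in tiles.values()]
        with pytest.raises(CoverageError):
            mosaic.mosaic_four(bad, self._landmark_sets(landmarks))

    def test_single_landmark_fails_downstream_registration(self, platform_scene):
        tiles, landmarks, _ = phantom.split_into_tiles(
            platform_scene, overlap_px=16, n_landmarks=1, seed=3)
        with pytest.raises(RegistrationError):
            mosaic.mosaic_four(list(tiles.values()), self._landmark_sets(landmarks))
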