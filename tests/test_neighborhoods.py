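"""Patch extraction, pyramid, pixel typing and augmentation behavior."""

import numpy as np
import pytest
from scipy import ndimage

from pixelseg import (
    Image,
    LabelMap,
    PatchSpec,
    augment_patch,
    build_pyramid,
    classify_pixel_type,
    extract_patch,
    harvest_patches,
    pixel_type_map,
)
from pixelseg.neighborhoods import (
    BOUNDARY,
    INTERIOR,
    extract_all_patches,
    rotation_matrix,
    sigma_for_scale,
)


def _img(arr):
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim == 2:
        a = a[..., None]
    return Image(data=a, is_normalized=True)


class TestPatchSpec:
    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            PatchSpec(N=4)

    def test_defaults_match_protocol(self):
        spec = PatchSpec()
        assert spec.N == 3
        assert spec.scales == (0, 1, 2, 3, 4)
        assert spec.rotation_angles_deg == (45.0, -45.0)
        assert set(spec.flips) == {"lr", "ud"}

    def test_feature_length(self):
        spec = PatchSpec(N=3)
        assert spec.feature_length(2, 1) == 9
        assert spec.feature_length(3, 1) == 27
        assert spec.feature_length(2, 3) == 27


class TestPyramid:
    def test_constant_image_unchanged_at_all_levels(self):
        img = _img(np.full((10, 10), 0.5))
        pyr = build_pyramid(img, PatchSpec(scales=(0, 1, 2, 3)))
        for s, level in pyr.levels.items():
            np.testing.assert_allclose(level, 0.5)

    def test_scale0_is_identity(self, small_texture_pair):
        img, _ = small_texture_pair
        pyr = build_pyramid(img, PatchSpec(scales=(0, 1)))
        np.testing.assert_array_equal(pyr.levels[0], img.data)

    def test_impulse_matches_direct_convolution(self):
        arr = np.zeros((15, 15))
        arr[7, 7] = 1.0
        pyr = build_pyramid(_img(arr), PatchSpec(scales=(1,)))
        # independent oracle: explicit truncated-Gaussian kernel convolution
        sigma = sigma_for_scale(1)
        r = int(4 * sigma + 0.5)
        x = np.arange(-r, r + 1)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        k1 /= k1.sum()
        expected = ndimage.convolve(
            ndimage.convolve(arr, k1[None, :], mode="nearest"),
            k1[:, None],
            mode="nearest",
        )
        np.testing.assert_allclose(pyr.levels[1][..., 0], expected, atol=1e-12)


class TestExtractPatch:
    def test_single_pixel_window(self):
        img = _img(np.arange(9.0).reshape(3, 3))
        pyr = build_pyramid(img, PatchSpec(N=1, scales=(0,)))
        assert extract_patch(pyr, (1, 2), 0, PatchSpec(N=1, scales=(0,))) == [5.0]

    def test_center_readoff_row_major(self):
        img = _img(np.arange(1.0, 10.0).reshape(3, 3))
        spec = PatchSpec(N=3, scales=(0,))
        pyr = build_pyramid(img, spec)
        np.testing.assert_array_equal(
            extract_patch(pyr, (1, 1), 0, spec), np.arange(1.0, 10.0)
        )

    def test_stride_two_samples_offsets(self):
        # horizontal ramp: column index as intensity; at s=1 offsets are +-2
        ramp = np.tile(np.arange(9.0), (9, 1))
        spec = PatchSpec(N=3, scales=(0, 1))
        pyr = build_pyramid(_img(ramp), spec)
        pyr.levels[1] = pyr.levels[0]  # isolate stride arithmetic from smoothing
        got = extract_patch(pyr, (4, 4), 1, spec)
        cols = np.array([2.0, 4.0, 6.0])
        expected = np.concatenate([cols, cols, cols])
        np.testing.assert_array_equal(got, expected)

    def test_edge_replication(self):
        img = _img(np.arange(1.0, 10.0).reshape(3, 3))
        spec = PatchSpec(N=3, scales=(0,))
        pyr = build_pyramid(img, spec)
        got = extract_patch(pyr, (0, 0), 0, spec)
        expected = np.array([1, 1, 2, 1, 1, 2, 4, 4, 5], dtype=float)
        np.testing.assert_array_equal(got, expected)

    def test_out_of_bounds_coordinate_rejected(self):
        spec = PatchSpec(N=3, scales=(0,))
        pyr = build_pyramid(_img(np.zeros((4, 4))), spec)
        with pytest.raises(ValueError):
            extract_patch(pyr, (4, 0), 0, spec)

    def test_vectorized_extraction_matches_single(self, small_texture_pair):
        img, _ = small_texture_pair
        spec = PatchSpec(N=3, scales=(0, 2))
        pyr = build_pyramid(img, spec)
        for s in (0, 2):
            F = extract_all_patches(pyr, s, spec)
            for flat in [0, 17, 48 * 48 - 1]:
                coord = np.unravel_index(flat, img.spatial_shape)
                np.testing.assert_array_equal(
                    F[flat], extract_patch(pyr, coord, s, spec)
                )

    def test_3d_window_length(self):
        vol = Image(data=np.zeros((5, 6, 7, 1)), is_normalized=True)
        spec = PatchSpec(N=3, scales=(0,))
        pyr = build_pyramid(vol, spec)
        assert extract_patch(pyr, (2, 3, 3), 0, spec).shape == (27,)


class TestPixelType:
    def test_uniform_window_is_interior(self):
        lm = LabelMap(labels=np.zeros((5, 5), dtype=int))
        assert classify_pixel_type(lm, (2, 2), 3) == INTERIOR

    def test_two_class_window_is_boundary(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[:, 3:] = 1
        lm = LabelMap(labels=labels)
        assert classify_pixel_type(lm, (2, 2), 3) == BOUNDARY

    def test_three_class_window_is_boundary(self):
        labels = np.zeros((3, 3), dtype=int)
        labels[0, 0], labels[2, 2] = 1, 2
        assert classify_pixel_type(LabelMap(labels=labels), (1, 1), 3) == BOUNDARY

    def test_even_window_rejected(self):
        lm = LabelMap(labels=np.zeros((4, 4), dtype=int))
        with pytest.raises(ValueError):
            classify_pixel_type(lm, (1, 1), 2)

    def test_map_matches_per_pixel_classification(self, random_labelmap):
        tmap = pixel_type_map(random_labelmap, 3)
        for coord in [(0, 0), (5, 7), (19, 23), (10, 0)]:
            assert tmap[coord] == classify_pixel_type(random_labelmap, coord, 3)

    def test_straight_boundary_fraction(self):
        # half-and-half split of an LxL image: exactly the two columns
        # adjacent to the interface are boundary with a 3-wide window
        L = 16
        labels = np.zeros((L, L), dtype=int)
        labels[:, L // 2 :] = 1
        frac = (pixel_type_map(LabelMap(labels=labels), 3) == BOUNDARY).mean()
        assert frac == pytest.approx(2.0 * L / L**2)


class TestAugmentation:
    def test_zero_rotation_is_identity(self):
        M = rotation_matrix(3, 0.0)
        np.testing.assert_allclose(M, np.eye(9), atol=1e-12)

    def test_rotation_matrix_matches_ndimage_on_random_patch(self, rng):
        patch = rng.uniform(size=(5, 5))
        M = rotation_matrix(5, 45.0)
        direct = ndimage.rotate(
            patch, 45.0, reshape=False, order=1, mode="nearest", prefilter=False
        )
        np.testing.assert_allclose((M @ patch.reshape(-1)).reshape(5, 5), direct, atol=1e-12)

    def test_flip_involution_exact(self, rng):
        spec = PatchSpec(N=3, scales=(0,), rotation_angles_deg=(), flips=("lr",))
        feats = rng.uniform(size=9)
        once = augment_patch(feats, spec, "2d")[1]
        twice = augment_patch(once, spec, "2d")[1]
        np.testing.assert_array_equal(twice, feats)

    def test_constant_patch_invariant(self):
        spec = PatchSpec(N=3, scales=(0,))
        versions = augment_patch(np.full(9, 0.3), spec, "2d")
        assert len(versions) == 9
        for v in versions:
            np.testing.assert_allclose(v, 0.3, atol=1e-12)

    def test_default_augmentation_count_2d(self, rng):
        # 3 rotation states (0, +45, -45) x 3 flip states (none, lr, ud)
        versions = augment_patch(rng.uniform(size=9), PatchSpec(), "2d")
        assert len(versions) == 9

    def test_3d_rotation_acts_per_z_slice(self, rng):
        spec = PatchSpec(N=3, scales=(0,), rotation_angles_deg=(45.0,), flips=())
        vol = rng.uniform(size=(3, 3, 3))
        rotated = augment_patch(vol.reshape(-1), spec, "3d")[1].reshape(3, 3, 3)
        M = rotation_matrix(3, 45.0)
        for z in range(3):
            np.testing.assert_allclose(
                rotated[z], (M @ vol[z].reshape(-1)).reshape(3, 3), atol=1e-12
            )

    def test_channels_rotate_independently(self, rng):
        spec = PatchSpec(N=3, scales=(0,), rotation_angles_deg=(45.0,), flips=())
        patch = rng.uniform(size=(9, 2))  # channel fastest in flattened form
        rotated = augment_patch(patch.reshape(-1), spec, "2d", channels=2)[1]
        M = rotation_matrix(3, 45.0)
        got = rotated.reshape(9, 2)
        for ch in range(2):
            np.testing.assert_allclose(got[:, ch], M @ patch[:, ch], atol=1e-12)


class TestHarvest:
    def test_constant_labels_yield_one_record_per_pixel(self, small_texture_pair):
        img, _ = small_texture_pair
        lm = LabelMap(labels=np.zeros(img.spatial_shape, dtype=int))
        out = harvest_patches(img, lm, PatchSpec(scales=(0, 1)))
        for s, pset in out.items():
            assert len(pset) == 48 * 48
            assert np.all(pset.pixel_types == INTERIOR)

    def test_boundary_pixels_augmented_ninefold(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[:, 4:] = 1
        img = Image(data=np.random.default_rng(0).uniform(size=(8, 8, 1)), is_normalized=True)
        lm = LabelMap(labels=labels)
        out = harvest_patches(img, lm, PatchSpec(scales=(0,)))
        n_boundary = int((pixel_type_map(lm, 3) == BOUNDARY).sum())
        # interior once, boundary 9x (3 rotation states x 3 flip states)
        assert len(out[0]) == 64 - n_boundary + 9 * n_boundary

    def test_all_pixels_covered_with_expected_length(self, small_texture_pair):
        img, lm = small_texture_pair
        out = harvest_patches(img, lm, PatchSpec(scales=(0,)))
        pset = out[0]
        assert pset.features.shape[1] == 9
        # every pixel appears at least once as an unaugmented record
        flat = set(map(tuple, pset.coords.tolist()))
        assert len(flat) == 48 * 48

    def test_patchset_cache_round_trip(self, small_texture_pair, tmp_path):
        img, lm = small_texture_pair
        pset = harvest_patches(img, lm, PatchSpec(scales=(0,)))[0]
        pset.save(tmp_path / "cache.npz")
        from pixelseg.neighborhoods import PatchSet

        back = PatchSet.load(tmp_path / "cache.npz")
        np.testing.assert_array_equal(back.features, pset.features)
        np.testing.assert_array_equal(back.labels, pset.labels)
        np.testing.assert_array_equal(back.coords, pset.coords)
        assert back.scale == pset.scale

    def test_shape_mismatch_rejected(self, small_texture_pair):
        img, _ = small_texture_pair
        with pytest.raises(ValueError):
            harvest_patches(img, LabelMap(labels=np.zeros((4, 4), dtype=int)), PatchSpec())
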