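import numpy as np
import pytest
from scipy import ndimage

from virtpol import dataprep as dp
from virtpol.errors import RegistrationFailureError, ShapeError, ValidationError
from virtpol.phantoms import PhantomSpec, apply_synthetic_deformation, generate_phantom, random_smooth_field


@pytest.fixture(scope="module")
def textured():
    """A feature-rich grayscale image for registration tests."""
    s = generate_phantom(PhantomSpec(image_size=256, n_amyloid_blobs=4, n_nuclei=20, seed=21))
    return dp._to_gray(s.brightfield_gt)


@pytest.fixture(scope="module")
def big_textured():
    """A larger non-repeating image for feature-based global registration."""
    s = generate_phantom(PhantomSpec(image_size=704, n_amyloid_blobs=10, n_nuclei=80, seed=22))
    return dp._to_gray(s.brightfield_gt)


class TestProjectiveTransform:
    def test_identity(self):
        tf = dp.ProjectiveTransform.identity()
        pts = np.array([[0.0, 0.0], [10.0, 5.0]])
        np.testing.assert_allclose(tf.apply(pts), pts)

    def test_normalised(self):
        tf = dp.ProjectiveTransform(2 * np.eye(3))
        assert tf.matrix[2, 2] == 1.0

    def test_singular_rejected(self):
        m = np.eye(3)
        m[0, 0] = 0.0
        m[0, 1] = 0.0
        with pytest.raises(ValidationError):
            dp.ProjectiveTransform(m)


class TestGlobalRegister:
    def test_self_registration_identity(self, big_textured):
        big = big_textured
        tf = dp.global_register(big, big, downsample_factor=2)
        h, w = big.shape
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
        mapped = tf.apply(corners)
        assert np.abs(mapped - corners).max() < 0.5

    def test_known_shift_recovered(self, big_textured):
        big = big_textured
        moving = ndimage.shift(big, (10, -7), order=1, mode="nearest")
        tf = dp.global_register(moving, big, downsample_factor=1)
        corners = np.array([[100, 100], [600, 100], [100, 600], [600, 600]], float)
        # moving -> fixed corner deltas recover the (negated) applied shift
        # moving -> fixed: feature at (r, c) in moving sits at (r-10, c+7) in fixed
        delta = tf.apply(corners) - corners
        np.testing.assert_allclose(delta.mean(axis=0), [7.0, -10.0], atol=1.0)

    def test_pure_noise_fails(self):
        rng = np.random.default_rng(0)
        a = rng.random((256, 256))
        b = rng.random((256, 256))
        with pytest.raises(RegistrationFailureError):
            dp.global_register(a, b, downsample_factor=1)

    def test_too_small_after_downsampling(self, textured):
        with pytest.raises(ValidationError):
            dp.global_register(textured, textured, downsample_factor=4)


class TestTilePairs:
    def _wsi(self, size):
        stack = np.zeros((4, size, size), np.float32)
        target = np.zeros((size, size, 3), np.float32)
        return stack, target

    def test_4096_gives_4_tiles(self):
        stack, target = self._wsi(4096)
        tiles = dp.tile_pairs(target, stack, tile_size=2048)
        assert len(tiles) == 4

    def test_5000_drops_remainder(self):
        stack, target = self._wsi(5000)
        tiles = dp.tile_pairs(target, stack, tile_size=2048)
        assert len(tiles) == 4

    def test_reassembly_lossless(self, rng):
        stack = rng.random((2, 128, 128)).astype(np.float32)
        target = rng.random((128, 128, 3)).astype(np.float32)
        tiles = dp.tile_pairs(target, stack, tile_size=64)
        rebuilt = np.zeros_like(target)
        for tp in tiles:
            r, c = tp.tile_origin
            rebuilt[r : r + 64, c : c + 64] = tp.target
        np.testing.assert_array_equal(rebuilt, target)

    def test_tile_too_large(self):
        stack, target = self._wsi(128)
        with pytest.raises(ValidationError):
            dp.tile_pairs(target, stack, tile_size=256)


class TestWarp:
    def test_zero_field_identity(self, rng):
        img = rng.random((32, 32, 3)).astype(np.float32)
        out = dp.warp(img, dp.DisplacementField.zero(32, 32))
        np.testing.assert_allclose(out, img, atol=1e-6)

    def test_constant_integer_shift_matches_roll(self, rng):
        img = rng.random((32, 32)).astype(np.float32)
        field = dp.DisplacementField(dx=np.full((32, 32), 3, np.float32), dy=np.zeros((32, 32), np.float32))
        out = dp.warp(img, field)
        np.testing.assert_allclose(out[:, :-3], img[:, 3:], atol=1e-6)
        # border replication on the right edge
        np.testing.assert_allclose(out[:, -3:], np.repeat(img[:, -1:], 3, axis=1), atol=1e-6)

    def test_round_trip_small_field(self, textured):
        field_arr = random_smooth_field(256, 2.0, seed=5)
        field = dp.DisplacementField(dx=field_arr[0], dy=field_arr[1])
        back = dp.warp(dp.warp(textured, field), dp.invert_field(field))
        inner = (slice(16, -16), slice(16, -16))
        assert np.abs(back[inner] - textured[inner]).mean() < 0.02

    def test_shape_mismatch(self, rng):
        with pytest.raises(ShapeError):
            dp.warp(rng.random((16, 16)), dp.DisplacementField.zero(8, 8))

    def test_channels_warped_identically(self, rng):
        img = np.repeat(rng.random((16, 16, 1)), 3, axis=2).astype(np.float32)
        field_arr = random_smooth_field(16, 1.5, seed=2)
        field = dp.DisplacementField(dx=field_arr[0], dy=field_arr[1])
        out = dp.warp(img, field)
        np.testing.assert_array_equal(out[..., 0], out[..., 1])
        np.testing.assert_array_equal(out[..., 0], out[..., 2])


class TestElasticRegister:
    def test_identity_small_field(self, textured):
        field = dp.elastic_register(textured, textured, levels=3, block_size=64)
        assert field.magnitude().mean() < 0.25

    def test_known_deformation_recovered(self, textured):
        true = random_smooth_field(256, 4.0, seed=7)
        tf = dp.DisplacementField(dx=true[0], dy=true[1])
        deformed = dp.warp(textured, tf)
        est = dp.elastic_register(deformed, textured, levels=3, block_size=32)
        inv = dp.invert_field(tf)
        epe = np.sqrt((est.dx - inv.dx) ** 2 + (est.dy - inv.dy) ** 2).mean()
        assert epe < 1.0

    def test_mae_reduction(self, textured):
        true = random_smooth_field(256, 4.0, seed=8)
        tf = dp.DisplacementField(dx=true[0], dy=true[1])
        deformed = dp.warp(textured, tf)
        est = dp.elastic_register(deformed, textured, levels=3, block_size=32)
        before = np.abs(deformed - textured).mean()
        after = np.abs(dp.warp(deformed, est) - textured).mean()
        assert after <= before * 0.5

    def test_flat_images_fail(self):
        flat = np.full((128, 128), 0.5)
        with pytest.raises(RegistrationFailureError):
            dp.elastic_register(flat, flat, levels=1, block_size=64)

    def test_guard_never_increases_mae(self, textured, rng):
        """Guarded fallback: registration never worsens alignment > 1%."""
        noise = rng.random((256, 256))
        est = dp.elastic_register(noise, textured, levels=2, block_size=64)
        before = np.abs(noise - textured).mean()
        after = np.abs(dp.warp(noise, est) - textured).mean()
        assert after <= before * 1.01


class TestInvertField:
    def test_inverse_of_zero_is_zero(self):
        z = dp.DisplacementField.zero(32, 32)
        inv = dp.invert_field(z)
        assert inv.magnitude().max() == 0.0

    def test_composition_near_identity(self):
        arr = random_smooth_field(64, 3.0, seed=3)
        f = dp.DisplacementField(dx=arr[0], dy=arr[1])
        inv = dp.invert_field(f)
        # f(x + inv(x)) + inv(x) ~ 0
        rr, cc = np.mgrid[0:64, 0:64].astype(np.float64)
        fx = ndimage.map_coordinates(f.dx, [rr + inv.dy, cc + inv.dx], order=1, mode="nearest")
        assert np.abs(fx + inv.dx).mean() < 0.05


class TestPrepareRegisteredDataset:
    def test_aligned_phantoms_converge_round_one(self):
        s = generate_phantom(PhantomSpec(image_size=128, seed=31))
        cfg = dp.PrepConfig(tile_size=128, pyramid_levels=2, block_size=32, max_rounds=2, skip_global=True)
        tiles, diag = dp.prepare_registered_dataset([s.stack], [s.brightfield_gt], cfg)
        assert len(diag["rounds"]) == 1
        assert diag["rounds"][0] < 0.5
        for tp in tiles:
            assert tp.stack.shape[1:] == tp.target.shape[:2]

    def test_style_transfer_loop_runs(self):
        """One round with a (briefly trained) style-transfer model produces
        valid tiles; the loop falls back to intensity correlation."""
        s = generate_phantom(PhantomSpec(image_size=128, seed=33))
        cfg = dp.PrepConfig(tile_size=128, pyramid_levels=2, block_size=32, max_rounds=1,
                            style_steps=6, skip_global=True)
        tiles, diag = dp.prepare_registered_dataset([s.stack], [s.brightfield_gt], cfg)
        assert len(tiles) == 1
        assert len(diag["rounds"]) == 1
        assert np.isfinite(diag["rounds"][0])

    def test_deformed_phantoms_residual_shrinks(self):
        s = generate_phantom(PhantomSpec(image_size=256, seed=32))
        deformed, _ = apply_synthetic_deformation(s, 4.0, seed=5)
        cfg = dp.PrepConfig(tile_size=256, pyramid_levels=3, block_size=32, max_rounds=3,
                            residual_threshold_px=0.5, skip_global=True)
        tiles, diag = dp.prepare_registered_dataset([s.stack], [deformed.brightfield_gt], cfg)
        residuals = diag["rounds"]
        assert residuals[-1] < 1.0
        # non-increasing residual over rounds (allow small jitter)
        for earlier, later in zip(residuals, residuals[1:]):
            assert later <= earlier + 0.1
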