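"""Stitching, color-based collagen extraction, MI, and affine recovery."""

import math

import numpy as np
import pytest

from collalign import (
    AffineTransform,
    ROI,
    StitchLayout,
    decorrelation_stretch,
    extract_collagen_mask,
    make_he_pair,
    mutual_information,
    register_affine,
    register_he_to_shg,
    stitch_tiles,
    transfer_rois,
)
from collalign.registration import split_into_tiles, warp_image
from collalign.stains import StainModel, compose_stains


def max_corner_error(recovered: AffineTransform, truth: AffineTransform, size: int) -> float:
    pts = np.array(
        [[0, 0], [size - 1, 0], [0, size - 1], [size - 1, size - 1], [size / 2, size / 2]],
        dtype=float,
    )
    return float(np.linalg.norm(recovered.apply(pts) - truth.apply(pts), axis=1).max())


class TestAffineTransform:
    def test_compose_and_inverse(self):
        t = AffineTransform.rotation(30.0, center=(10, 20)).compose(
            AffineTransform.translation(3.0, -4.0)
        )
        pts = np.array([[1.0, 2.0], [5.0, -3.0]])
        roundtrip = t.inverse().apply(t.apply(pts))
        assert np.allclose(roundtrip, pts, atol=1e-10)

    def test_json_round_trip(self, tmp_path):
        t = AffineTransform.scaling(1.05, 0.97, center=(50, 50))
        p = tmp_path / "t.json"
        t.to_json(p, mi=0.5)
        t2 = AffineTransform.from_json(p)
        assert np.allclose(t2.A, t.A) and np.allclose(t2.t, t.t)


class TestStitching:
    def test_single_tile_identity(self, rng):
        tile = rng.uniform(0, 255, (64, 64))
        layout = StitchLayout(grid=(1, 1), tile_size=(64, 64), overlap=0.1)
        assert np.allclose(stitch_tiles([[tile]], layout), tile)

    def test_constant_tiles_give_constant_composite(self):
        layout = StitchLayout(grid=(2, 2), tile_size=(64, 64), overlap=0.10)
        tiles = [[np.full((64, 64), 7.0)] * 2] * 2
        out = stitch_tiles(tiles, layout)
        stride = round(64 * 0.9)
        assert out.shape == (stride + 64, stride + 64)
        assert np.allclose(out, 7.0)

    def test_round_trip_reconstruction(self, shg_scene):
        img, _ = shg_scene  # 256x256
        layout = StitchLayout(grid=(2, 2), tile_size=(128, 128), overlap=0.10)
        h, w = layout.composite_shape
        scene = img[:h, :w]
        tiles = split_into_tiles(scene, layout)
        out = stitch_tiles(tiles, layout)
        assert np.abs(out - scene).mean() < 1.0

    def test_inconsistent_tile_sizes_rejected(self):
        layout = StitchLayout(grid=(1, 2), tile_size=(32, 32), overlap=0.0)
        with pytest.raises(ValueError):
            stitch_tiles([[np.zeros((32, 32)), np.zeros((16, 16))]], layout)

    def test_overlap_bounds(self):
        with pytest.raises(ValueError):
            StitchLayout(grid=(1, 1), tile_size=(32, 32), overlap=0.5)


class TestDecorrelationStretch:
    def test_constant_image_unchanged_with_warning(self):
        img = np.full((8, 8, 3), 100.0)
        with pytest.warns(UserWarning):
            out = decorrelation_stretch(img)
        assert np.array_equal(out, img)

    def test_output_channels_decorrelated(self, rng):
        base = rng.normal(128, 30, (64, 64))
        img = np.stack([base + rng.normal(0, 5, base.shape) for _ in range(3)], axis=-1)
        out = decorrelation_stretch(img, clip=False)
        flat = out.reshape(-1, 3)
        corr = np.corrcoef(flat, rowvar=False)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_whitened_input_rescaled_per_channel(self, rng):
        img = rng.normal(128, 10, (64, 64, 3))  # independent channels
        out = decorrelation_stretch(img, clip=False)
        for ch in range(3):
            r = np.corrcoef(img[..., ch].ravel(), out[..., ch].ravel())[0, 1]
            assert r > 0.99


class TestCollagenMask:
    def test_two_color_image_segmented(self, rng):
        from skimage.draw import disk

        sm = StainModel.he()
        conc = np.zeros((128, 128, 3))
        truth = np.zeros((128, 128), dtype=bool)
        for _ in range(12):
            rr, cc = disk((rng.uniform(0, 128), rng.uniform(0, 128)), 9, shape=(128, 128))
            conc[rr, cc, 1] = 0.8  # eosin blobs on white
            truth[rr, cc] = True
        rgb = np.clip(compose_stains(conc, sm), 0, 255).astype(np.uint8)
        mask = extract_collagen_mask(rgb, k=2, seed=0)
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.95

    def test_fixed_seed_deterministic(self, shg_scene):
        shg, fibers = shg_scene
        pair = make_he_pair(shg, fibers, AffineTransform.identity(), seed=8)
        m1 = extract_collagen_mask(pair.rgb, seed=3)
        m2 = extract_collagen_mask(pair.rgb, seed=3)
        assert np.array_equal(m1, m2)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            extract_collagen_mask(np.zeros((8, 8, 3), dtype=np.uint8), k=1)


class TestMutualInformation:
    def test_self_information_equals_entropy(self, rng):
        x = rng.uniform(0, 255, (64, 64))
        h, _ = np.histogram(x.ravel(), bins=32)
        p = h / h.sum()
        entropy = -(p[p > 0] * np.log2(p[p > 0])).sum()
        assert mutual_information(x, x, bins=32) == pytest.approx(entropy, abs=1e-12)

    def test_symmetry(self, rng):
        a = rng.uniform(0, 255, (64, 64))
        b = rng.uniform(0, 255, (64, 64))
        assert mutual_information(a, b) == pytest.approx(mutual_information(b, a), abs=1e-12)

    def test_independent_noise_near_zero(self, rng):
        a = rng.uniform(0, 255, (256, 256))
        b = rng.uniform(0, 255, (256, 256))
        assert mutual_information(a, b, bins=32) < 0.05

    def test_never_negative(self, rng):
        for _ in range(5):
            a = rng.integers(0, 4, (32, 32)).astype(float)
            b = rng.integers(0, 4, (32, 32)).astype(float)
            assert mutual_information(a, b, bins=8) >= 0.0


class TestRegistration:
    def test_self_registration_near_identity(self, shg_scene):
        shg, _ = shg_scene
        res = register_affine(shg, shg, seed=0)
        assert np.abs(res.transform.t).max() < 0.25
        assert np.abs(res.transform.A - np.eye(2)).max() < 0.005

    def test_known_translation_recovered(self, shg_scene):
        shg, fibers = shg_scene
        truth = AffineTransform.translation(10.0, 5.0)
        pair = make_he_pair(shg, fibers, truth, seed=8)
        res = register_he_to_shg(pair.rgb, shg, seed=0)
        assert np.abs(res.transform.t - truth.t).max() < 0.5

    def test_known_rotation_recovered(self, shg_scene):
        shg, fibers = shg_scene
        truth = AffineTransform.rotation(5.0, center=(128, 128))
        pair = make_he_pair(shg, fibers, truth, seed=8)
        res = register_he_to_shg(pair.rgb, shg, seed=0)
        ang = math.degrees(math.atan2(res.transform.A[1, 0], res.transform.A[0, 0]))
        assert abs(ang - 5.0) < 0.5

    def test_mi_trace_monotone_per_level(self, shg_scene):
        shg, fibers = shg_scene
        pair = make_he_pair(shg, fibers, AffineTransform.translation(-6.0, 9.0), seed=8)
        res = register_he_to_shg(pair.rgb, shg, seed=0)
        for level_trace in res.trace:
            assert all(b >= a - 1e-9 for a, b in zip(level_trace, level_trace[1:]))

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            register_affine(np.zeros((64, 64)), np.ones((64, 64)))

    def test_transform_composition_consistency(self, shg_scene):
        # registering A->B and B->C composes to approximately A->C
        shg, fibers = shg_scene
        t_ab = AffineTransform.translation(6.0, -4.0)
        t_bc = AffineTransform.translation(-3.0, 7.0)
        img_a = warp_image(shg, t_ab.inverse(), shg.shape)  # scene seen in frame A
        img_c = warp_image(shg, t_bc, shg.shape)
        r_ab = register_affine(shg, img_a, seed=1)  # A -> B(=shg frame)
        r_bc = register_affine(img_c, shg, seed=1)  # B -> C
        composed = r_bc.transform.compose(r_ab.transform)
        truth = t_bc.compose(t_ab)
        assert max_corner_error(composed, truth, 256) < 2.0


class TestRoiTransfer:
    def _rois(self):
        return [ROI(x=20, y=30, side_px=40, region="core", roi_id="r0")]

    def test_identity_unchanged(self):
        out = transfer_rois(self._rois(), AffineTransform.identity())
        assert (out[0].x, out[0].y, out[0].side_px) == (20, 30, 40)

    def test_translation_shifts_origin(self):
        out = transfer_rois(self._rois(), AffineTransform.translation(10, 5))
        assert (out[0].x, out[0].y, out[0].side_px) == (30, 35, 40)

    def test_right_angle_rotation_preserves_side(self):
        t = AffineTransform.rotation(90.0, center=(0, 0))
        out = transfer_rois(self._rois(), t)
        # corners (20,30),(60,30),(20,70),(60,70) -> x = -y, y = x
        assert out[0].side_px == 40
        assert (out[0].x, out[0].y) == (-70, 20)

    def test_out_of_bounds_clipped_and_flagged(self):
        out = transfer_rois(self._rois(), AffineTransform.translation(-30, 0), target_shape=(100, 100))
        assert out[0].clipped
        assert out[0].x == 0
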