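"""Slide QC: dominant colour, CIELAB conversion, dispersion, bone area,
analysable-tile counting."""

import numpy as np
import pandas as pd
import pytest

from hecif.qc import (
    analysable_tile_count,
    bone_area,
    colour_variation,
    compare_dispersion,
    dominant_colour,
    paired_comparison,
    rgb_to_cielab,
)


# -- scalar CIELAB oracle: standard sRGB -> XYZ(D65) -> L*a*b* formulas ----
def _lab_oracle(rgb8):
    def inv_gamma(u):
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    r, g, b = (inv_gamma(v / 255.0) for v in rgb8)
    # sRGB D65 matrix
    x = 0.412456439089692 * r + 0.357576077643909 * g + 0.180437483266399 * b
    y = 0.212672851405623 * r + 0.715152155287818 * g + 0.072174993306560 * b
    z = 0.019333895582329 * r + 0.119192025881303 * g + 0.950304078536368 * b
    xn, yn, zn = 0.95047, 1.0, 1.08883

    def f(t):
        d = 6 / 29
        return t ** (1 / 3) if t > d**3 else t / (3 * d**2) + 4 / 29

    fx, fy, fz = f(x / xn), f(y / yn), f(z / zn)
    return np.array([116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)])


class TestCielab:
    def test_white_point(self):
        lab = rgb_to_cielab((255, 255, 255))
        assert lab[0] == pytest.approx(100.0, abs=1e-4)
        assert abs(lab[1]) < 0.01 and abs(lab[2]) < 0.01

    def test_black(self):
        assert np.allclose(rgb_to_cielab((0, 0, 0)), (0, 0, 0), atol=1e-9)

    def test_grey_matches_scalar_oracle(self):
        assert np.allclose(rgb_to_cielab((128, 128, 128)), _lab_oracle((128, 128, 128)), atol=1e-6)

    def test_grid_matches_scalar_oracle(self):
        vals = [0, 96, 224]
        for r in vals:
            for g in vals:
                for b in vals:
                    assert np.allclose(
                        rgb_to_cielab((r, g, b)), _lab_oracle((r, g, b)), atol=1e-6
                    )

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(0)
        cols = rng.integers(0, 256, size=(50, 3)).astype(np.uint8)
        vec = rgb_to_cielab(cols)
        for i in range(50):
            assert np.allclose(vec[i], rgb_to_cielab(cols[i]), atol=1e-9)

    def test_roundtrip_within_half_unit(self):
        # inverse transform implemented here, for this test only
        from hecif.qc import _D65_WHITE, _SRGB_TO_XYZ

        def lab_to_rgb8(lab):
            d = 6 / 29
            fy = (lab[:, 0] + 16) / 116
            fx = fy + lab[:, 1] / 500
            fz = fy - lab[:, 2] / 200
            f = np.column_stack([fx, fy, fz])
            xyz = np.where(f > d, f**3, 3 * d * d * (f - 4 / 29)) * _D65_WHITE
            lin = xyz @ np.linalg.inv(_SRGB_TO_XYZ).T
            srgb = np.where(lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1 / 2.4) - 0.055)
            return np.clip(srgb * 255, 0, 255).round().astype(np.uint8)

        vals = np.linspace(10, 245, 7).astype(np.uint8)
        grid = np.stack(np.meshgrid(vals, vals, vals), axis=-1).reshape(-1, 3)
        lab = rgb_to_cielab(grid)
        lab_back = rgb_to_cielab(lab_to_rgb8(lab))
        assert np.abs(lab - lab_back).max() < 0.5


class TestDominantColour:
    def test_uniform_colour_returned_exactly(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        img[...] = (200, 30, 180)
        assert tuple(dominant_colour(img, np.ones((64, 64), bool))) == (200, 30, 180)

    def test_majority_colour_wins(self):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        img[:70] = (200, 30, 180)  # 70 %
        img[70:] = (30, 200, 60)  # 30 %
        assert tuple(dominant_colour(img, np.ones((100, 100), bool))) == (200, 30, 180)

    def test_empty_mask_error(self):
        with pytest.raises(ValueError):
            dominant_colour(np.zeros((8, 8, 3), np.uint8), np.zeros((8, 8), bool))

    def test_tracks_stain_drift_direction(self, make_constant_phantom):
        clean = make_constant_phantom(0.4, seed=33)
        drifted = make_constant_phantom(0.4, seed=33, stain_drift_sd=15.0)
        shift = np.median(
            drifted.he_image[clean.tissue_mask].astype(int)
            - clean.he_image[clean.tissue_mask].astype(int),
            axis=0,
        )
        dc_clean = dominant_colour(clean.he_image, clean.tissue_mask).astype(int)
        dc_drift = dominant_colour(drifted.he_image, clean.tissue_mask).astype(int)
        moved = dc_drift - dc_clean
        for c in range(3):
            if abs(shift[c]) >= 3:
                assert np.sign(moved[c]) == np.sign(shift[c])


class TestColourVariation:
    def test_identical_colours_zero_variance(self):
        cols = np.tile([[120, 80, 140]], (5, 1))
        out = colour_variation(cols)
        assert out["rgb_trace"] == 0.0 and out["lab_trace"] == 0.0

    def test_three_slide_textbook_variance(self):
        cols = np.array([[10, 0, 0], [20, 0, 0], [30, 0, 0]], dtype=float)
        out = colour_variation(cols)
        assert out["rgb_channel_variance"][0] == pytest.approx(100.0)  # var ddof=1
        assert out["rgb_channel_variance"][1] == 0.0

    def test_single_slide_error(self):
        with pytest.raises(ValueError):
            colour_variation(np.array([[1, 2, 3]]))

    def test_dispersion_flags_high_drift_arm(self):
        rng = np.random.default_rng(0)
        base = np.array([190, 160, 175], dtype=float)
        low = np.clip(base + rng.normal(0, 2, (10, 3)), 0, 255)
        high = np.clip(base + rng.normal(0, 10, (10, 3)), 0, 255)
        out = compare_dispersion(high, low, seed=1)
        assert out["trace_a"] > out["trace_b"]
        assert out["significant"]


class TestBoneArea:
    def test_empty_mask(self):
        assert bone_area(np.zeros((100, 100), bool), 1.0) == 0.0

    def test_unit_square(self):
        assert bone_area(np.ones((1000, 1000), bool), 1.0) == pytest.approx(1.0)

    def test_scales_with_mpp_squared(self):
        mask = np.ones((200, 300), bool)
        assert bone_area(mask, 0.5) == pytest.approx(bone_area(mask, 1.0) / 4)

    def test_phantom_bone_loss_measured(self, smooth_phantom):
        p = smooth_phantom
        from hecif.register import _warp_mask

        warped = _warp_mask(p.bone_mask, p.true_affine, p.bone_mask.shape) > 0.5
        a_ret = bone_area(p.ret_bone_mask, p.spec.mpp)
        a_he = bone_area(warped, p.spec.mpp)
        assert a_ret == pytest.approx(0.7 * a_he, rel=0.02)

    def test_bad_mpp(self):
        with pytest.raises(ValueError):
            bone_area(np.ones((4, 4), bool), 0.0)


class TestAnalysableCount:
    def _table(self, analysable, coords=None):
        n = len(analysable)
        coords = coords or [(i * 64, 0) for i in range(n)]
        return pd.DataFrame(
            {
                "index": range(n),
                "x0": [c[0] for c in coords],
                "y0": [c[1] for c in coords],
                "tile_size": [64] * n,
                "analysable": analysable,
            }
        )

    def test_none_analysable(self):
        assert analysable_tile_count(self._table([False] * 4)) == 0

    def test_constructed_count(self):
        assert analysable_tile_count(self._table([True] * 7 + [False] * 5)) == 7

    def test_annotation_restricts_to_half(self):
        coords = [((i % 4) * 64, (i // 4) * 64) for i in range(16)]
        table = self._table([True] * 16, coords)
        ann = np.zeros((256, 256), bool)
        ann[:, :128] = True  # left half = first two columns
        assert analysable_tile_count(table, ann) == 8


def test_paired_comparison_direction():
    a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    b = [2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
    out = paired_comparison(a, b)
    assert out["p_value"] < 0.05
    assert out["mean_a"] < out["mean_b"]
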