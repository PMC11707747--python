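"""Gradient-field distances, affine alignment and warping QC."""

import numpy as np
import pytest

import afstain as a
from afstain.phantom import LocalWarp
from afstain.registration import GridSpec, to_grayscale


def ramp(direction: str, n: int = 48) -> np.ndarray:
    y, x = np.mgrid[0:n, 0:n] / (n - 1)
    return x if direction == "x" else y


class TestGradientFieldDistance:
    def test_self_distance_matches_analytic_value(self):
        # d(a, a) = sum 1 - (|grad|^2 / (|grad|^2 + eps^2))^2: small where
        # gradients dominate eps, and the minimum over equal-norm partners
        rng = np.random.default_rng(0)
        patch = rng.random((32, 32))
        eps = 0.01
        gy, gx = np.gradient(patch)
        g2 = gx**2 + gy**2
        expected = np.sum(1.0 - (g2 / (g2 + eps**2)) ** 2)
        d = a.gradient_field_distance(patch, patch, "NGF", eps)
        assert d == pytest.approx(expected, rel=1e-12)
        assert a.gradient_field_distance(patch, patch, "NTG") < 1e-9

    def test_contrast_inversion_invariance_ngf(self):
        # gradient alignment is squared, so inverted contrast scores
        # exactly like self-comparison
        rng = np.random.default_rng(1)
        patch = rng.random((32, 32))
        d_self = a.gradient_field_distance(patch, patch, "NGF")
        d_inv = a.gradient_field_distance(patch, 1.0 - patch, "NGF")
        assert abs(d_self - d_inv) < 1e-9

    def test_orthogonal_ramps_maximal(self):
        # closed form: every interior pixel contributes ~1 - eps^2 terms
        n = 48
        d = a.gradient_field_distance(ramp("x", n), ramp("y", n), "NGF", eps=1e-4)
        assert d > 0.95 * n * n

    def test_symmetry_ngf(self):
        rng = np.random.default_rng(2)
        x, y = rng.random((32, 32)), rng.random((32, 32))
        assert a.gradient_field_distance(x, y) == pytest.approx(
            a.gradient_field_distance(y, x)
        )

    def test_constant_patch_with_zero_eps_raises(self):
        c = np.full((16, 16), 0.5)
        with pytest.raises(ZeroDivisionError):
            a.gradient_field_distance(c, c, "NGF", eps=0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            a.gradient_field_distance(np.zeros((8, 8)), np.zeros((9, 9)))


class TestGlobalAffine:
    def test_identity_for_equal_images(self, textured_patch_10x):
        tf = a.global_affine_align(textured_patch_10x, textured_patch_10x)
        assert tf.converged
        np.testing.assert_allclose(
            tf.matrix, np.array([[1, 0, 0], [0, 1, 0.0]]), atol=1e-3
        )

    def test_known_affine_recovered(self, textured_patch_10x):
        from scipy import ndimage

        ang = np.deg2rad(3.0)
        c, s = np.cos(ang), np.sin(ang)
        A = np.array([[c, -s], [s, c]])
        off = np.array([2.0, -1.5])
        fixed = textured_patch_10x.pixels
        moving = np.stack(
            [
                ndimage.affine_transform(fixed[:, :, k], A, offset=off,
                                         order=1, mode="nearest")
                for k in range(3)
            ],
            axis=-1,
        )
        tf = a.global_affine_align(moving, fixed)
        assert tf.converged
        # the recovered transform maps moving coords onto fixed coords,
        # i.e. it should reproduce f = A m + off at every corner
        n = fixed.shape[0] - 1
        corners = np.array([[8, 8], [8, n - 8], [n - 8, 8], [n - 8, n - 8]], float)
        np.testing.assert_allclose(
            tf.apply_to_points(corners), corners @ A.T + off, atol=0.5
        )

    def test_unrelated_images_flagged_as_failed(self):
        rng = np.random.default_rng(3)
        x = rng.random((64, 64, 1))
        y = rng.random((64, 64, 1))
        tf = a.global_affine_align(x, y)
        assert not tf.converged


class TestLocalTranslationScore:
    def test_identical_patches_score_zero(self, textured_patch_10x):
        s = a.local_translation_score(
            textured_patch_10x, textured_patch_10x, pixel_size_um=1.0
        )
        assert s.converged
        assert s.score_um_at_10x < 0.05

    def test_known_shift_recovered_as_5um(self, textured_patch_10x):
        warped = a.apply_warp(
            textured_patch_10x, a.WarpSpec(translation_xy_px=(3, 4)), order=3
        )
        s = a.local_translation_score(
            textured_patch_10x, warped, pixel_size_um=1.0
        )
        assert s.score_um_at_10x == pytest.approx(5.0, abs=0.25)

    def test_qc_decision_strict_at_threshold(self):
        mk = lambda um: a.AlignmentScore((um, 0.0), um, "NGF", True, 1.0)
        assert not a.qc_decision(mk(6.0)).misaligned  # exactly 6: retained
        assert a.qc_decision(mk(6.01)).misaligned

    def test_translation_equivariance(self, textured_patch_10x):
        w1 = a.apply_warp(textured_patch_10x, a.WarpSpec(translation_xy_px=(2, 0)), order=3)
        w2 = a.apply_warp(textured_patch_10x, a.WarpSpec(translation_xy_px=(5, 0)), order=3)
        s1 = a.local_translation_score(textured_patch_10x, w1, pixel_size_um=1.0)
        s2 = a.local_translation_score(textured_patch_10x, w2, pixel_size_um=1.0)
        # shifting b's content by +t moves the recovered vector by -t
        assert s2.translation_vector_px[0] - s1.translation_vector_px[0] == pytest.approx(
            -3.0, abs=0.25
        )

    def test_monotone_flagging_in_shift_magnitude(self, textured_patch_10x):
        decisions = []
        for um in (2.0, 5.0, 7.0, 9.0):
            w = a.apply_warp(
                textured_patch_10x,
                a.WarpSpec(translation_xy_px=(um * 0.6, um * 0.8)),
                order=3,
            )
            s = a.local_translation_score(textured_patch_10x, w, pixel_size_um=1.0)
            decisions.append(a.qc_decision(s).misaligned)
        assert decisions == sorted(decisions)  # False..False,True..True

    def test_ngf_and_ntg_decisions_agree(self, textured_patch_10x):
        for um in (3.0, 8.0):
            w = a.apply_warp(
                textured_patch_10x, a.WarpSpec(translation_xy_px=(um, 0)), order=3
            )
            d_ngf = a.qc_decision(
                a.local_translation_score(textured_patch_10x, w, "NGF",
                                          pixel_size_um=1.0)
            ).misaligned
            d_ntg = a.qc_decision(
                a.local_translation_score(textured_patch_10x, w, "NTG",
                                          pixel_size_um=1.0)
            ).misaligned
            assert d_ngf == d_ntg

    def test_small_patch_rejected(self):
        small = np.zeros((16, 16))
        with pytest.raises(ValueError):
            a.local_translation_score(small, small, pixel_size_um=1.0)


class TestExclusionMask:
    def test_identical_wsis_give_empty_mask(self, textured_patch_10x):
        mask, records = a.qc_exclusion_mask(
            textured_patch_10x, textured_patch_10x,
            GridSpec(tile_px=48), pixel_size_um=1.0,
        )
        assert not mask.any()
        assert all(not r["flagged"] for r in records)

    def test_local_warp_flags_only_affected_tiles(self):
        p = a.make_phantom(
            a.PhantomConfig(
                width_px=160, height_px=160, pixel_size_um=1.0,
                n_tumor=10, n_t_cell=8, n_cytotoxic=4, n_other=6,
                nucleus_radius_px=3.5, seed=9,
            )
        )
        img = a.render_he(p, a.RenderConfig(pixel_size_um=1.0, noise_sd=0.0))
        lw = LocalWarp(center_xy_px=(40, 40), radius_px=30,
                       displacement_xy_px=(10.0, 0.0))
        warped = a.apply_warp(img, a.WarpSpec(local_warps=(lw,)), order=3)
        mask, records = a.qc_exclusion_mask(
            img, warped, GridSpec(tile_px=64, overlap=0.5), pixel_size_um=1.0
        )
        assert mask[40, 40]  # warp center excluded
        assert not mask[150, 150]  # far corner untouched

    def test_subthreshold_global_residual_keeps_everything(self, textured_patch_10x):
        shifted = a.apply_warp(
            textured_patch_10x, a.WarpSpec(translation_xy_px=(2.0, 0.0)), order=3
        )
        mask, _ = a.qc_exclusion_mask(
            textured_patch_10x, shifted, GridSpec(tile_px=48), pixel_size_um=1.0
        )
        assert not mask.any()


def test_grayscale_modes():
    rgb = np.random.default_rng(0).random((8, 8, 3))
    bundle = a.ImageBundle(rgb, ("R", "G", "B"), 1.0)
    g = to_grayscale(bundle)
    assert g.shape == (8, 8) and g.min() >= 0 and g.max() <= 1
    multi = a.ImageBundle(np.random.default_rng(1).random((8, 8, 5)),
                          tuple("abcde"), 1.0)
    assert to_grayscale(multi).shape == (8, 8)
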