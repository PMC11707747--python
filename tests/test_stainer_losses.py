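"""Stainer loss components: pixel weighting, shift-invariant regression,
rotational consistency, adversarial terms, Fréchet distance, checkpoint
selection, and the autodiff gradient sanity check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import afstain as a
from afstain.nn import UNetGenerator
from afstain.nn import autodiff as ad
from afstain.stainer import (
    Checkpoint,
    DiscriminatorSet,
    RandomProjectionFeatures,
    TrainState,
    _shift_invariant_loss_tensor,
)


class TestPixelWeight:
    def test_unit_intensity_clamps_to_one(self):
        assert a.pixel_weight(1.0, a.WeightingScheme(imax=100.0)) == 1.0

    def test_cd8_clamp_below_15(self):
        assert a.pixel_weight(10.0, a.CD8_WEIGHTING) == 1.0
        assert a.pixel_weight(14.999, a.CD8_WEIGHTING) == 1.0
        assert a.pixel_weight(15.0, a.CD8_WEIGHTING) == np.log(15.0)

    def test_constant_above_imax(self):
        scheme = a.WeightingScheme(imax=50.0)
        w_at = a.pixel_weight(50.0, scheme)
        w_beyond = a.pixel_weight(500.0, scheme)
        assert w_at == w_beyond == np.log(50.0)

    def test_log10_base(self):
        scheme = a.WeightingScheme(imax=1000.0, log_base="10")
        assert a.pixel_weight(100.0, scheme) == pytest.approx(2.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.0, 400.0), st.floats(0.0, 400.0))
    def test_monotone_nondecreasing_and_floor(self, i1, i2):
        scheme = a.WeightingScheme(imax=255.0, clamp_below=15.0)
        lo, hi = sorted((i1, i2))
        assert 1.0 <= a.pixel_weight(lo, scheme) <= a.pixel_weight(hi, scheme)

    def test_vectorized_equals_scalar_loop(self):
        rng = np.random.default_rng(0)
        grid = rng.uniform(0, 400, (13, 7))
        scheme = a.WeightingScheme(imax=200.0, clamp_below=15.0)
        vec = a.pixel_weight(grid, scheme)
        loop = np.array([[a.pixel_weight(v, scheme) for v in row] for row in grid])
        np.testing.assert_array_equal(vec, loop)

    def test_degenerate_imax_rejected(self):
        with pytest.raises(ValueError):
            a.WeightingScheme(imax=1.0)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            a.pixel_weight(-1.0, a.WeightingScheme())


class TestShiftInvariantLoss:
    def make_target(self, seed=0, size=96, pad=16):
        rng = np.random.default_rng(seed)
        return rng.random((size, size, 2)), pad

    def test_center_crop_gives_zero_at_center_offset(self):
        tgt, pad = self.make_target()
        pred = tgt[pad:-pad, pad:-pad]
        loss, off = a.shift_invariant_regression_loss(pred, tgt)
        assert loss == 0.0
        assert off == (pad, pad)

    @pytest.mark.parametrize("off", [(0, 0), (4, 16), (32, 7), (32, 32)])
    def test_any_crop_within_pad_recovered_exactly(self, off):
        tgt, _ = self.make_target(seed=3)
        ox, oy = off
        pred = tgt[oy : oy + 64, ox : ox + 64]
        loss, rec = a.shift_invariant_regression_loss(pred, tgt)
        assert loss == 0.0
        assert rec == (ox, oy)

    def test_uniform_weights_match_unweighted(self):
        tgt, pad = self.make_target(seed=5)
        rng = np.random.default_rng(1)
        pred = rng.random((64, 64, 2))
        l_none, o_none = a.shift_invariant_regression_loss(pred, tgt)
        l_unif, o_unif = a.shift_invariant_regression_loss(
            pred, tgt, weights=np.full(tgt.shape[:2], 3.7)
        )
        assert l_none == pytest.approx(l_unif, rel=1e-12)
        assert o_none == o_unif

    def test_never_exceeds_fixed_center_loss(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            tgt = rng.random((96, 96, 1))
            pred = rng.random((64, 64, 1))
            shift_loss, _ = a.shift_invariant_regression_loss(pred, tgt)
            center = tgt[16:80, 16:80]
            d = pred - center
            fixed = np.abs(d).mean() + (d * d).mean()
            assert shift_loss <= fixed + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            a.shift_invariant_regression_loss(
                np.zeros((64, 64, 2)), np.zeros((96, 96, 3))
            )

    def test_tensor_version_matches_value(self):
        tgt, _ = self.make_target(seed=9)
        rng = np.random.default_rng(2)
        pred_val = rng.random((1, 64, 64, 2))
        pred = ad.Tensor(pred_val, requires_grad=True)
        loss_t = _shift_invariant_loss_tensor(pred, tgt[None], None)
        loss_f, _ = a.shift_invariant_regression_loss(pred_val[0], tgt)
        assert float(loss_t.value) == pytest.approx(loss_f, rel=1e-12)


class PointwiseGenerator:
    """Spatially pointwise toy model: exactly rotation-equivariant."""

    def __call__(self, x):
        t = ad.as_tensor(x)
        return ad.mul(t, 2.0)


class TestRotationalConsistency:
    def test_pointwise_generator_scores_zero(self):
        af = np.random.default_rng(0).random((8, 8, 3))
        for k in (1, 2, 3):
            assert a.rotational_consistency_loss(PointwiseGenerator(), af, k=k) == 0.0

    def test_orientation_biased_model_scores_positive(self):
        class Biased:
            def __call__(self, x):
                t = ad.as_tensor(x)
                ramp = np.linspace(0, 1, t.shape[2])[None, None, :, None]
                return t * 0.0 + ad.Tensor(np.broadcast_to(
                    ramp, t.shape).copy())

        af = np.ones((1, 8, 8, 2))
        assert a.rotational_consistency_loss(Biased(), af[0], k=1) > 0.1

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            a.rotational_consistency_loss(PointwiseGenerator(),
                                          np.zeros((8, 10, 2)))


class TestAdversarialLosses:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.discs = DiscriminatorSet(rng, af_channels=4, stain_channels=2)
        self.af = np.random.default_rng(1).random((2, 16, 16, 4))
        self.real = np.random.default_rng(2).random((2, 16, 16, 2))
        self.fake = np.random.default_rng(3).random((2, 16, 16, 2))

    def test_chance_discriminator_gives_log2_constants(self):
        # zero all discriminator weights -> every logit is 0 -> sigmoid 0.5
        for p in self.discs.parameters():
            p.value = np.zeros_like(p.value)
        g_adv, d_adv = a.adversarial_losses(self.discs, self.af, self.real,
                                            self.fake)
        assert float(g_adv.value) == pytest.approx(3 * np.log(2.0))
        assert float(d_adv.value) == pytest.approx(3 * np.log(2.0))

    def test_zero_branch_weight_removes_contribution(self):
        g_all, _ = a.adversarial_losses(self.discs, self.af, self.real,
                                        self.fake, (1.0, 1.0, 1.0))
        g_cond, _ = a.adversarial_losses(self.discs, self.af, self.real,
                                         self.fake, (1.0, 0.0, 0.0))
        g_unc, _ = a.adversarial_losses(self.discs, self.af, self.real,
                                        self.fake, (0.0, 1.0, 1.0))
        assert float(g_all.value) == pytest.approx(
            float(g_cond.value) + float(g_unc.value)
        )


class TestFrechet:
    def test_identical_sets_zero(self):
        x = np.random.default_rng(0).random((50, 4))
        assert a.frechet_feature_distance(x, x) == pytest.approx(0.0, abs=1e-8)

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (10000, 1))
        y = rng.normal(2, 1, (10000, 1))
        # equal covariances: distance = (mu1 - mu2)^2 = 4
        assert a.frechet_feature_distance(x, y) == pytest.approx(4.0, abs=0.3)

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        x, y = rng.random((30, 3)), rng.random((40, 3))
        assert a.frechet_feature_distance(x, y) == pytest.approx(
            a.frechet_feature_distance(y, x), rel=1e-9
        )

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError):
            a.frechet_feature_distance(np.zeros((1, 3)), np.zeros((5, 3)))

    def test_random_projection_features_deterministic(self):
        x = np.random.default_rng(3).random((4, 8, 8, 2))
        f1 = RandomProjectionFeatures(8, seed=1)(x)
        f2 = RandomProjectionFeatures(8, seed=1)(x)
        np.testing.assert_array_equal(f1, f2)


class TestSelectCheckpoint:
    @staticmethod
    def make_state(metrics):
        cps = [Checkpoint(step=s, arrays=[], val_l1=l1, val_fd=fd)
               for s, l1, fd in metrics]
        return TrainState(step=metrics[-1][0], config=None, generator=None,
                          history=[], val_records=[], checkpoints=cps)

    def test_single_checkpoint_selected(self):
        st_ = self.make_state([(100, 0.5, 2.0)])
        assert a.select_checkpoint(st_).step == 100

    def test_dominating_checkpoint_selected(self):
        st_ = self.make_state([(1, 0.9, 5.0), (2, 0.1, 1.0), (3, 0.5, 3.0)])
        assert a.select_checkpoint(st_).step == 2

    def test_rank_sum_crossing_case(self):
        # A best L1 (worst FD), B best FD (worst L1), C second in both:
        # ranks A=(1,3), B=(3,1), C=(2,2) -> tie 4,4,4 -> earliest step wins;
        # make C strictly best by worsening A's FD rank margin via a 4th entry
        st_ = self.make_state([
            (1, 0.1, 9.0),   # A: L1 rank 1, FD rank 4
            (2, 0.9, 1.0),   # B: L1 rank 4, FD rank 1
            (3, 0.2, 2.0),   # C: L1 rank 2, FD rank 2 -> sum 4 (best)
            (4, 0.3, 3.0),   # D: rank 3,3
        ])
        assert a.select_checkpoint(st_).step == 3

    def test_tie_goes_to_earlier_step(self):
        st_ = self.make_state([(5, 0.2, 2.0), (9, 0.2, 2.0)])
        assert a.select_checkpoint(st_).step == 5

    def test_empty_rejected(self):
        st_ = TrainState(step=0, config=None, generator=None, history=[],
                         val_records=[], checkpoints=[])
        with pytest.raises(ValueError):
            a.select_checkpoint(st_)


class TestGradients:
    def test_composite_loss_gradient_matches_finite_differences(self):
        gen = UNetGenerator(np.random.default_rng(0), in_channels=3,
                            out_channels=2, base_filters=4, depth=1)
        af = np.random.default_rng(1).random((1, 8, 8, 3))
        tgt = np.random.default_rng(2).random((1, 12, 12, 2))

        def composite():
            pred = gen(af)
            loss = _shift_invariant_loss_tensor(pred, tgt, None)
            loss = loss + 0.1 * gen.weight_sq_norm()
            return loss

        loss = composite()
        loss.backward()
        checked = 0
        for p in gen.parameters()[:3]:
            g = p.grad
            idx = tuple(0 for _ in p.value.shape)
            eps = 1e-6
            p.value[idx] += eps
            up = float(composite().value)
            p.value[idx] -= 2 * eps
            down = float(composite().value)
            p.value[idx] += eps
            fd = (up - down) / (2 * eps)
            assert fd == pytest.approx(g[idx], rel=1e-4, abs=1e-10)
            checked += 1
        assert checked == 3
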