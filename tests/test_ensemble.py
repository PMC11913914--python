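"""Tests for member training, augmentation, fusion and the soft Dice loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ennseg.ensemble import (
    EnsembleConfig,
    EnsembleModel,
    augment,
    fuse,
    member_seed,
    predict_slice,
    soft_dice_loss,
    train_member,
)
from ennseg.metrics import dice
from ennseg.nn import TinyUNet, sigmoid, soft_dice_loss_grad, standardize_slice


class TestFuse:
    def test_mean_of_identical_maps(self):
        m = np.random.default_rng(0).random((8, 8))
        pred = fuse([m, m, m])
        assert np.allclose(pred.fused_prob, m)

    def test_worked_average(self):
        maps = [np.full((1, 1), v) for v in (0.9, 0.9, 0.2, 0.2)]
        pred = fuse(maps)
        assert pred.fused_prob[0, 0] == pytest.approx(0.55)
        assert pred.binary_mask[0, 0]

    def test_tie_at_half_goes_to_foreground(self):
        pred = fuse([np.full((1, 1), 0.6), np.full((1, 1), 0.4)])
        assert pred.fused_prob[0, 0] == pytest.approx(0.5)
        assert pred.binary_mask[0, 0]

    def test_permutation_invariant_and_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        maps = [rng.random((6, 6)) for _ in range(5)]
        pred = fuse(maps)
        # Brute-force voxel loop oracle.
        expect = np.zeros((6, 6))
        for y in range(6):
            for x in range(6):
                expect[y, x] = sum(m[y, x] for m in maps) / len(maps)
        assert np.allclose(pred.fused_prob, expect)
        shuffled = fuse([maps[i] for i in rng.permutation(5)])
        assert np.allclose(pred.fused_prob, shuffled.fused_prob, rtol=0, atol=1e-14)

    def test_mask_consistent_with_threshold(self):
        rng = np.random.default_rng(9)
        pred = fuse([rng.random((16, 16)) for _ in range(3)])
        assert np.array_equal(pred.binary_mask, pred.fused_prob >= 0.5)

    def test_errors(self):
        with pytest.raises(ValueError):
            fuse([])
        with pytest.raises(ValueError):
            fuse([np.zeros((4, 4)), np.zeros((5, 5))])
        with pytest.raises(ValueError):
            fuse([np.full((2, 2), 1.5)])


class TestSoftDiceLoss:
    def test_identity_loss_zero(self):
        t = np.zeros((6, 6))
        t[2:4, 2:4] = 1.0
        assert soft_dice_loss(t, t, smooth=1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_complement_loss_one(self):
        t = np.zeros((6, 6))
        t[2:4, 2:4] = 1.0
        assert soft_dice_loss(1.0 - t, t, smooth=1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_worked_example_2x2(self):
        pred = np.full((2, 2), 0.5)
        target = np.array([[1.0, 1.0], [0.0, 0.0]])
        assert soft_dice_loss(pred, target, smooth=1e-12) == pytest.approx(1 / 3)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_equals_one_minus_hard_dice_on_binary(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((7, 7)) > 0.5
        t = rng.random((7, 7)) > 0.5
        if p.sum() + t.sum() == 0:
            return
        loss = soft_dice_loss(p.astype(float), t.astype(float), smooth=1e-12)
        assert loss == pytest.approx(1.0 - dice(p, t), abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((5, 5))
        t = (rng.random((5, 5)) > 0.5).astype(float)
        assert 0.0 <= soft_dice_loss(p, t) <= 1.0

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        logits = rng.normal(0, 1, (2, 4, 4))
        targets = (rng.random((2, 4, 4)) > 0.5).astype(float)
        loss, grad = soft_dice_loss_grad(logits, targets, smooth=1.0)
        eps = 1e-6
        for idx in [(0, 1, 2), (1, 3, 0), (0, 0, 0)]:
            bumped = logits.copy()
            bumped[idx] += eps
            lp, _ = soft_dice_loss_grad(bumped, targets, smooth=1.0)
            assert grad[idx] == pytest.approx((lp - loss) / eps, rel=1e-3, abs=1e-8)


class _StubRng:
    """Deterministic rng stand-in: no flips, fixed rotation angle, unit jitter."""

    def __init__(self, angle):
        self.angle = angle

    def random(self):
        return 0.9  # never triggers a p=0.5 flip

    def uniform(self, lo, hi):
        if (lo, hi) == (-90.0, 90.0):
            return self.angle
        return 1.0


class TestAugment:
    def test_identity_config_is_noop(self):
        rng = np.random.default_rng(0)
        img = np.arange(16.0).reshape(4, 4)
        mask = img > 7
        out_img, out_mask = augment(img, mask, rng, ops=())
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_mask, mask)

    def test_hflip_is_involution(self):
        img = np.arange(16.0).reshape(4, 4)
        mask = img > 7

        class AlwaysFlip:
            def random(self):
                return 0.0

        once_img, once_mask = augment(img, mask, AlwaysFlip(), ops=("hflip",))
        twice_img, twice_mask = augment(once_img, once_mask, AlwaysFlip(), ops=("hflip",))
        assert np.array_equal(twice_img, img)
        assert np.array_equal(twice_mask, mask)
        assert not np.array_equal(once_img, img)

    def test_rotation_moves_centroid_to_rotated_position(self):
        img = np.zeros((65, 65))
        mask = np.zeros((65, 65), dtype=bool)
        mask[10:14, 30:34] = True  # off-center blob above the center
        img[mask] = 100.0
        out_img, out_mask = augment(
            img, mask, _StubRng(90.0), ops=("rotate",), rotation_degrees=90.0
        )
        cy, cx = np.argwhere(out_mask).mean(axis=0)
        # 90 deg rotation about the image center maps (y, x) -> (c - (x - c), c + (y - c)).
        oy, ox = np.argwhere(mask).mean(axis=0)
        ey, ex = 32 - (ox - 32), 32 + (oy - 32)
        assert abs(cy - ey) <= 1.0 and abs(cx - ex) <= 1.0
        assert set(np.unique(out_mask)) <= {False, True}
        # Geometric transform applied identically: image support follows the mask.
        assert np.argwhere(out_img > 50).mean(axis=0) == pytest.approx((cy, cx), abs=1.0)

    def test_intensity_jitter_leaves_mask_untouched(self):
        rng = np.random.default_rng(1)
        img = np.ones((4, 4))
        mask = np.eye(4, dtype=bool)
        out_img, out_mask = augment(img, mask, rng, ops=("intensity",),
                                    intensity_jitter=(0.5, 0.5))
        assert np.allclose(out_img, 0.5)
        assert np.array_equal(out_mask, mask)


class TestTraining:
    def test_member_seeding_gives_distinct_initial_weights(self):
        cfgs = [member_seed(0, k) for k in range(4)]
        assert len(set(cfgs)) == 4
        checksums = {
            TinyUNet(rng=np.random.default_rng(np.random.SeedSequence(list(k)))).checksum()
            for k in cfgs
        }
        assert len(checksums) == 4

    def test_training_is_deterministic(self, small_cohort):
        from ennseg.pipeline import cohort_slice_pairs, split_cohort

        split = split_cohort(small_cohort, seed=3)
        pairs = cohort_slice_pairs(small_cohort, split.holdout)
        cfg = EnsembleConfig(n_members=2, epochs=2, channels=4, base_seed=11)
        a = train_member(pairs, [], cfg, 0)
        b = train_member(pairs, [], cfg, 0)
        assert a.log == b.log  # bitwise-identical loss curves
        assert a.model.checksum() == b.model.checksum()
        c = train_member(pairs, [], cfg, 1)
        assert c.log != a.log

    def test_loss_decreases_over_training(self, tiny_trained):
        for member in tiny_trained["model"].members:
            log = member.log
            assert log[-1]["train_loss"] < log[0]["train_loss"]
            assert member.best_epoch == int(
                np.argmin([r["val_loss"] for r in log])
            )

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_member([], [], EnsembleConfig(n_members=1, epochs=1), 0)

    def test_trained_ensemble_segments_holdout(self, tiny_trained):
        from ennseg.ensemble import predict_slices

        pairs = tiny_trained["holdout_pairs"]
        preds = predict_slices(tiny_trained["model"], [s for s, _ in pairs])
        scores = [dice(p.binary_mask, m.mask) for p, (_, m) in zip(preds, pairs)]
        # Miniature run (6 patients, 2 members, 8 epochs): well above chance,
        # below what the full-scale configuration reaches.
        assert np.median(scores) > 0.6

    def test_predict_slice_single_member_equals_model_output(self, tiny_trained):
        member = tiny_trained["model"].members[0]
        single = EnsembleModel(members=[member], config=tiny_trained["config"])
        ct_slice, _ = tiny_trained["holdout_pairs"][0]
        pred = predict_slice(single, ct_slice)
        direct = member.model.predict_proba(standardize_slice(ct_slice.pixels)[None])[0]
        assert np.allclose(pred.fused_prob, direct)

    def test_ensemble_of_copies_equals_member(self, tiny_trained):
        member = tiny_trained["model"].members[0]
        copies = EnsembleModel(
            members=[member, member, member], config=tiny_trained["config"]
        )
        ct_slice, _ = tiny_trained["holdout_pairs"][0]
        one = predict_slice(
            EnsembleModel(members=[member], config=tiny_trained["config"]), ct_slice
        )
        three = predict_slice(copies, ct_slice)
        assert np.allclose(one.fused_prob, three.fused_prob)

    def test_checkpoint_roundtrip(self, tmp_path, tiny_trained):
        model = tiny_trained["model"]
        model.save(tmp_path / "model")
        back = EnsembleModel.load(tmp_path / "model")
        assert back.n_members == model.n_members
        for a, b in zip(model.members, back.members):
            assert a.model.checksum() == b.model.checksum()
        ct_slice, _ = tiny_trained["holdout_pairs"][0]
        assert np.allclose(
            predict_slice(model, ct_slice).fused_prob,
            predict_slice(back, ct_slice).fused_prob,
        )

    def test_config_invariants(self):
        cfg = EnsembleConfig()
        assert (cfg.n_members, cfg.epochs, cfg.batch_size) == (10, 20, 64)
        assert (cfg.learning_rate, cfg.momentum) == (0.1, 0.9)
        with pytest.raises(ValueError):
            EnsembleConfig(backbone="deeplab")
        with pytest.raises(ValueError):
            EnsembleConfig(n_members=0)


class TestSigmoid:
    def test_extreme_logits_are_stable(self):
        z = np.array([-1000.0, 0.0, 1000.0])
        out = sigmoid(z)
        assert np.all(np.isfinite(out))
        assert out[0] == 0.0 and out[1] == 0.5 and out[2] == 1.0
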