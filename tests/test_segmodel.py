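"""Network contracts: shapes, loss algebra, augmentation pairing, training."""

import numpy as np
import pytest

from ttcseg import segmodel, synthdata
from ttcseg.scheme import N_CLASSES
from ttcseg.segmodel import (AugmentConfig, TrainConfig, augment, build_unet,
                             composite_loss, maps_to_mask, predict, train)


@pytest.fixture(scope="module")
def micro_faces():
    """A small learnable fixture: 64-px phantom faces."""
    cfg = synthdata.PhantomConfig(n_experiments=3, image_size=64, seed=21)
    exps, _ = synthdata.generate_cohort(cfg)
    return segmodel.collect_faces(exps, 64)


class TestBuildUnet:
    def test_output_shape_contract(self):
        cfg = TrainConfig.tiny(image_size=96)
        net = build_unet(cfg)
        x = np.zeros((2, 3, 96, 96), dtype=np.float32)
        assert net.forward(x).shape == (2, N_CLASSES, 96, 96)

    def test_indivisible_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            TrainConfig.tiny(image_size=100)
        with pytest.raises(ValueError, match="divisible"):
            segmodel.DynamicUNet(image_size=100, depth=3)

    def test_same_seed_identical_init(self):
        a = build_unet(TrainConfig.tiny(seed=9))
        b = build_unet(TrainConfig.tiny(seed=9))
        for pa, pb in zip(a.params, b.params):
            np.testing.assert_array_equal(pa, pb)

    def test_pretrained_weights_unavailable(self):
        with pytest.raises(ValueError, match="pretrained"):
            build_unet(TrainConfig.tiny(pretrained_encoder=True))


class TestCompositeLoss:
    def test_perfect_prediction_zero(self):
        tgt = np.random.default_rng(0).integers(0, 5, (8, 8))
        onehot = np.moveaxis(np.eye(5)[tgt], -1, 0)
        assert composite_loss(onehot, tgt) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_probability_mae(self):
        probs = np.full((5, 6, 6), 0.2)
        tgt = np.zeros((6, 6), dtype=int)
        # (0.8 + 4*0.2)/5 per pixel
        assert composite_loss(probs, tgt, component_weights=(0, 1, 0)) == \
            pytest.approx(0.32)

    def test_component_isolation(self, rng):
        probs = rng.dirichlet(np.ones(5), size=(6, 6)).transpose(2, 0, 1)
        tgt = rng.integers(0, 5, (6, 6))
        w = np.array([1.0, 2.0, 1.0, 3.0, 1.0])
        ce_only = composite_loss(probs, tgt, class_weights=w,
                                 component_weights=(1, 0, 0))
        pix_w = w[tgt]
        p_true = np.take_along_axis(probs, tgt[None], axis=0)[0]
        expected = np.sum(pix_w * -np.log(p_true)) / pix_w.sum()
        assert ce_only == pytest.approx(expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            composite_loss(np.zeros((5, 4, 4)), np.zeros((5, 5), dtype=int))

    def test_loss_gradient_matches_finite_difference(self, rng):
        logits = rng.standard_normal((1, 5, 4, 4))
        tgt = rng.integers(0, 5, (1, 4, 4))
        w = np.ones(5)
        loss, grad = segmodel._loss_and_grad(logits, tgt, w, (1.0, 1.0, 1.0))
        eps = 1e-6
        for _ in range(6):
            i = tuple(rng.integers(0, s) for s in logits.shape)
            up = logits.copy()
            up[i] += eps
            down = logits.copy()
            down[i] -= eps
            num = (segmodel._loss_and_grad(up, tgt, w, (1, 1, 1))[0]
                   - segmodel._loss_and_grad(down, tgt, w, (1, 1, 1))[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-5)


class TestAugment:
    def test_same_seed_identical(self, micro_faces):
        _, img, mask = micro_faces[0]
        a = augment(img, mask, np.random.default_rng(5))
        b = augment(img, mask, np.random.default_rng(5))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_mask_stays_in_scheme(self, micro_faces):
        _, img, mask = micro_faces[1]
        for seed in range(5):
            _, out_mask = augment(img, mask, np.random.default_rng(seed))
            assert set(np.unique(out_mask)) <= set(range(N_CLASSES))
            assert out_mask.shape == mask.shape

    def test_geometric_consistency_pure_rotation(self, micro_faces):
        """With only rotation enabled, the mask transform matches a direct
        rotation of the mask."""
        from skimage.transform import rotate as sk_rotate
        _, img, mask = micro_faces[2]
        cfg = AugmentConfig(rotate_deg=30, zoom=(1.0, 1.0), shear_deg=0.0,
                            brightness=0, contrast=0, saturation=0,
                            erase_prob=0, blur_prob=0)
        rng = np.random.default_rng(3)
        angle_probe = np.random.default_rng(3).uniform(-30, 30)
        _, out_mask = augment(img, mask, rng, cfg)
        agree = max(
            np.mean(out_mask == sk_rotate(
                mask, sign * angle_probe, order=0, preserve_range=True,
                center=(mask.shape[1] / 2, mask.shape[0] / 2)
            ).astype(mask.dtype))
            for sign in (1, -1)
        )
        # only thin class-boundary bands may disagree (half-pixel centers)
        assert agree > 0.95

    def test_paired_erasing(self, micro_faces):
        _, img, mask = micro_faces[0]
        cfg = AugmentConfig(rotate_deg=0, zoom=(1.0, 1.0), shear_deg=0.0,
                            brightness=0, contrast=0, saturation=0,
                            erase_prob=1.0, erase_frac=(0.1, 0.1), blur_prob=0)
        out_img, out_mask = augment(img, mask, np.random.default_rng(7), cfg)
        erased = np.all(out_img == 0, axis=-1) & ~np.all(img == 0, axis=-1)
        assert erased.any()
        assert (out_mask[erased] == 0).all()


class TestPredictAndArgmax:
    def test_probability_normalization(self, micro_faces):
        cfg = TrainConfig.tiny(image_size=64, min_epochs=1)
        net = build_unet(cfg)
        _, img, _ = micro_faces[0]
        maps = predict(net, img)
        assert maps.shape == (N_CLASSES, 64, 64)
        assert maps.max() <= 1.0 and maps.min() >= 0.0
        np.testing.assert_allclose(maps.sum(axis=0), 1.0, atol=1e-5)
        np.testing.assert_array_equal(maps, predict(net, img))

    def test_wrong_size_rejected(self, micro_faces):
        net = build_unet(TrainConfig.tiny(image_size=96))
        _, img, _ = micro_faces[0]
        with pytest.raises(ValueError, match="size"):
            predict(net, img)

    def test_argmax_and_tie_rule(self):
        maps = np.zeros((5, 1, 2))
        maps[:, 0, 0] = [0.1, 0.1, 0.1, 0.6, 0.1]
        maps[:, 0, 1] = [0.0, 0.5, 0.0, 0.5, 0.0]   # tie -> lowest index
        mask = maps_to_mask(maps)
        assert mask[0, 0] == 3
        assert mask[0, 1] == 1

    def test_onehot_inverse(self, rng):
        tgt = rng.integers(0, 5, (6, 6))
        onehot = np.moveaxis(np.eye(5)[tgt], -1, 0)
        np.testing.assert_array_equal(maps_to_mask(onehot), tgt)


class TestTraining:
    def test_learning_and_best_selection(self, micro_faces):
        pairs = [(img, m) for _, img, m in micro_faces]
        cfg = TrainConfig.tiny(image_size=64, min_epochs=4, batch_size=4,
                               seed=2)
        tm = train(pairs[:10], pairs[10:14], cfg)
        losses = [h["train_loss"] for h in tm.history]
        assert len(losses) == 4
        assert min(losses[1:]) < losses[0]          # it learns
        best_dsc = tm.history[tm.best_epoch - 1]["val_dsc"]
        assert best_dsc == max(h["val_dsc"] for h in tm.history)
        assert best_dsc >= tm.history[-1]["val_dsc"]

    def test_empty_sets_error(self, micro_faces):
        pairs = [(img, m) for _, img, m in micro_faces[:4]]
        with pytest.raises(ValueError):
            train([], pairs, TrainConfig.tiny(image_size=64))
        with pytest.raises(ValueError):
            train(pairs, [], TrainConfig.tiny(image_size=64))

    def test_save_load_round_trip(self, tmp_path, micro_faces):
        pairs = [(img, m) for _, img, m in micro_faces]
        cfg = TrainConfig.tiny(image_size=64, min_epochs=1, batch_size=4)
        tm = train(pairs[:6], pairs[6:8], cfg)
        tm.save(tmp_path / "model.npz")
        loaded = segmodel.TrainedModel.load(tmp_path / "model.npz")
        img = pairs[0][0]
        np.testing.assert_allclose(predict(tm, img), predict(loaded, img),
                                   atol=1e-6)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"learning_rate": 0.0},
        {"dropout_fraction": 1.0},
        {"batch_size": 0},
        {"class_weighting": "magic"},
    ])
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig.tiny(**kwargs)
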