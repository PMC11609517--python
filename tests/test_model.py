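"""Network contracts, resizing, augmentation, and the training loop."""

import numpy as np
import pytest

from octaplex import nn
from octaplex.model import (SegmentationModel, TrainConfig, TrainingPair,
                            as_training_pairs, augment, build_network,
                            largest_inscribed_square_side, resize_for_model,
                            resize_mask)


class TestNetwork:
    def test_softmax_sums_to_one_per_pixel(self):
        net = build_network(TrainConfig(input_size=32))
        x = np.random.default_rng(0).random((2, 32, 32, 1)).astype(np.float32)
        p = net.predict_proba(x)
        assert p.shape == (2, 32, 32, 3)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-5)

    def test_tiny_parameter_budget(self):
        net = build_network(TrainConfig(backbone_scale="tiny"))
        assert net.n_params < 1_000_000

    def test_architectures_differ_only_in_merge(self):
        u = build_network(TrainConfig(architecture="unet_like"))
        l = build_network(TrainConfig(architecture="linknet_like"))
        # encoders identical in shape; decoders differ at the merge convs
        for lu, ll in zip([u.adapter, u.stem] + u.enc + [u.bott],
                          [l.adapter, l.stem] + l.enc + [l.bott]):
            assert lu.W.shape == ll.W.shape
        for mu, ml in zip(u.merge, l.merge):
            assert mu.W.shape[0] == 2 * ml.W.shape[0]  # concat vs add
            assert mu.W.shape[1] == ml.W.shape[1]

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            nn.EncoderDecoder("segnet_like")

    def test_paper_scale_constructs_deeper_network(self):
        tiny = build_network(TrainConfig(backbone_scale="tiny"))
        paper = build_network(TrainConfig(backbone_scale="paper"))
        assert paper.n_params > 50 * tiny.n_params


class TestResize:
    def test_500_to_256(self):
        img = np.random.default_rng(0).uniform(0, 255, (500, 500))
        out = resize_for_model(img, 256)
        assert out.shape == (256, 256)

    def test_same_size_is_identity(self):
        img = np.random.default_rng(1).uniform(0, 255, (64, 64))
        np.testing.assert_array_equal(resize_for_model(img, 64), img)

    def test_constant_image_preserved(self):
        out = resize_for_model(np.full((100, 100), 37.0), 64)
        np.testing.assert_allclose(out, 37.0, atol=1e-9)

    def test_area_average_conserves_mean(self):
        img = np.random.default_rng(2).uniform(0, 255, (96, 96))
        out = resize_for_model(img, 48)
        assert out.mean() == pytest.approx(img.mean(), rel=1e-9)

    def test_mask_resize_stays_binary(self):
        mask = np.random.default_rng(3).random((100, 100)) > 0.5
        out = resize_mask(mask, 64)
        assert out.dtype == bool and out.shape == (64, 64)


class TestAugment:
    def test_flips_involution_with_zero_rotation(self):
        g = np.random.default_rng(0)
        img = g.uniform(0, 255, (32, 32))
        tgt = (g.random((32, 32)) > 0.5).astype(np.int8)

        class TwoFlipRng:
            """hflip twice, no vflip, no rotation"""
            def __init__(self):
                self.calls = 0
            def random(self):
                self.calls += 1
                return 0.0 if self.calls in (1, 3) else 1.0
            def uniform(self, a, b):
                return 0.0

        r = TwoFlipRng()
        i1, t1 = augment(img, tgt, r)
        i2, t2 = augment(i1, t1, r)
        np.testing.assert_array_equal(i2, img)
        np.testing.assert_array_equal(t2, tgt)

    def test_45_degree_crop_side(self):
        assert largest_inscribed_square_side(64, 45.0) == int(64 / np.sqrt(2))
        assert largest_inscribed_square_side(64, 0.0) == 64

    def test_no_padding_fill_survives(self):
        # image of constant 200 on every pixel: any padding would show as
        # values pulled toward the 0 fill
        img = np.full((64, 64), 200.0)
        tgt = np.ones((64, 64), dtype=np.int8)
        g = np.random.default_rng(4)
        for _ in range(10):
            out, _ = augment(img, tgt, g)
            assert out.min() >= 199.0

    def test_target_stays_categorical(self):
        g = np.random.default_rng(5)
        img = g.uniform(0, 255, (64, 64))
        tgt = g.integers(0, 3, (64, 64)).astype(np.int8)
        for _ in range(5):
            _, t = augment(img, tgt, g)
            assert set(np.unique(t)) <= {0, 1, 2}

    def test_single_class_target_class_set_unchanged(self):
        g = np.random.default_rng(6)
        img = g.uniform(0, 255, (64, 64))
        tgt = np.full((64, 64), 2, dtype=np.int8)
        for _ in range(5):
            _, t = augment(img, tgt, g)
            assert set(np.unique(t)) == {2}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            augment(np.zeros((32, 32)), np.zeros((16, 16)),
                    np.random.default_rng(0))


def _toy_pairs(n, size=32, seed=0):
    g = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        ci = i % 3
        base = [180.0, 90.0, 20.0][ci]
        img = np.clip(base + g.normal(0, 12, (size, size)), 0, 255)
        pairs.append(TrainingPair(image=img,
                                  labels=np.full((size, size), ci, np.int8),
                                  cube_id=f"c{i}", kind="single"))
    return pairs


class TestTraining:
    def test_loss_decreases_on_learnable_fixture(self):
        pairs = _toy_pairs(12)
        cfg = TrainConfig(input_size=32, epochs=40, batch_size=6,
                          backbone_scale="tiny", base_channels=4,
                          dataset_mix="single", augment=False, seed=0)
        res = SegmentationModel(pairs, config=cfg).fit()
        assert res.final_loss < res.history["loss"].iloc[0]

    def test_single_image_overfit_reaches_high_dice(self):
        """A working training loop drives Dice on one memorized image
        toward 1.0 within a couple hundred epochs."""
        from octaplex.metrics import dice
        g = np.random.default_rng(1)
        img = np.clip(100 + g.normal(0, 10, (32, 32)), 0, 255)
        labels = np.zeros((32, 32), np.int8)
        labels[:, 16:] = 1
        img[:, 16:] = np.clip(30 + g.normal(0, 5, (32, 16)), 0, 255)
        pair = TrainingPair(img, labels, "c0", "twoclass")
        cfg = TrainConfig(input_size=32, epochs=200, batch_size=1,
                          backbone_scale="tiny", base_channels=4,
                          dataset_mix="twoclass", augment=False, seed=0,
                          max_learning_rate=1e-3)
        res = SegmentationModel([pair], config=cfg).fit()
        pred = res.predict_labels([img])[0]
        d = np.mean([dice(pred == c, labels == c) for c in (0, 1)])
        assert d > 0.99

    def test_seeded_training_reproducible(self):
        pairs = _toy_pairs(6)
        cfg = TrainConfig(input_size=32, epochs=5, batch_size=3,
                          backbone_scale="tiny", base_channels=4,
                          dataset_mix="single", seed=7)
        r1 = SegmentationModel(pairs, config=cfg).fit()
        r2 = SegmentationModel(pairs, config=cfg).fit()
        assert r1.history["loss"].tolist() == r2.history["loss"].tolist()

    def test_leakage_aborts_fit(self):
        from octaplex.phantoms import generate_cohort
        from octaplex.splits import split_patients
        cohort = generate_cohort(3, (1, 1), (16, 16, 24), seed=0)
        split = split_patients(cohort, (1, 1, 1), seed=0)
        poc = cohort.patient_of_cube()
        test_cube = next(c for c, p in poc.items()
                         if split.group_of(p) == "test")
        pair = TrainingPair(np.zeros((16, 16)), np.zeros((16, 16), np.int8),
                            test_cube, "single")
        with pytest.raises(RuntimeError, match="leakage"):
            SegmentationModel([pair], config=TrainConfig(input_size=16),
                              patient_of_cube=poc, split=split)

    def test_summary_mentions_key_facts(self):
        pairs = _toy_pairs(3)
        cfg = TrainConfig(input_size=32, epochs=2, batch_size=3,
                          backbone_scale="tiny", base_channels=4,
                          dataset_mix="single", seed=0)
        res = SegmentationModel(pairs, config=cfg).fit()
        s = res.summary()
        assert "unet_like" in s and "epochs" in s and "loss" in s.lower()

    def test_checkpoint_round_trip(self, tmp_path):
        from octaplex.model import SegmentationResults
        pairs = _toy_pairs(3)
        cfg = TrainConfig(input_size=32, epochs=2, batch_size=3,
                          backbone_scale="tiny", base_channels=4,
                          dataset_mix="single", seed=0)
        res = SegmentationModel(pairs, config=cfg).fit()
        res.save(tmp_path / "model")
        back = SegmentationResults.load(tmp_path / "model")
        img = pairs[0].image
        np.testing.assert_allclose(back.predict_proba([img]),
                                   res.predict_proba([img]), atol=1e-6)


class TestAsTrainingPairs:
    def test_single_class_weak_labels(self):
        from octaplex.enface import EnFaceImage
        img = EnFaceImage(np.zeros((16, 16)), "deep", "c1")
        pairs = as_training_pairs(single_class=[img], dataset_mix="single")
        assert len(pairs) == 1
        assert (pairs[0].labels == 1).all()

    def test_twoclass_minority_labels(self):
        from octaplex.blending import blend_pair, make_blend_mask
        from octaplex.enface import EnFaceImage
        g = np.random.default_rng(0)
        maj = EnFaceImage(g.uniform(0, 255, (32, 32)), "deep", "c1")
        mino = EnFaceImage(g.uniform(0, 255, (32, 32)), "superficial", "c1")
        mask = make_blend_mask((32, 32), g, (0.05, 0.2), (1.0, 2.0))
        s = blend_pair(maj, mino, mask)
        pairs = as_training_pairs(twoclass=[s], dataset_mix="twoclass")
        assert (pairs[0].labels[s.target] == 0).all()
        assert (pairs[0].labels[~s.target] == 1).all()
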