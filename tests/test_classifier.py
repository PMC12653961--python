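"""Classifier data handling, the network itself, and the training protocol."""

import numpy as np
import pytest

from sitia.classifier import (
    Cnn6,
    Cnn6Spec,
    DatasetSplit,
    EvalResult,
    LabeledCrop,
    SplitSpec,
    TrainingConfig,
    balance_by_rotation,
    evaluate,
    load_crop_dir,
    load_model,
    predict_sex,
    save_crop_dir,
    save_model,
    split_balanced,
    train_from_scratch,
)
from sitia.classifier.nn import N_CONV_STAGES
from sitia.synthetic import make_crop_dataset


def _tiny_crops(n_male, n_female, side=6, seed=0):
    rng = np.random.default_rng(seed)
    crops = []
    for i in range(n_male):
        crops.append(LabeledCrop(rng.integers(0, 255, (side, side, 3), dtype=np.uint8), "male", f"m{i}"))
    for i in range(n_female):
        crops.append(LabeledCrop(rng.integers(0, 255, (side, side, 3), dtype=np.uint8), "female", f"f{i}"))
    return crops


class TestBalanceByRotation:
    def test_field_dataset_arithmetic(self):
        # 4799 female + 3719 male -> 1080 augmented males, 9598 total
        crops = _tiny_crops(3719, 4799, side=4)
        out = balance_by_rotation(crops, seed=0)
        assert len(out) == 9598
        added = [c for c in out if c.augmented]
        assert len(added) == 1080
        assert all(c.label == "male" for c in added)
        assert out[: len(crops)] == crops  # originals untouched, in order

    def test_balanced_input_is_identity(self):
        crops = _tiny_crops(5, 5)
        assert balance_by_rotation(crops, seed=1) == crops

    def test_small_deficit(self):
        out = balance_by_rotation(_tiny_crops(1, 3), seed=2)
        assert len(out) == 6
        assert sum(c.label == "male" for c in out) == 3

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            balance_by_rotation(_tiny_crops(3, 0))

    def test_rotation_is_quarter_turn(self):
        crops = _tiny_crops(1, 2, seed=3)
        out = balance_by_rotation(crops, seed=3)
        src = crops[0].pixels
        rotated = out[-1].pixels
        assert np.array_equal(rotated, np.rot90(src, 1)) or np.array_equal(
            rotated, np.rot90(src, 3)
        )

    def test_quarter_turn_four_times_is_identity(self):
        px = np.random.default_rng(0).integers(0, 255, (12, 12, 3), dtype=np.uint8)
        out = px
        for _ in range(4):
            out = np.rot90(out, 1)
        np.testing.assert_array_equal(out, px)


class TestSplitBalanced:
    def test_published_split_arithmetic(self):
        # 3272 balanced crops at 60/20/20 -> 1964 train (982/sex), 654, 654
        crops = _tiny_crops(1636, 1636, side=4)
        split = split_balanced(crops, SplitSpec(seed=0))
        assert split.counts() == {"train": 1964, "val": 654, "test": 654}
        for part in (split.train, split.val, split.test):
            males = sum(c.label == "male" for c in part)
            assert males == len(part) // 2

    def test_floor_arithmetic_small(self):
        split = split_balanced(_tiny_crops(5, 5), SplitSpec(seed=0))
        assert split.counts() == {"train": 6, "val": 2, "test": 2}

    def test_partitions_disjoint_and_exhaustive(self):
        crops = _tiny_crops(20, 20)
        split = split_balanced(crops, SplitSpec(seed=4))
        seen = [c.origin_id for c in split.train + split.val + split.test]
        assert sorted(seen) == sorted(c.origin_id for c in crops)
        assert len(set(seen)) == len(seen)

    def test_same_seed_same_membership(self):
        crops = _tiny_crops(10, 10)
        a = split_balanced(crops, SplitSpec(seed=9))
        b = split_balanced(crops, SplitSpec(seed=9))
        assert [c.origin_id for c in a.train] == [c.origin_id for c in b.train]

    def test_unbalanced_input_rejected(self):
        with pytest.raises(ValueError, match="balance"):
            split_balanced(_tiny_crops(4, 6), SplitSpec())

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_frac=0.5, val_frac=0.2, test_frac=0.2)


class TestCnn6Architecture:
    def test_param_count_matches_hand_derived_arithmetic(self):
        # independent layer-by-layer count for the default spec:
        # conv stages (3x3 kernels, same padding): in->8->16->32->64
        expected = 0
        c_in = 3
        for c_out in (8, 16, 32, 64):
            expected += (3 * 3 * c_in) * c_out + c_out
            c_in = c_out
        # after four 2x2 pools: 32 -> 2; flatten 2*2*64 = 256
        expected += 256 * 64 + 64  # hidden fully connected
        expected += 64 * 2 + 2  # output logits
        assert Cnn6(Cnn6Spec()).param_count() == expected

    def test_zero_weights_give_symmetric_logits(self):
        model = Cnn6(Cnn6Spec())
        for key in model.params:
            model.params[key][:] = 0.0
        x = np.random.default_rng(0).random((2, 32, 32, 3))
        logits = model.forward(x)
        np.testing.assert_allclose(logits[:, 0], logits[:, 1])

    def test_wrong_stage_count_rejected(self):
        with pytest.raises(ValueError, match="4"):
            Cnn6Spec(conv_channels=(8, 16, 32, 64, 128))

    def test_indivisible_input_side_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            Cnn6Spec(input_side_px=30)

    def test_gradients_match_finite_differences(self):
        spec = Cnn6Spec(input_side_px=16, conv_channels=(2, 3, 4, 5), fc_hidden=6)
        model = Cnn6(spec, seed=0)
        rng = np.random.default_rng(1)
        x = rng.random((3, 16, 16, 3))
        y = np.array([0, 1, 0])
        _, grads = model.loss_and_gradients(x, y)
        for name in ("conv0_w", "conv2_w", "conv3_b", "fc1_w", "fc2_b"):
            p = model.params[name]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-6
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = model.loss_and_gradients(x, y)
            p[idx] = orig - eps
            lm, _ = model.loss_and_gradients(x, y)
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(numeric, abs=1e-7, rel=1e-5)

    def test_forward_reproducible(self):
        model = Cnn6(seed=5)
        x = np.random.default_rng(2).random((1, 32, 32, 3))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))


class TestTraining:
    def test_one_epoch_curves_length_one(self):
        crops = make_crop_dataset(8, 32, seed=1)
        split = split_balanced(crops, SplitSpec(seed=1))
        _, curves = train_from_scratch(
            Cnn6(seed=1), split, TrainingConfig(epochs=1, seed=1)
        )
        assert len(curves) == 1
        assert list(curves.columns) == ["epoch", "train_acc", "val_acc"]

    def test_same_seed_identical_curves(self):
        crops = make_crop_dataset(10, 32, seed=2)
        split = split_balanced(crops, SplitSpec(seed=2))
        _, c1 = train_from_scratch(Cnn6(seed=2), split, TrainingConfig(epochs=3, seed=2))
        _, c2 = train_from_scratch(Cnn6(seed=2), split, TrainingConfig(epochs=3, seed=2))
        assert c1.equals(c2)

    def test_empty_train_partition_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_from_scratch(Cnn6(), DatasetSplit(), TrainingConfig(epochs=1))

    def test_trained_model_beats_chance_strongly(self, trained_model, dataset_split):
        result = evaluate(trained_model, dataset_split.test)
        assert result.accuracy >= 0.9


class TestPredictAndEvaluate:
    def test_zero_weight_model_confidence_half(self):
        model = Cnn6(Cnn6Spec())
        for key in model.params:
            model.params[key][:] = 0.0
        crop = np.random.default_rng(0).random((32, 32, 3))
        _, confidence = predict_sex(model, crop)
        assert confidence == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        model = Cnn6(Cnn6Spec())
        with pytest.raises(ValueError, match="match"):
            predict_sex(model, np.zeros((48, 48, 3)))

    def test_prediction_deterministic(self, trained_model):
        crop = make_crop_dataset(1, 32, seed=4)[0]
        from sitia.classifier.training import canonical_resize

        resized = canonical_resize(crop.pixels, trained_model.spec.input_side_px)
        assert predict_sex(trained_model, resized) == predict_sex(trained_model, resized)

    def test_eval_result_from_confusion(self):
        result = EvalResult.from_confusion(np.array([[9167 // 2, 24], [25, 9167 - 9167 // 2]]))
        assert result.n_evaluated == 9216
        # 49 off-diagonal of 9216: matches a 0.53% audit error rate
        assert round(100 * (1 - result.accuracy), 2) == 0.53

    def test_perfect_and_constant_predictors(self):
        perfect = EvalResult.from_confusion(np.array([[5, 0], [0, 5]]))
        assert perfect.accuracy == 1.0
        constant_male = EvalResult.from_confusion(np.array([[5, 0], [5, 0]]))
        assert constant_male.accuracy == 0.5


def test_crop_dir_and_model_roundtrip(tmp_path, trained_model):
    crops = make_crop_dataset(3, 32, seed=6)
    save_crop_dir(crops, tmp_path / "crops")
    back = load_crop_dir(tmp_path / "crops")
    assert len(back) == len(crops)
    np.testing.assert_array_equal(back[0].pixels, crops[0].pixels)
    assert [c.label for c in back] == [c.label for c in crops]

    save_model(trained_model, tmp_path / "model")
    loaded = load_model(tmp_path / "model")
    assert loaded.spec == trained_model.spec
    x = np.random.default_rng(0).random((2, loaded.spec.input_side_px, loaded.spec.input_side_px, 3))
    np.testing.assert_array_equal(loaded.forward(x), trained_model.forward(x))
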