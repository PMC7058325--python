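"""CNN architecture contracts, fold planning, augmentation, training."""

import dataclasses

import numpy as np
import pytest

import retinavasc.classify as classify_mod
from retinavasc.classify import (
    ClassifierConfig,
    CNNClassifier,
    augment,
    build_cnn,
    count_parameters,
    make_fold_plan,
)
from retinavasc.exceptions import ConfigurationError, DataError
from retinavasc._nn.layers import Conv2d, Dense

TINY = ClassifierConfig(
    conv_filters=(4, 4, 8, 8, 8),
    kernel_sizes=(3, 3, 3, 3, 3),
    strides=(1, 1, 1, 1, 1),
    pool_sizes=(2, 2, 2, 1, 0),
    dense_units=(8, 2),
    dropout_rates=(0.0, 0.0),
    input_side=32,
    train_resize_side=40,
    epochs=30,
    batch_size=4,
    learning_rate=3e-3,
    seed=0,
)


def _bar_images(n_per_class, side=40, seed=0):
    """Vertical-bar (hypertension) vs horizontal-bar (control) toy images."""
    gen = np.random.default_rng(seed)
    images, labels = [], []
    for i in range(n_per_class):
        v = gen.random((side, side)) * 0.2
        v[:, side // 3 : side // 3 + 4] = 1.0
        images.append(v)
        labels.append("hypertension")
        h = gen.random((side, side)) * 0.2
        h[side // 3 : side // 3 + 4, :] = 1.0
        images.append(h)
        labels.append("non-hypertension")
    return images, np.array(labels)


class TestBuildCnn:
    def test_softmax_output_is_probability_vector(self, rng):
        net = build_cnn(TINY)
        x = rng.random((3, 1, 32, 32)).astype(np.float32)
        from retinavasc._nn.layers import softmax

        probs = softmax(net.forward(x, train=False))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_layer_counts_match_architecture(self):
        net = build_cnn(TINY)
        assert sum(isinstance(l, Conv2d) for l in net.layers) == 5
        assert sum(isinstance(l, Dense) for l in net.layers) == 2

    def test_parameter_count_matches_shape_arithmetic(self):
        """Closed-form count: conv = f_out*(f_in*k*k) + f_out, batch-norm
        contributes 2 trainables per channel, dense = in*out + out."""
        net = build_cnn(TINY)
        expected = 0
        f_in = 1
        for f_out in TINY.conv_filters:
            expected += f_out * (f_in * 9) + f_out  # conv W + b
            expected += 2 * f_out  # batch-norm gamma + beta
            f_in = f_out
        expected += TINY.conv_filters[-1] * TINY.dense_units[0] + TINY.dense_units[0]
        expected += TINY.dense_units[0] * TINY.dense_units[1] + TINY.dense_units[1]
        assert count_parameters(net) == expected

    def test_config_arity_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            build_cnn(dataclasses.replace(TINY, conv_filters=(4, 4, 8)))
        with pytest.raises(ConfigurationError):
            build_cnn(dataclasses.replace(TINY, pool_sizes=(2, 2, 2, 2, 2)))
        with pytest.raises(ConfigurationError):
            build_cnn(dataclasses.replace(TINY, input_side=64, train_resize_side=64))
        with pytest.raises(ConfigurationError):
            build_cnn(dataclasses.replace(TINY, dropout_rates=(1.0, 0.0)))


class TestFoldPlan:
    def test_twenty_records_make_five_folds_of_four(self):
        labels = np.array(["hypertension", "non-hypertension"] * 10)
        plan = make_fold_plan(labels, k=5, group_by_subject=False, seed=1)
        sizes = [len(f["test"]) for f in plan.folds]
        assert sizes == [4] * 5

    @pytest.mark.parametrize("seed", range(50))
    def test_folds_are_disjoint_and_cover_everything(self, seed):
        labels = np.array(["h"] * 13 + ["n"] * 14)
        plan = make_fold_plan(labels, k=5, group_by_subject=False, seed=seed)
        all_test = np.concatenate([f["test"] for f in plan.folds])
        assert len(all_test) == 27
        assert len(np.unique(all_test)) == 27
        sizes = [len(f["test"]) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1
        for fold in plan.folds:
            assert set(fold["train"]) | set(fold["val"]) == set(fold["dev"])
            assert not (set(fold["train"]) & set(fold["val"]))

    def test_grouped_subjects_stay_in_one_fold(self):
        labels = np.array(["h"] * 20)
        subjects = np.array([f"s{i // 2}" for i in range(20)])  # two eyes each
        plan = make_fold_plan(labels, subjects=subjects, k=5, seed=3)
        for i in range(0, 20, 2):
            assert plan.assignments[i] == plan.assignments[i + 1]

    def test_development_split_is_75_25(self):
        labels = np.array(["h"] * 125)
        plan = make_fold_plan(labels, k=5, group_by_subject=False, seed=0)
        fold = plan.folds[0]
        assert len(fold["dev"]) == 100
        assert len(fold["train"]) == 75
        assert len(fold["val"]) == 25

    def test_more_folds_than_groups_rejected(self):
        with pytest.raises(DataError):
            make_fold_plan(np.array(["h"] * 3), k=5, group_by_subject=False)


class TestAugment:
    def test_output_side_matches_crop_side(self, rng):
        out = augment(rng.random((40, 40)), TINY, np.random.default_rng(0))
        assert out.shape == (32, 32)
        cfg224 = ClassifierConfig()
        out224 = augment(rng.random((256, 256)), cfg224, np.random.default_rng(0))
        assert out224.shape == (224, 224)

    def test_fixed_seed_reproduces_augmentation(self, rng):
        img = rng.random((40, 40))
        a = augment(img, TINY, np.random.default_rng(7))
        b = augment(img, TINY, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_output_is_flipped_contiguous_window_at_zero_jitter(self, rng):
        """Exhaustive oracle: with no brightness jitter the augmented image
        must equal one of the contiguous crop windows under one of the four
        flip combinations."""
        config = dataclasses.replace(TINY, brightness_jitter=0.0, input_side=8,
                                     train_resize_side=12)
        img = rng.random((12, 12))
        out = augment(img, config, np.random.default_rng(5))
        found = False
        for y0 in range(5):
            for x0 in range(5):
                win = img[y0 : y0 + 8, x0 : x0 + 8]
                for flip_h in (False, True):
                    for flip_v in (False, True):
                        cand = win[:, ::-1] if flip_h else win
                        cand = cand[::-1, :] if flip_v else cand
                        if np.array_equal(cand, out):
                            found = True
        assert found

    def test_brightness_stays_within_bounds_and_clipped(self, rng):
        img = np.full((40, 40), 0.5)
        for s in range(20):
            out = augment(img, TINY, np.random.default_rng(s))
            assert out.min() >= 0.5 * (1 - TINY.brightness_jitter) - 1e-12
            assert out.max() <= 0.5 * (1 + TINY.brightness_jitter) + 1e-12


@pytest.fixture(scope="module")
def overfit_model():
    images, labels = _bar_images(4)
    model = CNNClassifier.from_config(TINY).fit(images, labels)
    return model, images, labels


class TestTraining:
    def test_tiny_set_is_memorized(self, overfit_model):
        """Capacity check: 8 trivially separable images reach >= 95%
        training accuracy, and every hypertension image scores above 0.5."""
        model, images, labels = overfit_model
        pred = model.predict(images)
        assert (pred == labels).mean() >= 0.95
        scores = model.decision_scores(images)
        assert (scores[labels == "hypertension"] > 0.5).all()

    def test_history_length_equals_epochs(self, overfit_model):
        model, _, _ = overfit_model
        assert len(model.history_["train_loss"]) == TINY.epochs
        assert len(model.history_["val_loss"]) == TINY.epochs

    def test_prediction_is_deterministic_and_in_range(self, overfit_model):
        model, images, _ = overfit_model
        s1 = model.decision_scores(images[:3])
        s2 = model.decision_scores(images[:3])
        np.testing.assert_array_equal(s1, s2)
        assert (s1 >= 0).all() and (s1 <= 1).all()

    def test_validation_images_never_pass_through_augmentation(self, monkeypatch):
        """Instrumentation hook: count augment calls during fit; they must
        equal epochs x |train split| exactly, and the train/validation index
        sets must be disjoint."""
        calls = []
        original = classify_mod.augment

        def spy(pixels, config, gen):
            calls.append(1)
            return original(pixels, config, gen)

        monkeypatch.setattr(classify_mod, "augment", spy)
        images, labels = _bar_images(4)
        config = dataclasses.replace(TINY, epochs=3)
        model = CNNClassifier.from_config(config).fit(images, labels)
        assert len(calls) == config.epochs * len(model.train_indices_)
        assert not (set(model.train_indices_) & set(model.val_indices_))

    def test_single_class_training_split_rejected(self):
        images, _ = _bar_images(3)
        with pytest.raises(DataError):
            CNNClassifier.from_config(TINY).fit(images, ["hypertension"] * 6)

    def test_checkpoint_roundtrip_preserves_scores(self, overfit_model, tmp_path):
        model, images, _ = overfit_model
        model.save(tmp_path / "clf.npz")
        from retinavasc.classify import CNNClassifier as C

        loaded = C.load(tmp_path / "clf.npz")
        np.testing.assert_array_equal(
            model.decision_scores(images[:4]), loaded.decision_scores(images[:4])
        )
        assert list(loaded.classes_) == list(model.classes_)

    def test_same_seed_reproduces_training_exactly(self):
        images, labels = _bar_images(3)
        config = dataclasses.replace(TINY, epochs=3)
        m1 = CNNClassifier.from_config(config).fit(images, labels)
        m2 = CNNClassifier.from_config(config).fit(images, labels)
        assert m1.history_ == m2.history_
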