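"""Dataset splitting, subsampling, and the transformer training recipe."""

import numpy as np
import pytest

from fundex import (FixtureConfig, SplitSpec, TrainRecipe, generate_fixture,
                    predict, split_dataset, subsample_train, train_classifier)
from fundex.classifier import audit_no_leakage, load_classifier, save_classifier
from fundex.data import ImageDataset, LabeledImage
from fundex.metrics import roc_auc


def _dataset(n, seed=0, size=24):
    return generate_fixture(FixtureConfig(n_images=n, image_size=size, seed=seed))


@pytest.mark.parametrize("n,n_train", [(705, 564), (101, 80), (650, 520),
                                       (485, 388), (401, 320), (10, 8)])
def test_split_sizes_follow_floor_arithmetic(n, n_train):
    # avoid rendering hundreds of images: label-only stand-ins
    imgs = [LabeledImage(pixels=np.zeros((12, 12, 3)), label=i % 2, id=f"i{i}")
            for i in range(n)]
    ds = ImageDataset(imgs)
    train, val = split_dataset(ds, SplitSpec(seed=1))
    assert len(train) == n_train
    assert len(val) == n - n_train
    assert set(train.ids).isdisjoint(val.ids)
    assert sorted(train.ids + val.ids) == sorted(ds.ids)


def test_split_is_stratified_and_seeded():
    imgs = [LabeledImage(pixels=np.zeros((12, 12, 3)), label=int(i < 30), id=f"i{i}")
            for i in range(100)]
    ds = ImageDataset(imgs)
    train, _ = split_dataset(ds, SplitSpec(seed=3))
    assert sum(im.label for im in train) == 24  # 80% of the 30 cases
    train2, _ = split_dataset(ds, SplitSpec(seed=3))
    assert train.ids == train2.ids
    train3, _ = split_dataset(ds, SplitSpec(seed=4))
    assert train.ids != train3.ids


def test_split_rejects_synthetics_and_tiny_datasets():
    imgs = [LabeledImage(pixels=np.zeros((12, 12, 3)), label=i % 2, id=f"i{i}")
            for i in range(10)]
    synth = LabeledImage(pixels=np.zeros((12, 12, 3)), label=0, id="s",
                         source="synthetic", origin_id="i0")
    with pytest.raises(ValueError, match="real"):
        split_dataset(ImageDataset(imgs + [synth]), SplitSpec())
    with pytest.raises(ValueError, match="at least 5"):
        split_dataset(ImageDataset(imgs[:4]), SplitSpec())


def test_subsample_identity_sizes_and_nesting():
    ds = _dataset(100, seed=5)
    assert subsample_train(ds, 1.0, seed=0).ids == ds.ids
    assert len(subsample_train(ds, 0.5, seed=0)) == 50
    small = set(subsample_train(ds, 0.1, seed=7).ids)
    larger = set(subsample_train(ds, 0.2, seed=7).ids)
    assert small <= larger  # nested under a shared seed


def test_recipe_serialization_round_trip():
    rec = TrainRecipe(input_side=32, epochs=3, seed=9)
    back = TrainRecipe.from_dict(rec.to_dict())
    assert back == rec
    assert back.learning_rate == 6e-4 and back.weight_decay == 6e-2
    assert back.label_smoothing == 0.1 and back.batch_size == 16


def test_recipe_validation():
    with pytest.raises(ValueError, match="label_smoothing"):
        TrainRecipe(label_smoothing=0.6)
    with pytest.raises(ValueError, match="divisible"):
        TrainRecipe(input_side=30, model_scale="toy")


def test_zero_lr_predictions_match_untrained_model():
    ds = _dataset(24, seed=6)
    rec0 = TrainRecipe(input_side=24, epochs=2, learning_rate=0.0, seed=1)
    state0 = train_classifier(ds, rec0)
    fresh = train_classifier(ds, TrainRecipe(input_side=24, epochs=0,
                                             learning_rate=0.0, seed=1))
    assert np.allclose(predict(state0, ds), predict(fresh, ds))


def test_training_loss_decreases_on_separable_fixture():
    ds = _dataset(200, seed=8, size=24)
    rec = TrainRecipe(input_side=24, epochs=20, seed=2)
    state = train_classifier(ds, rec)
    log = np.asarray(state.train_log)
    k = len(log) // 5
    assert log[-k:].mean() < log[:k].mean()


def test_predict_scores_valid_and_deterministic():
    ds = _dataset(20, seed=9)
    state = train_classifier(ds, TrainRecipe(input_side=24, epochs=2, seed=3))
    scores = predict(state, ds)
    assert np.all(np.isfinite(scores))
    assert scores.min() >= 0.0 and scores.max() <= 1.0
    assert np.array_equal(scores, predict(state, ds))
    # duplicated image gets an identical score
    dup = ImageDataset([ds[0], LabeledImage(pixels=ds[0].pixels.copy(),
                                            label=ds[0].label, id="dup")])
    s = predict(state, dup)
    assert s[0] == s[1]


def test_toy_model_learns_separable_fixture_auc():
    full = _dataset(200, seed=10, size=24)
    train, val = split_dataset(full, SplitSpec(seed=1))
    rec = TrainRecipe(input_side=24, epochs=20, seed=4)
    state = train_classifier(train, rec, validation=val)
    auc = roc_auc(predict(state, val), val.labels)
    assert auc > 0.8


def test_single_class_training_rejected():
    imgs = [im for im in _dataset(20, seed=11) if im.label == 1]
    with pytest.raises(ValueError, match="both classes"):
        train_classifier(ImageDataset(imgs), TrainRecipe(input_side=24, epochs=1))


@pytest.mark.parametrize("balance", ["downsample", "weighted"])
def test_imbalance_handling_modes_run(balance):
    ds = generate_fixture(FixtureConfig(n_images=60, image_size=24,
                                        class_balance=0.25, seed=12))
    rec = TrainRecipe(input_side=24, epochs=2, balance=balance, seed=5)
    state = train_classifier(ds, rec)
    assert len(state.train_log) > 0


def test_leakage_audit_catches_foreign_synthetic():
    ds = _dataset(10, seed=13)
    bad = LabeledImage(pixels=ds[0].pixels.copy(), label=0, id="syn-bad",
                       source="synthetic", origin_id="not-in-train")
    with pytest.raises(ValueError, match="leak"):
        audit_no_leakage(ImageDataset(list(ds) + [bad]))


def test_classifier_checkpoint_round_trip(tmp_path):
    ds = _dataset(16, seed=14)
    state = train_classifier(ds, TrainRecipe(input_side=24, epochs=1, seed=6))
    save_classifier(state, tmp_path / "clf.npz")
    back = load_classifier(tmp_path / "clf.npz")
    assert np.array_equal(predict(state, ds), predict(back, ds))
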