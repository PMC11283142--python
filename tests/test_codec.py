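"""Dual-level codec: dimensional ledger, lossless tiling, position
independence, level independence, training behaviour, checkpointing."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundex import CodecConfig, FixtureConfig, generate_fixture, train_codec
from fundex.codec import (CodecState, PatchGrid, decode_full, decode_level1,
                          decode_level2, encode_full, encode_level1,
                          encode_level2, init_codec, load_checkpoint,
                          reconstruction_mae, save_checkpoint, tile_patches,
                          untile_patches)


@pytest.fixture(scope="module")
def codec96():
    return init_codec(CodecConfig(image_size=96, seed=0))


# -- tiling ---------------------------------------------------------------

@settings(max_examples=20, deadline=None, derandomize=True)
@given(gh=st.integers(1, 4), gw=st.integers(1, 4), seed=st.integers(0, 100))
def test_tiling_is_lossless_row_major(gh, gw, seed):
    img = np.random.default_rng(seed).uniform(size=(12 * gh, 12 * gw, 3))
    grid = tile_patches(img)
    assert grid.patches.shape == (gh, gw, 12, 12, 3)
    # row-major: tile (i, j) equals the corresponding image window
    assert np.array_equal(grid.patches[0, gw - 1],
                          img[0:12, 12 * (gw - 1):12 * gw])
    assert np.array_equal(untile_patches(grid), img)


def test_tiling_rejects_non_multiple_dimensions():
    with pytest.raises(ValueError, match="not divisible"):
        tile_patches(np.zeros((20, 24, 3)))


# -- dimensional ledger ---------------------------------------------------

def test_single_patch_maps_to_48_vector(codec96):
    grid = tile_patches(np.random.default_rng(1).uniform(size=(12, 12, 3)))
    assert grid.patches.shape[:2] == (1, 1)
    latent = encode_level1(grid, codec96)
    assert latent.shape == (48, 1, 1)


def test_96_image_traverses_48x8x8_to_1024(codec96):
    img = np.random.default_rng(2).uniform(size=(96, 96, 3))
    latent = encode_level1(tile_patches(img), codec96)
    assert latent.shape == (48, 8, 8)
    emb = encode_level2(latent, codec96)
    assert emb.shape == (1024,)
    assert decode_level2(emb, codec96).shape == (48, 8, 8)
    rec = decode_level1(latent, codec96)
    assert rec.shape == (96, 96, 3)
    assert rec.min() >= 0.0 and rec.max() <= 1.0
    full = encode_full(img, codec96)
    assert full.shape == (1024,)
    assert decode_full(full, codec96).shape == (96, 96, 3)


def test_patch_encoding_is_position_independent(codec96):
    patch = np.random.default_rng(3).uniform(size=(12, 12, 3))
    img = np.random.default_rng(4).uniform(size=(96, 96, 3))
    img[0:12, 0:12] = patch
    img[84:96, 72:84] = patch
    latent = encode_level1(tile_patches(img), codec96)
    assert np.allclose(latent[:, 0, 0], latent[:, 7, 6])


def test_zero_embedding_decodes_to_finite_latent(codec96):
    latent = decode_level2(np.zeros(1024), codec96)
    assert np.all(np.isfinite(latent))


def test_level2_codecs_are_swappable_over_fixed_level1():
    a = init_codec(CodecConfig(image_size=96, seed=1))
    b = init_codec(CodecConfig(image_size=96, seed=2))
    img = np.random.default_rng(5).uniform(size=(96, 96, 3))
    latent = encode_level1(tile_patches(img), a)
    # same latent feeds either Level-2 codec; outputs differ but are valid
    ea, eb = encode_level2(latent, a), encode_level2(latent, b)
    assert ea.shape == eb.shape == (1024,)
    assert not np.allclose(ea, eb)


def test_parameter_counts_frozen():
    state = init_codec(CodecConfig(image_size=96, seed=0))
    assert state.level1.n_parameters() == 115_263
    assert state.level2.n_parameters() == 2_786_896


# -- config ---------------------------------------------------------------

def test_config_freezes_patch_constants():
    with pytest.raises(ValueError, match="fixed"):
        CodecConfig(image_size=96, patch_size=16)
    with pytest.raises(ValueError, match="multiple"):
        CodecConfig(image_size=100)


def test_config_defaults_round_trip():
    cfg = CodecConfig(image_size=96)
    back = CodecConfig.from_dict(cfg.to_dict())
    assert back == cfg
    assert back.learning_rate == 3e-4 and back.weight_decay == 5e-7
    assert back.loss == "mae" and back.level2_embed_dim == 1024


# -- training -------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_train():
    return generate_fixture(FixtureConfig(n_images=16, image_size=24, seed=9))


def test_zero_lr_leaves_parameters_and_loss_constant(tiny_train):
    cfg = CodecConfig(image_size=24, learning_rate=0.0, seed=4)
    before = init_codec(cfg)
    ref = [a.copy() for a in before.level1.state_arrays()]
    state = train_codec(tiny_train, cfg, 1, steps=5, state=before, seed=0)
    for a, r in zip(state.level1.state_arrays(), ref):
        assert np.array_equal(a, r)
    assert np.allclose(state.loss_history, state.loss_history[0])


def test_loss_decreases_and_history_matches_steps(tiny_train):
    cfg = CodecConfig(image_size=24, seed=4)
    state = train_codec(tiny_train, cfg, 1, steps=150, seed=1)
    assert state.training_step == 150
    assert len(state.loss_history) == 150
    assert np.mean(state.loss_history[-30:]) < np.mean(state.loss_history[:30])


def test_level2_training_never_touches_level1(tiny_train):
    cfg = CodecConfig(image_size=24, seed=4)
    state = train_codec(tiny_train, cfg, 1, steps=30, seed=2)
    l1_before = [a.copy() for a in state.level1.state_arrays()]
    state = train_codec(tiny_train, cfg, 2, steps=30, state=state, seed=3)
    for a, r in zip(state.level1.state_arrays(), l1_before):
        assert np.array_equal(a, r)
    assert state.trained_levels == {1, 2}


def test_level2_requires_trained_level1(tiny_train):
    cfg = CodecConfig(image_size=24, seed=4)
    with pytest.raises(RuntimeError, match="Level-1"):
        train_codec(tiny_train, cfg, 2, steps=5)


def test_empty_dataset_rejected():
    from fundex.data import ImageDataset
    with pytest.raises(ValueError, match="empty"):
        train_codec(ImageDataset([]), CodecConfig(image_size=24), 1)


def test_checkpoint_round_trip(tmp_path, tiny_train):
    cfg = CodecConfig(image_size=24, seed=4)
    state = train_codec(tiny_train, cfg, 1, steps=10, seed=5)
    path = tmp_path / "codec.npz"
    save_checkpoint(state, path)
    back = load_checkpoint(path)
    assert back.config == state.config
    assert back.training_step == state.training_step
    assert back.trained_levels == state.trained_levels
    for a, b in zip(state.level1.state_arrays(), back.level1.state_arrays()):
        assert np.array_equal(a, b)
    img = tiny_train[0].pixels
    assert np.array_equal(encode_full(img, state), encode_full(img, back))


def test_fp16_checkpoint_stores_half_precision(tmp_path, tiny_train):
    cfg = CodecConfig(image_size=24, seed=4, fp16=True)
    state = train_codec(tiny_train, cfg, 1, steps=5, seed=6)
    path = tmp_path / "codec16.npz"
    save_checkpoint(state, path)
    with np.load(path) as z:
        assert z["l1_0"].dtype == np.float16
    back = load_checkpoint(path)
    assert np.allclose(back.level1.state_arrays()[0],
                       state.level1.state_arrays()[0], atol=1e-2)
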