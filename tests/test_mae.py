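"""Multimodal MAE: tokenization, masking, encoding, joint loss, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmri2img import nn
from fmri2img.mae import (MAEConfig, MultimodalMAE, OptimParams,
                          count_parameters, fmri_patches, image_patches,
                          make_token_batch, mask_count, mae_state_with_meta,
                          prepare_arrays, sample_mask, train_mae,
                          unpatchify_image)
from fmri2img.nn import Tensor
from fmri2img.synth import SyntheticWorld, make_dataset


@pytest.fixture(scope="module")
def cfg():
    return MAEConfig.desk()


@pytest.fixture(scope="module")
def model(cfg):
    return MultimodalMAE(cfg, np.random.default_rng(0))


@pytest.fixture(scope="module")
def small_world():
    return SyntheticWorld(noise_sd=0.2)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def test_config_validation():
    with pytest.raises(ValueError, match="mask"):
        MAEConfig(mask_ratio_image=1.0)
    with pytest.raises(ValueError, match="shared"):
        MAEConfig(shared_top_layers=13)
    with pytest.raises(ValueError, match="head"):
        MAEConfig(enc_dim=100, enc_heads=7)
    with pytest.raises(ValueError, match="pad"):
        MAEConfig(fmri_len=1690)


def test_token_counts():
    assert MAEConfig.full_scale(fmri_len=4192).n_fmri_tokens == 262
    assert MAEConfig.full_scale(fmri_len=4192, image_size=224).n_image_tokens == 196
    assert MAEConfig.desk().n_fmri_tokens == 106
    assert MAEConfig.desk().n_image_tokens == 16


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

def test_fmri_patchify_misaligned_errors():
    with pytest.raises(ValueError, match="pad_to_patch_multiple"):
        fmri_patches(np.zeros((1, 1685)), 16)


def test_image_patches_roundtrip():
    rng = np.random.default_rng(0)
    imgs = rng.random((2, 64, 64, 3)).astype(np.float32)
    p = image_patches(imgs, 16)
    assert p.shape == (2, 16, 768)
    np.testing.assert_array_equal(unpatchify_image(p, 16, 64), imgs)


def test_single_token_patchify():
    imgs = np.zeros((1, 16, 16, 3))
    assert image_patches(imgs, 16).shape[1] == 1


def test_zero_vector_gives_equal_token_embeddings(model, cfg):
    emb = model.embed_f(Tensor(fmri_patches(np.zeros((1, cfg.fmri_len)),
                                            cfg.patch_fmri))).data
    assert np.allclose(emb, emb[:, :1, :])     # bias only


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def test_mask_count_floor_rule():
    assert mask_count(262, 0.75) == 196
    assert mask_count(16, 0.75) == 12


def test_sample_mask_zero_ratio_empty():
    assert sample_mask(10, 0.0, np.random.default_rng(0)).size == 0


@given(st.integers(2, 300), st.floats(0.0, 0.95))
@settings(max_examples=50, deadline=None)
def test_mask_partition_property(n, ratio):
    rng = np.random.default_rng(7)
    masked = sample_mask(n, ratio, rng)
    assert masked.size == int(np.floor(ratio * n))
    assert np.unique(masked).size == masked.size
    assert masked.size == 0 or (0 <= masked.min() and masked.max() < n)


def test_token_batch_partition_checked(cfg):
    rng = np.random.default_rng(0)
    imgs = rng.random((3, 64, 64, 3)).astype(np.float32)
    fm = rng.standard_normal((3, cfg.fmri_len)).astype(np.float32)
    batch = make_token_batch(imgs, fm, cfg, rng)
    batch.check_partition()    # should not raise
    batch.masked_f[0, 0] = batch.visible_f[0, 0]
    with pytest.raises(AssertionError):
        batch.check_partition()


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def test_encode_requires_a_modality(model):
    with pytest.raises(ValueError, match="modality"):
        model.encode()


def test_encode_single_modality_works(model, cfg):
    rng = np.random.default_rng(1)
    fm = rng.standard_normal((2, cfg.fmri_len)).astype(np.float32)
    out = model.encode(tokens_f=model.patchify_fmri(fm))
    assert out["f"].shape == (2, cfg.n_fmri_tokens, cfg.enc_dim)


def test_encode_empty_visible_set_errors(model, cfg):
    empty = Tensor(np.zeros((1, 0, cfg.enc_dim), dtype=np.float32))
    with pytest.raises(ValueError, match="empty"):
        model.encode(tokens_f=empty)


def test_encoder_token_permutation_equivariance(model, cfg):
    """Without positional input the encoder stream is equivariant to token
    permutation."""
    rng = np.random.default_rng(2)
    tokens = Tensor(rng.standard_normal((1, 9, cfg.enc_dim))
                    .astype(np.float32))
    perm = np.random.default_rng(3).permutation(9)
    out = model.encode(tokens_f=tokens)["f"].data
    out_p = model.encode(tokens_f=Tensor(tokens.data[:, perm]))["f"].data
    np.testing.assert_allclose(out[:, perm], out_p, atol=2e-5)


def test_two_inputs_give_different_latents(model, cfg):
    rng = np.random.default_rng(4)
    a = rng.standard_normal((1, cfg.fmri_len)).astype(np.float32)
    b = rng.standard_normal((1, cfg.fmri_len)).astype(np.float32)
    la = model.encode_fmri_full(a).data
    lb = model.encode_fmri_full(b).data
    assert not np.allclose(la, lb)


def test_shared_layer_sharing(cfg):
    """Mutating a shared top layer moves both modalities' latents; mutating
    a private fMRI layer leaves image latents unchanged."""
    model = MultimodalMAE(cfg, np.random.default_rng(5))
    rng = np.random.default_rng(6)
    fm = rng.standard_normal((1, cfg.fmri_len)).astype(np.float32)
    imgs = rng.random((1, 64, 64, 3)).astype(np.float32)
    tf, tv = model.patchify_fmri(fm), model.patchify_image(imgs)
    base = model.encode(tokens_f=tf, tokens_v=tv)
    f0, v0 = base["f"].data.copy(), base["v"].data.copy()

    model.blocks_shared[0].fc1.weight.data += 0.05
    out = model.encode(tokens_f=tf, tokens_v=tv)
    assert not np.allclose(out["f"].data, f0)
    assert not np.allclose(out["v"].data, v0)

    model.blocks_shared[0].fc1.weight.data -= 0.05
    model.blocks_f[0].fc1.weight.data += 0.05
    out = model.encode(tokens_f=tf, tokens_v=tv)
    assert not np.allclose(out["f"].data, f0)
    np.testing.assert_allclose(out["v"].data, v0, atol=1e-6)


# ---------------------------------------------------------------------------
# decoding & loss
# ---------------------------------------------------------------------------

def _forward(model, cfg, seed=0):
    rng = np.random.default_rng(seed)
    imgs = rng.random((2, cfg.image_size, cfg.image_size, 3)) \
        .astype(np.float32)
    fm = rng.standard_normal((2, cfg.fmri_len)).astype(np.float32)
    return imgs, fm, model.forward_batch(imgs, fm, np.random.default_rng(9))


def test_decoder_output_shapes(model, cfg):
    _, _, out = _forward(model, cfg)
    assert out["recon_f"].shape == (2, cfg.n_fmri_tokens, cfg.patch_fmri)
    assert out["recon_v"].shape == (2, cfg.n_image_tokens,
                                    cfg.patch_image ** 2 * 3)


def test_loss_decomposition_and_nonnegative(model, cfg):
    _, _, out = _forward(model, cfg)
    lf, lv, lrec = out["L_f"].item(), out["L_v"].item(), out["L_rec"].item()
    assert lf >= 0 and lv >= 0
    assert lrec == pytest.approx(0.5 * lf + 0.5 * lv, rel=1e-6)


def test_perfect_reconstruction_zero_loss(model, cfg):
    rng = np.random.default_rng(0)
    imgs = rng.random((2, 64, 64, 3)).astype(np.float32)
    fm = rng.standard_normal((2, cfg.fmri_len)).astype(np.float32)
    batch = make_token_batch(imgs, fm, cfg, np.random.default_rng(1))
    losses = model.loss_rec(Tensor(batch.patches_f), Tensor(batch.patches_v),
                            batch)
    assert losses["L_f"].item() == 0.0
    assert losses["L_v"].item() == 0.0
    assert losses["L_rec"].item() == 0.0


def test_loss_single_patch_constant_offset(cfg):
    """One masked fMRI patch off by c in all 16 entries gives
    L_f = 16 c^2 / (alpha_f n_f) under the within-patch-sum convention."""
    model = MultimodalMAE(cfg, np.random.default_rng(0))
    rng = np.random.default_rng(0)
    imgs = rng.random((1, 64, 64, 3)).astype(np.float32)
    fm = rng.standard_normal((1, cfg.fmri_len)).astype(np.float32)
    batch = make_token_batch(imgs, fm, cfg, np.random.default_rng(1))
    c = 0.5
    recon_f = batch.patches_f.copy()
    i0 = batch.masked_f[0, 0]
    recon_f[0, i0] += c
    losses = model.loss_rec(Tensor(recon_f), Tensor(batch.patches_v), batch)
    expect = 16 * c ** 2 / (cfg.mask_ratio_fmri * cfg.n_fmri_tokens)
    assert losses["L_f"].item() == pytest.approx(expect, rel=1e-4)


def test_loss_depends_only_on_masked_tokens(model, cfg):
    rng = np.random.default_rng(0)
    imgs = rng.random((1, 64, 64, 3)).astype(np.float32)
    fm = rng.standard_normal((1, cfg.fmri_len)).astype(np.float32)
    batch = make_token_batch(imgs, fm, cfg, np.random.default_rng(1))
    recon_f = Tensor(rng.standard_normal(batch.patches_f.shape)
                     .astype(np.float32))
    recon_v = Tensor(rng.standard_normal(batch.patches_v.shape)
                     .astype(np.float32))
    l0 = model.loss_rec(recon_f, recon_v, batch)["L_rec"].item()
    batch.patches_f[0, batch.visible_f[0, 0]] += 10.0   # perturb a visible patch
    batch.patches_v[0, batch.visible_v[0, 0]] += 10.0
    l1 = model.loss_rec(recon_f, recon_v, batch)["L_rec"].item()
    assert l0 == l1


def test_decode_with_zero_weights_gives_bias(cfg):
    model = MultimodalMAE(cfg, np.random.default_rng(0))
    for _, p in model.head_f.named_parameters():
        p.data[:] = 0.0
    model.head_f.bias.data[:] = 0.25
    _, _, out = _forward(model, cfg)
    np.testing.assert_allclose(out["recon_f"].data, 0.25, atol=1e-6)


# ---------------------------------------------------------------------------
# parameter count
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("config", [
    MAEConfig.desk(),
    MAEConfig.full_scale(fmri_len=4192, image_size=224),
    MAEConfig(enc_layers=3, enc_dim=64, enc_mlp=128, enc_heads=4,
              shared_top_layers=1, dec_layers=2, dec_dim=48, dec_mlp=96,
              dec_heads=4, image_size=64, fmri_len=1696),
])
def test_count_parameters_matches_model(config):
    model = MultimodalMAE(config, np.random.default_rng(0))
    assert model.n_parameters() == count_parameters(config)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_training(small_world):
    cfg = MAEConfig(enc_layers=2, enc_dim=32, enc_mlp=64, enc_heads=2,
                    shared_top_layers=1, dec_layers=1, dec_dim=32, dec_mlp=64,
                    dec_heads=2, image_size=64, fmri_len=1696)
    ds = make_dataset(120, small_world, seed=3)
    optim = OptimParams(batch_size=32, lr=2e-3, epochs=5)
    model, hist, norm = train_mae(ds, cfg, "pretrain", optim, seed=17)
    return cfg, ds, optim, model, hist, norm


def test_training_reduces_loss(tiny_training):
    _, _, _, _, hist, _ = tiny_training
    assert hist[-1]["L_rec"] < hist[0]["L_rec"]


def test_training_seed_determinism(tiny_training, small_world):
    cfg, ds, optim, _, hist, _ = tiny_training
    _, hist2, _ = train_mae(ds, cfg, "pretrain", optim, seed=17)
    assert [h["L_rec"] for h in hist] == [h["L_rec"] for h in hist2]


def test_training_zero_lr_leaves_weights_constant(tiny_training):
    """With lr = 0 the optimizer must not move any parameter, so the loss
    fluctuates only through random masking, not through learning."""
    cfg, ds, _, _, _, _ = tiny_training
    optim = OptimParams(batch_size=32, lr=0.0, epochs=2,
                        augment_images=False)
    model0, _, _ = train_mae(ds, cfg, "pretrain",
                             OptimParams(batch_size=32, lr=0.0, epochs=0),
                             seed=21)
    model1, hist, _ = train_mae(ds, cfg, "pretrain", optim, seed=21)
    for (k0, p0), (k1, p1) in zip(model0.named_parameters(),
                                  model1.named_parameters()):
        assert k0 == k1
        np.testing.assert_array_equal(p0.data, p1.data)
    assert abs(hist[0]["L_rec"] - hist[1]["L_rec"]) < 0.05 * hist[0]["L_rec"]


def test_finetune_requires_checkpoint(tiny_training):
    cfg, ds, optim, _, _, _ = tiny_training
    with pytest.raises(ValueError, match="initial weights"):
        train_mae(ds, cfg, "finetune", optim, seed=0)


def test_finetune_across_voxel_counts_reinits_patch_embed(tiny_training,
                                                          small_world):
    """Fine-tuning onto a different voxel count keeps transformer weights
    and re-initialises the fMRI patch embedding."""
    cfg, ds, optim, model, _, _ = tiny_training
    state = mae_state_with_meta(model)
    from dataclasses import replace
    cfg2 = replace(cfg, fmri_len=944)
    ds2 = make_dataset(70, SyntheticWorld(
        roi_table=(("EVC", 931),),
        feature_maps={"EVC": __import__("fmri2img.synth", fromlist=["evc_features"]).evc_features},
        noise_sd=0.2, categories=small_world.categories), seed=5)
    optim2 = OptimParams(batch_size=32, lr=1e-3, epochs=1)
    model2, _, _ = train_mae(ds2, cfg2, "finetune", optim2, seed=23,
                             init_state=state)
    # transformer weights transferred (then updated): start from same values
    model3, _, _ = train_mae(ds2, cfg2, "finetune",
                             OptimParams(batch_size=32, lr=0.0, epochs=0),
                             seed=23, init_state=state)
    np.testing.assert_array_equal(
        model3.blocks_shared[0].fc1.weight.data,
        model.blocks_shared[0].fc1.weight.data)
    assert not np.array_equal(model3.embed_f.weight.data,
                              model.embed_f.weight.data)
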