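"""Diffusion machinery: schedule, objectives, guidance, DDIM sampling."""

import numpy as np
import pytest
from scipy import stats

from fmri2img import nn
from fmri2img.diffusion import (CondUNet, DiffusionConfig, FmriConditioner,
                                NoiseSchedule, cfg_estimate, ddim_sample,
                                denoise_loss, fmri_condition)
from fmri2img.mae import MAEConfig, MultimodalMAE
from fmri2img.nn import Tensor


@pytest.fixture(scope="module")
def dcfg():
    return DiffusionConfig.desk()


@pytest.fixture(scope="module")
def schedule(dcfg):
    return NoiseSchedule(dcfg)


@pytest.fixture(scope="module")
def unet(dcfg):
    return CondUNet(dcfg, np.random.default_rng(0))


def _latents(dcfg, n, seed=0):
    rng = np.random.default_rng(seed)
    return rng.standard_normal(
        (n, dcfg.latent_ch, dcfg.latent_hw, dcfg.latent_hw)).astype(np.float32)


# ---------------------------------------------------------------------------
# configuration / schedule
# ---------------------------------------------------------------------------

def test_config_validation():
    with pytest.raises(ValueError):
        DiffusionConfig(beta_start=0.5, beta_end=0.1)
    with pytest.raises(ValueError):
        DiffusionConfig(T=10, ddim_steps=50)


def test_beta_schedule_monotone(schedule):
    assert np.all(np.diff(schedule.betas) > 0)
    assert 0 < schedule.betas[0] < schedule.betas[-1] < 1
    assert np.all(np.diff(schedule.alpha_bar) < 0)
    assert schedule.alpha_bar[0] == 1.0


def test_q_sample_limits(schedule, dcfg):
    z0 = _latents(dcfg, 3)
    eps = _latents(dcfg, 3, seed=1)
    np.testing.assert_allclose(schedule.q_sample(z0, 0, eps), z0, atol=1e-6)
    zT = schedule.q_sample(z0, dcfg.T, eps)
    ab_T = schedule.alpha_bar[dcfg.T]
    np.testing.assert_allclose(
        zT, np.sqrt(ab_T) * z0 + np.sqrt(1 - ab_T) * eps, atol=1e-5)
    assert ab_T < 0.05                      # nearly pure noise at t = T


def test_q_sample_variance_preserving(schedule, dcfg):
    """Unit-variance z0 stays unit-variance at every t (Monte Carlo)."""
    rng = np.random.default_rng(2)
    z0 = rng.standard_normal((10000, 1)).astype(np.float32)
    eps = rng.standard_normal((10000, 1)).astype(np.float32)
    for t in (10, 50, 100):
        var = schedule.q_sample(z0, t, eps).var()
        assert abs(var - 1.0) < 0.05


def test_q_sample_range_check(schedule, dcfg):
    z0 = _latents(dcfg, 1)
    with pytest.raises(ValueError, match="range"):
        schedule.q_sample(z0, dcfg.T + 1, z0)


def test_ddim_timesteps_even_and_include_T(schedule, dcfg):
    ts = schedule.ddim_timesteps(25)
    assert ts[0] == dcfg.T
    assert ts[-1] == 1
    assert np.all(np.diff(ts) < 0)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def test_denoise_loss_oracle_predictor_zero(schedule, dcfg):
    """A predictor returning the injected noise exactly gives loss 0."""
    z0 = _latents(dcfg, 2)
    eps = _latents(dcfg, 2, seed=3)

    class Oracle:
        def __call__(self, z_t, t, cond=None):
            return Tensor(eps)

    loss = denoise_loss(z0, None, np.array([5, 50]), eps, Oracle(), schedule)
    assert loss.item() == 0.0


def test_denoise_loss_zero_predictor_near_one(schedule, dcfg):
    """Predicting 0 leaves E||eps||^2 / n = 1 in expectation."""
    rng = np.random.default_rng(4)
    z0 = rng.standard_normal((64, 4, 8, 8)).astype(np.float32)
    eps = rng.standard_normal(z0.shape).astype(np.float32)

    class Zero:
        def __call__(self, z_t, t, cond=None):
            return Tensor(np.zeros_like(z_t.data))

    loss = denoise_loss(z0, None, rng.integers(1, 101, 64), eps, Zero(),
                        schedule)
    assert abs(loss.item() - 1.0) < 0.05


def test_denoise_loss_shape_mismatch(schedule, dcfg, unet):
    z0 = _latents(dcfg, 2)
    with pytest.raises(ValueError, match="shape"):
        denoise_loss(z0, None, np.array([1, 2]), z0[:, :, :4], unet, schedule)


def test_denoise_loss_decreases_on_toy_fit(schedule, dcfg):
    """A few hundred gradient steps reduce the eps-prediction error."""
    rng = np.random.default_rng(5)
    unet = CondUNet(dcfg, rng)
    z0 = rng.standard_normal((32, dcfg.latent_ch, dcfg.latent_hw,
                              dcfg.latent_hw)).astype(np.float32)
    opt = nn.Adam(unet.parameters(), lr=2e-3)
    losses = []
    for step in range(60):
        t = rng.integers(1, dcfg.T + 1, 32)
        eps = rng.standard_normal(z0.shape).astype(np.float32)
        loss = denoise_loss(z0, None, t, eps, unet, schedule)
        unet.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    assert np.mean(losses[-10:]) < np.mean(losses[:10])


# ---------------------------------------------------------------------------
# classifier-free guidance
# ---------------------------------------------------------------------------

def test_cfg_identities_and_arithmetic(unet, schedule, dcfg):
    """w=0 gives the conditional estimate, w=-1 the unconditional one, and
    w=1.5 the elementwise combination 2.5 a - 1.5 b."""
    rng = np.random.default_rng(6)
    z_t = _latents(dcfg, 2, seed=7)
    t = np.array([10, 60])
    cond = Tensor(rng.standard_normal(
        (2, dcfg.cond_tokens, dcfg.cond_dim)).astype(np.float32))
    with nn.no_grad():
        a = unet(Tensor(z_t), t, cond).data
        b = unet(Tensor(z_t), t, None).data
    np.testing.assert_array_equal(cfg_estimate(z_t, t, cond, 0.0, unet), a)
    np.testing.assert_allclose(cfg_estimate(z_t, t, cond, -1.0, unet), b,
                               atol=1e-6)
    np.testing.assert_allclose(cfg_estimate(z_t, t, cond, 1.5, unet),
                               2.5 * a - 1.5 * b, atol=1e-5)


# ---------------------------------------------------------------------------
# DDIM sampling
# ---------------------------------------------------------------------------

def test_ddim_requires_trained_network(unet, schedule):
    unet.trained = False
    with pytest.raises(RuntimeError, match="untrained"):
        ddim_sample(unet, schedule, None, 1, 0.0, np.random.default_rng(0))


def test_ddim_deterministic_given_seed(schedule, dcfg):
    unet = CondUNet(dcfg, np.random.default_rng(8))
    unet.trained = True
    cond = Tensor(np.random.default_rng(9).standard_normal(
        (1, dcfg.cond_tokens, dcfg.cond_dim)).astype(np.float32))
    a = ddim_sample(unet, schedule, cond, 2, 1.5, np.random.default_rng(11))
    b = ddim_sample(unet, schedule, cond, 2, 1.5, np.random.default_rng(11))
    np.testing.assert_array_equal(a, b)


def _gaussian_oracle_eps(mu, sigma2, schedule):
    """Exact eps-prediction for a 1-D Gaussian N(mu, sigma2) data
    distribution: z_t ~ N(sqrt(ab) mu, ab sigma2 + 1 - ab)."""
    def eps_fn(z_t, t):
        ab = schedule.alpha_bar[t[0]]
        var = ab * sigma2 + 1.0 - ab
        return np.sqrt(1.0 - ab) * (z_t - np.sqrt(ab) * mu) / var
    return eps_fn


@pytest.mark.parametrize("mu,sigma", [(1.2, 0.7), (-0.5, 1.5)])
def test_ddim_full_steps_matches_gaussian_target(mu, sigma):
    """With the analytic score of a known Gaussian, full-step DDIM transports
    N(0,1) to the target within Monte-Carlo error (two-sample tests,
    alpha = 0.01, n = 2000)."""
    dcfg = DiffusionConfig(T=100, beta_start=1e-3, beta_end=0.2,
                           ddim_steps=100, latent_hw=8, latent_ch=1,
                           cond_tokens=4, cond_dim=8)
    schedule = NoiseSchedule(dcfg)
    unet = CondUNet(dcfg, np.random.default_rng(0))
    unet.trained = True
    eps_fn = _gaussian_oracle_eps(mu, sigma ** 2, schedule)
    # sample 2000 scalars: use latent shape and flatten
    n_lat = int(np.ceil(2000 / (dcfg.latent_hw ** 2)))
    z = ddim_sample(unet, schedule, None, n_lat, 0.0,
                    np.random.default_rng(123), ddim_steps=dcfg.T,
                    eps_fn=eps_fn)
    samples = z.ravel()[:2000]
    target = np.random.default_rng(321).normal(mu, sigma, 2000)
    t_p = stats.ttest_ind(samples, target, equal_var=False).pvalue
    v_p = stats.levene(samples, target).pvalue
    assert t_p > 0.01
    assert v_p > 0.01
    assert abs(samples.mean() - mu) < 0.1
    assert abs(samples.std() - sigma) < 0.1


# ---------------------------------------------------------------------------
# stage-3 selective fine-tuning
# ---------------------------------------------------------------------------

def _stage3_setup(tiny_ctx):
    from fmri2img.mae import MultimodalMAE, OptimParams
    from fmri2img.seeding import substream
    from fmri2img.synth import split_of

    cfgt = tiny_ctx.preset.mae_cfg
    dcfg = tiny_ctx.preset.diffusion_cfg
    mae = MultimodalMAE(cfgt, substream(5, "mae"))
    head = FmriConditioner(cfgt.n_fmri_tokens, cfgt.enc_dim, dcfg,
                           substream(5, "head"))
    unet = CondUNet(dcfg, substream(5, "shape"))
    unet.load_state_dict(tiny_ctx.unet_init)
    unet.trained = True
    train = split_of(tiny_ctx.target_data, "train")[:48]
    optim = OptimParams(batch_size=16, lr=2e-3, epochs=2,
                        betas=(0.9, 0.999))
    return mae, head, unet, train, optim, dcfg


def test_stage3_keeps_frozen_parameters(tiny_ctx):
    """Latent AE, non-cross-attention denoiser weights and the null
    embedding are unchanged by stage-3 fine-tuning (checksum contract)."""
    from fmri2img.diffusion import train_stage3

    mae, head, unet, train, optim, dcfg = _stage3_setup(tiny_ctx)
    frozen_before = {
        "ae": {k: v.copy() for k, v in tiny_ctx.ae.state_dict().items()},
        "null": unet.null_cond.data.copy(),
        "conv_in": unet.conv_in.weight.data.copy(),
    }
    train_stage3(train, mae, head, unet, tiny_ctx.ae, tiny_ctx.scaler,
                 dcfg, optim, seed=9, normalizer=tiny_ctx.normalizer)
    for k, v in tiny_ctx.ae.state_dict().items():
        np.testing.assert_array_equal(v, frozen_before["ae"][k])
    np.testing.assert_array_equal(unet.null_cond.data, frozen_before["null"])
    np.testing.assert_array_equal(unet.conv_in.weight.data,
                                  frozen_before["conv_in"])


def test_stage3_deterministic_given_seed(tiny_ctx):
    from fmri2img.diffusion import train_stage3

    hists = []
    heads = []
    for _ in range(2):
        mae, head, unet, train, optim, dcfg = _stage3_setup(tiny_ctx)
        hists.append(train_stage3(train, mae, head, unet, tiny_ctx.ae,
                                  tiny_ctx.scaler, dcfg, optim, seed=11,
                                  normalizer=tiny_ctx.normalizer))
        heads.append(head.state_dict())
    assert hists[0] == hists[1]
    for k in heads[0]:
        np.testing.assert_array_equal(heads[0][k], heads[1][k])


def test_stage3_loss_decreases(desk_ctx):
    """The conditional eps-prediction objective decreases over a short
    stage-3 run on 200 synthetic pairs."""
    from fmri2img.diffusion import train_stage3
    from fmri2img.mae import MultimodalMAE, OptimParams
    from fmri2img.seeding import substream
    from fmri2img.synth import split_of

    cfgt = desk_ctx.preset.mae_cfg
    dcfg = desk_ctx.preset.diffusion_cfg
    mae = MultimodalMAE(cfgt, substream(21, "mae"))
    head = FmriConditioner(cfgt.n_fmri_tokens, cfgt.enc_dim, dcfg,
                           substream(21, "head"))
    unet = CondUNet(dcfg, substream(21, "shape"))
    unet.load_state_dict(desk_ctx.unet_init)
    unet.trained = True
    train = split_of(desk_ctx.target_data, "train")[:200]
    hist = train_stage3(train, mae, head, unet, desk_ctx.ae,
                        desk_ctx.scaler, dcfg,
                        OptimParams(batch_size=16, lr=5e-3, epochs=4,
                                    betas=(0.9, 0.999)),
                        seed=23, normalizer=desk_ctx.normalizer)
    assert hist[-1]["loss"] < hist[0]["loss"]


# ---------------------------------------------------------------------------
# latent autoencoder
# ---------------------------------------------------------------------------

def test_latent_ae_reaches_configured_tolerance(desk_ctx):
    """The preset training schedule brings held-out reconstruction MSE
    below the configured desk tolerance."""
    assert desk_ctx.ae_history is not None
    final = desk_ctx.ae_history[-1]["mse_holdout"]
    assert final < 0.02, f"held-out MSE {final:.4f}"
    # and the training curve actually descended
    assert final < 0.5 * desk_ctx.ae_history[0]["mse_holdout"]


def test_latent_ae_reconstructions_keep_colour(desk_ctx):
    """Mean RGB of reconstructions tracks the originals (no grey collapse)."""
    import numpy as np

    from fmri2img.synth import split_of

    imgs = np.stack([s.image for s in
                     split_of(desk_ctx.target_data, "test")[:8]])
    rec = desk_ctx.ae.reconstruct(imgs.astype(np.float32))
    err = np.abs(rec.mean(axis=(1, 2)) - imgs.mean(axis=(1, 2)))
    assert err.mean() < 0.05


def test_latent_ae_nonconvergence_raises():
    from fmri2img.diffusion import train_latent_ae

    rng = np.random.default_rng(0)
    imgs = rng.random((110, 64, 64, 3)).astype(np.float32)
    with pytest.raises(RuntimeError, match="converge"):
        train_latent_ae(imgs, DiffusionConfig.desk(), seed=0, epochs=1,
                        n_candidates=1, probe_epochs=1, tol=1e-6)


def test_latent_ae_requires_enough_images():
    from fmri2img.diffusion import train_latent_ae

    with pytest.raises(ValueError, match="100"):
        train_latent_ae(np.zeros((50, 64, 64, 3), dtype=np.float32),
                        DiffusionConfig.desk(), seed=0)


def test_latent_ae_training_deterministic():
    from fmri2img.diffusion import train_latent_ae

    rng = np.random.default_rng(1)
    imgs = np.clip(rng.random((110, 64, 64, 3)), 0, 1).astype(np.float32)
    ae1, h1 = train_latent_ae(imgs, DiffusionConfig.desk(), seed=5, epochs=1,
                              n_candidates=1, probe_epochs=1, tol=np.inf)
    ae2, h2 = train_latent_ae(imgs, DiffusionConfig.desk(), seed=5, epochs=1,
                              n_candidates=1, probe_epochs=1, tol=np.inf)
    assert h1 == h2
    for (k1, p1), (k2, p2) in zip(ae1.named_parameters(),
                                  ae2.named_parameters()):
        np.testing.assert_array_equal(p1.data, p2.data)


# ---------------------------------------------------------------------------
# conditioning head
# ---------------------------------------------------------------------------

def test_conditioning_shape_paper_preset():
    """The full-scale conditioning head emits 77 token positions x 768
    channels, the text-embedding shape it stands in for."""
    cfg = MAEConfig.full_scale(fmri_len=1696, image_size=224)
    mae = MultimodalMAE(cfg, np.random.default_rng(0))
    dcfg = DiffusionConfig.full_scale()
    cond_head = FmriConditioner(cfg.n_fmri_tokens, cfg.enc_dim, dcfg,
                                np.random.default_rng(1))
    fm = np.random.default_rng(2).standard_normal((1, 1696)) \
        .astype(np.float32)
    with nn.no_grad():
        out = fmri_condition(fm, mae, cond_head)
    assert out.shape == (1, 77, 768)


def test_conditioning_shape_desk_preset(dcfg):
    cfg = MAEConfig.desk()
    mae = MultimodalMAE(cfg, np.random.default_rng(0))
    cond_head = FmriConditioner(cfg.n_fmri_tokens, cfg.enc_dim, dcfg,
                                np.random.default_rng(1))
    fm = np.random.default_rng(2).standard_normal((3, 1696)) \
        .astype(np.float32)
    with nn.no_grad():
        out = fmri_condition(fm, mae, cond_head)
    assert out.shape == (3, dcfg.cond_tokens, dcfg.cond_dim)


def test_conditioning_wrong_length_errors(dcfg):
    cfg = MAEConfig.desk()
    mae = MultimodalMAE(cfg, np.random.default_rng(0))
    cond_head = FmriConditioner(cfg.n_fmri_tokens, cfg.enc_dim, dcfg,
                                np.random.default_rng(1))
    with pytest.raises(ValueError, match="length"):
        fmri_condition(np.zeros((1, 1685), dtype=np.float32), mae, cond_head)


def test_conditioning_zero_linear_map_constant(dcfg):
    cfg = MAEConfig.desk()
    mae = MultimodalMAE(cfg, np.random.default_rng(0))
    cond_head = FmriConditioner(cfg.n_fmri_tokens, cfg.enc_dim, dcfg,
                                np.random.default_rng(1))
    cond_head.channel_map.weight.data[:] = 0.0
    cond_head.channel_map.bias.data[:] = 0.5
    fm = np.random.default_rng(2).standard_normal((2, 1696)) \
        .astype(np.float32)
    with nn.no_grad():
        out = fmri_condition(fm, mae, cond_head)
    np.testing.assert_allclose(out.data, 0.5, atol=1e-6)
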