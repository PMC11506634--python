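"""Conditional latent diffusion for fMRI-to-image decoding.

A convolutional autoencoder maps images to a compact latent space; a
time-conditional U-Net with cross-attention denoises latents; an fMRI
conditioning head (the MAE fMRI encoder run with zero masking followed by a
linear token/channel map) produces the token matrix the cross-attention
layers attend to.  Training minimises the standard eps-prediction objective

    L = E_{z0, y, eps, t} || eps - eps_theta(z_t, t, tau(y)) ||^2

and sampling uses a deterministic DDIM update (eta = 0) over an evenly
spaced timestep subsequence, with classifier-free guidance

    eps_hat = (1 + w) * eps_theta(z_t, t, tau(y)) - w * eps_theta(z_t, t),

the unconditional branch using a learned null-conditioning embedding.

The latent autoencoder and the unconditionally pre-trained denoiser form the
frozen generative backbone; stage-3 fine-tuning trains only the
cross-attention blocks, the fMRI encoder and the conditioning linear map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .mae import MAEConfig, MultimodalMAE, OptimParams, prepare_arrays
from .seeding import substream
from .synth import FmriNormalizer, PairedSample, augment, voxel_dropout


# ---------------------------------------------------------------------------
# configuration and schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffusionConfig:
    T: int = 1000
    beta_start: float = 1e-4
    beta_end: float = 0.02
    schedule: str = "linear"
    ddim_steps: int = 50
    guidance_scale: float = 1.5
    latent_hw: int = 32
    latent_ch: int = 4
    cond_tokens: int = 77
    cond_dim: int = 768
    base_ch: int = 32             # denoiser width
    ae_ch: int = 32               # autoencoder width
    time_dim: int = 64
    z0_clip: float | None = 3.0   # static threshold on predicted z0 during
                                  # sampling (latents are ~unit variance);
                                  # None disables

    def __post_init__(self):
        if not (0 < self.beta_start < self.beta_end < 1):
            raise ValueError("need 0 < beta_start < beta_end < 1")
        if not (1 <= self.ddim_steps <= self.T):
            raise ValueError("need 1 <= ddim_steps <= T")

    @classmethod
    def full_scale(cls) -> "DiffusionConfig":
        return cls()

    @classmethod
    def desk(cls) -> "DiffusionConfig":
        # beta endpoints scaled by 1000/T so alpha_bar(T) is still ~1e-5
        # (the forward process must end at essentially pure noise)
        return cls(T=100, beta_start=1e-3, beta_end=0.2, ddim_steps=25,
                   cond_tokens=16, cond_dim=64, latent_hw=8, latent_ch=12)


class NoiseSchedule:
    """Variance-preserving forward process with a linear beta schedule."""

    def __init__(self, cfg: DiffusionConfig):
        if cfg.schedule != "linear":
            raise ValueError(f"unknown beta schedule {cfg.schedule!r}")
        self.cfg = cfg
        self.betas = np.linspace(cfg.beta_start, cfg.beta_end, cfg.T,
                                 dtype=np.float64)
        self.alphas = 1.0 - self.betas
        # alpha_bar[t] for t = 0..T, with alpha_bar[0] = 1 (no noise)
        self.alpha_bar = np.concatenate(
            [[1.0], np.cumprod(self.alphas)]).astype(np.float64)

    def q_sample(self, z0: np.ndarray, t: int | np.ndarray,
                 eps: np.ndarray) -> np.ndarray:
        """Closed-form forward marginal z_t = sqrt(ab_t) z0 + sqrt(1-ab_t) eps."""
        t = np.asarray(t)
        if np.any(t < 0) or np.any(t > self.cfg.T):
            raise ValueError(f"timestep out of range [0, {self.cfg.T}]")
        ab = self.alpha_bar[t]
        while ab.ndim < z0.ndim:
            ab = ab[..., None]
        return (np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps).astype(np.float32)

    def ddim_timesteps(self, n_steps: int) -> np.ndarray:
        """Evenly spaced decreasing subsequence of 1..T, starting at T."""
        ts = np.linspace(self.cfg.T, 1, n_steps)
        return np.unique(np.round(ts).astype(int))[::-1]


# ---------------------------------------------------------------------------
# latent autoencoder
# ---------------------------------------------------------------------------

class LatentAE(nn.Module):
    """Conv encoder/decoder between image space and the diffusion latent."""

    def __init__(self, cfg: DiffusionConfig, image_size: int,
                 rng: np.random.Generator):
        factor = image_size // cfg.latent_hw
        n_down = int(round(math.log2(factor)))
        if 2 ** n_down != factor or n_down < 2:
            raise ValueError(
                f"image_size/latent_hw must be a power of 2 >= 4, got {factor}")
        c = cfg.ae_ch
        chans = [c // 2] + [c] * (n_down - 1)
        self.enc_convs = []
        self.enc_norms = []
        prev = 3
        for ch in chans:
            self.enc_convs.append(nn.Conv2d(prev, ch, 3, rng, stride=2,
                                            padding=1))
            self.enc_norms.append(nn.ChannelNorm(ch))
            prev = ch
        self.enc_out = nn.Conv2d(prev, cfg.latent_ch, 3, rng, padding=1)
        self.dec_in = nn.Conv2d(cfg.latent_ch, chans[-1], 3, rng, padding=1)
        self.dec_convs = []
        self.dec_norms = [nn.ChannelNorm(chans[-1])]
        rev = list(reversed(chans))
        for i in range(n_down - 1):
            self.dec_convs.append(nn.Conv2d(rev[i], rev[i + 1], 3, rng,
                                            padding=1))
            self.dec_norms.append(nn.ChannelNorm(rev[i + 1]))
        self.dec_out = nn.Conv2d(chans[0], 3, 3, rng, padding=1)
        # He-style gain on the conv weights: the GELU stack trains
        # noticeably faster and less init-sensitively at this scale
        for name, p in self.named_parameters():
            if name.endswith("weight") and p.data.ndim == 4:
                p.data *= 1.73

    def _encode(self, x: Tensor) -> Tensor:
        h = x
        for conv, norm in zip(self.enc_convs, self.enc_norms):
            h = norm(conv(h)).gelu()
        return self.enc_out(h)

    def _decode(self, z: Tensor) -> Tensor:
        h = self.dec_norms[0](self.dec_in(z)).gelu()
        for conv, norm in zip(self.dec_convs, self.dec_norms[1:]):
            h = norm(conv(nn.upsample2x(h))).gelu()
        return self.dec_out(nn.upsample2x(h))     # opponent colour space

    # convenience numpy APIs (HWC RGB in [0,1] <-> latent arrays)
    def encode_images(self, images: np.ndarray) -> Tensor:
        x = Tensor(rgb_to_opponent(_to_nchw(images)))
        return self._encode(x)

    def decode_latents(self, z: np.ndarray | Tensor) -> np.ndarray:
        zt = z if isinstance(z, Tensor) else Tensor(z)
        with nn.no_grad():
            out = self._decode(zt)
        rgb = opponent_to_rgb(out.data)
        return np.clip(_to_nhwc(rgb), 0.0, 1.0)

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        with nn.no_grad():
            z = self.encode_images(images)
            out = self._decode(z)
        rgb = opponent_to_rgb(out.data)
        return np.clip(_to_nhwc(rgb), 0.0, 1.0)


def _to_nchw(images: np.ndarray) -> np.ndarray:
    if images.ndim == 3:
        images = images[None]
    return np.ascontiguousarray(images.transpose(0, 3, 1, 2).astype(np.float32))


def _to_nhwc(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x.transpose(0, 2, 3, 1))


# Orthonormal opponent colour transform (luminance, red-green, blue-yellow).
# The AE operates in this space: chroma becomes an explicit channel instead
# of a small differential mode of RGB, which speeds up hue learning greatly.
_OPP = np.array([
    [1 / math.sqrt(3), 1 / math.sqrt(3), 1 / math.sqrt(3)],
    [1 / math.sqrt(2), -1 / math.sqrt(2), 0.0],
    [1 / math.sqrt(6), 1 / math.sqrt(6), -2 / math.sqrt(6)],
], dtype=np.float32)


def rgb_to_opponent(images_nchw: np.ndarray) -> np.ndarray:
    return np.einsum("ij,bjhw->bihw", _OPP, images_nchw)


def opponent_to_rgb(x_nchw: np.ndarray) -> np.ndarray:
    return np.einsum("ji,bjhw->bihw", _OPP, x_nchw)


def train_latent_ae(images: np.ndarray, cfg: DiffusionConfig, seed: int,
                    epochs: int = 60, batch_size: int = 16, lr: float = 8e-3,
                    holdout_frac: float = 0.1, tol: float = 0.01,
                    chroma_weight: float = 2.0, n_candidates: int = 3,
                    probe_epochs: int = 5) -> tuple[LatentAE, list[dict]]:
    """Train the image autoencoder; error if held-out MSE stays above `tol`.

    The loss lives in the opponent colour space with the chroma channels
    up-weighted (`chroma_weight`), which equalises how fast luminance and
    hue are learned; reported/held-out MSEs are plain RGB MSE (the opponent
    transform is orthonormal).

    Convergence is sensitive to the initial weights, so `n_candidates`
    inits race for `probe_epochs` and the best one continues to the full
    schedule (deterministic given `seed`).
    """
    if len(images) < 100:
        raise ValueError("need at least 100 images to train the latent AE")
    n_hold = max(8, int(holdout_frac * len(images)))
    perm0 = substream(seed, "ae-split").permutation(len(images))
    hold, train = images[perm0[:n_hold]], images[perm0[n_hold:]]
    cw = Tensor(np.array([1.0, chroma_weight, chroma_weight],
                         dtype=np.float32).reshape(1, 3, 1, 1))
    x_hold = Tensor(rgb_to_opponent(_to_nchw(hold)))

    def run_epochs(ae, opt, rng, history, start, stop):
        for epoch in range(start, stop):
            lr_e = nn.cosine_lr(lr, epoch, epochs)
            perm = rng.permutation(len(train))
            tot, nb = 0.0, 0
            for s in range(0, len(train), batch_size):
                xb = Tensor(rgb_to_opponent(
                    _to_nchw(train[perm[s: s + batch_size]])))
                out = ae._decode(ae._encode(xb))
                diff = out - xb
                loss = (diff * diff * cw).mean()
                ae.zero_grad()
                loss.backward()
                opt.step(lr=lr_e)
                tot += loss.item()
                nb += 1
            with nn.no_grad():
                dh = ae._decode(ae._encode(x_hold)) - x_hold
                mse_hold = float((dh.data ** 2).mean())     # == RGB MSE
            history.append({"epoch": epoch, "mse_train": tot / nb,
                            "mse_holdout": mse_hold, "lr": lr_e})

    candidates = []
    probe = min(probe_epochs, epochs)
    for k in range(max(1, n_candidates)):
        ae = LatentAE(cfg, images.shape[1], substream(seed, f"ae-init-{k}"))
        opt = nn.Adam(ae.parameters(), lr=lr)
        rng = substream(seed, f"ae-order-{k}")
        history: list[dict] = []
        run_epochs(ae, opt, rng, history, 0, probe)
        candidates.append((history[-1]["mse_holdout"], k, ae, opt, rng,
                           history))
    candidates.sort(key=lambda c: (c[0], c[1]))
    _, _, ae, opt, rng, history = candidates[0]
    run_epochs(ae, opt, rng, history, probe, epochs)
    if history[-1]["mse_holdout"] > tol:
        raise RuntimeError(
            f"latent AE did not converge: held-out MSE "
            f"{history[-1]['mse_holdout']:.4f} > tol {tol}")
    return ae, history


# ---------------------------------------------------------------------------
# denoising U-Net
# ---------------------------------------------------------------------------

class ResBlock(nn.Module):
    def __init__(self, ch: int, time_dim: int, rng: np.random.Generator):
        self.norm1 = nn.ChannelNorm(ch)
        self.conv1 = nn.Conv2d(ch, ch, 3, rng, padding=1)
        self.time_proj = nn.Linear(time_dim, ch, rng)
        self.norm2 = nn.ChannelNorm(ch)
        self.conv2 = nn.Conv2d(ch, ch, 3, rng, padding=1)

    def forward(self, x: Tensor, t_emb: Tensor) -> Tensor:
        h = self.conv1(self.norm1(x).gelu())
        bias = self.time_proj(t_emb)
        B, C = bias.shape
        h = h + bias.reshape(B, C, 1, 1)
        h = self.conv2(self.norm2(h).gelu())
        return x + h


class SpatialCrossAttention(nn.Module):
    """Cross-attention of spatial positions over conditioning tokens.

    The output projection starts at zero so an untrained conditional branch
    coincides exactly with the unconditional one and fine-tuning can only
    improve on it."""

    def __init__(self, ch: int, cond_dim: int, n_heads: int,
                 rng: np.random.Generator):
        self.norm = nn.ChannelNorm(ch)
        self.attn = nn.MultiHeadAttention(ch, n_heads, rng,
                                          context_dim=cond_dim)
        self.attn.out.weight.data[:] = 0.0

    def forward(self, x: Tensor, cond: Tensor) -> Tensor:
        B, C, H, W = x.shape
        q = self.norm(x).reshape(B, C, H * W).transpose(0, 2, 1)
        out = self.attn(q, context=cond)
        return x + out.transpose(0, 2, 1).reshape(B, C, H, W)


class CondUNet(nn.Module):
    """Two-resolution time-conditional U-Net with cross-attention at the
    downsampled and bottleneck blocks, plus a learned null-conditioning
    embedding for classifier-free guidance."""

    def __init__(self, cfg: DiffusionConfig, rng: np.random.Generator):
        c, td = cfg.base_ch, cfg.time_dim
        self.cfg = cfg
        self.time_fc1 = nn.Linear(td, td, rng)
        self.time_fc2 = nn.Linear(td, td, rng)
        self.conv_in = nn.Conv2d(cfg.latent_ch, c, 3, rng, padding=1)
        self.res_top = ResBlock(c, td, rng)
        self.xattn_top = SpatialCrossAttention(c, cfg.cond_dim, 4, rng)
        self.down = nn.Conv2d(c, 2 * c, 3, rng, stride=2, padding=1)
        self.res_down = ResBlock(2 * c, td, rng)
        self.xattn_down = SpatialCrossAttention(2 * c, cfg.cond_dim, 4, rng)
        self.res_mid1 = ResBlock(2 * c, td, rng)
        self.xattn_mid = SpatialCrossAttention(2 * c, cfg.cond_dim, 4, rng)
        self.res_mid2 = ResBlock(2 * c, td, rng)
        self.up_conv = nn.Conv2d(2 * c, c, 3, rng, padding=1)
        self.fuse = nn.Conv2d(2 * c, c, 3, rng, padding=1)
        self.res_out = ResBlock(c, td, rng)
        self.xattn_out = SpatialCrossAttention(c, cfg.cond_dim, 4, rng)
        self.norm_out = nn.ChannelNorm(c)
        self.conv_out = nn.Conv2d(c, cfg.latent_ch, 3, rng, padding=1)
        self.null_cond = nn.Parameter(
            0.02 * rng.standard_normal((cfg.cond_tokens, cfg.cond_dim)))
        self.trained = False

    def null_conditioning(self, batch: int) -> Tensor:
        return self.null_cond.reshape(1, *self.null_cond.shape) * Tensor(
            np.ones((batch, 1, 1), dtype=np.float32))

    def forward(self, z_t: Tensor, t: np.ndarray,
                cond: Tensor | None = None) -> Tensor:
        if cond is None:
            cond = self.null_conditioning(z_t.shape[0])
        te = Tensor(nn.timestep_embedding(t, self.cfg.time_dim))
        te = self.time_fc2(self.time_fc1(te).gelu())
        h0 = self.res_top(self.conv_in(z_t), te)
        h0 = self.xattn_top(h0, cond)
        h = self.res_down(self.down(h0), te)
        h = self.xattn_down(h, cond)
        h = self.res_mid1(h, te)
        h = self.xattn_mid(h, cond)
        h = self.res_mid2(h, te)
        h = self.up_conv(nn.upsample2x(h))
        h = self.fuse(nn.concat([h, h0], axis=1))
        h = self.res_out(h, te)
        h = self.xattn_out(h, cond)
        return self.conv_out(self.norm_out(h).gelu())

    def cross_attention_parameters(self) -> list[tuple[str, nn.Parameter]]:
        return [(k, p) for k, p in self.named_parameters()
                if k.startswith("xattn_")]


# ---------------------------------------------------------------------------
# conditioning head
# ---------------------------------------------------------------------------

class FmriConditioner(nn.Module):
    """Linear map from MAE fMRI latents (n_f x enc_dim) to the conditioning
    token matrix (cond_tokens x cond_dim), factorised over the token and
    channel axes."""

    def __init__(self, n_fmri_tokens: int, enc_dim: int,
                 cfg: DiffusionConfig, rng: np.random.Generator):
        self.token_map = nn.Linear(n_fmri_tokens, cfg.cond_tokens, rng)
        self.channel_map = nn.Linear(enc_dim, cfg.cond_dim, rng)
        # small output at init: near-zero conditioning tokens look like the
        # padded caption slots the backbone was pre-trained with, so stage-3
        # fine-tuning starts from in-distribution conditioning
        self.channel_map.weight.data *= 0.1

    def forward(self, latents: Tensor) -> Tensor:
        mixed = self.token_map(latents.transpose(0, 2, 1)).transpose(0, 2, 1)
        return self.channel_map(mixed)


def fmri_condition(fmri_padded: np.ndarray, mae: MultimodalMAE,
                   conditioner: FmriConditioner) -> Tensor:
    """tau(y): all-visible MAE encoding followed by the linear map."""
    fmri_padded = np.atleast_2d(fmri_padded)
    if fmri_padded.shape[1] != mae.cfg.fmri_len:
        raise ValueError(
            f"fMRI length {fmri_padded.shape[1]} != expected {mae.cfg.fmri_len}")
    return conditioner(mae.encode_fmri_full(fmri_padded))


# ---------------------------------------------------------------------------
# objectives, guidance, sampling
# ---------------------------------------------------------------------------

def denoise_loss(z0: np.ndarray, cond: Tensor | None, t: np.ndarray,
                 eps: np.ndarray, unet: CondUNet,
                 schedule: NoiseSchedule) -> Tensor:
    """Eq-style eps-prediction MSE at q_sample(z0, t, eps)."""
    if eps.shape != z0.shape:
        raise ValueError("eps must match z0 shape")
    z_t = schedule.q_sample(z0, t, eps)
    pred = unet(Tensor(z_t), t, cond)
    diff = pred - Tensor(eps)
    return (diff * diff).mean()


def cfg_estimate(z_t: np.ndarray, t: np.ndarray, cond: Tensor, w: float,
                 unet: CondUNet) -> np.ndarray:
    """Classifier-free guided estimate (1+w)*cond - w*uncond."""
    with nn.no_grad():
        e_cond = unet(Tensor(z_t), t, cond).data
        e_uncond = unet(Tensor(z_t), t, None).data
    return (1.0 + w) * e_cond - w * e_uncond


def ddim_sample(unet: CondUNet, schedule: NoiseSchedule,
                cond: Tensor | None, n_samples: int, w: float,
                rng: np.random.Generator,
                ddim_steps: int | None = None,
                eps_fn=None) -> np.ndarray:
    """Deterministic DDIM (eta = 0) from seeded Gaussian initial latents.

    `cond` is a (B, tokens, dim) conditioning batch (rows are repeated
    `n_samples` times each) or None for unconditional sampling.  `eps_fn`
    overrides the network (analytic-oracle hooks in tests).
    """
    if eps_fn is None and not unet.trained:
        raise RuntimeError("denoiser is untrained; train or set trained=True")
    cfgd = schedule.cfg
    steps = schedule.ddim_timesteps(ddim_steps or cfgd.ddim_steps)
    B = 1 if cond is None else cond.shape[0]
    total = B * n_samples
    shape = (total, cfgd.latent_ch, cfgd.latent_hw, cfgd.latent_hw)
    z = rng.standard_normal(shape).astype(np.float32)
    cond_rep = None
    if cond is not None:
        cond_rep = Tensor(np.repeat(cond.data, n_samples, axis=0))
    for i, t in enumerate(steps):
        tb = np.full(total, t)
        if eps_fn is not None:
            eps_hat = eps_fn(z, tb)
        elif cond_rep is not None and w != 0.0:
            eps_hat = cfg_estimate(z, tb, cond_rep, w, unet)
        else:
            with nn.no_grad():
                eps_hat = unet(Tensor(z), tb, cond_rep).data
        ab_t = schedule.alpha_bar[t]
        t_prev = steps[i + 1] if i + 1 < len(steps) else 0
        ab_prev = schedule.alpha_bar[t_prev]
        z0_pred = (z - math.sqrt(1.0 - ab_t) * eps_hat) / math.sqrt(ab_t)
        if cfgd.z0_clip is not None:
            # static thresholding: keeps the trajectory on-manifold when the
            # eps error is amplified by 1/sqrt(alpha_bar) at early steps
            z0_pred = np.clip(z0_pred, -cfgd.z0_clip, cfgd.z0_clip)
        z = (math.sqrt(ab_prev) * z0_pred
             + math.sqrt(1.0 - ab_prev) * eps_hat).astype(np.float32)
    return z


# ---------------------------------------------------------------------------
# backbone pre-training and stage-3 fine-tuning
# ---------------------------------------------------------------------------

@dataclass
class LatentScaler:
    """Affine scaling of AE latents to roughly unit variance for diffusion."""

    mean: float
    sd: float

    @classmethod
    def fit(cls, latents: np.ndarray) -> "LatentScaler":
        return cls(float(latents.mean()), float(latents.std() + 1e-8))

    def scale(self, z: np.ndarray) -> np.ndarray:
        return ((z - self.mean) / self.sd).astype(np.float32)

    def unscale(self, z: np.ndarray) -> np.ndarray:
        return (z * self.sd + self.mean).astype(np.float32)


def class_conditioning_table(z0_scaled: np.ndarray, labels: np.ndarray,
                             n_classes: int,
                             cfg: DiffusionConfig) -> np.ndarray:
    """Fixed caption-style embeddings: the class-mean latent of each class,
    laid out over the conditioning token grid (zero-padded)."""
    flat = z0_scaled.reshape(len(z0_scaled), -1)
    means = np.stack([
        flat[labels == c].mean(axis=0) if np.any(labels == c)
        else np.zeros(flat.shape[1], dtype=np.float32)
        for c in range(n_classes)])
    slots = cfg.cond_tokens * cfg.cond_dim
    if means.shape[1] > slots:
        raise ValueError(
            f"latent dim {means.shape[1]} exceeds conditioning capacity "
            f"{slots}")
    table = np.zeros((n_classes, slots), dtype=np.float32)
    table[:, : means.shape[1]] = means
    return table.reshape(n_classes, cfg.cond_tokens, cfg.cond_dim)


def train_ldm_backbone(images: np.ndarray, labels: np.ndarray, ae: LatentAE,
                       cfg: DiffusionConfig, seed: int, n_classes: int,
                       epochs: int = 80, batch_size: int = 32,
                       lr: float = 2e-3, cond_dropout: float = 0.1
                       ) -> tuple[CondUNet, LatentScaler, np.ndarray,
                                  list[dict]]:
    """Caption-conditional denoiser pre-training on AE latents.

    This is the desk-scale stand-in for an externally pre-trained
    text-conditional diffusion checkpoint: conditioning tokens are fixed
    class-mean-latent embeddings (the role a frozen caption encoder plays),
    and conditioning dropout trains the learned null branch used by
    classifier-free guidance.  The result is a backbone whose
    cross-attention layers already route caption-shaped conditioning —
    stage 3 then only has to map fMRI into that embedding space.
    """
    schedule = NoiseSchedule(cfg)
    unet = CondUNet(cfg, substream(seed, "unet-init"))
    with nn.no_grad():
        lat = ae.encode_images(images).data
    scaler = LatentScaler.fit(lat)
    z0_all = scaler.scale(lat)
    cond_table = class_conditioning_table(z0_all, labels, n_classes, cfg)
    opt = nn.Adam(unet.parameters(), lr=lr)
    rng = substream(seed, "unet-order")
    noise_rng = substream(seed, "unet-noise")
    history = []
    for epoch in range(epochs):
        lr_e = nn.cosine_lr(lr, epoch, epochs)
        perm = rng.permutation(len(z0_all))
        tot, nb = 0.0, 0
        for s in range(0, len(z0_all), batch_size):
            idx = perm[s: s + batch_size]
            z0 = z0_all[idx]
            cond = (None if noise_rng.uniform() < cond_dropout
                    else Tensor(cond_table[labels[idx]]))
            t = noise_rng.integers(1, cfg.T + 1, size=len(z0))
            eps = noise_rng.standard_normal(z0.shape).astype(np.float32)
            loss = denoise_loss(z0, cond, t, eps, unet, schedule)
            unet.zero_grad()
            loss.backward()
            opt.step(lr=lr_e)
            tot += loss.item()
            nb += 1
        history.append({"epoch": epoch, "loss": tot / nb, "lr": lr_e})
    unet.trained = True
    return unet, scaler, cond_table, history


FULLSCALE_STAGE3 = OptimParams(batch_size=32, lr=5.3e-5, epochs=500,
                           betas=(0.9, 0.999), weight_decay=0.01)


def train_stage3(samples: list[PairedSample], mae: MultimodalMAE,
                 conditioner: FmriConditioner, unet: CondUNet, ae: LatentAE,
                 scaler: LatentScaler, dcfg: DiffusionConfig,
                 optim: OptimParams, seed: int,
                 normalizer: FmriNormalizer | None = None,
                 cond_dropout: float = 0.0,
                 fmri_dropout_rate: float = 0.2,
                 encoder_lr_scale: float = 0.2,
                 xattn_lr_scale: float = 0.1,
                 xattn_start_frac: float = 2.0 / 3.0,
                 n_aug_variants: int = 0) -> list[dict]:
    """Stage-3 selective fine-tuning with the eps-prediction objective.

    Trainable: the conditioning linear map (full learning rate), the fMRI
    encoder (patch embedding, fMRI-side private layers, shared top layers,
    final norm; `encoder_lr_scale` x lr) and the cross-attention blocks
    (`xattn_lr_scale` x lr, joining after `xattn_start_frac` of the
    schedule).  The staggering matters at desk scale: the conditioning map
    must first align to the backbone's caption-embedding space through the
    *intact* cross-attention; co-adapting the cross-attention from step one
    overwrites the backbone's conditioning pathway before the fMRI map is
    informative.  Everything else — latent AE, the rest of the denoiser,
    the learned null embedding — stays frozen, asserted by checksum.

    Augmentation: a fresh random crop/resize of every image per epoch
    (pre-encoded to latents in chunks; `n_aug_variants` > 0 instead fixes
    that many pre-encoded variants) and fresh `fmri_dropout_rate` voxel
    dropout per batch.
    """
    schedule = NoiseSchedule(dcfg)
    images, fmri, normalizer = prepare_arrays(samples, mae.cfg, normalizer)

    mae_trainable = [(f"mae.{k}", p) for k, p in mae.named_parameters()
                     if k.startswith(("embed_f", "blocks_f", "blocks_shared",
                                      "enc_norm"))]
    cond_params = [(f"cond.{k}", p) for k, p in
                   conditioner.named_parameters()]
    xattn_params = [(f"xattn.{k}", p) for k, p in
                    unet.cross_attention_parameters()]
    trainable = xattn_params + mae_trainable + cond_params
    trainable_ids = {id(p) for _, p in trainable}
    frozen = {f"unet.{k}": p for k, p in unet.named_parameters()
              if id(p) not in trainable_ids}
    frozen.update({f"ae.{k}": p for k, p in ae.named_parameters()})
    frozen.update({f"mae.{k}": p for k, p in mae.named_parameters()
                   if id(p) not in trainable_ids})
    checksum_before = sum(float(np.abs(p.data).sum()) for p in frozen.values())

    opt_cond = nn.Adam([p for _, p in cond_params], lr=optim.lr,
                       betas=optim.betas, weight_decay=optim.weight_decay)
    opt_enc = nn.Adam([p for _, p in mae_trainable],
                      lr=optim.lr * encoder_lr_scale, betas=optim.betas,
                      weight_decay=optim.weight_decay)
    opt_x = nn.Adam([p for _, p in xattn_params],
                    lr=optim.lr * xattn_lr_scale, betas=optim.betas,
                    weight_decay=optim.weight_decay)

    aug_rng = substream(seed, "s3-aug")
    n = len(samples)
    # pre-encode augmented image variants to latents (the backbone AE is
    # frozen, so this is exact, not an approximation); n_aug_variants = 0
    # falls back to fresh augmentation + encoding every batch
    z0_variants = None
    if n_aug_variants > 0:
        variants = []
        for _ in range(n_aug_variants):
            if optim.augment_images:
                aug = np.stack([
                    augment(im, "stage3", aug_rng,
                            out_size=mae.cfg.image_size)
                    for im in images]).astype(np.float32)
            else:
                aug = images
            with nn.no_grad():
                variants.append(scaler.scale(ae.encode_images(aug).data))
        z0_variants = np.stack(variants)        # K x N x C x H x W

    def encode_chunked(imgs_aug: np.ndarray) -> np.ndarray:
        outs = []
        with nn.no_grad():
            for s in range(0, len(imgs_aug), 128):
                outs.append(scaler.scale(
                    ae.encode_images(imgs_aug[s: s + 128]).data))
        return np.concatenate(outs)

    order_rng = substream(seed, "s3-order")
    noise_rng = substream(seed, "s3-noise")
    drop_rng = substream(seed, "s3-drop")
    history = []
    xattn_start = int(math.floor(xattn_start_frac * optim.epochs))
    for epoch in range(optim.epochs):
        f_lr = nn.cosine_lr(1.0, epoch, optim.epochs)
        if z0_variants is None:
            if optim.augment_images:
                aug = np.stack([
                    augment(im, "stage3", aug_rng,
                            out_size=mae.cfg.image_size)
                    for im in images]).astype(np.float32)
            else:
                aug = images
            z0_epoch = encode_chunked(aug)
        perm = order_rng.permutation(n)
        tot, nb = 0.0, 0
        for s in range(0, n, optim.batch_size):
            idx = perm[s: s + optim.batch_size]
            if z0_variants is not None:
                kvar = aug_rng.integers(0, z0_variants.shape[0],
                                        size=len(idx))
                z0 = z0_variants[kvar, idx]
            else:
                z0 = z0_epoch[idx]
            fm = np.stack([
                voxel_dropout(v, fmri_dropout_rate, drop_rng)
                for v in fmri[idx]])
            if cond_dropout > 0 and drop_rng.uniform() < cond_dropout:
                cond = None      # trains the unconditional (null) branch
            else:
                cond = fmri_condition(fm, mae, conditioner)
            t = noise_rng.integers(1, dcfg.T + 1, size=len(z0))
            eps = noise_rng.standard_normal(z0.shape).astype(np.float32)
            loss = denoise_loss(z0, cond, t, eps, unet, schedule)
            for p in frozen.values():
                p.grad = None
            unet.zero_grad()
            mae.zero_grad()
            conditioner.zero_grad()
            loss.backward()
            opt_cond.step(lr=optim.lr * f_lr)
            opt_enc.step(lr=optim.lr * encoder_lr_scale * f_lr)
            if epoch >= xattn_start:
                opt_x.step(lr=optim.lr * xattn_lr_scale * f_lr)
            tot += loss.item()
            nb += 1
        history.append({"epoch": epoch, "loss": tot / nb,
                        "lr": optim.lr * f_lr})
    checksum_after = sum(float(np.abs(p.data).sum()) for p in frozen.values())
    if not math.isclose(checksum_before, checksum_after, rel_tol=0, abs_tol=1e-6):
        raise RuntimeError(
            f"frozen parameters drifted during stage 3: "
            f"{checksum_before} -> {checksum_after}")
    return history


# ---------------------------------------------------------------------------
# end-to-end decoder
# ---------------------------------------------------------------------------

class BrainDecoder:
    """Bundles the trained stack into an fMRI -> images sampler."""

    def __init__(self, mae: MultimodalMAE, conditioner: FmriConditioner,
                 unet: CondUNet, ae: LatentAE, scaler: LatentScaler,
                 dcfg: DiffusionConfig, normalizer: FmriNormalizer):
        self.mae = mae
        self.conditioner = conditioner
        self.unet = unet
        self.ae = ae
        self.scaler = scaler
        self.dcfg = dcfg
        self.normalizer = normalizer
        self.schedule = NoiseSchedule(dcfg)

    def decode_padded(self, fmri_padded: np.ndarray, n_samples: int = 1,
                      guidance: float | None = None,
                      seed: int = 0) -> np.ndarray:
        """Sample images for already normalized+padded vectors.

        Returns (B, n_samples, H, W, 3) images in [0, 1].
        """
        if not self.unet.trained:
            raise RuntimeError("decoder networks are untrained")
        w = self.dcfg.guidance_scale if guidance is None else guidance
        with nn.no_grad():
            cond = fmri_condition(np.atleast_2d(fmri_padded), self.mae,
                                  self.conditioner)
        z = ddim_sample(self.unet, self.schedule, cond, n_samples, w,
                        substream(seed, "ddim-init"),
                        ddim_steps=self.dcfg.ddim_steps)
        imgs = self.ae.decode_latents(self.scaler.unscale(z))
        B = np.atleast_2d(fmri_padded).shape[0]
        H = imgs.shape[1]
        return imgs.reshape(B, n_samples, H, H, 3)

    def decode(self, fmri_raw: np.ndarray, n_samples: int = 1,
               guidance: float | None = None, seed: int = 0) -> np.ndarray:
        """Sample images for raw (unnormalized, unpadded) fMRI vectors."""
        from .synth import pad_to_patch_multiple

        z = self.normalizer.transform(np.atleast_2d(fmri_raw))
        padded = np.stack([
            pad_to_patch_multiple(v, self.mae.cfg.patch_fmri) for v in z])
        return self.decode_padded(padded, n_samples, guidance, seed)
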