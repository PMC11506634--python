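"""Mid-fusion multimodal masked autoencoder for paired image–fMRI data.

Both modalities are tokenized (non-overlapping 1-D fMRI patches, square image
patches), a random subset of tokens per modality is masked, and only visible
tokens enter the encoders.  The lower encoder layers are private per
modality; the top layers share weights across modalities (mid-fusion).  A
single shared decoder sees the concatenated fMRI+image sequence — with
learned mask tokens reinserted at masked positions and a learned modality
tag — and per-modality linear heads reconstruct the original patches.

The joint reconstruction objective averages the two modality losses with
equal weight:

    L_f = 1/(alpha_f * n_f) * sum_{i in M_f} ||recon_f_i - x_f_i||^2
    L_v = 1/(alpha_v * n_v) * sum_{i in M_v} ||recon_v_i - x_v_i||^2
    L_rec = 0.5 * L_f + 0.5 * L_v

where alpha are the mask ratios, n the token counts, M the masked index
sets, and ||.||^2 sums squared errors within a patch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn import Tensor
from .seeding import substream
from .synth import PairedSample, FmriNormalizer, augment, pad_to_patch_multiple


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MAEConfig:
    enc_layers: int = 12
    enc_dim: int = 768
    enc_mlp: int = 3072
    enc_heads: int = 12
    shared_top_layers: int = 2
    dec_layers: int = 4
    dec_dim: int = 512
    dec_mlp: int = 2048
    dec_heads: int = 8
    patch_image: int = 16
    patch_fmri: int = 16
    mask_ratio_image: float = 0.75
    mask_ratio_fmri: float = 0.75
    image_size: int = 224
    fmri_len: int = 4192          # padded length

    def __post_init__(self):
        if not (0 <= self.mask_ratio_image < 1 and 0 <= self.mask_ratio_fmri < 1):
            raise ValueError("mask ratios must be in [0, 1)")
        if self.shared_top_layers > self.enc_layers:
            raise ValueError("shared_top_layers cannot exceed enc_layers")
        if self.enc_dim % self.enc_heads or self.dec_dim % self.dec_heads:
            raise ValueError("embedding dims must be divisible by head counts")
        if self.fmri_len % self.patch_fmri:
            raise ValueError("fmri_len must be a multiple of patch_fmri; "
                             "pad with pad_to_patch_multiple first")
        if self.image_size % self.patch_image:
            raise ValueError("image_size must be a multiple of patch_image")

    @property
    def n_fmri_tokens(self) -> int:
        return self.fmri_len // self.patch_fmri

    @property
    def n_image_tokens(self) -> int:
        return (self.image_size // self.patch_image) ** 2

    @classmethod
    def full_scale(cls, fmri_len: int = 4192, image_size: int = 224) -> "MAEConfig":
        """Full-scale preset (12-layer/768-d encoder, 4-layer/512-d decoder)."""
        return cls(fmri_len=fmri_len, image_size=image_size)

    @classmethod
    def desk(cls, fmri_len: int = 1696, image_size: int = 64) -> "MAEConfig":
        """Small preset used throughout the tested desk-scale path."""
        return cls(enc_layers=4, enc_dim=128, enc_mlp=256, enc_heads=4,
                   shared_top_layers=2, dec_layers=2, dec_dim=64, dec_mlp=128,
                   dec_heads=4, fmri_len=fmri_len, image_size=image_size)


@dataclass(frozen=True)
class OptimParams:
    batch_size: int = 64
    lr: float = 1e-3
    epochs: int = 10
    betas: tuple[float, float] = (0.9, 0.98)
    weight_decay: float = 0.01
    augment_images: bool = True


FULLSCALE_PRETRAIN = OptimParams(batch_size=512, lr=2e-4, epochs=300,
                             betas=(0.9, 0.98), weight_decay=0.01)
FULLSCALE_FINETUNE = OptimParams(batch_size=64, lr=1e-4, epochs=100,
                             betas=(0.9, 0.98), weight_decay=0.01)


# ---------------------------------------------------------------------------
# tokenization and masking
# ---------------------------------------------------------------------------

def fmri_patches(fmri: np.ndarray, patch: int) -> np.ndarray:
    """(B, L) -> (B, L/patch, patch) non-overlapping patches."""
    fmri = np.atleast_2d(fmri)
    B, L = fmri.shape
    if L % patch:
        raise ValueError(
            f"fMRI length {L} not divisible by patch size {patch}; "
            "apply pad_to_patch_multiple first")
    return fmri.reshape(B, L // patch, patch)


def image_patches(images: np.ndarray, patch: int) -> np.ndarray:
    """(B, H, W, 3) -> (B, (H/p)*(W/p), p*p*3), row-major patch order."""
    if images.ndim == 3:
        images = images[None]
    B, H, W, C = images.shape
    if H % patch or W % patch:
        raise ValueError(f"image size {H}x{W} not divisible by patch {patch}")
    x = images.reshape(B, H // patch, patch, W // patch, patch, C)
    return x.transpose(0, 1, 3, 2, 4, 5).reshape(
        B, (H // patch) * (W // patch), patch * patch * C)


def unpatchify_image(patches: np.ndarray, patch: int, size: int) -> np.ndarray:
    B, n, _ = patches.shape
    g = size // patch
    x = patches.reshape(B, g, g, patch, patch, 3)
    return x.transpose(0, 1, 3, 2, 4, 5).reshape(B, size, size, 3)


def mask_count(n_tokens: int, ratio: float) -> int:
    """Number of masked tokens: floor(ratio * n_tokens)."""
    return int(math.floor(ratio * n_tokens))


def sample_mask(n_tokens: int, ratio: float,
                rng: np.random.Generator) -> np.ndarray:
    """Uniform random masked index set of size floor(ratio * n), sorted."""
    if not 0 <= ratio < 1:
        raise ValueError(f"mask ratio must be in [0, 1), got {ratio}")
    k = mask_count(n_tokens, ratio)
    return np.sort(rng.choice(n_tokens, size=k, replace=False))


def _complement(idx: np.ndarray, n: int) -> np.ndarray:
    keep = np.ones(n, dtype=bool)
    keep[idx] = False
    return np.nonzero(keep)[0]


@dataclass
class TokenBatch:
    """Per-modality patch targets with visible/masked index partitions."""

    patches_f: np.ndarray        # B x n_f x patch_f
    patches_v: np.ndarray        # B x n_v x (patch_v^2*3)
    masked_f: np.ndarray         # B x |M_f|
    masked_v: np.ndarray         # B x |M_v|
    visible_f: np.ndarray
    visible_v: np.ndarray

    def check_partition(self):
        for masked, visible, n in (
                (self.masked_f, self.visible_f, self.patches_f.shape[1]),
                (self.masked_v, self.visible_v, self.patches_v.shape[1])):
            for b in range(masked.shape[0]):
                union = np.union1d(masked[b], visible[b])
                if union.size != n or not np.array_equal(union, np.arange(n)):
                    raise AssertionError("mask/visible sets do not partition")


def make_token_batch(images: np.ndarray, fmri: np.ndarray, cfg: MAEConfig,
                     rng: np.random.Generator) -> TokenBatch:
    pf = fmri_patches(fmri, cfg.patch_fmri)
    pv = image_patches(images, cfg.patch_image)
    B, n_f, _ = pf.shape
    n_v = pv.shape[1]
    mf = np.stack([sample_mask(n_f, cfg.mask_ratio_fmri, rng) for _ in range(B)])
    mv = np.stack([sample_mask(n_v, cfg.mask_ratio_image, rng) for _ in range(B)])
    vf = np.stack([_complement(mf[b], n_f) for b in range(B)])
    vv = np.stack([_complement(mv[b], n_v) for b in range(B)])
    return TokenBatch(pf, pv, mf, mv, vf, vv)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class MultimodalMAE(nn.Module):
    def __init__(self, cfg: MAEConfig, rng: np.random.Generator):
        self.cfg = cfg
        D, Dd = cfg.enc_dim, cfg.dec_dim
        n_private = cfg.enc_layers - cfg.shared_top_layers
        self.embed_f = nn.Linear(cfg.patch_fmri, D, rng)
        self.embed_v = nn.Linear(cfg.patch_image ** 2 * 3, D, rng)
        self.blocks_f = [nn.TransformerBlock(D, cfg.enc_heads, cfg.enc_mlp, rng)
                         for _ in range(n_private)]
        self.blocks_v = [nn.TransformerBlock(D, cfg.enc_heads, cfg.enc_mlp, rng)
                         for _ in range(n_private)]
        self.blocks_shared = [
            nn.TransformerBlock(D, cfg.enc_heads, cfg.enc_mlp, rng)
            for _ in range(cfg.shared_top_layers)]
        self.enc_norm = nn.LayerNorm(D)
        self.dec_embed = nn.Linear(D, Dd, rng)
        self.mask_token_f = nn.Parameter(0.02 * rng.standard_normal(Dd))
        self.mask_token_v = nn.Parameter(0.02 * rng.standard_normal(Dd))
        self.mod_tag_f = nn.Parameter(0.02 * rng.standard_normal(Dd))
        self.mod_tag_v = nn.Parameter(0.02 * rng.standard_normal(Dd))
        self.blocks_dec = [
            nn.TransformerBlock(Dd, cfg.dec_heads, cfg.dec_mlp, rng)
            for _ in range(cfg.dec_layers)]
        self.dec_norm = nn.LayerNorm(Dd)
        self.head_f = nn.Linear(Dd, cfg.patch_fmri, rng)
        self.head_v = nn.Linear(Dd, cfg.patch_image ** 2 * 3, rng)
        # fixed sinusoidal positional tables, one per modality and stage
        self.pos_enc_f = nn.sinusoidal_encoding(cfg.n_fmri_tokens, D)
        self.pos_enc_v = nn.sinusoidal_encoding(cfg.n_image_tokens, D)
        self.pos_dec_f = nn.sinusoidal_encoding(cfg.n_fmri_tokens, Dd)
        self.pos_dec_v = nn.sinusoidal_encoding(cfg.n_image_tokens, Dd)

    # -- tokenization ---------------------------------------------------
    def patchify_fmri(self, fmri: np.ndarray) -> Tensor:
        """Padded fMRI vectors -> positional patch embeddings (B, n_f, D)."""
        p = fmri_patches(fmri, self.cfg.patch_fmri)
        return self.embed_f(Tensor(p)) + Tensor(self.pos_enc_f[None])

    def patchify_image(self, images: np.ndarray) -> Tensor:
        p = image_patches(images, self.cfg.patch_image)
        return self.embed_v(Tensor(p)) + Tensor(self.pos_enc_v[None])

    # -- encoder ----------------------------------------------------------
    def _run_stream(self, x: Tensor, private: list) -> Tensor:
        for blk in private:
            x = blk(x)
        for blk in self.blocks_shared:
            x = blk(x)
        return self.enc_norm(x)

    def encode(self, tokens_f: Tensor | None = None,
               tokens_v: Tensor | None = None) -> dict:
        """Run visible tokens through private-bottom + shared-top layers."""
        if tokens_f is None and tokens_v is None:
            raise ValueError("encode requires at least one modality stream")
        out = {}
        if tokens_f is not None:
            if tokens_f.shape[1] == 0:
                raise ValueError("empty visible fMRI token set")
            out["f"] = self._run_stream(tokens_f, self.blocks_f)
        if tokens_v is not None:
            if tokens_v.shape[1] == 0:
                raise ValueError("empty visible image token set")
            out["v"] = self._run_stream(tokens_v, self.blocks_v)
        return out

    def encode_fmri_full(self, fmri: np.ndarray) -> Tensor:
        """All-visible (zero masking) fMRI latents, used for conditioning."""
        return self.encode(tokens_f=self.patchify_fmri(fmri))["f"]

    # -- decoder ----------------------------------------------------------
    def _assemble(self, latents: Tensor, masked: np.ndarray,
                  visible: np.ndarray, mask_token: Tensor, mod_tag: Tensor,
                  pos_dec: np.ndarray, n_tokens: int) -> Tensor:
        B = latents.shape[0]
        if masked.size and masked.max() >= n_tokens:
            raise IndexError("masked index out of range")
        dec = self.dec_embed(latents)
        mtok = mask_token.reshape(1, 1, -1) * Tensor(
            np.ones((B, masked.shape[1], 1), dtype=np.float32))
        seq = nn.concat([dec, mtok], axis=1)          # visible-then-masked
        order = np.argsort(np.concatenate([visible, masked], axis=1), axis=1)
        full = seq[np.arange(B)[:, None], order]      # original token order
        return full + Tensor(pos_dec[None]) + mod_tag.reshape(1, 1, -1)

    def decode_joint(self, latent_f: Tensor, latent_v: Tensor,
                     masked_f: np.ndarray, visible_f: np.ndarray,
                     masked_v: np.ndarray, visible_v: np.ndarray
                     ) -> tuple[Tensor, Tensor]:
        """Shared decoding of the concatenated fMRI+image sequence."""
        cfg = self.cfg
        seq_f = self._assemble(latent_f, masked_f, visible_f,
                               self.mask_token_f, self.mod_tag_f,
                               self.pos_dec_f, cfg.n_fmri_tokens)
        seq_v = self._assemble(latent_v, masked_v, visible_v,
                               self.mask_token_v, self.mod_tag_v,
                               self.pos_dec_v, cfg.n_image_tokens)
        x = nn.concat([seq_f, seq_v], axis=1)         # fMRI first, then image
        for blk in self.blocks_dec:
            x = blk(x)
        x = self.dec_norm(x)
        n_f = cfg.n_fmri_tokens
        return self.head_f(x[:, :n_f]), self.head_v(x[:, n_f:])

    # -- loss --------------------------------------------------------------
    def loss_rec(self, recon_f: Tensor, recon_v: Tensor,
                 batch: TokenBatch) -> dict:
        cfg = self.cfg
        losses = {}
        for key, recon, target, masked, alpha, n in (
                ("L_f", recon_f, batch.patches_f, batch.masked_f,
                 cfg.mask_ratio_fmri, cfg.n_fmri_tokens),
                ("L_v", recon_v, batch.patches_v, batch.masked_v,
                 cfg.mask_ratio_image, cfg.n_image_tokens)):
            if masked.shape[1] == 0:
                if alpha > 0:
                    raise ValueError(
                        f"empty masked set for modality with ratio {alpha}")
                losses[key] = Tensor(0.0)
                continue
            B = recon.shape[0]
            bidx = np.arange(B)[:, None]
            diff = recon[bidx, masked] - Tensor(target[bidx, masked])
            per_token = (diff * diff).sum(axis=-1)      # ||.||^2 within patch
            losses[key] = per_token.sum() * (1.0 / (alpha * n * B))
        losses["L_rec"] = 0.5 * losses["L_f"] + 0.5 * losses["L_v"]
        return losses

    def forward_batch(self, images: np.ndarray, fmri: np.ndarray,
                      rng: np.random.Generator) -> dict:
        batch = make_token_batch(images, fmri, self.cfg, rng)
        batch.check_partition()
        B = batch.patches_f.shape[0]
        bidx = np.arange(B)[:, None]
        emb_f = self.patchify_fmri(fmri)[bidx, batch.visible_f]
        emb_v = self.patchify_image(images)[bidx, batch.visible_v]
        lat = self.encode(tokens_f=emb_f, tokens_v=emb_v)
        recon_f, recon_v = self.decode_joint(
            lat["f"], lat["v"], batch.masked_f, batch.visible_f,
            batch.masked_v, batch.visible_v)
        out = self.loss_rec(recon_f, recon_v, batch)
        out.update(batch=batch, recon_f=recon_f, recon_v=recon_v)
        return out


def count_parameters(cfg: MAEConfig) -> int:
    """Closed-form parameter count of MultimodalMAE as a function of config."""
    def block(d, m):
        attn = 4 * (d * d + d)
        return 2 * (2 * d) + attn + (d * m + m) + (m * d + d)

    D, Dd = cfg.enc_dim, cfg.dec_dim
    n_private = cfg.enc_layers - cfg.shared_top_layers
    pv = cfg.patch_image ** 2 * 3
    total = (cfg.patch_fmri * D + D) + (pv * D + D)
    total += (2 * n_private + cfg.shared_top_layers) * block(D, cfg.enc_mlp)
    total += 2 * D                                   # encoder norm
    total += D * Dd + Dd                             # decoder embed
    total += 4 * Dd                                  # mask tokens + mod tags
    total += cfg.dec_layers * block(Dd, cfg.dec_mlp)
    total += 2 * Dd                                  # decoder norm
    total += Dd * cfg.patch_fmri + cfg.patch_fmri
    total += Dd * pv + pv
    return total


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def prepare_arrays(samples: list[PairedSample], cfg: MAEConfig,
                   normalizer: FmriNormalizer | None = None
                   ) -> tuple[np.ndarray, np.ndarray, FmriNormalizer]:
    """Stack images and z-scored, padded fMRI vectors from paired samples."""
    images = np.stack([s.image for s in samples]).astype(np.float32)
    fmri_raw = np.stack([s.fmri for s in samples])
    if normalizer is None:
        normalizer = FmriNormalizer.fit(fmri_raw)
    z = normalizer.transform(fmri_raw)
    padded = np.stack([pad_to_patch_multiple(v, cfg.patch_fmri) for v in z])
    if padded.shape[1] != cfg.fmri_len:
        raise ValueError(
            f"padded fMRI length {padded.shape[1]} != config fmri_len "
            f"{cfg.fmri_len}")
    return images, padded.astype(np.float32), normalizer


def train_mae(samples: list[PairedSample], cfg: MAEConfig, stage: str,
              optim: OptimParams, seed: int,
              init_state: dict | None = None,
              normalizer: FmriNormalizer | None = None,
              reinit_fmri_embed: bool = True,
              ) -> tuple[MultimodalMAE, list[dict], FmriNormalizer]:
    """Masked-reconstruction training (stage='pretrain' or 'finetune').

    Fine-tuning requires `init_state`; when the target voxel count differs
    from the pre-training one, the fMRI patch embedding is re-initialized
    (positional tables are fixed sinusoids and adapt automatically) while all
    transformer weights are kept.
    """
    if stage not in ("pretrain", "finetune"):
        raise ValueError(f"stage must be pretrain|finetune, got {stage!r}")
    if stage == "finetune" and init_state is None:
        raise ValueError("finetune requires initial weights from pretraining")

    model = MultimodalMAE(cfg, substream(seed, "mae-init"))
    if init_state is not None:
        own = model.state_dict()
        state = dict(init_state)
        for k in list(state):
            if k not in own or own[k].shape != state[k].shape:
                del state[k]   # meta entries / incompatible shapes
        own.update(state)
        model.load_state_dict(own)
        if reinit_fmri_embed and init_state.get("__fmri_len__") is not None:
            prev = int(np.asarray(init_state["__fmri_len__"]))
            if prev != cfg.fmri_len:
                fresh = MultimodalMAE(cfg, substream(seed, "mae-reinit"))
                model.embed_f.weight.data = fresh.embed_f.weight.data.copy()
                model.embed_f.bias.data = fresh.embed_f.bias.data.copy()

    images, fmri, normalizer = prepare_arrays(samples, cfg, normalizer)
    n = len(samples)
    opt = nn.Adam(model.parameters(), lr=optim.lr, betas=optim.betas,
                  weight_decay=optim.weight_decay)
    order_rng = substream(seed, "mae-order")
    mask_rng = substream(seed, "mae-mask")
    aug_rng = substream(seed, "mae-aug")
    history: list[dict] = []
    for epoch in range(optim.epochs):
        lr = nn.cosine_lr(optim.lr, epoch, optim.epochs)
        perm = order_rng.permutation(n)
        ep = {"epoch": epoch, "L_f": 0.0, "L_v": 0.0, "L_rec": 0.0, "lr": lr}
        n_batches = 0
        for start in range(0, n, optim.batch_size):
            idx = perm[start: start + optim.batch_size]
            imgs = images[idx]
            if optim.augment_images:
                imgs = np.stack([
                    augment(im, "stage12", aug_rng, out_size=cfg.image_size)
                    for im in imgs]).astype(np.float32)
            out = model.forward_batch(imgs, fmri[idx], mask_rng)
            model.zero_grad()
            out["L_rec"].backward()
            opt.step(lr=lr)
            for k in ("L_f", "L_v", "L_rec"):
                ep[k] += out[k].item()
            n_batches += 1
        for k in ("L_f", "L_v", "L_rec"):
            ep[k] /= max(n_batches, 1)
        history.append(ep)
    return model, history, normalizer


def mae_state_with_meta(model: MultimodalMAE) -> dict:
    state = model.state_dict()
    state["__fmri_len__"] = np.array(model.cfg.fmri_len)
    return state
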