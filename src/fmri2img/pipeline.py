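"""Three-stage training pipeline, ablation runner and evaluation wiring.

Stage 1 pre-trains the multimodal MAE on a large paired dataset (a
pre-training world with a different voxel partition, mirroring the shift
from an early-visual-cortex pre-training set to the five-ROI target set);
stage 2 fine-tunes the MAE with masked reconstruction on the target
dataset; stage 3 fine-tunes the fMRI encoder, conditioning map and the
denoiser's cross-attention blocks against the latent-diffusion objective.
The frozen generative backbone (latent autoencoder + unconditionally
pre-trained denoiser) plays the role of an external pretrained diffusion
checkpoint and is shared across ablation arms and replicate seeds, as are
the datasets and evaluation seeds; arms differ only in which training
stages run.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .diffusion import (BrainDecoder, CondUNet, DiffusionConfig, FmriConditioner,
                        LatentAE, LatentScaler, train_latent_ae,
                        train_ldm_backbone, train_stage3)
from .mae import (MAEConfig, MultimodalMAE, OptimParams, mae_state_with_meta,
                  train_mae)
from .metrics import MetricReport, build_standins, evaluate
from .seeding import substream, substream_seed
from .synth import (DEFAULT_ROI_TABLE, FmriNormalizer, SyntheticWorld,
                    evc_features, loc_features, make_dataset, opa_features,
                    split_of)

ARMS = ("stage3", "stage2+stage3", "stage1+stage3", "stage1+stage2+stage3")


def pretrain_world(noise_sd: float = 0.2) -> SyntheticWorld:
    """Early-visual pre-training world: four V1–V4-style ROIs, 931 voxels
    (padded to 944), distinct readout seed."""
    return SyntheticWorld(
        roi_table=(("V1", 250), ("V2", 240), ("V3", 230), ("V4", 211)),
        feature_maps={"V1": evc_features, "V2": evc_features,
                      "V3": loc_features, "V4": opa_features},
        noise_sd=noise_sd,
        readout_seed=271828,
    )


@dataclass(frozen=True)
class DeskPreset:
    """Problem sizes and schedules for the desk-scale pipeline."""

    n_target: int = 500
    n_pretrain: int = 500
    noise_sd: float = 0.2
    mae_cfg: MAEConfig = field(default_factory=lambda: MAEConfig(
        enc_layers=3, enc_dim=64, enc_mlp=128, enc_heads=4,
        shared_top_layers=1, dec_layers=2, dec_dim=48, dec_mlp=96,
        dec_heads=4, image_size=64, fmri_len=1696))
    diffusion_cfg: DiffusionConfig = field(
        default_factory=DiffusionConfig.desk)
    stage1: OptimParams = OptimParams(batch_size=64, lr=2e-3, epochs=4,
                                      betas=(0.9, 0.98), weight_decay=0.01)
    stage2: OptimParams = OptimParams(batch_size=64, lr=1e-3, epochs=3,
                                      betas=(0.9, 0.98), weight_decay=0.01)
    stage3: OptimParams = OptimParams(batch_size=16, lr=5e-3, epochs=15,
                                      betas=(0.9, 0.999), weight_decay=0.01)
    ae_epochs: int = 45
    ae_tol: float = 0.02
    ae_max_images: int = 240
    backbone_epochs: int = 80
    standins_epochs: int = 40
    standins_floor: float = 0.9
    n_samples_per_item: int = 1
    guidance: float = 1.5


@dataclass
class StagePlan:
    """Which training arms to run; stage 3 is always required."""

    arms: tuple[str, ...] = ("stage1", "stage2", "stage3")
    seed: int = 0
    out_dir: str | None = None
    preset: DeskPreset = field(default_factory=DeskPreset)

    def __post_init__(self):
        valid = {"stage1", "stage2", "stage3"}
        unknown = set(self.arms) - valid
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if "stage3" not in self.arms:
            raise ValueError("stage3 must be part of every plan")

    @property
    def arm_name(self) -> str:
        order = [s for s in ("stage1", "stage2", "stage3") if s in self.arms]
        return "+".join(order)


@dataclass
class SharedContext:
    """World, datasets, backbone and evaluation stand-ins shared across
    ablation arms and replicate seeds."""

    target_world: SyntheticWorld
    pre_world: SyntheticWorld
    target_data: list
    pretrain_data: list
    normalizer: FmriNormalizer
    ae: LatentAE
    unet_init: dict
    scaler: LatentScaler
    extractors: dict
    preset: DeskPreset
    seed: int
    cond_table: np.ndarray | None = None   # backbone caption embeddings
    ae_history: list | None = None         # latent-AE training log


def build_shared_context(seed: int, preset: DeskPreset | None = None,
                         ae: LatentAE | None = None,
                         scaler: LatentScaler | None = None,
                         unet_init: dict | None = None) -> SharedContext:
    """Generate data and train the frozen backbone + metric stand-ins.

    `ae`/`scaler`/`unet_init` may be passed in to reuse an existing trained
    backbone (it is frozen during stage 3, so sharing is sound).
    """
    preset = preset or DeskPreset()
    target_world = SyntheticWorld(noise_sd=preset.noise_sd)
    pre_world = pretrain_world(noise_sd=preset.noise_sd)
    target_data = make_dataset(preset.n_target, target_world,
                               seed=substream_seed(seed, "target-data"))
    pretrain_data = make_dataset(
        preset.n_pretrain, pre_world, split_fractions=(0.9, 0.1, 0.0),
        seed=substream_seed(seed, "pretrain-data"))
    train = split_of(target_data, "train")
    train_imgs = np.stack([s.image for s in train]).astype(np.float32)
    train_labels = np.array([s.category_index for s in train])
    normalizer = FmriNormalizer.fit(np.stack([s.fmri for s in train]))

    dcfg = preset.diffusion_cfg
    ae_history = None
    if ae is None:
        ae_imgs = train_imgs[:preset.ae_max_images]
        ae, ae_history = train_latent_ae(
            ae_imgs, dcfg, seed=substream_seed(seed, "ae"),
            epochs=preset.ae_epochs, tol=preset.ae_tol)
    cond_table = None
    if unet_init is None or scaler is None:
        unet, scaler, cond_table, _ = train_ldm_backbone(
            train_imgs, train_labels, ae, dcfg,
            seed=substream_seed(seed, "backbone"),
            n_classes=len(target_world.categories),
            epochs=preset.backbone_epochs)
        unet_init = unet.state_dict()
    extractors = build_standins(target_world, train_imgs, train_labels,
                                seed=substream_seed(seed, "standins"),
                                epochs=preset.standins_epochs,
                                accuracy_floor=preset.standins_floor)
    return SharedContext(target_world, pre_world, target_data, pretrain_data,
                         normalizer, ae, unet_init, scaler, extractors,
                         preset, seed, cond_table, ae_history)


def _fresh_unet(ctx: SharedContext) -> CondUNet:
    unet = CondUNet(ctx.preset.diffusion_cfg,
                    substream(ctx.seed, "unet-shape"))
    unet.load_state_dict(ctx.unet_init)
    unet.trained = True
    return unet


def run_arm(ctx: SharedContext, plan: StagePlan,
            stage1_cache: dict | None = None
            ) -> tuple[BrainDecoder, MetricReport, dict]:
    """Execute one training arm and evaluate it on the shared test split.

    `stage1_cache` lets callers reuse the stage-1 checkpoint across arms of
    the same replicate seed (identical inputs give identical weights).
    """
    preset = ctx.preset
    seed = plan.seed
    cfg_target = preset.mae_cfg
    logs: dict = {"arm": plan.arm_name, "seed": seed}

    state = None
    if "stage1" in plan.arms:
        if stage1_cache is not None and "state" in stage1_cache:
            state = stage1_cache["state"]
            logs["stage1"] = stage1_cache["history"]
        else:
            cfg_pre = replace(cfg_target,
                              fmri_len=_padded_len(ctx.pre_world, cfg_target))
            mae_pre, hist1, _ = train_mae(
                split_of(ctx.pretrain_data, "train"), cfg_pre, "pretrain",
                preset.stage1, seed=substream_seed(seed, "stage1"))
            state = mae_state_with_meta(mae_pre)
            logs["stage1"] = hist1
            if stage1_cache is not None:
                stage1_cache.update(state=state, history=hist1)

    train = split_of(ctx.target_data, "train")
    if "stage2" in plan.arms:
        stage = "finetune" if state is not None else "pretrain"
        mae, hist2, _ = train_mae(
            train, cfg_target, stage, preset.stage2,
            seed=substream_seed(seed, "stage2"), init_state=state,
            normalizer=ctx.normalizer)
        logs["stage2"] = hist2
    elif state is not None:
        mae, _, _ = train_mae(train, cfg_target, "finetune",
                              replace(preset.stage2, epochs=0),
                              seed=substream_seed(seed, "stage2-init"),
                              init_state=state, normalizer=ctx.normalizer)
    else:
        mae = MultimodalMAE(cfg_target, substream(seed, "mae-scratch"))

    dcfg = preset.diffusion_cfg
    conditioner = FmriConditioner(cfg_target.n_fmri_tokens,
                                  cfg_target.enc_dim, dcfg,
                                  substream(seed, "conditioner"))
    unet = _fresh_unet(ctx)
    hist3 = train_stage3(train, mae, conditioner, unet, ctx.ae, ctx.scaler,
                         dcfg, preset.stage3,
                         seed=substream_seed(seed, "stage3"),
                         normalizer=ctx.normalizer)
    logs["stage3"] = hist3

    decoder = BrainDecoder(mae, conditioner, unet, ctx.ae, ctx.scaler, dcfg,
                           ctx.normalizer)
    report = evaluate(decoder, split_of(ctx.target_data, "test"),
                      ctx.extractors,
                      n_samples_per_item=preset.n_samples_per_item,
                      seed=substream_seed(ctx.seed, "eval"),
                      guidance=preset.guidance)
    return decoder, report, logs


def _padded_len(world: SyntheticWorld, cfg: MAEConfig) -> int:
    p = cfg.patch_fmri
    return int(np.ceil(world.n_voxels / p)) * p


def run_stages(plan: StagePlan, ctx: SharedContext | None = None) -> dict:
    """Run one full plan and write a manifest of everything needed to
    reproduce it."""
    ctx = ctx or build_shared_context(plan.seed, plan.preset)
    decoder, report, logs = run_arm(ctx, plan)
    manifest = {
        "arm": plan.arm_name,
        "seed": plan.seed,
        "preset": _preset_dict(plan.preset),
        "world": ctx.target_world.to_dict(),
        "pretrain_world": ctx.pre_world.to_dict(),
        "data_hash": dataset_hash(ctx.target_data),
        "pretrain_data_hash": dataset_hash(ctx.pretrain_data),
        "metrics": report.row(),
    }
    if plan.out_dir:
        os.makedirs(plan.out_dir, exist_ok=True)
        with open(os.path.join(plan.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        from .io import save_checkpoint, write_log_csv
        save_checkpoint(os.path.join(plan.out_dir, "mae.npz"),
                        decoder.mae.state_dict(),
                        {"arm": plan.arm_name, "seed": plan.seed})
        save_checkpoint(os.path.join(plan.out_dir, "unet.npz"),
                        decoder.unet.state_dict(), {})
        for stage_name in ("stage1", "stage2", "stage3"):
            if stage_name in logs and isinstance(logs[stage_name], list):
                write_log_csv(os.path.join(plan.out_dir,
                                           f"{stage_name}_log.csv"),
                              logs[stage_name])
    manifest["_decoder"] = decoder
    manifest["_report"] = report
    return manifest


def run_ablation(base_seed: int, n_seeds: int = 5,
                 preset: DeskPreset | None = None,
                 arms: tuple[str, ...] = ARMS,
                 ctx: SharedContext | None = None) -> dict:
    """Stagewise-training ablation: shared data/backbone/eval, per-seed
    training of each arm; means over seeds per metric column."""
    preset = preset or DeskPreset()
    ctx = ctx or build_shared_context(base_seed, preset)
    arm_plans = {
        "stage3": ("stage3",),
        "stage2+stage3": ("stage2", "stage3"),
        "stage1+stage3": ("stage1", "stage3"),
        "stage1+stage2+stage3": ("stage1", "stage2", "stage3"),
    }
    for arm in arms:
        if arm not in arm_plans:
            raise ValueError(f"unknown arm {arm!r}")
    rows: dict = {arm: [] for arm in arms}
    items: dict = {arm: [] for arm in arms}
    for k in range(n_seeds):
        seed_k = substream_seed(base_seed, "ablation-seed", str(k))
        s1_cache: dict = {}
        for arm in arms:
            plan = StagePlan(arms=arm_plans[arm], seed=seed_k, preset=preset)
            _, report, _ = run_arm(ctx, plan, stage1_cache=s1_cache)
            rows[arm].append(report.row())
            items[arm].append(report.per_item)
    table = {}
    for arm in arms:
        cols = {}
        for key in ("ssim", "low_two_way", "high1_two_way", "high2_two_way",
                    "fifty_way"):
            cols[key] = float(np.mean([r[key] for r in rows[arm]]))
        table[arm] = cols
    return {"table": table, "per_seed": rows, "per_item": items,
            "n_seeds": n_seeds, "base_seed": base_seed}


def low_noise_probe(ctx: SharedContext, seed: int, noise_sd: float = 0.05,
                    n_samples_per_item: int = 2,
                    stage3_epochs: int = 30) -> MetricReport:
    """End-to-end decodability probe on a low-noise paired dataset.

    The generative backbone, metric stand-ins and pre-training corpus are
    reused from `ctx` (images do not depend on the fMRI noise level); only
    the target dataset is regenerated at `noise_sd` and the full
    stage-1+2+3 arm is trained on it, with a longer stage-3 schedule than
    the replicated ablation arms (one run, so the budget allows it).
    """
    import copy

    world = SyntheticWorld(noise_sd=noise_sd)
    data = make_dataset(ctx.preset.n_target, world,
                        seed=substream_seed(seed, "lownoise-data"))
    train = split_of(data, "train")
    normalizer = FmriNormalizer.fit(np.stack([s.fmri for s in train]))
    ctx2 = copy.copy(ctx)
    ctx2.target_world = world
    ctx2.target_data = data
    ctx2.normalizer = normalizer
    ctx2.preset = replace(ctx.preset, noise_sd=noise_sd,
                          n_samples_per_item=n_samples_per_item,
                          stage3=replace(ctx.preset.stage3,
                                         epochs=stage3_epochs))
    plan = StagePlan(arms=("stage1", "stage2", "stage3"),
                     seed=substream_seed(seed, "lownoise-run"),
                     preset=ctx2.preset)
    _, report, _ = run_arm(ctx2, plan)
    return report


def dataset_hash(samples: list) -> str:
    h = hashlib.sha256()
    for s in samples:
        h.update(s.image.tobytes())
        h.update(s.fmri.tobytes())
        h.update(s.category.encode())
        h.update(s.split.encode())
    return h.hexdigest()[:16]


def _preset_dict(p: DeskPreset) -> dict:
    return {
        "n_target": p.n_target, "n_pretrain": p.n_pretrain,
        "noise_sd": p.noise_sd,
        "mae_cfg": vars(p.mae_cfg).copy() if not hasattr(
            p.mae_cfg, "__dataclass_fields__") else {
            k: getattr(p.mae_cfg, k)
            for k in p.mae_cfg.__dataclass_fields__},
        "stage1_epochs": p.stage1.epochs, "stage2_epochs": p.stage2.epochs,
        "stage3_epochs": p.stage3.epochs, "ae_epochs": p.ae_epochs,
        "backbone_epochs": p.backbone_epochs,
        "n_samples_per_item": p.n_samples_per_item,
        "guidance": p.guidance,
    }
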