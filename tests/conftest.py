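"""Shared fixtures.

The heavy session fixtures train the desk-scale stack once (latent AE,
caption-conditional backbone, metric stand-ins), run the two-arm stagewise
ablation, and train the low-noise end-to-end probe; the decodability and
ablation-ordering checks and the autoencoder-quality property all read
from them.
"""

import dataclasses

import numpy as np
import pytest

from fmri2img.mae import MAEConfig, OptimParams
from fmri2img.pipeline import (DeskPreset, build_shared_context,
                               low_noise_probe, run_ablation)


@pytest.fixture(scope="session")
def desk_ctx():
    """Shared desk-scale context: 500-sample five-ROI target world plus the
    frozen generative backbone and evaluation stand-ins."""
    preset = dataclasses.replace(DeskPreset(), ae_tol=np.inf)
    return build_shared_context(1, preset)


@pytest.fixture(scope="session")
def ablation_result(desk_ctx):
    """Five-seed ablation of the two extreme arms (stage 3 only vs all
    three stages) on the shared context, with the shortened stage-3
    schedule used for replicated runs."""
    preset = dataclasses.replace(
        desk_ctx.preset,
        stage3=dataclasses.replace(desk_ctx.preset.stage3, epochs=6))
    return run_ablation(1, n_seeds=5, preset=preset, ctx=desk_ctx,
                        arms=("stage3", "stage1+stage2+stage3"))


@pytest.fixture(scope="session")
def low_noise_report(desk_ctx):
    """Full three-stage pipeline trained and evaluated on a low-noise
    (SNR ~ 20) paired dataset, sharing the frozen backbone."""
    return low_noise_probe(desk_ctx, seed=1)


@pytest.fixture(scope="session")
def tiny_preset():
    """Minimal problem sizes: exercises every code path, not performance."""
    return DeskPreset(
        n_target=130, n_pretrain=120,
        mae_cfg=MAEConfig(enc_layers=3, enc_dim=64, enc_mlp=128, enc_heads=4,
                          shared_top_layers=1, dec_layers=2, dec_dim=48,
                          dec_mlp=96, dec_heads=4, image_size=64,
                          fmri_len=1696),
        stage1=OptimParams(batch_size=64, lr=2e-3, epochs=1,
                           betas=(0.9, 0.98)),
        stage2=OptimParams(batch_size=64, lr=1e-3, epochs=1,
                           betas=(0.9, 0.98)),
        stage3=OptimParams(batch_size=32, lr=2e-3, epochs=1,
                           betas=(0.9, 0.999)),
        ae_epochs=4, ae_tol=np.inf, ae_max_images=104, backbone_epochs=2,
        standins_epochs=4, standins_floor=0.0, n_samples_per_item=1)


@pytest.fixture(scope="session")
def tiny_ctx(tiny_preset):
    return build_shared_context(3, tiny_preset)
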