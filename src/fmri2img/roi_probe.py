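"""Probing ROI function by decoding synthetic ±1 activation patterns.

An artificial fMRI pattern sets every voxel of the "activated" ROIs to +1
and every other voxel to -1 (in z-score-like units, i.e. injected after the
normalization stage), pads it to the patch grid, and decodes images from it.
Per-pattern profiles — the mean class-score distribution under the stand-in
classifier and mean low-level filter energies — quantify what each ROI (or
ROI pair) drives the generator towards; a cosine dominance score compares a
coactivation profile with each constituent ROI's single-activation profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .metrics import FeatureExtractor, SmallConvNet, filter_bank_features
from .seeding import substream_seed
from .synth import SyntheticWorld, pad_to_patch_multiple


@dataclass
class ROIPattern:
    """±1 assignment over ROIs realised as a voxel vector."""

    assignment: dict            # roi_name -> +1 | -1
    vector: np.ndarray          # length-V, pre-padding
    padded: np.ndarray          # padded to the patch grid

    @property
    def name(self) -> str:
        active = [r for r, v in self.assignment.items() if v > 0]
        return "+".join(active) if active else "none"


def make_pattern(active_set, world: SyntheticWorld,
                 patch_size: int = 16) -> ROIPattern:
    """+1 on voxels of active ROIs, -1 elsewhere, padded with zeros."""
    active = set(active_set)
    unknown = active - set(world.roi_names)
    if unknown:
        raise KeyError(
            f"unknown ROI name(s) {sorted(unknown)}; known: {world.roi_names}")
    assignment = {r: (1 if r in active else -1) for r in world.roi_names}
    vector = np.empty(world.n_voxels, dtype=np.float32)
    for roi, val in assignment.items():
        vector[world.roi_slice(roi)] = val
    return ROIPattern(assignment, vector,
                      pad_to_patch_multiple(vector, patch_size))


def single_patterns(world: SyntheticWorld, patch_size: int = 16
                    ) -> list[ROIPattern]:
    return [make_pattern({r}, world, patch_size) for r in world.roi_names]


def pairwise_patterns(world: SyntheticWorld, patch_size: int = 16
                      ) -> list[ROIPattern]:
    """C(n,2) coactivation patterns over the world's ROIs."""
    return [make_pattern(set(pair), world, patch_size)
            for pair in combinations(world.roi_names, 2)]


def probe(patterns: list[ROIPattern], decoder, n_samples: int = 10,
          seed: int = 0, guidance: float | None = None) -> np.ndarray:
    """Decode `n_samples` images per pattern.

    Returns (n_patterns, n_samples, H, W, 3).  Sample seeds derive from
    (seed, pattern index) so the report is reproducible and patterns are
    independent.
    """
    if not decoder.unet.trained:
        raise RuntimeError("decoder networks are untrained")
    out = []
    for pi, pat in enumerate(patterns):
        imgs = decoder.decode_padded(
            pat.padded[None], n_samples=n_samples, guidance=guidance,
            seed=substream_seed(seed, "probe", str(pi)))
        out.append(imgs[0])
    return np.stack(out)


def summarize(images_per_pattern: np.ndarray,
              classifier: SmallConvNet,
              low_extractor: FeatureExtractor | None = None) -> list[dict]:
    """Per-pattern profile: mean class-score distribution (rows sum to 1)
    and mean low-level filter-energy features."""
    profiles = []
    for imgs in images_per_pattern:
        scores = classifier.predict_scores(imgs)
        mean_scores = scores.mean(axis=0)
        mean_scores = mean_scores / mean_scores.sum()
        low = (low_extractor(imgs) if low_extractor is not None
               else filter_bank_features(imgs))
        profiles.append({
            "class_profile": mean_scores,
            "low_level": low.mean(axis=0),
        })
    return profiles


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def dominance(coact_profile: dict, single_a: dict, single_b: dict) -> dict:
    """Cosine similarity of a coactivation class profile to each single-ROI
    profile; the larger similarity marks the dominant ROI."""
    return {
        "sim_a": cosine(coact_profile["class_profile"],
                        single_a["class_profile"]),
        "sim_b": cosine(coact_profile["class_profile"],
                        single_b["class_profile"]),
    }


def probe_report(world: SyntheticWorld, decoder, classifier: SmallConvNet,
                 n_samples: int = 10, seed: int = 0,
                 include_pairs: bool = True,
                 guidance: float | None = None) -> dict:
    """Full probing analysis: single activations, optional coactivations,
    profiles and pairwise dominance scores (JSON-serializable)."""
    singles = single_patterns(world)
    imgs_s = probe(singles, decoder, n_samples, seed, guidance)
    prof_s = summarize(imgs_s, classifier)
    report = {
        "single": {
            p.name: {"class_profile": pr["class_profile"].tolist(),
                     "low_level": pr["low_level"].tolist()}
            for p, pr in zip(singles, prof_s)},
        "n_samples": n_samples,
        "seed": seed,
    }
    if include_pairs:
        pairs = pairwise_patterns(world)
        imgs_p = probe(pairs, decoder, n_samples,
                       substream_seed(seed, "pairs"), guidance)
        prof_p = summarize(imgs_p, classifier)
        by_name = dict(zip([p.name for p in singles], prof_s))
        pair_block = {}
        for p, pr in zip(pairs, prof_p):
            a, b = [r for r, v in p.assignment.items() if v > 0]
            dom = dominance(pr, by_name[a], by_name[b])
            pair_block[p.name] = {
                "class_profile": pr["class_profile"].tolist(),
                "low_level": pr["low_level"].tolist(),
                "dominance": {a: dom["sim_a"], b: dom["sim_b"]},
            }
        report["pairs"] = pair_block
    return report


def save_image_grid(images: np.ndarray, path: str) -> None:
    """Rows = patterns, columns = samples; PNG output."""
    from PIL import Image

    n_pat, n_s, H, W, _ = images.shape
    grid = np.zeros((n_pat * H, n_s * W, 3), dtype=np.float32)
    for i in range(n_pat):
        for j in range(n_s):
            grid[i * H:(i + 1) * H, j * W:(j + 1) * W] = images[i, j]
    Image.fromarray((np.clip(grid, 0, 1) * 255).astype(np.uint8)).save(path)
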