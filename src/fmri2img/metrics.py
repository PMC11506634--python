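"""Reconstruction evaluation: SSIM, n-way identification, 50-way accuracy.

Identification follows the forced-choice protocol standard in visual
decoding: a reconstruction is scored by whether its feature vector
correlates more with its own ground truth than with a distractor's
(two-way), or whether a classifier ranks the true class highest among a
candidate set of 50 classes (50-way).  Feature extractors are desk-scale
stand-ins for the pretrained networks used at full scale: an untrained
oriented-filter energy bank (low level) and two small convolutional
networks trained on labelled synthetic images (high level).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.ndimage import convolve as _ndconvolve
from skimage.color import rgb2gray
from skimage.metrics import structural_similarity as _sk_ssim

from . import nn
from .nn import Tensor
from .seeding import substream
from .synth import SyntheticWorld


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------

def ssim(image_a: np.ndarray, image_b: np.ndarray, win_size: int = 7,
         sigma: float = 1.5) -> float:
    """Structural similarity on grayscale with a Gaussian window."""
    if image_a.shape != image_b.shape:
        raise ValueError(
            f"shape mismatch: {image_a.shape} vs {image_b.shape}")
    ga, gb = rgb2gray(image_a), rgb2gray(image_b)
    return float(_sk_ssim(ga, gb, win_size=win_size, gaussian_weights=True,
                          sigma=sigma, use_sample_covariance=False,
                          data_range=1.0))


# ---------------------------------------------------------------------------
# feature extractors
# ---------------------------------------------------------------------------

@dataclass
class FeatureExtractor:
    """Deterministic image -> feature-vector map (batched)."""

    name: str
    level: str                      # "low" | "high"
    fn: Callable[[np.ndarray], np.ndarray]   # (N,H,W,3) -> (N,D)

    def __call__(self, images: np.ndarray) -> np.ndarray:
        if images.ndim == 3:
            return self.fn(images[None])[0]
        return self.fn(images)


_ORIENTED_KERNELS = [
    np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float),      # 0
    np.array([[0, 1, 2], [-1, 0, 1], [-2, -1, 0]], dtype=float),      # 45
    np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float),      # 90
    np.array([[2, 1, 0], [1, 0, -1], [0, -1, -2]], dtype=float),      # 135
]


def filter_bank_features_single(image: np.ndarray, grid: int = 4) -> np.ndarray:
    """Low-level features of one image: oriented filter energies pooled on a
    grid + mean colour.  Untrained and deterministic."""
    g = rgb2gray(image)
    H, W = g.shape
    feats = []
    for k in _ORIENTED_KERNELS:
        e = _ndconvolve(g, k, mode="nearest") ** 2
        pooled = e.reshape(grid, H // grid, grid, W // grid).mean(axis=(1, 3))
        feats.append(pooled.ravel())
    feats.append(image.mean(axis=(0, 1)))
    return np.concatenate(feats)


def filter_bank_features(images: np.ndarray, grid: int = 4) -> np.ndarray:
    if images.ndim == 3:
        images = images[None]
    return np.stack([filter_bank_features_single(im, grid) for im in images])


class SmallConvNet(nn.Module):
    """Compact convolutional classifier over synthetic categories.

    Pooled conv activations are concatenated with mean colour and a coarse
    4x4 luminance grid before the embedding layer — cheap global context
    that speeds up convergence at desk scale.
    """

    def __init__(self, n_classes: int, image_size: int,
                 rng: np.random.Generator, width: int = 16,
                 embed_dim: int = 48):
        self.conv1 = nn.Conv2d(3, width, 3, rng, stride=2, padding=1)
        self.conv2 = nn.Conv2d(width, 2 * width, 3, rng, stride=2, padding=1)
        self.conv3 = nn.Conv2d(2 * width, 2 * width, 3, rng, stride=2,
                               padding=1)
        self.fc_embed = nn.Linear(2 * width + 3 + 16, embed_dim, rng)
        self.fc_out = nn.Linear(embed_dim, n_classes, rng)
        self._grid_cell = image_size // 4

    def features(self, images: np.ndarray) -> Tensor:
        if images.ndim == 3:
            images = images[None]
        x = Tensor(np.ascontiguousarray(
            images.transpose(0, 3, 1, 2).astype(np.float32)))
        h = self.conv1(x).gelu()
        h = self.conv2(h).gelu()
        h = self.conv3(h).gelu()
        B, C, Hh, Ww = h.shape
        pooled = h.reshape(B, C, Hh * Ww).mean(axis=-1)
        mean_rgb = Tensor(images.mean(axis=(1, 2)).astype(np.float32))
        g = images.mean(axis=3)
        k = self._grid_cell
        grid = Tensor(g.reshape(B, 4, k, 4, k).mean(axis=(2, 4))
                      .reshape(B, 16).astype(np.float32))
        cat = nn.concat([pooled, mean_rgb, grid], axis=1)
        return self.fc_embed(cat).gelu()

    def logits(self, images: np.ndarray) -> Tensor:
        return self.fc_out(self.features(images))

    def predict_scores(self, images: np.ndarray) -> np.ndarray:
        with nn.no_grad():
            return self.logits(images).softmax(axis=-1).data

    def embed(self, images: np.ndarray) -> np.ndarray:
        with nn.no_grad():
            return self.features(images).data


def _blur_noise(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random Gaussian blur + pixel noise: makes the stand-in evaluators
    robust to the softened detail of generated images (the role ImageNet
    pre-training plays for the full-scale extractors)."""
    from scipy.ndimage import gaussian_filter

    out = images.copy()
    for i in range(len(out)):
        sigma = rng.uniform(0.0, 1.5)
        if sigma > 0.05:
            out[i] = gaussian_filter(out[i], sigma=(sigma, sigma, 0))
        out[i] += rng.normal(0.0, 0.02, out[i].shape).astype(np.float32)
    return np.clip(out, 0.0, 1.0)


def _train_classifier(images: np.ndarray, labels: np.ndarray,
                      n_classes: int, seed: int, epochs: int,
                      width: int, embed_dim: int, lr: float = 5e-3,
                      batch_size: int = 32) -> SmallConvNet:
    net = SmallConvNet(n_classes, images.shape[1],
                       substream(seed, "clf-init"), width, embed_dim)
    opt = nn.Adam(net.parameters(), lr=lr)
    rng = substream(seed, "clf-order")
    aug_rng = substream(seed, "clf-aug")
    onehot = np.eye(n_classes, dtype=np.float32)[labels]
    for epoch in range(epochs):
        lr_e = nn.cosine_lr(lr, epoch, epochs)
        perm = rng.permutation(len(images))
        for s in range(0, len(images), batch_size):
            idx = perm[s: s + batch_size]
            batch = _blur_noise(images[idx].astype(np.float32), aug_rng)
            logit = net.logits(batch)
            logp = (logit.softmax(axis=-1) + 1e-9).log()
            loss = -(Tensor(onehot[idx]) * logp).sum() * (1.0 / len(idx))
            net.zero_grad()
            loss.backward()
            opt.step(lr=lr_e)
    return net


def build_standins(world: SyntheticWorld, train_images: np.ndarray,
                   train_labels: np.ndarray, seed: int,
                   epochs: int = 40, accuracy_floor: float = 0.9
                   ) -> dict:
    """Train the desk-scale extractor/classifier suite.

    Returns a dict with a low-level extractor (untrained filter bank), two
    high-level extractors (penultimate features of two independently trained
    conv nets) and the class-score classifier.  Raises if the classifier's
    held-out accuracy is below `accuracy_floor`.
    """
    n_classes = len(world.categories)
    rng = substream(seed, "standin-split")
    perm = rng.permutation(len(train_images))
    n_hold = max(16, len(train_images) // 10)
    hold, tr = perm[:n_hold], perm[n_hold:]
    net1 = _train_classifier(train_images[tr], train_labels[tr], n_classes,
                             substream(seed, "net1").integers(2**31),
                             epochs, width=16, embed_dim=48)
    # the second (embedding) net carries no accuracy floor; a shorter
    # schedule suffices for informative penultimate features
    net2 = _train_classifier(train_images[tr], train_labels[tr], n_classes,
                             substream(seed, "net2").integers(2**31),
                             max(10, int(0.6 * epochs)), width=12,
                             embed_dim=32)
    scores = net1.predict_scores(train_images[hold])
    acc = float((scores.argmax(axis=1) == train_labels[hold]).mean())
    if acc < accuracy_floor:
        raise RuntimeError(
            f"stand-in classifier held-out accuracy {acc:.3f} < floor "
            f"{accuracy_floor}")
    return {
        "low": FeatureExtractor("filterbank", "low", filter_bank_features),
        "high1": FeatureExtractor("convnet-features", "high", net1.embed),
        "high2": FeatureExtractor("embednet-features", "high", net2.embed),
        "classifier": net1,
        "holdout_accuracy": acc,
    }


def extract_features(extractor: FeatureExtractor,
                     images: np.ndarray) -> np.ndarray:
    return extractor(images)


# ---------------------------------------------------------------------------
# identification metrics
# ---------------------------------------------------------------------------

def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def two_way(recon_features: np.ndarray, truth_features_all: np.ndarray,
            item_index: int, rng: np.random.Generator,
            n_trials: int = 50) -> float:
    """Two-way identification accuracy for one item.

    Correct iff corr(recon, truth_item) > corr(recon, truth_distractor);
    ties score 0.5.  Exhaustive over all distractors when
    n_trials >= n_items - 1.
    """
    n_items = truth_features_all.shape[0]
    if n_items < 2:
        raise ValueError("two_way requires at least 2 items")
    own = _corr(recon_features, truth_features_all[item_index])
    others = [j for j in range(n_items) if j != item_index]
    if n_trials >= n_items - 1:
        distractors = others
    else:
        distractors = rng.choice(others, size=n_trials, replace=True)
    wins = 0.0
    for j in distractors:
        other = _corr(recon_features, truth_features_all[j])
        if own > other:
            wins += 1.0
        elif own == other:
            wins += 0.5
    return wins / len(distractors)


def two_way_batch(recon_feats: np.ndarray, truth_feats: np.ndarray,
                  rng: np.random.Generator, n_trials: int = 50) -> np.ndarray:
    return np.array([
        two_way(recon_feats[i], truth_feats, i, rng, n_trials)
        for i in range(len(recon_feats))])


def fifty_way(recon_images: np.ndarray, true_labels: np.ndarray,
              classifier: SmallConvNet, rng: np.random.Generator,
              n_ways: int = 50, n_repeats: int = 1) -> float:
    """n-way classification accuracy of reconstructions.

    Per item: candidate set = true class + (n_ways - 1) sampled distractor
    classes; correct iff the true class scores highest within candidates.
    """
    scores = classifier.predict_scores(recon_images)
    n_classes = scores.shape[1]
    if n_classes < n_ways:
        raise ValueError(
            f"need >= {n_ways} categories, classifier has {n_classes}")
    correct = []
    for _ in range(n_repeats):
        for i, label in enumerate(true_labels):
            others = np.delete(np.arange(n_classes), label)
            cand = np.concatenate(
                [[label], rng.choice(others, size=n_ways - 1, replace=False)])
            correct.append(
                float(cand[np.argmax(scores[i][cand])] == label))
    return float(np.mean(correct))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Mean +- sd per metric over test items, Table-style columns.

    `per_item` optionally holds the underlying per-test-item values
    (averaged over generated samples), for downstream uncertainty
    estimates."""

    ssim: tuple[float, float]
    low_two_way: tuple[float, float]
    high1_two_way: tuple[float, float]
    high2_two_way: tuple[float, float]
    fifty_way: tuple[float, float]
    per_item: dict | None = None

    def row(self) -> dict:
        return {
            "ssim": self.ssim[0], "ssim_sd": self.ssim[1],
            "low_two_way": self.low_two_way[0],
            "low_two_way_sd": self.low_two_way[1],
            "high1_two_way": self.high1_two_way[0],
            "high1_two_way_sd": self.high1_two_way[1],
            "high2_two_way": self.high2_two_way[0],
            "high2_two_way_sd": self.high2_two_way[1],
            "fifty_way": self.fifty_way[0],
            "fifty_way_sd": self.fifty_way[1],
        }


def _mean_sd(x) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    return float(x.mean()), float(x.std())


def evaluate_images(recon: np.ndarray, truth: np.ndarray,
                    labels: np.ndarray, extractors: dict, seed: int,
                    n_ways: int = 50, n_way_trials: int = 50) -> MetricReport:
    """Score a set of reconstructions (one per test item) against truth."""
    if len(recon) == 0:
        raise ValueError("empty test set")
    rng = substream(seed, "metrics")
    ssims = [ssim(r, t) for r, t in zip(recon, truth)]
    rows = {}
    for key in ("low", "high1", "high2"):
        ex = extractors[key]
        rf = extract_features(ex, recon)
        tf = extract_features(ex, truth)
        rows[key] = two_way_batch(rf, tf, rng, n_way_trials)
    scores = extractors["classifier"].predict_scores(recon)
    n_classes = scores.shape[1]
    fw = []
    for i, label in enumerate(labels):
        others = np.delete(np.arange(n_classes), label)
        cand = np.concatenate(
            [[label], rng.choice(others, size=n_ways - 1, replace=False)])
        fw.append(float(cand[np.argmax(scores[i][cand])] == label))
    return MetricReport(
        ssim=_mean_sd(ssims),
        low_two_way=_mean_sd(rows["low"]),
        high1_two_way=_mean_sd(rows["high1"]),
        high2_two_way=_mean_sd(rows["high2"]),
        fifty_way=_mean_sd(fw),
    )


def evaluate(decoder, test_samples: list, extractors: dict,
             n_samples_per_item: int = 4, seed: int = 0,
             guidance: float | None = None,
             n_ways: int = 50) -> MetricReport:
    """Decode each test fMRI `n_samples_per_item` times; score every
    generated sample, average per item, and report mean +- sd over items."""
    if not test_samples:
        raise ValueError("empty test set")
    truth = np.stack([s.image for s in test_samples]).astype(np.float32)
    labels = np.array([s.category_index for s in test_samples])
    fmri = np.stack([s.fmri for s in test_samples])
    gen = decoder.decode(fmri, n_samples=n_samples_per_item,
                         guidance=guidance, seed=substream_seed_int(seed))
    n = len(test_samples)
    keys = ("ssim", "low_two_way", "high1_two_way", "high2_two_way",
            "fifty_way")
    acc = {key: np.zeros(n) for key in keys}
    rng = substream(seed, "metrics")
    truth_feats = {k: extractors[k](truth) for k in ("low", "high1", "high2")}
    n_classes = len(extractors["classifier"].fc_out.bias.data)
    for k in range(n_samples_per_item):
        recon = gen[:, k]
        acc["ssim"] += [ssim(r, t) for r, t in zip(recon, truth)]
        for fk, mk in (("low", "low_two_way"), ("high1", "high1_two_way"),
                       ("high2", "high2_two_way")):
            rf = extractors[fk](recon)
            acc[mk] += two_way_batch(rf, truth_feats[fk], rng, n - 1)
        scores = extractors["classifier"].predict_scores(recon)
        for i, label in enumerate(labels):
            others = np.delete(np.arange(n_classes), label)
            cand = np.concatenate(
                [[label],
                 rng.choice(others, size=n_ways - 1, replace=False)])
            acc["fifty_way"][i] += float(
                cand[np.argmax(scores[i][cand])] == label)
    per_item = {key: val / n_samples_per_item for key, val in acc.items()}
    return MetricReport(
        **{key: _mean_sd(per_item[key]) for key in keys},
        per_item=per_item,
    )


def substream_seed_int(seed: int) -> int:
    return int(substream(seed, "decode").integers(0, 2**31 - 1))
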