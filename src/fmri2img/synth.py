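"""Synthetic paired image–fMRI worlds with ROI-structured responses.

The generator emulates the statistical structure that visual decoding
assumes: each cortical region of interest (ROI) responds, through a fixed
linear readout, to a distinct family of image features —

* **EVC** (early visual cortex): low-level features — mean colour and
  oriented gradient energies,
* **LOC** (lateral occipital complex): object-shape statistics of the
  foreground mask (area, centroid, moments),
* **OPA / PPA / RSC** (scene regions): layout statistics of a low-passed
  version of the image (column profiles, row profiles, coarse global
  structure respectively),

plus i.i.d. Gaussian voxel noise.  Images are deterministic category
renderings (background hue, horizon layout, object shape/colour/size,
background texture orientation) with per-sample jitter, so both low-level
and categorical information is decodable.

The feature families are built so that EVC features are carried exclusively
by high-spatial-frequency content: a period-2 texture change leaves the 2x2
low-pass image, the foreground mask and the mean colour untouched, hence
perturbs only EVC voxels.
"""

from __future__ import annotations

import colorsys
import math
from dataclasses import dataclass, field

import h5py
import numpy as np
from skimage.transform import resize as _sk_resize

DEFAULT_ROI_TABLE: tuple[tuple[str, int], ...] = (
    ("EVC", 500),
    ("LOC", 400),
    ("OPA", 280),
    ("PPA", 305),
    ("RSC", 200),
)
# total 1685 voxels, mirroring the five-ROI target set; padded to 1696 for
# patch size 16.


# ---------------------------------------------------------------------------
# feature maps
# ---------------------------------------------------------------------------

def _gray(image: np.ndarray) -> np.ndarray:
    return image.mean(axis=2)


def _lowpass(image: np.ndarray) -> np.ndarray:
    """2x2 block-mean of the grayscale image (exactly cancels period-2 texture)."""
    g = _gray(image)
    H, W = g.shape
    return g.reshape(H // 2, 2, W // 2, 2).mean(axis=(1, 3))


def _mask(image: np.ndarray, thresh: float = 0.25) -> np.ndarray:
    g = _gray(image)
    return np.abs(g - np.median(g)) > thresh


def evc_features(image: np.ndarray) -> np.ndarray:
    """Low-level: mean RGB + 4 oriented finite-difference energies."""
    g = _gray(image)
    dx = g[:, 1:] - g[:, :-1]
    dy = g[1:, :] - g[:-1, :]
    d1 = g[1:, 1:] - g[:-1, :-1]
    d2 = g[1:, :-1] - g[:-1, 1:]
    return np.array([
        image[..., 0].mean(), image[..., 1].mean(), image[..., 2].mean(),
        (dx ** 2).mean(), (dy ** 2).mean(), (d1 ** 2).mean(), (d2 ** 2).mean(),
    ])


def loc_features(image: np.ndarray) -> np.ndarray:
    """Object shape: moments of the foreground mask."""
    m = _mask(image)
    n = m.sum()
    H, W = m.shape
    if n == 0:
        return np.zeros(8)
    ys, xs = np.nonzero(m)
    cy, cx = ys.mean() / H, xs.mean() / W
    sy, sx = ys.std() / H, xs.std() / W
    cov = ((ys / H - cy) * (xs / W - cx)).mean()
    dmx = np.abs(np.diff(m.astype(float), axis=1)).mean()
    dmy = np.abs(np.diff(m.astype(float), axis=0)).mean()
    return np.array([n / m.size, cx, cy, sx, sy, cov, dmx, dmy])


def _cosine_proj(profile: np.ndarray, n_coef: int) -> np.ndarray:
    n = profile.size
    t = (np.arange(n) + 0.5) / n
    basis = np.cos(np.pi * np.outer(np.arange(1, n_coef + 1), t))
    return basis @ profile / n


def opa_features(image: np.ndarray) -> np.ndarray:
    """Scene layout, horizontal organisation: column-profile cosine coefficients."""
    return _cosine_proj(_lowpass(image).mean(axis=0), 6)


def ppa_features(image: np.ndarray) -> np.ndarray:
    """Scene layout, vertical organisation (horizon): row-profile coefficients."""
    return _cosine_proj(_lowpass(image).mean(axis=1), 6)


def rsc_features(image: np.ndarray) -> np.ndarray:
    """Coarse global scene statistics."""
    L = _lowpass(image)
    h, w = L.shape
    top, bot = L[: h // 2].mean(), L[h // 2:].mean()
    left, right = L[:, : w // 2].mean(), L[:, w // 2:].mean()
    cen = L[h // 4: 3 * h // 4, w // 4: 3 * w // 4].mean()
    quads = [L[: h // 2, : w // 2].mean(), L[: h // 2, w // 2:].mean(),
             L[h // 2:, : w // 2].mean(), L[h // 2:, w // 2:].mean()]
    return np.array([L.mean(), top - bot, left - right, cen - L.mean(), *quads])


DEFAULT_FEATURE_MAPS = {
    "EVC": evc_features,
    "LOC": loc_features,
    "OPA": opa_features,
    "PPA": ppa_features,
    "RSC": rsc_features,
}


# ---------------------------------------------------------------------------
# world / sample containers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorld:
    """Fixed generative description of a paired image–fMRI universe."""

    roi_table: tuple[tuple[str, int], ...] = DEFAULT_ROI_TABLE
    categories: tuple[str, ...] = tuple(f"cat{i:02d}" for i in range(60))
    image_size: int = 64
    noise_sd: float = 0.2
    readout_seed: int = 314159
    feature_maps: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_MAPS))

    def __post_init__(self):
        if set(n for n, _ in self.roi_table) != set(self.feature_maps):
            raise ValueError("roi_table names must match feature_maps keys")
        if self.image_size % 4:
            raise ValueError("image_size must be a multiple of 4")
        self._readouts = {}
        rng = np.random.default_rng(self.readout_seed)
        probe = np.zeros((self.image_size, self.image_size, 3))
        for name, n_vox in self.roi_table:
            dim = self.feature_maps[name](probe).size
            self._readouts[name] = (
                rng.standard_normal((n_vox, dim)) / math.sqrt(dim))
        self._calibrate_features(rng)

    def _calibrate_features(self, rng: np.random.Generator):
        """Fix per-feature affine standardization constants from a probe
        ensemble of this world's own categories, so every ROI's response has
        roughly unit variance across stimuli and `noise_sd` reads as a
        relative noise level (SNR ~ 1/noise_sd)."""
        n_probe = min(64, 2 * len(self.categories))
        cats = rng.integers(0, len(self.categories), size=n_probe)
        feats = {name: [] for name in self.feature_maps}
        for c in cats:
            img = make_image(int(c), rng, self)
            for name, fn in self.feature_maps.items():
                feats[name].append(fn(img))
        self._feat_mean, self._feat_sd = {}, {}
        for name, rows in feats.items():
            arr = np.stack(rows)
            self._feat_mean[name] = arr.mean(axis=0)
            sd = arr.std(axis=0)
            sd[sd < 1e-8] = 1.0
            self._feat_sd[name] = sd

    def standardized_features(self, name: str, image: np.ndarray) -> np.ndarray:
        raw = self.feature_maps[name](image)
        return (raw - self._feat_mean[name]) / self._feat_sd[name]

    @property
    def n_voxels(self) -> int:
        return sum(n for _, n in self.roi_table)

    @property
    def roi_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.roi_table)

    def roi_slice(self, name: str) -> slice:
        off = 0
        for n, cnt in self.roi_table:
            if n == name:
                return slice(off, off + cnt)
            off += cnt
        raise KeyError(f"unknown ROI {name!r}; known: {self.roi_names}")

    def to_dict(self) -> dict:
        return {
            "roi_table": [[n, int(c)] for n, c in self.roi_table],
            "categories": list(self.categories),
            "image_size": int(self.image_size),
            "noise_sd": float(self.noise_sd),
            "readout_seed": int(self.readout_seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticWorld":
        return cls(
            roi_table=tuple((n, int(c)) for n, c in d["roi_table"]),
            categories=tuple(d["categories"]),
            image_size=int(d["image_size"]),
            noise_sd=float(d["noise_sd"]),
            readout_seed=int(d["readout_seed"]),
        )


@dataclass
class PairedSample:
    """One (image, fMRI, category, split) record — the unit of training."""

    image: np.ndarray          # H x W x 3 in [0, 1]
    fmri: np.ndarray           # length-V, pre-padding
    category: str
    category_index: int
    split: str                 # train | val | test


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

_SHAPES = ("disc", "square", "triangle", "cross", "ring")


def _category_recipe(index: int, n_categories: int) -> dict:
    """Deterministic rendering attributes for one category."""
    hue = (index * 0.618034) % 1.0
    return {
        "bg_hue": hue,
        "bg_val": 0.40 + 0.15 * ((index // 7) % 3),
        "horizon": 0.25 + 0.5 * ((index // 5) % 4) / 3.0,
        "shape": _SHAPES[index % len(_SHAPES)],
        "obj_hue": (hue + 0.45 + 0.08 * ((index // 3) % 3)) % 1.0,
        "obj_frac": 0.18 + 0.07 * ((index // 4) % 3),
        "tex_orient": (index % 4) * 45.0,
        "tex_amp": 0.10 + 0.05 * ((index // 2) % 2),
    }


def make_image(category: str | int, rng: np.random.Generator,
               world: SyntheticWorld | None = None) -> np.ndarray:
    """Render one category image with per-sample position/phase jitter.

    Deterministic given (category, rng state).  Raises ``KeyError`` for a
    category not in the world's list.
    """
    world = world or SyntheticWorld()
    if isinstance(category, (int, np.integer)):
        if not 0 <= category < len(world.categories):
            raise KeyError(f"unknown category index {category}")
        idx = int(category)
    else:
        if category not in world.categories:
            raise KeyError(f"unknown category {category!r}")
        idx = world.categories.index(category)
    r = _category_recipe(idx, len(world.categories))
    S = world.image_size

    sky = np.array(colorsys.hsv_to_rgb(r["bg_hue"], 0.35,
                                       min(1.0, r["bg_val"] * 1.45)))
    ground = np.array(colorsys.hsv_to_rgb(r["bg_hue"], 0.45,
                                          r["bg_val"] * 0.62))
    obj_col = np.array(colorsys.hsv_to_rgb(r["obj_hue"], 0.9, 1.0))

    img = np.empty((S, S, 3))
    hline = int(r["horizon"] * S)
    img[:hline] = sky
    img[hline:] = ground

    # oriented stripe texture on the ground region (period 4 px)
    yy, xx = np.mgrid[0:S, 0:S].astype(float)
    th = math.radians(r["tex_orient"])
    phase = rng.uniform(0, 2 * math.pi)
    stripes = np.sin(2 * math.pi * (xx * math.cos(th) + yy * math.sin(th)) / 4.0
                     + phase)
    tex = r["tex_amp"] * stripes
    img[hline:] = np.clip(img[hline:] + tex[hline:, :, None], 0.0, 1.0)

    # object
    size = r["obj_frac"] * S
    jit = 0.08 * S
    cx = S / 2 + rng.uniform(-jit, jit)
    cy = S * (0.35 + 0.4 * r["horizon"] / 0.75) / 1.4 + rng.uniform(-jit, jit)
    dx, dy = xx - cx, yy - cy
    shape = r["shape"]
    if shape == "disc":
        m = dx ** 2 + dy ** 2 <= size ** 2
    elif shape == "square":
        m = (np.abs(dx) <= size) & (np.abs(dy) <= size * 0.85)
    elif shape == "triangle":
        m = (dy >= -size) & (dy <= size) & (np.abs(dx) <= (dy + size) * 0.6)
    elif shape == "cross":
        m = ((np.abs(dx) <= size * 0.35) & (np.abs(dy) <= size)) | \
            ((np.abs(dy) <= size * 0.35) & (np.abs(dx) <= size))
    else:  # ring
        rr = dx ** 2 + dy ** 2
        m = (rr <= size ** 2) & (rr >= (0.55 * size) ** 2)
    img[m] = obj_col
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# fMRI encoding
# ---------------------------------------------------------------------------

def encode_to_fmri(image: np.ndarray, world: SyntheticWorld,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulated voxel responses: per-ROI linear feature readout + noise.

    With ``world.noise_sd == 0`` the map is deterministic.
    """
    S = world.image_size
    if image.shape != (S, S, 3):
        raise ValueError(
            f"image shape {image.shape} does not match world size ({S},{S},3)")
    parts = []
    for name, n_vox in world.roi_table:
        feats = world.standardized_features(name, image)
        resp = world._readouts[name] @ feats
        if world.noise_sd > 0:
            if rng is None:
                raise ValueError("rng required when noise_sd > 0")
            resp = resp + world.noise_sd * rng.standard_normal(n_vox)
        parts.append(resp)
    return np.concatenate(parts).astype(np.float32)


# ---------------------------------------------------------------------------
# padding / augmentation
# ---------------------------------------------------------------------------

def pad_to_patch_multiple(vector: np.ndarray, patch_size: int,
                          pad_value: float = 0.0) -> np.ndarray:
    """Pad a 1-D vector up to the next multiple of ``patch_size``.

    E.g. 4183 -> 4192 and 1685 -> 1696 at patch size 16.  Idempotent when
    already aligned; padding appends ``pad_value`` (default 0, which after
    per-voxel z-scoring sits at the data mean).
    """
    vector = np.asarray(vector)
    if vector.ndim != 1:
        raise ValueError("pad_to_patch_multiple expects a 1-D vector")
    if patch_size <= 0:
        raise ValueError(f"patch_size must be positive, got {patch_size}")
    target = int(math.ceil(vector.size / patch_size)) * patch_size
    if target == vector.size:
        return vector.copy()
    out = np.full(target, pad_value, dtype=vector.dtype)
    out[: vector.size] = vector
    return out


def augment(image: np.ndarray, mode: str, rng: np.random.Generator,
            out_size: int | None = None,
            crop_scale: tuple[float, float] = (0.8, 1.0)) -> np.ndarray:
    """Random square crop + resize, the stage-1/2/3 image augmentation."""
    if mode not in ("stage12", "stage3"):
        raise ValueError(f"mode must be stage12|stage3, got {mode!r}")
    H, W, _ = image.shape
    out_size = out_size or H
    s = rng.uniform(*crop_scale)
    side = int(round(s * min(H, W)))
    if side > min(H, W) or side < 1:
        raise ValueError(f"crop side {side} invalid for image {H}x{W}")
    y0 = rng.integers(0, H - side + 1)
    x0 = rng.integers(0, W - side + 1)
    crop = image[y0: y0 + side, x0: x0 + side]
    if side == out_size:
        return crop.copy()
    return _sk_resize(crop, (out_size, out_size, 3), order=1,
                      anti_aliasing=False, preserve_range=True)


def voxel_dropout(fmri: np.ndarray, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Zero a uniformly chosen round(rate * V) subset of voxels (stage 3)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    V = fmri.size
    k = int(round(rate * V))
    out = fmri.copy()
    if k:
        idx = rng.choice(V, size=k, replace=False)
        out[idx] = 0.0
    return out


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def make_dataset(n_samples: int, world: SyntheticWorld,
                 split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                 seed: int = 0) -> list[PairedSample]:
    """Generate a balanced, reproducible paired dataset.

    Categories are balanced globally within +-1 sample and within each split
    via per-category largest-remainder allocation.
    """
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    C = len(world.categories)
    if n_samples < C:
        raise ValueError(
            f"n_samples={n_samples} < number of categories ({C})")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_samples, C)
    k_per_cat = np.array([base + (1 if ci < extra else 0) for ci in range(C)])

    # split quotas by largest remainder on n * fraction
    raw = [f * n_samples for f in split_fractions]
    quotas = [int(f) for f in raw]
    order = sorted(range(3), key=lambda i: raw[i] - quotas[i], reverse=True)
    for i in order[: n_samples - sum(quotas)]:
        quotas[i] += 1

    # distribute each split's quota across categories as evenly as the
    # remaining per-category capacity allows (keeps balance within +-1)
    split_names = ("train", "val", "test")
    remaining = k_per_cat.copy()
    alloc = np.zeros((C, 3), dtype=int)
    for si in range(3):
        q = quotas[si]
        give = np.minimum(q // C, remaining)
        left = q - int(give.sum())
        remaining_after = remaining - give
        # hand out the leftover one at a time to categories with most capacity
        pri = np.lexsort((np.arange(C), -remaining_after))
        j = 0
        while left > 0:
            c = pri[j % C]
            if remaining_after[c] > 0:
                give[c] += 1
                remaining_after[c] -= 1
                left -= 1
            j += 1
        alloc[:, si] = give
        remaining = remaining_after

    samples: list[PairedSample] = []
    for ci, cat in enumerate(world.categories):
        assignment = [s for s, c in zip(split_names, alloc[ci]) for _ in range(c)]
        for split in assignment:
            img = make_image(cat, rng, world)
            fmri = encode_to_fmri(img, world, rng)
            samples.append(PairedSample(
                image=img.astype(np.float32), fmri=fmri,
                category=cat, category_index=ci, split=split))
    perm = rng.permutation(len(samples))
    return [samples[i] for i in perm]


def split_of(samples: list[PairedSample], split: str) -> list[PairedSample]:
    return [s for s in samples if s.split == split]


class FmriNormalizer:
    """Per-voxel z-scoring with training-split statistics."""

    def __init__(self, mean: np.ndarray, sd: np.ndarray):
        self.mean = mean.astype(np.float32)
        self.sd = sd.astype(np.float32)

    @classmethod
    def fit(cls, train_fmri: np.ndarray) -> "FmriNormalizer":
        mean = train_fmri.mean(axis=0)
        sd = train_fmri.std(axis=0)
        sd[sd < 1e-8] = 1.0
        return cls(mean, sd)

    def transform(self, fmri: np.ndarray) -> np.ndarray:
        return ((fmri - self.mean) / self.sd).astype(np.float32)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_SPLIT_CODE = {"train": 0, "val": 1, "test": 2}
_SPLIT_NAME = {v: k for k, v in _SPLIT_CODE.items()}


def save_dataset(samples: list[PairedSample], world: SyntheticWorld,
                 path: str) -> None:
    """HDF5 layout: /images, /fmri, /labels, /splits (+ world manifest attrs).

    Written with ``track_times=False`` so identical data gives byte-identical
    files.
    """
    import yaml

    with h5py.File(path, "w", track_order=True) as f:
        kw = dict(track_times=False)
        f.create_dataset("images",
                         data=np.stack([s.image for s in samples]), **kw)
        f.create_dataset("fmri",
                         data=np.stack([s.fmri for s in samples]), **kw)
        f.create_dataset("labels",
                         data=np.array([s.category_index for s in samples],
                                       dtype=np.int32), **kw)
        f.create_dataset("splits",
                         data=np.array([_SPLIT_CODE[s.split] for s in samples],
                                       dtype=np.int8), **kw)
        f.attrs["world"] = yaml.safe_dump(world.to_dict())


def load_dataset(path: str) -> tuple[list[PairedSample], SyntheticWorld]:
    import yaml

    with h5py.File(path, "r") as f:
        world = SyntheticWorld.from_dict(yaml.safe_load(f.attrs["world"]))
        images = f["images"][:]
        fmri = f["fmri"][:]
        labels = f["labels"][:]
        splits = f["splits"][:]
    samples = [PairedSample(
        image=images[i], fmri=fmri[i],
        category=world.categories[labels[i]],
        category_index=int(labels[i]),
        split=_SPLIT_NAME[int(splits[i])]) for i in range(len(labels))]
    return samples, world


def export_png(samples: list[PairedSample], out_dir: str,
               limit: int = 16) -> list[str]:
    """Write the first `limit` images as PNGs for visual inspection."""
    import os

    from PIL import Image

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, s in enumerate(samples[:limit]):
        p = os.path.join(out_dir, f"{i:03d}_{s.category}_{s.split}.png")
        Image.fromarray((s.image * 255).astype(np.uint8)).save(p)
        paths.append(p)
    return paths
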