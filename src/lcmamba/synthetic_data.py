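"""Deterministic liver-phantom generator and the augmentation pipeline.

The generator emulates the phenomenology a 2-D liver-lesion segmenter is
trained on, without any pretence of CT/MR physics: an elliptical organ with
band-limited parenchymal texture on a dark background, elliptical lesions
of controlled equivalent diameter and intensity contrast placed fully
inside the organ, optional hypointense (necrotic) cores, smooth sigmoid
margins, and additive Gaussian noise.  The binary mask is the union of
lesion supports at half-maximum, so the measured equivalent diameter of a
generated lesion tracks the requested one.

All randomness flows from explicit integer seeds; item ``i`` of a dataset
uses ``seed ^ i`` so regeneration is order-independent.  Intensities live
in [0, 1] and are written as 8-bit PNG (with a JSON spacing sidecar) or
float32 NIfTI (spacing in the header).
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import io as lcio


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomConfig:
    image_size: tuple[int, int] = (64, 64)
    spacing_mm: float = 1.0
    n_lesions: int = 1
    diameter_range_mm: tuple[float, float] = (10.0, 26.0)
    lesion_contrast: float = 0.35
    necrotic_core_prob: float = 0.0
    noise_sd: float = 0.05
    texture_scale: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.diameter_range_mm[0] <= 0 or self.diameter_range_mm[1] < self.diameter_range_mm[0]:
            raise ConfigError("diameter range must be positive and ordered")
        if self.spacing_mm <= 0:
            raise ConfigError("spacing must be positive")
        if not (0 <= self.necrotic_core_prob <= 1):
            raise ConfigError("necrotic_core_prob must be in [0, 1]")
        max_d_px = self.diameter_range_mm[1] / self.spacing_mm
        if max_d_px >= 0.7 * min(self.image_size):
            raise ConfigError(
                f"lesion diameter up to {max_d_px:.0f} px does not fit the "
                f"{self.image_size} organ"
            )


BACKGROUND = 0.15
PARENCHYMA = 0.50
TEXTURE_AMP = 0.06


def _organ_support(H: int, W: int, rng: np.random.Generator) -> np.ndarray:
    cy, cx = H / 2 + rng.uniform(-0.02, 0.02) * H, W / 2 + rng.uniform(-0.02, 0.02) * W
    ay, ax = 0.40 * H * rng.uniform(0.95, 1.05), 0.44 * W * rng.uniform(0.95, 1.05)
    yy, xx = np.mgrid[0:H, 0:W]
    rho = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    return rho <= 1.0


def _lesion_field(H: int, W: int, cy: float, cx: float, r_px: float,
                  theta: float, ratio: float) -> np.ndarray:
    """Normalised elliptical radius field (1.0 on the nominal contour)."""
    yy, xx = np.mgrid[0:H, 0:W]
    dy, dx = yy - cy, xx - cx
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    a = r_px * np.sqrt(ratio)
    b = r_px / np.sqrt(ratio)
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def generate_phantom(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray, float]:
    """One phantom slice: (image in [0,1], binary mask, spacing in mm)."""
    H, W = cfg.image_size
    rng = np.random.default_rng(cfg.seed)
    organ = _organ_support(H, W, rng)

    texture = ndimage.gaussian_filter(rng.standard_normal((H, W)), cfg.texture_scale)
    tsd = texture.std() or 1.0
    image = np.full((H, W), BACKGROUND)
    image[organ] = PARENCHYMA + TEXTURE_AMP * (texture[organ] / tsd)

    # lesions must sit fully inside the organ, >= 2 px from its border
    mask = np.zeros((H, W), dtype=np.uint8)
    for _ in range(cfg.n_lesions):
        d_mm = rng.uniform(*cfg.diameter_range_mm)
        r_px = 0.5 * d_mm / cfg.spacing_mm
        margin = int(np.ceil(r_px)) + 2
        allowed = ndimage.binary_erosion(organ, iterations=margin) if margin else organ
        if not allowed.any():
            raise ConfigError("lesion diameter exceeds the organ size")
        ys, xs = np.nonzero(allowed)
        for _try in range(50):
            k = rng.integers(len(ys))
            cy, cx = float(ys[k]), float(xs[k])
            field = _lesion_field(H, W, cy, cx, r_px,
                                  rng.uniform(0, np.pi), rng.uniform(0.8, 1.25))
            support = field <= 1.0
            if not (support & (mask > 0)).any():
                break
        edge = max(1.0 / r_px, 0.08)  # sigmoid margin width in rho units
        profile = 1.0 / (1.0 + np.exp((field - 1.0) / edge))
        image += cfg.lesion_contrast * profile
        if rng.uniform() < cfg.necrotic_core_prob:
            core = 1.0 / (1.0 + np.exp((field / 0.45 - 1.0) / edge))
            image -= 0.6 * cfg.lesion_contrast * core
        mask[support] = 1

    if cfg.noise_sd:
        image = image + cfg.noise_sd * rng.standard_normal((H, W))
    return np.clip(image, 0.0, 1.0), mask, cfg.spacing_mm


# ---------------------------------------------------------------------------
# Augmentation (rotation +-15 degrees, horizontal/vertical flips)
# ---------------------------------------------------------------------------

MAX_ROTATION_DEG = 15.0


def sample_transform(seed: int) -> tuple[float, bool, bool]:
    """Draw (rotation angle in degrees, horizontal flip, vertical flip)."""
    rng = np.random.default_rng(seed)
    angle = rng.uniform(-MAX_ROTATION_DEG, MAX_ROTATION_DEG)
    return float(angle), bool(rng.uniform() < 0.5), bool(rng.uniform() < 0.5)


def augment(image: np.ndarray, mask: np.ndarray, seed: int,
            rotate: bool = True, flips: bool = True,
            out_size: tuple[int, int] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Jointly transform an image/mask pair.

    Rotation angle is uniform in [-15, +15] degrees (bilinear for the image,
    nearest-neighbour for the mask, so the mask stays binary); horizontal
    and vertical flips each fire with probability 1/2; an optional resize is
    applied last."""
    angle, hflip, vflip = sample_transform(seed)
    img, msk = np.asarray(image, dtype=float), np.asarray(mask)
    if rotate:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        msk = ndimage.rotate(msk, angle, reshape=False, order=0, mode="nearest")
    if flips:
        if hflip:
            img, msk = img[:, ::-1], msk[:, ::-1]
        if vflip:
            img, msk = img[::-1, :], msk[::-1, :]
    if out_size is not None and tuple(out_size) != img.shape:
        img = lcio.resize_image(img, out_size)
        msk = lcio.resize_mask(msk, out_size)
    return np.clip(np.ascontiguousarray(img), 0.0, 1.0), \
        np.ascontiguousarray(msk).astype(np.uint8)


AUGMENT_PRESETS = {
    "none": dict(rotate=False, flips=False),
    "basic": dict(rotate=False, flips=True),
    "full": dict(rotate=True, flips=True),
}


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder rounding of split fractions to integer sizes."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError("split fractions must sum to 1")
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    rem = n - sum(sizes)
    order = np.argsort([s - r for s, r in zip(sizes, raw)])  # largest remainder first
    for i in range(rem):
        sizes[order[i]] += 1
    if any(s == 0 for s in sizes):
        raise ConfigError(f"split {fractions} of n={n} leaves an empty subset")
    return tuple(sizes)


def generate_arrays(n_slices: int, cfg: PhantomConfig):
    """In-memory dataset: list of (image, mask, spacing); item i seeds seed^i."""
    out = []
    for i in range(n_slices):
        img, msk, sp = generate_phantom(replace(cfg, seed=cfg.seed ^ i))
        out.append((img, msk, sp))
    return out


def generate_dataset(n_slices: int, split: tuple[float, float, float],
                     cfg: PhantomConfig, out_dir, fmt: str = "png",
                     split_seed: int = 42) -> dict:
    """Write a phantom dataset and its manifest.

    Slices are assigned to train/val/test by shuffling indices with the
    fixed split seed (default 42) and cutting at the largest-remainder
    sizes; per-item phantom seeds are ``cfg.seed ^ i`` so any file can be
    regenerated independently."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    sizes = split_sizes(n_slices, split)
    order = np.random.default_rng(split_seed).permutation(n_slices)
    split_of = {}
    start = 0
    for name, size in zip(("train", "val", "test"), sizes):
        for idx in order[start:start + size]:
            split_of[int(idx)] = name
        start += size

    entries = []
    for i in range(n_slices):
        img, msk, sp = generate_phantom(replace(cfg, seed=cfg.seed ^ i))
        ext = "png" if fmt == "png" else "nii"
        img_path = out_dir / "images" / f"slice_{i:04d}.{ext}"
        msk_path = out_dir / "masks" / f"slice_{i:04d}.{ext}"
        if fmt == "png":
            lcio.write_png(img_path, img, spacing_mm=sp)
            lcio.write_png_mask(msk_path, msk)
        elif fmt == "nifti":
            lcio.write_nifti(img_path, img, spacing_mm=sp)
            lcio.write_nifti(msk_path, msk.astype(np.float32), spacing_mm=sp)
        else:
            raise ConfigError(f"unknown format {fmt!r} (png or nifti)")
        entries.append({
            "id": i, "image": str(img_path.relative_to(out_dir)),
            "mask": str(msk_path.relative_to(out_dir)),
            "spacing_mm": sp, "seed": cfg.seed ^ i, "split": split_of[i],
            "sha256_mask": hashlib.sha256(msk.tobytes()).hexdigest()[:16],
        })

    manifest = {
        "n_slices": n_slices, "split_seed": split_seed, "format": fmt,
        "phantom_config": asdict(cfg), "entries": entries,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
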