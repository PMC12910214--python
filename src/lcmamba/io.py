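"""File I/O: PNG and NIfTI images/masks, spacing sidecars, checkpoints,
configs.  Grayscale images are stored 8-bit in PNG mode and float32 in
NIfTI mode; masks are strict {0, 255} PNGs or {0, 1} NIfTI volumes, and any
other value is rejected on read."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from PIL import Image
from skimage.transform import resize as _sk_resize

logger = logging.getLogger("lcmamba")

DEFAULT_SPACING_MM = 1.0


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PNG
# ---------------------------------------------------------------------------

def write_png(path, image: np.ndarray, spacing_mm: float | None = None) -> None:
    """Write a [0,1] float image as 8-bit grayscale; optional spacing sidecar."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)
    if spacing_mm is not None:
        sidecar(path).write_text(json.dumps({"spacing_mm": float(spacing_mm)}))


def write_png_mask(path, mask: np.ndarray) -> None:
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise FormatError("mask must be binary before writing")
    Image.fromarray((m * 255).astype(np.uint8), mode="L").save(path)


def read_png(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG to floats in [0, 1]."""
    return np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0


def read_png_mask(path) -> np.ndarray:
    """Read a {0, 255} PNG mask to {0, 1}; any other value is an error."""
    arr = np.asarray(Image.open(path).convert("L"))
    bad = np.setdiff1d(np.unique(arr), [0, 255])
    if bad.size:
        raise FormatError(
            f"mask {path} contains values {bad.tolist()}; only 0 and 255 are allowed"
        )
    return (arr == 255).astype(np.uint8)


def sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def read_spacing(path) -> float:
    """Spacing from a PNG sidecar, or the logged 1.0 mm default."""
    sc = sidecar(path)
    if sc.exists():
        return float(json.loads(sc.read_text())["spacing_mm"])
    logger.warning("no spacing sidecar for %s; assuming %.1f mm", path,
                   DEFAULT_SPACING_MM)
    return DEFAULT_SPACING_MM


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def write_nifti(path, image: np.ndarray, spacing_mm: float = 1.0) -> None:
    img = nib.Nifti1Image(np.asarray(image, dtype=np.float32), affine=np.eye(4))
    img.header.set_zooms((float(spacing_mm), float(spacing_mm)))
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    return data, float(img.header.get_zooms()[0])


def read_nifti_mask(path) -> tuple[np.ndarray, float]:
    data, sp = read_nifti(path)
    u = np.unique(data)
    if not np.isin(u, (0.0, 1.0)).all():
        raise FormatError(f"mask {path} contains non-binary values {u[:6].tolist()}")
    return data.astype(np.uint8), sp


def read_image_any(path) -> tuple[np.ndarray, float]:
    path = Path(path)
    if path.suffix == ".png":
        return read_png(path), read_spacing(path)
    if path.suffix in (".nii", ".gz"):
        return read_nifti(path)
    raise FormatError(f"unknown image format {path.suffix!r}; supported: .png, .nii")


def read_mask_any(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".png":
        return read_png_mask(path)
    if path.suffix in (".nii", ".gz"):
        return read_nifti_mask(path)[0]
    raise FormatError(f"unknown mask format {path.suffix!r}; supported: .png, .nii")


# ---------------------------------------------------------------------------
# Resizing
# ---------------------------------------------------------------------------

def resize_image(image: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    return _sk_resize(np.asarray(image, dtype=float), out_size, order=1,
                      anti_aliasing=False, preserve_range=True)


def resize_mask(mask: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    out = _sk_resize(np.asarray(mask, dtype=float), out_size, order=0,
                     anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def to_three_channel(image: np.ndarray) -> np.ndarray:
    """Replicate a grayscale slice to the 3-channel layout the stem expects."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        return np.repeat(img[None], 3, axis=0)
    if img.ndim == 3 and img.shape[0] == 3:
        return img
    raise FormatError(f"expected HxW or 3xHxW image, got shape {img.shape}")


# ---------------------------------------------------------------------------
# Checkpoints and configs
# ---------------------------------------------------------------------------

def save_checkpoint(path, model, config: dict) -> None:
    """Single-file archive: named parameter/buffer arrays + embedded config."""
    state = model.state_dict()
    np.savez(path, __config__=np.frombuffer(
        json.dumps(config).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    try:
        archive = np.load(path, allow_pickle=False)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read checkpoint {path}: {exc}") from exc
    if "__config__" not in archive:
        raise FormatError(f"checkpoint {path} has no embedded config")
    config = json.loads(bytes(archive["__config__"]).decode())
    state = {k: archive[k] for k in archive.files if k != "__config__"}
    return state, config


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    raise FormatError(f"unknown config format {path.suffix!r}; use YAML or JSON")


def save_config(path, config: dict) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    else:
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
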