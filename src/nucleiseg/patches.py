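"""Patch extraction, train/validation splitting and augmentation.

Images are decomposed into 256x256 patches on a structured grid with
spacing equal to the patch size; images smaller than a patch are
zero-padded, and when a dimension is larger but not divisible by the patch
size an extra boundary patch is re-cropped flush with the image edge so the
whole image is covered.  Additional random patches are kept only when the
foreground/background pixel ratio strictly exceeds a threshold (0.4 by
default).  Patches are split 8:2 into training and validation sets.

Augmentation draws photometric transforms (Gaussian/median/average blur,
contrast, saturation and hue jitter) applied to the image only, and
geometric transforms (flips, right-angle rotations) applied identically to
image and mask.  Hue/saturation on a grayscale image go through a
temporary 3-channel copy and return via luminance.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter, uniform_filter
from skimage.color import hsv2rgb, rgb2hsv

__all__ = ["PatchGridConfig", "PatchRecord", "AugmentConfig",
           "grid_patches", "random_patches", "split_train_val", "augment"]


@dataclass
class PatchGridConfig:
    patch_size: int = 256
    grid_dx: int = 256
    grid_dy: int = 256
    fg_ratio_threshold: float = 0.4
    n_random_patches_per_image: int = 4
    split_ratio: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.grid_dx != self.patch_size or self.grid_dy != self.patch_size:
            raise ValueError("grid spacing must equal the patch size")


@dataclass
class PatchRecord:
    source_id: str
    row0: int
    col0: int
    image_patch: np.ndarray
    mask_patch: np.ndarray
    was_padded: bool = False
    origin: str = "grid"  # grid | boundary | random

    def __post_init__(self):
        if self.image_patch.shape != self.mask_patch.shape:
            raise ValueError("image and mask patches must have equal shape")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("patch offsets must be non-negative")


def _axis_offsets(size: int, ps: int) -> tuple[list[int], bool]:
    """Grid offsets along one axis plus whether padding is needed."""
    if size < ps:
        return [0], True
    offsets = list(range(0, size - ps + 1, ps))
    if size % ps:
        offsets.append(size - ps)  # boundary re-crop flush with the edge
    return offsets, False


def grid_patches(image: np.ndarray, mask: np.ndarray,
                 config: PatchGridConfig = PatchGridConfig()) -> list[PatchRecord]:
    """Deterministic grid + boundary decomposition covering every pixel."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.size == 0:
        raise ValueError("cannot extract patches from an empty image")
    if image.shape != mask.shape:
        raise ValueError("image and mask must have the same shape")
    ps = config.patch_size
    h, w = image.shape
    rows, pad_r = _axis_offsets(h, ps)
    cols, pad_c = _axis_offsets(w, ps)
    padded = pad_r or pad_c
    if padded:
        img_p = np.zeros((max(h, ps), max(w, ps)), dtype=image.dtype)
        msk_p = np.zeros((max(h, ps), max(w, ps)), dtype=mask.dtype)
        img_p[:h, :w] = image
        msk_p[:h, :w] = mask
        image, mask = img_p, msk_p
    out = []
    for r in rows:
        for c in cols:
            on_grid = (r % ps == 0) and (c % ps == 0)
            out.append(PatchRecord(
                source_id="", row0=r, col0=c,
                image_patch=image[r:r + ps, c:c + ps].copy(),
                mask_patch=(mask[r:r + ps, c:c + ps] > 0).astype(np.uint8),
                was_padded=padded,
                origin="grid" if on_grid else "boundary"))
    return out


def _patch_rng(config: PatchGridConfig, source_id: str) -> np.random.Generator:
    tag = zlib.crc32(source_id.encode())
    return np.random.default_rng(np.random.SeedSequence((config.seed, tag)))


def random_patches(image: np.ndarray, mask: np.ndarray,
                   config: PatchGridConfig = PatchGridConfig(),
                   source_id: str = "") -> list[PatchRecord]:
    """Random patches whose fg/bg pixel ratio strictly exceeds the threshold."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    ps = config.patch_size
    h, w = image.shape
    if h < ps or w < ps:
        return []
    rng = _patch_rng(config, source_id)
    n_target = config.n_random_patches_per_image
    out = []
    attempts = 0
    while len(out) < n_target and attempts < 50 * max(n_target, 1):
        attempts += 1
        r = int(rng.integers(0, h - ps + 1))
        c = int(rng.integers(0, w - ps + 1))
        mp = (mask[r:r + ps, c:c + ps] > 0).astype(np.uint8)
        fg = int(mp.sum())
        bg = mp.size - fg
        ratio = np.inf if bg == 0 else fg / bg
        if ratio > config.fg_ratio_threshold:  # strictly greater
            out.append(PatchRecord(source_id, r, c,
                                   image[r:r + ps, c:c + ps].copy(), mp,
                                   was_padded=False, origin="random"))
    return out


def split_train_val(patches: list, config: PatchGridConfig = PatchGridConfig()):
    """Random 8:2 split (|train| = round(split_ratio * n)); a partition."""
    if not patches:
        raise ValueError("cannot split an empty patch list")
    n = len(patches)
    n_train = int(np.floor(config.split_ratio * n + 0.5))
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    train = [patches[i] for i in order[:n_train]]
    val = [patches[i] for i in order[n_train:]]
    return train, val


@dataclass
class AugmentConfig:
    p_blur: float = 0.3
    p_contrast: float = 0.3
    p_saturation: float = 0.2
    p_hue: float = 0.2
    p_flip: float = 0.5
    p_rot90: float = 0.5
    blur_sigma_range: tuple[float, float] = (0.5, 1.5)
    contrast_range: tuple[float, float] = (0.7, 1.3)
    saturation_range: tuple[float, float] = (0.7, 1.3)
    hue_shift_range: tuple[float, float] = (-0.05, 0.05)

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(p_blur=0, p_contrast=0, p_saturation=0, p_hue=0,
                   p_flip=0, p_rot90=0)


_LUMA = np.array([0.299, 0.587, 0.114])


def augment_arrays(image: np.ndarray, mask: np.ndarray, rng,
                   config: AugmentConfig = AugmentConfig()):
    """Augment an (image, mask) pair; photometric ops touch the image only."""
    img = np.asarray(image, dtype=float).copy()
    msk = np.asarray(mask).copy()
    # photometric
    if rng.random() < config.p_blur:
        kind = rng.choice(["gaussian", "median", "average"])
        if kind == "gaussian":
            img = gaussian_filter(img, sigma=rng.uniform(*config.blur_sigma_range))
        elif kind == "median":
            img = median_filter(img, size=3)
        else:
            img = uniform_filter(img, size=3)
    if rng.random() < config.p_contrast:
        factor = rng.uniform(*config.contrast_range)
        img = (img - img.mean()) * factor + img.mean()
    do_sat = rng.random() < config.p_saturation
    do_hue = rng.random() < config.p_hue
    if do_sat or do_hue:
        rgb = np.clip(np.stack([img] * 3, axis=-1), 0.0, 1.0)
        hsv = rgb2hsv(rgb)
        if do_sat:
            hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(*config.saturation_range),
                                  0.0, 1.0)
        if do_hue:
            hsv[..., 0] = (hsv[..., 0] + rng.uniform(*config.hue_shift_range)) % 1.0
        img = hsv2rgb(hsv) @ _LUMA  # back to grayscale via luminance
    # geometric, identical for image and mask
    if rng.random() < config.p_flip:
        if rng.random() < 0.5:
            img, msk = img[::-1, :], msk[::-1, :]
        else:
            img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < config.p_rot90:
        k = int(rng.integers(1, 4))
        img, msk = np.rot90(img, k), np.rot90(msk, k)
    return np.ascontiguousarray(np.clip(img, 0.0, 1.0)), np.ascontiguousarray(msk)


def augment(patch: PatchRecord, seed: int,
            aug_config: AugmentConfig = AugmentConfig()) -> PatchRecord:
    """Return an augmented copy of ``patch`` (deterministic under seed)."""
    rng = np.random.default_rng(seed)
    img, msk = augment_arrays(patch.image_patch, patch.mask_patch, rng, aug_config)
    return replace(patch, image_patch=img, mask_patch=msk)
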