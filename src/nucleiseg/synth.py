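"""Synthetic bright/dark-field-like nuclei images with instance ground truth.

The generator emulates the variability that makes real microscopy nuclei
data hard: elliptical nuclei of varying size, orientation and brightness,
a smoothly varying background illumination field, soft (blurred) nucleus
boundaries and additive Gaussian noise.  Every sample is reproducible from
``(config.seed, index)`` alone: one RNG stream per sample.

Images are quantized to 8-bit levels (multiples of 1/255) so that writing
to PNG and reading back is lossless.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse
from skimage.measure import label as _sk_label

__all__ = ["SynthConfig", "PlacementError", "generate_sample", "generate_dataset"]


class PlacementError(RuntimeError):
    """Raised when the requested nuclei cannot be placed in the image."""


@dataclass
class SynthConfig:
    image_height: int = 256
    image_width: int = 256
    n_nuclei_range: tuple[int, int] = (10, 15)
    radius_range: tuple[float, float] = (8.0, 12.0)
    nucleus_intensity_range: tuple[float, float] = (0.55, 0.95)
    background_level: float = 0.15
    illumination_gradient_amplitude: float = 0.2
    noise_sigma: float = 0.02
    allow_touching: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.radius_range[0] < 2:
            raise ValueError("minimum nucleus radius must be >= 2 px")
        for lo, hi in (self.nucleus_intensity_range,):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("intensity range must lie within [0, 1]")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must lie within [0, 1]")
        if not 0.0 <= self.illumination_gradient_amplitude <= 1.0:
            raise ValueError("illumination amplitude must lie within [0, 1]")
        if self.n_nuclei_range[0] > self.n_nuclei_range[1]:
            raise ValueError("n_nuclei_range must be (min, max) with min <= max")


def _sample_rng(config: SynthConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(config.seed), int(index))))


def _place_nuclei(config: SynthConfig, rng) -> np.ndarray:
    h, w = config.image_height, config.image_width
    n = int(rng.integers(config.n_nuclei_range[0], config.n_nuclei_range[1] + 1))
    mask = np.zeros((h, w), dtype=np.int32)
    blocked = np.zeros((h, w), dtype=bool)  # occupied + 1 px separation halo
    placed = 0
    attempts = 0
    max_attempts = 200 * max(n, 1)
    while placed < n:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {n} nuclei of radius "
                f"{config.radius_range} in a {h}x{w} image "
                f"({placed} placed after {max_attempts} attempts)")
        r_major = rng.uniform(*config.radius_range)
        r_minor = r_major * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0.0, np.pi)
        cy = rng.uniform(r_major, h - r_major)
        cx = rng.uniform(r_major, w - r_major)
        rr, cc = ellipse(cy, cx, r_major, r_minor, shape=(h, w), rotation=theta)
        if rr.size == 0:
            continue
        if not config.allow_touching and blocked[rr, cc].any():
            continue
        if config.allow_touching:
            # instances stay disjoint: the newcomer is clipped to free pixels
            free = mask[rr, cc] == 0
            if not free.any():
                continue
            cand = np.zeros((h, w), dtype=bool)
            cand[rr[free], cc[free]] = True
            if _sk_label(cand, connectivity=1).max() != 1:
                continue  # clipping broke 4-connectivity; retry elsewhere
            placed += 1
            mask[cand] = placed
            continue
        placed += 1
        mask[rr, cc] = placed
        if not config.allow_touching:
            # block the footprint plus a 1-px halo so instances stay separated
            blocked[rr, cc] = True
            blocked[np.clip(rr + 1, 0, h - 1), cc] = True
            blocked[np.clip(rr - 1, 0, h - 1), cc] = True
            blocked[rr, np.clip(cc + 1, 0, w - 1)] = True
            blocked[rr, np.clip(cc - 1, 0, w - 1)] = True
    return mask


def generate_sample(config: SynthConfig, index: int):
    """Render one (image, instance mask) pair.

    Returns (image, mask): image float64 in [0, 1] quantized to 8-bit
    levels; mask int32 with background 0 and nuclei labelled 1..K.
    """
    rng = _sample_rng(config, index)
    h, w = config.image_height, config.image_width
    mask = _place_nuclei(config, rng)
    k = int(mask.max())

    yy, xx = np.mgrid[0:h, 0:w]
    yn = yy / max(h - 1, 1) - 0.5
    xn = xx / max(w - 1, 1) - 0.5
    # low-order polynomial illumination field, amplitude-limited
    coef = rng.uniform(-1.0, 1.0, size=4)
    field = coef[0] * yn + coef[1] * xn + coef[2] * yn * xn + coef[3] * (xn ** 2 - yn ** 2)
    span = np.ptp(field)
    if span > 0:
        field = field / span * config.illumination_gradient_amplitude
    img = config.background_level + field - field.min()

    fg = np.zeros((h, w))
    lo, hi = config.nucleus_intensity_range
    for lab in range(1, k + 1):
        fg[mask == lab] = rng.uniform(lo, hi)
    fg = gaussian_filter(fg, sigma=1.0)  # soft, slightly blurred boundaries
    img = np.maximum(img, fg)
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=(h, w))
    img = np.clip(img, 0.0, 1.0)
    img = np.round(img * 255.0) / 255.0  # 8-bit quantization, PNG-lossless
    return img, mask


def _sample_id(config: SynthConfig, index: int) -> str:
    tag = hashlib.sha1(
        f"{config.seed}-{index}-{config.image_height}x{config.image_width}"
        .encode()).hexdigest()[:8]
    return f"synth{index:04d}_{tag}"


def generate_dataset(config: SynthConfig, n_images: int, out_dir) -> list[dict]:
    """Write ``n_images`` samples in the per-sample directory layout.

    Layout per sample: <out_dir>/<id>/images/<id>.png (8-bit grayscale) and
    <out_dir>/<id>/masks/<id>_<k>.png (one binary file per instance).
    Returns the manifest: a list of dicts with id, paths and instance count.
    """
    from pathlib import Path

    out = Path(out_dir)
    manifest = []
    for index in range(int(n_images)):
        img, mask = generate_sample(config, index)
        sid = _sample_id(config, index)
        img_dir = out / sid / "images"
        msk_dir = out / sid / "masks"
        img_dir.mkdir(parents=True, exist_ok=True)
        msk_dir.mkdir(parents=True, exist_ok=True)
        img_path = img_dir / f"{sid}.png"
        iio.imwrite(img_path, np.round(img * 255.0).astype(np.uint8))
        k = int(mask.max())
        mask_paths = []
        for lab in range(1, k + 1):
            p = msk_dir / f"{sid}_{lab:03d}.png"
            iio.imwrite(p, ((mask == lab) * 255).astype(np.uint8))
            mask_paths.append(str(p))
        manifest.append({"sample_id": sid, "image": str(img_path),
                         "masks": mask_paths, "n_instances": k})
    return manifest
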