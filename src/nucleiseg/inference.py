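"""Whole-image prediction: tiling, overlap-max fusion, morphological cleanup.

A test image is preprocessed exactly like the training data, decomposed
into 256x256 patches by the same grid rules (zero-padding small images,
boundary re-crops for indivisible sizes), run through the network, and the
per-patch probability maps are fused back: where boundary re-crops overlap,
each pixel takes the maximum predicted probability.  The map is then
thresholded at 0.5 (strictly greater), small connected components are
removed and small background holes filled, and the surviving foreground is
decomposed into labelled instances.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as sk_label
from skimage.morphology import remove_small_holes, remove_small_objects

from .nn import GraphModel
from .patches import PatchGridConfig, grid_patches
from .preprocess import PreprocConfig, preprocess

__all__ = ["PostprocConfig", "predict_image", "binarize_and_clean",
           "label_instances"]


@dataclass
class PostprocConfig:
    prob_threshold: float = 0.5
    min_object_area: int = 300
    max_hole_area: int = 300

    def __post_init__(self):
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must lie strictly inside (0, 1)")
        if self.min_object_area < 0 or self.max_hole_area < 0:
            raise ValueError("morphology areas must be >= 0")


def predict_image(model, image: np.ndarray,
                  preproc: PreprocConfig | None = PreprocConfig(),
                  grid: PatchGridConfig = PatchGridConfig(),
                  batch_size: int = 4) -> np.ndarray:
    """Probability map for a whole image (same shape as the input).

    ``model`` needs a ``predict(batch) -> probs`` method taking NHWC float
    arrays; pass ``preproc=None`` to skip preprocessing.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("predict_image expects a non-empty 2-D image")
    if preproc is not None:
        image = preprocess(image, preproc).astype(np.float32)
    h, w = image.shape
    ps = grid.patch_size
    records = grid_patches(image, np.zeros_like(image), grid)
    canvas = np.full((max(h, ps), max(w, ps)), -np.inf, dtype=np.float32)
    batch, coords = [], []

    def flush():
        if not batch:
            return
        x = np.stack(batch)[..., None]
        probs = np.asarray(model.predict(x))[..., 0]
        for (r, c), pm in zip(coords, probs):
            region = canvas[r:r + ps, c:c + ps]
            np.maximum(region, pm, out=region)  # overlap-max fusion
        batch.clear()
        coords.clear()

    for rec in records:
        batch.append(rec.image_patch)
        coords.append((rec.row0, rec.col0))
        if len(batch) >= batch_size:
            flush()
    flush()
    return np.asarray(canvas[:h, :w], dtype=np.float64)


def binarize_and_clean(prob: np.ndarray,
                       config: PostprocConfig = PostprocConfig()) -> np.ndarray:
    """Threshold strictly above prob_threshold, then morphological cleanup.

    Foreground components with area < min_object_area are removed
    (8-connected); background holes with area < max_hole_area are filled
    (holes are 4-connected).
    """
    prob = np.asarray(prob)
    if (prob < 0).any() or (prob > 1).any():
        raise ValueError("probability map values must lie in [0, 1]")
    mask = prob > config.prob_threshold
    if config.min_object_area > 0:
        # max_size removes areas <= its value; the filter is strict (< area)
        mask = remove_small_objects(mask, max_size=config.min_object_area - 1,
                                    connectivity=2)
    if config.max_hole_area > 0:
        mask = remove_small_holes(mask, max_size=config.max_hole_area - 1,
                                  connectivity=1)
    return mask.astype(np.uint8)


def label_instances(mask: np.ndarray) -> np.ndarray:
    """8-connected component labelling; labels contiguous 1..K."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("label_instances expects a binary mask")
    return sk_label(mask, connectivity=2).astype(np.int32)
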