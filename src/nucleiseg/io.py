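"""Dataset reading/writing: per-sample directory layout and run-length masks.

The directory layout is the one used by the 2018 Data Science Bowl stage-1
release: one directory per sample containing ``images/<id>.png`` and
``masks/<id>_*.png`` with one binary file per nucleus instance.  Run-length
encoding follows the Kaggle dialect: pixels are numbered **column-major**
(top to bottom, then left to right), starting at 1, and a mask is a list of
``(start, length)`` runs.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord", "RleMask", "DatasetError",
    "load_dataset", "rle_decode", "rle_encode",
    "read_rle_csv", "write_rle_csv",
]


class DatasetError(ValueError):
    """Malformed dataset contents (overlapping instances, bad runs, ...)."""


@dataclass
class SampleRecord:
    sample_id: str
    image: np.ndarray      # 2-D float in [0, 1]
    instances: np.ndarray  # 2-D int, 0 = background, 1..K = nuclei

    def __post_init__(self):
        if self.image.shape != self.instances.shape:
            raise DatasetError(
                f"{self.sample_id}: image {self.image.shape} and instance "
                f"mask {self.instances.shape} shapes differ")


@dataclass
class RleMask:
    sample_id: str
    height: int
    width: int
    runs: list  # [(start, length)], 1-based column-major starts

    def __post_init__(self):
        prev_end = 0
        for start, length in self.runs:
            if start <= prev_end:
                raise DatasetError(
                    f"{self.sample_id}: runs must be sorted and non-overlapping")
            if length < 1:
                raise DatasetError(f"{self.sample_id}: run length must be >= 1")
            prev_end = start + length - 1
        if prev_end > self.height * self.width:
            raise DatasetError(
                f"{self.sample_id}: run exceeds the {self.height}x{self.width} "
                f"image area")


def _to_float01(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr / 255.0
    if arr.dtype == np.uint16:
        return arr / 65535.0
    return np.clip(arr.astype(float), 0.0, 1.0)


def _is_grayscale(arr: np.ndarray) -> bool:
    if arr.ndim == 2:
        return True
    rgb = arr[..., :3]
    return bool((rgb == rgb[..., :1]).all())


def load_dataset(root, grayscale_only: bool = False) -> list[SampleRecord]:
    """Load every sample directory under ``root``.

    Per-instance binary masks are merged into one label map, labels assigned
    in lexicographic file-name order.  With ``grayscale_only`` samples whose
    image channels are not all pixel-wise equal are excluded.  Overlapping
    instance files raise :class:`DatasetError` naming the sample.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    records = []
    for sample_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        sid = sample_dir.name
        img_dir = sample_dir / "images"
        msk_dir = sample_dir / "masks"
        img_files = sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.tif*"))
        if not img_files:
            raise FileNotFoundError(f"{sid}: no image file under {img_dir}")
        raw = np.asarray(iio.imread(img_files[0]))
        if grayscale_only and not _is_grayscale(raw):
            continue
        if raw.ndim == 3:
            raw = raw[..., 0]
        image = _to_float01(raw)
        if not msk_dir.is_dir():
            raise FileNotFoundError(f"{sid}: missing masks directory {msk_dir}")
        instances = np.zeros(image.shape, dtype=np.int32)
        occupied = np.zeros(image.shape, dtype=bool)
        for lab, mfile in enumerate(sorted(msk_dir.glob("*.png")), start=1):
            m = np.asarray(iio.imread(mfile))
            if m.ndim == 3:
                m = m[..., 0]
            binary = m > 0
            if (occupied & binary).any():
                raise DatasetError(
                    f"{sid}: instance mask {mfile.name} overlaps a previous one")
            occupied |= binary
            instances[binary] = lab
        records.append(SampleRecord(sid, image, instances))
    return records


def rle_decode(rle: RleMask) -> np.ndarray:
    """Decode a column-major 1-based run-length mask to a {0,1} array."""
    flat = np.zeros(rle.height * rle.width, dtype=np.uint8)
    for start, length in rle.runs:
        flat[start - 1:start - 1 + length] = 1
    return flat.reshape((rle.width, rle.height)).T


def rle_encode(mask: np.ndarray, sample_id: str = "") -> RleMask:
    """Encode a 2-D {0,1} mask as maximal column-major runs."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise DatasetError("rle_encode expects a 2-D mask")
    if not np.isin(mask, (0, 1)).all():
        raise DatasetError("rle_encode expects a binary {0,1} mask")
    h, w = mask.shape
    flat = mask.T.reshape(-1)
    padded = np.concatenate([[0], flat, [0]])
    changes = np.flatnonzero(np.diff(padded))
    starts = changes[::2] + 1          # 1-based
    lengths = changes[1::2] - changes[::2]
    runs = list(zip(starts.tolist(), lengths.tolist()))
    return RleMask(sample_id, h, w, runs)


def write_rle_csv(path, rles: list[RleMask]) -> None:
    """Write masks as a CSV with columns ImageId, EncodedPixels."""
    rows = []
    for r in rles:
        encoded = " ".join(f"{s} {l}" for s, l in r.runs)
        rows.append({"ImageId": r.sample_id, "EncodedPixels": encoded,
                     "Height": r.height, "Width": r.width})
    pd.DataFrame(rows, columns=["ImageId", "EncodedPixels", "Height", "Width"]
                 ).to_csv(path, index=False)


def read_rle_csv(path, shapes: dict | None = None) -> list[RleMask]:
    """Read an ImageId/EncodedPixels CSV.

    Shapes come from Height/Width columns when present, else from the
    ``shapes`` mapping {sample_id: (height, width)}.
    """
    df = pd.read_csv(path, dtype={"EncodedPixels": str})
    out = []
    for _, row in df.iterrows():
        sid = str(row["ImageId"])
        if "Height" in df.columns and not pd.isna(row.get("Height")):
            h, w = int(row["Height"]), int(row["Width"])
        elif shapes and sid in shapes:
            h, w = shapes[sid]
        else:
            raise DatasetError(f"{sid}: no image shape available for decoding")
        toks = [] if pd.isna(row["EncodedPixels"]) else str(row["EncodedPixels"]).split()
        pairs = list(zip((int(t) for t in toks[::2]), (int(t) for t in toks[1::2])))
        out.append(RleMask(sid, h, w, pairs))
    return out
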