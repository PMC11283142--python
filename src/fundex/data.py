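"""Labeled image containers and manifest I/O.

A dataset is an ordered collection of :class:`LabeledImage`; each image
carries its pixels (H×W×3 float, intensities in [0, 1]), a binary label
(0 control / 1 case), a provenance tag (``real`` or ``synthetic``) and, for
synthetic images, the identifier of the real image it derives from.

On disk a dataset is a directory of PNG files plus a ``manifest.csv`` with
columns ``path, label, source, origin_id``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["LabeledImage", "ImageDataset", "save_dataset", "load_dataset"]

MANIFEST_COLUMNS = ["path", "label", "source", "origin_id"]


@dataclasses.dataclass
class LabeledImage:
    pixels: np.ndarray  # (H, W, 3) float64 in [0, 1]
    label: int  # 0 control, 1 case
    id: str
    source: str = "real"  # "real" | "synthetic"
    origin_id: str = ""  # for synthetics: id of the source real image

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {self.pixels.shape}")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.source not in ("real", "synthetic"):
            raise ValueError(f"source must be 'real' or 'synthetic', got {self.source}")
        if self.source == "synthetic" and not self.origin_id:
            raise ValueError("synthetic images must carry a non-empty origin_id")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


class ImageDataset:
    """Ordered, indexable collection of labeled images."""

    def __init__(self, images: list[LabeledImage]):
        self.images = list(images)
        ids = [im.id for im in self.images]
        if len(set(ids)) != len(ids):
            raise ValueError("image ids must be unique within a dataset")

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i) -> LabeledImage:
        return self.images[i]

    def __iter__(self):
        return iter(self.images)

    @property
    def labels(self) -> np.ndarray:
        return np.array([im.label for im in self.images], dtype=np.int64)

    @property
    def ids(self) -> list[str]:
        return [im.id for im in self.images]

    def pixel_stack(self) -> np.ndarray:
        """All images as one (N, H, W, 3) array; requires uniform shapes."""
        return np.stack([im.pixels for im in self.images])

    def subset(self, indices) -> "ImageDataset":
        return ImageDataset([self.images[i] for i in indices])

    def real_only(self) -> "ImageDataset":
        return ImageDataset([im for im in self.images if im.source == "real"])

    def synthetic_only(self) -> "ImageDataset":
        return ImageDataset([im for im in self.images if im.source == "synthetic"])

    def class_counts(self) -> tuple[int, int]:
        """(n_controls, n_cases)."""
        y = self.labels
        return int((y == 0).sum()), int((y == 1).sum())


def save_dataset(dataset: ImageDataset, out_dir: str | Path) -> Path:
    """Write PNGs plus ``manifest.csv``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in dataset:
        fname = f"{im.id}.png"
        arr = np.clip(np.round(im.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(out_dir / fname)
        rows.append({"path": fname, "label": im.label,
                     "source": im.source, "origin_id": im.origin_id})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest: str | Path) -> ImageDataset:
    """Read a manifest CSV and its PNG/JPEG files (8-bit → [0, 1] floats)."""
    manifest = Path(manifest)
    if manifest.is_dir():
        manifest = manifest / "manifest.csv"
    df = pd.read_csv(manifest, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = manifest.parent
    images = []
    for _, row in df.iterrows():
        arr = np.asarray(Image.open(base / row["path"]).convert("RGB"))
        images.append(LabeledImage(
            pixels=arr.astype(np.float64) / 255.0,
            label=int(row["label"]),
            id=Path(row["path"]).stem,
            source=str(row["source"]),
            origin_id=str(row["origin_id"]),
        ))
    return ImageDataset(images)
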