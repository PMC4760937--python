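"""Image and manifest I/O.

Images are plain 2-D ``float64`` arrays with intensities in [0, 255]
(the convention every descriptor in this package assumes).  Datasets are
described by a manifest: a table of (file, label, parent_id) rows, where
``parent_id`` groups the subwindows cut from one microscope acquisition so
that cross-validation can be performed at image level.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights, the classic RGB -> gray conversion.
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)

MANIFEST_COLUMNS = ("file", "label", "parent_id")


@dataclass(frozen=True)
class DatasetManifest:
    """Rows of (file, label, parent_id) plus the ordered class list."""

    frame: pd.DataFrame
    classes: tuple[str, ...] = field(default=())

    def __post_init__(self):
        classes = self.classes or tuple(sorted(self.frame["label"].unique()))
        object.__setattr__(self, "classes", classes)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def files(self) -> list[str]:
        return list(self.frame["file"])

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    @property
    def parent_ids(self) -> np.ndarray:
        return self.frame["parent_id"].to_numpy()

    def subset(self, mask) -> "DatasetManifest":
        return DatasetManifest(self.frame[mask].reset_index(drop=True), self.classes)


def as_gray_array(pixels) -> np.ndarray:
    """Validate and return a float64 [0,255] grayscale image array."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("image intensities must lie in [0, 255]")
    return arr


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma conversion: 0.2989 R + 0.5870 G + 0.1140 B."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("rgb_to_gray expects an (H, W, 3+) array")
    r, g, b = LUMA_WEIGHTS
    return r * rgb[..., 0] + g * rgb[..., 1] + b * rgb[..., 2]


def load_gray(path: str | os.PathLike) -> np.ndarray:
    """Load a PNG/TIFF/JPEG image as a [0,255] grayscale array.

    RGB(A) inputs are converted with the BT.601 luma weights; grayscale
    inputs pass through unchanged.
    """
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im, dtype=np.float64)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.ndim == 3:
        arr = rgb_to_gray(arr)
    return as_gray_array(np.clip(arr, 0.0, 255.0))


def save_gray(path: str | os.PathLike, pixels: np.ndarray) -> None:
    """Save a [0,255] array as an 8-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0, 255)
    Image.fromarray(np.round(arr).astype(np.uint8), mode="L").save(path)


def split_subwindows(image: np.ndarray, grid: tuple[int, int]) -> list[np.ndarray]:
    """Tile an image into ``rows x cols`` subwindows in row-major order.

    Dimensions that do not divide evenly are truncated to the largest
    divisible area (a warning is logged); padding would fabricate texture.
    """
    image = as_gray_array(image)
    rows, cols = grid
    h, w = image.shape
    if rows < 1 or cols < 1:
        raise ValueError("grid must be at least (1, 1)")
    if rows > h or cols > w:
        raise ValueError(f"grid {grid} larger than image {image.shape}")
    th, tw = h // rows, w // cols
    if th * rows != h or tw * cols != w:
        logger.warning(
            "image %dx%d not divisible by grid %dx%d; truncating to %dx%d",
            h, w, rows, cols, th * rows, tw * cols,
        )
    tiles = []
    for i in range(rows):
        for j in range(cols):
            tiles.append(image[i * th:(i + 1) * th, j * tw:(j + 1) * tw].copy())
    return tiles


def load_manifest(path: str | os.PathLike) -> DatasetManifest:
    """Load and validate a dataset manifest (CSV or JSON records).

    The manifest must provide columns ``file,label,parent_id``; file paths
    are resolved relative to the manifest's directory, every file must
    exist, and rows are sorted by file path for deterministic ordering.
    """
    path = os.fspath(path)
    if not os.path.exists(path) or os.path.getsize(path) == 0:
        raise OSError(f"manifest {path!r} is missing or empty")
    if path.endswith(".json"):
        frame = pd.read_json(path, dtype=str)
    else:
        frame = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"manifest {path!r} missing columns {missing_cols}")
    frame = frame[list(MANIFEST_COLUMNS)].copy()
    base = os.path.dirname(os.path.abspath(path))
    frame["file"] = [
        f if os.path.isabs(f) else os.path.join(base, f) for f in frame["file"]
    ]
    bad = frame.loc[
        frame["parent_id"].isna()
        | (frame["parent_id"] == "")
        | frame["label"].isna(),
    ]
    if len(bad):
        raise ValueError(f"manifest rows with empty label/parent_id: {bad.index.tolist()}")
    missing = [f for f in frame["file"] if not os.path.exists(f)]
    if missing:
        raise ValueError(f"manifest references nonexistent files: {missing[:5]}")
    frame = frame.sort_values("file", kind="stable").reset_index(drop=True)
    return DatasetManifest(frame)


def save_manifest(manifest: DatasetManifest, path: str | os.PathLike,
                  relative_to: str | os.PathLike | None = None) -> None:
    frame = manifest.frame.copy()
    if relative_to is not None:
        base = os.path.abspath(os.fspath(relative_to))
        frame["file"] = [os.path.relpath(f, base) for f in frame["file"]]
    frame.to_csv(path, index=False)
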