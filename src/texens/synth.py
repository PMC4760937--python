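"""Seeded synthetic cell-mosaic textures.

Renders Voronoi-style cell mosaics that emulate the three morphologies a
retinal-pigment-epithelium culture passes through while maturing:

* ``fusiform``     — elongated, spindle-shaped, sparsely packed cells;
* ``epithelioid``  — globular cells at intermediate density;
* ``cobblestone``  — tightly packed, near-hexagonal, pigmented cells with
  well-defined cell walls (seeds on a jittered hexagonal lattice).

Each parent image is tiled into subwindows (the classification sample
unit) and a manifest CSV is written so the full training/evaluation
pipeline can run without any external dataset.  Generation is bitwise
deterministic for a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imgio import DatasetManifest, save_gray, save_manifest, split_subwindows


@dataclass(frozen=True)
class CellParams:
    """Mosaic parameters for one morphology class.

    elongation : major/minor axis ratio of the anisotropic cell metric
    cell_diameter : typical cell diameter in pixels (packing density)
    pigment : 0..1; higher = darker cells with more per-cell variation
    noise_sd : additive Gaussian noise standard deviation (intensity units)
    hexagonal : place seeds on a jittered hexagonal lattice
    """

    elongation: float = 1.0
    cell_diameter: float = 24.0
    pigment: float = 0.2
    noise_sd: float = 8.0
    hexagonal: bool = False

    def key(self) -> tuple:
        return (self.elongation, self.cell_diameter, self.pigment,
                self.noise_sd, self.hexagonal)


DEFAULT_CLASS_PARAMS: dict[str, CellParams] = {
    "fusiform": CellParams(elongation=3.0, cell_diameter=40.0, pigment=0.15,
                           noise_sd=8.0),
    "epithelioid": CellParams(elongation=1.3, cell_diameter=24.0, pigment=0.25,
                              noise_sd=8.0),
    "cobblestone": CellParams(elongation=1.0, cell_diameter=13.0, pigment=0.7,
                              noise_sd=8.0, hexagonal=True),
}


@dataclass(frozen=True)
class SynthConfig:
    n_parent_images: int = 5
    grid: tuple[int, int] = (4, 4)
    seed: int = 0
    image_size: tuple[int, int] = (256, 256)
    class_params: dict[str, CellParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))

    def __post_init__(self):
        keys = [p.key() for p in self.class_params.values()]
        if len(set(keys)) != len(keys):
            raise ValueError(
                "class_params must differ in at least one parameter per class; "
                "identical classes would be unlearnable")
        if self.n_parent_images < 1:
            raise ValueError("need at least one parent image per class")


def _seed_points(rng: np.random.Generator, shape: tuple[int, int],
                 params: CellParams) -> np.ndarray:
    """Cell seed coordinates (y, x); hexagonal lattice + jitter or uniform."""
    h, w = shape
    d = params.cell_diameter
    if params.hexagonal:
        dy = d * np.sqrt(3) / 2
        ys = np.arange(-d, h + d, dy)
        pts = []
        for i, y in enumerate(ys):
            x0 = (d / 2) if i % 2 else 0.0
            xs = np.arange(x0 - d, w + d, d)
            pts.extend((y, x) for x in xs)
        pts = np.array(pts)
        pts += rng.normal(scale=0.12 * d, size=pts.shape)
        return pts
    n = max(4, int(round(h * w / d ** 2)))
    return np.column_stack([rng.uniform(0, h, n), rng.uniform(0, w, n)])


def render_mosaic(shape: tuple[int, int], params: CellParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Render one parent mosaic image as a [0,255] grayscale array."""
    h, w = shape
    seeds = _seed_points(rng, shape, params)
    n = len(seeds)
    # One dominant orientation per image (cells co-align) with per-cell jitter.
    base_angle = rng.uniform(0, np.pi)
    angles = base_angle + rng.normal(scale=0.25, size=n)
    cos_a, sin_a = np.cos(angles), np.sin(angles)
    # Per-cell interior intensity: darker and more variable with pigment.
    base = 185.0 - 110.0 * params.pigment
    spread = 10.0 + 30.0 * params.pigment
    cell_level = np.clip(rng.normal(base, spread, size=n), 30.0, 230.0)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    img = np.empty((h, w))
    d1 = np.empty((h, w))
    d2 = np.empty((h, w))
    owner = np.empty((h, w), dtype=np.intp)
    # Anisotropic nearest/second-nearest seed distances, row-chunked to
    # bound the (pixels x seeds) broadcast.
    chunk = max(1, int(2.0e6 // max(n, 1)) // w)
    for r0 in range(0, h, chunk):
        r1 = min(h, r0 + chunk)
        dy = yy[r0:r1, :, None] - seeds[:, 0]
        dx = xx[r0:r1, :, None] - seeds[:, 1]
        u = dx * cos_a + dy * sin_a          # along the cell's major axis
        v = -dx * sin_a + dy * cos_a
        dist = np.sqrt((u / params.elongation) ** 2 + v ** 2)
        part = np.partition(dist, 1, axis=-1)
        d1[r0:r1] = part[..., 0]
        d2[r0:r1] = part[..., 1]
        owner[r0:r1] = np.argmin(dist, axis=-1)
    img[:] = cell_level[owner]
    # Cell walls: dark ridge where the two nearest seeds are equidistant;
    # sharper/stronger walls for pigmented cobblestone-like cells.
    wall_width = 0.06 * params.cell_diameter + 0.6
    wall_strength = 60.0 + 60.0 * params.pigment
    img -= wall_strength * np.exp(-((d2 - d1) / wall_width) ** 2)
    # Nucleus: small bright-rimmed dark blob at the cell centre.
    nucleus_r = 0.16 * params.cell_diameter
    img -= 35.0 * np.exp(-(d1 / nucleus_r) ** 2)
    img += rng.normal(scale=params.noise_sd, size=(h, w))
    return np.clip(img, 0.0, 255.0)


def generate_synthetic_dataset(config: SynthConfig, out_dir: str | os.PathLike,
                               ) -> DatasetManifest:
    """Render the dataset, save subwindow PNGs + ``manifest.csv``.

    Parent images are rendered per class, tiled by ``config.grid`` into
    subwindows (row-major), and every subwindow saved as an 8-bit PNG.
    ``parent_id`` is the parent image name, so image-level cross-validation
    folds keep sibling subwindows together.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    class_names = sorted(config.class_params)
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(len(class_names) * config.n_parent_images)
    k = 0
    for cls in class_names:
        params = config.class_params[cls]
        for i in range(config.n_parent_images):
            rng = np.random.default_rng(child_seeds[k])
            k += 1
            parent = f"{cls}_{i:03d}"
            image = render_mosaic(config.image_size, params, rng)
            for t, tile in enumerate(split_subwindows(image, config.grid)):
                fname = f"{parent}_t{t:02d}.png"
                save_gray(os.path.join(out_dir, fname), tile)
                rows.append((os.path.join(out_dir, fname), cls, parent))
    frame = pd.DataFrame(rows, columns=["file", "label", "parent_id"])
    frame = frame.sort_values("file", kind="stable").reset_index(drop=True)
    manifest = DatasetManifest(frame, tuple(class_names))
    save_manifest(manifest, os.path.join(out_dir, "manifest.csv"),
                  relative_to=out_dir)
    return manifest
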