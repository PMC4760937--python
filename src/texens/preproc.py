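"""Preprocessing channels and their ensembles.

Instead of (or before) extracting a descriptor from the original image,
the image is expanded into a set of processed channels, one classifier
per channel, fused by sum rule:

* ``Wa``  — single-level db4 wavelet decomposition (4 subimages);
* ``WaH`` — two-level db4 decomposition (7 subimages);
* ``MRS`` — Gaussian scale space: original + k=3 and k=5 lowpass, sigma 1;
* ``OR``  — soft-quantized gradient orientation images (d = 3);
* ``Ga``  — Gabor bank, 4 scales x 4 directions (16 subimages);
* ``Comb`` — Wa + OR + Ga applied to each of the 3 MRS images,
  (4+3+16) x 3 = 69 channels.

Every channel is linearly rescaled to [0, 255] before descriptor
extraction (constant channels map to all-zero), since the downstream
BSIF/LPQ threshold grids assume that intensity range.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pywt
from scipy.signal import fftconvolve

from .descriptors import circle_offsets

SCHEME_SIZES = {"O": 1, "Wa": 4, "WaH": 7, "OR": 3, "Ga": 16,
                "Wa+OR": 7, "Wa+OR+Ga": 23, "Comb": 69}

WAVELET = "db4"          # Daubechies, four vanishing moments
DWT_MODE = "periodization"


def rescale_255(channel: np.ndarray) -> np.ndarray:
    """Linear rescale to [0, 255]; a constant channel maps to all zeros."""
    channel = np.asarray(channel, dtype=np.float64)
    lo, hi = channel.min(), channel.max()
    # relative guard: numerically-constant channels (FFT roundoff) map to 0
    if hi - lo < 1e-9 * (max(abs(lo), abs(hi)) + 1.0):
        return np.zeros_like(channel)
    return (channel - lo) / (hi - lo) * 255.0


def wavelet_channels(image: np.ndarray) -> list[np.ndarray]:
    """Single-level 2-D DWT (db4, periodized): A, H, V, D subimages."""
    ca, (ch, cv, cd) = pywt.dwt2(np.asarray(image, float), WAVELET,
                                 mode=DWT_MODE)
    return [rescale_255(c) for c in (ca, ch, cv, cd)]


def wavelet_two_level_channels(image: np.ndarray) -> list[np.ndarray]:
    """Two-level db4 decomposition: H1,V1,D1, H2,V2,D2 and A2 (7 channels)."""
    ca1, (ch1, cv1, cd1) = pywt.dwt2(np.asarray(image, float), WAVELET,
                                     mode=DWT_MODE)
    ca2, (ch2, cv2, cd2) = pywt.dwt2(ca1, WAVELET, mode=DWT_MODE)
    return [rescale_255(c) for c in (ch1, cv1, cd1, ch2, cv2, cd2, ca2)]


@lru_cache(maxsize=None)
def _gaussian_kernel(k: int, sigma: float) -> np.ndarray:
    half = (k - 1) / 2.0
    ax = np.arange(k) - half
    g1 = np.exp(-ax ** 2 / (2 * sigma ** 2))
    ker = np.outer(g1, g1)
    return ker / ker.sum()


def _convolve_replicate(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image, ((ph, kernel.shape[0] - 1 - ph),
                            (pw, kernel.shape[1] - 1 - pw)), mode="edge")
    return fftconvolve(padded, kernel, mode="valid")


def gaussian_multiscale(image: np.ndarray) -> list[np.ndarray]:
    """MRS scale space: [original, Gaussian k=3 sigma=1, Gaussian k=5 sigma=1]."""
    image = np.asarray(image, dtype=np.float64)
    return [image.copy(),
            _convolve_replicate(image, _gaussian_kernel(3, 1.0)),
            _convolve_replicate(image, _gaussian_kernel(5, 1.0))]


def orientation_channels(image: np.ndarray, d: int = 3, w: int = 5,
                         L: float = 3.0, n: int = 8,
                         tau_or: float = 0.01) -> list[np.ndarray]:
    """Soft-quantized gradient-orientation images (one per orientation bin).

    1. Per-pixel gradient magnitude m(p) and orientation theta(p) in
       [0, 2*pi); the magnitude is split linearly between the two nearest
       of the d orientation-bin centres (soft quantization).
    2. Cell aggregation: each bin map summed over the w x w cell around p.
    3. Self-similarity: OR^i(p) = sum_j f((mt^i(p) - mt^i(c_j))^2) 2^-j
       over n cells c_j on a circle of radius L around p (ordered
       counterclockwise from +x), f(x) = 1 iff x >= tau_or; the aggregated
       maps are normalized to [0, 1] before comparison.
    """
    image = np.asarray(image, dtype=np.float64)
    gy, gx = np.gradient(image)
    mag = np.hypot(gy, gx)
    theta = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    width = 2 * np.pi / d
    pos = theta / width                       # continuous bin coordinate
    lo = np.floor(pos).astype(int) % d
    frac = pos - np.floor(pos)
    soft = np.zeros((d,) + image.shape)
    for i in range(d):
        soft[i] += np.where(lo == i, (1 - frac) * mag, 0.0)
        soft[i] += np.where((lo + 1) % d == i, frac * mag, 0.0)
    ker = np.ones((w, w))
    agg = np.stack([_convolve_replicate(s, ker) for s in soft])
    peak = agg.max()
    if peak > 0:
        agg = agg / peak
    # circle cells, counterclockwise from +x (y axis points down)
    offsets = circle_offsets(L, n)
    pad = int(np.ceil(L)) + 1
    maps = []
    h, wid = image.shape
    for i in range(d):
        padded = np.pad(agg[i], pad, mode="edge")
        out = np.zeros_like(image)
        for j, (dy, dx) in enumerate(offsets, start=1):
            y0 = int(np.floor(dy)) + pad
            x0 = int(np.floor(dx)) + pad
            ty, tx = dy - np.floor(dy), dx - np.floor(dx)
            shifted = ((1 - ty) * (1 - tx) * padded[y0:y0 + h, x0:x0 + wid]
                       + (1 - ty) * tx * padded[y0:y0 + h, x0 + 1:x0 + 1 + wid]
                       + ty * (1 - tx) * padded[y0 + 1:y0 + 1 + h, x0:x0 + wid]
                       + ty * tx * padded[y0 + 1:y0 + 1 + h, x0 + 1:x0 + 1 + wid])
            fire = (agg[i] - shifted) ** 2 >= tau_or
            out += fire * 2.0 ** (-j)
        maps.append(rescale_255(out) if out.any() else out)
    return maps


def gabor_kernel(scale: int, theta_deg: float) -> np.ndarray:
    """Cosine Gabor kernel; scale s -> nu = 0.25/2^(s-1), sigma = 0.56/nu.

    The kernel mean is subtracted (DC correction) so constant regions
    respond with zero.
    """
    nu = 0.25 / 2.0 ** (scale - 1)
    sigma = 0.56 / nu
    half = int(np.ceil(3 * sigma))
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    t = np.deg2rad(theta_deg)
    xp = x * np.sin(t) + y * np.cos(t)
    yp = x * np.cos(t) - y * np.sin(t)
    g = np.exp(-(xp ** 2 + yp ** 2) / (2 * sigma ** 2)) * np.cos(2 * np.pi * nu * xp)
    g -= g.mean()
    return g / np.linalg.norm(g)       # unit energy: channels comparable


GABOR_SCALES = (1, 2, 3, 4)
GABOR_DIRECTIONS = (0.0, 45.0, 90.0, 135.0)


def gabor_channels(image: np.ndarray) -> list[np.ndarray]:
    """Gabor bank magnitudes: 4 scales x 4 directions = 16 channels."""
    image = np.asarray(image, dtype=np.float64)
    out = []
    for s in GABOR_SCALES:
        for th in GABOR_DIRECTIONS:
            resp = _convolve_replicate(image, gabor_kernel(s, th))
            out.append(rescale_255(np.abs(resp)))
    return out


def build_preproc_set(image: np.ndarray, scheme: str,
                      ) -> list[tuple[str, np.ndarray]]:
    """Tagged processed-image channels for a named scheme."""
    image = np.asarray(image, dtype=np.float64)
    if scheme == "O":
        return [("orig", image.copy())]
    if scheme == "Wa":
        return list(zip(("wa_A", "wa_H", "wa_V", "wa_D"),
                        wavelet_channels(image)))
    if scheme == "WaH":
        tags = ("wah_H1", "wah_V1", "wah_D1", "wah_H2", "wah_V2", "wah_D2",
                "wah_A2")
        return list(zip(tags, wavelet_two_level_channels(image)))
    if scheme == "OR":
        return [(f"or_{i}", ch) for i, ch in
                enumerate(orientation_channels(image))]
    if scheme == "Ga":
        tags = [f"gabor_s{s}_d{int(t)}" for s in GABOR_SCALES
                for t in GABOR_DIRECTIONS]
        return list(zip(tags, gabor_channels(image)))
    if scheme == "MRS":
        return [(f"mrs{k}", ch) for k, ch in
                zip((0, 3, 5), gaussian_multiscale(image))]
    if "+" in scheme and scheme != "Comb":
        parts = scheme.split("+")
        if not all(p in ("Wa", "WaH", "OR", "Ga", "O") for p in parts):
            raise ValueError(f"unknown preprocessing scheme {scheme!r}")
        out = []
        for p in parts:
            out.extend(build_preproc_set(image, p))
        return out
    if scheme == "Comb":
        out = []
        for k, base in zip((0, 3, 5), gaussian_multiscale(image)):
            for sub in ("Wa", "OR", "Ga"):
                for tag, ch in build_preproc_set(base, sub):
                    out.append((f"mrs{k}/{tag}", ch))
        return out
    raise ValueError(f"unknown preprocessing scheme {scheme!r}; "
                     f"known: {sorted(SCHEME_SIZES)}")
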