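"""Region-based histogram splitting.

A descriptor's label image is computed once from the original image;
a pair of complementary binary masks (Map+, Map-) then splits its
histogram into two blocks, each feeding its own classifier (fused by sum
rule).  Mask pairs come from Sobel edges, difference of Gaussians,
DCT-signature saliency (thresholds 0.5 and 0.7), or wavelet detail
coefficients thresholded at their mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.fft import dctn, idctn
from scipy.ndimage import gaussian_filter
from skimage.filters import sobel, threshold_otsu
from skimage.transform import resize

from .descriptors import DescriptorLabels, descriptor_labels, label_counts

REGION_SCHEME_SIZES = {"O": 1, "Edge": 2, "DoG": 2, "Saliency": 4,
                       "Wavelet": 6, "Saliency+Wavelet": 10, "All": 12,
                       "All+O": 13}

REGION_DESCRIPTORS = ("lbp", "ltp", "lpq", "riclbp", "wld")


@dataclass(frozen=True)
class RegionMapPair:
    """Complementary pixel masks partitioning the image grid."""

    map_plus: np.ndarray
    map_minus: np.ndarray
    source: str

    def __post_init__(self):
        if self.map_plus.shape != self.map_minus.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.map_plus & self.map_minus):
            raise ValueError("masks overlap")
        if not np.all(self.map_plus | self.map_minus):
            raise ValueError("masks do not cover the image")


def _pair(mask: np.ndarray, source: str) -> RegionMapPair:
    mask = mask.astype(bool)
    return RegionMapPair(mask, ~mask, source)


def edge_maps(image: np.ndarray) -> RegionMapPair:
    """Sobel gradient magnitude binarized by Otsu: edge / non-edge masks."""
    image = np.asarray(image, dtype=np.float64)
    grad = sobel(image)
    if np.ptp(grad) < 1e-12:
        return _pair(np.zeros(image.shape, dtype=bool), "edge")
    return _pair(grad > threshold_otsu(grad), "edge")


def dog_maps(image: np.ndarray, sigma1: float = 1.0,
             sigma2: float = 2.0) -> RegionMapPair:
    """Difference of Gaussians: positive side vs. negative side of edges."""
    if sigma1 >= sigma2:
        raise ValueError("require sigma1 < sigma2")
    image = np.asarray(image, dtype=np.float64)
    d = gaussian_filter(image, sigma1) - gaussian_filter(image, sigma2)
    return _pair(d > 0, "dog")


def saliency_map(image: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """DCT image-signature saliency, min-max normalized to [0, 1].

    xbar = IDCT(sign(DCT(x)));  m = Gaussian(sigma) * (xbar o xbar).
    A constant input yields the all-zero map.
    """
    x = np.asarray(image, dtype=np.float64)
    xbar = idctn(np.sign(dctn(x, norm="ortho")), norm="ortho")
    m = gaussian_filter(xbar * xbar, sigma)
    lo, hi = m.min(), m.max()
    if hi - lo < 1e-12:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def saliency_region_pairs(image: np.ndarray,
                          thresholds: tuple[float, ...] = (0.5, 0.7),
                          ) -> list[RegionMapPair]:
    """One (above, below) mask pair per saliency threshold (0.5 and 0.7)."""
    sal = saliency_map(image)
    return [_pair(sal > th, f"saliency({th})") for th in thresholds]


def wavelet_region_pairs(image: np.ndarray,
                         include_approximation: bool = False,
                         ) -> list[RegionMapPair]:
    """Mask pairs from db4 detail subbands (H, V, D).

    Absolute coefficient matrices are bilinearly resized to the image
    size; pixels strictly above each subband's mean form Map+.
    """
    image = np.asarray(image, dtype=np.float64)
    ca, (ch, cv, cd) = pywt.dwt2(image, "db4", mode="periodization")
    bands = [("wavelet(H)", ch), ("wavelet(V)", cv), ("wavelet(D)", cd)]
    if include_approximation:
        bands.append(("wavelet(A)", ca))
    pairs = []
    for name, band in bands:
        up = resize(np.abs(band), image.shape, order=1, mode="edge",
                    anti_aliasing=False)
        if np.ptp(up) < 1e-9 * (np.abs(up).max() + 1.0):
            pairs.append(_pair(np.zeros(image.shape, dtype=bool), name))
        else:
            pairs.append(_pair(up > up.mean(), name))
    return pairs


def masked_histograms(desc: DescriptorLabels, pair: RegionMapPair,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Split a descriptor's histogram by a mask pair -> (H+, H-).

    Each side is normalized per group block; an empty region yields an
    all-zero block rather than NaN.
    """
    def side(mask):
        blocks = []
        for group in desc.groups:
            counts = sum(label_counts(lab, mask) for lab in group)
            total = counts.sum()
            blocks.append(counts / total if total > 0 else counts)
        return np.concatenate(blocks)

    return side(pair.map_plus), side(pair.map_minus)


def region_pairs(image: np.ndarray, scheme: str) -> list[RegionMapPair]:
    """The mask pairs a named region scheme uses."""
    if scheme == "Edge":
        return [edge_maps(image)]
    if scheme == "DoG":
        return [dog_maps(image)]
    if scheme == "Saliency":
        return saliency_region_pairs(image)
    if scheme == "Wavelet":
        return wavelet_region_pairs(image)
    if scheme == "Saliency+Wavelet":
        return saliency_region_pairs(image) + wavelet_region_pairs(image)
    if scheme == "All":
        return (saliency_region_pairs(image) + [edge_maps(image)]
                + wavelet_region_pairs(image))
    raise ValueError(f"unknown region scheme {scheme!r}; "
                     f"known: {sorted(REGION_SCHEME_SIZES)}")


def build_region_channels(image: np.ndarray, descriptor_tag: str,
                          scheme: str) -> list[tuple[str, np.ndarray]]:
    """Tagged masked-histogram channels for a descriptor + region scheme.

    The label image is computed once from the original image; masks only
    select which pixels contribute to each histogram.
    """
    descriptor_tag = descriptor_tag.lower()
    if descriptor_tag not in REGION_DESCRIPTORS:
        raise ValueError(f"descriptor {descriptor_tag!r} not supported for "
                         f"region splitting; use one of {REGION_DESCRIPTORS}")
    desc = descriptor_labels(image, descriptor_tag)
    if scheme == "O":
        return [(f"{descriptor_tag}/plain", desc.histogram())]
    channels = []
    base_scheme = scheme[:-2] if scheme.endswith("+O") else scheme
    for pair in region_pairs(image, base_scheme):
        h_plus, h_minus = masked_histograms(desc, pair)
        channels.append((f"{descriptor_tag}/{pair.source}+", h_plus))
        channels.append((f"{descriptor_tag}/{pair.source}-", h_minus))
    if scheme.endswith("+O"):
        channels.append((f"{descriptor_tag}/plain", desc.histogram()))
    return channels
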