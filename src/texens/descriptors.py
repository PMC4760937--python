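"""Base texture descriptors.

All descriptors consume a 2-D grayscale array in [0, 255] and return a
1-D feature vector whose normalized blocks each sum to one.  Codes are
computed only where the full neighborhood fits inside the image (no
padding), and circular sampling positions that fall between pixels are
read with bilinear interpolation.

Implemented here: multi-scale uniform LBP and LTP, (multi-scale) LPQ in
binary and ternary flavours, the local configuration pattern (LCP),
rotation-invariant co-occurrence of adjacent LBP (RICLBP), the Weber law
descriptor (WLD), and the per-channel colour statistics (COLORS).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import convolve2d

from .imgio import as_gray_array
from .mapping import mapping_table, rotate_code

#: the standard multi-scale (radius, points) configurations
DEFAULT_CONFIGS = ((1, 8), (2, 16))


# ---------------------------------------------------------------------------
# sampling and label images

def circle_offsets(radius: float, points: int) -> np.ndarray:
    """(dy, dx) sampling offsets on a circle at angles 2*pi*k/P.

    The image convention is row-major with y increasing downward, so the
    k-th point sits at (dy, dx) = (-R sin a, R cos a), a = 2*pi*k/P.
    """
    ang = 2.0 * np.pi * np.arange(points) / points
    off = np.column_stack([-radius * np.sin(ang), radius * np.cos(ang)])
    off[np.abs(off) < 1e-12] = 0.0
    return off


def offsets_margin(offsets: np.ndarray) -> int:
    return int(np.ceil(np.max(np.abs(offsets)) - 1e-9))


def neighbor_stack(image: np.ndarray, offsets: np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """Bilinear-interpolated neighbor intensities over the valid region.

    Returns ``(stack, center, margin)`` where ``stack[y, x, k]`` is the
    intensity at position (y+dy_k, x+dx_k) for every interior pixel of
    the valid region ``image[m:-m, m:-m]``.
    """
    image = np.asarray(image, dtype=np.float64)
    m = offsets_margin(offsets)
    h, w = image.shape
    if h < 2 * m + 1 or w < 2 * m + 1:
        raise ValueError(f"image {image.shape} too small for margin {m}")
    center = image[m:h - m, m:w - m]
    ch, cw = center.shape
    stack = np.empty((ch, cw, len(offsets)))
    for k, (dy, dx) in enumerate(offsets):
        y0, x0 = int(np.floor(dy)), int(np.floor(dx))
        ty, tx = dy - y0, dx - x0
        def block(ddy, ddx):
            r0, c0 = m + y0 + ddy, m + x0 + ddx
            return image[r0:r0 + ch, c0:c0 + cw]
        if ty == 0.0 and tx == 0.0:
            stack[:, :, k] = block(0, 0)
        else:
            stack[:, :, k] = ((1 - ty) * (1 - tx) * block(0, 0)
                              + (1 - ty) * tx * block(0, 1)
                              + ty * (1 - tx) * block(1, 0)
                              + ty * tx * block(1, 1))
    return stack, center, m


def sample_neighbors(image: np.ndarray, offsets: np.ndarray,
                     p: tuple[int, int]) -> np.ndarray:
    """Neighbor intensity vector at a single pixel ``p = (y, x)``."""
    stack, _, m = neighbor_stack(np.asarray(image, float), np.asarray(offsets))
    y, x = p
    ch, cw = stack.shape[:2]
    if not (m <= y < m + ch and m <= x < m + cw):
        raise ValueError(f"pixel {p} outside the valid region (margin {m})")
    return stack[y - m, x - m]


@dataclass(frozen=True)
class LabelImage:
    """Per-pixel integer codes over the interior valid region.

    ``offset`` is the (row, col) of the valid region's top-left corner in
    the coordinates of the original image, so region masks can be cropped
    into alignment.
    """

    codes: np.ndarray
    n_codes: int
    offset: tuple[int, int]

    def histogram(self, mask: np.ndarray | None = None,
                  normalize: bool = True) -> np.ndarray:
        counts = label_counts(self, mask)
        if not normalize:
            return counts
        total = counts.sum()
        return counts / total if total > 0 else counts


def label_counts(label: LabelImage, mask: np.ndarray | None = None) -> np.ndarray:
    """Raw code counts, optionally restricted to a full-size boolean mask."""
    codes = label.codes
    if mask is not None:
        r0, c0 = label.offset
        h, w = codes.shape
        sub = mask[r0:r0 + h, c0:c0 + w]
        codes = codes[sub]
    return np.bincount(codes.ravel(), minlength=label.n_codes).astype(float)


@dataclass(frozen=True)
class DescriptorLabels:
    """The label images a descriptor produces, grouped by histogram block.

    Each group accumulates into one normalized histogram block; the
    descriptor's plain histogram is the concatenation over groups.  This
    is the structure the region-based methods mask.
    """

    groups: tuple[tuple[LabelImage, ...], ...]

    def histogram(self, mask: np.ndarray | None = None) -> np.ndarray:
        blocks = []
        for group in self.groups:
            counts = sum(label_counts(lab, mask) for lab in group)
            total = counts.sum()
            blocks.append(counts / total if total > 0 else counts)
        return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# LBP / LTP

def lbp_label_image(image: np.ndarray, radius: float, points: int,
                    mapping: str = "u2") -> LabelImage:
    stack, center, m = neighbor_stack(image, circle_offsets(radius, points))
    bits = stack >= center[:, :, None]          # s(q_p - q_c) with s(0) = 1
    codes = (bits << np.arange(points)).sum(axis=2)
    table, n_bins = mapping_table(points, mapping)
    return LabelImage(table[codes], n_bins, (m, m))


def lbp_labels(image, configs=DEFAULT_CONFIGS, mapping="u2") -> DescriptorLabels:
    return DescriptorLabels(tuple(
        (lbp_label_image(image, r, p, mapping),) for r, p in configs))


def lbp_histogram(image, configs=DEFAULT_CONFIGS, mapping="u2") -> np.ndarray:
    """Multi-scale uniform LBP: per-config normalized histograms, concatenated."""
    return lbp_labels(image, configs, mapping).histogram()


def ltp_label_images(image, radius, points, tau, mapping="u2",
                     ) -> tuple[LabelImage, LabelImage]:
    """Positive/negative binary-pattern label images of the ternary coding."""
    stack, center, m = neighbor_stack(image, circle_offsets(radius, points))
    diff = stack - center[:, :, None]
    pos = diff >= tau                            # digit +1
    neg = diff < -tau                            # digit -1
    weights = 1 << np.arange(points)
    table, n_bins = mapping_table(points, mapping)
    return (LabelImage(table[(pos * weights).sum(axis=2)], n_bins, (m, m)),
            LabelImage(table[(neg * weights).sum(axis=2)], n_bins, (m, m)))


def ltp_labels(image, configs=DEFAULT_CONFIGS, tau=5.0,
               mapping="u2") -> DescriptorLabels:
    groups = []
    for r, p in configs:
        lab_pos, lab_neg = ltp_label_images(image, r, p, tau, mapping)
        groups += [(lab_pos,), (lab_neg,)]
    return DescriptorLabels(tuple(groups))


def ltp_histograms(image, configs=DEFAULT_CONFIGS, tau=5.0,
                   mapping="u2") -> np.ndarray:
    """Multi-scale uniform LTP: positive + negative histograms per config."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return ltp_labels(image, configs, tau, mapping).histogram()


# ---------------------------------------------------------------------------
# LPQ

@lru_cache(maxsize=None)
def _lpq_model(r: int, a: float, rho: float):
    """STFT kernels (DC-corrected) and the whitening transform for LPQ.

    Four low, non-DC frequencies u in {(f,0),(0,f),(f,f),(f,-f)} with
    f = a/r are evaluated over the r x r window; the 8 real/imaginary
    responses are decorrelated under the Gaussian image-correlation model
    cov(x_i, x_j) = rho^{||x_i - x_j||}.
    """
    if r % 2 == 0 or r < 3:
        raise ValueError("LPQ window size r must be odd and >= 3")
    mhalf = (r - 1) // 2
    pos = np.arange(-mhalf, mhalf + 1)
    yy, xx = np.meshgrid(pos, pos, indexing="ij")
    f = a / r
    freqs = [(f, 0.0), (0.0, f), (f, f), (f, -f)]
    kernels = []
    for uy, ux in freqs:
        k = np.exp(-2j * np.pi * (uy * yy + ux * xx))
        k -= k.mean()          # zero-DC: constant images respond exactly 0
        kernels.append(k)
    # covariance of window pixels under the correlation model
    xs = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    dist = np.linalg.norm(xs[:, None, :] - xs[None, :, :], axis=2)
    cov = rho ** dist
    m_rows = []
    for k in kernels:
        m_rows.append(np.real(k).ravel())
        m_rows.append(np.imag(k).ravel())
    m_mat = np.array(m_rows)
    d_mat = m_mat @ cov @ m_mat.T
    # Symmetric (inverse-square-root) whitening: unlike an SVD basis it
    # is a unique matrix function of D, well-defined even when the
    # symmetric frequency pairs make eigenvalues degenerate.
    evals, evecs = np.linalg.eigh(d_mat)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(np.abs(evals), 1e-12))
    vt = (evecs * inv_sqrt) @ evecs.T
    return tuple(kernels), vt


def lpq_components(image: np.ndarray, r: int = 3, a: float = 1.0,
                   rho: float = 0.9) -> tuple[np.ndarray, int]:
    """Decorrelated 8-component STFT response stack over the valid region."""
    image = np.asarray(image, dtype=np.float64)
    kernels, vt = _lpq_model(r, float(a), float(rho))
    comps = []
    for k in kernels:
        resp = convolve2d(image, k[::-1, ::-1], mode="valid")
        comps.append(np.real(resp))
        comps.append(np.imag(resp))
    raw = np.stack(comps, axis=-1)
    white = raw @ vt.T
    white[np.abs(white) < 1e-8] = 0.0   # so sign(0) -> bit 0 holds exactly
    return white, (r - 1) // 2


def lpq_label_images(image, r=3, a=1.0, rho=0.9, ternary_tau=None,
                     ) -> tuple[LabelImage, ...]:
    white, m = lpq_components(image, r, a, rho)
    weights = 1 << np.arange(8)
    if ternary_tau is None:
        codes = ((white > 0) * weights).sum(axis=2)
        return (LabelImage(codes, 256, (m, m)),)
    # Ternary coding on variance-normalized components so the threshold
    # grids {0.2 .. 1} land on a meaningful scale for [0,255] images.
    sd = white.reshape(-1, 8).std(axis=0)
    sd[sd == 0] = 1.0
    norm = white / sd
    pos = ((norm >= ternary_tau) * weights).sum(axis=2)
    neg = ((norm < -ternary_tau) * weights).sum(axis=2)
    return (LabelImage(pos, 256, (m, m)), LabelImage(neg, 256, (m, m)))


def lpq_labels(image, rs=(3, 5), a=1.0, rho=0.9,
               ternary_tau=None) -> DescriptorLabels:
    groups = []
    for r in rs:
        groups += [(lab,) for lab in
                   lpq_label_images(image, r, a, rho, ternary_tau)]
    return DescriptorLabels(tuple(groups))


def lpq_histogram(image, r=3, a=1.0, rho=0.9, ternary_tau=None) -> np.ndarray:
    """Single-window-size LPQ histogram: 256 bins (binary) / 512 (ternary)."""
    return DescriptorLabels(tuple(
        (lab,) for lab in lpq_label_images(image, r, a, rho, ternary_tau)
    )).histogram()


def multiscale_lpq_histogram(image, rs=(3, 5), a=1.0, rho=0.9,
                             ternary_tau=None) -> np.ndarray:
    """Multi-scale LPQ: window sizes 3 and 5 concatenated."""
    return lpq_labels(image, rs, a, rho, ternary_tau).histogram()


# ---------------------------------------------------------------------------
# LCP

def lcp_features_from_patterns(stack: np.ndarray, center: np.ndarray,
                               classes: np.ndarray, n_classes: int,
                               ridge: float = 1e-6) -> np.ndarray:
    """LCP block given neighbor stacks and a per-pixel pattern class map.

    For every pattern class the least-squares weights reconstructing the
    centre intensity from its neighbors are estimated over all pixels of
    the class (ridge-regularized so constant images stay finite); the
    feature is |DFT(weights)| per class plus the normalized class
    occurrence histogram.
    """
    points = stack.shape[-1]
    neigh = stack.reshape(-1, points)
    cent = center.ravel()
    cls = classes.ravel()
    mags = np.zeros((n_classes, points))
    counts = np.zeros(n_classes)
    for k in range(n_classes):
        sel = cls == k
        counts[k] = sel.sum()
        if counts[k] == 0:
            continue
        a_mat = neigh[sel]
        gram = a_mat.T @ a_mat + ridge * np.eye(points)
        w = np.linalg.solve(gram, a_mat.T @ cent[sel])
        mags[k] = np.abs(np.fft.fft(w))
    occ = counts / counts.sum() if counts.sum() else counts
    return np.concatenate([mags.ravel(), occ])


def lcp_features(image, configs=DEFAULT_CONFIGS) -> np.ndarray:
    """Multi-scale local configuration pattern features.

    Per configuration: (P+2) riu2 pattern classes x P DFT magnitudes of
    the reconstruction weights, plus the P+2 occurrence histogram.
    """
    blocks = []
    for r, p in configs:
        stack, center, _ = neighbor_stack(image, circle_offsets(r, p))
        bits = stack >= center[:, :, None]
        codes = (bits << np.arange(p)).sum(axis=2)
        table, n_bins = mapping_table(p, "riu2")
        blocks.append(lcp_features_from_patterns(
            stack, center, table[codes], n_bins))
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# RICLBP

@lru_cache(maxsize=None)
def riclbp_orbit_table(points: int = 4, n_dirs: int = 4,
                       ) -> tuple[np.ndarray, int]:
    """Rotation orbits of (code1, code2, direction) co-occurrence triples.

    The displacement directions step by 45 deg; the orbit group is
    generated by the quarter-turn g: rotate both codes by P/4 bits and
    advance the direction two steps, swapping the pair when the
    displacement flips through 180 deg.  Enumerated by brute force.
    """
    n = 1 << points
    step = points // 4                 # bits per quarter turn
    table = np.full(n * n * n_dirs, -1, dtype=np.int64)

    def succ(c1, c2, d):
        c1r, c2r = rotate_code(c1, points, step), rotate_code(c2, points, step)
        d2 = d + 2
        if d2 >= n_dirs:               # direction passed 180 deg: swap pair
            return c2r, c1r, d2 - n_dirs
        return c1r, c2r, d2

    n_classes = 0
    for c1 in range(n):
        for c2 in range(n):
            for d in range(n_dirs):
                idx = (c1 * n + c2) * n_dirs + d
                if table[idx] >= 0:
                    continue
                orbit = [(c1, c2, d)]
                cur = succ(c1, c2, d)
                while cur != (c1, c2, d):
                    orbit.append(cur)
                    cur = succ(*cur)
                for (a, b, dd) in orbit:
                    table[(a * n + b) * n_dirs + dd] = n_classes
                n_classes += 1
    return table, n_classes


def riclbp_label_images(image, radius: int, points: int = 4,
                        ) -> tuple[LabelImage, ...]:
    """Orbit-class label images, one per co-occurrence direction."""
    stack, center, m = neighbor_stack(image, circle_offsets(radius, points))
    bits = stack >= center[:, :, None]
    codes = (bits << np.arange(points)).sum(axis=2)
    table, n_classes = riclbp_orbit_table(points)
    disp = 2 * radius
    dirs = [(0, disp), (-disp, disp), (-disp, 0), (-disp, -disp)]
    n = 1 << points
    h, w = codes.shape
    labels = []
    for d, (dy, dx) in enumerate(dirs):
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        c1 = codes[y0:y1, x0:x1]
        c2 = codes[y0 + dy:y1 + dy, x0 + dx:x1 + dx]
        pair = (c1 * n + c2) * 4 + d
        labels.append(LabelImage(table[pair], n_classes,
                                 (m + y0, m + x0)))
    return tuple(labels)


def riclbp_labels(image, radii=(1, 2, 4), points: int = 4) -> DescriptorLabels:
    return DescriptorLabels(tuple(
        riclbp_label_images(image, r, points) for r in radii))


def riclbp_histogram(image, radii=(1, 2, 4), points: int = 4) -> np.ndarray:
    """Rotation-invariant co-occurrence of adjacent LBP, radii {1, 2, 4}."""
    return riclbp_labels(image, radii, points).histogram()


# ---------------------------------------------------------------------------
# WLD

def wld_label_image(image, excitation_bins: int = 6, orientation_bins: int = 8,
                    ) -> LabelImage:
    image = np.asarray(image, dtype=np.float64)
    c = image[1:-1, 1:-1]
    acc = np.zeros_like(c)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            acc += image[1 + dy:image.shape[0] - 1 + dy,
                         1 + dx:image.shape[1] - 1 + dx] - c
    xi = np.arctan(acc / (c + 1.0))
    gy = image[2:, 1:-1] - image[:-2, 1:-1]
    gx = image[1:-1, 2:] - image[1:-1, :-2]
    theta = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    e_bin = np.clip(((xi + np.pi / 2) / np.pi * excitation_bins).astype(int),
                    0, excitation_bins - 1)
    o_bin = np.clip((theta / (2 * np.pi) * orientation_bins).astype(int),
                    0, orientation_bins - 1)
    return LabelImage(e_bin * orientation_bins + o_bin,
                      excitation_bins * orientation_bins, (1, 1))


def wld_labels(image, excitation_bins=6, orientation_bins=8) -> DescriptorLabels:
    return DescriptorLabels(
        ((wld_label_image(image, excitation_bins, orientation_bins),),))


def wld_histogram(image, excitation_bins: int = 6,
                  orientation_bins: int = 8) -> np.ndarray:
    """Weber law descriptor: joint differential-excitation/orientation histogram.

    Differential excitation xi = arctan(sum_8(q_p - q_c) / (q_c + 1));
    gradient orientation from central differences, both uniformly binned.
    """
    return wld_labels(image, excitation_bins, orientation_bins).histogram()


# ---------------------------------------------------------------------------
# COLORS

def _glcm_homogeneity(channel: np.ndarray, levels: int = 8) -> float:
    """Co-occurrence homogeneity at offset (0, 1): sum p(i,j)/(1+|i-j|)."""
    q = np.clip((channel / 256.0 * levels).astype(int), 0, levels - 1)
    i, j = q[:, :-1].ravel(), q[:, 1:].ravel()
    glcm = np.zeros((levels, levels))
    np.add.at(glcm, (i, j), 1.0)
    glcm /= glcm.sum()
    ii, jj = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    return float((glcm / (1.0 + np.abs(ii - jj))).sum())


def colors_features(rgb_image: np.ndarray) -> np.ndarray:
    """Per-channel colour statistics (42 values).

    For each of the three channels: mean, co-occurrence homogeneity,
    standard deviation, third/fourth/fifth central moments, and an 8-bin
    marginal histogram.  Statistics are scaled to comparable [0,1]-ish
    ranges (mean and sd by 255, the k-th central moment by 255^k).
    """
    rgb = np.asarray(rgb_image, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("colors_features requires a 3-channel image; "
                         "skip COLORS for grayscale inputs")
    feats = []
    for ch in range(3):
        x = rgb[..., ch]
        mu = x.mean()
        centered = x - mu
        sd = x.std()
        moments = [np.mean(centered ** k) / 255.0 ** k for k in (3, 4, 5)]
        hist = np.histogram(x, bins=8, range=(0, 256))[0].astype(float)
        hist /= hist.sum()
        feats.extend([mu / 255.0, _glcm_homogeneity(x), sd / 255.0,
                      *moments, *hist])
    return np.array(feats)


# ---------------------------------------------------------------------------
# registry used by the region-based methods

def descriptor_labels(image, tag: str, mapping: str = "u2") -> DescriptorLabels:
    """Label-image decomposition for the region-maskable descriptors."""
    tag = tag.lower()
    if tag == "lbp":
        return lbp_labels(image, mapping=mapping)
    if tag == "ltp":
        return ltp_labels(image, mapping=mapping)
    if tag == "lpq":
        return lpq_labels(image)
    if tag == "riclbp":
        return riclbp_labels(image)
    if tag == "wld":
        return wld_labels(image)
    raise ValueError(f"descriptor {tag!r} has no label-image form; "
                     "expected one of lbp, ltp, lpq, riclbp, wld")
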