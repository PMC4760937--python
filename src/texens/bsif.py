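"""Binarized statistical image features (BSIF).

A BSIF descriptor assigns each pixel an n-bit label: bit i is set when
the response of the i-th linear filter over the l x l neighborhood
exceeds a threshold ``th`` (0 in the stand-alone descriptor).  Filters
are learned by maximizing the statistical independence of their
responses (PCA whitening followed by fixed-point ICA) on image patches.
Shipping natural photographs is out of scope, so the default patch
source is seeded 1/f^2-spectrum noise, whose power spectrum mimics the
second-order statistics of natural images; externally learned filter
banks can be loaded from file instead.

Two ensembles are built on top of the stand-alone descriptor:

* ``Size_Bsif`` — one channel per filter size l in {3, 5, 7, 9, 11};
* ``Full_Bsif`` — additionally varies the binarization threshold
  th in {-9, -6, -3, 0, 3, 6, 9}, giving 35 channels.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .descriptors import LabelImage

BSIF_SIZES = (3, 5, 7, 9, 11)
BSIF_THRESHOLDS = (-9, -6, -3, 0, 3, 6, 9)
DEFAULT_BITS = 8
#: seed for the default filter banks, fixed so channel definitions are stable
DEFAULT_BANK_SEED = 20160219


@dataclass(frozen=True)
class BsifFilterBank:
    """Stack of n zero-DC unit-norm linear filters of size l x l."""

    filters: np.ndarray           # (n, l, l)
    provenance: str = "learned"

    @property
    def n_bits(self) -> int:
        return self.filters.shape[0]

    @property
    def size(self) -> int:
        return self.filters.shape[1]

    def __post_init__(self):
        n, l, l2 = self.filters.shape
        if l != l2 or l % 2 == 0:
            raise ValueError("filters must be square with odd size")
        if n > l * l - 1:
            raise ValueError(f"at most l^2-1={l * l - 1} independent zero-DC "
                             f"filters exist for size {l}")
        w = self.filters.reshape(n, -1)
        if np.max(np.abs(w.sum(axis=1))) > 1e-6:
            raise ValueError("filters must have zero DC response")
        if np.linalg.matrix_rank(w) < n:
            raise ValueError("filters must be linearly independent")


def pink_noise_images(n_images: int, shape: tuple[int, int],
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded noise with a 1/f^2 power spectrum (natural-image surrogate)."""
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.sqrt(fy ** 2 + fx ** 2)
    f[0, 0] = 1.0
    amp = 1.0 / f
    out = []
    for _ in range(n_images):
        phase = rng.uniform(0, 2 * np.pi, size=(h, w))
        spectrum = amp * np.exp(1j * phase)
        img = np.real(np.fft.ifft2(spectrum))
        img = (img - img.min()) / (np.ptp(img) or 1.0) * 255.0
        out.append(img)
    return out


def extract_patches(images: list[np.ndarray], l: int, n_patches: int,
                    rng: np.random.Generator) -> np.ndarray:
    patches = np.empty((n_patches, l * l))
    for i in range(n_patches):
        img = images[rng.integers(len(images))]
        y = rng.integers(img.shape[0] - l + 1)
        x = rng.integers(img.shape[1] - l + 1)
        patches[i] = img[y:y + l, x:x + l].ravel()
    return patches


def learn_filters(l: int, n: int = DEFAULT_BITS, seed: int = DEFAULT_BANK_SEED,
                  patch_source: list[np.ndarray] | None = None,
                  n_patches: int = 6000) -> BsifFilterBank:
    """Learn an ICA filter bank from image patches.

    Patches are per-patch mean-subtracted (which confines them to the
    zero-DC subspace, so every learned filter has zero sum), whitened to
    ``n`` principal components, and unmixed by fixed-point ICA.  Rows are
    canonicalized — unit norm, sorted by descending response variance on
    the training patches, sign fixed so the max-|coefficient| is
    positive — making the bank deterministic for a fixed seed.
    """
    if n > l * l - 1:
        raise ValueError(f"n={n} exceeds the l^2-1={l * l - 1} zero-DC budget")
    rng = np.random.default_rng(seed)
    if patch_source is None:
        patch_source = pink_noise_images(24, (96, 96), rng)
    need = 50 * l * l
    avail = sum(max(0, (im.shape[0] - l + 1) * (im.shape[1] - l + 1))
                for im in patch_source)
    if avail < need:
        raise ValueError(f"too few patches available ({avail} < {need})")
    patches = extract_patches(patch_source, l, max(n_patches, need), rng)
    patches -= patches.mean(axis=1, keepdims=True)
    ica = FastICA(n_components=n, whiten="unit-variance", max_iter=5000,
                  tol=1e-4, random_state=int(rng.integers(2 ** 31)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        ica.fit(patches)
    w = ica.components_.copy()
    w -= w.mean(axis=1, keepdims=True)          # exact zero-DC
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    var = ((patches @ w.T) ** 2).mean(axis=0)
    w = w[np.argsort(-var)]
    for i in range(n):
        j = np.argmax(np.abs(w[i]))
        if w[i, j] < 0:
            w[i] = -w[i]
    return BsifFilterBank(w.reshape(n, l, l), provenance=f"learned(seed={seed})")


def save_bank(bank: BsifFilterBank, path: str | os.PathLike) -> None:
    """Store a bank as CSV (one filter per row) plus a JSON header."""
    n, l, _ = bank.filters.shape
    np.savetxt(path, bank.filters.reshape(n, -1), delimiter=",")
    with open(os.fspath(path) + ".json", "w") as fh:
        json.dump({"l": l, "n": n, "provenance": bank.provenance}, fh)


def load_bank(path: str | os.PathLike) -> BsifFilterBank:
    with open(os.fspath(path) + ".json") as fh:
        head = json.load(fh)
    mat = np.loadtxt(path, delimiter=",", ndmin=2)
    return BsifFilterBank(mat.reshape(head["n"], head["l"], head["l"]),
                          provenance=f"loaded({os.fspath(path)})")


def bsif_responses(image: np.ndarray, bank: BsifFilterBank) -> np.ndarray:
    """Raw filter responses s_i = w_i^T x over every interior neighborhood."""
    image = np.asarray(image, dtype=np.float64)
    resp = np.stack([convolve2d(image, f[::-1, ::-1], mode="valid")
                     for f in bank.filters], axis=-1)
    resp[np.abs(resp) < 1e-9] = 0.0     # exact zero on constant regions
    return resp


def encode_responses(responses: np.ndarray, th: float, size: int) -> LabelImage:
    m = (size - 1) // 2
    bits = responses > th
    codes = (bits << np.arange(responses.shape[-1])).sum(axis=-1)
    return LabelImage(codes, 2 ** responses.shape[-1], (m, m))


def bsif_encode(image: np.ndarray, bank: BsifFilterBank,
                th: float = 0.0) -> LabelImage:
    """n-bit BSIF label image: bit i set iff s_i > th."""
    return encode_responses(bsif_responses(image, bank), th, bank.size)


def bsif_histogram(image: np.ndarray, bank: BsifFilterBank,
                   th: float = 0.0) -> np.ndarray:
    """Normalized 2^n-bin histogram of BSIF labels over the valid region."""
    return bsif_encode(image, bank, th).histogram()


_BANK_CACHE: dict[tuple[int, int, int], BsifFilterBank] = {}


def default_bank(l: int, n: int = DEFAULT_BITS,
                 seed: int = DEFAULT_BANK_SEED) -> BsifFilterBank:
    key = (l, n, seed)
    if key not in _BANK_CACHE:
        _BANK_CACHE[key] = learn_filters(l, n, seed)
    return _BANK_CACHE[key]


def bsif_channel_grid(mode: str = "full") -> list[tuple[int, float]]:
    """(size, threshold) pairs for a named ensemble mode."""
    if mode == "baseline":
        return [(7, 0.0)]
    if mode == "size":
        return [(l, 0.0) for l in BSIF_SIZES]
    if mode == "full":
        return [(l, float(th)) for l in BSIF_SIZES for th in BSIF_THRESHOLDS]
    raise ValueError(f"unknown BSIF mode {mode!r}; use baseline, size or full")


def build_bsif_channels(image: np.ndarray, mode: str = "full",
                        banks: dict[int, BsifFilterBank] | None = None,
                        ) -> list[tuple[str, np.ndarray]]:
    """Tagged BSIF histogram channels for one image.

    Filter responses are computed once per size and re-thresholded for
    each th, so ``full`` costs barely more than ``size``.
    """
    grid = bsif_channel_grid(mode)
    sizes = sorted({l for l, _ in grid})
    channels = []
    resp = {}
    for l in sizes:
        bank = (banks or {}).get(l) or default_bank(l)
        resp[l] = (bsif_responses(image, bank), bank.size)
    for l, th in grid:
        r, size = resp[l]
        hist = encode_responses(r, th, size).histogram()
        tag = f"bsif_size{l}_th{int(th)}"
        channels.append((tag, hist))
    return channels
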