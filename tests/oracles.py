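"""Independent brute-force oracles used to validate the descriptors.

Everything here is written with explicit Python loops and its own
helper arithmetic (bit fiddling via strings, bilinear interpolation by
hand), deliberately sharing no code with the package implementation.
"""

import numpy as np


def bilinear(image, y, x):
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    ty, tx = y - y0, x - x0
    y1 = y0 + 1 if ty > 0 else y0
    x1 = x0 + 1 if tx > 0 else x0
    return ((1 - ty) * (1 - tx) * image[y0, x0]
            + (1 - ty) * tx * image[y0, x1]
            + ty * (1 - tx) * image[y1, x0]
            + ty * tx * image[y1, x1])


def circle_positions(radius, points):
    out = []
    for k in range(points):
        a = 2 * np.pi * k / points
        dy, dx = -radius * np.sin(a), radius * np.cos(a)
        if abs(dy) < 1e-12:
            dy = 0.0
        if abs(dx) < 1e-12:
            dx = 0.0
        out.append((dy, dx))
    return out


def is_uniform(bits):
    """<= 2 transitions along the circular bit string."""
    t = sum(bits[i] != bits[(i + 1) % len(bits)] for i in range(len(bits)))
    return t <= 2


def u2_bin(bits):
    """Bin index of a bit tuple under the u2 mapping (code-value order)."""
    p = len(bits)
    code = sum(b << i for i, b in enumerate(bits))
    uniform_codes = [c for c in range(1 << p)
                     if is_uniform([(c >> i) & 1 for i in range(p)])]
    if code in uniform_codes:
        return uniform_codes.index(code)
    return len(uniform_codes)


def u2_bins(p):
    return p * (p - 1) + 2 + 1


def lbp_histogram_oracle(image, radius, points):
    """Nested-loop multi-bin u2 LBP histogram over the valid region."""
    m = int(np.ceil(radius))
    h, w = image.shape
    counts = np.zeros(u2_bins(points))
    for y in range(m, h - m):
        for x in range(m, w - m):
            bits = []
            for dy, dx in circle_positions(radius, points):
                q = bilinear(image, y + dy, x + dx)
                bits.append(1 if q - image[y, x] >= 0 else 0)
            counts[u2_bin(tuple(bits))] += 1
    return counts / counts.sum()


def ltp_histogram_oracle(image, radius, points, tau):
    """(positive, negative) u2 histograms of the ternary coding."""
    m = int(np.ceil(radius))
    h, w = image.shape
    pos = np.zeros(u2_bins(points))
    neg = np.zeros(u2_bins(points))
    for y in range(m, h - m):
        for x in range(m, w - m):
            pbits, nbits = [], []
            for dy, dx in circle_positions(radius, points):
                diff = bilinear(image, y + dy, x + dx) - image[y, x]
                pbits.append(1 if diff >= tau else 0)
                nbits.append(1 if diff < -tau else 0)
            pos[u2_bin(tuple(pbits))] += 1
            neg[u2_bin(tuple(nbits))] += 1
    return pos / pos.sum(), neg / neg.sum()


def lpq_labels_oracle(image, r, a, rho):
    """Binary LPQ labels by explicit per-window computation.

    Rebuilds the DC-corrected STFT kernels, the correlation model and
    the SVD whitening from first principles with loops.
    """
    mh = (r - 1) // 2
    f = a / r
    freqs = [(f, 0.0), (0.0, f), (f, f), (f, -f)]
    window = [(j, i) for j in range(-mh, mh + 1) for i in range(-mh, mh + 1)]
    kernels = []
    for uy, ux in freqs:
        vals = [np.exp(-2j * np.pi * (uy * j + ux * i)) for j, i in window]
        mean = sum(vals) / len(vals)
        kernels.append([v - mean for v in vals])
    rows = []
    for k in kernels:
        rows.append([v.real for v in k])
        rows.append([v.imag for v in k])
    m_mat = np.array(rows)
    cov = np.array([[rho ** np.hypot(j1 - j2, i1 - i2)
                     for (j2, i2) in window] for (j1, i1) in window])
    d_mat = m_mat @ cov @ m_mat.T
    evals, evecs = np.linalg.eigh(d_mat)
    vt = (evecs / np.sqrt(np.maximum(np.abs(evals), 1e-12))) @ evecs.T
    h, w = image.shape
    labels = np.zeros((h - 2 * mh, w - 2 * mh), dtype=int)
    for y in range(mh, h - mh):
        for x in range(mh, w - mh):
            patch = [image[y + j, x + i] for j, i in window]
            comp = []
            for k in kernels:
                s = sum(p * v for p, v in zip(patch, k))
                comp.extend([s.real, s.imag])
            white = vt @ np.array(comp)
            white[np.abs(white) < 1e-8] = 0.0
            code = sum((1 << i) for i in range(8) if white[i] > 0)
            labels[y - mh, x - mh] = code
    return labels


def wld_histogram_oracle(image, e_bins, o_bins):
    h, w = image.shape
    counts = np.zeros(e_bins * o_bins)
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            acc = sum(image[y + dy, x + dx] - image[y, x]
                      for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                      if (dy, dx) != (0, 0))
            xi = np.arctan(acc / (image[y, x] + 1.0))
            gy = image[y + 1, x] - image[y - 1, x]
            gx = image[y, x + 1] - image[y, x - 1]
            theta = np.arctan2(gy, gx) % (2 * np.pi)
            e = min(int((xi + np.pi / 2) / np.pi * e_bins), e_bins - 1)
            o = min(int(theta / (2 * np.pi) * o_bins), o_bins - 1)
            counts[e * o_bins + o] += 1
    return counts / counts.sum()


def riclbp_orbit_count_oracle(points, n_dirs=4):
    """Number of rotation orbits of (code, code, direction) triples."""
    def rot(c, k):
        k %= points
        return ((c << k) | (c >> (points - k))) & ((1 << points) - 1)

    step = points // 4
    seen = set()
    n_orbits = 0
    for c1 in range(1 << points):
        for c2 in range(1 << points):
            for d in range(n_dirs):
                if (c1, c2, d) in seen:
                    continue
                n_orbits += 1
                cur = (c1, c2, d)
                while cur not in seen:
                    seen.add(cur)
                    a, b, dd = cur
                    a, b = rot(a, step), rot(b, step)
                    dd += 2
                    if dd >= n_dirs:
                        a, b, dd = b, a, dd - n_dirs
                    cur = (a, b, dd)
    return n_orbits


def auc_pair_count_oracle(scores, positives):
    """AUC by exhaustive concordant-pair counting (ties count half)."""
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
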