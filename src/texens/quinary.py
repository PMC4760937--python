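"""Multi-quinary coding over geometric loci.

The quinary coding generalizes LBP's binary thresholding of the
neighbor-minus-centre difference x to five levels via two thresholds
0 < tau1 < tau2:

    s(x) =  2  if x >= tau2
            1  if tau1 <= x < tau2
            0  if -tau1 <= x < tau1
           -1  if -tau2 <= x < -tau1
           -2  otherwise

Each quinary pattern is split into four binary patterns (one per digit
value c in {2, 1, -1, -2}), histogrammed with the u2 mapping, and the
four blocks concatenated.  The multi-threshold version (MLQP) uses the
grid tau1 in {1,3,5,7,9}, tau2 = tau1 + {2,4,6,8,10} (25 pairs), and the
neighborhood may follow non-circular geometric loci (ellipse, parabola,
hyperbola, spiral; rotated by 0/45/90/135 deg) to capture anisotropy.
MLCP applies the same machinery to the LCP feature; MLPQ/MLPQens are the
multi-threshold ternary variants of LPQ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import (LabelImage, DescriptorLabels, circle_offsets,
                          lcp_features_from_patterns, lpq_labels,
                          neighbor_stack)
from .mapping import mapping_table


@dataclass(frozen=True)
class QuinaryThresholds:
    tau1: float
    tau2: float

    def __post_init__(self):
        if not (0 < self.tau1 < self.tau2):
            raise ValueError("require 0 < tau1 < tau2")


#: tau1 in {1,3,5,7,9}, tau2 = tau1 + {2,4,6,8,10}: the 25 threshold pairs
MLQP_THRESHOLDS: tuple[QuinaryThresholds, ...] = tuple(
    QuinaryThresholds(t1, t1 + dt)
    for t1 in (1, 3, 5, 7, 9) for dt in (2, 4, 6, 8, 10))

MLPQ_TAUS = (0.2, 0.4, 0.6, 0.8, 1.0)
MLPQENS_TAUS = (0.2, 0.5, 0.8)
MLPQENS_RS = (3, 5)
MLPQENS_AS = (0.8, 1.2, 1.6, 2.0)
MLPQENS_RHOS = (0.75, 1.15, 1.55, 1.95)


def quinary_encode(x, th: QuinaryThresholds):
    """Quinary digit(s) of an intensity difference; accepts arrays."""
    x = np.asarray(x, dtype=np.float64)
    d = np.zeros(x.shape, dtype=np.int64)
    d[x >= th.tau2] = 2
    d[(x >= th.tau1) & (x < th.tau2)] = 1
    d[(x < -th.tau1) & (x >= -th.tau2)] = -1
    d[x < -th.tau2] = -2
    return d if d.shape else int(d)


def split_quinary(digits: np.ndarray) -> tuple[np.ndarray, ...]:
    """Four binary patterns b_c, c = 2, 1, -1, -2 in that order."""
    digits = np.asarray(digits)
    return tuple((digits == c).astype(np.int64) for c in (2, 1, -1, -2))


# ---------------------------------------------------------------------------
# geometric loci

@dataclass(frozen=True)
class GeometricLocus:
    """A sampled neighborhood curve around the centre pixel.

    kind/params per curve: circle(r), ellipse(a,b), parabola(c),
    hyperbola(a,b), spiral(a,b); beta rotates the point set (the circle
    is rotation-free); P is the number of sampling points.
    """

    kind: str
    params: tuple[float, ...]
    beta: float = 0.0          # degrees
    points: int = 8

    def __post_init__(self):
        if self.points < 4:
            raise ValueError("need at least 4 sampling points")
        if any(p < 0 for p in self.params):
            raise ValueError("locus parameters must be non-negative")
        if self.kind == "circle" and self.beta != 0.0:
            raise ValueError("the circle is rotation-free; beta must be 0")

    @property
    def tag(self) -> str:
        p = "_".join(f"{v:g}" for v in self.params)
        return f"{self.kind}({p})b{int(self.beta)}"


def locus_points(locus: GeometricLocus) -> np.ndarray:
    """(dy, dx) offsets of the locus sampling points (pixel units).

    Sampling is uniform in the curve parameter: angle for circle and
    ellipse, the hyperbolic parameter t (both branches, P/2 points each,
    |x| <= 2a) for the hyperbola, the abscissa in [-2c, 2c] for the
    parabola, and theta in [0, 4*pi] for the spiral r = a + b*theta.
    """
    kind, params, p = locus.kind, locus.params, locus.points
    if kind == "circle":
        (r,) = params
        if r <= 0:
            raise ValueError("degenerate circle")
        return circle_offsets(r, p)
    if kind == "ellipse":
        a, b = params
        if a <= 0 or b <= 0:
            raise ValueError("degenerate ellipse")
        t = 2 * np.pi * np.arange(p) / p
        xy = np.column_stack([a * np.cos(t), b * np.sin(t)])
    elif kind == "parabola":
        (c,) = params
        if c <= 0:
            raise ValueError("degenerate parabola")
        x = np.linspace(-2 * c, 2 * c, p)
        xy = np.column_stack([x, -x ** 2 / (2 * c) + c / 2])
    elif kind == "hyperbola":
        a, b = params
        if a <= 0 or b <= 0:
            raise ValueError("degenerate hyperbola")
        if p % 2:
            raise ValueError("hyperbola needs an even number of points")
        tmax = np.arccosh(2.0)          # reach |x| = 2a
        t = np.linspace(-tmax, tmax, p // 2)
        right = np.column_stack([a * np.cosh(t), b * np.sinh(t)])
        left = np.column_stack([-a * np.cosh(t), b * np.sinh(t)])
        xy = np.vstack([right, left])
    elif kind == "spiral":
        a, b = params
        if a <= 0:
            raise ValueError("degenerate spiral")
        theta = np.linspace(0, 4 * np.pi, p, endpoint=False)
        r = a + b * theta
        xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    else:
        raise ValueError(f"unknown locus kind {locus.kind!r}")
    beta = np.deg2rad(locus.beta)
    rot = np.array([[np.cos(beta), -np.sin(beta)],
                    [np.sin(beta), np.cos(beta)]])
    xy = xy @ rot.T
    # convert math (x, y up) to image (dy down, dx right) offsets
    off = np.column_stack([-xy[:, 1], xy[:, 0]])
    off[np.abs(off) < 1e-12] = 0.0
    return off


def default_loci(points: int = 8) -> tuple[GeometricLocus, ...]:
    """Circle + 4 rotations of ellipse/parabola/hyperbola/spiral (17 loci)."""
    loci = [GeometricLocus("circle", (1.0,), 0.0, points)]
    families = [("ellipse", (2.0, 1.0)), ("parabola", (1.0,)),
                ("hyperbola", (1.0, 1.0)), ("spiral", (1.0, 0.2))]
    for kind, params in families:
        for beta in (0.0, 45.0, 90.0, 135.0):
            loci.append(GeometricLocus(kind, params, beta, points))
    return tuple(loci)


CIRCLE_ONLY = (GeometricLocus("circle", (1.0,), 0.0, 8),)


# ---------------------------------------------------------------------------
# channel builders

def _quinary_patterns(image, locus: GeometricLocus, th: QuinaryThresholds):
    stack, center, m = neighbor_stack(np.asarray(image, float),
                                      locus_points(locus))
    digits = quinary_encode(stack - center[:, :, None], th)
    weights = 1 << np.arange(locus.points)
    return [((pat * weights).sum(axis=2), m)
            for pat in split_quinary(digits)], stack, center


def mlqp_channel(image, th: QuinaryThresholds, locus: GeometricLocus,
                 mapping: str = "u2") -> np.ndarray:
    """One LQP channel: four u2-mapped binary-pattern histograms, concatenated."""
    pats, _, _ = _quinary_patterns(image, locus, th)
    table, n_bins = mapping_table(locus.points, mapping)
    groups = tuple((LabelImage(table[codes], n_bins, (m, m)),)
                   for codes, m in pats)
    return DescriptorLabels(groups).histogram()


def mlqp_channels(image, thresholds=MLQP_THRESHOLDS, loci=CIRCLE_ONLY,
                  mapping: str = "u2") -> list[tuple[str, np.ndarray]]:
    """The MLQP channel grid, ordered threshold-major then locus."""
    return [(f"mlqp_t{th.tau1:g}_{th.tau2:g}_{locus.tag}",
             mlqp_channel(image, th, locus, mapping))
            for th in thresholds for locus in loci]


def mlcp_channel(image, th: QuinaryThresholds, locus: GeometricLocus,
                 ) -> np.ndarray:
    """One MLCP channel: the LCP feature per quinary binary pattern.

    For each of the four binary patterns, riu2 pattern classes are formed
    and the LCP construction (reconstruction-weight DFT magnitudes +
    occurrence histogram) is applied; the four blocks are concatenated.
    """
    pats, stack, center = _quinary_patterns(image, locus, th)
    table, n_bins = mapping_table(locus.points, "riu2")
    blocks = []
    for codes, _m in pats:
        blocks.append(lcp_features_from_patterns(
            stack, center, table[codes], n_bins))
    return np.concatenate(blocks)


def mlcp_channels(image, thresholds=MLQP_THRESHOLDS, loci=CIRCLE_ONLY,
                  ) -> list[tuple[str, np.ndarray]]:
    return [(f"mlcp_t{th.tau1:g}_{th.tau2:g}_{locus.tag}",
             mlcp_channel(image, th, locus))
            for th in thresholds for locus in loci]


def mlpq_channels(image, mode: str = "mlpq") -> list[tuple[str, np.ndarray]]:
    """Multi-threshold ternary LPQ channels.

    ``mlpq``: 5 channels (thresholds {0.2,0.4,0.6,0.8,1}), each the
    concatenation of window sizes r = 3 and 5.  ``mlpqens``: the 96-way
    grid r x a x rho x tau = 2 x 4 x 4 x 3, one channel each.
    """
    if mode == "mlpq":
        return [(f"mlpq_tau{tau:g}",
                 lpq_labels(image, rs=(3, 5), ternary_tau=tau).histogram())
                for tau in MLPQ_TAUS]
    if mode == "mlpqens":
        out = []
        for r in MLPQENS_RS:
            for a in MLPQENS_AS:
                for rho in MLPQENS_RHOS:
                    for tau in MLPQENS_TAUS:
                        hist = lpq_labels(image, rs=(r,), a=a, rho=rho,
                                          ternary_tau=tau).histogram()
                        out.append((f"mlpqens_r{r}_a{a:g}_rho{rho:g}_tau{tau:g}",
                                    hist))
        return out
    raise ValueError(f"unknown MLPQ mode {mode!r}; use 'mlpq' or 'mlpqens'")
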