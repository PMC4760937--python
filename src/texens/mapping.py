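"""Code-alphabet reductions for binary-pattern descriptors.

``u2`` groups the 2^P circular binary patterns by "uniformity": patterns
with at most two 0/1 transitions along the circle keep individual bins
(P*(P-1)+2 of them) and all remaining patterns share one bin.  ``riu2``
additionally merges rotation orbits, leaving P+2 bins indexed by the
number of set bits (plus one non-uniform bin).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def transitions(code: int, p: int) -> int:
    """Number of 0/1 transitions in the circular P-bit pattern."""
    rotated = ((code << 1) | (code >> (p - 1))) & ((1 << p) - 1)
    return bin(code ^ rotated).count("1")


def rotate_code(code: int, p: int, k: int = 1) -> int:
    """Rotate a P-bit circular code left by k bits."""
    k %= p
    mask = (1 << p) - 1
    return ((code << k) | (code >> (p - k))) & mask


@lru_cache(maxsize=None)
def uniform_table(p: int) -> tuple[np.ndarray, int]:
    """u2 lookup table mapping each P-bit code to its bin. -> (table, n_bins)"""
    n = 1 << p
    n_uniform = p * (p - 1) + 2
    table = np.full(n, n_uniform, dtype=np.int64)  # non-uniform bin = last
    nxt = 0
    for code in range(n):
        if transitions(code, p) <= 2:
            table[code] = nxt
            nxt += 1
    assert nxt == n_uniform
    return table, n_uniform + 1


@lru_cache(maxsize=None)
def rotation_invariant_uniform_table(p: int) -> tuple[np.ndarray, int]:
    """riu2 lookup table: uniform codes -> popcount bin, others -> bin P+1."""
    n = 1 << p
    table = np.full(n, p + 1, dtype=np.int64)
    for code in range(n):
        if transitions(code, p) <= 2:
            table[code] = bin(code).count("1")
    return table, p + 2


def mapping_table(p: int, mapping: str) -> tuple[np.ndarray, int]:
    """Lookup table for a named mapping: 'u2', 'riu2' or 'none'."""
    if mapping == "u2":
        return uniform_table(p)
    if mapping == "riu2":
        return rotation_invariant_uniform_table(p)
    if mapping == "none":
        return np.arange(1 << p, dtype=np.int64), 1 << p
    raise ValueError(f"unknown mapping {mapping!r}")
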