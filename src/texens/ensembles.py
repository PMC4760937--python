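"""Named ensemble configurations and their channel extractors.

An ensemble configuration is a '+'-separated list of terms in the
notation *preprocessing(descriptor)* — e.g. ``Comb(RICLBP)`` — plus
stand-alone terms (``Full_Bsif``, ``MLPQens``, ``MLCP``, ``COLORS``, or
a bare descriptor name meaning *O(descriptor)*).  Every term expands to
a list of tagged feature channels per image; one SVM is trained per
channel and all channels are fused by sum rule.
"""

from __future__ import annotations

import re
from functools import partial

import numpy as np
from PIL import Image

from . import bsif, quinary
from .descriptors import (colors_features, lbp_histogram, lcp_features,
                          ltp_histograms, multiscale_lpq_histogram,
                          riclbp_histogram, wld_histogram)
from .preproc import SCHEME_SIZES, build_preproc_set
from .regions import REGION_DESCRIPTORS, REGION_SCHEME_SIZES, \
    build_region_channels

#: descriptor name -> histogram function on a grayscale image
DESCRIPTOR_FUNCS = {
    "LBP": lbp_histogram,
    "LBP-ri": partial(lbp_histogram, mapping="riu2"),
    "LTP": ltp_histograms,
    "LTP-ri": partial(ltp_histograms, mapping="riu2"),
    "LPQ": multiscale_lpq_histogram,
    "LCP": lcp_features,
    "RICLBP": riclbp_histogram,
    "WLD": wld_histogram,
}

SPECIAL_TERMS = ("Bsif", "Size_Bsif", "Full_Bsif", "MLQP", "MLCP", "MLPQ",
                 "MLPQens", "COLORS")

_TERM_RE = re.compile(r"^(?P<scheme>[A-Za-z+]+)\((?P<desc>[A-Za-z-]+)\)$")


def _standalone(token: str) -> bool:
    return token.endswith(")") or token in SPECIAL_TERMS \
        or token in DESCRIPTOR_FUNCS


def parse_config(config: str) -> list[str]:
    """Split a configuration string into terms.

    '+' separates terms, but scheme names such as ``Wa+OR`` or ``All+O``
    also contain '+': a token that is not a complete term by itself is
    re-joined with its successor, so ``Wa+OR(LBP)`` parses as one term.
    """
    tokens = [t.strip() for t in config.split("+") if t.strip()]
    terms: list[str] = []
    buf = ""
    for tok in tokens:
        buf = f"{buf}+{tok}" if buf else tok
        if _standalone(buf):
            terms.append(buf)
            buf = ""
    if buf:
        raise ValueError(f"cannot parse ensemble term {buf!r} in {config!r}")
    return terms


def term_channels(term: str, gray: np.ndarray,
                  rgb: np.ndarray | None = None,
                  mlqp_loci=quinary.CIRCLE_ONLY,
                  ) -> list[tuple[str, np.ndarray]]:
    """Expand one configuration term into tagged feature channels."""
    if term == "Bsif":
        return bsif.build_bsif_channels(gray, mode="baseline")
    if term == "Size_Bsif":
        return bsif.build_bsif_channels(gray, mode="size")
    if term == "Full_Bsif":
        return bsif.build_bsif_channels(gray, mode="full")
    if term == "MLQP":
        return quinary.mlqp_channels(gray, loci=mlqp_loci)
    if term == "MLCP":
        return quinary.mlcp_channels(gray, loci=mlqp_loci)
    if term == "MLPQ":
        return quinary.mlpq_channels(gray, mode="mlpq")
    if term == "MLPQens":
        return quinary.mlpq_channels(gray, mode="mlpqens")
    if term == "COLORS":
        if rgb is None:
            raise ValueError("COLORS requires an RGB image")
        return [("colors", colors_features(rgb))]
    if term in DESCRIPTOR_FUNCS:                 # bare descriptor = O(desc)
        return [(f"O:orig/{term}", DESCRIPTOR_FUNCS[term](gray))]
    m = _TERM_RE.match(term)
    if not m:
        raise ValueError(
            f"unknown ensemble term {term!r}; valid terms are "
            f"scheme(descriptor) with schemes {sorted(SCHEME_SIZES)} / "
            f"{sorted(REGION_SCHEME_SIZES)}, descriptors "
            f"{sorted(DESCRIPTOR_FUNCS)}, or one of {SPECIAL_TERMS}")
    scheme, desc = m.group("scheme"), m.group("desc")
    if scheme in SCHEME_SIZES:
        if desc not in DESCRIPTOR_FUNCS:
            raise ValueError(f"unknown descriptor {desc!r}; "
                             f"known: {sorted(DESCRIPTOR_FUNCS)}")
        func = DESCRIPTOR_FUNCS[desc]
        return [(f"{scheme}:{tag}/{desc}", func(img))
                for tag, img in build_preproc_set(gray, scheme)]
    if scheme in REGION_SCHEME_SIZES:
        if desc.lower() not in REGION_DESCRIPTORS:
            raise ValueError(
                f"region schemes support descriptors {REGION_DESCRIPTORS}, "
                f"not {desc!r}")
        return [(f"{scheme}:{tag}", h) for tag, h in
                build_region_channels(gray, desc.lower(), scheme)]
    raise ValueError(f"unknown scheme {scheme!r} in term {term!r}")


def extract_channels(config: str, gray: np.ndarray,
                     rgb: np.ndarray | None = None,
                     mlqp_loci=quinary.CIRCLE_ONLY,
                     ) -> list[tuple[str, np.ndarray]]:
    """All tagged channels of a configuration for one image."""
    channels = []
    for term in parse_config(config):
        channels.extend(term_channels(term, gray, rgb, mlqp_loci))
    return channels


def load_rgb(path: str) -> np.ndarray | None:
    """The RGB pixel array of an image file, or None if it is grayscale."""
    with Image.open(path) as im:
        im.load()
        arr = np.asarray(im, dtype=np.float64)
    return arr[..., :3] if arr.ndim == 3 else None


#: Representative experiment configurations, one per reported table row,
#: runnable against any manifest (the published microscopy dataset or the
#: synthetic fixture).
TABLE_CONFIGS: dict[str, str] = {
    # stand-alone descriptors and their fusions
    "LBP": "O(LBP)",
    "LTP": "O(LTP)",
    "LPQ": "O(LPQ)",
    "LCP": "O(LCP)",
    "RICLBP": "O(RICLBP)",
    "WLD": "O(WLD)",
    "MLQP": "MLQP",
    "MLCP": "MLCP",
    "MLPQ": "MLPQ",
    "MLPQens": "MLPQens",
    "RICLBP+MLPQens": "RICLBP+MLPQens",
    "RICLBP+MLPQens+MLCP": "RICLBP+MLPQens+MLCP",
    # preprocessing ensembles (shown here for RICLBP, the best stand-alone)
    "Wa(RICLBP)": "Wa(RICLBP)",
    "WaH(RICLBP)": "WaH(RICLBP)",
    "OR(RICLBP)": "OR(RICLBP)",
    "Ga(RICLBP)": "Ga(RICLBP)",
    "Wa+OR(RICLBP)": "Wa+OR(RICLBP)",
    "Wa+OR+Ga(RICLBP)": "Wa+OR+Ga(RICLBP)",
    "Comb(RICLBP)": "Comb(RICLBP)",
    # region-based ensembles
    "Edge(LTP)": "Edge(LTP)",
    "DoG(LTP)": "DoG(LTP)",
    "Saliency(LTP)": "Saliency(LTP)",
    "Wavelet(LTP)": "Wavelet(LTP)",
    "Saliency+Wavelet(LTP)": "Saliency+Wavelet(LTP)",
    "All(LTP)": "All(LTP)",
    "All+O(LTP)": "All+O(LTP)",
    # BSIF ensembles
    "Bsif": "Bsif",
    "Size_Bsif": "Size_Bsif",
    "Full_Bsif": "Full_Bsif",
    # headline ensembles
    "final": "Comb(RICLBP)+Full_Bsif+MLPQens+MLCP",
    "final+COLORS": "Comb(RICLBP)+Full_Bsif+MLPQens+MLCP+COLORS",
}
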