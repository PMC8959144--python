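"""Histogram-matching intensity normalization.

Fluorescence intensity varies between animals and imaging sessions; to make
signal comparable across a cohort, every image is remapped so its intensity
histogram matches that of one representative reference case.  The map is
the classical discrete CDF-quantile assignment: source intensity s goes to
the smallest reference intensity whose cumulative frequency reaches the
cumulative frequency of s.  The lookup is monotone non-decreasing (pixel
intensity ordering is preserved, ties may merge) and reapplying it against
the same reference is the identity.
"""

from __future__ import annotations

import numpy as np

from ponsquant.types import SectionImage


def image_histogram(img: SectionImage | np.ndarray, bit_depth: int | None = None) -> np.ndarray:
    """Intensity histogram over the full bit range (length 2**bit_depth)."""
    if isinstance(img, SectionImage):
        pixels, depth = img.pixels, img.bit_depth
    else:
        pixels = np.asarray(img)
        depth = bit_depth if bit_depth is not None else (8 if pixels.dtype == np.uint8 else 16)
    n = 2**depth
    return np.bincount(pixels.ravel().astype(np.int64), minlength=n)[:n]


def build_histogram_map(
    source_hist: np.ndarray, reference_hist: np.ndarray
) -> np.ndarray:
    """Monotone lookup sending source intensities onto the reference CDF.

    Both histograms must span the same bit range.  Each occupied source bin
    s maps to the lowest reference intensity r with
    CDF_ref(r) ≥ CDF_src(s); plateaus therefore resolve deterministically
    to the lowest attaining intensity.
    """
    src = np.asarray(source_hist, dtype=float)
    ref = np.asarray(reference_hist, dtype=float)
    if src.shape != ref.shape:
        raise ValueError("histograms must cover the same bit range")
    if src.sum() == 0 or ref.sum() == 0:
        raise ValueError("empty histogram")
    cdf_src = np.cumsum(src) / src.sum()
    cdf_ref = np.cumsum(ref) / ref.sum()
    # smallest r with cdf_ref[r] >= cdf_src[s]; guard float round-off so a
    # shared quantile maps onto itself
    lookup = np.searchsorted(cdf_ref, cdf_src - 1e-12, side="left")
    return np.minimum(lookup, len(ref) - 1).astype(np.int64)


def apply_histogram_map(img: SectionImage, lookup: np.ndarray) -> SectionImage:
    """Pixel-wise application of a histogram map (same bit depth required)."""
    if len(lookup) != 2**img.bit_depth:
        raise ValueError(
            f"lookup length {len(lookup)} does not match bit depth {img.bit_depth}"
        )
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    return img.with_pixels(lookup[img.pixels.astype(np.int64)].astype(dtype))


def match_histogram(img: SectionImage, reference: SectionImage) -> SectionImage:
    """Remap one section so its histogram matches the reference case."""
    if img.bit_depth != reference.bit_depth:
        raise ValueError("image and reference bit depths differ")
    lookup = build_histogram_map(image_histogram(img), image_histogram(reference))
    return apply_histogram_map(img, lookup)


def max_cdf_discrepancy(hist_a: np.ndarray, hist_b: np.ndarray) -> float:
    """Sup-norm distance between two histograms' CDFs (a matching metric)."""
    a = np.asarray(hist_a, dtype=float)
    b = np.asarray(hist_b, dtype=float)
    return float(np.abs(np.cumsum(a) / a.sum() - np.cumsum(b) / b.sum()).max())
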