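"""Two-channel colocalization statistics and masked ratio imaging.

Three complementary statistics are provided.  Pearson's correlation
coefficient measures pixel-by-pixel covariance of the two signals
independently of their absolute intensities (1 = complete positive
correlation, -1 = exclusion, 0 = no correlation).  Li's intensity
correlation quotient (ICQ) is the fraction of pixels whose mean-centred
intensities covary positively, minus 0.5, so it runs from -0.5 (mutually
exclusive staining) through 0 (random) to +0.5 (dependent staining).
Manders' overlap coefficients M1/M2 quantify fractional overlap of
above-threshold signal in each channel with the other, from 0 to 1.

Conventions: ICQ counts zero-product pixels (a pixel exactly at either
channel mean) as non-positive — they stay in the denominator.  M1/M2 default
to the pixel-count form; an intensity-weighted form is available via
``weighted=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu


@dataclass(frozen=True)
class ColocResult:
    pearson_cc: float
    icq: float
    m1: float
    m2: float
    thresholds: tuple[float, float]
    n_pixels: int


def _masked_flat(A, B, mask):
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("channels must share a shape")
    if mask is None:
        return A.ravel(), B.ravel()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != A.shape:
        raise ValueError("mask must share the channel shape")
    return A[mask], B[mask]


def _check_nonconstant(a, b):
    if a.size < 2:
        raise ValueError("need at least 2 masked pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant channel")


def pearson_cc(A, B, mask=None) -> float:
    """Pearson product-moment correlation over (masked) pixels."""
    a, b = _masked_flat(A, B, mask)
    _check_nonconstant(a, b)
    return float(np.corrcoef(a, b)[0, 1])


def li_icq(A, B, mask=None) -> float:
    """Li's intensity correlation quotient over (masked) pixels."""
    a, b = _masked_flat(A, B, mask)
    _check_nonconstant(a, b)
    prod = (a - a.mean()) * (b - b.mean())
    return float((prod > 0).mean() - 0.5)


def manders_overlap(A, B, thrA: float, thrB: float, weighted: bool = False):
    """Manders' overlap coefficients (M1, M2) at fixed channel thresholds.

    M1 = fraction of channel-A-positive pixels (A > thrA) that are also
    channel-B-positive; M2 symmetric.  ``weighted=True`` weights pixels by
    their channel intensity instead of counting them.
    """
    if thrA < 0 or thrB < 0:
        raise ValueError("thresholds must be >= 0")
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("channels must share a shape")
    in_a = A > thrA
    in_b = B > thrB
    if not in_a.any() or not in_b.any():
        raise ValueError("no above-threshold pixels in one channel")
    both = in_a & in_b
    if weighted:
        m1 = float(A[both].sum() / A[in_a].sum())
        m2 = float(B[both].sum() / B[in_b].sum())
    else:
        m1 = float(both.sum() / in_a.sum())
        m2 = float(both.sum() / in_b.sum())
    return m1, m2


def coloc_stats(A, B, mask=None, thrA=None, thrB=None) -> ColocResult:
    """All three statistics at once; thresholds default to Otsu per channel."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if thrA is None:
        thrA = float(threshold_otsu(A))
    if thrB is None:
        thrB = float(threshold_otsu(B))
    m1, m2 = manders_overlap(A, B, thrA, thrB)
    a, _ = _masked_flat(A, B, mask)
    return ColocResult(
        pearson_cc=pearson_cc(A, B, mask),
        icq=li_icq(A, B, mask),
        m1=m1,
        m2=m2,
        thresholds=(thrA, thrB),
        n_pixels=int(a.size),
    )


def masked_ratio_image(numerator, denominator, mask_source, threshold=None):
    """Pixel-by-pixel ratio restricted to a structure mask.

    The mask is ``mask_source > threshold`` (Otsu if threshold is None); both
    inputs are multiplied by the binary mask and the ratio is computed only
    where the masked denominator is positive — all other pixels are NaN
    (undefined, not an error).
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    src = np.asarray(mask_source, dtype=float)
    if not (num.shape == den.shape == src.shape):
        raise ValueError("all rasters must share a shape")
    if threshold is None:
        threshold = float(threshold_otsu(src))
    mask = src > threshold
    num_m = num * mask
    den_m = den * mask
    out = np.full(num.shape, np.nan)
    defined = den_m > 0
    out[defined] = num_m[defined] / den_m[defined]
    return out
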