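"""Entropy-based image thresholding and CT volumetry.

``yen_threshold`` implements Yen's maximum-entropic-correlation automatic
threshold on an intensity histogram: with normalised histogram ``p_i``,
cumulative mass ``P(t)`` and cumulative squared masses ``G1(t) = sum_{i<=t}
p_i^2`` and ``G2(t) = sum_{i>t} p_i^2``, the threshold maximises

    TC(t) = -ln( G1(t) * G2(t) / (P(t)^2 * (1 - P(t))^2) )

over all split points with both classes nonempty; ties break toward the lower
threshold, and the threshold bin belongs to the background (a pixel is
positive when strictly above the returned value).

``ct_volume`` counts voxels at or above a Hounsfield-unit threshold and
multiplies by the voxel volume; the study's thresholds are 800, 1250 and
1800 HU, optionally normalised by mean cortical thickness (mm).
"""

from __future__ import annotations

import numpy as np


class DegenerateImageError(ValueError):
    """Raised when an image has no intensity contrast to threshold."""


def yen_threshold(image, n_bins: int = 256) -> float:
    """Yen's automatic threshold of an intensity image.

    The histogram is built on `n_bins` equal-width bins spanning the image's
    intensity range; the returned value is the upper edge of the chosen
    background bin. Raises :class:`DegenerateImageError` on a constant image.
    """
    values = np.asarray(image, dtype=float).ravel()
    if not np.isfinite(values).all():
        raise ValueError("image contains non-finite values")
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise DegenerateImageError("constant image: threshold undefined")
    hist, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = hist / hist.sum()
    crit = yen_criterion(p)
    t = int(np.nanargmax(crit))
    return float(edges[t + 1])


def yen_criterion(p: np.ndarray) -> np.ndarray:
    """Yen's entropic correlation criterion at every split point.

    `p` is a normalised histogram; entry ``t`` of the result scores the split
    "bins 0..t = background, t+1.. = foreground". Splits leaving either class
    empty score ``-inf``. NaN-free for valid splits.
    """
    p = np.asarray(p, dtype=float)
    P = np.cumsum(p)
    g = np.cumsum(p**2)
    g_total = g[-1]
    crit = np.full(len(p) - 1, -np.inf)
    for t in range(len(p) - 1):
        P1 = P[t]
        P2 = 1.0 - P1
        if P1 <= 0 or P2 <= 0:
            continue
        g1 = g[t]
        g2 = g_total - g[t]
        if g1 <= 0 or g2 <= 0:
            continue
        crit[t] = -np.log(g1 * g2 / (P1**2 * P2**2))
    if not np.isfinite(crit).any():
        raise DegenerateImageError("no valid split point")
    return crit


def positive_fraction(image, threshold: float, pixel_area: float = None):
    """Fraction of pixels strictly above `threshold`.

    Returns the fraction, or ``(fraction, absolute_area)`` when `pixel_area`
    (area of one pixel) is given.
    """
    values = np.asarray(image, dtype=float)
    frac = float((values > threshold).mean()) if values.size else 0.0
    if pixel_area is not None:
        return frac, frac * values.size * pixel_area
    return frac


def positive_fraction_fields(images, threshold: float):
    """Per-field positive fractions and their mean over fields (hpf)."""
    fracs = [positive_fraction(img, threshold) for img in images]
    return fracs, float(np.mean(fracs))


def ct_volume(
    volume,
    hu_threshold: float,
    voxel_volume_mm3: float,
    cortical_thickness_mm: float = None,
):
    """Mineralised-tissue volume above a Hounsfield threshold.

    ``volume = #(voxels with HU >= hu_threshold) * voxel_volume_mm3``;
    boundary voxels are included. Returns the volume in mm^3, or
    ``(volume, volume / thickness)`` when a mean cortical thickness is given
    (mm^3 per mm, the congenital-phenotype normalisation).
    """
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel volume must be positive")
    arr = np.asarray(volume, dtype=float)
    vol = float((arr >= hu_threshold).sum()) * voxel_volume_mm3
    if cortical_thickness_mm is not None:
        if cortical_thickness_mm <= 0:
            raise ValueError("cortical thickness must be positive")
        return vol, vol / cortical_thickness_mm
    return vol
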