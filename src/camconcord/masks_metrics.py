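"""Binarization and agreement primitives for saliency maps.

Two saliency maps are compared after reducing each to the region the model
"mainly focused on": the [0,1]-normalised map is thresholded by Otsu's
method (a fixed threshold would not transfer across architectures, whose
activation scales differ), and the resulting binary masks are compared by
intersection-over-union.  Where the attention *is* matters too, so each
map's intensity-weighted centre of mass is computed and the Euclidean
distance between two centres is expressed as a fraction of the image
diagonal (CaD), making it resolution-independent.

The centre of mass supports two normalisations: ``mass`` (divide the
weighted coordinate sums by the total mass — the standard geometric CoM,
the default) and ``as_printed`` (divide by W*H, reproducing a variant whose
coordinates scale with the total mass).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .saliency import SaliencyMap

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMask",
    "CentreOfMass",
    "DegenerateMapError",
    "otsu_threshold",
    "binarize",
    "iou",
    "centre_of_mass",
    "cartesian_distance",
]


class DegenerateMapError(ValueError):
    """Raised when an operation requires a non-constant map."""


@dataclass
class BinaryMask:
    """Boolean attention mask with the threshold that produced it."""

    mask: np.ndarray  # (H, W) bool
    threshold: float
    source: tuple = ("", "", "")  # (image_id, model_id, method)


@dataclass
class CentreOfMass:
    """Intensity-weighted centroid of a saliency map.

    ``x_cm`` is the column coordinate and ``y_cm`` the row coordinate, in
    pixels (0-based, pixel centres at integers).  ``ref_size`` records the
    (W, H) grid the map lived on, so distances are only taken between
    centres computed on a common grid.
    """

    x_cm: float
    y_cm: float
    total_mass: float
    normalisation: str  # "mass" | "as_printed"
    ref_size: tuple[int, int] = (0, 0)  # (W, H)


def _values(map_or_array: Union[SaliencyMap, np.ndarray]) -> np.ndarray:
    if isinstance(map_or_array, SaliencyMap):
        return map_or_array.values
    return np.asarray(map_or_array, dtype=np.float64)


def otsu_threshold(map_or_array: Union[SaliencyMap, np.ndarray], bins: int = 256) -> float:
    """Otsu's threshold on a fixed ``bins``-bin histogram of [0, 1] values.

    Returns the bin edge maximising the between-class variance
    w0*w1*(mu0 - mu1)^2 of the split {values below the edge} vs {values at or
    above it}; ties break toward the lowest qualifying edge.  A constant map
    has no threshold and raises :class:`DegenerateMapError`.
    """
    v = _values(map_or_array).ravel()
    if v.min() < 0 or v.max() > 1:
        raise ValueError("otsu_threshold expects values in [0, 1]; normalise first")
    if v.max() == v.min():
        raise DegenerateMapError("constant map has no Otsu threshold")
    hist, edges = np.histogram(v, bins=bins, range=(0.0, 1.0))
    hist = hist.astype(np.float64)
    n = hist.sum()
    centres = (edges[:-1] + edges[1:]) / 2.0

    w0 = np.cumsum(hist)[:-1]  # mass strictly below edge i+1
    w1 = n - w0
    csum = np.cumsum(hist * centres)[:-1]
    total = float(np.sum(hist * centres))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (total - csum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    best = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximiser
    return float(edges[best + 1])


def binarize(
    map_or_array: Union[SaliencyMap, np.ndarray],
    threshold: float,
    source: tuple = ("", "", ""),
) -> BinaryMask:
    """Mask of pixels strictly above the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    v = _values(map_or_array)
    return BinaryMask(mask=v > threshold, threshold=float(threshold), source=source)


def iou(a: BinaryMask, b: BinaryMask) -> float:
    """Jaccard index |A∩B| / |A∪B| of two equal-shape masks.

    Two empty masks are defined as identical (IoU 1.0); a warning is logged
    because this usually signals degenerate saliency maps upstream.
    """
    ma = a.mask if isinstance(a, BinaryMask) else np.asarray(a, dtype=bool)
    mb = b.mask if isinstance(b, BinaryMask) else np.asarray(b, dtype=bool)
    if ma.shape != mb.shape:
        raise ValueError(f"mask shapes differ: {ma.shape} vs {mb.shape}")
    union = np.logical_or(ma, mb).sum()
    if union == 0:
        logger.warning("IoU of two empty masks defined as 1.0")
        return 1.0
    return float(np.logical_and(ma, mb).sum() / union)


def centre_of_mass(
    map_or_array: Union[SaliencyMap, np.ndarray], normalisation: str = "mass"
) -> CentreOfMass:
    """Intensity-weighted centroid of a non-negative map.

    ``mass`` mode divides the weighted coordinate sums by the total mass
    (standard centroid, always inside the grid); ``as_printed`` divides by
    the pixel count W*H instead.
    """
    if normalisation not in ("mass", "as_printed"):
        raise ValueError(f"unknown normalisation {normalisation!r}")
    p = _values(map_or_array)
    if p.ndim != 2:
        raise ValueError("centre_of_mass expects a 2-D map")
    if p.min() < 0:
        raise ValueError("centre_of_mass expects non-negative values")
    h, w = p.shape
    total = float(p.sum())
    yy, xx = np.mgrid[0:h, 0:w]
    sx = float((xx * p).sum())
    sy = float((yy * p).sum())
    if normalisation == "mass":
        if total == 0:
            raise DegenerateMapError("centre of mass undefined for zero total mass")
        x_cm, y_cm = sx / total, sy / total
    else:
        x_cm, y_cm = sx / (w * h), sy / (w * h)
    return CentreOfMass(
        x_cm=x_cm, y_cm=y_cm, total_mass=total,
        normalisation=normalisation, ref_size=(w, h),
    )


def cartesian_distance(c1: CentreOfMass, c2: CentreOfMass, W: int, H: int) -> float:
    """Euclidean distance between two centres, as a fraction of the diagonal.

    Both centres must have been computed on the (W, H) grid given.
    """
    for c in (c1, c2):
        if c.ref_size not in ((0, 0), (W, H)):
            raise ValueError(
                f"centre of mass computed on grid {c.ref_size}, expected {(W, H)}"
            )
    d = float(np.hypot(c1.x_cm - c2.x_cm, c1.y_cm - c2.y_cm))
    return d / float(np.hypot(W, H))
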