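"""From saliency map to bounding box.

The post-processing chain: apply the class's sign policy and take the
(signed or absolute) rectified saliency, blur with a normalised 5x5
Gaussian kernel to obtain a non-negative *confidence map*, threshold it
with the Isodata fixed-point rule, keep the largest connected component of
the mask, and fit the minimum axis-aligned rectangle around it.  Boxes use
0-based half-open ``[rmin, rmax) x [cmin, cmax)`` coordinates throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .network import Network
from .saliency import SaliencyMap, weighted_saliency

__all__ = [
    "BoundingBox",
    "LocalisationError",
    "confidence_map",
    "isodata_threshold",
    "largest_component_bbox",
    "localise",
    "iou",
]


class LocalisationError(RuntimeError):
    """A stage of the localisation chain failed (e.g. empty mask)."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle, half-open in both dimensions."""

    rmin: int
    cmin: int
    rmax: int
    cmax: int

    def __post_init__(self) -> None:
        if not (self.rmin < self.rmax and self.cmin < self.cmax):
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> int:
        return (self.rmax - self.rmin) * (self.cmax - self.cmin)


def _gaussian_kernel(size: int = 5, sigma: float = 1.0) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def confidence_map(s: SaliencyMap | np.ndarray, mode: str = "both",
                   sigma: float = 1.0) -> np.ndarray:
    """Rectify a saliency map per the sign policy and blur it.

    ``positive_only`` keeps ``max(S, 0)``, ``negative_only`` keeps
    ``max(-S, 0)``, ``both`` keeps ``|S|``; the result is smoothed with a
    unit-sum 5x5 Gaussian kernel and is non-negative everywhere.
    """
    values = np.asarray(getattr(s, "values", s), dtype=np.float64)
    if mode == "positive_only":
        rect = np.maximum(values, 0)
    elif mode == "negative_only":
        rect = np.maximum(-values, 0)
    elif mode == "both":
        rect = np.abs(values)
    else:
        raise ValueError(f"unknown sign mode {mode!r}")
    kernel = _gaussian_kernel(5, sigma)
    return ndimage.convolve(rect, kernel, mode="nearest")


def isodata_threshold(values: np.ndarray, tol: float = 1e-6,
                      max_iter: int = 100) -> float:
    """Continuous Isodata threshold: the fixed point of
    ``t = (mean(values < t) + mean(values >= t)) / 2``, iterated from the
    global mean.  Works directly on the float values (no histogram)."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.min() == v.max():
        raise ValueError("Isodata threshold undefined for a constant map")
    t = v.mean()
    for _ in range(max_iter):
        below = v[v < t]
        above = v[v >= t]
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


def largest_component_bbox(mask: np.ndarray,
                           connectivity: int = 8) -> BoundingBox:
    """Tight box around the largest connected component of a binary mask.

    Ties in component size resolve to the component whose first pixel comes
    earliest in raster order (labelling order).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise LocalisationError("empty mask: nothing to localise")
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask, structure=structure)
    sizes = np.bincount(labels.ravel())[1:]
    # labels are assigned in raster order of first encounter, so argmax's
    # first-maximum rule implements the raster-order tie-break
    best = int(np.argmax(sizes)) + 1
    rows, cols = np.nonzero(labels == best)
    return BoundingBox(int(rows.min()), int(cols.min()),
                       int(rows.max()) + 1, int(cols.max()) + 1)


def localise(net: Network, frame, k: int, mode: str = "both",
             sigma: float = 1.0, connectivity: int = 8) -> BoundingBox:
    """Full weak-localisation chain for class ``k`` on one frame.

    Saliency -> sign-policy confidence map -> Isodata threshold -> largest
    component -> minimum box.  Any stage failure raises
    :class:`LocalisationError` naming the stage; in particular a class
    score map with no positive activation yields a zero saliency map and a
    reported failure rather than a fallback box.
    """
    stage = "saliency"
    try:
        smap = weighted_saliency(net, frame, k)
        stage = "confidence_map"
        conf = confidence_map(smap, mode=mode, sigma=sigma)
        stage = "isodata_threshold"
        t = isodata_threshold(conf)
        stage = "largest_component_bbox"
        return largest_component_bbox(conf >= t, connectivity=connectivity)
    except (ValueError, LocalisationError) as exc:
        raise LocalisationError(f"{stage}: {exc}") from exc


def iou(b1: BoundingBox, b2: BoundingBox) -> float:
    """Intersection over union of two boxes under half-open semantics."""
    ih = min(b1.rmax, b2.rmax) - max(b1.rmin, b2.rmin)
    iw = min(b1.cmax, b2.cmax) - max(b1.cmin, b2.cmin)
    inter = max(ih, 0) * max(iw, 0)
    union = b1.area + b2.area - inter
    return inter / union
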