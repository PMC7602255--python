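"""Lesion segmentation: per-plane Otsu thresholding plus a morphological
cleanup cascade.

The lesion is assumed darker than the surrounding skin (melanocytic
polarity).  Each RGB plane is thresholded independently by Otsu's
between-class-variance criterion, the three binary masks are combined by
majority vote, and the combined mask is cleaned by area opening, an
iterative median cascade (7x7 -> 5x5 -> 3x3), an adaptive morphological
open-close filter, and a 5%-of-image-area size filter.  Component
borders are finally traced as ordered, closed 8-connected contours.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .preprocess import DermoscopyImage

logger = logging.getLogger(__name__)

#: pre-filter removing speckle components below this area (pixels, at 256x256)
DEFAULT_MIN_AREA = 100

#: components below this fraction of the image area are spurious artifacts
SIZE_FILTER_FRACTION = 0.05


class DegenerateHistogramError(ValueError):
    """Single occupied intensity level: no two classes to separate."""


class EmptySegmentationError(ValueError):
    """No component survived the size filter."""


@dataclasses.dataclass
class LesionMask:
    """Binary lesion raster (True = lesion) with a component census."""

    mask: np.ndarray
    n_components: int = dataclasses.field(init=False)
    component_areas: List[int] = dataclasses.field(init=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        labels = measure.label(self.mask, connectivity=2)
        areas = np.bincount(labels.ravel())[1:]
        self.n_components = int(len(areas))
        self.component_areas = [int(a) for a in areas]

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass
class Contour:
    """Ordered closed pixel chain along one component border.

    ``points`` are (row, col) coordinates of 8-connected border pixels,
    ordered clockwise in image coordinates (row down, col right).
    """

    points: np.ndarray
    closed: bool = True


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold for a 256-bin intensity histogram.

    Returns the level t in [0, 255] maximizing the between-class
    variance of the classes {<= t} and {> t}; ties break toward the
    smallest t.  Raises :class:`DegenerateHistogramError` when only one
    level is occupied.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("histogram has fewer than two occupied levels")

    total = hist.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist) / total            # class {<= t} weight
    mu0_sum = np.cumsum(hist * levels) / total
    mu_total = mu0_sum[-1]
    w1 = 1.0 - w0
    # between-class variance: w0*w1*(mu0 - mu1)^2; undefined where a class is empty
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu0_sum / w0
        mu1 = (mu_total - mu0_sum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def plane_masks(img: DermoscopyImage) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-plane dark-side Otsu masks for the R, G and B planes.

    A degenerate (single-level) plane yields an all-zero mask and a
    logged warning.
    """
    masks = []
    for c, name in enumerate("RGB"):
        plane = img.pixels[:, :, c]
        hist = np.bincount(plane.ravel(), minlength=256)
        try:
            t = otsu_threshold(hist)
            masks.append(plane <= t)
        except DegenerateHistogramError:
            logger.warning("plane %s is degenerate (single intensity level); "
                           "emitting empty mask", name)
            masks.append(np.zeros(plane.shape, dtype=bool))
    return tuple(masks)


def combine_masks(m1: np.ndarray, m2: np.ndarray, m3: np.ndarray,
                  rule: str = "majority") -> LesionMask:
    """Combine the three plane masks into one lesion mask.

    ``rule`` is "majority" (pixel set iff set in >= 2 of 3 planes, the
    default), "and", or "or".
    """
    m1, m2, m3 = (np.asarray(m, dtype=bool) for m in (m1, m2, m3))
    if not (m1.shape == m2.shape == m3.shape):
        raise ValueError("plane masks must share dimensions")
    votes = m1.astype(np.uint8) + m2.astype(np.uint8) + m3.astype(np.uint8)
    if rule == "majority":
        combined = votes >= 2
    elif rule == "and":
        combined = votes == 3
    elif rule == "or":
        combined = votes >= 1
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    return LesionMask(combined)


def area_opening(mask: LesionMask, min_area: int = DEFAULT_MIN_AREA) -> LesionMask:
    """Remove 8-connected components with area strictly below ``min_area``."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    # max_size removes components with area <= value, hence min_area - 1
    # keeps the strict "< min_area" removal convention
    cleaned = morphology.remove_small_objects(mask.mask, max_size=min_area - 1,
                                              connectivity=2)
    return LesionMask(cleaned)


def median_cascade(mask: LesionMask,
                   sizes: Tuple[int, ...] = (7, 5, 3)) -> LesionMask:
    """Binary median filtering with gradually decreasing windows.

    Applies square median windows in the given order (7x7, then 5x5,
    then 3x3 by default) with reflective borders; each pass keeps a
    pixel iff the foreground holds the majority of its window.
    """
    m = mask.mask.astype(np.uint8)
    for size in sizes:
        m = ndimage.median_filter(m, size=size, mode="reflect")
    return LesionMask(m.astype(bool))


def adaptive_element_radius(shape: Tuple[int, int]) -> int:
    """Disc radius for the open-close filter: 1% of the short side."""
    return max(1, round(0.01 * min(shape[:2])))


def open_close_adaptive(mask: LesionMask, radius: Optional[int] = None,
                        iterations: int = 2) -> LesionMask:
    """Morphological opening then closing with a size-adaptive disc.

    The structuring element radius scales with the image (1% of the
    short side, i.e. 3 px at 256x256) so speckle and thin protrusions
    smaller than the element are erased while large components keep
    their shape and area.
    """
    if radius is None:
        radius = adaptive_element_radius(mask.mask.shape)
    selem = morphology.disk(radius)
    m = mask.mask
    for _ in range(iterations):
        m = morphology.opening(m, selem)
        m = morphology.closing(m, selem)
    return LesionMask(m)


def size_filter(mask: LesionMask, image_area: Optional[int] = None,
                fraction: float = SIZE_FILTER_FRACTION) -> LesionMask:
    """Remove components smaller than ``fraction`` of the image area.

    Raises :class:`EmptySegmentationError` when nothing survives, so the
    caller can fall back to the largest pre-filter component.
    """
    if image_area is None:
        image_area = mask.mask.size
    if image_area <= 0:
        raise ValueError("image_area must be positive")
    cutoff = fraction * image_area
    labels = measure.label(mask.mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    keep = areas >= cutoff
    out = keep[labels]
    if not out.any():
        raise EmptySegmentationError(
            f"no component reaches {fraction:.0%} of the image area")
    return LesionMask(out)


def largest_component(mask: LesionMask) -> LesionMask:
    """Keep only the largest 8-connected component (fallback path)."""
    labels = measure.label(mask.mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    if len(areas) < 2:
        return LesionMask(np.zeros_like(mask.mask))
    areas[0] = 0
    return LesionMask(labels == int(np.argmax(areas)))


# Moore border following: clockwise neighbour offsets starting East,
# in image coordinates (row increases downward).
_MOORE = np.array([(0, 1), (1, 1), (1, 0), (1, -1),
                   (0, -1), (-1, -1), (-1, 0), (-1, 1)])


def _trace_component(comp: np.ndarray, start: Tuple[int, int]) -> np.ndarray:
    """Moore border following from the top-left border pixel, clockwise.

    Terminates by Jacob's criterion: stop when the start pixel is about
    to be exited in the same direction as the first move.
    """
    h, w = comp.shape
    points = [start]
    cur = start
    # the backtrack initially points West of the start pixel, which is
    # outside the component since start is its topmost-leftmost pixel
    backtrack = 4  # index of (0, -1) in _MOORE
    first_move = None
    while True:
        nxt = None
        # scan clockwise starting just after the backtrack direction
        for k in range(1, 9):
            d = (backtrack + k) % 8
            r, c = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if 0 <= r < h and 0 <= c < w and comp[r, c]:
                nxt = (r, c)
                break
        if nxt is None:  # isolated single pixel
            break
        if first_move is None:
            first_move = (cur, d)
        elif (cur, d) == first_move:
            points.pop()  # drop the re-appended start pixel
            break
        cur = nxt
        points.append(cur)
        backtrack = (d + 4) % 8
    return np.array(points, dtype=int)


def trace_contours(mask: LesionMask) -> List[Contour]:
    """One closed, clockwise 8-connected border contour per component."""
    labels = measure.label(mask.mask, connectivity=2)
    contours = []
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        rows, cols = np.nonzero(comp)
        # topmost, then leftmost foreground pixel
        i = np.lexsort((cols, rows))[0]
        start = (int(rows[i]), int(cols[i]))
        pts = _trace_component(comp, start)
        contours.append(Contour(points=pts, closed=True))
    return contours


def segment(img: DermoscopyImage,
            combination_rule: str = "majority",
            min_area: int = DEFAULT_MIN_AREA,
            size_fraction: float = SIZE_FILTER_FRACTION,
            element_radius: Optional[int] = None,
            open_close_iterations: int = 2,
            ) -> Tuple[LesionMask, List[Contour]]:
    """Full segmentation cascade for a standardized image.

    Runs plane_masks -> combine_masks -> area_opening -> median_cascade
    -> open_close_adaptive -> size_filter -> trace_contours.  When the
    size filter empties the mask, the largest pre-filter component is
    kept instead (logged); a fully degenerate image yields an empty mask.
    """
    m1, m2, m3 = plane_masks(img)
    mask = combine_masks(m1, m2, m3, rule=combination_rule)
    if mask.area == 0:
        logger.warning("empty segmentation for %s (degenerate image)",
                       img.source_path or "<in-memory>")
        return mask, []
    mask = area_opening(mask, min_area=min_area)
    mask = median_cascade(mask)
    mask = open_close_adaptive(mask, radius=element_radius,
                               iterations=open_close_iterations)
    pre_filter = mask
    try:
        mask = size_filter(mask, fraction=size_fraction)
    except EmptySegmentationError:
        logger.warning("size filter removed every component for %s; "
                       "keeping the largest one",
                       img.source_path or "<in-memory>")
        mask = largest_component(pre_filter)
    return mask, trace_contours(mask)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
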