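"""Coarse boundary extraction.

Converts a delineated segmentation mask (or a grayscale image, which is
first Otsu-binarized) into a single closed, one-pixel-wide, cyclically
ordered boundary contour.  The stages are

1. Otsu threshold + binarization,
2. morphological clean-up: opening with a 2x2 all-ones template (removes
   stray delineation pixels and thin protrusions) followed by closing with
   a 5x5 disk (bridges small gaps), which keeps the boundary in place on
   smooth shapes,
3. edge extraction (inner morphological boundary for binary rasters,
   Canny for grayscale),
4. tracing of the largest closed loop into clockwise cyclic order.

Conventions: 0-based (row, col) coordinates, row increasing downward;
rasters are conceptually padded with background for erosion-footprint
tests and edge extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny as _skimage_canny
from skimage.filters import threshold_otsu as _skimage_otsu

from .errors import (
    DegenerateInputError,
    EmptyMaskError,
    OpenContourError,
    PipelineStageError,
)

__all__ = [
    "StructuringElement",
    "SQUARE_2X2",
    "DISK_5X5",
    "Contour",
    "otsu_threshold",
    "binarize",
    "extract_edges",
    "erode",
    "dilate",
    "trace_contour",
    "extract_coarse_contour",
]


@dataclass(frozen=True)
class StructuringElement:
    """A binary footprint with an explicit (row, col) anchor.

    The anchor need not be the geometric centre; the 2x2 all-ones template
    has no centred pixel, so its anchor is the top-left entry.
    """

    footprint: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self):
        fp = np.asarray(self.footprint, dtype=bool)
        object.__setattr__(self, "footprint", fp)
        if fp.ndim != 2 or not fp.any():
            raise ValueError("footprint must be 2-D with at least one set entry")
        r, c = self.origin
        if not (0 <= r < fp.shape[0] and 0 <= c < fp.shape[1]):
            raise ValueError("origin must lie inside the footprint")

    @property
    def offsets(self) -> np.ndarray:
        """(K, 2) array of set-pixel offsets relative to the anchor."""
        return np.argwhere(self.footprint) - np.asarray(self.origin)

    def reflected(self) -> "StructuringElement":
        """Point reflection through the anchor (used by erosion/dilation duality)."""
        fp = self.footprint[::-1, ::-1]
        h, w = fp.shape
        r, c = self.origin
        return StructuringElement(fp, (h - 1 - r, w - 1 - c))


def _disk_footprint(size: int = 5, radius: float = 2.5) -> np.ndarray:
    c = (size - 1) / 2
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


#: 2x2 all-ones template (anchor top-left) used for erosion-side clean-up.
SQUARE_2X2 = StructuringElement(np.ones((2, 2), dtype=bool), (0, 0))

#: 5x5 disk (Euclidean distance <= 2.5 from the centre) used for dilation-side clean-up.
DISK_5X5 = StructuringElement(_disk_footprint(), (2, 2))

# 4-neighbour cross used by inner-boundary edge extraction.
_CROSS = StructuringElement(
    np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool), (1, 1)
)


@dataclass
class Contour:
    """A cyclically ordered pixel contour.

    ``points`` is an (N, 2) integer array of (row, col) coordinates.  For a
    traced contour consecutive points (including last -> first) are
    8-connected; sub-sampled contours (e.g. after per-column filtering) set
    ``connected=False``.
    """

    points: np.ndarray
    shape: tuple[int, int]
    clockwise: bool = True
    connected: bool = True

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.int64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def validate(self) -> None:
        pts = self.points
        h, w = self.shape
        if (pts < 0).any() or (pts[:, 0] >= h).any() or (pts[:, 1] >= w).any():
            raise ValueError("contour points out of raster bounds")
        if len(np.unique(pts, axis=0)) != len(pts):
            raise ValueError("duplicate contour points")
        if self.connected and len(pts) > 1:
            diffs = np.abs(pts - np.roll(pts, -1, axis=0))
            if not (diffs.max(axis=1) <= 1).all():
                raise ValueError("consecutive contour points are not 8-connected")


def _as_float_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale raster")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    else:
        arr = arr.astype(np.float64)
    if not np.isfinite(arr).all():
        raise DegenerateInputError("image contains non-finite intensities")
    return arr


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D mask")
    return arr > 0 if arr.dtype != bool else arr


def otsu_threshold(img: np.ndarray) -> float:
    """Otsu's adaptive threshold over a 256-bin histogram.

    Returns the intensity maximizing between-class variance; binarizing
    with ``>`` at the returned value yields non-empty foreground and
    background.  Raises :class:`DegenerateInputError` on constant images.
    """
    arr = _as_float_image(img)
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        raise DegenerateInputError(
            f"constant image (all intensities equal {lo!r}); no Otsu threshold exists"
        )
    return float(_skimage_otsu(arr, nbins=256))


def binarize(img: np.ndarray, threshold: float) -> np.ndarray:
    """Pixel = 1 iff intensity > threshold.  Returns a uint8 {0,1} mask."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return (_as_float_image(img) > threshold).astype(np.uint8)


def erode(mask: np.ndarray, se: StructuringElement, border: int = 0) -> np.ndarray:
    """Binary erosion: output 1 iff the anchored footprint fits inside foreground.

    ``border`` is the conceptual padding value outside the raster
    (0 = background, the default convention).
    """
    m = _as_bool_mask(mask)
    return _morph(m, se.offsets, all_of=True, border=bool(border))


def dilate(mask: np.ndarray, se: StructuringElement, border: int = 0) -> np.ndarray:
    """Binary dilation: output 1 iff the reflected anchored footprint hits foreground."""
    m = _as_bool_mask(mask)
    return _morph(m, -se.offsets, all_of=False, border=bool(border))


def _morph(m: np.ndarray, offsets: np.ndarray, all_of: bool, border: bool) -> np.ndarray:
    h, w = m.shape
    pad = int(np.abs(offsets).max(initial=0))
    padded = np.pad(m, pad, constant_values=border)
    acc = None
    for dr, dc in offsets:
        view = padded[pad + dr : pad + dr + h, pad + dc : pad + dc + w]
        if acc is None:
            acc = view.copy()
        elif all_of:
            acc &= view
        else:
            acc |= view
    return acc.astype(np.uint8)


def extract_edges(
    mask: np.ndarray,
    low: float = 0.1,
    high: float = 0.2,
    sigma: float = 1.0,
) -> np.ndarray:
    """Thin edge raster of a mask or image.

    For a strictly binary input this is the inner morphological boundary:
    foreground pixels with at least one 4-neighbour in the background
    (raster padded with background).  Grayscale inputs go through Canny
    with the given thresholds and Gaussian sigma.
    """
    arr = np.asarray(mask)
    vals = set(np.unique(arr).astype(np.float64)) if arr.size else set()
    binary = vals <= {0.0, 1.0} or vals <= {0.0, 255.0}
    if binary:
        m = arr > 0
        if not m.any():
            raise EmptyMaskError("edge extraction on a mask with empty foreground")
        inner = erode(m, _CROSS, border=0).astype(bool)
        return (m & ~inner).astype(np.uint8)
    img = _as_float_image(arr)
    edges = _skimage_canny(img, sigma=sigma, low_threshold=low, high_threshold=high)
    if not edges.any():
        raise EmptyMaskError("Canny found no edges")
    return edges.astype(np.uint8)


# Clockwise Moore neighbourhood: N, NE, E, SE, S, SW, W, NW in (row, col).
_MOORE = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)],
    dtype=np.int64,
)


def _moore_trace(region: np.ndarray) -> np.ndarray:
    """Clockwise boundary trace of a filled region (padded; start topmost-leftmost)."""
    fg = np.argwhere(region)
    start = tuple(fg[np.lexsort((fg[:, 1], fg[:, 0]))][0])
    padded = np.pad(region, 1)
    cur = (start[0] + 1, start[1] + 1)
    b = 6  # backtrack direction = W; the start pixel has no N/NW/NE/W neighbour
    pts = [cur]
    max_steps = 4 * region.size + 8
    for _ in range(max_steps):
        moved = False
        for k in range(1, 9):
            d = (b + k) % 8
            dr, dc = _MOORE[d]
            nxt = (cur[0] + dr, cur[1] + dc)
            if padded[nxt]:
                cur = nxt
                b = (d + 4) % 8
                moved = True
                break
        if not moved:  # isolated pixel
            break
        if cur == pts[0]:
            break
        pts.append(cur)
    arr = np.asarray(pts, dtype=np.int64) - 1
    return arr


def trace_contour(edge: np.ndarray) -> Contour:
    """Order the largest closed 8-connected loop of an edge raster clockwise.

    The trace starts at the topmost-then-leftmost pixel of the loop.  If no
    component forms a closed loop an :class:`OpenContourError` reports the
    number of open endpoints found.
    """
    e = _as_bool_mask(edge)
    if not e.any():
        raise OpenContourError(0)
    lbl, ncomp = ndimage.label(e, structure=np.ones((3, 3)))
    degree = ndimage.correlate(e.astype(np.int32), np.ones((3, 3), dtype=np.int32), mode="constant") - 1
    candidates = []
    n_endpoints = 0
    for i in range(1, ncomp + 1):
        comp = lbl == i
        size = int(comp.sum())
        comp_endpoints = int(((degree <= 1) & comp).sum())
        if comp_endpoints == 0 and size >= 3:
            filled = ndimage.binary_fill_holes(comp)
            pts = np.argwhere(comp)
            anchor = tuple(pts[np.lexsort((pts[:, 1], pts[:, 0]))][0])
            candidates.append((size, (-anchor[0], -anchor[1]), comp, filled))
        else:
            n_endpoints += comp_endpoints
    if not candidates:
        raise OpenContourError(n_endpoints)
    candidates.sort(key=lambda t: (t[0], t[1]), reverse=True)
    _, _, comp, filled = candidates[0]
    pts = _moore_trace(filled)
    # The boundary of the filled loop is the loop itself; keep only edge pixels.
    on_edge = comp[pts[:, 0], pts[:, 1]]
    pts = pts[on_edge]
    # Guard against pathological re-visits (one-pixel-wide spurs).
    _, first_idx = np.unique(pts, axis=0, return_index=True)
    if len(first_idx) != len(pts):
        pts = pts[np.sort(first_idx)]
    contour = Contour(points=pts, shape=e.shape, clockwise=True, connected=True)
    return contour


def extract_coarse_contour(mask_or_img: np.ndarray) -> Contour:
    """Full coarse stage: binarize, morphological clean-up, edges, trace.

    Accepts either a delineated binary mask (values {0,1} or {0,255}) or a
    grayscale image, which is Otsu-binarized first.  Stage errors are
    re-raised as :class:`PipelineStageError` naming the failing stage.
    """
    arr = np.asarray(mask_or_img)
    vals = np.unique(arr)
    is_binary = len(vals) <= 2 and (
        set(np.asarray(vals, dtype=np.float64)) <= {0.0, 1.0}
        or set(np.asarray(vals, dtype=np.float64)) <= {0.0, 255.0}
    )

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineStageError(name, exc) from exc

    if is_binary:
        mask = (arr > 0).astype(np.uint8)
        if not mask.any() or mask.all():
            raise PipelineStageError(
                "binarize", DegenerateInputError("mask has no boundary (empty or full)")
            )
    else:
        thr = _stage("binarize", otsu_threshold, arr)
        mask = _stage("binarize", binarize, arr, thr)

    opened = _stage("erode", erode, mask, SQUARE_2X2)
    opened = _stage("dilate", dilate, opened, SQUARE_2X2)
    closed = _stage("dilate", dilate, opened, DISK_5X5)
    closed = _stage("erode", erode, closed, DISK_5X5)
    edges = _stage("extract_edges", extract_edges, closed)
    return _stage("trace_contour", trace_contour, edges)
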