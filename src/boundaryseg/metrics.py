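"""Segmentation evaluation metrics.

Standard binary-segmentation overlap metrics: region IOU, Dice (DSC),
Jaccard (JC), overall pixel accuracy (PA) and two-class mean IOU (MIOU),
plus rasterization of a key-point polygon into the region it encloses
(pixel-centre even-odd rule, boundary counted as inside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegeneratePolygonError, ShapeMismatchError, UndefinedMetricError
from .keypoints import KeyPoints

__all__ = [
    "MetricsReport",
    "iou",
    "dice",
    "jaccard",
    "pixel_accuracy",
    "mean_iou",
    "region_from_keypoints",
    "evaluate_masks",
]


@dataclass(frozen=True)
class MetricsReport:
    pixel_accuracy: float
    mean_iou: float
    dice: float
    jaccard: float
    iou: float


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    if a.shape != b.shape:
        raise ShapeMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def iou(a, b) -> float:
    """|a n b| / |a u b| of two binary masks (union must be non-empty)."""
    a, b = _pair(a, b)
    union = (a | b).sum()
    if union == 0:
        raise UndefinedMetricError("IOU undefined: both masks are empty")
    return float((a & b).sum() / union)


def jaccard(a, b) -> float:
    """Jaccard coefficient; identical to :func:`iou`."""
    return iou(a, b)


def dice(a, b) -> float:
    """Dice similarity 2|a n b| / (|a| + |b|)."""
    a, b = _pair(a, b)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise UndefinedMetricError("Dice undefined: both masks are empty")
    return float(2.0 * (a & b).sum() / denom)


def pixel_accuracy(pred, gt) -> float:
    """Fraction of pixels on which prediction and ground truth agree."""
    a, b = _pair(pred, gt)
    return float((a == b).mean())


def mean_iou(pred, gt) -> float:
    """Mean of foreground IOU and background IOU (two-class MIOU)."""
    a, b = _pair(pred, gt)
    return float((iou(a, b) + iou(~a, ~b)) / 2.0)


def evaluate_masks(pred, gt) -> MetricsReport:
    """All metrics of one predicted/ground-truth mask pair."""
    j = jaccard(pred, gt)
    return MetricsReport(
        pixel_accuracy=pixel_accuracy(pred, gt),
        mean_iou=mean_iou(pred, gt),
        dice=dice(pred, gt),
        jaccard=j,
        iou=j,
    )


def region_from_keypoints(kps: KeyPoints | np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill the closed polygon through the cyclic key points.

    A pixel is foreground iff its centre is strictly inside (even-odd
    crossing rule) or exactly on the polygon boundary.  Fewer than three
    points, or a zero-area (collinear) polygon, raise
    :class:`DegeneratePolygonError`.
    """
    pts = kps.points if isinstance(kps, KeyPoints) else np.asarray(kps, dtype=np.int64)
    if len(pts) < 3:
        raise DegeneratePolygonError("polygon needs at least 3 key points")
    # Shoelace on (x=col, y=row); zero signed area means collinear points.
    x = pts[:, 1].astype(np.int64)
    y = pts[:, 0].astype(np.int64)
    area2 = int(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if area2 == 0:
        raise DegeneratePolygonError("zero-area (collinear) key-point polygon")

    h, w = shape
    gy, gx = np.mgrid[0:h, 0:w]
    crossings = np.zeros((h, w), dtype=np.int64)
    on_edge = np.zeros((h, w), dtype=bool)
    n = len(pts)
    for i in range(n):
        x1, y1 = int(x[i]), int(y[i])
        x2, y2 = int(x[(i + 1) % n]), int(y[(i + 1) % n])
        # Exact on-segment test (integer vertices, integer pixel centres).
        cross = (x2 - x1) * (gy - y1) - (y2 - y1) * (gx - x1)
        within = (
            (gx >= min(x1, x2))
            & (gx <= max(x1, x2))
            & (gy >= min(y1, y2))
            & (gy <= max(y1, y2))
        )
        on_edge |= (cross == 0) & within
        if y1 == y2:
            continue  # horizontal edges contribute no crossings
        straddles = (y1 > gy) != (y2 > gy)
        x_at = x1 + (gy - y1) * (x2 - x1) / (y2 - y1)
        crossings += (straddles & (gx < x_at)).astype(np.int64)
    return (((crossings % 2) == 1) | on_edge).astype(np.uint8)
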