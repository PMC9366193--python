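"""Boundary supervision maps.

Rasterizes key points (hard disks) or a full mask boundary into the
[0, 1] target maps the deep-supervision heads are trained against.  Two
source kinds exist, mirroring the two supervision variants: sparse
sampled boundary points and the full one-pixel boundary mask.
"""

from __future__ import annotations

import numpy as np

from .coarse import extract_edges
from .errors import EmptyMaskError, OutOfBoundsError
from .keypoints import KeyPoints

__all__ = ["BoundaryMap", "points_to_map", "mask_to_map", "DEFAULT_STAMP_RADIUS"]

#: Default key-point stamp radius in pixels (hard disks, binary targets).
DEFAULT_STAMP_RADIUS = 2


class BoundaryMap(np.ndarray):
    """A [0, 1] float raster with a ``source_kind`` tag.

    Subclasses ndarray so maps behave like plain arrays everywhere else.
    """

    source_kind: str

    def __new__(cls, data, source_kind: str):
        obj = np.asarray(data, dtype=np.float64).view(cls)
        obj.source_kind = source_kind
        return obj

    def __array_finalize__(self, obj):
        if obj is not None:
            self.source_kind = getattr(obj, "source_kind", "unknown")


def points_to_map(
    kps: KeyPoints | np.ndarray,
    shape: tuple[int, int],
    radius: int = DEFAULT_STAMP_RADIUS,
) -> BoundaryMap:
    """Stamp each key point as a filled Euclidean disk of value 1.

    An empty point set yields an all-zeros map; a point outside ``shape``
    raises :class:`OutOfBoundsError`.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    pts = kps.points if isinstance(kps, KeyPoints) else np.asarray(kps, dtype=np.int64)
    h, w = shape
    out = np.zeros((h, w), dtype=np.float64)
    if len(pts):
        if (pts < 0).any() or (pts[:, 0] >= h).any() or (pts[:, 1] >= w).any():
            raise OutOfBoundsError("key point outside the raster")
        rr = np.arange(-radius, radius + 1)
        dy, dx = np.meshgrid(rr, rr, indexing="ij")
        disk = np.argwhere(dy**2 + dx**2 <= radius**2) - radius
        for r, c in pts:
            stamped = disk + (r, c)
            ok = (
                (stamped[:, 0] >= 0)
                & (stamped[:, 0] < h)
                & (stamped[:, 1] >= 0)
                & (stamped[:, 1] < w)
            )
            out[stamped[ok, 0], stamped[ok, 1]] = 1.0
    return BoundaryMap(out, source_kind="sampled_points")


def mask_to_map(mask: np.ndarray) -> BoundaryMap:
    """Inner-boundary pixels of a mask at value 1 (the boundary-mask variant)."""
    m = np.asarray(mask)
    if not (m > 0).any():
        raise EmptyMaskError("cannot build a boundary map from an empty mask")
    edges = extract_edges((m > 0).astype(np.uint8))
    return BoundaryMap(edges.astype(np.float64), source_kind="boundary_mask")
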