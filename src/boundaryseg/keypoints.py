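"""Coarse-to-fine boundary key-point selection.

Starting from a traced coarse contour, the finer stage

1. keeps at most two points per image column (the vertical extremes),
   discarding the interior "disturbing" points of a thick delineation,
2. seeds the shape with four salient points: the topmost, rightmost,
   bottommost and leftmost contour points,
3. iteratively inserts, between every pair of adjacent key points, the
   contour point nearest the chord's perpendicular bisector, until a
   target count is reached or no arc offers a candidate (the bottleneck
   case), producing a near-equidistant key-point distribution.

The chord direction between two points (x1, y1), (x2, y2),

    (Dx, Dy) = ((x1-x2)/L, (y1-y2)/L),   L = ||p1 - p2||,

is the normal of the perpendicular bisector; a candidate q is scored by
|(q - m) . D| with m the chord midpoint.  Coordinates map as x = column,
y = row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .coarse import Contour
from .errors import DegeneratePairError, MembershipError, SalientSelectionError

__all__ = [
    "DirectionVector",
    "KeyPoints",
    "filter_two_per_column",
    "select_salient_points",
    "perpendicular_direction",
    "interpolate_candidate",
    "refine_keypoints",
    "random_contour_sample",
]

#: Safety cap on refinement iterations (termination on pathological contours).
MAX_ITERATIONS = 10


class DirectionVector(NamedTuple):
    """Unit chord vector (dx, dy) in x = col, y = row coordinates."""

    dx: float
    dy: float


@dataclass
class KeyPoints:
    """Ordered sparse key points on a source contour.

    ``indices`` are cyclic positions within the source contour,
    ``iterations[i]`` records the insertion round of point ``i``
    (1 = the four salient seeds), and ``iteration_log[k]`` the number of
    points inserted in round ``k + 2``.
    """

    points: np.ndarray
    indices: np.ndarray
    iterations: np.ndarray
    iteration_log: list[int] = field(default_factory=list)
    shape: tuple[int, int] | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.int64)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.iterations = np.asarray(self.iterations, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.points)


def filter_two_per_column(contour: Contour) -> Contour:
    """Keep, per occupied column, only the minimum-row and maximum-row points.

    The cyclic order of the retained subsequence follows the source
    contour; the result is generally no longer 8-connected.
    """
    pts = contour.points
    if len(pts) == 0:
        raise ValueError("empty contour")
    keep = np.zeros(len(pts), dtype=bool)
    for col in np.unique(pts[:, 1]):
        sel = np.nonzero(pts[:, 1] == col)[0]
        rows = pts[sel, 0]
        keep[sel[np.argmin(rows)]] = True
        keep[sel[np.argmax(rows)]] = True
    return Contour(
        points=pts[keep],
        shape=contour.shape,
        clockwise=contour.clockwise,
        connected=False,
    )


def _extreme_index(pts: np.ndarray, values: np.ndarray, take_max: bool,
                   taken: set[int]) -> int | None:
    """Index of the extreme point; ties broken by smaller column then smaller row.

    Points already selected for another direction are skipped (on shapes
    with flat sides, e.g. a square, the tie-break would otherwise pick the
    same corner for two directions).
    """
    target = values.max() if take_max else values.min()
    cand = np.nonzero(values == target)[0]
    order = np.lexsort((pts[cand, 0], pts[cand, 1]))
    for j in order:
        if int(cand[j]) not in taken:
            return int(cand[j])
    return None


def select_salient_points(contour: Contour) -> KeyPoints:
    """Four salient seeds: topmost, rightmost, bottommost, leftmost points.

    Returned in cyclic (clockwise) contour order starting from the topmost
    point.  Degenerate contours (fewer than four distinct extremes, or all
    points collinear) raise :class:`SalientSelectionError`.
    """
    pts = contour.points
    if len(pts) < 4:
        raise SalientSelectionError("contour has fewer than 4 points")
    if len(np.unique(pts[:, 0])) < 2 or len(np.unique(pts[:, 1])) < 2:
        raise SalientSelectionError("contour spans fewer than 2 rows or 2 columns")
    taken: set[int] = set()
    idx: list[int] = []
    for values, take_max in (
        (pts[:, 0], False),  # topmost
        (pts[:, 1], True),   # rightmost
        (pts[:, 0], True),   # bottommost
        (pts[:, 1], False),  # leftmost
    ):
        i = _extreme_index(pts, values, take_max, taken)
        if i is None:
            raise SalientSelectionError("salient extremes coincide (degenerate contour)")
        taken.add(i)
        idx.append(i)
    top = idx[0]
    order = sorted(idx, key=lambda i: (i - top) % len(pts))
    order = np.asarray(order, dtype=np.int64)
    return KeyPoints(
        points=pts[order],
        indices=order,
        iterations=np.ones(4, dtype=np.int64),
        iteration_log=[],
        shape=contour.shape,
    )


def perpendicular_direction(p1: Sequence[float], p2: Sequence[float]) -> DirectionVector:
    """Unit chord vector between two (x, y) points.

    This vector is the normal of the perpendicular bisector of the chord.
    Coincident points raise :class:`DegeneratePairError`.  Swapping the
    arguments negates the result.
    """
    x1, y1 = float(p1[0]), float(p1[1])
    x2, y2 = float(p2[0]), float(p2[1])
    dx, dy = x1 - x2, y1 - y2
    norm = float(np.hypot(dx, dy))
    if norm == 0.0:
        raise DegeneratePairError(f"coincident points {tuple(p1)!r}")
    return DirectionVector(dx / norm, dy / norm)


def _find_index(contour: Contour, p) -> int:
    match = np.nonzero((contour.points == np.asarray(p, dtype=np.int64)).all(axis=1))[0]
    if len(match) == 0:
        raise MembershipError(f"point {tuple(p)!r} is not on the contour")
    return int(match[0])


def interpolate_candidate(p1, p2, contour: Contour) -> Optional[tuple[int, int]]:
    """Contour point of the open arc p1 -> p2 nearest the perpendicular bisector.

    ``p1`` and ``p2`` are (row, col) members of ``contour``; candidates are
    restricted to the open cyclic arc from p1 forward to p2 so the
    bisector's far-side intersection is never picked.  Ties are broken by
    distance to the chord midpoint, then by smaller cyclic index.  Returns
    ``None`` when the arc has no interior point (the bottleneck case).
    """
    i1 = _find_index(contour, p1)
    i2 = _find_index(contour, p2)
    cand_idx = _arc_indices(i1, i2, len(contour))
    if len(cand_idx) == 0:
        return None
    return tuple(contour.points[_best_candidate(contour.points, i1, i2, cand_idx)])


def _arc_indices(i1: int, i2: int, n: int) -> np.ndarray:
    span = (i2 - i1) % n
    if span <= 1:
        return np.empty(0, dtype=np.int64)
    return (i1 + 1 + np.arange(span - 1)) % n


def _best_candidate(pts: np.ndarray, i1: int, i2: int, cand_idx: np.ndarray) -> int:
    # x = col, y = row; only the dot-product magnitude matters, so the
    # axis mapping does not change the winner but is kept explicit.
    p1 = pts[i1][::-1].astype(np.float64)
    p2 = pts[i2][::-1].astype(np.float64)
    d = np.asarray(perpendicular_direction(p1, p2), dtype=np.float64)
    m = (p1 + p2) / 2.0
    q = pts[cand_idx][:, ::-1].astype(np.float64)
    line_dist = np.abs((q - m) @ d)
    mid_dist = np.linalg.norm(q - m, axis=1)
    arc_pos = np.arange(len(cand_idx))
    order = np.lexsort((arc_pos, mid_dist, line_dist))
    return int(cand_idx[order[0]])


def refine_keypoints(contour: Contour, target_n: int) -> KeyPoints:
    """Iterative perpendicular-bisector interpolation up to ``target_n`` points.

    Each round visits every adjacent key-point pair and inserts the arc's
    bisector candidate (skipping empty arcs); it stops once the point
    count reaches ``target_n``, when a round inserts nothing, or after
    ``MAX_ITERATIONS`` rounds.
    """
    if target_n < 4:
        raise ValueError("target_n must be >= 4")
    seed = select_salient_points(contour)
    indices = list(seed.indices)
    iterations = list(seed.iterations)
    log: list[int] = []
    n = len(contour)
    pts = contour.points
    round_no = 1
    while len(indices) < target_n and round_no <= MAX_ITERATIONS:
        round_no += 1
        new_indices: list[int] = []
        new_iters: list[int] = []
        inserted = 0
        k = len(indices)
        for j in range(k):
            i1, i2 = indices[j], indices[(j + 1) % k]
            new_indices.append(i1)
            new_iters.append(iterations[j])
            cand_idx = _arc_indices(i1, i2, n)
            if len(cand_idx) == 0:
                continue
            best = _best_candidate(pts, i1, i2, cand_idx)
            new_indices.append(best)
            new_iters.append(round_no)
            inserted += 1
        indices, iterations = new_indices, new_iters
        if inserted == 0:
            break
        log.append(inserted)
    idx = np.asarray(indices, dtype=np.int64)
    return KeyPoints(
        points=pts[idx],
        indices=idx,
        iterations=np.asarray(iterations, dtype=np.int64),
        iteration_log=log,
        shape=contour.shape,
    )


def random_contour_sample(contour: Contour, n: int, rng) -> KeyPoints:
    """Baseline: ``n`` uniformly-random distinct contour points in cyclic order.

    This is the random-sampling point selection the bisector refinement is
    compared against in property tests and the comparison harness.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    total = len(contour)
    if n > total:
        raise ValueError(f"cannot sample {n} distinct points from {total}")
    idx = np.sort(rng.choice(total, size=n, replace=False))
    return KeyPoints(
        points=contour.points[idx],
        indices=idx,
        iterations=np.zeros(n, dtype=np.int64),
        iteration_log=[],
        shape=contour.shape,
    )
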