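"""Readers and writers for the package's plain file formats.

Images are 8-bit grayscale PNG/TIFF; masks are PNG with {0, 255};
contours and key points are CSV with a header row; key points also
round-trip through JSON together with their insertion log.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .coarse import Contour
from .keypoints import KeyPoints

__all__ = [
    "read_gray",
    "write_gray_png",
    "read_mask",
    "write_mask_png",
    "write_contour_csv",
    "read_contour_csv",
    "write_keypoints_csv",
    "read_keypoints_csv",
    "write_keypoints_json",
    "read_keypoints_json",
]


def read_gray(path) -> np.ndarray:
    """Load a grayscale image as float64 in [0, 1] (8-bit inputs are scaled)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def write_gray_png(path, img: np.ndarray) -> None:
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0 + 0.5).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    """Load a {0, 255} (or {0, 1}) mask PNG as a uint8 {0, 1} raster."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)


def write_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), ((np.asarray(mask) > 0) * np.uint8(255)))


def write_contour_csv(path, contour: Contour) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "row", "col"])
        for i, (r, c) in enumerate(contour.points):
            writer.writerow([i, int(r), int(c)])


def read_contour_csv(path, shape: tuple[int, int]) -> Contour:
    pts = np.loadtxt(path, delimiter=",", skiprows=1, dtype=np.int64, ndmin=2)
    return Contour(points=pts[:, 1:3], shape=shape, connected=False)


def write_keypoints_csv(path, kps: KeyPoints) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "row", "col", "iteration"])
        for i, ((r, c), it) in enumerate(zip(kps.points, kps.iterations)):
            writer.writerow([i, int(r), int(c), int(it)])


def read_keypoints_csv(path) -> KeyPoints:
    rows = np.loadtxt(path, delimiter=",", skiprows=1, dtype=np.int64, ndmin=2)
    return KeyPoints(
        points=rows[:, 1:3],
        indices=rows[:, 0],
        iterations=rows[:, 3],
        iteration_log=[],
    )


def write_keypoints_json(path, kps: KeyPoints) -> None:
    payload = {
        "points": [[int(r), int(c)] for r, c in kps.points],
        "iterations": [int(i) for i in kps.iterations],
        "iteration_log": [int(i) for i in kps.iteration_log],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_keypoints_json(path) -> KeyPoints:
    with open(path) as fh:
        payload = json.load(fh)
    pts = np.asarray(payload["points"], dtype=np.int64)
    return KeyPoints(
        points=pts,
        indices=np.arange(len(pts)),
        iterations=np.asarray(payload["iterations"], dtype=np.int64),
        iteration_log=list(payload["iteration_log"]),
    )
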