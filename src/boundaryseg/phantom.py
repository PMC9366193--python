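"""Synthetic ultrasound-like phantoms.

Generates smooth star-convex foreground blobs (a perturbed ellipse radial
function) rendered with the degradations that make ultrasound boundaries
ambiguous: multiplicative unit-mean gamma speckle, Gaussian blur and low
foreground/background contrast.  Every sample is a pure function of
``(spec.seed, index)``, so datasets are reproducible and need no
download.

The simulator emulates the data regime the method targets; it is not a
physical ultrasound model (no RF-domain point-spread function, no
shadowing).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import io as bsio
from .coarse import extract_coarse_contour
from .errors import ConfigError
from .keypoints import filter_two_per_column, refine_keypoints
from .maps import DEFAULT_STAMP_RADIUS, mask_to_map, points_to_map

__all__ = ["PhantomSpec", "sample_mask", "render_image", "make_dataset", "generate_arrays"]


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom generation parameters (desk-scale defaults).

    The blob is a filled region r(theta) = r_ellipse(theta) * (1 + sum_k
    a_k cos(k theta + phi_k)); amplitudes are bounded so the curve stays
    simple and star-convex.  Intensities: piecewise-constant fg/bg levels
    multiplied by unit-mean gamma speckle of the given shape, then
    Gaussian-blurred and clipped to [0, 1].
    """

    raster_size: tuple[int, int] = (64, 64)
    center_jitter: float = 2.0
    semi_axes_range: tuple[float, float] = (12.0, 22.0)
    boundary_perturb_harmonics: int = 3
    perturb_amplitude: float = 0.15
    fg_level: float = 0.55
    bg_level: float = 0.35
    speckle_shape: float = 4.0
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.raster_size
        amax = self.semi_axes_range[1]
        margin = min(h, w) / 2 - amax * (1 + self.perturb_amplitude) - self.center_jitter
        if margin < 4:
            raise ConfigError(
                f"semi-axes up to {amax} do not fit the {h}x{w} raster with >= 4 px margin"
            )
        if not (0 <= self.perturb_amplitude < 0.5):
            raise ConfigError("perturb_amplitude must be in [0, 0.5)")
        if self.fg_level == self.bg_level:
            raise ConfigError("fg_level must differ from bg_level")
        if self.speckle_shape <= 0:
            raise ConfigError("speckle_shape must be positive")


def _rng_for(spec: PhantomSpec, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(index), stream]))


def sample_mask(spec: PhantomSpec, index: int) -> np.ndarray:
    """Deterministic star-convex binary mask for ``(spec.seed, index)``."""
    rng = _rng_for(spec, index, 0)
    h, w = spec.raster_size
    cy = h / 2 + rng.uniform(-spec.center_jitter, spec.center_jitter)
    cx = w / 2 + rng.uniform(-spec.center_jitter, spec.center_jitter)
    a = rng.uniform(*spec.semi_axes_range)  # semi-axis along columns
    b = rng.uniform(*spec.semi_axes_range)  # semi-axis along rows
    k = spec.boundary_perturb_harmonics
    amps = rng.uniform(0, spec.perturb_amplitude, size=k)
    total = amps.sum()
    if total > spec.perturb_amplitude > 0:
        amps *= spec.perturb_amplitude / total
    phases = rng.uniform(0, 2 * np.pi, size=k)

    gy, gx = np.mgrid[0:h, 0:w]
    dy = gy - cy
    dx = gx - cx
    theta = np.arctan2(dy, dx)
    rho = np.hypot(dy, dx)
    r_ell = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    perturb = np.zeros_like(theta)
    for i in range(k):
        perturb += amps[i] * np.cos((i + 1) * theta + phases[i])
    return (rho <= r_ell * (1.0 + perturb)).astype(np.uint8)


def render_image(mask: np.ndarray, spec: PhantomSpec, index: int) -> np.ndarray:
    """Speckled, blurred, low-contrast rendering of a mask; values in [0, 1]."""
    rng = _rng_for(spec, index, 1)
    m = np.asarray(mask) > 0
    base = np.where(m, spec.fg_level, spec.bg_level).astype(np.float64)
    speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, size=m.shape)
    img = base * speckle
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    return np.clip(img, 0.0, 1.0)


def extract_case_keypoints(mask: np.ndarray, target_n: int):
    """Full boundary pipeline for one mask: coarse trace, column filter, refine."""
    coarse = extract_coarse_contour(mask)
    filtered = filter_two_per_column(coarse)
    return refine_keypoints(filtered, target_n)


def generate_arrays(
    n: int,
    spec: PhantomSpec,
    target_n: int = 16,
    radius: int = DEFAULT_STAMP_RADIUS,
    supervision: str = "sampled_points",
    start_index: int = 0,
):
    """In-memory dataset: images, masks and supervision maps as float arrays.

    Returns a dict with arrays of shape (n, H, W); used by the training
    smoke tests and the acceptance harness without touching disk.
    """
    imgs, masks, maps = [], [], []
    for i in range(start_index, start_index + n):
        m = sample_mask(spec, i)
        imgs.append(render_image(m, spec, i))
        masks.append(m.astype(np.float64))
        if supervision == "boundary_mask":
            maps.append(np.asarray(mask_to_map(m), dtype=np.float64))
        else:
            kps = extract_case_keypoints(m, target_n)
            maps.append(np.asarray(points_to_map(kps, m.shape, radius), dtype=np.float64))
    return {
        "images": np.stack(imgs),
        "masks": np.stack(masks),
        "maps": np.stack(maps),
    }


def make_dataset(
    n: int,
    spec: PhantomSpec,
    out_dir,
    target_n: int = 16,
    radius: int = DEFAULT_STAMP_RADIUS,
) -> dict:
    """Write ``n`` phantom cases (image, mask, key points, boundary map) plus a manifest.

    Produces per case: ``img_XXX.png`` (8-bit grayscale), ``mask_XXX.png``
    ({0, 255}), ``kp_XXX.csv`` (index,row,col,iteration) and
    ``bmap_XXX.png``; ``manifest.json`` lists paths, the spec and the seed.
    Fully deterministic given ``(spec, n)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out}: {exc}") from exc
    cases = []
    for i in range(n):
        m = sample_mask(spec, i)
        img = render_image(m, spec, i)
        kps = extract_case_keypoints(m, target_n)
        bmap = points_to_map(kps, m.shape, radius)
        paths = {
            "image": f"img_{i:03d}.png",
            "mask": f"mask_{i:03d}.png",
            "keypoints": f"kp_{i:03d}.csv",
            "boundary_map": f"bmap_{i:03d}.png",
        }
        bsio.write_gray_png(out / paths["image"], img)
        bsio.write_mask_png(out / paths["mask"], m)
        bsio.write_keypoints_csv(out / paths["keypoints"], kps)
        bsio.write_gray_png(out / paths["boundary_map"], np.asarray(bmap))
        cases.append(paths)
    manifest = {
        "n": n,
        "seed": spec.seed,
        "target_n": target_n,
        "stamp_radius": radius,
        "spec": asdict(spec),
        "cases": cases,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
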