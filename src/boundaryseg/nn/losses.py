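"""Training losses.

Both the boundary-map loss and the segmentation loss are pixel-mean
binary cross-entropies; the map loss sums the per-stage means over all
supervision stages, and the total loss is their sum:

    L_map   = sum_i mean_px [ -M log M_i_hat - (1-M) log(1-M_i_hat) ]
    L_seg   =        mean_px [ -G log S      - (1-G) log(1-S)       ]
    L_total = L_map + L_seg

Predictions are probabilities; they are clipped to [eps, 1-eps] with
eps = 1e-7 before the logs, since the cross-entropy is undefined at 0/1.
Per-pixel means keep the loss scale resolution-independent while the
stage sum preserves the additive multi-stage structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ShapeMismatchError

__all__ = ["CLIP_EPS", "LossBundle", "bce_mean", "map_loss", "seg_loss", "total_loss"]

#: Probability clipping inside both cross-entropies.
CLIP_EPS = 1e-7


@dataclass(frozen=True)
class LossBundle:
    """Loss components of one batch; total = map + seg exactly."""

    map_loss: float
    seg_loss: float
    total_loss: float
    per_stage: tuple[float, ...] = ()


def bce_mean(pred: np.ndarray, target: np.ndarray) -> float:
    """Pixel-mean binary cross-entropy of probabilities vs a {0,1} target."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ShapeMismatchError(f"prediction {p.shape} vs target {t.shape}")
    p = np.clip(p, CLIP_EPS, 1.0 - CLIP_EPS)
    return float(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean())


def map_loss(predicted_maps, gt_map: np.ndarray) -> float:
    """Sum over stages of the per-stage pixel-mean cross-entropy vs the shared map."""
    return float(sum(bce_mean(p, _broadcast(p, gt_map)) for p in predicted_maps))


def seg_loss(pred: np.ndarray, gt_mask: np.ndarray) -> float:
    """Pixel-mean cross-entropy of the segmentation probability vs ground truth."""
    return bce_mean(pred, _broadcast(pred, gt_mask))


def _broadcast(pred, target):
    t = np.asarray(target, dtype=np.float64)
    p = np.asarray(pred)
    if t.shape != p.shape:
        try:
            t = np.broadcast_to(t, p.shape)
        except ValueError as exc:
            raise ShapeMismatchError(f"prediction {p.shape} vs target {t.shape}") from exc
    return t


def total_loss(predicted_maps, gt_map, seg_pred, gt_mask) -> LossBundle:
    """Composite loss bundle: map and segmentation terms plus their exact sum."""
    per_stage = tuple(bce_mean(p, _broadcast(p, gt_map)) for p in predicted_maps)
    lm = float(sum(per_stage))
    ls = seg_loss(seg_pred, gt_mask)
    return LossBundle(map_loss=lm, seg_loss=ls, total_loss=lm + ls, per_stage=per_stage)
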