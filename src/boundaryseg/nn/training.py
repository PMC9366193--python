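"""Training loop, cross-validation folds and inference.

Adam updates on shuffled mini-batches; the retained checkpoint is the
epoch with the lowest validation total loss (training loss when no
validation split is given).  Gradients enter the network at the output
logits: for a sigmoid + pixel-mean cross-entropy the logit gradient is
(probability - target) / n_pixels per stage, which is exact and avoids
clipping artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DataError, TrainingError
from .config import TrainingConfig
from .layers import Adam, sigmoid
from .losses import LossBundle, total_loss
from .unet import BoundaryUNet

__all__ = ["EpochRecord", "TrainResult", "train", "predict", "kfold_split", "evaluate_loss"]


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    map_loss: float
    seg_loss: float
    total_loss: float
    val_total_loss: float


@dataclass
class TrainResult:
    model: BoundaryUNet
    history: list[EpochRecord]
    best_epoch: int
    best_val_loss: float


def _check_dataset(data) -> int:
    for key in ("images", "masks", "maps"):
        if key not in data:
            raise DataError(f"dataset is missing '{key}'")
    n = len(data["images"])
    if n == 0:
        raise DataError("dataset is empty")
    if not (len(data["masks"]) == len(data["maps"]) == n):
        raise DataError("dataset arrays have inconsistent lengths")
    return n


def _batch_losses(model: BoundaryUNet, x, g, m) -> LossBundle:
    seg_logits, head_logits = model.forward(x)
    return total_loss(
        [sigmoid(h) for h in head_logits], m, sigmoid(seg_logits), g
    )


def evaluate_loss(model: BoundaryUNet, data, batch_size: int = 8) -> LossBundle:
    """Mean loss bundle over a dataset (no gradient updates)."""
    n = _check_dataset(data)
    sums = np.zeros(3)
    batches = 0
    for s in range(0, n, batch_size):
        sl = slice(s, min(s + batch_size, n))
        bundle = _batch_losses(
            model,
            data["images"][sl][:, None],
            data["masks"][sl][:, None],
            data["maps"][sl][:, None],
        )
        sums += (bundle.map_loss, bundle.seg_loss, bundle.total_loss)
        batches += 1
    return LossBundle(*(sums / batches), per_stage=())


def train(
    model: BoundaryUNet,
    data,
    tcfg: TrainingConfig,
    val_data=None,
) -> TrainResult:
    """Train in place; returns the model restored to its best checkpoint.

    ``data`` (and optional ``val_data``) are dicts with ``images``,
    ``masks`` and ``maps`` arrays of shape (N, H, W).  Raises
    :class:`TrainingError` naming the epoch if the loss goes non-finite.
    """
    n = _check_dataset(data)
    rng = np.random.default_rng(np.random.SeedSequence([int(tcfg.seed), 0x7A1]))
    opt = Adam(model.params(), lr=tcfg.learning_rate)

    x_all = np.asarray(data["images"], dtype=np.float32)[:, None]
    g_all = np.asarray(data["masks"], dtype=np.float32)[:, None]
    m_all = np.asarray(data["maps"], dtype=np.float32)[:, None]

    history: list[EpochRecord] = []
    best_state = model.state_dict()
    best_val = np.inf
    best_epoch = 0

    for epoch in range(1, tcfg.max_epochs + 1):
        order = rng.permutation(n)
        ep_sums = np.zeros(3)
        n_batches = 0
        for s in range(0, n, tcfg.batch_size):
            idx = order[s : s + tcfg.batch_size]
            x, g, m = x_all[idx], g_all[idx], m_all[idx]
            seg_logits, head_logits = model.forward(x)
            seg_prob = sigmoid(seg_logits)
            head_probs = [sigmoid(h) for h in head_logits]
            bundle = total_loss(head_probs, m, seg_prob, g)
            if not np.isfinite(bundle.total_loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}", epoch=epoch
                )
            npix = seg_prob.size
            dseg = (seg_prob - g) / npix
            dheads = [(p - m) / p.size for p in head_probs]
            model.zero_grad()
            model.backward(dseg, dheads)
            opt.step()
            ep_sums += (bundle.map_loss, bundle.seg_loss, bundle.total_loss)
            n_batches += 1
        ep_mean = ep_sums / n_batches
        if val_data is not None:
            val_total = evaluate_loss(model, val_data).total_loss
        else:
            val_total = ep_mean[2]
        history.append(
            EpochRecord(epoch, ep_mean[0], ep_mean[1], ep_mean[2], val_total)
        )
        if val_total < best_val:
            best_val = val_total
            best_epoch = epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    return TrainResult(model=model, history=history, best_epoch=best_epoch, best_val_loss=float(best_val))


def predict(model: BoundaryUNet, img: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Segment one grayscale image into a uint8 {0,1} mask."""
    seg_logits, _ = model.forward(np.asarray(img, dtype=np.float32))
    prob = sigmoid(seg_logits)[0, 0]
    return (prob > threshold).astype(np.uint8)


def predict_proba(model: BoundaryUNet, img: np.ndarray) -> np.ndarray:
    """Segmentation probability raster for one image."""
    seg_logits, _ = model.forward(np.asarray(img, dtype=np.float32))
    return sigmoid(seg_logits)[0, 0]


def kfold_split(n_items: int, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold partition: list of (train_idx, test_idx), disjoint and exhaustive."""
    if folds < 2 or folds > n_items:
        raise DataError(f"folds must be in [2, {n_items}]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF01D]))
    order = rng.permutation(n_items)
    chunks = np.array_split(order, folds)
    out = []
    for i in range(folds):
        test = np.sort(chunks[i])
        train = np.sort(np.concatenate([chunks[j] for j in range(folds) if j != i]))
        out.append((train, test))
    return out
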