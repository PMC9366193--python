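"""Boundary-supervised U-Net with deep-supervision heads.

A classic encoder-decoder with skip connections: ``depth`` encoder blocks
(two 3x3 conv + ReLU each, followed by 2x2 max pooling), a bottleneck
block, and ``depth`` mirrored decoder blocks (nearest upsampling, a 3x3
conv halving channels, concatenation with the skip feature, two 3x3 conv
+ ReLU).  After each convolution block selected by the head placement, a
prediction head — a zero-initialised 1x1 convolution followed directly by
nearest-neighbour upsampling to input resolution — emits one boundary-map
logit channel per supervision stage.  The final segmentation output is a
zero-initialised 1x1 convolution at full resolution.

Zero-initialising the output convolutions makes every predicted
probability start at exactly 0.5, so early training is driven purely by
the learned boundary/region signal rather than by random initial logits.
"""

from __future__ import annotations

import numpy as np

from ..errors import ShapeMismatchError
from .config import NetworkConfig
from .layers import Conv2d, MaxPool2, ReLU, UpsampleNearest

__all__ = ["ConvBlock", "Head", "BoundaryUNet", "build_model"]


class ConvBlock:
    """Two 3x3 convolutions, each followed by ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.layers = [Conv2d(c_in, c_out, 3, rng), ReLU(), Conv2d(c_out, c_out, 3, rng), ReLU()]

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Head:
    """Deep-supervision head: 1x1 conv to one channel, upsample to input size."""

    def __init__(self, c_in: int, factor: int, rng: np.random.Generator):
        self.conv = Conv2d(c_in, 1, 1, rng, zero_init=True)
        self.up = UpsampleNearest(factor)

    def params(self):
        return self.conv.params()

    def forward(self, x):
        return self.up.forward(self.conv.forward(x))

    def backward(self, dy):
        return self.conv.backward(self.up.backward(dy))


class BoundaryUNet:
    """See module docstring.  All tensors are NCHW float32."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0BD5]))
        d, base = cfg.depth, cfg.base_channels
        self.ch = [base * 2**i for i in range(d)]          # per-level channels
        ch_bott = base * 2**d

        self.enc = []
        c_prev = 1
        for i in range(d):
            self.enc.append(ConvBlock(c_prev, self.ch[i], rng))
            c_prev = self.ch[i]
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = ConvBlock(self.ch[-1], ch_bott, rng)

        self.ups = [UpsampleNearest(2) for _ in range(d)]
        self.up_convs = []
        self.dec = []
        c_below = ch_bott
        for i in reversed(range(d)):  # built bottom -> top; stored per level index
            self.up_convs.insert(0, Conv2d(c_below, self.ch[i], 3, rng))
            self.dec.insert(0, ConvBlock(2 * self.ch[i], self.ch[i], rng))
            c_below = self.ch[i]
        self.final = Conv2d(self.ch[0], 1, 1, rng, zero_init=True)

        self.enc_heads = None
        self.dec_heads = None
        if cfg.head_placement in ("encoder", "both"):
            self.enc_heads = [Head(self.ch[i], 2**i, rng) for i in range(d)]
        if cfg.head_placement in ("decoder", "both"):
            self.dec_heads = [Head(self.ch[i], 2**i, rng) for i in range(d)]

    # -- parameter plumbing -------------------------------------------------

    def _modules(self):
        mods = list(self.enc) + [self.bottleneck] + self.up_convs + self.dec + [self.final]
        for heads in (self.enc_heads, self.dec_heads):
            if heads:
                mods.extend(heads)
        return mods

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def state_dict(self):
        return [p.copy() for p, _ in self.params()]

    def load_state_dict(self, state):
        pairs = self.params()
        if len(state) != len(pairs):
            raise ShapeMismatchError("checkpoint does not match the model architecture")
        for (p, _), s in zip(pairs, state):
            p[...] = s

    @property
    def n_stages(self) -> int:
        return self.cfg.n_stages

    # -- forward / backward -------------------------------------------------

    @staticmethod
    def _normalize(x: np.ndarray) -> np.ndarray:
        """Per-image standardisation (applied identically in train and predict)."""
        mean = x.mean(axis=(1, 2, 3), keepdims=True)
        std = x.std(axis=(1, 2, 3), keepdims=True)
        return ((x - mean) / (std + 1e-6)).astype(np.float32)

    def forward(self, x: np.ndarray):
        """Returns (seg_logits, head_logits) with every output at input resolution.

        ``head_logits`` is ordered encoder stages shallow-to-deep followed
        by decoder stages deep-to-shallow (matching the forward data path).
        """
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        h, w = x.shape[2:]
        if (h, w) != tuple(self.cfg.input_size):
            raise ShapeMismatchError(
                f"input {h}x{w} does not match configured {self.cfg.input_size}"
            )
        xn = self._normalize(x)

        d = self.cfg.depth
        feats = []
        cur = xn
        for i in range(d):
            f = self.enc[i].forward(cur)
            feats.append(f)
            cur = self.pools[i].forward(f)
        bott = self.bottleneck.forward(cur)

        dec_feats = [None] * d
        cur = bott
        for i in reversed(range(d)):
            up = self.ups[i].forward(cur)
            u = self.up_convs[i].forward(up)
            cat = np.concatenate([feats[i], u], axis=1)
            cur = self.dec[i].forward(cat)
            dec_feats[i] = cur
        seg_logits = self.final.forward(dec_feats[0])

        head_logits = []
        if self.enc_heads:
            head_logits.extend(self.enc_heads[i].forward(feats[i]) for i in range(d))
        if self.dec_heads:
            head_logits.extend(
                self.dec_heads[i].forward(dec_feats[i]) for i in reversed(range(d))
            )
        self._fwd = {"feats": feats, "dec_feats": dec_feats}
        return seg_logits, head_logits

    def backward(self, dseg: np.ndarray, dheads: list[np.ndarray] | None = None):
        """Accumulate parameter gradients given output-logit gradients."""
        d = self.cfg.depth
        feats = self._fwd["feats"]
        dec_feats = self._fwd["dec_feats"]
        d_feats = [np.zeros_like(f) for f in feats]
        d_dec = [np.zeros_like(f) for f in dec_feats]

        d_dec[0] += self.final.backward(np.asarray(dseg, dtype=np.float32))

        if dheads is not None:
            dheads = [np.asarray(g, dtype=np.float32) for g in dheads]
            k = 0
            if self.enc_heads:
                for i in range(d):
                    d_feats[i] += self.enc_heads[i].backward(dheads[k])
                    k += 1
            if self.dec_heads:
                for i in reversed(range(d)):
                    d_dec[i] += self.dec_heads[i].backward(dheads[k])
                    k += 1

        ch = self.ch
        d_bott = None
        for i in range(d):  # decoder top -> bottom
            dcat = self.dec[i].backward(d_dec[i])
            d_feats[i] += dcat[:, : ch[i]]
            dup = self.up_convs[i].backward(dcat[:, ch[i] :])
            dprev = self.ups[i].backward(dup)
            if i + 1 < d:
                d_dec[i + 1] += dprev
            else:
                d_bott = dprev
        d_pool_in = self.bottleneck.backward(d_bott)
        d_feats[d - 1] += self.pools[d - 1].backward(d_pool_in)
        for i in reversed(range(d)):
            dx = self.enc[i].backward(d_feats[i])
            if i > 0:
                d_feats[i - 1] += self.pools[i - 1].backward(dx)

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0


def build_model(cfg: NetworkConfig, seed: int = 0) -> BoundaryUNet:
    """Construct a :class:`BoundaryUNet` with reproducible initialisation."""
    return BoundaryUNet(cfg, seed=seed)
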