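"""U-topology encoder-decoder assembled from exchangeable block styles.

The encoder halves resolution and doubles width at each stage; the
decoder mirrors it with nearest-neighbour upsampling and skip
concatenation at every resolution; a 1x1 head plus per-pixel softmax
produces class probabilities.  The block style emulates the flavor of
the common classification backbones: plain stacked convolutions
("vgg-like"), residual blocks ("resnet-like"), parallel multi-kernel
branches ("inception-like"), and depthwise-separable convolutions
("efficient-like", the lightest in parameters).
"""

from __future__ import annotations

import numpy as np

from .layers import (DTYPE, Adam, Conv2D, DepthwiseConv2D, GroupNorm,
                     MaxPool2, ReLU, Upsample2)

__all__ = ["UNet", "make_block", "ENCODER_FAMILIES"]


class _Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g


class _VGGBlock(_Sequential):
    def __init__(self, rng, cin, cout):
        super().__init__(Conv2D(rng, cin, cout), GroupNorm(cout), ReLU(),
                         Conv2D(rng, cout, cout), GroupNorm(cout), ReLU())


class _ResBlock:
    """conv-relu-conv plus 1x1 projection shortcut, relu after the sum."""

    def __init__(self, rng, cin, cout):
        self.c1 = Conv2D(rng, cin, cout)
        self.n1 = GroupNorm(cout)
        self.r1 = ReLU()
        self.c2 = Conv2D(rng, cout, cout)
        self.n2 = GroupNorm(cout)
        self.proj = Conv2D(rng, cin, cout, k=1)
        self.rout = ReLU()

    def params(self):
        return (self.c1.params() + self.n1.params() + self.c2.params()
                + self.n2.params() + self.proj.params())

    def forward(self, x):
        h = self.r1.forward(self.n1.forward(self.c1.forward(x)))
        return self.rout.forward(
            self.n2.forward(self.c2.forward(h)) + self.proj.forward(x))

    def backward(self, g):
        gpre = self.rout.backward(g)
        dx = self.proj.backward(gpre)
        dx += self.c1.backward(self.n1.backward(self.r1.backward(
            self.c2.backward(self.n2.backward(gpre)))))
        return dx


class _InceptionBlock:
    """Parallel 1x1 and 3x3 branches, concatenated and fused by 1x1."""

    def __init__(self, rng, cin, cout):
        ch = max(cout // 2, 1)
        self.ch = ch
        self.b1 = _Sequential(Conv2D(rng, cin, ch, k=1), GroupNorm(ch),
                              ReLU())
        self.b2 = _Sequential(Conv2D(rng, cin, ch, k=3), GroupNorm(ch),
                              ReLU())
        self.fuse = _Sequential(Conv2D(rng, 2 * ch, cout, k=1),
                                GroupNorm(cout), ReLU())

    def params(self):
        return self.b1.params() + self.b2.params() + self.fuse.params()

    def forward(self, x):
        cat = np.concatenate([self.b1.forward(x), self.b2.forward(x)], axis=1)
        return self.fuse.forward(cat)

    def backward(self, g):
        dcat = self.fuse.backward(g)
        d1, d2 = dcat[:, :self.ch], dcat[:, self.ch:]
        return self.b1.backward(d1) + self.b2.backward(d2)


class _SepBlock(_Sequential):
    """Two depthwise-separable conv units (depthwise 3x3 + pointwise 1x1)."""

    def __init__(self, rng, cin, cout):
        super().__init__(
            DepthwiseConv2D(rng, cin), Conv2D(rng, cin, cout, k=1),
            GroupNorm(cout), ReLU(),
            DepthwiseConv2D(rng, cout), Conv2D(rng, cout, cout, k=1),
            GroupNorm(cout), ReLU())


ENCODER_FAMILIES = {
    "vgg-like": _VGGBlock,
    "resnet-like": _ResBlock,
    "inception-like": _InceptionBlock,
    "efficient-like": _SepBlock,
}


def make_block(rng, family: str, cin: int, cout: int):
    try:
        cls = ENCODER_FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown encoder_family {family!r}; expected one of "
                         f"{sorted(ENCODER_FAMILIES)}") from None
    return cls(rng, cin, cout)


class UNet:
    """Encoder-decoder with skip connections and per-pixel softmax output."""

    def __init__(self, family: str, depth: int, base_channels: int,
                 n_classes: int, in_channels: int = 1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.n_classes = n_classes
        chans = [base_channels * 2 ** i for i in range(depth + 1)]
        self.enc = []
        cin = in_channels
        for i in range(depth):
            self.enc.append(make_block(rng, family, cin, chans[i]))
            cin = chans[i]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = make_block(rng, family, chans[depth - 1], chans[depth])
        self.ups = [Upsample2() for _ in range(depth)]
        self.dec = []
        for i in reversed(range(depth)):
            self.dec.append(make_block(rng, family, chans[i + 1] + chans[i],
                                       chans[i]))
        self.head = Conv2D(rng, chans[0], n_classes, k=1)
        self._chans = chans

    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for blk in self.dec:
            out += blk.params()
        out += self.head.params()
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities for a batch.

        ``x`` is (N, H, W) or (N, 1, H, W); returns (N, n_classes, H, W)
        softmax-normalized over the class axis.
        """
        if x.ndim == 3:
            x = x[:, None]
        x = np.ascontiguousarray(x, dtype=DTYPE)
        # per-image standardization: stabilizes optimization and removes
        # global brightness/contrast shifts at train and inference alike
        mean = x.mean(axis=(1, 2, 3), keepdims=True)
        sd = x.std(axis=(1, 2, 3), keepdims=True)
        x = (x - mean) / (sd + np.float32(1e-6))
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        for i, (up, blk) in enumerate(zip(self.ups, self.dec)):
            h = up.forward(h)
            skip = skips[self.depth - 1 - i]
            h = np.concatenate([h, skip], axis=1)
            blk._split = h.shape[1] - skip.shape[1]
            h = blk.forward(h)
        z = self.head.forward(h)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._probs = e / e.sum(axis=1, keepdims=True)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients given dLoss/dProbabilities."""
        p = self._probs
        dz = (p * (dprobs - (dprobs * p).sum(axis=1, keepdims=True))).astype(DTYPE)
        g = self.head.backward(dz)
        # Decoder stage i (applied i-th in the forward pass) consumed the
        # skip from encoder stage depth-1-i; hold each skip gradient until
        # the matching encoder stage is reached on the way down.
        skip_grads = [None] * self.depth
        for i in reversed(range(self.depth)):
            blk = self.dec[i]
            g = blk.backward(g)
            split = blk._split
            g_up, g_skip = g[:, :split], g[:, split:]
            skip_grads[self.depth - 1 - i] = g_skip
            g = self.ups[i].backward(np.ascontiguousarray(g_up))
        g = self.bottleneck.backward(g)
        for stage in reversed(range(self.depth)):
            g = self.pools[stage].backward(g) + skip_grads[stage]
            g = self.enc[stage].backward(g)
        return g

    def get_weights(self):
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params(), weights):
            p.value[...] = w
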