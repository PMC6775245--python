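"""The encoder-decoder graph and its optimizer.

Encoder: four VGG-style stages of stacked 3x3 convolutions (2, 2, 3, 3 per
stage) each followed by 2x2 max pooling, so the feature map shrinks by 2^4.
Bottleneck: a single 3x3 convolution. Decoder: four stages of nearest-neighbor
2x up-sampling, concatenation with the matching encoder output (the skip
connection), and two 3x3 convolutions. A final 1x1 convolution with a sigmoid
yields a one-channel probability map at input resolution.
"""

from __future__ import annotations

import numpy as np

from .layers import F32, Conv, MaxPool2, Upsample2

ENCODER_CONVS_PER_STAGE = (2, 2, 3, 3)  # VGG-16 blocks 1-4
N_POOL = 4


class UNet:
    """The network graph. ``widths`` are the per-stage encoder channel counts
    (already scaled by any width multiplier); ``bottleneck`` the bottleneck
    channel count."""

    def __init__(self, widths, bottleneck: int, seed: int = 0):
        widths = [int(w) for w in widths]
        if len(widths) != 4 or min(widths) < 1 or bottleneck < 1:
            raise ValueError("need 4 positive encoder widths and a positive bottleneck")
        self.widths = widths
        self.bottleneck_channels = int(bottleneck)
        rng = np.random.default_rng(seed)
        self.enc_stages: list[list[Conv]] = []
        cin = 3
        for s, w in enumerate(widths):
            stage = []
            for c in range(ENCODER_CONVS_PER_STAGE[s]):
                stage.append(Conv(3, cin, w, rng))
                cin = w
            self.enc_stages.append(stage)
        self.pools = [MaxPool2() for _ in range(N_POOL)]
        self.bottleneck = Conv(3, widths[-1], bottleneck, rng)
        self.ups = [Upsample2() for _ in range(N_POOL)]
        self.dec_stages: list[list[Conv]] = []
        cin = bottleneck
        for s in reversed(range(4)):
            w = widths[s]
            stage = [Conv(3, cin + w, w, rng), Conv(3, w, w, rng)]
            self.dec_stages.append(stage)
            cin = w
        self.head = Conv(1, widths[0], 1, rng, relu=False)

    # -- parameter plumbing ---------------------------------------------
    def _conv_layers(self) -> list[Conv]:
        layers = [c for st in self.enc_stages for c in st]
        layers.append(self.bottleneck)
        layers += [c for st in self.dec_stages for c in st]
        layers.append(self.head)
        return layers

    @property
    def params(self):
        return [p for layer in self._conv_layers() for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self._conv_layers() for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, H, W, 3) float32 in [0, 1], H and W divisible by 16.
        Returns sigmoid probabilities (N, H, W)."""
        x = np.ascontiguousarray(x, dtype=F32)
        if x.ndim != 4 or x.shape[3] != 3:
            raise ValueError("expected (N, H, W, 3) input")
        if x.shape[1] % 16 or x.shape[2] % 16:
            raise ValueError("spatial size must be divisible by 2^4")
        skips = []
        h = x
        for stage, pool in zip(self.enc_stages, self.pools):
            for conv in stage:
                h = conv.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        for up, stage, skip in zip(self.ups, self.dec_stages, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([h, skip], axis=3)
            for conv in stage:
                h = conv.forward(h)
        z = self.head.forward(h)[..., 0]
        # numerically stable sigmoid
        self._p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                           np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
        return self._p

    def backward(self, target: np.ndarray) -> None:
        """Backprop of mean binary cross-entropy; call right after forward.
        ``target`` is the (N, H, W) binary mask of the same batch."""
        p = self._p
        dz = ((p - target.astype(F32)) / p.size)[..., None]
        d = self.head.backward(dz)
        skip_grads = []  # filled shallow-to-deep: index i = encoder stage i
        for up, stage, skip_w in zip(
            reversed(self.ups), reversed(self.dec_stages), self.widths
        ):
            for conv in reversed(stage):
                d = conv.backward(d)
            d, dskip = d[..., : d.shape[3] - skip_w], d[..., d.shape[3] - skip_w:]
            d = up.backward(d)
            skip_grads.append(dskip)
        d = self.bottleneck.backward(d)
        for s in reversed(range(4)):
            d = self.pools[s].backward(d)
            d = d + skip_grads[s]
            for conv in reversed(self.enc_stages[s]):
                d = conv.backward(d)


class Adam:
    """Adam optimizer over a fixed parameter list (updates in place)."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
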