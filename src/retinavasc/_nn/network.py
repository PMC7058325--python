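"""Network containers built from the layer primitives."""

from __future__ import annotations

import numpy as np

from .layers import (
    F32,
    Adam,
    BatchNorm2d,
    Conv2d,
    Layer,
    MaxPool2d,
    ReLU,
    Upsample2x,
)


class Sequential:
    """A plain layer chain with support for reading intermediate gradients.

    ``forward(..., record_at=i)`` stashes the output of layer ``i``;
    ``backward(dout, stop_at=i)`` propagates only through layers ``i+1..end``
    and returns the gradient arriving at layer ``i``'s output. Together these
    give class-score gradients at any convolutional depth, which is exactly
    what Grad-CAM needs.
    """

    def __init__(self, layers):
        self.layers = list(layers)
        self.recorded = None

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def state(self):
        out = []
        for layer in self.layers:
            out.extend(layer.state())
        return out

    def forward(self, x, train: bool = False, record_at: int | None = None):
        self.recorded = None
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train)
            if record_at is not None and i == record_at:
                self.recorded = x
        return x

    def backward(self, dout, stop_at: int | None = None):
        stop = -1 if stop_at is None else stop_at
        for i in range(len(self.layers) - 1, stop, -1):
            dout = self.layers[i].backward(dout)
        return dout


def _conv_block(in_ch, out_ch, rng):
    return [
        Conv2d(in_ch, out_ch, 3, rng=rng),
        BatchNorm2d(out_ch),
        ReLU(),
        Conv2d(out_ch, out_ch, 3, rng=rng),
        BatchNorm2d(out_ch),
        ReLU(),
    ]


def _run_forward(layers, x, train):
    for layer in layers:
        x = layer.forward(x, train)
    return x


def _run_backward(layers, dout):
    for layer in reversed(layers):
        dout = layer.backward(dout)
    return dout


class UNet:
    """Encoder-decoder segmentation network with skip connections.

    ``depth`` encoder levels of two 3x3 conv + batch-norm + ReLU blocks,
    2x max-pool downsampling, a bottleneck block, and a mirrored decoder
    that upsamples (nearest + 3x3 conv) and concatenates the encoder skip
    before each decoder block. A final 1x1 convolution emits one logit per
    pixel; the sigmoid lives in the loss / prediction code.
    """

    def __init__(self, depth=2, base_filters=8, in_ch=1, seed=0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.enc_blocks, self.pools = [], []
        ch = in_ch
        for level in range(depth):
            out_ch = base_filters * (2**level)
            self.enc_blocks.append(_conv_block(ch, out_ch, rng))
            self.pools.append(MaxPool2d(2))
            ch = out_ch
        self.bottleneck = _conv_block(ch, ch * 2, rng)
        ch *= 2
        self.up_layers, self.dec_blocks = [], []
        for level in range(depth - 1, -1, -1):
            out_ch = base_filters * (2**level)
            self.up_layers.append([Upsample2x(), Conv2d(ch, out_ch, 3, rng=rng)])
            self.dec_blocks.append(_conv_block(2 * out_ch, out_ch, rng))
            ch = out_ch
        self.out_conv = Conv2d(ch, 1, 1, rng=rng)

    def params(self):
        out = []
        groups = (
            self.enc_blocks + [self.bottleneck] + self.up_layers + self.dec_blocks
        )
        for group in groups:
            for layer in group:
                out.extend(layer.params())
        out.extend(self.out_conv.params())
        return out

    def state(self):
        out = []
        groups = (
            self.enc_blocks + [self.bottleneck] + self.up_layers + self.dec_blocks
        )
        for group in groups:
            for layer in group:
                out.extend(layer.state())
        out.extend(self.out_conv.state())
        return out

    def forward(self, x, train: bool = False):
        x = np.ascontiguousarray(x, dtype=F32)
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = _run_forward(block, x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = _run_forward(self.bottleneck, x, train)
        self._skip_channels = []
        for up, block, skip in zip(self.up_layers, self.dec_blocks, reversed(skips)):
            x = _run_forward(up, x, train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = _run_forward(block, x, train)
        return self.out_conv.forward(x, train)

    def backward(self, dout):
        dout = self.out_conv.backward(dout)
        dskips = []
        for block, up, n_skip in zip(
            reversed(self.dec_blocks), reversed(self.up_layers), reversed(self._skip_channels)
        ):
            dout = _run_backward(block, dout)
            dskips.append(dout[:, :n_skip])
            dout = _run_backward(up, dout[:, n_skip:])
        dout = _run_backward(self.bottleneck, dout)
        for block, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            dout = pool.backward(dout) + dskip
            dout = _run_backward(block, dout)
        return dout


__all__ = ["Sequential", "UNet", "Adam", "Layer"]
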