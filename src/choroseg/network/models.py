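"""U-Net and SegNet-style encoder-decoder segmentation models.

Both use an encoder depth of four with the filter count doubled at every
pooling stage.  The U-Net concatenates each encoder stage's features into
the matching decoder stage (skip connections) and upsamples with learned
2x2 transposed convolutions; the SegNet-style variant carries no skips and
upsamples by max-unpooling with the indices memorized by the encoder's
pooling layers.  Outputs are per-pixel logits for the three categories
(interstitial, lumen, sclera).
"""

from __future__ import annotations

import numpy as np

from .layers import Conv1x1, Conv3x3, MaxPool2, ReLU, UpConv2, softmax, unpool2

N_CLASSES = 3


class ConvBlock:
    """Two 3x3 conv + ReLU pairs."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, name: str):
        self.conv1 = Conv3x3(c_in, c_out, rng, f"{name}.conv1")
        self.relu1 = ReLU()
        self.conv2 = Conv3x3(c_out, c_out, rng, f"{name}.conv2")
        self.relu2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.relu2.forward(self.conv2.forward(self.relu1.forward(self.conv1.forward(x))))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv1.backward(self.relu1.backward(self.conv2.backward(self.relu2.backward(dy))))

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()


class SegModel:
    """Common surface of the segmentation models."""

    architecture: str = ""
    n_classes: int = N_CLASSES
    base_filters: int = 16
    depth: int = 4

    def parameters(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def _check_geometry(self, x: np.ndarray) -> None:
        if x.ndim != 4:
            raise ValueError("expected (C, N, H, W) input")
        h, w = x.shape[2:]
        m = 2**self.depth
        if h % m or w % m:
            raise ValueError(
                f"input geometry {h}x{w} not divisible by 2^depth = {m}"
            )

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities for a ``(C, N, H, W)`` batch."""
        return softmax(self.forward(x))

    @property
    def filter_counts(self) -> list[int]:
        """Encoder filter counts plus the bottleneck (doubling rule)."""
        return [self.base_filters * 2**d for d in range(self.depth + 1)]


class UNet(SegModel):
    architecture = "u-net"

    def __init__(self, base_filters: int = 16, depth: int = 4, in_channels: int = 3, seed: int = 0):
        self.base_filters = base_filters
        self.depth = depth
        rng = np.random.default_rng([seed, 7])
        self.enc: list[ConvBlock] = []
        self.pools: list[MaxPool2] = []
        c = in_channels
        for d in range(depth):
            f = base_filters * 2**d
            self.enc.append(ConvBlock(c, f, rng, f"enc{d}"))
            self.pools.append(MaxPool2())
            c = f
        self.bottleneck = ConvBlock(c, base_filters * 2**depth, rng, "bottleneck")
        self.ups: list[UpConv2] = []
        self.dec: list[ConvBlock] = []
        c = base_filters * 2**depth
        for d in reversed(range(depth)):
            f = base_filters * 2**d
            self.ups.append(UpConv2(c, f, rng, f"up{d}"))
            self.dec.append(ConvBlock(2 * f, f, rng, f"dec{d}"))
            c = f
        self.head = Conv1x1(base_filters, N_CLASSES, rng, "head")

    def parameters(self):
        params = []
        for block in self.enc:
            params += block.parameters()
        params += self.bottleneck.parameters()
        for up, block in zip(self.ups, self.dec):
            params += up.parameters() + block.parameters()
        return params + self.head.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check_geometry(x)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[0])
            x = block.forward(np.concatenate([skip, x], axis=0))
        return self.head.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.head.backward(dy)
        dskips = []
        for up, block, c_skip in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            d = block.backward(dy)
            dskips.append(d[:c_skip])
            dy = up.backward(d[c_skip:])
        dy = self.bottleneck.backward(dy)
        # dskips were collected shallow-to-deep; the encoder unwinds deep-first
        for block, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            dy = block.backward(pool.backward(dy) + dskip)
        return dy


class SegNetStyle(SegModel):
    """Encoder-decoder without skips; upsampling by max-unpooling indices."""

    architecture = "segnet-style"

    def __init__(self, base_filters: int = 16, depth: int = 4, in_channels: int = 3, seed: int = 0):
        self.base_filters = base_filters
        self.depth = depth
        rng = np.random.default_rng([seed, 11])
        self.enc: list[ConvBlock] = []
        self.pools: list[MaxPool2] = []
        c = in_channels
        for d in range(depth):
            f = base_filters * 2**d
            self.enc.append(ConvBlock(c, f, rng, f"enc{d}"))
            self.pools.append(MaxPool2())
            c = f
        self.dec: list[ConvBlock] = []
        for d in reversed(range(depth)):
            f_out = base_filters * 2 ** max(d - 1, 0)
            self.dec.append(ConvBlock(base_filters * 2**d, f_out, rng, f"dec{d}"))
        self.head = Conv1x1(base_filters, N_CLASSES, rng, "head")

    def parameters(self):
        params = []
        for block in self.enc:
            params += block.parameters()
        for block in self.dec:
            params += block.parameters()
        return params + self.head.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check_geometry(x)
        self._pool_shapes = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            self._pool_shapes.append(x.shape)
            x = pool.forward(x)
        for pool, shape, block in zip(
            reversed(self.pools), reversed(self._pool_shapes), self.dec
        ):
            x = unpool2(x, pool.indices, shape)
            x = block.forward(x)
        return self.head.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.head.backward(dy)
        for pool, block in zip(self.pools, reversed(self.dec)):
            dy = block.backward(dy)
            # gradient through unpooling = gathering back at the indices
            c, n, h, w = dy.shape
            blocks = (
                dy.reshape(c, n, h // 2, 2, w // 2, 2)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(c, n, h // 2, w // 2, 4)
            )
            dy = np.take_along_axis(blocks, pool.indices[..., None], axis=-1)[..., 0]
        for block, pool in zip(reversed(self.enc), reversed(self.pools)):
            dy = pool.backward(dy)
            dy = block.backward(dy)
        return dy


__all__ = ["ConvBlock", "N_CLASSES", "SegModel", "SegNetStyle", "UNet"]
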