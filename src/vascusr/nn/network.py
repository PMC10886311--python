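"""Compact residual U-Net with a subpixel super-resolution decoder.

Structure: a convolutional stem, ``depth`` encoder stages (stride-2
convolution + residual block), a mirrored decoder whose upsampling is done
with learnable subpixel (pixel-shuffle) layers joined to the encoder by
skip connections, then ``log2(scale)`` additional subpixel stages that take
the feature map beyond the input resolution, and a linear head producing a
single output frame at ``scale`` times the input side.  Each subpixel layer
is followed by a normalized zero-order-hold (box) blur to suppress
checkerboard artifacts.
"""

from __future__ import annotations

import numpy as np

from .layers import BoxBlur, Conv2d, Layer, Param, PixelShuffle, ReLU


class ResBlock(Layer):
    """conv-relu-conv + identity skip, relu after the sum."""

    def __init__(self, ch: int, rng: np.random.Generator):
        self.conv1 = Conv2d(ch, ch, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(ch, ch, rng=rng)
        self.relu_out = ReLU()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x):
        h = self.relu1.forward(self.conv1.forward(x))
        return self.relu_out.forward(self.conv2.forward(h) + x)

    def backward(self, g):
        gs = self.relu_out.backward(g)
        gh = self.conv1.backward(self.relu1.backward(self.conv2.backward(gs)))
        return gs + gh


class DownStage(Layer):
    """Stride-2 convolution (halves the side) followed by a residual block."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.down = Conv2d(in_ch, out_ch, stride=2, rng=rng)
        self.relu = ReLU()
        self.res = ResBlock(out_ch, rng)

    def params(self):
        return self.down.params() + self.res.params()

    def forward(self, x):
        return self.res.forward(self.relu.forward(self.down.forward(x)))

    def backward(self, g):
        return self.down.backward(self.relu.backward(self.res.backward(g)))


class SubpixelUp(Layer):
    """conv to 4x channels -> pixel shuffle x2 -> optional ZOH blur -> relu."""

    def __init__(self, in_ch: int, out_ch: int, blur: bool, rng: np.random.Generator):
        self.conv = Conv2d(in_ch, out_ch * 4, rng=rng)
        self.shuffle = PixelShuffle(2)
        self.blur = BoxBlur(2) if blur else None
        self.relu = ReLU()

    def params(self):
        return self.conv.params()

    def forward(self, x):
        h = self.shuffle.forward(self.conv.forward(x))
        if self.blur is not None:
            h = self.blur.forward(h)
        return self.relu.forward(h)

    def backward(self, g):
        g = self.relu.backward(g)
        if self.blur is not None:
            g = self.blur.backward(g)
        return self.conv.backward(self.shuffle.backward(g))


class UpStage(Layer):
    """Decoder stage: subpixel upsample, concat the encoder skip, fuse."""

    def __init__(self, in_ch: int, out_ch: int, skip_ch: int, blur: bool, rng):
        self.up = SubpixelUp(in_ch, out_ch, blur, rng)
        self.fuse = Conv2d(out_ch + skip_ch, out_ch, rng=rng)
        self.relu = ReLU()
        self._split = None

    def params(self):
        return self.up.params() + self.fuse.params()

    def forward(self, x, skip):
        u = self.up.forward(x)
        self._split = u.shape[1]
        cat = np.concatenate([u, skip], axis=1)
        return self.relu.forward(self.fuse.forward(cat))

    def backward(self, g):
        gc = self.fuse.backward(self.relu.backward(g))
        gu, gskip = gc[:, : self._split], gc[:, self._split :]
        return self.up.backward(gu), gskip


class ResUNet:
    """The assembled network; a pure-numpy callable with explicit backward."""

    def __init__(
        self,
        in_frames: int = 1,
        scale: int = 4,
        encoder_depth: int = 4,
        base_channels: int = 32,
        blur_after_upsample: bool = True,
        zero_init_head: bool = False,
        seed: int = 0,
    ):
        if in_frames not in (1, 5):
            raise ValueError("in_frames must be 1 or 5")
        if scale < 1 or scale & (scale - 1):
            raise ValueError("scale must be a power of 2")
        if encoder_depth < 1:
            raise ValueError("encoder_depth must be >= 1")
        self.in_frames = in_frames
        self.scale = scale
        self.encoder_depth = encoder_depth
        self.base_channels = base_channels
        self.blur_after_upsample = blur_after_upsample
        self.seed = seed
        rng = np.random.default_rng(seed)

        ch = [base_channels * (2 ** min(i, 2)) for i in range(encoder_depth + 1)]
        self.stem = Conv2d(in_frames, ch[0], rng=rng)
        self.stem_relu = ReLU()
        self.downs = [DownStage(ch[i], ch[i + 1], rng) for i in range(encoder_depth)]
        self.ups = [
            UpStage(ch[i + 1], ch[i], ch[i], blur_after_upsample, rng)
            for i in reversed(range(encoder_depth))
        ]
        n_sr = int(np.log2(scale)) if scale > 1 else 0
        self.sr_stages = [
            SubpixelUp(ch[0], ch[0], blur_after_upsample, rng) for _ in range(n_sr)
        ]
        self.head = Conv2d(ch[0], 1, rng=rng)
        if zero_init_head:
            # with a global residual skip, a zero head makes the untrained
            # network the identity correction (output starts at the baseline)
            self.head.W.value.fill(0.0)
            self.head.b.value.fill(0.0)

    # ---- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        out = self.stem.params() + self.head.params()
        for s in self.downs + self.ups + self.sr_stages:
            out += s.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w

    # ---- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, in_frames, H, W) with H, W divisible by 2**encoder_depth."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != self.in_frames:
            raise ValueError(
                f"expected (B, {self.in_frames}, H, W) input, got {x.shape}"
            )
        H, W = x.shape[2:]
        d = 2**self.encoder_depth
        if H % d or W % d:
            raise ValueError(f"input side must be divisible by {d}")
        h = self.stem_relu.forward(self.stem.forward(x))
        skips = [h]
        for stage in self.downs:
            h = stage.forward(h)
            skips.append(h)
        for stage, skip in zip(self.ups, reversed(skips[:-1])):
            h = stage.forward(h, skip)
        for stage in self.sr_stages:
            h = stage.forward(h)
        return self.head.forward(h)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.head.backward(g)
        for stage in reversed(self.sr_stages):
            g = stage.backward(g)
        # ups[j] consumed skips[depth-1-j]; reversed order therefore emits
        # skip gradients for levels 0, 1, ..., depth-1
        depth = len(self.downs)
        skip_grads: list[np.ndarray | None] = [None] * depth
        for level, stage in enumerate(reversed(self.ups)):
            g, skip_grads[level] = stage.backward(g)
        # walk the encoder backwards, adding each level's skip gradient at the
        # point where that activation branched
        for i in reversed(range(depth)):
            g = self.downs[i].backward(g)
            g = g + skip_grads[i]
        return self.stem.backward(self.stem_relu.backward(g))

    def predict(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Inference over a batch without caching growth; output (B, 1, sH, sW)."""
        outs = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)
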