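"""Semi-synthetic training-pair generation.

A real (or phantom) high-resolution frame is degraded into a plausible
low-resolution acquisition by injecting sensor noise and then downscaling
fourfold (512x512 -> 128x128 at acquisition scale).  Training pairs built
this way stand in for expensive paired LR/HR acquisitions.

Noise models (all operate on frames scaled to [0, 1]):

``none``
    Downscaling only; the reference degradation.
``poisson``
    Shot noise.  A pixel value p maps to an expected photon count ``g*p``
    (gain ``g``, default 50 counts at full scale); the draw is rescaled by
    ``1/g``.
``gaussian``
    Additive white noise ``N(mu, sigma^2)`` on the [0, 1] scale
    (defaults mu=0, sigma=0.1).
``additive_gaussian``
    Signal-dependent noise ``N(mu/255, (sigma/255)^2 + local_var_scale * p)``
    per pixel.  ``mu`` and ``sigma`` are given on the 8-bit [0, 255] scale
    (defaults mu=0, sigma=5) and ``local_var_scale`` (default 0.001) scales
    a variance term proportional to the local signal, mimicking the
    signal-proportional component of detector noise.

All noisy outputs are clipped back to [0, 1] (saturating sensor).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal, Sequence

import numpy as np
from skimage.measure import block_reduce

NoiseKind = Literal["none", "poisson", "gaussian", "additive_gaussian"]


@dataclasses.dataclass
class NoiseConfig:
    """Which noise model to inject before downscaling, and its parameters."""

    kind: NoiseKind = "additive_gaussian"
    mu: float = 0.0
    sigma: float = 5.0
    local_var_scale: float = 0.001
    poisson_gain: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "poisson", "gaussian", "additive_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.local_var_scale < 0:
            raise ValueError("local_var_scale must be >= 0")
        if self.poisson_gain <= 0:
            raise ValueError("poisson_gain must be > 0")


@dataclasses.dataclass
class TrainingSample:
    """One LR input (1 frame, or a 5-frame axial window) with its HR target.

    ``lr_input`` has shape (h, w) for single-frame samples and (5, h, w) for
    multi-frame samples; the HR target side is exactly ``scale`` times the LR
    side.  For multi-frame samples the target corresponds to the middle
    (third) frame of the window.
    """

    lr_input: np.ndarray
    hr_target: np.ndarray
    z_index: int
    stack_id: str = "stack0"

    @property
    def n_input_frames(self) -> int:
        return 1 if self.lr_input.ndim == 2 else self.lr_input.shape[0]


def inject_noise(frame: np.ndarray, cfg: NoiseConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply the configured noise model to a frame scaled to [0, 1]."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.min() < 0.0 or frame.max() > 1.0:
        raise ValueError("frame values must lie in [0, 1]")
    if cfg.kind == "none":
        return frame.copy()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.kind == "poisson":
        g = cfg.poisson_gain
        noisy = rng.poisson(g * frame).astype(np.float64) / g
    elif cfg.kind == "gaussian":
        noisy = frame + rng.normal(cfg.mu, cfg.sigma, size=frame.shape)
    else:  # additive_gaussian: mu/sigma on the 8-bit scale, variance + c*I
        var = (cfg.sigma / 255.0) ** 2 + cfg.local_var_scale * frame
        noisy = frame + cfg.mu / 255.0 + rng.standard_normal(frame.shape) * np.sqrt(var)
    return np.clip(noisy, 0.0, 1.0)


def downscale(frame: np.ndarray, factor: int = 4, method: str = "area") -> np.ndarray:
    """Downscale a frame by an integer factor.

    ``area`` (default) averages each ``factor x factor`` block exactly and
    therefore conserves the mean intensity; ``bilinear`` subsamples with
    half-pixel-centred linear interpolation.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    h, w = frame.shape
    if h % factor or w % factor:
        raise ValueError(f"frame sides {frame.shape} not divisible by {factor}")
    if method == "area":
        return block_reduce(frame, (factor, factor), np.mean)
    if method == "bilinear":
        from scipy import ndimage

        return ndimage.zoom(frame, 1.0 / factor, order=1, grid_mode=True, mode="nearest")
    raise ValueError(f"unknown method {method!r}")


def make_single_frame_dataset(
    hr_frames: Sequence[np.ndarray],
    cfg: NoiseConfig,
    factor: int = 4,
    stack_id: str = "stack0",
) -> list[TrainingSample]:
    """Build one LR/HR pair per preprocessed HR frame.

    ``lr_input = downscale(inject_noise(frame))``; deterministic for a given
    ``cfg.seed`` (an independent substream per frame index).
    """
    frames = [np.asarray(f, dtype=np.float64) for f in hr_frames]
    if not frames:
        raise ValueError("empty input: no HR frames")
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(len(frames))
    samples = []
    for z, (frame, ss) in enumerate(zip(frames, streams)):
        noisy = inject_noise(frame, cfg, rng=np.random.default_rng(ss))
        lr = downscale(noisy, factor=factor)
        samples.append(TrainingSample(lr, frame.copy(), z_index=z, stack_id=stack_id))
    return samples


def make_multiframe_dataset(
    samples: Sequence[TrainingSample], window: int = 5
) -> list[TrainingSample]:
    """Assemble axial windows of LR frames around each valid centre.

    Input samples must be single-frame and ordered by z.  Each output sample
    stacks ``window`` consecutive LR frames (from the same stack only; windows
    never span stack boundaries) and keeps the HR target of the centre frame.
    A stack of n frames yields ``n - window + 1`` samples.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    half = window // 2
    out: list[TrainingSample] = []
    # group by stack while preserving order
    groups: dict[str, list[TrainingSample]] = {}
    for s in samples:
        if s.n_input_frames != 1:
            raise ValueError("make_multiframe_dataset expects single-frame samples")
        groups.setdefault(s.stack_id, []).append(s)
    for stack_id, group in groups.items():
        group = sorted(group, key=lambda s: s.z_index)
        if len(group) < window:
            warnings.warn(
                f"stack {stack_id!r} has {len(group)} < {window} frames; skipped",
                stacklevel=2,
            )
            continue
        for i in range(half, len(group) - half):
            lr = np.stack([group[j].lr_input for j in range(i - half, i + half + 1)])
            out.append(
                TrainingSample(lr, group[i].hr_target.copy(), group[i].z_index, stack_id)
            )
    return out
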