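"""Super-resolution model: configuration, training, inference, baseline.

The central object is :class:`ResUNetUpscaler`, a scikit-learn style
estimator wrapping the numpy residual U-Net in :mod:`vascusr.nn`.  ``fit``
minimizes the mean squared error between predicted and true high-resolution
frames with Adam (learning rate 9e-4 for single-frame input, 1e-4 for
multi-frame input), tracks per-epoch train/validation losses and keeps the
best-validation-loss weights.  ``predict`` maps low-resolution frames (in
[0, 1]) to frames ``scale`` times larger.

:class:`BilinearUpscaler` is the traditional non-learned baseline.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .nn import Adam, BoxBlur, PixelShuffle, ResUNet, mse_loss
from .preprocess import ImageStack, from_float
from .semisynth import TrainingSample

CHECKPOINT_SCHEMA = 1


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters of the residual U-Net."""

    in_frames: int = 1
    scale: int = 4
    encoder_depth: int = 4
    base_channels: int = 32
    blur_after_upsample: bool = True
    global_residual: bool = True
    init: str = "random"  # or a checkpoint path to warm-start the encoder
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_frames not in (1, 5):
            raise ValueError("in_frames must be 1 or 5")
        if self.scale < 1 or self.scale & (self.scale - 1):
            raise ValueError("scale must be a power of 2")


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings.  The default learning rate depends on the
    input layout: 9e-4 (single-frame) or 1e-4 (multi-frame)."""

    learning_rate: float | None = None
    epochs: int = 5
    batch_size: int = 8
    loss: str = "mse"
    seed: int = 0

    def resolve_lr(self, in_frames: int) -> float:
        if self.learning_rate is not None:
            if self.learning_rate <= 0:
                raise ValueError("learning_rate must be > 0")
            return self.learning_rate
        return 9e-4 if in_frames == 1 else 1e-4


def build_model(cfg: ModelConfig) -> ResUNet:
    """Construct the residual U-Net for the given configuration."""
    net = ResUNet(
        in_frames=cfg.in_frames,
        scale=cfg.scale,
        encoder_depth=cfg.encoder_depth,
        base_channels=cfg.base_channels,
        blur_after_upsample=cfg.blur_after_upsample,
        zero_init_head=cfg.global_residual,
        seed=cfg.seed,
    )
    if cfg.init != "random":
        _warm_start_encoder(net, cfg.init)
    return net


def _warm_start_encoder(net: ResUNet, checkpoint_path: str) -> None:
    """Load encoder weights from a previously saved checkpoint."""
    est = load_checkpoint(checkpoint_path)
    src = est.model_
    if (src.encoder_depth, src.base_channels, src.in_frames) != (
        net.encoder_depth,
        net.base_channels,
        net.in_frames,
    ):
        raise ValueError("warm-start checkpoint has an incompatible encoder")
    for dst_p, src_p in zip(
        net.stem.params() + [p for s in net.downs for p in s.params()],
        src.stem.params() + [p for s in src.downs for p in s.params()],
    ):
        dst_p.value[...] = src_p.value


def subpixel_upsample(
    feature_map: np.ndarray, factor: int = 2, blur: bool = True
) -> np.ndarray:
    """Pixel-shuffle a (B, C*factor^2, H, W) map to (B, C, H*f, W*f).

    With ``blur`` on, a normalized zero-order-hold (box) kernel of width
    ``factor`` is applied with reflection padding to suppress checkerboard
    artifacts.
    """
    out = PixelShuffle(factor).forward(np.asarray(feature_map, dtype=np.float64))
    if blur:
        out = BoxBlur(factor).forward(out)
    return out


def zoh_blur_kernel(factor: int) -> np.ndarray:
    """The normalized box kernel used after each subpixel layer (sums to 1)."""
    return np.full((factor, factor), 1.0 / (factor * factor))


class ResUNetUpscaler(RegressorMixin, BaseEstimator):
    """Residual U-Net super-resolution estimator (single- or multi-frame).

    Parameters mirror :class:`ModelConfig` and :class:`TrainConfig`.  ``fit``
    expects LR inputs ``X`` of shape ``(n, h, w)`` (single-frame) or
    ``(n, 5, h, w)`` (multi-frame) and HR targets ``y`` of shape
    ``(n, h*scale, w*scale)``, all scaled to [0, 1].

    Attributes
    ----------
    model_ : ResUNet
        The trained network (best-validation-loss weights).
    loss_history_ : list of dict
        Per-epoch ``train_loss``, ``val_loss`` and running ``best_val_loss``
        (the latter monotone non-increasing).
    best_val_loss_ : float
    """

    def __init__(
        self,
        in_frames: int = 1,
        scale: int = 4,
        encoder_depth: int = 4,
        base_channels: int = 32,
        blur_after_upsample: bool = True,
        global_residual: bool = True,
        init: str = "random",
        learning_rate: float | None = None,
        epochs: int = 5,
        batch_size: int = 8,
        val_fraction: float = 0.15,
        seed: int = 0,
    ):
        self.in_frames = in_frames
        self.scale = scale
        self.encoder_depth = encoder_depth
        self.base_channels = base_channels
        self.blur_after_upsample = blur_after_upsample
        self.global_residual = global_residual
        self.init = init
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.seed = seed

    # -- helpers --------------------------------------------------------------
    def _validate_xy(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if self.in_frames == 1:
            if X.ndim != 3:
                raise ValueError("single-frame X must be (n, h, w)")
            X = X[:, None]
        else:
            if X.ndim != 4 or X.shape[1] != 5:
                raise ValueError("multi-frame X must be (n, 5, h, w)")
        if y.ndim != 3:
            raise ValueError("y must be (n, H, W)")
        if len(X) != len(y) or len(X) == 0:
            raise ValueError("X and y must be equal-length and non-empty")
        if y.shape[1] != X.shape[2] * self.scale or y.shape[2] != X.shape[3] * self.scale:
            raise ValueError(
                f"target side must be {self.scale}x the input side "
                f"(got {X.shape[2:]} -> {y.shape[1:]})"
            )
        return X, y[:, None]

    def _residual_base(self, X: np.ndarray) -> np.ndarray:
        """Bilinear upsample of the (centre) input frame: the global skip."""
        center = X[:, 0] if self.in_frames == 1 else X[:, 2]
        return np.stack(
            [bilinear_upscale_frame(f, self.scale) for f in center]
        )[:, None]

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        X, y = self._validate_xy(X, y)
        rng = np.random.default_rng(self.seed)
        if X_val is None:
            n_val = max(1, int(round(self.val_fraction * len(X)))) if len(X) > 1 else 0
            perm = rng.permutation(len(X))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            Xtr, ytr, Xva, yva = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
        else:
            Xtr, ytr = X, y
            Xva, yva = self._validate_xy(X_val, y_val)
        if len(Xtr) == 0:
            raise ValueError("no training samples left after validation split")

        if self.global_residual:
            # train on the correction to the bilinear upsample of the input
            ytr = ytr - self._residual_base(Xtr)
            if len(Xva):
                yva = yva - self._residual_base(Xva)

        cfg = ModelConfig(
            in_frames=self.in_frames,
            scale=self.scale,
            encoder_depth=self.encoder_depth,
            base_channels=self.base_channels,
            blur_after_upsample=self.blur_after_upsample,
            global_residual=self.global_residual,
            init=self.init,
            seed=self.seed,
        )
        net = build_model(cfg)
        lr = TrainConfig(learning_rate=self.learning_rate).resolve_lr(self.in_frames)
        opt = Adam(net.params(), lr=lr)

        self.loss_history_ = []
        best = np.inf
        best_weights = net.get_weights()
        for _epoch in range(self.epochs):
            order = rng.permutation(len(Xtr))
            ep_losses = []
            for start in range(0, len(order), self.batch_size):
                idx = order[start : start + self.batch_size]
                pred = net.forward(Xtr[idx])
                loss, grad = mse_loss(pred, ytr[idx])
                opt.zero_grad()
                net.backward(grad)
                opt.step()
                ep_losses.append(loss)
            train_loss = float(np.mean(ep_losses))
            val_loss = (
                self._eval_loss(net, Xva, yva) if len(Xva) else train_loss
            )
            if val_loss < best:
                best = val_loss
                best_weights = net.get_weights()
            self.loss_history_.append(
                {
                    "train_loss": train_loss,
                    "val_loss": float(val_loss),
                    "best_val_loss": float(best),
                }
            )
        net.set_weights(best_weights)
        self.model_ = net
        self.best_val_loss_ = float(best)
        return self

    @staticmethod
    def _eval_loss(net: ResUNet, X, y, batch_size: int = 8) -> float:
        total, n = 0.0, 0
        for i in range(0, len(X), batch_size):
            pred = net.forward(X[i : i + batch_size])
            diff = pred - y[i : i + batch_size]
            total += float(np.sum(diff * diff))
            n += diff.size
        return total / n

    def predict(self, X) -> np.ndarray:
        """Upscale LR frames in [0, 1]; returns (n, H, W) clipped to [0, 1]."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if self.in_frames == 1 and X.ndim == 3:
            X = X[:, None]
        out = self.model_.predict(X, batch_size=self.batch_size)
        if self.global_residual:
            out = out + self._residual_base(X)
        return np.clip(out[:, 0], 0.0, 1.0)


def train(
    samples: Sequence[TrainingSample],
    val_samples: Sequence[TrainingSample] | None = None,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> ResUNetUpscaler:
    """Train an upscaler from :class:`TrainingSample` sequences."""
    if not samples:
        raise ValueError("empty training set")
    model_cfg = model_cfg or ModelConfig(
        in_frames=samples[0].n_input_frames
    )
    train_cfg = train_cfg or TrainConfig()
    est = ResUNetUpscaler(
        in_frames=model_cfg.in_frames,
        scale=model_cfg.scale,
        encoder_depth=model_cfg.encoder_depth,
        base_channels=model_cfg.base_channels,
        blur_after_upsample=model_cfg.blur_after_upsample,
        global_residual=model_cfg.global_residual,
        init=model_cfg.init,
        learning_rate=train_cfg.learning_rate,
        epochs=train_cfg.epochs,
        batch_size=train_cfg.batch_size,
        seed=train_cfg.seed,
    )
    X = np.stack([s.lr_input for s in samples])
    y = np.stack([s.hr_target for s in samples])
    if val_samples:
        Xv = np.stack([s.lr_input for s in val_samples])
        yv = np.stack([s.hr_target for s in val_samples])
        return est.fit(X, y, X_val=Xv, y_val=yv)
    return est.fit(X, y)


def _reflect_index(i: int, n: int) -> int:
    """Reflect an out-of-range frame index back into [0, n) (no edge repeat)."""
    if n == 1:
        return 0
    period = 2 * (n - 1)
    i = abs(i) % period
    return period - i if i >= n else i


def upscale(est: ResUNetUpscaler, stack: ImageStack) -> ImageStack:
    """Apply a trained model frame-by-frame (or window-by-window) to a stack.

    Multi-frame models take a 5-frame axial window per output frame; windows
    at the stack boundary reflect their indices so the output has the same
    frame count as the input.  Output intensities fill the stack's bit range.
    """
    frames = stack.astype_float()
    n = stack.n_frames
    if est.in_frames == 1:
        X = frames
    else:
        if n < 1:
            raise ValueError("empty stack")
        X = np.stack(
            [
                np.stack([frames[_reflect_index(i + o, n)] for o in range(-2, 3)])
                for i in range(n)
            ]
        )
    out = est.predict(X)
    z, y, x = stack.spacing_um
    return from_float(
        out,
        bit_depth=stack.bit_depth,
        spacing_um=(z, y / est.scale, x / est.scale),
    )


def bilinear_upscale(stack: ImageStack, factor: int = 4) -> ImageStack:
    """Per-frame separable bilinear interpolation (half-pixel-centre
    convention); the non-learned baseline."""
    frames = stack.astype_float()
    out = np.stack(
        [
            ndimage.zoom(f, factor, order=1, grid_mode=True, mode="nearest")
            for f in frames
        ]
    )
    z, y, x = stack.spacing_um
    return from_float(
        out, bit_depth=stack.bit_depth, spacing_um=(z, y / factor, x / factor)
    )


def bilinear_upscale_frame(frame: np.ndarray, factor: int = 4) -> np.ndarray:
    """Bilinear upscaling of a single float frame in [0, 1]."""
    return ndimage.zoom(
        np.asarray(frame, dtype=np.float64),
        factor,
        order=1,
        grid_mode=True,
        mode="nearest",
    )


# -- checkpoints --------------------------------------------------------------

def save_checkpoint(est: ResUNetUpscaler, path: str | Path) -> None:
    """Single-file archive: weights + configuration + training seed."""
    if not hasattr(est, "model_"):
        raise RuntimeError("cannot checkpoint an unfitted estimator")
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "params": est.get_params(),
        "loss_history": est.loss_history_,
        "best_val_loss": est.best_val_loss_,
    }
    weights = {f"w{i}": w for i, w in enumerate(est.model_.get_weights())}
    np.savez_compressed(path, meta=json.dumps(meta), **weights)


def load_checkpoint(path: str | Path) -> ResUNetUpscaler:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    est = ResUNetUpscaler(**meta["params"])
    net = build_model(
        ModelConfig(
            in_frames=est.in_frames,
            scale=est.scale,
            encoder_depth=est.encoder_depth,
            base_channels=est.base_channels,
            blur_after_upsample=est.blur_after_upsample,
            global_residual=est.global_residual,
            seed=est.seed,
        )
    )
    net.set_weights(weights)
    est.model_ = net
    est.loss_history_ = meta["loss_history"]
    est.best_val_loss_ = meta["best_val_loss"]
    return est


class BilinearUpscaler(TransformerMixin, BaseEstimator):
    """Stateless bilinear upscaling baseline with the estimator interface."""

    def __init__(self, factor: int = 4):
        self.factor = factor

    def fit(self, X=None, y=None):
        self.fitted_ = True
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            return bilinear_upscale_frame(X, self.factor)
        return np.stack([bilinear_upscale_frame(f, self.factor) for f in X])

    def predict(self, X) -> np.ndarray:
        return self.transform(X)
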