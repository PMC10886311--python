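import numpy as np
import pytest

from vascusr.preprocess import ImageStack, from_float


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_stack16(rng):
    """Random 16-bit stack, 6 frames of 32x32."""
    vox = rng.integers(0, 65536, size=(6, 32, 32), dtype=np.uint16)
    return ImageStack(vox, spacing_um=(3.0, 1.367, 1.367), bit_depth=16)


@pytest.fixture
def random_stack8(rng):
    vox = rng.integers(0, 256, size=(6, 32, 32), dtype=np.uint8)
    return ImageStack(vox, spacing_um=(3.0, 1.367, 1.367), bit_depth=8)


@pytest.fixture
def tiny_trained_upscaler(rng):
    """A very small single-frame model trained briefly on a toy task.

    The task maps noisy downscaled frames of smooth random images back to
    the originals; a handful of epochs suffices for sanity-level learning.
    """
    from scipy import ndimage

    from vascusr.semisynth import NoiseConfig, make_single_frame_dataset
    from vascusr.srnet import ResUNetUpscaler

    frames = [
        ndimage.gaussian_filter(rng.random((32, 32)), 3.0) for _ in range(24)
    ]
    frames = [
        (f - f.min()) / (f.max() - f.min() + 1e-12) for f in frames
    ]
    samples = make_single_frame_dataset(
        frames, NoiseConfig(kind="gaussian", sigma=0.05, seed=0), factor=4
    )
    X = np.stack([s.lr_input for s in samples])
    y = np.stack([s.hr_target for s in samples])
    est = ResUNetUpscaler(
        in_frames=1, scale=4, encoder_depth=1, base_channels=8, epochs=3, seed=0
    )
    est.fit(X, y)
    return est
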