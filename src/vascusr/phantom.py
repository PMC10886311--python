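"""Synthetic 3D vascular phantoms with exact ground truth.

Every pipeline stage is testable without acquired data: this module grows a
random tubular network (smooth random-walk centerlines with per-point
radii), rasterizes it into a ground-truth mask and a PSF-blurred intensity
volume, and calibrates additive background noise so the image hits a target
contrast-to-noise ratio (default 0.94, typical of in vivo two-photon
vascular stacks).  The generator also returns the strand table, so
morphology statistics can be checked against their analytic values.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import vector_eval
from .metrics import cnr
from .preprocess import ImageStack, from_float, write_stack
from .vector_eval import Strand


@dataclasses.dataclass
class PhantomConfig:
    """Geometry, optics and noise settings of the phantom generator.

    ``target_fg_fraction`` drives how many strands are grown (vascular
    foreground occupies roughly 5-10% of a cortical volume); ``n_strands``
    can instead request an exact strand count (set ``target_fg_fraction``
    to None to disable density targeting).  ``psf_sigma_um`` is the Gaussian
    PSF (z, y, x); the axial width is larger, mimicking the elongated
    two-photon focal volume.
    """

    volume_shape: tuple[int, int, int] = (32, 128, 128)
    spacing_um: tuple[float, float, float] = (3.0, 1.367, 1.367)
    n_strands: int | None = None
    radius_range_um: tuple[float, float] = (2.0, 4.0)
    tortuosity_amplitude: float = 0.15
    target_fg_fraction: float | None = 0.075
    fg_tolerance: float = 0.02
    target_cnr: float = 0.94
    psf_sigma_um: tuple[float, float, float] = (2.0, 0.5, 0.5)
    fg_intensity: float = 0.60
    bg_intensity: float = 0.20
    bit_depth: int = 8
    step_um: float = 2.0
    strand_length_range_um: tuple[float, float] = (40.0, 160.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range_um[0] <= 0 or self.radius_range_um[1] < self.radius_range_um[0]:
            raise ValueError("radius_range_um must be positive and ordered")
        if self.target_fg_fraction is not None and not (
            0.0 < self.target_fg_fraction < 0.5
        ):
            raise ValueError("target_fg_fraction must be in (0, 0.5)")
        if self.target_cnr <= 0:
            raise ValueError("target_cnr must be > 0")
        if self.n_strands is None and self.target_fg_fraction is None:
            raise ValueError("set n_strands or target_fg_fraction")

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.volume_shape, dtype=np.float64) * np.asarray(
            self.spacing_um
        )


def _random_strand(cfg: PhantomConfig, rng: np.random.Generator) -> Strand | None:
    """Grow one smooth random-walk polyline inside the volume, or None if it
    immediately leaves."""
    extent = cfg.extent_um
    margin = cfg.radius_range_um[1]
    start = rng.uniform(margin, extent - margin)
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    target_len = rng.uniform(*cfg.strand_length_range_um)
    n_steps = max(2, int(round(target_len / cfg.step_um)))
    base_r = rng.uniform(*cfg.radius_range_um)
    pts = [start]
    p = start.copy()
    for _ in range(n_steps):
        d = d + cfg.tortuosity_amplitude * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        q = p + cfg.step_um * d
        if (q < 0).any() or (q >= extent).any():
            break
        pts.append(q)
        p = q
    if len(pts) < 2:
        return None
    pts = np.asarray(pts)
    radii = base_r * (1.0 + 0.1 * np.sin(np.linspace(0.0, np.pi, len(pts))))
    return Strand(pts, radii)


def _rasterize_strand(
    strand: Strand, cfg: PhantomConfig, mask: np.ndarray
) -> None:
    """OR the strand's tube (voxel centers within the locally interpolated
    radius of the centerline) into ``mask`` in place."""
    spacing = np.asarray(cfg.spacing_um)
    shape = np.asarray(cfg.volume_shape)
    pts, radii = strand.centerline, strand.radii
    for a, b, ra, rb in zip(pts[:-1], pts[1:], radii[:-1], radii[1:]):
        rmax = max(ra, rb)
        lo = np.maximum(np.floor((np.minimum(a, b) - rmax) / spacing).astype(int), 0)
        hi = np.minimum(
            np.ceil((np.maximum(a, b) + rmax) / spacing).astype(int) + 1, shape
        )
        if (lo >= hi).any():
            continue
        zz, yy, xx = np.meshgrid(
            (np.arange(lo[0], hi[0]) + 0.5) * spacing[0],
            (np.arange(lo[1], hi[1]) + 0.5) * spacing[1],
            (np.arange(lo[2], hi[2]) + 0.5) * spacing[2],
            indexing="ij",
        )
        pvox = np.stack([zz, yy, xx], axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip(((pvox - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
        closest = a + t[..., None] * ab
        dist = np.linalg.norm(pvox - closest, axis=-1)
        local_r = ra + t * (rb - ra)
        sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        sub |= dist <= local_r


def generate_strands(cfg: PhantomConfig) -> list[Strand]:
    """Generate the phantom's strand set, deterministic per seed.

    With ``target_fg_fraction`` set, strands are added until the rasterized
    foreground fraction falls within ``target +/- fg_tolerance`` (an error is
    raised if the request cannot be met within a bounded number of
    attempts); with ``n_strands`` set and no target, exactly that many
    strands are returned.
    """
    rng = np.random.default_rng(cfg.seed)
    strands: list[Strand] = []
    if cfg.target_fg_fraction is None:
        attempts = 0
        while len(strands) < (cfg.n_strands or 0):
            s = _random_strand(cfg, rng)
            attempts += 1
            if s is not None:
                strands.append(s)
            if attempts > 50 * cfg.n_strands + 100:
                raise RuntimeError("could not place the requested strands")
        return strands

    lo = cfg.target_fg_fraction - cfg.fg_tolerance
    hi = cfg.target_fg_fraction + cfg.fg_tolerance
    mask = np.zeros(cfg.volume_shape, dtype=bool)
    max_attempts = 2000
    for _ in range(max_attempts):
        frac = mask.mean()
        if frac >= cfg.target_fg_fraction:  # lands just above the target
            if frac <= hi:
                return strands
            raise RuntimeError(
                f"foreground fraction {frac:.3f} overshot the band "
                f"[{lo:.3f}, {hi:.3f}]"
            )
        if cfg.n_strands is not None and len(strands) >= cfg.n_strands:
            break
        s = _random_strand(cfg, rng)
        if s is None:
            continue
        trial = mask.copy()
        _rasterize_strand(s, cfg, trial)
        if trial.mean() > hi:  # this strand would overshoot; try another
            continue
        mask = trial
        strands.append(s)
    frac = mask.mean()
    if lo <= frac <= hi:
        return strands
    raise RuntimeError(
        f"impossible density request: reached fraction {frac:.3f}, "
        f"band [{lo:.3f}, {hi:.3f}]"
    )


def rasterize(
    strands: list[Strand], cfg: PhantomConfig
) -> tuple[np.ndarray, ImageStack]:
    """Rasterize strands into a ground-truth mask and a clean blurred image.

    The mask is geometry only (independent of intensities); the clean image
    paints ``fg_intensity`` inside the mask over ``bg_intensity`` and applies
    the anisotropic Gaussian PSF.
    """
    mask = np.zeros(cfg.volume_shape, dtype=bool)
    for s in strands:
        _rasterize_strand(s, cfg, mask)
    img = np.where(mask, cfg.fg_intensity, cfg.bg_intensity).astype(np.float64)
    sigma_vox = np.asarray(cfg.psf_sigma_um) / np.asarray(cfg.spacing_um)
    if (sigma_vox > 0).any():
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="reflect")
    clean = from_float(img, bit_depth=cfg.bit_depth, spacing_um=cfg.spacing_um)
    return mask, clean


def calibrate_noise_to_cnr(
    clean_image: ImageStack,
    truth_mask: np.ndarray,
    target_cnr: float = 0.94,
    seed: int = 0,
    tol: float = 5e-3,
) -> ImageStack:
    """Add Gaussian background noise so the measured CNR hits the target.

    One standard-normal field is drawn per seed; its scale sigma is solved by
    bisection so that the CNR of the final quantized, clipped stack (fg/bg
    means and bg standard deviation taken over the truth mask) matches
    ``target_cnr``.  Deterministic per seed.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if not truth_mask.any() or truth_mask.all():
        raise ValueError("mask must contain both foreground and background")
    clean = clean_image.astype_float()
    bg = ~truth_mask
    contrast = float(clean[truth_mask].mean() - clean[bg].mean())
    if contrast <= 0:
        raise ValueError("target unreachable: clean image has no contrast")
    rng = np.random.default_rng(seed)
    field = rng.standard_normal(clean.shape)

    def noisy_stack(sigma: float) -> ImageStack:
        return from_float(
            clean + sigma * field,
            bit_depth=clean_image.bit_depth,
            spacing_um=clean_image.spacing_um,
        )

    def measured(sigma: float) -> float:
        return cnr(noisy_stack(sigma).voxels, truth_mask, bg)

    lo = contrast / target_cnr / 50.0
    hi = contrast / target_cnr * 50.0
    if measured(lo) < target_cnr or measured(hi) > target_cnr:
        raise ValueError("target CNR outside the reachable range")
    best_sigma, best_err = lo, np.inf
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        got = measured(mid)
        err = abs(got - target_cnr)
        if err < best_err:
            best_sigma, best_err = mid, err
        if err < tol:
            break
        if got > target_cnr:
            lo = mid
        else:
            hi = mid
    return noisy_stack(best_sigma)


@dataclasses.dataclass
class PhantomVolume:
    """One generated phantom: noisy stack, truth mask, strands and table."""

    image: ImageStack
    truth_mask: np.ndarray
    strands: list[Strand]
    strand_table: pd.DataFrame
    seed: int


def make_phantom(cfg: PhantomConfig) -> PhantomVolume:
    """Generate a single phantom volume from a config (pure in ``cfg.seed``)."""
    strands = generate_strands(cfg)
    mask, clean = rasterize(strands, cfg)
    noisy = calibrate_noise_to_cnr(clean, mask, cfg.target_cnr, seed=cfg.seed)
    table = vector_eval.strand_table(strands)
    return PhantomVolume(noisy, mask, strands, table, cfg.seed)


def make_phantom_dataset(
    cfg: PhantomConfig, n_volumes: int, out_dir: str | Path | None = None
) -> list[PhantomVolume]:
    """Generate independent phantoms with per-volume seeds derived from the
    master seed; optionally write TIFFs, strand tables and a manifest."""
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(cfg.seed).spawn(n_volumes)
    ]
    volumes = []
    for seed in child_seeds:
        vcfg = dataclasses.replace(cfg, seed=seed)
        volumes.append(make_phantom(vcfg))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for i, vol in enumerate(volumes):
            img_path = out_dir / f"phantom_{i:03d}.tif"
            mask_path = out_dir / f"phantom_{i:03d}_mask.tif"
            table_path = out_dir / f"phantom_{i:03d}_strands.tsv"
            write_stack(vol.image, img_path)
            write_stack(
                from_float(
                    vol.truth_mask.astype(np.float64),
                    bit_depth=8,
                    spacing_um=vol.image.spacing_um,
                ),
                mask_path,
            )
            vol.strand_table.to_csv(table_path, sep="\t", index=False)
            manifest.append(
                {
                    "volume": i,
                    "seed": vol.seed,
                    "image": img_path.name,
                    "mask": mask_path.name,
                    "strand_table": table_path.name,
                }
            )
        pd.DataFrame(manifest).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return volumes
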