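"""Image-quality and statistical comparison metrics.

PSNR and SSIM compare restored frames against ground truth; CNR measures
vessel contrast against background noise; paired Wilcoxon signed-rank tests
with Bonferroni-adjusted thresholds compare per-frame metric series between
upscaling methods, mirroring how restoration methods are ranked on held-out
stacks.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats


@dataclasses.dataclass
class SsimParams:
    """Stabilization constants and local window for SSIM.

    Defaults follow the common convention: ``C1 = (0.01 R)^2``,
    ``C2 = (0.03 R)^2`` for peak value R, an 11-pixel Gaussian-weighted
    window with sigma 1.5.
    """

    C1: float
    C2: float
    window: int = 11
    sigma: float = 1.5

    @classmethod
    def for_peak(cls, peak: float) -> "SsimParams":
        return cls(C1=(0.01 * peak) ** 2, C2=(0.03 * peak) ** 2)

    def __post_init__(self) -> None:
        if self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("C1 and C2 must be > 0")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and positive")


def psnr(x: np.ndarray, y: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio, ``10 log10(R^2 / MSE)`` in decibels.

    Identical frames give ``+inf``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if peak <= 0:
        raise ValueError("peak must be > 0")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak * peak / mse)


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    r = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(r**2) / (2.0 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    params: SsimParams | None = None,
    peak: float = 255.0,
) -> float:
    """Structural similarity index in [-1, 1].

    The SSIM map is computed on Gaussian-weighted local windows (weighted
    means, variances and covariance) at every position where the full window
    fits, and averaged.  Stabilizers enter as ``(2 mx my + C1)(2 sxy + C2) /
    ((mx^2 + my^2 + C1)(sx^2 + sy^2 + C2))``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    p = params or SsimParams.for_peak(peak)
    if min(x.shape) < p.window:
        raise ValueError(f"frame smaller than the {p.window}-pixel SSIM window")
    w = _gaussian_window(p.window, p.sigma)
    xw = sliding_window_view(x, (p.window, p.window))
    yw = sliding_window_view(y, (p.window, p.window))
    mx = np.einsum("ijkl,kl->ij", xw, w)
    my = np.einsum("ijkl,kl->ij", yw, w)
    mxx = np.einsum("ijkl,kl->ij", xw * xw, w)
    myy = np.einsum("ijkl,kl->ij", yw * yw, w)
    mxy = np.einsum("ijkl,kl->ij", xw * yw, w)
    vx = mxx - mx * mx
    vy = myy - my * my
    cxy = mxy - mx * my
    num = (2 * mx * my + p.C1) * (2 * cxy + p.C2)
    den = (mx * mx + my * my + p.C1) * (vx + vy + p.C2)
    return float(np.mean(num / den))


def cnr(image: np.ndarray, fg_mask: np.ndarray, bg_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio: (mean fg - mean bg) / std bg.

    The background standard deviation is the population (ddof=0) value.
    """
    image = np.asarray(image, dtype=np.float64)
    fg_mask = np.asarray(fg_mask, dtype=bool)
    bg_mask = np.asarray(bg_mask, dtype=bool)
    if not fg_mask.any() or not bg_mask.any():
        raise ValueError("masks must be non-empty")
    if (fg_mask & bg_mask).any():
        raise ValueError("foreground and background masks must be disjoint")
    bg = image[bg_mask]
    sd = float(bg.std())
    if sd == 0.0:
        raise ValueError("zero background variance")
    return float((image[fg_mask].mean() - bg.mean()) / sd)


def paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon's convention); ties receive
    mid-ranks.  The exact null distribution is used for n <= 25, the normal
    approximation with continuity correction above.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("series must be equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    if d.size < 5:
        warnings.warn("fewer than 5 non-zero differences; p-value unreliable",
                      stacklevel=2)
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= 25 and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"), method=method,
        alternative="two-sided",
    )
    return float(res.pvalue)


def bonferroni(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-adjusted significance threshold, ``alpha / m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def metric_report(
    entries: list[dict],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate per-frame metrics with median/IQR summary rows.

    ``entries`` holds dicts with keys ``frame``, ``method``, ``psnr``,
    ``ssim``.  Non-finite PSNR values (identical frames) are excluded from
    the summaries with a warning.
    """
    df = pd.DataFrame(entries, columns=["frame", "method", "psnr", "ssim"])
    rows = []
    for method, grp in df.groupby("method", sort=False):
        ps = grp["psnr"].to_numpy(dtype=float)
        if np.isinf(ps).any():
            warnings.warn(
                f"{np.isinf(ps).sum()} infinite PSNR values excluded from the "
                f"summary for {method!r}", stacklevel=2,
            )
            ps = ps[np.isfinite(ps)]
        ss = grp["ssim"].to_numpy(dtype=float)
        rows.append(
            {
                "method": method,
                "psnr_median": float(np.median(ps)) if ps.size else float("nan"),
                "psnr_iqr": float(np.subtract(*np.percentile(ps, [75, 25])))
                if ps.size
                else float("nan"),
                "ssim_median": float(np.median(ss)),
                "ssim_iqr": float(np.subtract(*np.percentile(ss, [75, 25]))),
            }
        )
    summary = pd.DataFrame(rows)
    return df, summary
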