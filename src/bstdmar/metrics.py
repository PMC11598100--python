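"""Image-quality evaluation: SSIM, PSNR, background normalization,
difference maps and intensity profiles.

SSIM here defaults to the *global* form

    SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
           / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

with image-wide moments and c1 = (k1 L)^2, c2 = (k2 L)^2; a windowed mode
(mean of sliding-square-window evaluations, stride 1) is available for
comparability with common windowed implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy import ndimage

log = logging.getLogger("bstdmar")

__all__ = [
    "SSIMParams",
    "compute_ssim",
    "compute_psnr",
    "normalize_background",
    "absdiff_map",
    "intensity_profile",
    "remove_baseline",
]


@dataclass(frozen=True)
class SSIMParams:
    L: float = 1.0  # dynamic range
    k1: float = 0.01
    k2: float = 0.03
    mode: str = "global"  # global | windowed
    window: int = 8

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("dynamic range L must be positive")
        if self.mode not in ("global", "windowed"):
            raise ValueError(f"unknown SSIM mode {self.mode!r}")

    @property
    def c1(self) -> float:
        return (self.k1 * self.L) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.L) ** 2


def _ssim_from_moments(mx, my, vx, vy, cov, c1, c2):
    return ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )


def compute_ssim(a: np.ndarray, b: np.ndarray, params: SSIMParams = SSIMParams()) -> float:
    """Structural similarity index in [-1, 1]; 1 iff identical."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    c1, c2 = params.c1, params.c2
    if params.mode == "global":
        return float(
            _ssim_from_moments(a.mean(), b.mean(), a.var(), b.var(),
                               np.mean((a - a.mean()) * (b - b.mean())), c1, c2)
        )
    # windowed: uniform local moments, valid region only (stride-1 windows)
    w = params.window
    half = w // 2
    kw = dict(size=w, mode="constant")
    ma = ndimage.uniform_filter(a, **kw)
    mb = ndimage.uniform_filter(b, **kw)
    va = ndimage.uniform_filter(a * a, **kw) - ma**2
    vb = ndimage.uniform_filter(b * b, **kw) - mb**2
    cab = ndimage.uniform_filter(a * b, **kw) - ma * mb
    smap = _ssim_from_moments(ma, mb, va, vb, cab, c1, c2)
    valid = smap[half : a.shape[0] - half, half : a.shape[1] - half]
    return float(valid.mean())


def compute_psnr(a: np.ndarray, b: np.ndarray, max_i: float) -> float:
    """Peak signal-to-noise ratio, 20 log10(MAX) - 10 log10(MSE), in dB.

    Identical images return ``inf`` (the documented sentinel).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return 20.0 * np.log10(max_i) - 10.0 * np.log10(mse)


def _auto_background(ref: np.ndarray) -> np.ndarray:
    """Lowest-decile reference pixels: the air region."""
    return ref <= np.quantile(ref, 0.10)


def normalize_background(
    img: np.ndarray,
    ref: np.ndarray,
    background_region: np.ndarray | None = None,
    match_std: bool = True,
) -> np.ndarray:
    """Rescale ``img`` so its background statistics match ``ref``'s.

    Mirrors the evaluation step of equalizing the background level to the
    implant-free reference before comparing reconstructions.  By default
    the match is affine (mean and standard deviation); ``match_std=False``
    equalizes the background level only, appropriate when both images are
    already on one physical scale and the background is structureless, so
    its standard deviation measures noise rather than gain.
    """
    img = np.asarray(img, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    region = _auto_background(ref) if background_region is None else np.asarray(background_region, bool)
    if not region.any():
        raise ValueError("empty background region")
    mi, si = img[region].mean(), img[region].std()
    mr, sr = ref[region].mean(), ref[region].std()
    if not match_std:
        return img - mi + mr
    if si == 0.0:
        log.warning("normalize_background: zero background variance, offset-only match")
        return img - mi + mr
    return (img - mi) * (sr / si) + mr


def absdiff_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Absolute per-pixel brightness difference |a - b|."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return np.abs(a - b)


def intensity_profile(img: np.ndarray, line: int, axis: str = "row") -> np.ndarray:
    """Extract one row (axis='row') or column (axis='col') as a profile."""
    img = np.asarray(img)
    n = img.shape[0] if axis == "row" else img.shape[1]
    if not 0 <= line < n:
        raise IndexError(f"{axis} index {line} out of range [0, {n})")
    return img[line, :].astype(np.float64) if axis == "row" else img[:, line].astype(np.float64)


def remove_baseline(profile: np.ndarray, order: int = 1) -> np.ndarray:
    """Subtract a least-squares polynomial baseline (default linear)."""
    profile = np.asarray(profile, dtype=np.float64)
    x = np.arange(profile.size)
    coeffs = np.polynomial.polynomial.polyfit(x, profile, order)
    return profile - np.polynomial.polynomial.polyval(x, coeffs)
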