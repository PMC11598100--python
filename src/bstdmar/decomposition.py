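"""Soft/hard-tissue decomposition of a single projection.

The image-formation model is ``f = U*(1 - S) + S`` with all three images
in [0, 1].  Here ``f`` is the attenuation-style projection (1 minus the
flat-field-normalized transmittance, so dense objects are bright), ``S``
the soft-tissue component and ``U`` the hard-tissue (metal/bone)
component.  In this domain the model is exactly multiplicative
Beer-Lambert — ``(1 - f) = (1 - U)*(1 - S)`` — so ``U`` is the dense
object's own attenuation image and ``S`` the soft tissue's.

``S`` inside the mask is estimated by membrane interpolation of the
boundary values; ``U`` follows by algebraic inversion of the model,
``U = (f - S) / (1 - S)``, which is its unique solution away from the
``S -> 1`` degeneracy (guarded by ``eps_clamp``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .membrane import MembraneResult, PyramidFilters, membrane_interpolate

__all__ = [
    "Mask",
    "DecompositionPair",
    "normalize_transmittance",
    "attenuation_image",
    "compute_mask",
    "decompose",
    "recompose",
]


@dataclass
class Mask:
    """Binary high-density mask for one projection frame."""

    pixels: np.ndarray
    threshold_used: float
    dilation_radius: int = 1

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)


@dataclass
class DecompositionPair:
    S: np.ndarray
    U: np.ndarray
    mask: Mask
    eps_clamp: float = 1e-3


def normalize_transmittance(raw: np.ndarray, i0: float | None = None) -> np.ndarray:
    """Flat-field normalization ``t = clip(raw / i0, 0, 1)``.

    ``i0`` defaults to the 99.9th percentile of the frame, a robust proxy
    for the unattenuated (air) intensity when no flat field is available.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if i0 is None:
        i0 = float(np.percentile(raw, 99.9))
    if i0 <= 0:
        raise ValueError(f"i0 must be positive, got {i0}")
    return np.clip(raw / i0, 0.0, 1.0)


def attenuation_image(transmittance: np.ndarray) -> np.ndarray:
    """Map transmittance t in [0,1] to the attenuation image f = 1 - t
    (dense objects bright), the domain of the decomposition model."""
    return 1.0 - np.asarray(transmittance, dtype=np.float64)


def compute_mask(
    raw: np.ndarray, threshold: float, dilation_radius: int = 1
) -> Mask:
    """Threshold the raw-count frame: metal absorbs strongly and appears
    *dark* on the detector, so mask pixels are LOW-count pixels
    (``raw < threshold``), then dilated by a disk to absorb partial-volume
    fringes.  An empty mask is legal (decompose returns S=f, U=0)."""
    raw = np.asarray(raw)
    pixels = raw < threshold
    if dilation_radius > 0 and pixels.any():
        pixels = ndimage.binary_dilation(pixels, structure=disk(dilation_radius))
    return Mask(pixels=pixels, threshold_used=float(threshold), dilation_radius=dilation_radius)


def decompose(
    f: np.ndarray,
    mask: Mask,
    filters: PyramidFilters | None = None,
    eps_clamp: float = 1e-3,
) -> DecompositionPair:
    """Split the attenuation image ``f`` into (S, U).

    S equals ``f`` bit-exactly outside the mask and the membrane fill
    inside; U is ``(f - S)/(1 - S)`` inside the mask (denominator clamped
    below at ``eps_clamp``), clipped to [0, 1] — slight negative values
    arise only from noise, since a dense object can only add attenuation —
    and 0 outside.
    """
    f = np.asarray(f, dtype=np.float64)
    if f.min() < -1e-6 or f.max() > 1 + 1e-6:
        raise ValueError("f must lie in [0, 1]: normalize first")
    m = mask.pixels
    if not m.any():
        return DecompositionPair(S=f.copy(), U=np.zeros_like(f), mask=mask, eps_clamp=eps_clamp)
    S = membrane_interpolate(f, m, filters).values
    U = np.zeros_like(f)
    denom = np.maximum(1.0 - S[m], eps_clamp)
    U[m] = np.clip((f[m] - S[m]) / denom, 0.0, 1.0)
    return DecompositionPair(S=S, U=U, mask=mask, eps_clamp=eps_clamp)


def recompose(S: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Forward model ``f = U*(1 - S) + S``."""
    S = np.asarray(S, dtype=np.float64)
    U = np.asarray(U, dtype=np.float64)
    if S.shape != U.shape:
        raise ValueError(f"shape mismatch: {S.shape} vs {U.shape}")
    return U * (1.0 - S) + S
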