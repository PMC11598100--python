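"""Membrane interpolation: smooth fill of a masked region from its boundary.

Given an image ``f`` and a binary mask ``M`` of pixels to replace, the
membrane is the inverse-distance-weighted (Shepard) interpolant of the
boundary values ``f|dM``,

    r(x) = sum_k w_k(x) b(x_k) / sum_k w_k(x),    w_k(x) = d(x_k, x)^-p

with ``p = 3`` by default.  It is the discrete stand-in for the Laplace
problem ``lap S = 0, S|dM = f|dM`` used to estimate the unobstructed
soft-tissue signal underneath a dense object.

Two evaluators are provided:

* :func:`shepard_direct` — the exact O(K*n) double sum; the reference
  implementation ("oracle") used in the test suite.
* :func:`membrane_interpolate` — the O(n) convolution-pyramid
  approximation: the interpolant is written as a ratio of two convolutions
  with the large-support kernel ``w(d) = d^-p`` (numerator: boundary values
  extended by zero; denominator: the boundary indicator), and each
  convolution is approximated by a multiscale analysis/synthesis pass with
  three small fitted kernels ``(h1, h2, g)``.

The fitted kernels shipped with the package were produced by
:func:`fit_filters` and are loaded lazily; users never need to refit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import ndimage, optimize, signal

__all__ = [
    "BoundaryExtension",
    "PyramidFilters",
    "MembraneResult",
    "extract_boundary",
    "shepard_direct",
    "convpyr_convolve",
    "membrane_interpolate",
    "fit_filters",
    "default_filters",
    "exact_weight_convolve",
]

#: denominator guard in the ratio of convolutions
EPS_DEN = 1e-12


@dataclass(frozen=True)
class BoundaryExtension:
    """Boundary values extended by zero.

    ``r_hat`` equals ``f`` on boundary pixels and 0 elsewhere; ``chi`` is
    the boundary indicator (1 exactly where ``r_hat`` holds a value).
    """

    r_hat: np.ndarray
    chi: np.ndarray

    def __post_init__(self):
        if self.r_hat.shape != self.chi.shape:
            raise ValueError("r_hat and chi must share a shape")


@dataclass
class PyramidFilters:
    """Separable kernel triple driving the convolution pyramid.

    ``h1`` is the analysis (pre-decimation) filter, ``h2`` the synthesis
    (post-zero-insertion) filter, ``g`` the per-level direct contribution.
    ``n_levels=None`` selects ``floor(log2(min side)) - 1`` per image.
    """

    h1: np.ndarray
    h2: np.ndarray
    g: np.ndarray
    n_levels: int | None = None
    weight_exponent: float = 3.0

    def __post_init__(self):
        for name in ("h1", "h2", "g"):
            k = np.asarray(getattr(self, name), dtype=np.float64)
            if k.ndim != 1 or k.size % 2 != 1:
                raise ValueError(f"{name} must be 1D with odd length")
            if not np.all(np.isfinite(k)):
                raise ValueError(f"{name} contains non-finite values")
            if not np.allclose(k, k[::-1]):
                raise ValueError(f"{name} must be symmetric about its center")
            setattr(self, name, k)


@dataclass(frozen=True)
class MembraneResult:
    """Interpolation result; ``values`` is defined inside mask + boundary
    (and, for :func:`membrane_interpolate`, equals the input elsewhere)."""

    values: np.ndarray
    mask: np.ndarray


def extract_boundary(f: np.ndarray, mask: np.ndarray) -> BoundaryExtension:
    """Extract the exterior 8-connected boundary ring of ``mask``.

    The boundary consists of pixels *outside* the mask that are 8-adjacent
    to a mask pixel, so boundary values are never contaminated by in-mask
    (metal) intensities.  Masks touching the image edge lose the part of
    their ring that falls outside the frame; pad beforehand if that matters.
    """
    f = np.asarray(f, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if f.shape != mask.shape:
        raise ValueError("f and mask must share a shape")
    if not mask.any():
        raise ValueError("mask is empty: nothing to interpolate")
    if mask.all():
        raise ValueError("mask covers the whole image: no boundary exists")
    ring = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool)) & ~mask
    if not ring.any():
        raise ValueError("mask has no in-frame boundary (touches every edge?)")
    r_hat = np.where(ring, f, 0.0)
    return BoundaryExtension(r_hat=r_hat, chi=ring)


def shepard_direct(
    bext: BoundaryExtension,
    mask: np.ndarray,
    weight_exponent: float = 3.0,
    chunk: int = 4096,
) -> MembraneResult:
    """Exact inverse-distance-weighted interpolation (the test oracle).

    For every pixel inside ``mask`` the full sum over boundary pixels is
    evaluated with Euclidean distances and weights ``d**-weight_exponent``.
    Boundary pixels keep their exact values; pixels outside mask+boundary
    are NaN.  Complexity O(K * n): use only at small sizes.
    """
    mask = np.asarray(mask, dtype=bool)
    by, bx = np.nonzero(bext.chi)
    b = bext.r_hat[bext.chi]
    if b.size == 0:
        raise ValueError("no boundary pixels")
    iy, ix = np.nonzero(mask)
    out = np.full(mask.shape, np.nan)
    out[bext.chi] = b
    # boundary and interior are disjoint by construction, so d > 0 always
    for lo in range(0, iy.size, chunk):
        sl = slice(lo, lo + chunk)
        d2 = (iy[sl, None] - by) ** 2.0 + (ix[sl, None] - bx) ** 2.0
        assert d2.min() > 0, "boundary pixel inside the mask"
        w = d2 ** (-weight_exponent / 2.0)
        out[iy[sl], ix[sl]] = (w @ b) / w.sum(axis=1)
    return MembraneResult(values=out, mask=mask)


# ---------------------------------------------------------------------------
# convolution pyramid
# ---------------------------------------------------------------------------


def _sepconv(a: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Separable symmetric convolution, zero outside the array."""
    a = ndimage.correlate1d(a, k, axis=0, mode="constant", cval=0.0)
    return ndimage.correlate1d(a, k, axis=1, mode="constant", cval=0.0)


def _auto_levels(shape: tuple[int, int]) -> int:
    return max(1, int(np.floor(np.log2(min(shape)))) - 1)


def convpyr_convolve(x: np.ndarray, filters: PyramidFilters) -> np.ndarray:
    """Approximate ``w * x`` for the large-support kernel via a pyramid.

    Analysis: ``a_{l+1} = down2(h1 * a_l)``.  Synthesis (from the coarsest
    level): ``a_l = h2 * up2(a_{l+1}) + g * a0_l`` where ``a0_l`` is the
    stored analysis result at level ``l``; the level-0 synthesis output is
    returned.  The image is zero-padded by the coarsest-level support and
    cropped afterwards to avoid truncating mass that re-enters near edges.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    n_levels = filters.n_levels or _auto_levels(x.shape)
    # shrink automatically for images too small for the requested depth
    max_levels = max(1, int(np.floor(np.log2(max(4, min(x.shape))))) - 1)
    n_levels = min(n_levels, max_levels)

    pad = 2**n_levels + len(filters.h1)
    xp = np.pad(x, pad, mode="constant")

    levels = [xp]
    a = xp
    for _ in range(n_levels):
        a = _sepconv(a, filters.h1)[::2, ::2]
        levels.append(a)

    ah = _sepconv(levels[-1], filters.g)
    for lev in range(n_levels - 1, -1, -1):
        up = np.zeros_like(levels[lev])
        up[::2, ::2] = ah
        ah = _sepconv(up, filters.h2) + _sepconv(levels[lev], filters.g)
    return ah[pad:-pad, pad:-pad]


def membrane_interpolate(
    f: np.ndarray,
    mask: np.ndarray,
    filters: PyramidFilters | None = None,
    eps_den: float = EPS_DEN,
) -> MembraneResult:
    """Fill ``mask`` with the pyramid-approximated Shepard interpolant.

    Inside the mask the value is the elementwise ratio
    ``convpyr(r_hat) / convpyr(chi)``; outside the mask ``f`` is returned
    unchanged, so the result matches ``f`` bit-exactly on and beyond the
    boundary ring.
    """
    if filters is None:
        filters = default_filters()
    f = np.asarray(f, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    bext = extract_boundary(f, mask)
    num = convpyr_convolve(bext.r_hat, filters)
    den = convpyr_convolve(bext.chi.astype(np.float64), filters)
    inside = mask
    if np.any(den[inside] < eps_den):
        raise FloatingPointError(
            "pyramid denominator vanished inside the mask; "
            "filters are broken or the boundary is empty"
        )
    out = f.copy()
    out[inside] = num[inside] / den[inside]
    return MembraneResult(values=out, mask=mask)


# ---------------------------------------------------------------------------
# kernel fitting
# ---------------------------------------------------------------------------


def weight_kernel(shape: tuple[int, int], weight_exponent: float = 3.0) -> np.ndarray:
    """Dense ``d**-p`` kernel image over all offsets of ``shape``.

    The undefined zero-offset tap is set to 0; comparisons against the
    pyramid are made away from source pixels where it plays no role.
    """
    ky = np.arange(-(shape[0] - 1), shape[0])
    kx = np.arange(-(shape[1] - 1), shape[1])
    d = np.hypot(ky[:, None], kx[None, :])
    with np.errstate(divide="ignore"):
        k = np.where(d > 0, d**-weight_exponent, 0.0)
    return k


def exact_weight_convolve(x: np.ndarray, weight_exponent: float = 3.0) -> np.ndarray:
    """O(n^2) ground-truth convolution with the ``d**-p`` kernel."""
    k = weight_kernel(x.shape, weight_exponent)
    return signal.fftconvolve(x, k, mode="same")


def _unpack(params: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c0, c1, c2, d0, d1, d2, e0, e1 = params
    h1 = np.array([c2, c1, c0, c1, c2])
    h2 = np.array([d2, d1, d0, d1, d2])
    g = np.array([e1, e0, e1])
    return h1, h2, g


def _training_set(rng: np.random.Generator, size: int, n_images: int) -> list[np.ndarray]:
    imgs = []
    imp = np.zeros((size, size))
    imp[size // 2, size // 2] = 1.0
    imgs.append(imp)
    for _ in range(n_images - 1):
        x = np.zeros((size, size))
        k = max(8, size * size // 100)
        idx = rng.choice(size * size, size=k, replace=False)
        x.flat[idx] = rng.uniform(0.1, 1.0, size=k)
        imgs.append(x)
    return imgs


def fit_filters(
    weight_exponent: float = 3.0,
    training_size: int = 64,
    n_images: int = 5,
    seed: int = 0,
    tol: float = 0.05,
) -> PyramidFilters:
    """Fit the ``(h1, h2, g)`` triple against the exact ``d**-p`` kernel.

    Minimizes the squared error between :func:`convpyr_convolve` and the
    exact convolution over a seeded set of sparse random images, evaluated
    away from source pixels (the zero-offset tap of ``d**-p`` is undefined
    and never used by the membrane ratio).  Deterministic given ``seed``.

    Raises ``RuntimeError`` if the relative L2 residual exceeds ``tol``.
    """
    if weight_exponent <= 0:
        raise ValueError("weight_exponent must be positive")
    rng = np.random.default_rng(seed)
    imgs = _training_set(rng, training_size, n_images)
    exact = [exact_weight_convolve(x, weight_exponent) for x in imgs]
    masks = [x == 0 for x in imgs]
    norms = [np.linalg.norm(e[m]) for e, m in zip(exact, masks)]

    def residuals(params: np.ndarray) -> np.ndarray:
        h1, h2, g = _unpack(params)
        filt = PyramidFilters(h1=h1, h2=h2, g=g, weight_exponent=weight_exponent)
        res = []
        for x, e, m, nz in zip(imgs, exact, masks, norms):
            approx = convpyr_convolve(x, filt)
            res.append((approx[m] - e[m]) / nz)
        return np.concatenate(res)

    x0 = np.array([0.375, 0.25, 0.0625, 1.5, 1.0, 0.25, 1.7, 0.6])
    sol = optimize.least_squares(residuals, x0, method="trf", xtol=1e-12, ftol=1e-12)
    h1, h2, g = _unpack(sol.x)
    r = residuals(sol.x)
    rel = float(np.sqrt(np.sum(r**2) / len(imgs)))
    if rel > tol:
        raise RuntimeError(
            f"filter fit did not converge: mean relative L2 residual {rel:.3f} > {tol}"
        )
    return PyramidFilters(h1=h1, h2=h2, g=g, weight_exponent=weight_exponent)


_DEFAULT_CACHE: dict[float, PyramidFilters] = {}


def default_filters(weight_exponent: float = 3.0) -> PyramidFilters:
    """Load the fitted kernels shipped as package data."""
    if weight_exponent not in _DEFAULT_CACHE:
        fname = f"convpyr_w{weight_exponent:g}.json"
        try:
            text = resources.files("bstdmar.data").joinpath(fname).read_text()
        except FileNotFoundError as err:
            raise FileNotFoundError(
                f"no cached filters for weight exponent {weight_exponent:g}; "
                "run fit_filters() and save_filters()"
            ) from err
        d = json.loads(text)
        _DEFAULT_CACHE[weight_exponent] = PyramidFilters(
            h1=np.array(d["h1"]),
            h2=np.array(d["h2"]),
            g=np.array(d["g"]),
            weight_exponent=d["weight_exponent"],
        )
    return _DEFAULT_CACHE[weight_exponent]


def save_filters(filters: PyramidFilters, path) -> None:
    """Serialize a fitted kernel triple as plain JSON."""
    with open(path, "w") as fh:
        json.dump(
            {
                "h1": filters.h1.tolist(),
                "h2": filters.h2.tolist(),
                "g": filters.g.tolist(),
                "weight_exponent": filters.weight_exponent,
            },
            fh,
            indent=2,
        )
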