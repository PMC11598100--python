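"""Reference MAR methods: sinogram-domain LI-MAR and NMAR.

LI-MAR replaces metal-trace bins of each angle-row by 1D linear
interpolation between the nearest clean neighbors; NMAR first divides the
sinogram by a forward-projected tissue-classified prior, interpolates the
normalized trace, and multiplies back.  Interpolation is always performed
on attenuation line integrals (-log transmittance), the domain in which
metal traces are approximately additive; inputs and outputs keep the
stack's stated domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Geometry, ProjectionStack, Volume
from .reconstruction import forward_project

log = logging.getLogger("bstdmar")

__all__ = [
    "Sinogram",
    "build_sinograms",
    "unbuild_sinograms",
    "limar",
    "nmar",
    "make_nmar_prior",
    "prior_sinogram",
]

#: floor on transmittance before taking logs
EPS_T = 1e-6


@dataclass
class Sinogram:
    """One detector row across all angles.

    ``domain`` is ``transmittance`` (values in [0,1], converted to -log
    internally), or ``line_integral`` (already -log).
    """

    values: np.ndarray  # (n_angles, n_cols)
    trace: np.ndarray  # binary, metal-affected bins
    domain: str = "transmittance"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.trace = np.asarray(self.trace, dtype=bool)
        if self.values.shape != self.trace.shape:
            raise ValueError("trace shape must match values")
        if self.domain not in ("transmittance", "line_integral"):
            raise ValueError(f"unknown domain {self.domain!r}")


def build_sinograms(stack: ProjectionStack, masks: np.ndarray) -> list[Sinogram]:
    """Rearrange (angle, row, col) frames into per-row sinograms."""
    frames = stack.frames
    masks = np.asarray(masks, dtype=bool)
    if masks.shape != frames.shape:
        raise ValueError("mask stack misaligned with projection stack")
    if stack.domain == "raw_counts":
        raise ValueError("normalize the stack to transmittance before sinogram work")
    return [
        Sinogram(values=frames[:, r, :], trace=masks[:, r, :], domain="transmittance")
        for r in range(frames.shape[1])
    ]


def unbuild_sinograms(sinos: list[Sinogram], stack: ProjectionStack) -> ProjectionStack:
    """Inverse of :func:`build_sinograms`; restores a stack exactly."""
    frames = np.stack([s.values for s in sinos], axis=1)
    return ProjectionStack(
        frames=frames,
        angles=stack.angles,
        pixel_pitch=stack.pixel_pitch,
        domain=stack.domain,
    )


def _to_line_integral(sino: Sinogram) -> np.ndarray:
    if sino.domain == "line_integral":
        return sino.values.copy()
    return -np.log(np.maximum(sino.values, EPS_T))


def _from_line_integral(p: np.ndarray, sino: Sinogram) -> np.ndarray:
    if sino.domain == "line_integral":
        return p
    return np.exp(-p)


def _interp_rows(p: np.ndarray, trace: np.ndarray) -> np.ndarray:
    """Linear interpolation across traced bins of each angle-row; runs
    touching the row edge are filled by nearest-value extension (np.interp
    endpoint behavior).  Fully traced rows fall back to the mean of the
    adjacent angles' rows."""
    out = p.copy()
    n_cols = p.shape[1]
    cols = np.arange(n_cols)
    full_rows = []
    for i in range(p.shape[0]):
        tr = trace[i]
        if not tr.any():
            continue
        if tr.all():
            full_rows.append(i)
            continue
        out[i, tr] = np.interp(cols[tr], cols[~tr], p[i, ~tr])
    for i in full_rows:
        neighbors = [j for j in (i - 1, i + 1) if 0 <= j < p.shape[0] and not trace[j].all()]
        if neighbors:
            out[i] = np.mean([out[j] for j in neighbors], axis=0)
        log.warning("limar: whole row traced at angle index %d; filled from neighbors", i)
    return out


def limar(sino: Sinogram) -> Sinogram:
    """Linear-interpolation MAR; identity outside the trace, idempotent."""
    p = _to_line_integral(sino)
    filled = _interp_rows(p, sino.trace)
    values = sino.values.copy()
    values[sino.trace] = _from_line_integral(filled, sino)[sino.trace]
    return Sinogram(values=values, trace=sino.trace, domain=sino.domain)


def nmar(sino: Sinogram, prior_sino: Sinogram) -> Sinogram:
    """Normalized MAR: interpolate the prior-normalized sinogram.

    ``prior_sino`` should hold the forward-projected prior in the
    line-integral domain.  For a constant prior, NMAR reduces exactly to
    LI-MAR.
    """
    p = _to_line_integral(sino)
    prior = _to_line_integral(prior_sino) if prior_sino.domain == "transmittance" else prior_sino.values
    if prior.shape != p.shape:
        raise ValueError("prior sinogram shape mismatch")
    if not np.any(prior > 0):
        raise ValueError("prior sinogram is all zero")
    eps = 1e-6 * float(prior.max())
    prior_f = np.maximum(prior, eps)
    norm = p / prior_f
    filled = _interp_rows(norm, sino.trace)
    p_out = filled * prior_f
    values = sino.values.copy()
    values[sino.trace] = _from_line_integral(p_out, sino)[sino.trace]
    return Sinogram(values=values, trace=sino.trace, domain=sino.domain)


def make_nmar_prior(
    uncorrected: Volume, air_threshold: float, soft_threshold: float
) -> Volume:
    """Tissue-classified prior image from an uncorrected reconstruction.

    Voxels below ``air_threshold`` become 0; everything else (including
    metal voxels above ``soft_threshold``) is set to the median
    soft-tissue value, flattening streaks before forward projection.
    """
    v = np.asarray(uncorrected.voxels, dtype=np.float64)
    air = v < air_threshold
    soft = (v >= air_threshold) & (v <= soft_threshold)
    prior = np.zeros_like(v)
    if not soft.any():
        log.warning("make_nmar_prior: degenerate histogram, constant prior")
        return Volume(voxels=prior, voxel_size=uncorrected.voxel_size)
    soft_val = float(np.median(v[soft]))
    prior[~air] = soft_val
    return Volume(voxels=prior, voxel_size=uncorrected.voxel_size)


def prior_sinogram(prior: Volume, geometry: Geometry, slice_index: int = 0) -> Sinogram:
    """Forward-project one prior slice into a line-integral sinogram."""
    img = prior.voxels[slice_index]
    p = forward_project(img, geometry.angles, prior.voxel_size)
    return Sinogram(values=p, trace=np.zeros_like(p, dtype=bool), domain="line_integral")
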