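"""Filtered backprojection (2D parallel) and FDK (3D cone-beam).

Shared conventions: world x right, y up, z along the rotation axis; image
column ``c`` maps to ``x = (c - N//2) * pitch`` and row ``r`` to
``y = (N//2 - r) * pitch``.  A parallel projection at angle ``theta``
(degrees, CCW) integrates along lines ``x cos(theta) + y sin(theta) = s``
with detector coordinate ``s`` centered on index ``N//2`` — the same
convention as ``skimage.transform.radon``, which serves as the forward
projector.

Rows are filtered with a ramp |nu| apodized by a Hamming window
``0.54 + 0.46 cos(pi nu / nu_max)`` (or unapodized, Ram-Lak), applied in
the frequency domain after zero-padding to the next power of two >= twice
the row length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import radon as _sk_radon

from .io import Geometry, ProjectionStack, Volume

__all__ = [
    "FilterSpec",
    "filter_rows",
    "fbp2d",
    "fdk",
    "forward_project",
]


@dataclass(frozen=True)
class FilterSpec:
    kind: str = "hamming"  # hamming | ram-lak
    padding: int | None = None  # next power of two >= 2*N when None

    def __post_init__(self):
        if self.kind not in ("hamming", "ram-lak"):
            raise ValueError(f"unknown filter kind {self.kind!r}")

    def response(self, n_pad: int) -> np.ndarray:
        """Real, even frequency response, zero at DC."""
        nu = np.fft.fftfreq(n_pad)  # cycles / sample, |nu| <= 0.5
        ramp = np.abs(nu)
        if self.kind == "hamming":
            ramp = ramp * (0.54 + 0.46 * np.cos(np.pi * nu / 0.5))
        return ramp


def _pad_length(n: int, spec: FilterSpec) -> int:
    if spec.padding is not None:
        if spec.padding < n:
            raise ValueError("padding shorter than the row")
        return spec.padding
    return int(2 ** np.ceil(np.log2(max(2, 2 * n))))


def filter_rows(rows: np.ndarray, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Apply the windowed ramp to each row (last axis); linear operator.

    Output is in cycles-per-sample units; backprojection divides by the
    physical sample spacing.
    """
    rows = np.asarray(rows, dtype=np.float64)
    if not np.all(np.isfinite(rows)):
        raise ValueError("non-finite values in rows")
    n = rows.shape[-1]
    n_pad = _pad_length(n, spec)
    resp = spec.response(n_pad)
    fr = np.fft.fft(rows, n=n_pad, axis=-1)
    out = np.fft.ifft(fr * resp, axis=-1).real
    return out[..., :n]


def fbp2d(
    sino,
    geometry: Geometry,
    spec: FilterSpec = FilterSpec(),
    size: int | None = None,
    circle: bool = True,
) -> np.ndarray:
    """Parallel-beam filtered backprojection of one sinogram.

    ``sino`` is (n_angles, n_cols) (a ``Sinogram``'s values attribute is
    accepted).  Returns a ``size`` x ``size`` slice (default ``n_cols``)
    in attenuation units of mm^-1, centered on the rotation axis; pixels
    outside the inscribed circle are zeroed when ``circle``.
    """
    values = getattr(sino, "values", sino)
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("sinogram must be 2D (n_angles, n_cols)")
    n_angles, n_cols = values.shape
    if n_angles < 2:
        raise ValueError("need at least 2 angles")
    angles = geometry.angles
    if len(angles) != n_angles:
        raise ValueError("geometry angle count does not match sinogram")
    span = angles[-1] - angles[0] + (angles[-1] - angles[0]) / max(1, n_angles - 1)
    if span < 180 - 1e-6:
        raise ValueError("parallel FBP needs angles spanning at least 180 degrees")
    pitch = geometry.pixel_pitch
    size = size or n_cols

    filt = filter_rows(values, spec) / pitch

    coords = (np.arange(size) - size // 2) * pitch
    X, Yd = np.meshgrid(coords, coords)  # Yd increases downward with row
    Y = -Yd
    out = np.zeros((size, size))
    det = np.arange(n_cols, dtype=np.float64)
    for i, th in enumerate(np.deg2rad(angles)):
        s = (X * np.cos(th) + Y * np.sin(th)) / pitch + n_cols // 2
        out += np.interp(s.ravel(), det, filt[i], left=0.0, right=0.0).reshape(size, size)
    out *= np.pi / n_angles
    if circle:
        r2 = X**2 + Yd**2
        out[r2 > (min(size // 2, size - size // 2 - 1) * pitch) ** 2] = 0.0
    return out


def fdk(
    stack: ProjectionStack,
    geometry: Geometry,
    spec: FilterSpec = FilterSpec(),
    volume_shape: tuple[int, int, int] | None = None,
    circle: bool = True,
) -> Volume:
    """Feldkamp-Davis-Kress reconstruction over a full circular scan.

    Projections are cosine-weighted by ``D / sqrt(D^2 + u^2 + v^2)``
    (detector rescaled to the isocenter), row-filtered with the windowed
    ramp, and backprojected voxel-driven with the ``(D / (D + l))^2``
    distance weight.  For quasi-parallel distances the central slice
    reduces to :func:`fbp2d` of the central-row sinogram.

    ``stack`` must hold line integrals (e.g. -log transmittance).
    """
    if geometry.beam != "cone":
        raise ValueError("fdk requires cone-beam geometry")
    d_so = geometry.source_object_dist
    frames = np.asarray(stack.frames, dtype=np.float64)
    n_angles, n_rows, n_cols = frames.shape
    pitch_iso = geometry.pixel_pitch / geometry.magnification

    u = (np.arange(n_cols) - n_cols // 2) * pitch_iso
    v = (n_rows // 2 - np.arange(n_rows)) * pitch_iso
    cosw = d_so / np.sqrt(d_so**2 + u[None, :] ** 2 + v[:, None] ** 2)

    if volume_shape is None:
        volume_shape = (n_rows, n_cols, n_cols)
    nz, ny, nx = volume_shape
    xs = (np.arange(nx) - nx // 2) * pitch_iso
    ys = (ny // 2 - np.arange(ny)) * pitch_iso
    zs = (np.arange(nz) - nz // 2) * pitch_iso

    X = xs[None, None, :]
    Y = ys[None, :, None]
    Z = zs[:, None, None]

    vol = np.zeros(volume_shape)
    angles = np.deg2rad(stack.angles)
    for i, beta in enumerate(angles):
        p = filter_rows(frames[i] * cosw, spec) / pitch_iso
        t = X * np.cos(beta) + Y * np.sin(beta)
        ell = -X * np.sin(beta) + Y * np.cos(beta)
        L = d_so + ell
        mag = d_so / L
        cu = (t * mag) / pitch_iso + n_cols // 2
        rv = n_rows // 2 - (Z * mag) / pitch_iso
        sample = ndimage.map_coordinates(
            p,
            np.stack([np.broadcast_to(rv, volume_shape).ravel(),
                      np.broadcast_to(cu, volume_shape).ravel()]),
            order=1,
            mode="constant",
            cval=0.0,
        ).reshape(volume_shape)
        vol += mag**2 * sample
    vol *= np.pi / n_angles
    if circle:
        r2 = xs[None, :] ** 2 + ys[:, None] ** 2
        vol[:, r2 > (min(nx, ny) // 2 * pitch_iso) ** 2] = 0.0
    return Volume(voxels=vol, voxel_size=pitch_iso)


def forward_project(image: np.ndarray, angles_deg: np.ndarray, pixel_pitch: float = 1.0) -> np.ndarray:
    """Parallel-beam line integrals of a 2D image (mm^-1 voxels -> unitless).

    Thin wrapper over ``skimage.transform.radon`` returning shape
    (n_angles, n_cols) in this module's angle/detector convention; the
    image must vanish outside the inscribed circle.
    """
    sino = _sk_radon(np.asarray(image, dtype=np.float64), theta=np.asarray(angles_deg), circle=True)
    return sino.T * pixel_pitch
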