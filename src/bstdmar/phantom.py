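"""Polychromatic phantom simulator for paired with/without-metal scans.

The scene emulates a bench-top micro-CT test object: a plastic sleeve
(annulus) holding brick-like rectangular inserts and a wooden strip, with
an optional high-attenuation metal rod.  The with/without pair shares the
exact geometry, spectrum, flat field and noise stream and differs only
where the metal sits, so the metal-free scan is a true reference.

Attenuation follows a two-term model mu(E) = a * E^-3 + b (mm^-1, E in
keV): the E^-3 photoelectric term preferentially absorbs low-energy
photons, producing the beam-hardening streaks the decomposition method is
designed to remove, while b is the weakly energy-dependent Compton floor.
Detected intensity per ray is the spectrum-weighted Beer-Lambert sum

    I = i0 * sum_E w(E) * exp(-sum_m mu_m(E) * l_m)

with material path lengths l_m from parallel-beam ray tracing of the
per-material indicator maps (cone-beam 3D scenes use a stepping ray
marcher).  A single-bin spectrum disables beam hardening and serves as
ground truth.

Randomness uses ``numpy.random.default_rng`` (PCG64) seeded explicitly;
all outputs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Geometry, ProjectionStack, Volume
from .reconstruction import FilterSpec, fbp2d, forward_project

__all__ = [
    "Material",
    "MaterialPhantom",
    "Spectrum",
    "SimConfig",
    "default_materials",
    "default_spectrum",
    "make_phantom",
    "make_phantom_3d",
    "polychromatic_project",
    "cone_project",
    "paired_dataset",
]

AIR, PLASTIC, WOOD, METAL = 0, 1, 2, 3

#: transmittance floor before taking logs for the reference reconstruction
EPS_REF = 1e-9


@dataclass(frozen=True)
class Material:
    """mu(E) = a * E^-3 + b, in mm^-1 with E in keV."""

    name: str
    a: float
    b: float

    def mu(self, energy_kev) -> np.ndarray:
        e = np.asarray(energy_kev, dtype=np.float64)
        out = self.a * e**-3.0 + self.b
        if np.any(out < 0):
            raise ValueError(f"negative attenuation for {self.name}")
        return out


def default_materials() -> dict[int, Material]:
    # chosen so metal >> plastic > wood > air at every modeled energy, and
    # so the metal shadow of a 1 mm rod spans the raw-count range that the
    # 5,000-10,000 mask thresholds probe (see docs/methods.md)
    return {
        AIR: Material("air", 0.0, 0.0),
        PLASTIC: Material("plastic", 2.5e3, 0.025),
        WOOD: Material("wood", 1.0e3, 0.012),
        METAL: Material("metal", 1.5e5, 0.3),
    }


@dataclass(frozen=True)
class Spectrum:
    """Discrete photon spectrum: keV bin centers and fractions."""

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "energies", np.asarray(self.energies, dtype=np.float64))
        w = np.asarray(self.weights, dtype=np.float64)
        if np.any(w < 0):
            raise ValueError("spectrum weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("spectrum weights must sum to 1")
        object.__setattr__(self, "weights", w)


def default_spectrum() -> Spectrum:
    return Spectrum(energies=[30.0, 50.0, 70.0], weights=[0.25, 0.5, 0.25])


def mono_spectrum(energy_kev: float = 50.0) -> Spectrum:
    return Spectrum(energies=[energy_kev], weights=[1.0])


@dataclass
class MaterialPhantom:
    labels: np.ndarray  # 2D (ny, nx) or 3D (nz, ny, nx) material ids
    materials: dict[int, Material]
    pixel_size: float  # mm

    def mu_map(self, energy_kev: float) -> np.ndarray:
        out = np.zeros(self.labels.shape)
        for mid, mat in self.materials.items():
            out[self.labels == mid] = mat.mu(energy_kev)
        return out


def make_phantom(
    size: int = 256,
    with_metal: bool = True,
    seed: int = 0,
    pixel_size: float = 0.1,
    metal_radius_px: int = 10,
) -> MaterialPhantom:
    """Seeded 2D slice phantom: plastic sleeve, brick inserts, wooden
    strip, optional metal rod.

    The with/without-metal pair for one seed differs ONLY at metal-labeled
    pixels (paired-acquisition contract).
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    rng = np.random.default_rng(seed)
    labels = np.zeros((size, size), dtype=np.int8)
    yy, xx = np.mgrid[:size, :size]
    cy = cx = size // 2
    r = np.hypot(yy - cy, xx - cx)

    r_out = int(size * 0.46)
    labels[(r < r_out) & (r >= r_out - size // 32)] = PLASTIC

    # brick-like rectangular inserts
    n_bricks = rng.integers(4, 7)
    for _ in range(n_bricks):
        h = rng.integers(size // 16, size // 6)
        w = rng.integers(size // 16, size // 6)
        y0 = rng.integers(cy - r_out // 2, cy + r_out // 2 - h)
        x0 = rng.integers(cx - r_out // 2, cx + r_out // 2 - w)
        labels[y0 : y0 + h, x0 : x0 + w] = PLASTIC

    # wooden strip across the interior
    sy = rng.integers(cy - r_out // 2, cy + r_out // 2)
    th = max(3, size // 40)
    strip = (yy >= sy) & (yy < sy + th) & (r < r_out - size // 32)
    labels[strip] = WOOD

    # mounting channel for the implant, drilled in BOTH variants so the
    # pair differs only at metal pixels and the rod displaces nothing
    off = size // 14
    my, mx = cy - off, cx + off // 2
    rod_r = np.hypot(yy - my, xx - mx)
    labels[rod_r < metal_radius_px + 2] = AIR
    if with_metal:
        labels[rod_r < metal_radius_px] = METAL

    return MaterialPhantom(labels=labels, materials=default_materials(), pixel_size=pixel_size)


def make_phantom_3d(
    size: int = 64, with_metal: bool = True, seed: int = 0, pixel_size: float = 0.2
) -> MaterialPhantom:
    """Small 3D scene (sphere in a sleeve, axial metal rod) for cone-beam
    smoke runs."""
    rng = np.random.default_rng(seed)
    labels = np.zeros((size, size, size), dtype=np.int8)
    zz, yy, xx = np.mgrid[:size, :size, :size]
    c = size // 2
    r = np.hypot(yy - c, xx - c)
    labels[(r < size * 0.4) & (r >= size * 0.34)] = PLASTIC
    sy, sx = rng.integers(c - size // 8, c + size // 8, 2)
    sphere = (zz - c) ** 2 + (yy - sy) ** 2 + (xx - sx) ** 2 < (size // 6) ** 2
    labels[sphere] = WOOD
    if with_metal:
        rod = (np.hypot(yy - c + size // 8, xx - c - size // 8) < size // 16) & (
            np.abs(zz - c) < size // 4
        )
        labels[rod] = METAL
    return MaterialPhantom(labels=labels, materials=default_materials(), pixel_size=pixel_size)


@dataclass
class SimConfig:
    """Study conditions of the scaled-down paired experiment."""

    size: int = 256
    n_angles: int = 360
    detector_rows: int = 32
    metal_rows: tuple[int, int] | None = None  # rod z-extent; central half when None
    pixel_pitch: float = 0.1  # mm
    i0: float = 30000.0
    noise: str = "poisson"  # none | poisson
    spectrum: Spectrum = field(default_factory=default_spectrum)
    reference_energy: float = 50.0  # keV, monochromatic ground-truth bin

    def resolved_metal_rows(self) -> tuple[int, int]:
        if self.metal_rows is not None:
            return self.metal_rows
        return (self.detector_rows // 4, 3 * self.detector_rows // 4)

    def geometry(self) -> Geometry:
        return Geometry(
            detector_rows=self.detector_rows,
            detector_cols=self.size,
            pixel_pitch=self.pixel_pitch,
            beam="parallel",
            n_angles=self.n_angles,
        )


def _material_path_lengths(
    phantom: MaterialPhantom, angles_deg: np.ndarray
) -> dict[int, np.ndarray]:
    """Parallel-beam intersection lengths (mm) per material, (n_angles, n_cols)."""
    out = {}
    for mid in np.unique(phantom.labels):
        if mid == AIR:
            continue
        ind = (phantom.labels == mid).astype(np.float64)
        out[int(mid)] = forward_project(ind, angles_deg, phantom.pixel_size)
    return out


def polychromatic_project(
    phantom: MaterialPhantom,
    geometry: Geometry,
    spectrum: Spectrum,
    i0: float = 30000.0,
    noise: str = "none",
    seed: int = 0,
    metal_rows: tuple[int, int] | None = None,
) -> ProjectionStack:
    """Forward-project a 2D slice phantom into full 2D detector frames.

    Non-metal materials are extruded uniformly along the rotation axis
    (every detector row sees the same structure); the metal rod has finite
    axial extent ``metal_rows`` so its shadow is interior to the frame, as
    an implant's would be.  Rays missing the object see the full flat
    field ``i0``.
    """
    if phantom.labels.ndim != 2:
        raise ValueError("polychromatic_project expects a 2D slice phantom")
    angles = geometry.angles
    paths = _material_path_lengths(phantom, angles)
    n_rows = geometry.detector_rows
    if metal_rows is None:
        metal_rows = (n_rows // 4, 3 * n_rows // 4)

    def attenuated(include_metal_row: bool) -> np.ndarray:
        t = np.zeros((geometry.n_angles, geometry.detector_cols))
        for e, w in zip(spectrum.energies, spectrum.weights):
            od = np.zeros_like(t)
            for mid, ell in paths.items():
                if mid == METAL and not include_metal_row:
                    continue
                od += phantom.materials[mid].mu(e) * ell
            t += w * np.exp(-od)
        return t

    t_struct = attenuated(include_metal_row=False)
    has_metal = METAL in paths
    t_metal = attenuated(include_metal_row=True) if has_metal else t_struct

    frames = np.empty((geometry.n_angles, n_rows, geometry.detector_cols))
    r0, r1 = metal_rows
    for r in range(n_rows):
        frames[:, r, :] = i0 * (t_metal if (has_metal and r0 <= r < r1) else t_struct)

    if noise == "poisson":
        rng = np.random.default_rng(seed)
        frames = rng.poisson(frames).astype(np.float64)
    elif noise != "none":
        raise ValueError(f"unknown noise model {noise!r}")
    return ProjectionStack(
        frames=frames, angles=angles, pixel_pitch=geometry.pixel_pitch, domain="raw_counts"
    )


def cone_project(
    phantom: MaterialPhantom,
    geometry: Geometry,
    spectrum: Spectrum,
    i0: float = 30000.0,
    noise: str = "none",
    seed: int = 0,
    step_vox: float = 0.5,
) -> ProjectionStack:
    """Cone-beam polychromatic projection of a 3D phantom by ray marching.

    Rays step through the label volume at ``step_vox`` voxel increments
    with nearest-neighbor lookup — adequate for smoke-scale scenes.
    """
    if phantom.labels.ndim != 3:
        raise ValueError("cone_project expects a 3D phantom")
    if geometry.beam != "cone":
        raise ValueError("cone_project needs cone-beam geometry")
    nz, ny, nx = phantom.labels.shape
    vox = phantom.pixel_size
    d_so, d_sd = geometry.source_object_dist, geometry.source_detector_dist
    nr, nc = geometry.detector_rows, geometry.detector_cols
    pitch = geometry.pixel_pitch

    mids = [int(m) for m in np.unique(phantom.labels) if m != AIR]
    mus = {
        m: np.array([phantom.materials[m].mu(e) for e in spectrum.energies])
        for m in mids
    }

    u = (np.arange(nc) - nc // 2) * pitch
    v = (nr // 2 - np.arange(nr)) * pitch
    U, V = np.meshgrid(u, v)

    half = max(nx, ny, nz) * vox / 2 * np.sqrt(3)
    n_steps = int(2 * half / (step_vox * vox)) + 2
    ts = d_so - half + np.arange(n_steps) * (2 * half / n_steps)
    dt = 2 * half / n_steps

    frames = np.empty((geometry.n_angles, nr, nc))
    for i, beta in enumerate(np.deg2rad(geometry.angles)):
        src = np.array([d_so * np.sin(beta), -d_so * np.cos(beta), 0.0])
        det_u = np.array([np.cos(beta), np.sin(beta), 0.0])
        det_v = np.array([0.0, 0.0, 1.0])
        det_dir = np.array([-np.sin(beta), np.cos(beta), 0.0])
        det_pos = (
            src[None, None, :]
            + d_sd * det_dir[None, None, :]
            + U[..., None] * det_u[None, None, :]
            + V[..., None] * det_v[None, None, :]
        )
        rays = det_pos - src
        rays /= np.linalg.norm(rays, axis=-1, keepdims=True)
        lengths = {m: np.zeros((nr, nc)) for m in mids}
        for t in ts:
            pos = src[None, None, :] + t * rays
            ix = np.rint(pos[..., 0] / vox + nx // 2).astype(int)
            iy = np.rint(ny // 2 - pos[..., 1] / vox).astype(int)
            iz = np.rint(pos[..., 2] / vox + nz // 2).astype(int)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
            lab = np.zeros((nr, nc), dtype=np.int8)
            lab[ok] = phantom.labels[iz[ok], iy[ok], ix[ok]]
            for m in mids:
                lengths[m] += (lab == m) * dt
        t_frame = np.zeros((nr, nc))
        for k, w in enumerate(spectrum.weights):
            od = np.zeros((nr, nc))
            for m in mids:
                od += mus[m][k] * lengths[m]
            t_frame += w * np.exp(-od)
        frames[i] = i0 * t_frame

    if noise == "poisson":
        rng = np.random.default_rng(seed)
        frames = rng.poisson(frames).astype(np.float64)
    return ProjectionStack(
        frames=frames, angles=geometry.angles, pixel_pitch=pitch, domain="raw_counts"
    )


def paired_dataset(config: SimConfig | None = None, seed: int = 0) -> dict:
    """Simulate the paired with/without-metal experiment.

    Both stacks share geometry, angles, spectrum, flat field and noise
    seed; ``reference_volume`` is the monochromatic, noise-free, metal-free
    reconstruction (the ground-truth analogue of the reference scan).
    """
    config = config or SimConfig()
    geo = config.geometry()
    ph_with = make_phantom(config.size, with_metal=True, seed=seed, pixel_size=config.pixel_pitch)
    ph_wo = make_phantom(config.size, with_metal=False, seed=seed, pixel_size=config.pixel_pitch)

    kw = dict(
        geometry=geo,
        spectrum=config.spectrum,
        i0=config.i0,
        noise=config.noise,
        seed=seed,
        metal_rows=config.resolved_metal_rows(),
    )
    with_metal = polychromatic_project(ph_with, **kw)
    without_metal = polychromatic_project(ph_wo, **kw)

    # monochromatic metal-free ground truth, reconstructed noise-free
    mono = polychromatic_project(
        ph_wo,
        geometry=geo,
        spectrum=mono_spectrum(config.reference_energy),
        i0=config.i0,
        noise="none",
        seed=seed,
        metal_rows=config.resolved_metal_rows(),
    )
    t = np.clip(mono.frames[:, config.detector_rows // 2, :] / config.i0, EPS_REF, 1.0)
    ref_slice = fbp2d(-np.log(t), geo, FilterSpec("hamming"))
    return {
        "with_metal": with_metal,
        "without_metal": without_metal,
        "reference_volume": Volume(voxels=ref_slice[None], voxel_size=config.pixel_pitch),
        "phantom_with": ph_with,
        "phantom_without": ph_wo,
        "geometry": geo,
        "config": config,
    }
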