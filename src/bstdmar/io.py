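"""Projection-stack, mask and volume I/O plus acquisition geometry.

Conventions (stated once, used everywhere):

* angles are in degrees, counter-clockwise positive; frame ``i`` sits at
  ``angles[i]``; uniform spacing is endpoint-exclusive
  (``0 ... range*(n-1)/n``);
* detector row 0 is the top, column 0 the left, 0-based indexing;
* all internal computation is 64-bit float; raw files keep their native
  dtype until transmittance normalization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

log = logging.getLogger("bstdmar")

__all__ = [
    "Geometry",
    "ProjectionStack",
    "Volume",
    "read_projection_stack",
    "write_projection_stack",
    "read_volume",
    "write_volume",
    "write_mask_stack",
    "geometry_from_yaml",
]


@dataclass
class Geometry:
    """Acquisition geometry of a circular-trajectory scan."""

    detector_rows: int
    detector_cols: int
    pixel_pitch: float  # mm at the detector
    beam: str = "parallel"  # parallel | fan | cone
    n_angles: int = 360
    rotation_deg: float = 360.0
    source_object_dist: float | None = None  # mm
    source_detector_dist: float | None = None  # mm

    def __post_init__(self):
        if self.beam not in ("parallel", "fan", "cone"):
            raise ValueError(f"unknown beam type {self.beam!r}")
        if self.beam in ("fan", "cone"):
            if self.source_object_dist is None or self.source_detector_dist is None:
                raise ValueError(f"{self.beam} beam requires source distances")
            if not (self.source_detector_dist > self.source_object_dist > 0):
                raise ValueError(
                    "need source_detector_dist > source_object_dist > 0"
                )

    @property
    def angles(self) -> np.ndarray:
        """Uniform endpoint-exclusive angle grid in degrees."""
        n = self.n_angles
        return np.arange(n) * (self.rotation_deg / n)

    @property
    def magnification(self) -> float:
        if self.beam == "parallel":
            return 1.0
        return self.source_detector_dist / self.source_object_dist

    def to_dict(self) -> dict:
        return {
            "detector_rows": self.detector_rows,
            "detector_cols": self.detector_cols,
            "pixel_pitch": self.pixel_pitch,
            "beam": self.beam,
            "n_angles": self.n_angles,
            "rotation_deg": self.rotation_deg,
            "source_object_dist": self.source_object_dist,
            "source_detector_dist": self.source_detector_dist,
        }


@dataclass
class ProjectionStack:
    """Ordered stack of 2D detector frames with their angles.

    ``domain`` flags whether frames hold detector counts (``raw_counts``)
    or flat-field-normalized transmittance in [0, 1] (``transmittance``).
    """

    frames: np.ndarray  # (n_angles, rows, cols)
    angles: np.ndarray  # degrees, strictly increasing
    pixel_pitch: float
    domain: str = "raw_counts"

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_angles, rows, cols)")
        if len(self.angles) != self.frames.shape[0]:
            raise ValueError("n_angles != len(angles)")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.domain not in ("raw_counts", "transmittance"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.domain == "raw_counts" and self.frames.size and self.frames.min() < 0:
            raise ValueError("raw counts must be non-negative")
        if self.domain == "transmittance" and self.frames.size:
            if self.frames.min() < 0 or self.frames.max() > 1 + 1e-6:
                raise ValueError("transmittance must lie in [0, 1]")

    @property
    def n_angles(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class Volume:
    """Reconstructed scalar field; the volume center sits on the rotation
    axis."""

    voxels: np.ndarray  # (nz, ny, nx)
    voxel_size: float  # mm

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 2D or 3D")


_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_projection_stack(path, config: Geometry) -> ProjectionStack:
    """Load a projection stack from multi-page TIFF, a directory of
    per-angle TIFFs (lexicographic order = angle order), or HDF5.

    Angles come from ``config`` (uniform endpoint-exclusive spacing) unless
    a sidecar is present: ``angles.txt`` in the directory, ``<file>.angles.txt``
    next to a TIFF, or an ``angles`` dataset in HDF5.
    """
    path = Path(path)
    sidecar_angles = None
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no TIFF files in {path}")
        frames = []
        shape = None
        for p in files:
            img = tifffile.imread(p)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(
                    f"frame shape mismatch: {p.name} is {img.shape}, expected {shape}"
                )
            frames.append(img)
        frames = np.stack(frames)
        ang_file = path / "angles.txt"
        if ang_file.exists():
            sidecar_angles = np.loadtxt(ang_file, ndmin=1)
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        ang_file = path.with_suffix(path.suffix + ".angles.txt")
        if ang_file.exists():
            sidecar_angles = np.loadtxt(ang_file, ndmin=1)
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            frames = fh["projections"][()]
            if "angles" in fh:
                sidecar_angles = fh["angles"][()]
    else:
        raise ValueError(f"unsupported projection container: {path}")

    n = frames.shape[0]
    if sidecar_angles is not None:
        if len(sidecar_angles) != n:
            raise ValueError("angle sidecar length does not match frame count")
        angles = np.asarray(sidecar_angles, dtype=np.float64)
    else:
        if config is None:
            raise ValueError("no angle information: pass a Geometry config")
        angles = np.arange(n) * (config.rotation_deg / n)
    log.info("read_projection_stack: %s frames %s from %s", n, frames.shape[1:], path)
    return ProjectionStack(
        frames=frames,
        angles=angles,
        pixel_pitch=config.pixel_pitch,
        domain="raw_counts",
    )


def write_projection_stack(stack: ProjectionStack, path) -> Path:
    """Write frames as a multi-page TIFF (native dtype preserved)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    np.savetxt(path.with_suffix(path.suffix + ".angles.txt"), stack.angles)
    return path


def write_mask_stack(masks: np.ndarray, path) -> Path:
    """Masks are stored as 8-bit TIFF stacks (0/255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(masks, bool) * np.uint8(255)), photometric="minisblack")
    return path


def write_volume(vol: Volume, path) -> Path:
    """Slice-per-page float32 TIFF plus a JSON sidecar with voxel_size.

    Read-back through :func:`read_volume` is bit-exact for float32 data.
    """
    if not np.all(np.isfinite(vol.voxels)):
        raise ValueError("volume contains NaN/Inf voxels")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vol.voxels.astype(np.float32), photometric="minisblack")
    meta = path.with_suffix(path.suffix + ".meta.json")
    meta.write_text(json.dumps({"voxel_size_mm": vol.voxel_size}, indent=2))
    return path


def read_volume(path) -> Volume:
    path = Path(path)
    voxels = tifffile.imread(path)
    meta = path.with_suffix(path.suffix + ".meta.json")
    voxel_size = 1.0
    if meta.exists():
        voxel_size = float(json.loads(meta.read_text())["voxel_size_mm"])
    return Volume(voxels=voxels, voxel_size=voxel_size)


def geometry_from_yaml(src) -> Geometry:
    """Build a :class:`Geometry` from a YAML/JSON file or a mapping."""
    if isinstance(src, (str, Path)):
        with open(src) as fh:
            src = yaml.safe_load(fh)
    return Geometry(**src)
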