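"""End-to-end workflow: simulate/load -> mask -> decompose -> reconstruct
-> evaluate, with LI-MAR/NMAR baselines for comparison.

The scaled-down working surface is the central detector row of a
parallel-beam stack, reconstructed with 2D FBP; full cone-beam volumes go
through :func:`bstdmar.reconstruction.fdk` with the same projection-domain
processing.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .baselines import Sinogram, limar, make_nmar_prior, nmar, prior_sinogram
from .decomposition import attenuation_image, compute_mask, decompose, normalize_transmittance
from .io import Geometry, ProjectionStack, Volume, write_mask_stack, write_projection_stack, write_volume, read_projection_stack
from .membrane import PyramidFilters, default_filters
from .metrics import SSIMParams, absdiff_map, compute_psnr, compute_ssim, normalize_background
from .phantom import METAL, SimConfig, paired_dataset
from .reconstruction import FilterSpec, fbp2d, forward_project

log = logging.getLogger("bstdmar")

__all__ = [
    "RunConfig",
    "decompose_stack",
    "reconstruct_row",
    "evaluate_against_reference",
    "run_pipeline",
    "threshold_sweep",
]

EPS_T = 1e-9


@dataclass
class RunConfig:
    """One pipeline run; exactly one of ``input_path``/``simulate`` is set."""

    input_path: str | None = None
    geometry: Geometry | None = None
    simulate: SimConfig | None = None
    mask_threshold: float = 10000.0
    mask_dilation: int = 1
    method: str = "bstd"  # bstd | limar | nmar | none
    component: str = "soft"  # soft | hard | both
    filter_kind: str = "hamming"
    prior_air_th: float = 0.01  # mm^-1, NMAR prior classification
    prior_soft_th: float = 0.1
    output_dir: str = "bstdmar_out"
    seed: int = 0

    def __post_init__(self):
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path / simulate must be given")
        if self.method not in ("bstd", "limar", "nmar", "none"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.component not in ("soft", "hard", "both"):
            raise ValueError(f"unknown component {self.component!r}")


def decompose_stack(
    stack: ProjectionStack,
    threshold: float,
    dilation: int = 1,
    filters: PyramidFilters | None = None,
    i0: float | None = None,
):
    """Mask and decompose every projection frame.

    Masks are thresholded on RAW COUNTS (comparable with scanner-unit
    thresholds); the decomposition itself runs on attenuation images
    ``1 - transmittance``.  Returns (S_stack, U_stack, mask_stack,
    t_stack) where S/U are attenuation-domain and t is the input
    transmittance.
    """
    if filters is None:
        filters = default_filters()
    frames = stack.frames
    n = frames.shape[0]
    S = np.empty(frames.shape)
    U = np.empty(frames.shape)
    masks = np.empty(frames.shape, dtype=bool)
    t_stack = np.empty(frames.shape)
    for i in range(n):
        raw = frames[i]
        t = normalize_transmittance(raw, i0) if stack.domain == "raw_counts" else raw
        f = attenuation_image(t)
        # thresholds are raw-count units; for already-normalized stacks the
        # same rule applies with a transmittance-scale threshold
        mask = compute_mask(raw, threshold, dilation)
        pair = decompose(f, mask, filters)
        S[i], U[i], masks[i], t_stack[i] = pair.S, pair.U, mask.pixels, t
    return S, U, masks, t_stack


def reconstruct_row(
    t_sino: np.ndarray, geometry: Geometry, spec: FilterSpec
) -> np.ndarray:
    """FBP of one transmittance sinogram row (-log line integrals)."""
    p = -np.log(np.maximum(t_sino, EPS_T))
    return fbp2d(p, geometry, spec)


def evaluate_against_reference(
    recon: np.ndarray, reference: np.ndarray, windowed: bool = False
) -> dict:
    """Background-normalize then score SSIM/PSNR against the reference."""
    recn = normalize_background(recon, reference, match_std=False)
    L = float(reference.max())
    params = SSIMParams(L=L, mode="windowed" if windowed else "global")
    return {
        "ssim": compute_ssim(recn, reference, params),
        "psnr_db": compute_psnr(recn, reference, max_i=L),
        "absdiff_mean": float(absdiff_map(recn, reference).mean()),
    }


def _central_row_sinogram(t_stack: np.ndarray, row: int) -> np.ndarray:
    return t_stack[:, row, :]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the four-step workflow and write every intermediate.

    Steps: acquire/simulate projections f_i -> per-projection masks M_i ->
    decomposition (S_i, U_i) -> reconstruction of the selected
    component(s).  ``method='none'`` skips MAR; ``limar``/``nmar`` replace
    the decomposition with sinogram interpolation.  Fully deterministic
    for a fixed config + seed.
    """
    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "acquire"
    try:
        reference = None
        if config.simulate is not None:
            data = paired_dataset(config.simulate, seed=config.seed)
            stack = data["with_metal"]
            geometry = data["geometry"]
            reference = data["reference_volume"].voxels[0]
            i0 = config.simulate.i0
            row = config.simulate.detector_rows // 2
            write_projection_stack(stack, out / "projections.tif")
        else:
            geometry = config.geometry
            if geometry is None:
                raise ValueError("loading projections requires a geometry")
            stack = read_projection_stack(config.input_path, geometry)
            i0 = None
            row = geometry.detector_rows // 2
        spec = FilterSpec(config.filter_kind)

        stage = "mask+decompose"
        S, U, masks, t_stack = decompose_stack(
            stack, config.mask_threshold, config.mask_dilation, i0=i0
        )
        write_mask_stack(masks, out / "masks.tif")
        _write_f32(out / "soft_attenuation.tif", S)
        _write_f32(out / "hard_attenuation.tif", U)

        stage = f"correct[{config.method}]"
        t_sino = _central_row_sinogram(t_stack, row)
        trace = masks[:, row, :]
        if config.method == "bstd":
            t_soft = 1.0 - S[:, row, :]
            corrected = {"soft": t_soft}
            if config.component in ("hard", "both"):
                corrected["hard"] = 1.0 - U[:, row, :]
        elif config.method in ("limar", "nmar"):
            sino = Sinogram(values=t_sino, trace=trace, domain="transmittance")
            if config.method == "limar":
                fixed = limar(sino)
            else:
                uncorr = fbp2d(-np.log(np.maximum(t_sino, EPS_T)), geometry, spec)
                prior = make_nmar_prior(
                    Volume(voxels=uncorr[None], voxel_size=geometry.pixel_pitch),
                    config.prior_air_th,
                    config.prior_soft_th,
                )
                fixed = nmar(sino, prior_sinogram(prior, geometry))
            corrected = {"soft": fixed.values}
        else:  # none
            corrected = {"soft": t_sino}

        stage = "reconstruct"
        volumes = {}
        for name, t_corr in corrected.items():
            sl = reconstruct_row(t_corr, geometry, spec)
            vol = Volume(voxels=sl[None], voxel_size=geometry.pixel_pitch)
            write_volume(vol, out / f"recon_{name}.tif")
            volumes[name] = vol

        stage = "evaluate"
        metrics = {}
        if reference is not None and "soft" in volumes:
            metrics = evaluate_against_reference(volumes["soft"].voxels[0], reference)
            with open(out / "metrics.csv", "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["method", "ssim", "psnr_db", "absdiff_mean"])
                w.writerow([config.method, metrics["ssim"], metrics["psnr_db"], metrics["absdiff_mean"]])

        provenance = {
            "package_version": __version__,
            "seed": config.seed,
            "config": _config_dict(config),
            "elapsed_s": time.time() - t_start,
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
        return {"volumes": volumes, "metrics": metrics, "provenance": provenance}
    except Exception:
        (out / ".partial").touch()
        log.error("pipeline failed at stage %r", stage)
        raise


def threshold_sweep(config: RunConfig, thresholds: list[float]) -> list[dict]:
    """Run the pipeline once per mask threshold; returns one metrics row
    per threshold (plus metal-coverage when simulating).

    On simulated data the metal-shadow coverage of the mask is
    non-decreasing in the threshold, and the best SSIM is reached once the
    mask fully covers the implant shadow.
    """
    if len(thresholds) < 2:
        raise ValueError("need at least 2 thresholds to sweep")
    rows = []
    true_trace = None
    if config.simulate is not None:
        sim = config.simulate
        from .phantom import make_phantom  # local import avoids cycle at module load

        ph = make_phantom(sim.size, with_metal=True, seed=config.seed, pixel_size=sim.pixel_pitch)
        ell = forward_project((ph.labels == METAL).astype(float), sim.geometry().angles, sim.pixel_pitch)
        true_trace = ell > 0.5 * sim.pixel_pitch
    for th in thresholds:
        cfg = RunConfig(**{**_config_dict(config), "mask_threshold": th,
                           "output_dir": str(Path(config.output_dir) / f"th_{int(th)}")})
        res = run_pipeline(cfg)
        entry = {"threshold": th, **res["metrics"]}
        if true_trace is not None:
            import tifffile

            masks = tifffile.imread(Path(cfg.output_dir) / "masks.tif") > 0
            row = config.simulate.detector_rows // 2
            entry["metal_coverage"] = float(
                (masks[:, row, :] & true_trace).sum() / true_trace.sum()
            )
        rows.append(entry)
    return rows


def _write_f32(path: Path, arr: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32), photometric="minisblack")


def _config_dict(config: RunConfig) -> dict:
    d = {k: v for k, v in config.__dict__.items()}
    return d


def run_config_from_yaml(path) -> RunConfig:
    """Build a RunConfig from a YAML file (simulate block -> SimConfig)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "simulate" in d and d["simulate"] is not None:
        sim = d["simulate"]
        if "spectrum" in sim:
            from .phantom import Spectrum

            sim["spectrum"] = Spectrum(**sim["spectrum"])
        if "metal_rows" in sim:
            sim["metal_rows"] = tuple(sim["metal_rows"])
        d["simulate"] = SimConfig(**sim)
    if "geometry" in d and d["geometry"] is not None:
        d["geometry"] = Geometry(**d["geometry"])
    return RunConfig(**d)
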