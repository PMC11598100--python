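# bstdmar

Projection-domain metal-artifact reduction (MAR) for X-ray
microtomography via **bone- and soft-tissue decomposition (BSTD)**.

Metal objects inside a scanned sample absorb X-rays so strongly —
preferentially at low photon energies, with photoelectric probability
scaling like (Z/E)³ — that filtered-backprojection reconstructions
develop star-shaped beam-hardening streaks around them. `bstdmar`
suppresses these artifacts *before* reconstruction: every raw projection
is split into a soft-tissue image and a hard-tissue image, and the
reconstructor only ever sees the projections without the dense object.

## The model

Each projection `f` (attenuation-style, `f = 1 − I/I₀`, so dense objects
are bright) is modeled as

```
f(x,y) = U(x,y) · (1 − S(x,y)) + S(x,y)
```

with soft-tissue component `S` and hard-tissue component `U`, both in
[0, 1]. Equivalently `(1 − f) = (1 − U)(1 − S)`: transmittances multiply,
which is exactly Beer–Lambert for two superimposed absorbers.

Inside a binary metal mask `M` (low raw-count pixels, thresholded and
dilated), `S` is the *membrane*: the smooth fill of the masked region
from its boundary values, the discrete stand-in for the Laplace problem
`ΔS = 0, S|∂M = f|∂M`. It is evaluated as Shepard inverse-distance
interpolation with weights `w(d) = d⁻³`,

```
S(x) = Σₖ w(d(xₖ,x)) f(xₖ) / Σₖ w(d(xₖ,x)),   xₖ ∈ ∂M
```

written as a ratio of two convolutions with the large-support kernel
`d⁻³` and computed in O(n) by a **convolution pyramid** — a multiscale
analysis/synthesis pass with three small fitted kernels (h1, h2, g)
shipped as package data. `U` follows by algebraic inversion,
`U = (f − S)/(1 − S)`. Reconstruction (2D parallel FBP or 3D FDK, with a
Hamming-windowed ramp filter) then uses `−log` of the soft-tissue
transmittance `1 − S`; reconstructing from `U` instead yields a
high-contrast image of the dense structures alone.

The package also provides the standard sinogram-interpolation baselines
LI-MAR and NMAR, global/windowed SSIM and PSNR evaluation, and a
polychromatic phantom simulator that emulates paired with/without-metal
acquisitions of a plastic-sleeve test object with a metal rod.

## Worked example

Simulate the paired phantom, then reconstruct with and without MAR:

```python
from bstdmar.phantom import SimConfig, paired_dataset
from bstdmar.pipeline import decompose_stack, reconstruct_row, evaluate_against_reference
from bstdmar.reconstruction import FilterSpec

cfg = SimConfig()                      # 256² phantom, 360 angles, Poisson noise
data = paired_dataset(cfg, seed=1)
row = cfg.detector_rows // 2
S, U, masks, t = decompose_stack(data["with_metal"], threshold=10000, i0=cfg.i0)

ref = data["reference_volume"].voxels[0]
rec_none = reconstruct_row(t[:, row, :], data["geometry"], FilterSpec("hamming"))
rec_bstd = reconstruct_row(1.0 - S[:, row, :], data["geometry"], FilterSpec("hamming"))
print("no MAR:", evaluate_against_reference(rec_none, ref))
print("BSTD  :", evaluate_against_reference(rec_bstd, ref))
```

prints

```
no MAR: {'ssim': 0.099, 'psnr_db': -4.54, 'absdiff_mean': 0.00809}
BSTD  : {'ssim': 0.947, 'psnr_db': 20.12, 'absdiff_mean': 0.00236}
```

i.e. against the metal-free reference reconstruction, the decomposition
raises structural similarity from 0.10 to 0.95 and PSNR by ~25 dB, and
shrinks the mean absolute difference map by ~70% — the streaks and the
bright rod are gone, while the structures the rod obscured are restored.

The same workflow is available from the shell:

```
bstdmar simulate --out sim --seed 1
bstdmar run --config run.yaml --method bstd --threshold 10000
bstdmar sweep --config run.yaml --thresholds 5000,6000,7000,8000,9000,10000
bstdmar evaluate --recon out/recon_soft.tif --reference sim/reference.tif
```

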