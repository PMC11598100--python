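# Methods

## Image-formation model and its domain

The decomposition model `f = U(1 − S) + S` is stated on attenuation-style
images: `f = 1 − I/I₀` with `I` the detected counts and `I₀` the flat
field, so `f = 0` is air and `f = 1` total absorption. In this domain the
model is exactly multiplicative Beer–Lambert, `(1 − f) = (1 − U)(1 − S)`:
`S` is the attenuation image of the soft material alone and `U` that of
the dense object alone. This choice makes every contract self-consistent:
a dense object can only *add* attenuation, so `f ≥ S` under the mask and
`U = (f − S)/(1 − S) ∈ [0, 1]`. (On raw transmittance images the same
inversion would give `U ≤ 0`, which is why the pipeline converts
`t → 1 − t` before decomposing and back after.) Reconstruction input for
MAR is the soft-tissue line integral `−log(1 − S)`; hard-tissue mode
reconstructs `−log(1 − U)`.

`U` is clipped to [0, 1]. The lower clip only acts where the membrane
fill overestimates the true soft signal (noise, imperfect boundaries);
wherever no clipping occurs, `recompose(decompose(f)) = f` to better than
1e−9 as long as `1 − S ≥ eps_clamp` (default 1e−3, guarding the opaque
`S → 1` degeneracy where the model loses information about `U`).

## Membrane interpolation

The masked region is filled by Shepard inverse-distance interpolation of
the exterior 8-connected boundary ring, weights `w(d) = d⁻ᵖ` with `p = 3`
(exposed as a parameter). The boundary is taken *outside* the mask so
its values are never contaminated by metal intensities. Two evaluators:

* `shepard_direct` — the exact O(K·n) sum, used as the in-repo oracle;
* `membrane_interpolate` — the ratio of convolutions
  `(w ∗ r̂)/(w ∗ χ)` with `r̂` the zero-extended boundary values and `χ`
  the boundary indicator, each convolution approximated in O(n) by a
  convolution pyramid.

Pyramid specifics: analysis `a_{l+1} = ↓₂(h1 ∗ a_l)` (filter then take
every 2nd sample), synthesis `â_l = h2 ∗ ↑₂(â_{l+1}) + g ∗ a_l`
(zero-insertion upsampling), depth `⌊log₂ min(H, W)⌋ − 1` by default and
automatically reduced for small images. Images are zero-padded by the
coarsest-level support and cropped afterwards so mass leaving the frame
at coarse levels cannot bias the ratio near edges. `h1`, `h2` are 5-tap
and `g` 3-tap symmetric separable kernels fitted numerically
(`fit_filters`, deterministic least squares against the exact `d⁻³`
convolution on seeded sparse images); the fitted triple is cached as
plain-JSON package data (`data/convpyr_w3.json`) so users never refit.
The `d⁻³` kernel's zero-offset tap is undefined and never used — interior
pixels are never boundary pixels — so it is set to 0 in the oracle and
excluded from the fit. Achieved accuracy: ≈3.8% relative L2 on an
impulse, and ≤1% mean deviation from the direct Shepard fill on random
blob masks (numerator and denominator errors largely cancel in the
ratio). The denominator is checked against 1e−12 before dividing; a
violation indicates broken filters, not data.

## Masking

Masks are thresholded on raw counts — metal absorbs strongly, so it is
*dark* on the detector: `mask = (counts < threshold)` — then dilated by a
1-pixel disk (default) to absorb partial-volume fringes. Thresholds are
therefore in scanner units (16-bit counts), keeping them comparable
across exposure settings. Masks are per-projection and independent; a
volume-domain mask re-projected into each view can be substituted by the
caller where projection-wise thresholding is unreliable.

## Reconstruction

2D parallel-beam FBP is the primary working surface; 3D circular-orbit
FDK handles cone-beam stacks and reduces (verified to <1% RMSE) to FBP
at quasi-parallel distances. Rows are filtered in the frequency domain
with `|ν|` apodized by a Hamming window `0.54 + 0.46 cos(πν/ν_max)`
(Ram-Lak available), zero-padded to the next power of two ≥ twice the row
length. Conventions: angles in degrees CCW, frame `i` at the uniform
endpoint-exclusive angle grid; detector/image center at index `N//2`;
x right, y up, z along the rotation axis — identical to
`skimage.transform.radon`, which serves as the forward projector for
parallel geometry and as an independent reconstruction cross-check in the
tests. Backprojection is pixel-driven with linear interpolation; output
is in mm⁻¹ and pixels outside the inscribed circle are zeroed.

## Phantom simulator

The simulator emulates a bench-top paired experiment: a plastic sleeve
holding brick-like inserts and a wooden strip, plus a metal rod seated in
a drilled air channel that exists in *both* variants, so the with/without
pair differs only at metal pixels and the rod displaces no structure.
Attenuation is `μ(E) = a·E⁻³ + b` (photoelectric + flat Compton floor),
E in keV, with coefficients (mm⁻¹):

| material | a      | b     | μ(50 keV) |
|----------|--------|-------|-----------|
| air      | 0      | 0     | 0         |
| plastic  | 2.5e3  | 0.025 | 0.045     |
| wood     | 1.0e3  | 0.012 | 0.020     |
| metal    | 1.5e5  | 0.3   | 1.50      |

Default spectrum: bins {30, 50, 70} keV with weights {0.25, 0.5, 0.25};
flat field `i0 = 30000` counts; optional Poisson noise (default on),
PCG64 generator, fully seeded. The metal coefficients place a 1 mm rod's
shadow counts across the 5,000–10,000 range, so the six-point mask
threshold sweep moves the mask from partially to fully covering the
implant shadow — the regime the threshold study probes. A single-bin
spectrum disables beam hardening; the metal-free monochromatic
reconstruction is the ground-truth reference. The default scene is a
256² slice extruded across a 32-row detector at 360 angles (the rod
spanning the central half of the rows, so its shadow is interior to each
frame); a small 3D mode (`make_phantom_3d` + `cone_project`, stepping
ray marcher with nearest-neighbor lookup) exercises FDK.

Not emulated: scatter, detector blur and afterglow, spectral detector
response, focal-spot size, mechanical wobble, and the exact geometry of
any physical test object. Passing tests therefore demonstrate the
algorithmic chain — masking, membrane fill, inversion, reconstruction,
scoring — under controlled beam-hardening physics, not robustness to
every real-detector effect.

## Evaluation

SSIM defaults to the single global evaluation of the standard formula
(`c1 = (0.01L)²`, `c2 = (0.03L)²`, `L` = max of the reference); a
windowed mode (uniform sliding window, stride 1, valid region) is
provided since published SSIM values often come from windowed
implementations. PSNR is `20 log₁₀(MAX) − 10 log₁₀(MSE)`, `+inf` for
identical images. Before scoring, reconstructions are background-
equalized to the reference over its lowest-decile (air) region; the
general utility matches mean and standard deviation (affine), while the
evaluation path matches the mean only — both images are already in mm⁻¹,
and the air region's standard deviation measures noise, so matching it
against a noise-free reference would destroy the scale.

LI-MAR interpolates metal-trace bins of each angle-row linearly in the
line-integral (−log transmittance) domain, with nearest-value extension
at row edges and a neighboring-angle fallback for fully traced rows.
NMAR divides by a forward-projected tissue-classified prior (air → 0,
everything else → median soft value, metal flattened to soft) before
interpolating and multiplies back, with the prior floored at
1e−6 × max(prior); for a constant prior it reduces exactly to LI-MAR.

## Problem sizes and numerical choices

The shipped study conditions (256² phantom, 360 angles, 32 detector
rows, 20× membrane instances at 64², 50× decomposition instances) were
chosen as the smallest sizes at which streak artifacts, threshold
behavior and method ordering are unambiguous; everything completes in
seconds to a couple of minutes on one CPU. Transmittances are floored at
1e−9 before logs; internal computation is float64 throughout; ties and
degenerate inputs (empty masks, empty traces, all-air priors) follow the
documented error/fallback contracts rather than silent repair.

## Known limitations

* The membrane fill estimates the soft signal from the shadow's
  surroundings; structure completely hidden in every view cannot be
  recovered, and the filled region is smooth by construction.
* Masks that touch the frame edge lose the out-of-frame part of their
  boundary ring; pad projections first if the implant reaches the
  detector border.
* FDK is the standard approximate algorithm: cone-angle artifacts grow
  away from the central plane.
* The CLI's scaled-down `run` path reconstructs the central detector row;
  full multi-slice/cone reconstruction goes through the library API.
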