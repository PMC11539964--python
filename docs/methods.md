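# Methods

This note documents the models inside `petlesionsim`, the parameters that
matter, and the design decisions taken where several defensible choices
existed.

## System model

The acquisition model for expected trues per sinogram bin is

    λ = c · ε · exp(-∫ μ dl) · ∫ a dl

with `a` the activity map (kBq/mL), `μ` the 511 keV attenuation map (1/cm),
`ε` a per-bin detection efficiency (identity by default) and `c` the count
scale, a single calibration constant absorbing acquisition duration,
sensitivity and branching ratio. Measured data are one Poisson draw per bin.
Scatter and randoms are not modelled (trues-only); decay, dead time and
detector structure are likewise out of scope.

**Projector.** Parallel-beam, uniform angles over [0°, 180°), radial spacing
equal to the voxel size, radial extent covering the grid diagonal. The
projector is pixel-driven: each voxel's footprint on the radial axis (half
width `(dx·|cosθ| + dy·|sinθ|)/2`) is integrated with 4 midpoint samples,
each sample deposited into the two nearest bins by linear interpolation,
weighted by voxel area / radial spacing so bins approximate line integrals
in value·mm. The back-projector applies the transposed weights, so the pair
is an exact adjoint — the property EM reconstruction actually needs. On the
default 128×3 mm grid the worst-angle error of a central-ray line integral
through a 20 cm disc is ~2% (verified against the closed form e^-1.95); the
per-view bin sum is exact to round-off.

**Noise placement for insertion.** The base acquisition and the lesion-only
sinogram receive independent Poisson draws with separate, logged seeds; the
lesion counts are added to the base counts. The inserted lesion is always
attenuated with the ground-truth (CTAC) map, mimicking physical acquisition;
the AC method under test enters only at reconstruction (a flag in
`insert_lesions`' caller can pass any map).

## Reconstruction

OSEM with the system model above inside the update:
`x ← x / s_S · BP_S(y / FP_S(x))`, subset sensitivity `s_S = BP_S(1)`,
uniform positive initial image, bins with model projection below 1e-12
skipped, non-negativity by construction. Because the count scale is part of
the modelled system matrix, the fixed point is directly in kBq/mL. Defaults:
2 iterations, 16 subsets, PSF on.

* **PSF**: isotropic in-plane Gaussian (default FWHM 4.5 mm) applied in
  image space inside the forward model and, being self-adjoint, also in the
  back-projection. FWHM 0 reduces exactly to the no-PSF pipeline.
* **Subsets**: on uniform angle grids subsets are *mirror-closed* — each
  subset contains both members of every (θ, 180°−θ) pair, pairs dealt
  cyclically so every subset keeps an even angular spread. Rationale: every
  subset update then commutes with left–right mirroring, so reconstructions
  of exactly symmetric data are symmetric to round-off and contralateral
  lesion pairs are exactly comparable; a round-robin partition leaves a ~2%
  order-dependent asymmetry at 2 iterations. Round-robin is the fallback
  when the pairs cannot tile the requested subset count (odd subset size).
  Subset order is fixed; everything is deterministic under fixed seeds.
* Non-TOF: time-of-flight weighting is not modelled. TOF localisation damps
  the quantitative consequences of a wrong μ-map, so all AC-mismatch biases
  here are at the larger, non-TOF end; conclusions are about signs and
  ordering, not clinical magnitudes.

## Attenuation maps

CTAC uses the standard bilinear conversion with the break at 0 HU:
μ = 0.0975·(1 + HU/1000) for HU ≤ 0, μ = 0.0975 + 5.64·10⁻⁵·HU above
(clamped at zero; both coefficients config-exposed). The Dixon-style MRAC is
derived from the ground-truth labels (perfect water/fat segmentation — the
study isolates the AC consequence of missing bone, not segmentation
fidelity) and assigns fixed per-class coefficients. The defaults are the
CTAC bilinear values of the nominal class CT numbers — fat 0.0887 (−90 HU),
soft tissue 0.0998 (+40 HU), bone = soft tissue — so that on bone-free
anatomy MRAC and CTAC coincide exactly and any MRAC error is attributable to
bone alone. Assigning the literature water value 0.0975 to soft tissue
instead (possible via config) adds a global ~−0.2%/cm mismatch that accrues
to roughly −6% over a pelvis-sized body and swamps the bone effect; that
offset is a statement about coefficient conventions, not about bone, which
is why it is not the default.

## Phantoms

A phantom is three co-registered volumes: labels {air, fat, soft, bone},
activity, HU. Anatomy: an elliptical body (lateral semi-axis 0.40 of the
lateral FOV, AP 0.30 of the AP FOV), a 9 mm subcutaneous fat rim, a midline
sacral bone (semi-axes 0.09·a × 0.06·b) and two mirrored iliac/acetabular
discs (radius 0.06·a at (±0.55·a, −0.20·b)). A per-seed ±4% jitter of these
dimensions stands in for inter-patient variability. Bone structures are kept
slim so that the lines of response of the soft-tissue target sites carry
little bone (ray-level ACF mismatch ~1–1.5%), while the bone sites stay
clearly negative — matching the qualitative structure of pelvic MRAC errors.
With `symmetric=True` all masks are even functions of the lateral coordinate
about the grid midline, so labels and activity are exactly mirror-invariant;
activity is a uniform background (default 5 kBq/mL ≙ SUV 1 at 370 MBq /
74 kg) in every non-air voxel. Nominal CT numbers: air −1000, fat −90, soft
+40, bone +700 HU, with optional per-class-clipped Gaussian texture.

Target sites: the acetabular VOI sits mostly inside the right bone disc
(bone fraction ≈ 0.7–1.0); the sacral VOI straddles the left sacral edge,
placed by a deterministic scan of the discretized labels targeting an
intermediate fraction (≈ 0.2–0.3); lymph-node (sidewall) and
posterior-bladder (central) VOIs contain no bone. The ordering
acetabulum > sacrum > soft sites is enforced and holds across seeds and
grid resolutions (verified 2.34–6 mm).

What the generator does **not** emulate: organ-specific uptake, lesion
texture, respiratory/patient motion, continuous HU distributions, metal,
scatter. Passing tests therefore demonstrate correctness of the insertion
and evaluation machinery and the bone-driven AC error structure — not
clinical error magnitudes on real anatomy.

## Study recipes and problem sizes

Desk-scale defaults (chosen as the package's standard conditions): 128×128
voxels at 3 mm, 96 views, expected total trues calibrated to 5·10⁵ per
slice, OSEM 2i/16s, PSF 4.5 mm.

* **Matched contralateral study**: 4 symmetric phantoms, 16 original
  lesions total, diameters uniform in 9–40 mm, concentrations 15–50 kBq/mL,
  placed non-overlapping in left-half soft tissue (twins then cannot collide
  with originals). The original lesions are part of the simulated patient
  activity; the base acquisition is reconstructed once with CTAC to measure
  each original's mean VOI value, which becomes the twin's inserted
  concentration (`match_contrast="recon"`; `"true"` uses the ground-truth
  concentration). Both members' SUV Error Ratios are measured in the hybrid
  reconstructions, which share one sinogram and differ only in μ-map.
* **Targeted study**: one 12 mm, 5000 kBq/mL lesion per site per phantom
  (4×4 = 16), each reconstructed under both AC methods; per-site statistics
  pool the voxel differences across the cohort. The recipe default keeps
  Poisson noise on; the sign-structure analysis is run noise-free.

## Numerical and statistical choices

* Sphere/VOI membership: a voxel belongs iff its centre lies within
  diameter/2 — one rule shared by rasterization and VOI masks, so lesion and
  VOI supports coincide exactly. A lesion capturing no voxel centre fills
  its nearest voxel rather than vanishing.
* Eq. for diff% excludes voxels with reference SUV below 1e-6 (count
  reported); σ uses the population divisor N (the VOI voxel set is
  exhaustive), Bland–Altman uses the sample divisor N−1 (pairs are a
  sample) with raw (not percentage) differences.
* `diff%max` is reported signed (largest magnitude, sign kept) alongside
  the absolute maximum.
* Injected dose is treated as decay-corrected to scan start; SUV =
  activity / (dose/weight) with dose in kBq and weight in g.
* EM division guards at 1e-12; all randomness flows through
  `numpy.random.default_rng` seeds derived from one master seed; JSON is
  written with sorted keys so identical configs give byte-identical outputs.

## Known limitations

Single-slice core (thin-3-D mode reconstructs slices independently);
parallel-beam geometry rather than cylindrical-ring; no scatter/randoms, so
count levels map to contrast-to-noise optimistically; non-TOF biases are
larger than a TOF system would show; the Bland–Altman and trend statistics
are descriptive (no multiplicity control, matching the descriptive study
design).
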