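# Methods

`ovopet` emulates a quantitative-accuracy study of *in ovo* PET/MRI as a
closed simulation loop: phantom → attenuated forward projection → Poisson
counts → MLEM reconstruction under different attenuation-correction (AC)
configurations → VOI quantification. This note records the model, its
assumptions, the default parameters and why they are what they are, and
what the synthetic data do and do not show about real scanners.

## Phantoms and ground truth

**Uniform egg phantom.** The liquid compartment is an ellipsoid with
semi-axes (22.5, 22.5, 28.5) mm (long axis along z), giving an egg of
~4.6 × 4.6 × 5.8 cm including shell — a typical hen's egg; the exact
phantom dimensions are a free geometric choice and are configurable. The
liquid carries a uniform activity concentration and the true linear
attenuation coefficient of water at 511 keV, μ = 0.096 cm⁻¹. The shell is
a 0.35-mm calcite-like layer at μ = 0.17 cm⁻¹. The per-configuration fill
concentrations (117.0 … 61.4 kBq/cc) replicate the decaying activity of a
measurement series across the five hardware configurations and are treated
as inputs.

**Hardware.** The animal bed is an arc shell (radius 28 mm, 120°, 8 mm
thick) below the scanner axis; MRI coils are full annuli around the axis
(72 or 86 mm inner diameter). Their attenuation coefficients are
*calibration knobs*, not materials physics: they were set once, against the
emission-weighted mean-acf oracle, so that the bed removes ≈3.6% and a
PET-optimised coil ≈12% of the whole-egg signal (bed μ = 0.065 cm⁻¹;
optimised coils μ = 0.15 cm⁻¹, 4-mm wall; the non-optimised 72-mm coil
μ = 0.22 cm⁻¹, 6-mm wall, ≈24%), magnitudes typical of preclinical
PET/MRI hardware. The 4-mm optimised-coil wall also keeps the 86-mm coil
(outer radius 47 mm) inside the default 96-mm grid span.

**In ovo phantom.** Brain (sphere, 2× background uptake), liver
(ellipsoid, 3×) and CAM xenograft (sphere near the shell, 4×) are carved
into the liquid background; only uptake *ratios* across AC configurations
are ever claimed, never absolute organ uptakes. The image total is scaled
so that, decayed to the frame start, it equals the activity actually in
the egg:

    true in-egg = dispensed − residual − lost,

while the dose calibrator reports `dispensed − residual` (the "injected
dose"). The `lost` term models blood that leaks from the CAM vessel after
injection and is dabbed off without being measured — the practical pitfall
that makes calibrator-normalised %ID/cc unreliable. For dataset-1
emulation (method-development phase, F-18, dispensed ~ N(4.89, 2.26) MBq)
the lost fraction is drawn from a truncated normal (mean 0.10, sd 0.10,
clipped to [0, 0.4]); dataset-2 emulation (established protocol, Ga-68,
~ N(10.32, 8.08) MBq) loses nothing. This reproduces the characteristic
variance ordering: the calibrator-vs-image deviation spread of dataset 1
far exceeds dataset 2's.

**Surrogate MR/CT.** MR volumes are piecewise-constant label images
(liquid/organs ≈ 100, air ≈ 2) plus clipped Gaussian noise (sd 5); no
pulse-sequence physics is simulated. The shell and all hardware are
MR-invisible, as bone/plastic are on FLASH-type sequences — so AC-1 maps
genuinely miss the shell, one source of its residual bias. CT volumes are
the exact inverse of the bilinear HU→μ scaling, so the bed-template round
trip (μ → HU → μ) is an identity check of the scaling stage, not of CT
physics.

## Attenuation-correction maps

* **AC-1** — Otsu threshold on the MR histogram, largest connected
  component, interior hole filling; tissue assigned 0.1023 cm⁻¹ exactly
  (the standard rodent value; deliberately ~7% above water, producing a
  slight overcorrection in the liquid). A fixed-threshold override exists.
* **AC-2** — AC-1 plus the CT-derived, bilinear-scaled bed template. The
  bilinear scaling anchors μ(−1000 HU) = 0 and μ(0 HU) = 0.096 cm⁻¹; the
  high slope (7.4·10⁻⁵ cm⁻¹/HU) maps 1000 HU to a cortical-bone-like
  0.17 cm⁻¹.
* **AC-3** — AC-2 plus the coil template, used directly with known μ
  (emulating CAD-derived vendor templates).

Composite maps are voxelwise sums; μ(NO-AC) ≤ μ(AC-1) ≤ μ(AC-2) ≤ μ(AC-3)
pointwise, which forces the monotone accuracy ordering seen in every run.
Templates are generated on the shared grid; no registration is estimated
(the hardware is rigid and reproducibly placed).

## Forward model

The scanner is a stack of independent 2-D parallel-beam slice sinograms
(120 angles over 180°, radial bins of one voxel covering the grid
diagonal). This 2.5-D simplification of the real cylindrical geometry
(150 mm axial × 80 mm radial field of view, oblique LORs) preserves the
attenuation phenomenology under study while keeping a full hardware sweep
in minutes on one CPU. A single sparse system matrix per slice geometry —
ray-driven, bilinear interpolation, step = voxel/2, weights in mm — serves
projection and (as its transpose) back-projection, so the projector/
back-projector pair is adjoint to machine precision. Attenuation factors
are `exp(−Σ μ·Δl)` with Δl in cm along the same rays.

Scatter uses a dual-energy-window emulation: the scatter sinogram is the
attenuated trues smoothed radially with a 30-mm FWHM Gaussian, scaled to a
global scatter fraction of 0.15 (typical for a small water-equivalent
object in a preclinical system with a 358–664 keV window); a tail window
records k × scatter (k = 0.5, a free parameter) and is the only
information the correction uses. Poisson noise scales the sinogram so the
expected attenuated-trues total equals the count budget (default 5·10⁶,
large enough that Poisson error is small against the biases under study).
Randoms, deadtime, detector blur, positron range and non-collinearity are
not simulated; normalisation is a scalar sensitivity. Decay bookkeeping
uses half-lives of 109.77 min (F-18) and 67.71 min (Ga-68); the
frame-averaged decay factor `exp(−λt₀)·(1−exp(−λT))/(λT)` is available,
and phantom/quantification bookkeeping consistently references activities
to the frame start and decay-corrects results to injection time (the
reference-time convention is a package choice).

## Reconstruction

Pure MLEM (no subsets), ε = 10⁻¹⁰ guards, uniform positive
initialisation, exactly 12 iterations for the uniform phantom protocol and
16 for the *in ovo* protocol. Attenuation enters as multiplicative per-LOR
factors in the system model.

**Scatter handling.** The dual-window estimate (radially smoothed tail
counts / k) is *subtracted from the prompts before the update*, without
clamping; the image is clipped at zero each iteration instead. Two
standard alternatives were measured and rejected as defaults:

* keeping the estimate as an additive background in the forward
  denominator (ordinary-Poisson MLEM) is statistically exact but damps the
  update where scatter is large; at the fixed 12 iterations the object
  edge converges visibly less and the whole-egg mean drops by ~1.6
  percentage points (noise-free: −3.0% vs −1.4%), confounding the AC bias
  being measured. It remains available as
  `ReconSettings(scatter_mode="background")` and is used for the
  likelihood-monotonicity property, which holds for the ordinary-Poisson
  form.
* clamped pre-subtraction `max(y−s, 0)` biases the many low-count
  off-object bins upward (≈ P(y=0)·s per bin), creating a background haze
  that steals ~1.3 points from the whole-egg mean at the default count
  budget.

Unclamped pre-subtraction behaves like scatter-free MLEM at matched
iteration count and leaves the quantified deviations reflecting
attenuation alone. The post-reconstruction 2-mm FWHM Gaussian filter is
applied in the quantification stage (replicate averaging), not inside the
reconstruction.

## Quantification

VOI means average voxels whose centres fall inside the VOI. The phantom
VOIs are the whole liquid compartment (label mask) and two 1-cm spheres,
one at the egg centre and one "near the shell" at 75% of the short
semi-axis (the placement is a package choice; no coordinates are
prescribed). Percent deviations are reported to one decimal,
half-away-from-zero. The *in ovo* whole-egg total uses a 30-mm-radius
sphere; a warning is recorded if the egg support extends beyond it. Organ
concentrations in the study runner come from ground-truth label masks
(replacing manual delineation); a spherical brain VOI of radius 1.2 mm is
implemented and tested but is sub-voxel on the desk-scale 1.5-mm grid, so
the study defaults to masks. (A 1-mm brain radius appears as a plausible
alternative; the radius is configurable.) %ID/cc is
`100 · concentration / normaliser` with the normaliser either the
image-derived total or the calibrator-injected activity; the image mode is
exactly scale-invariant, and the lost-fraction estimator
`f̂ = 1 − imageTotal/calibratorInjected` recovers the simulated bleeding
loss up to the reconstruction's small global bias (≲1 point).

## Desk-scale problem sizes

Phantom study: 96×96×96 grid at 1 mm, 120 angles, 5·10⁶ true counts,
3 replicates filtered at 2 mm FWHM and averaged. In ovo study: 64³ at
1.5 mm (the 96-mm span keeps the 86-mm coil on-grid), 10 eggs, 16 MLEM
iterations, four AC reconstructions each. The full acceptance recomputation
runs in ~2 minutes on one CPU; the complete phantom hardware sweep in
~10 minutes.

## Numerical and degenerate-input behaviour

All ellipsoid/annulus rasterisation is voxel-centre based and converges to
analytic volumes as the voxel shrinks (tested at 1.0 vs 0.5 mm). Errors
are raised for: phantoms exceeding the grid (naming the axis), overlapping
or out-of-compartment organs (naming the pair), empty tissue segments,
HU below −1024, μ outside the invertible bilinear range, grid mismatches,
all-zero prompts, acf outside (0, 1], empty VOIs, and scatter kernels
wider than the radial field of view. All randomness flows from explicit
seeds through `numpy.random.SeedSequence`; identical configurations
reproduce bit-identical outputs.

## What passing tests do and do not show

The generator emulates the *structure* of real acquisitions — self- and
hardware attenuation, MR-invisible shell, dual-window scatter, Poisson
statistics, dose bookkeeping with unmeasured losses — under an idealised,
matched 2.5-D system model. Passing tests therefore demonstrate the
internal consistency of the AC/quantification logic and the direction and
rough magnitude of the biases, not scanner-specific absolute values: real
no-AC deficits also fold in oblique-LOR geometry, vendor normalisation and
residual scatter effects that are not modelled, and the absolute deficit
of a ~4.5-cm water egg under in-plane LORs is ~29–31%, smaller than a real
3-D measurement chain reports. The emulation's value is comparative: the
ordering NO-AC < AC-1 < AC-2 < AC-3, the centre-vs-shell gradient, the ≤2%
full-AC recovery, and the robustness of image-normalised %ID/cc are all
reproduced quantitatively.

## Known limitations

No MR sequence physics, B0/B1 fields, embryo motion or eggshell chemistry;
no randoms/deadtime, time-of-flight, energy-resolved transport, or
PSF-in-reconstruction; slice-wise in-plane LORs only; scatter is a
parametric emulation whose dual-window scaling factor k is free, not
vendor-published. The real per-egg injected activities and organ uptakes
are only known as distributions; the emulation samples them.
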