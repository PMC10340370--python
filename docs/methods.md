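# Methods

`spectac` is a closed-loop test bed for deep-learning attenuation
correction in myocardial perfusion SPECT.  It simulates paired CT/emission
thorax phantoms, models a dual-head SPECT acquisition, reconstructs images
with OSEM, trains a convolutional generator that maps non-attenuation-
corrected (NAC) emission slices to attenuation coefficient maps (ACMs),
and quantifies how reconstructions made with synthetic maps agree with
those made with the measured maps — at the voxel, segment and
clinical-score level.

## Phantoms

Each subject is an analytic thorax on a 64 x 64 x 64 grid of 6.9 mm
isotropic voxels: a soft-tissue body ellipse, two lung ellipsoids, a liver
ellipsoid, a spine cylinder, and a left ventricle modelled as a prolate
half-ellipsoid shell (outer radius 40 mm, wall 15 mm, length 85 mm) whose
long axis lies along z, so axial slices are short-axis slices.  Default
tissue values span both branches of the bilinear HU-to-mu transform
(air -1000, lung -700, soft tissue +40, liver +60, spine +400 HU) and
uptake ratios emulate a 99mTc-sestamibi distribution (LV wall 100,
liver 60, lung 5, background 2).  CT volumes carry additive Gaussian noise
(sigma 20 HU by default) emulating low-dose hybrid-scanner CT; activity
volumes are noise-free (emission noise enters through photon counting).

A population generator jitters organ sizes, positions and uptakes, draws
the body scale from two habitus clusters (smaller and larger subjects,
emulating female/male strata), retains a random axial range of 20-30
slices around the heart, and gives a configurable fraction of subjects
(default 25%) a perfusion defect confined to one AHA segment with severity
0.3-1.0.  Defects multiply wall activity by `1 - severity`.  Anatomically
impossible draws (LV outside the body) are rejected and redrawn.

What the generator does *not* emulate: respiratory/cardiac motion,
breast-tissue variability, metal implants, extra-cardiac focal uptake, and
truncation.  Passing tests therefore demonstrate the internal consistency
of the method under idealised anatomy, not clinical performance.

## Attenuation maps

CT volumes are converted to linear attenuation coefficients at 140 keV
with the standard bilinear model: below 0 HU,
`mu = mu_water * (HU + 1000)/1000` clamped at zero; above 0 HU,
`mu = mu_water + HU * bone_slope`, with `mu_water = 0.1537 cm^-1` and
`bone_slope = 7e-5 cm^-1/HU`.  Both constants are configuration, not
fitted values.  Maps used as training targets and for reconstruction are
smoothed with a 13 mm FWHM Gaussian (nearest-edge boundary handling) to
match the resolution of the reconstructed emission images.

## Acquisition model

The dual-head L-mode acquisition (two heads at 90 degrees, 30 steps over
90 degrees) is modelled as 60 equally spaced parallel-beam views over
180 degrees.  The projector is voxel-driven: each voxel splats onto the
two nearest detector bins with linear interpolation, weighted by
`exp(-integral mu dl)` along its exit path (trapezoidal integral on a
rotated grid).  Distance-dependent collimator blur uses
`sigma(d) = 3 mm + 0.02 * d` applied as a transaxial Gaussian per distance
group (8 groups), with a 280 mm radius of rotation.  Axial slices are
independent (parallel-hole collimation).  The back-projector is the exact
matrix transpose of the forward model; adjointness is asserted to 1e-10 in
the tests, which makes the OSEM sensitivity and update algebra exact.

Scatter: the lower-window (111-119 keV) signal is modelled as photopeak
primaries broadened by a 30 mm FWHM Gaussian and scaled to a 30% scatter
fraction; the photopeak contamination is `k * (21/8)` times the scatter
window, with `k = 0.5`, i.e. exactly the dual-energy-window (DEW) estimate
used by the correction, so the correction is consistent in expectation and
residual scatter error comes from noise alone.  Poisson noise scales
expected projections to 2e5 total photopeak counts per study.

## Reconstruction

OSEM with multiplicative updates
`x <- x / sens_S * A_S^T [ y_S / (A_S x + s_S + eps) ]`, interleaved view
subsets, uniform initialisation inside a cylindrical support, `eps = 1e-12`
division guards, and zero-sensitivity voxels frozen at zero.  The clinical
protocol is 3 iterations, 10 subsets; NAC images use no attenuation or
scatter term, AC-SC images include the attenuation map in the system model
and the DEW scatter estimate in the denominator.  PSF modelling reuses the
projector's blur (matched modelling).  A single-subset configuration
reduces to MLEM and is verified voxelwise against an explicit
dense-system-matrix reference.

## The generator

A five-level 2-D U-Net maps three adjacent NAC slices (z-1, z, z+1,
normalised to [0, 1] per volume) to the attenuation map of the central
slice in cm^-1: 3x3 convolutions with batch normalisation, ReLU and
dropout, stride-2 convolutions for downsampling, transposed convolutions
for upsampling, symmetric skip concatenations, and a ReLU output head
enforcing nonnegativity.  The output-head bias is initialised at
0.05 cm^-1 (a typical body-average attenuation) so early training corrects
structure rather than global scale.  Attenuation maps are never
normalised.

The loss is `L = alpha * (1 - MSSIM) + (1 - alpha) * MRE` with
`alpha = 0.8`.  MSSIM uses the standard product form l*c*s with an 11x11
Gaussian window (sigma 1.5), exponents 1, `C3 = C2/2`, and a fixed data
range of 0.25 cm^-1 for attenuation maps (1.0 for normalised emission), so
scores are comparable across subjects.  MRE enters the loss as a fraction:
the mean of `|y - yhat| / (y + eps)` over voxels where the target exceeds
`eps = 1e-3 * max(y)`; the relative error diverges at zero, so near-zero
reference voxels are excluded, and the sum is implemented as a mean (the
metric is an *average* percentage difference).  The loss gradient is
analytic — the windowed SSIM statistics are Gaussian filterings of the
prediction, its square and its product with the target, so the chain rule
reduces to three adjoint filterings — and is verified against finite
differences in the tests.

The network and its training loop are implemented directly on NumPy
(im2col convolutions, hand-written backward passes, Adam), with float32
parameters and activations for CPU speed; every layer's gradient is
finite-difference checked in float64.

Augmentation applies the identical random transform to input and target:
in-plane rotation within +/-5 degrees, coronal/sagittal mirror flips, a
through-plane channel reversal (the 2-D analogue of an axial flip), and
integer shifts of at most 7 voxels.

After training, predicted attenuation values are passed through a
monotone recalibration curve fitted on the validation split: the SSIM
luminance factor saturates near 1 for small relative offsets, so the loss
exerts little pressure on the last few percent of global attenuation
scale, and line integrals amplify any residual tissue-level shift into a
reconstruction bias.  The curve maps prediction-quantile bin means to the
corresponding target means (kept monotone, interpolated linearly, zero
maps to zero); it leaves well-calibrated regions (air, lungs) untouched
and corrects the tissue plateau.  It is fitted once per training run on
validation predictions only.

Training minimises the loss with Adam, records per-epoch training and
validation losses, stops early when validation loss has not improved for
`patience` epochs, and restores the best-validation weights.  The
optimizer moments can be warm-restarted every `restart_every` epochs:
the structural-similarity term produces long plateaus, and the
momentarily larger bias-corrected steps after a restart escape them
reliably where a continuous run stalls.  All randomness (weight init,
shuffling, dropout, augmentation) derives from named seeds.  A small random-search utility over the config space
(learning rate, alpha, dropout, optimizer) is provided for hyperparameter
exploration with a deliberately small default budget.

## Scaled study conditions

The bundled experiment driver runs a desk-scale analogue of a clinical
cohort: 46 subjects (30 training / 6 validation / 10 held-out test), the
acquisition and reconstruction protocol above, and a reduced-width
generator (base width 4, doubling per level) trained with learning rate
2e-3, batch 16, for at most 150 epochs (patience 30, optimizer warm
restarts every 20 epochs).  The width and schedule were chosen on the
validation split of this synthetic cohort; the test split is never used
for selection.  One full run takes tens of minutes on a single CPU core.

## Evaluation

* **Image quality**: MSSIM, NMAE (mean absolute error as a percentage of
  the reference dynamic range), MRE and MSE, for synthetic-vs-measured
  ACMs and for AC-SC reconstructions made with synthetic vs measured maps
  (emission pairs are scaled by the reference maximum before scoring;
  NMAE/MRE are scale-invariant, MSSIM then uses the unit data range).
* **Voxel agreement**: Bland-Altman of percent differences relative to the
  reference, restricted to voxels above 10% of the per-subject reference
  maximum (relative differences diverge at zero and low-uptake regions
  dominate otherwise); limits of agreement are `bias +/- 1.96 * sd`
  (sample sd).  The NAC-vs-AC-SC comparison rescales NAC to the reference
  mean inside the mask first, so it isolates the spatial attenuation
  artifact rather than the global count scale.
* **Polar maps**: radial-maximum sampling per axial slice and angular bin
  within the known LV geometry (the phantom's known orientation replaces
  manual cardiac reorientation), AHA 17-segment averaging (6 basal, 6 mid,
  4 apical, apex), coronary territories (LAD 1,2,7,8,13,14,17 — reported
  with and without the apex — LCX 5,6,11,12,16; RCA 3,4,9,10,15), segment
  scores 0-4 from uptake thresholds (70/50/30/10% — score 0 down to 4),
  SSS, its clinical category (<4 normal or minimally abnormal, 4-8 mild,
  9-13 moderate, >=14 significant extensive ischemia) and percent
  myocardium abnormal (100 * SSS / 68).  The 9-13 / >=14 split resolves
  the overlapping printed category bounds consistently with a patient
  moving from the severe to the moderate category across that boundary.
* **Normal-reference scoring**: clinical quantitation scores against a
  normal database, which removes the systematic regional heterogeneity
  that distance-dependent blur imprints on every polar map (apex and
  basal segments read low even in perfect subjects).  The pipeline builds
  a synthetic stand-in: the polar map of a noise-free, defect-free
  standard subject acquired and reconstructed under the same protocol.
  Test subjects are scored on uptake relative to this reference.  In the
  end-to-end scoring validation the acquisition is instead run without
  resolution blur and scored on absolute thresholds, which isolates the
  geometric correctness of segment mapping and scoring from the
  collimator MTF.

## Registration

Attenuation maps can be aligned to NAC volumes by a three-degree-of-
freedom translation maximising mutual information (32-bin joint
histogram), searched exhaustively over integer-voxel shifts (global and
deterministic at these grid sizes; ties break toward the smallest-norm
shift) and refined per axis by a quadratic fit to half-voxel precision.
Out-of-field voxels are filled with the moving volume's minimum.  The
simulation pipeline produces intrinsically aligned pairs, so registration
is exercised by its own recovery tests rather than inside the closed loop;
it is the intended path for external (clinical NIfTI) inputs.

## Numerical choices and degenerate inputs

* Projection bins outside the detector are dropped; voxels that no ray
  reaches have zero sensitivity and stay at zero through OSEM.
* `hu_to_mu` clamps below-air HU to mu = 0; smoothing clips negative
  ringing (there is none for the nearest-edge Gaussian) to keep the
  nonnegativity invariant.
* MI registration below a one-voxel search range is refused; constant
  reference images are refused by NMAE; all-zero volumes are refused by
  the normaliser.
* Score-level Bland-Altman needs at least three subjects; smaller test
  cohorts report the bias alone.

## Known limitations

* The projector is 2-D per slice (no axial divergence or axial PSF).
* Scatter is a stationary-kernel model, not photon transport; the DEW
  consistency between simulation and correction is by construction, so
  scatter-correction *calibration* is not tested, only its plumbing.
* Single-segment transmural defects reconstructed under the full
  collimator blur (about 19 mm FWHM at the heart) retain roughly 10-25%
  apparent uptake by radial-maximum sampling; deep defect scores saturate
  at 3 under the clinical protocol.  This is a physics consequence of
  resolution, shared with real cameras, not a property of the scoring
  code (which is validated blur-free).
* Phantom anatomy is idealised; performance numbers from the closed loop
  characterise the method's internal consistency at desk scale, not
  clinical accuracy.
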