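# Methods

This note records the models, parameter choices and numerical decisions
behind `pcct-cardiac`, and what the synthetic studies do and do not
demonstrate about real data.

## Spectral physics

Attenuation per unit concentration is a two-basis model:
`mu(E) = pe * (30/E)^3 + cs * KN(E)/KN(30)`, with `KN` the Klein–Nishina
total cross-section shape.  Materials with a K-edge multiply the whole
expression by a jump factor for `E >= E_edge`, so the across-edge ratio is
exactly the configured jump — convenient for testing and sufficient for a
self-consistent pipeline.  The weights are calibration parameters chosen to
give realistic magnitudes at micro-CT energies (water ≈ 0.37 cm⁻¹ at
30 keV; iodine ≈ 0.023 cm⁻¹ per mg/mL below its 33.2 keV edge with jump
2.2; calcium ≈ 0.0036 cm⁻¹ per mg/mL).  They are not tabulated cross
sections, and absolute dosimetry is out of scope.

Mixtures are linear in concentration — the assumption the image-domain
material decomposition relies on.

## Phantoms

*Cardiac phantom.*  A soft-tissue (water) thorax disk with mild seeded
texture (2% SD), an iodine-enhanced LV blood pool, optional calcified
plaque, and optional calibration vials (I 5 mg/mL, Ca 20 mg/mL, water).
The LV volume follows a raised cosine between the diastolic (DLVV) and
systolic (SLVV) volumes; only the extrema enter the cardiac metrics, so the
waveform shape is a free choice.  The blood-pool iodine concentration after
liposomal-iodine injection is a config parameter (default 8 mg/mL, a
mid-range blood-pool enhancement for long-circulating iodine agents).
Rendering uses supersampled area-fraction anti-aliasing; the binary LV
label selects the `round(pi r^2)` highest-coverage voxels so its area
matches the analytic area to the nearest voxel.  In the default 2D mode the
disk is the equatorial slice of a spherical ventricle, and mask areas are
converted to volumes through that sphere model; a small-3D mode renders
spheres directly.

*Detectability phantom.*  Cylinders of 0.5–2.5 mm diameter in four rows
(Ca 10, 20, 40 mg/mL; I 10 mg/mL) inside a uniform iodine-loaded background
(10 mg/mL), plus an iodine-free water vial used for sensitivity
calibration.

## Acquisition

Parallel-beam, single-slice geometry at 100 Hz view rate (10 ms/exposure);
the default cardiac scan is 1000 views over 10 s — a deliberate desk-scale
reduction of the full 7000-view protocol that keeps every algorithm
identical while fitting in CPU minutes.  The spectrum is Kramers
bremsstrahlung with a fixed filtration factor, normalized to
`photons_per_ray` (tube current folded in; default 2·10⁴ per ray for
cardiac scans, 5·10⁴ for the static detectability phantom, where exposure
is not motion-limited).  Detector bins are ideal threshold intervals
(25/34/50/60 keV at 80 kVp) with no charge sharing or pile-up; expected
counts integrate the transmitted spectrum per bin and are Poisson-sampled
with a seeded generator.  A 100 Hz view rate places the fastest expected
heart rate (600 bpm = 10 Hz) well below the 50 Hz Nyquist limit.

The projector is Joseph-type (bilinear sampling at unit steps); the
backprojector applies the exact transpose of the sampling weights, so
adjointness holds to floating point — a requirement for the conjugate-
gradient data-fidelity solver.  FBP uses the discrete Ram–Lak kernel
(DFT of the spatial kernel rather than |f| sampling), which removes the
small DC bias of the naive ramp; a central-ROI water value lands within
~2% of the bin-effective attenuation, the residual being genuine beam
hardening.

## Intrinsic gating

The ungated lowest-bin FBP volume is reprojected at every view angle and
subtracted from the measured log projections.  The per-view trace is the
*signed detector mean* of this residual: for parallel rays it is
proportional to the instantaneous total attenuation, i.e. to the LV volume
waveform, keeping the spectral fundamental at the heart rate.
Magnitude-style reductions (RMS, kept as an option) rectify the waveform
and shift its power to twice the rate — outside the 300–600 bpm search band
for any physiologic rate — which is why they are not the default.

The heart rate is the dominant peak of the Hann-windowed, 4x zero-padded
FFT inside the band, refined by quadratic log-amplitude interpolation
(raw resolution for a 10 s scan is 6 bpm; interpolation brings recovery to
within ±2 bpm at the default photon budget).  Rejection rules for "no
cardiac signal": in-band peak below 5x the in-band median amplitude (flat
noise spectrum — static phantom), a peak pinned to a band edge (leakage
from out-of-band power), or in-band power dominated by sub-band
respiratory-range content.  Phases come from peaks of a zero-phase
band-passed trace (minimum separation 0.8 cycles, parabolic sub-sample
refinement); a steady rhythm is fit by one linear cycle coordinate through
all peaks, with piecewise-linear interpolation as the fallback for
irregular rhythms.  Ten phase bins partition the views exactly; phase 0 is
end-diastole by construction (the signal peak is the volume maximum).

## Reconstruction

The multi-channel objective is
`Σ_{t,e} ½‖R X(t,e) − Y(t,e)‖² + λ_s·wTV_space + λ_t·wTV_phase + λ_e·‖·‖_*`,
all convex: edge-aware (bilateral) weighted anisotropic TV in space, the
same across the cyclic phase axis, and a nuclear norm on the (pixel × bin)
matrix per phase — a simplified rank-sparse regularizer across energies
with the same fixed points as kernel-regression variants (rank-1 spectra
survive up to threshold shrinkage).  Bilateral weights are frozen from the
initial FBP stack (range sigma = 3x the robust noise estimate), keeping the
problem convex.

Solver: split Bregman with a conjugate-gradient X-update (12 inner
iterations), shrinkage/singular-value-thresholding d-updates, optional
add-residual-back re-injection of the data residual (default on — it
counteracts regularization-induced intensity bias), and a backtracking
safeguard that halves the outer step until the composite objective does not
increase — making the recorded objective trace non-increasing by
construction while leaving well-behaved steps untouched.  `λ` defaults to a
per-channel noise-proportional rule (`lambda_scale` x a robust noise
estimate of the FBP channel), the standard practice when no oracle value
exists.  Convergence is declared at a relative objective change below 1e-4.
On the noisy water phantom the iterative result reaches less than half the
FBP ROI standard deviation at an ROI mean matched within 3%; the paper-scale
system reports substantially larger factors, which desk-scale problem sizes
are not expected to reproduce.

Two standalone filters expose the regularizer components:
`temporal_bilateral_filter` (cyclic, edge-preserving along phase) and
`energy_rank_sparse_filter` (SVD soft-threshold across bins, adaptive
threshold = 1.5x the smallest singular value; optional joint
kernel-regression smoothing with weights from the bin-averaged image via
`joint_kernel_filter`).  The joint kernel filter is what the detectability
study uses: it reduces per-bin noise without touching per-voxel spectral
directions, which pure spectral shrinkage would distort.

## Material decomposition

Sensitivity calibration solves `S = A M` by least squares over vial ROIs
(A holds known concentrations; water enters as a unit-fraction column), and
refuses rank-deficient designs.  Decomposition solves `x = c M` per voxel
(least squares when bins > materials, optional inverse-variance bin
weights).  Non-negativity uses orthogonal subspace projection realized as
iterative active-set removal: any voxel with a negative coefficient is
re-solved on the span of the remaining bases until all coefficients are
non-negative; the operation is idempotent and leaves untouched voxels exact
to 1e-9.  Each cardiac phase is decomposed independently.  The 34 keV
threshold straddles iodine's K-edge; merging the two lowest bins measurably
worsens the iodine–calcium–water condition number, which the tests assert.

## Detectability analysis

CNR follows the mean-difference-over-background-sigma definition with the
signal ROI eroded one voxel from the cylinder boundary and the background
an annulus of ≥3x the signal area in the surrounding iodine region.
Cylinders whose eroded ROI drops below 2 voxels are flagged unresolvable,
and noise-free backgrounds produce a capped CNR rather than infinity.
Because 10 mg/mL iodine out-attenuates even 40 mg/mL calcium in the lowest
threshold image, single-energy CNR is negative for calcium inserts at any
photon budget — the spectral decomposition is what makes the calcium map
cross the Rose criterion (CNR > 3) for the larger, higher-concentration
cylinders.  The study reports means and standard errors over 10 seeded
noise realizations of one noiseless scan.

## Segmentation

The network is a compact 2D U-Net written directly in numpy (im2col
convolutions, manual backpropagation, Adam): 3 resolution levels, 8 base
channels, 64x64 inputs by default, with depth/width/3D-ness configurable.
Training uses the composite loss BCE + (1 − soft Dice) (smoothing constant
1; the soft form is the differentiable surrogate — evaluation uses the
binarized Dice), learning rate 5e-4, batch 4, 14 epochs by default (50 is
the configured maximum), and the plateau rule: 10x learning-rate decay
after 5 consecutive epochs without validation improvement.  The best-
validation checkpoint is returned.  Augmentation applies seeded intensity
shifts, zooms and rotations, transforming the mask with nearest-neighbor
interpolation and re-normalizing the image to zero mean / unit SD.  The
decision threshold minimizes |precision − recall| on the training set over
the 0.01–0.99 grid (ties to the lowest threshold; thresholds with no
positive predictions are never selected).  AUC is computed on a seeded
voxel subsample capped at 10⁶ voxels.

The synthetic LV slices emulate reconstructed short-axis appearance (body
ellipse, bright blood pool, myocardial rim, blur, additive noise) and a
decomposed iodine-map variant; a harness trains both input kinds with the
same architecture.  They do not contain papillary muscles, neighboring
chambers, motion artifacts or inter-animal anatomical variability, so the
held-out Dice ≥ 0.85 demonstrated here validates the training machinery —
not performance on real scans.

## Cardiac metrics and statistics

SV = DLVV − SLVV, EF = 100·SV/DLVV, CO = SV·HR, CI = CO/body-weight (body
weight stands in for body surface area).  In the pipeline, gates are
centered on the detected diastole peak (half-bin shift of the phase grid),
so bin-averaged images represent the cycle extremes with minimal amplitude
loss (a one-sided first gate loses ~1.5% of the volume amplitude even with
perfect segmentation).  Per-phase masks are CNN predictions snapped to the
mid-contrast boundary within a narrow band around the prediction — the CNN
localizes the blood pool, the image intensity fixes the boundary, the
automated analog of user-guided region growing — and diastole/systole are
the extrema of a cyclically smoothed phase-volume curve, guarding against
segmentation-noise-inflated extrema.

Age outliers are removed per (isoform x sex) group by the 1.5 IQR rule with
type-7 (linear-interpolation) quantiles; groups below 4 records pass
through with a warning.  Factorial models (e.g.
`CO ~ Sex*Age*Weight*HN*Genotype`) are ordinary least squares on a patsy
design; the ANOVA is type II computed by rank-aware model comparison, which
handles the structural aliasing of the knockout line (no humanized-NOS2
variant exists, so HN x KO interactions carry zero degrees of freedom and
are reported as aliased rather than crashing the fit).  Post-hoc contrasts
use estimated marginal means computed by counterfactual substitution over
the observed covariate distribution (with HN forced to 0 whenever the
knockout level is substituted), Tukey-adjusted through the studentized
range with k = family size; a family of one reduces exactly to the
two-sided t-test.  Cohen F is `sqrt(eta2/(1−eta2))` with eta2 from the
term's type-II sum of squares; diet–weight association uses the
point-biserial correlation.

The synthetic cohort generator reproduces the study's group structure
(27 non-empty diet x genotype x sex cells, 123 subjects at natural size),
with age ~12 ± 1.2 months, weight by diet (29 vs 43 g ± 5), DLVV
0.045 ± 0.010 mL, EF 50 ± 12%, HR 450 ± 40 bpm, and supports injecting
known effects for power studies.  It draws each subject independently and
carries no real-animal values, so statistical results on it validate the
machinery (type-I/II behavior, power at injected effect sizes), not the
published biology.

## Problem sizes

Default study sizes are chosen for CPU-minute turnaround: 48–128 px grids
(0.125–0.25 mm pixels), 120–1000 views, 10 cardiac phases, 4 energy bins,
200-sample segmentation runs, 200–500 simulation replicates.  All are
configuration parameters; the algorithms are size-agnostic.

## Known limitations

* Parallel-beam 2D geometry (cone-beam weighting and full 3D volumes are
  out of scope; the phantom supports a small-3D mode but the imaging chain
  is 2D).
* Ideal detector (no charge sharing, pile-up, scatter) and no dosimetry.
* Respiratory motion has a signal path but defaults to zero amplitude;
  respiratory-gated reconstruction is not implemented.
* The rank-sparse energy regularizer is a simplified nuclear-norm/kernel
  scheme sharing fixed points with published kernel-regression variants,
  not a re-implementation of them.
* Real-data headline numbers (Dice 0.91/0.89, water-vial noise factors,
  cohort tables of cardiac metrics) depend on unavailable scans and
  hardware; the package reproduces their structure and qualitative
  directions on synthetic data only.
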