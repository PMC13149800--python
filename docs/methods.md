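# Methods

`carotidfr` re-creates, at desk scale, an analysis chain for measuring
carotid arterial stiffness from cardiac-resolved ("4D") non-contrast MR
angiography, with M-mode ultrasound as the comparison modality.  This
note records the models, the conventions, and the design choices made
where the problem was genuinely open, so that every number the package
produces can be traced to a stated rule.

## The physical picture

The common carotid artery distends with each heartbeat: its lumen
diameter oscillates between a diastolic minimum D_d and a systolic
maximum D_s (healthy magnitudes ~5.5 and ~6.4 mm).  The relative
diameter change together with the brachial pressure pair (P_s, P_d)
yields five standard stiffness indices:

    RDC  = (D_s - D_d) / D_d x 100                    [%]
    beta = ln(P_s / P_d) / ((D_s - D_d) / D_d)        [-]
    AC   = pi (D_s^2 - D_d^2) / (4 (P_s - P_d))       [mm^2/kPa]
    PWV  = sqrt(beta P_s / (2 rho))                   [m/s]
    E    = (P_s - P_d) / ((D_s - D_d) / D_d)          [kPa]

with blood density rho = 1050 kg/m^3, pressures converted at
1 mmHg = 133.322 Pa where a unit is required (AC, E in kPa; PWV in Pa).
beta uses the raw pressure ratio and is unit-free.  The left/right
"average" is the arithmetic mean of the metrics, not the metrics of
mean diameters (the alternative differs only at second order in the
side asymmetry).

An MRI scanner cannot image a single heartbeat at 0.6-mm isotropic
resolution, so the acquisition runs free (continuously, ungated) for
minutes while a pulse oximeter records trigger times; readouts are
retrospectively sorted by their offset within the cardiac cycle and one
image is reconstructed per cardiac bin.

## Synthetic data: what is emulated, what is not

The generator produces every input with known ground truth:

* **Diameter waveform.**  Two shapes on a uniform phase grid (default
  40 points): `"bump"` — a raised-cosine systolic bump, symmetric about
  mid-systole, over a systolic fraction of 0.35, with an exactly flat
  diastole; and `"pulse"` — a distension-like profile with the same
  fast upstroke but a slow raised-cosine decay occupying the rest of
  the cycle, so the minimum is reached only at the brief end-diastolic
  foot.  The bump's symmetry is deliberate: an asymmetric peak biases
  any local quadratic peak-refinement by a sizeable fraction of a
  sample, which would contaminate the exact-recovery tests.  The
  sampled extrema are pinned to the exact D_d/D_s.  The default study
  uses "bump"; the protocol sweeps use "pulse" (see below).
* **Phantom.**  Two bright axial cylinders (lumen 10, wall 0.6,
  background 1.0 in arbitrary units; the 10:1 lumen/background ratio is
  a free parameter standing in for inflow contrast) on a 64^3 grid of
  (0.6 mm)^3 voxels, rendered with 4x in-plane supersampling so edge
  voxels carry sub-voxel partial-volume weights and the rendering is
  smooth and monotone in diameter.
* **Trajectory.**  Interleaved spiral phyllotaxis: global spoke index
  n = j * n_segments + s has polar angle (pi/2) sqrt(n / (N-1)) from
  the +z pole and azimuth n x 137.50776405 deg.  Within a segment the
  polar angle sweeps top-to-bottom; consecutive segments differ by one
  golden angle at fixed within-segment index.  Spokes span +/-k_max, so
  the hemisphere of directions covers the full measurement sphere.
  Units are cycles/voxel (grid Nyquist 0.5); physical 1/mm appears only
  at I/O.  22 readouts per segment by default (the interleave length
  is a free protocol parameter, configurable).
* **Acquisition.**  Readout i is acquired at t = i x TR (TR = 5.97 ms);
  its cardiac phase is the elapsed fraction of the current RR interval
  (so the waveform is RR-invariant, while binning uses millisecond
  offsets — a deliberate, physiological mismatch), mapped to the
  nearest waveform grid point.  Sample values are the non-uniform
  Fourier transform of the coil-weighted phantom plus i.i.d. complex
  Gaussian noise.  Coil maps are 4 smooth Gaussian-profile
  sensitivities with gentle linear phases, sum-of-squares normalized to
  one.  Triggers come from RR ~ Normal(960, 20) ms clipped at 3 sd.
* **M-mode traces.**  Outer-wall boundaries at 250 frames/s:
  center -/+ (D(t)/2 + IMT) plus a shared linear drift and independent
  Gaussian noise per boundary.  The IMT (default 0.6 mm) is an input;
  its measurement is out of scope.  The nominal 0.1-mm scanner
  resolution is metadata: delineated boundaries are continuous, as
  manual delineation is sub-pixel.
* **Pressures.**  Pre/post-scan cuff readings (truth 113/63 mmHg) with
  Gaussian noise, averaged.

Not modelled: MR signal physics (T1/T2, flip angle, flow profiles),
respiration and swallowing, B0/B1 inhomogeneity, coil-map estimation.
Passing tests therefore demonstrate the correctness of the *analysis
chain* under a known forward model, not robustness to in-vivo
confounders.

The k-space noise default is 2% of the rms sample magnitude, chosen so
the reconstructed apparent SNR (below) lands in the 20-30 range typical
of diagnostic non-contrast carotid MRA; 5% was tried and judged
unrealistically poor (apparent SNR ~12).

## Cardiac binning

The number of bins is floor(mean RR / width) with the mean over all
recorded cycles; a readout with offset t - tau from its preceding
trigger goes to bin floor((t - tau)/width).  Readouts beyond
n_bins x width (the late-cycle residual of cycles longer than average)
and readouts before the first trigger are discarded — bins stay
duration-homogeneous and non-overlapping.  No arrhythmia rejection is
applied.  The default width is 80 ms; 40/80/160/240 ms are swept.

## Reconstruction

The cardiac-resolved image solves

    x_hat = argmin_x ||F C x - y||_2^2 + lambda_c ||grad_c x||_1

with F the per-bin non-uniform Fourier transform, C the coil maps and
grad_c the first-order cyclic finite difference across cardiac phases
(the cardiac dimension is periodic).

**NUFFT.**  Kaiser-Bessel gridding (Beatty-optimal shape parameter):
deapodize, zero-pad to a sigma-oversampled FFT-friendly grid, FFT,
separable interpolation.  The adjoint is the literal transpose of each
step, so operator pairs pass dot-product tests at rounding error by
construction.  Presets: "fast" (sigma 1.5, width 6, ~1e-4 relative
error — used inside iterations) and "precise" (sigma 2, width 16,
~1e-14 — used for oracle comparisons and point-spread construction).
An exact O(N M) direct-summation DFT operator serves as the
independent oracle and as an inverse-crime-free forward model on small
problems.  The per-phase Gram F^H F is applied as a Toeplitz circular
convolution on the doubled grid (point-spread function built once per
bin), which makes the inner iterations FFT-bound.

**ADMM.**  Splitting z = grad_c x: an x-update by warm-started
conjugate gradient on the normal equations (at most 10 inner
iterations, tolerance 1e-6), complex soft-thresholding for z, dual
ascent; 10 outer iterations; initialization is the density-compensated
(|k|^2 ramp) adjoint, amplitude-calibrated by a scalar least-squares
fit to the data — the ramp adjoint's gain is arbitrary and the inner
solver cannot remove a four-orders-of-magnitude miscalibration in ten
iterations.  Iterates are complex64 by default (double precision is a
flag; the small-problem solver tests use it).

**Weight normalization.**  A bare lambda_c is meaningless without a
scaling convention.  Here the data term is divided by the encoding
operator's spectral norm (estimated by power iteration on the fullest
bin) and the image is scaled so the initialization has unit maximum
magnitude.  On top of this, an explicit calibration constant
`lambda_scale` (0.003) maps the reference weight scale onto the
convention; it was fixed once by sweeping the reference phantom at both
study scales so that the reference lambda_c = 0.01 sits at the knee of
the diameter-error curve — the same calibration such a protocol
performs when optimizing its regularization weight against reference
diameters.
The ADMM penalty rho scales linearly with the effective weight so the
soft-threshold level in image units stays constant while very large
weights genuinely stiffen the temporal coupling (lambda_c = 1e6
flattens the phases, as it must).

**Apparent SNR.**  aSNR = mean lumen magnitude / sd of background
magnitude, evaluated on a single late-diastolic phase in the sweeps:
temporal regularization reduces per-phase noise, which the phase-mean
image would hide.  Note the background of a magnitude image is
half-normal/Rayleigh-like, not Gaussian.

## Lumen contouring (MRA arm)

From a seed inside the bright lumen, 64 equally spaced rays are cast
from the current centroid; along each ray (sampled by bilinear
interpolation at 0.1-voxel steps) the boundary is the outermost
linearly interpolated crossing of half the signal range, computed per
ray (robust to shading).  The centroid is iterated to a fixed point
(at most 10 rounds, 0.1-voxel tolerance).  The polygon is fan-
triangulated from its centroid (equal to the shoelace area for these
star-shaped contours) and converted to the effective diameter
D = 2 sqrt(A/pi).  Per slice, D_s/D_d are the extrema over phases;
the reported values average three adjacent slices
(extrema-then-average; curve-averaging first is available behind a
flag).  No IMT correction: the lumen signal is targeted directly.
Voxel centers sit at integer indices; mm = index x voxel size.

## M-mode analysis (ultrasound arm)

Boundaries are linearly interpolated to the uniform 250-fps grid and
subtracted; a fitted line is removed slope-only (mean preserved, so
absolute diameters survive).  The trend line is anchored to the
diastolic feet (minimum between consecutive systolic peaks) rather
than fitted to all samples: a periodic pulse has a non-zero
least-squares slope over any finite window (its systolic mass sits
asymmetrically in the cycle), so full-trace OLS detrending tilts the
waveform and biases the extrema by ~0.01 mm; the end-diastolic trend
line — the convention in distension-waveform processing — removes
genuine drift and nothing else.  OLS detrending remains available.

Peaks and troughs come from automatic multiscale peak detection: a
local-maxima scalogram over window scales, the global scale as the
arg-min of the row sums, and peaks as the samples that are strict
maxima at every scale up to it.  Two robustness measures: the trace is
extended by odd (anti-symmetric) reflection so near-boundary peaks are
compared against a natural continuation instead of being discarded,
and the scanned scales are capped at a quarter of the half-length —
beyond the beat period a peak ties with its own repetition and the
every-scale criterion would discard it (valid for traces of >= 3
beats; the protocol uses 5).  Detected indices are refined to the
vertex of a least-squares parabola over a quarter beat (sub-sample
localization; degenerate fits keep the raw index).  On a flat
diastole, strict minima do not exist, so missing troughs fall back to
the arg-min between consecutive peaks.  The first five peak/trough
values are averaged and 2 x IMT is subtracted from both (outer-wall
delineation -> lumen diameter).

## Repeatability and agreement statistics

ICC(2,1): two-way random effects, absolute agreement, single
measurement, from the ANOVA mean squares, with the exact F-bound 95%
confidence interval (Satterthwaite denominator df).  The test-retest
CV is the root-mean-square over subjects of (within-subject sd /
subject mean) — the standard convention where none is stated.
Bland-Altman uses bias +/- 1.96 sample sd of the paired differences;
agreement regressions are ordinary least squares with Pearson r;
paired comparisons are Shapiro-Wilk-gated (t-test if the differences
look normal, Wilcoxon signed-rank otherwise).  No multiple-testing
correction is applied.

The scan-rescan cohort simulator works at the diameter level: each of
14 subjects has a true (D_d, RDC) per side; each modality x session
measurement adds Gaussian noise with a modality-specific sd (MRA
0.10 mm, US 0.25 mm — magnitudes chosen from the reported CV ranges of
the two arms, reflecting the semi-automatic vs manual analysis
chains).  Reconstructing 14 x 2 x 2 full acquisitions is out of desk
scale; the full-physics path exists for single subjects.

## Study conditions and problem sizes

The default experiment is deliberately scaled down to a laptop CPU:
64^3 voxels (38.4-mm field of view at 0.6 mm), 120 s of simulated
scanning (~20,000 readouts of 64 samples, 4 coils), 12 cardiac bins of
80 ms at RR 960 +/- 20 ms, 10 ADMM iterations — one full simulate +
reconstruct + measure cycle takes a few minutes single-threaded.  The
protocol sweeps use a further-reduced configuration (32^3, two coils,
30-s scan, "pulse" waveform) so that eight reconstructions remain
affordable.  The sweep waveform differs from the default on purpose:
the characteristic sweep behavior — the diastolic diameter inflating
with bin width while the systolic diameter stays put — belongs to the
asymmetric in-vivo distension pulse, whose minimum lives only in the
brief end-diastolic foot; a flat-diastole bump is structurally immune
to diastolic averaging and would invert the effect.

## Known limitations

* The phantom has no through-slab structure (cylinders are axial and
  z-invariant), so slice-averaging tests exercise bookkeeping, not
  anatomy.
* The noise model is additive white complex Gaussian in k-space;
  correlated coil noise and physiological signal fluctuations are
  absent.
* FWHM contouring under heavy noise or strong undersampling biases
  diameters low (the half level rides up on noise peaks); the package
  reports what it measures and makes no bias correction.
* On a noisy trace with an exactly flat diastole, the detected trough
  is the deepest noise excursion of the plateau — an extreme-value-
  biased minimum that inflates the M-mode RDC by a few points at the
  default noise level.  Real distension traces have a sloped diastole
  and manually delineated boundaries without a white-noise floor, so
  this is a property of the synthetic worst case, not of the analysis
  rule.
* The cohort statistics simulator bypasses image formation; it tests
  the statistical machinery and the study's ordering logic
  (MRA more repeatable than US), not imaging performance.
* Patch-based post-denoising (commonly applied after compressed-
  sensing reconstruction) is not implemented; an optional no-op hook
  marks where it would attach.
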