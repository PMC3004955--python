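# Methods

`muxepi` is a desk-scale model of multiplexed echo planar imaging (EPI):
a pulse sequence that combines temporal multiplexing (*m* simultaneous-image-
refocused, SIR, excitations whose echoes interleave within each readout
period) with spatial multiplexing (*n*-band multiband RF pulses exciting *n*
widely spaced slices at once), so that a single echo train encodes `m × n`
slices instead of one.  The package simulates the acquisition, inverts it,
quantifies the noise and distortion costs of the acceleration, and
implements the resting-state fMRI sensitivity analysis that motivates
running EPI at short repetition times.  Everything runs on synthetic
phantoms generated in-package; no external data is required.

## Phantom and coil model

The phantom is a stack of 2D complex slices built from nested ellipses:
white-matter core, ventricular CSF, a cortical gray-matter shell, a
signal-free skull gap and a 2–3 voxel subcutaneous fat ring.  Per-voxel maps
carry proton density, T1, T2*, off-resonance (a smooth seeded random field,
default 12 Hz RMS) and fat fraction.  Tissue parameters are 3 T literature
values (GM: T1 1.2 s, T2* 50 ms; WM: 0.8 s / 45 ms; CSF: 4 s / 100 ms; fat:
0.37 s / 60 ms).  Air has exactly zero proton density.  Slice outlines
shrink away from the mid-slice.

Receive coils use an analytic loop-falloff model: magnitude
`a² / (a² + d²)` with `d` the 3-D distance from the loop centre (an
inverse-distance-squared law), linear phase plus a seeded per-coil offset.
Loops are distributed azimuthally; because a single planar ring would give
every slice the same sensitivity pattern (making the multiband inverse
singular), the loops sit on two axially staggered rings with seeded axial
jitter, optionally tilted about the y axis — in real head arrays the axial
encoding likewise comes from the three-dimensional heterogeneity of the
coil fields rather than from the nominal ring geometry.  Each coil map is
normalised to unit mean-square energy over the FOV, so tilting
redistributes but never rescales coil energy; only relative patterns matter
to the reconstruction.  Test fixtures with few slices set
`slice_thickness_mm` so that the slices of one multiband group sit a
realistic `FOV/n` apart.

## Timing, SAR and chemical shift arithmetic

All sequence bookkeeping is deterministic arithmetic over a `ProtocolSpec`:

- echo spacing `= m·t_flat + t_ramp_total`, with `t_flat = 1/bw_per_pixel`.
  `t_ramp_total` defaults to 0.28 ms, which reproduces the measured 1.05 /
  1.44 ms spacings at m = 2, 3 for 2604 Hz/pixel; ramp sampling (available
  only at m = 1) is modelled as a reduced `t_ramp_total`, not at waveform
  level.
- echo train `= ceil(matrix·pf/R_pe)` lines × echo spacing — the distortion
  / train-length trade: the train lengthens ∝ m and shortens ∝ 1/R.
- minimum TR: per shot, fat-sat + m excitation pulses (+ one refocusing
  pulse for spin echo) + TE fill + half the train + spoiler, times
  `n_slices/(m·n)` shots.  Each term is a configurable parameter because no
  single published decomposition exists; the per-slice times reported for
  the fMRI protocols (TR/n_slices) do not depend on it.
- the SAR proxy is pulse-energy bookkeeping relative to the single-band
  protocol covering the same slices at `TR_ref = m·n·TR`: a multiband pulse
  of the same envelope deposits n² the energy; the single SIR refocusing
  pulse serves all m excitations (count reduced by m); the fat-sat pulse is
  shared by all m·n images of a shot.  Relative refocusing-pulse energy
  defaults to 2 (double duration at half amplitude for the 180°).  This is
  not a W/kg model.
- fat displacement `D = δ·B0/Gs` (mm, with δ in ppm and Gs in mT/m — the
  gyromagnetic ratio cancels).  δ defaults to 3.35 ppm.
- reported values use round-half-even at printed precision
  (`timing.printed`), e.g. 13 ms/4 → 3.2 ms.

## Forward model

The simulator renders each acquired echo as the Fourier line of the
instantaneous object: per-voxel steady-state amplitude
`S = sin α (1−E1)/(1−cos α E1)`, off-resonance and fat chemical-shift phase
accrued along the train relative to TE, optional per-voxel T2* decay,
multiband summation through the coil maps, SIR interleaving of the m
sub-readouts within each echo (with whole-readout reversal on odd echoes,
undone deterministically by the reconstruction), (R, partial-Fourier)
sampling aligned so the DC line is always acquired, and circular complex
Gaussian noise of equal per-component standard deviation on every coil
(identity coil covariance — no measured covariance exists for a synthetic
array).  It is a discrete-object simulation (FT of the voxelised phantom):
the inverse crime is acceptable because acceptance is structure recovery,
and noise injection breaks exact inversion.  The TE offset between adjacent
SIR images is exposed as a parameter (`sir_te_offset`, default 0) rather
than derived, since it depends on unmodelled gradient details.

Spin-echo fat behaviour uses a slab-overlap model: the excitation slab and
the m-times wider, m-times further displaced refocusing slab (the SIR
refocusing gradient is m times weaker) overlap over a fraction of the slice;
fat signal is scaled by that fraction.  At m = 1 the two bands coincide
(full fat signal, the classic chemical-shift ghost); once `m·D` exceeds the
slab the overlap — and the fat signal — vanishes: inherent fat suppression
without fat-saturation pulses.

## Reconstruction

Temporal separation precedes coil-based separation: SIR de-interleaving is
an exact bijection on the samples.  Multiband separation is a k-space
projection operator: for each target (slice, coil), a least-squares fit
maps sliding 7×7 multi-coil neighbourhoods of the *summed* single-band
calibration k-space to the single-slice, single-coil centre point, and the
fitted kernel is slid over the composite data.  Calibration and target data
live on the compact lattice of acquired lines (spacing R_pe), so the kernel
geometry always matches.  Numerical choices:

- Tikhonov regularisation on the normal equations, `λ = reg ·
  trace(AᴴA)/n_unknowns`, with `reg = 1e-6` by default.  Stronger
  regularisation visibly over-smooths the kernel (percent-level fit
  residuals); `reg = 0` switches to an SVD minimum-norm solve.
- the kernel wraps around k-space edges.  The DFT of a discretely sampled
  object is exactly periodic, so periodic extension is the faithful
  boundary; zero-padding injects large errors at the edges because the
  k-space tails of a sharp-edged object do not decay.
- calibration patches are drawn only from the fully interior region, and
  under-determined fits (fewer patches than unknowns) are rejected.

In-plane unaliasing is a standard GRAPPA fit per missing-line offset (four
source lines × three readout columns × all coils) calibrated per slice from
its single-band k-space; the sampled band's lattice extends `R−1` rows past
the last acquired line, while rows below the partial-Fourier edge stay
unfilled.  Partial Fourier completion is zero-fill by default or Hermitian
(conjugate-symmetry) fill — exact for a real object except for the
self-conjugate Nyquist row.  Images are formed by centred 2D inverse FFT
and root-sum-of-squares coil combination; complex coil images are retained
for noise work.  No inter-slice FOV shifting (CAIPIRINHA-style) is used:
coil geometry alone encodes the slices.  Off-resonance correction and ghost
calibration beyond the deterministic polarity flip are out of scope.

## Quality metrics

The analytic g-factor stacks the coil sensitivities of every aliased voxel
set (multiband group × phase-encode folds) into an encoding matrix E and
reports `g = sqrt(diag((EᴴE)⁻¹)·diag(EᴴE))` with identity noise covariance;
rank-deficient sets are flagged infinite.  The pseudo-replica estimate
pushes noise-only realisations through any reconstruction callable and a
matched-filter single-band reference, normalising by the square root of the
per-image k-space undersampling (R_pe; pure multiband shares all lines, so
1).  The least-squares SENSE separator provided in the same module is the
estimator whose noise amplification *is* the analytic g, which makes the
Monte-Carlo/analytic comparison a genuine cross-check rather than a
tautology.  Slice leakage decomposes each reconstructed slice onto the true
slice patterns by least squares and reports per-pattern energy fractions.
ROI SNR is mean(tissue)/mean(air), and the volumetric-undersampling law is
`SNR ∝ 1/(g·sqrt(R1·R2))`.

## Resting-state sensitivity pipeline

The generator emulates a multi-TR resting-state comparison on a fixed
10-minute run.  Ground truth holds: (i) network amplitude maps — Gaussian
blobs confined to gray matter, peak 1% of the mean signal, widths a fixed
fraction of the brain, centres kept apart so networks are spatially
distinct; (ii) band-limited (0.01–0.1 Hz, exact Fourier-domain brick-wall)
network timecourses defined on a 50 ms grid and resampled at any TR, with
the sampled series normalised to unit variance so the amplitude maps are
exactly the percent fluctuation standard deviation; (iii) cardiac (≈1 Hz)
and respiratory (≈0.3 Hz) confounds with random-walk phase (decorrelation
over a few seconds, like heart-rate variability), smooth amplitude maps and
— for cardiac — a voxelwise phase-offset map.  Confound phases are
evaluated at each slice's own acquisition time within the TR, so a
volume-level regressor can capture them well only when the TR is short
relative to the phase-jitter correlation time; this reproduces the
physiological-sampling advantage of fast acquisitions.  Thermal noise has a
constant standard deviation per sample (default 0.01 a.u., giving
gray-matter tSNR ≈ 70 at TR 2.5 s), while the mean image carries the Bloch
steady-state amplitude, so image SNR falls as TR drops.

The analysis stages follow the standard group pipeline: per-voxel highpass
by projection onto discrete-cosine drift components below 1/200 s⁻¹ (mean
preserved), 5 mm FWHM Gaussian smoothing, per-dataset PCA reduction with
variance equalisation and temporal concatenation (three datasets at 200
components give the 600 concatenated maps a group ICA would consume — ICA
itself is deliberately an external step: group maps are an input, ground
truth in synthetic runs).  Dual regression: stage 1 regresses each volume
on the spatially demeaned group maps; the resulting timecourses are
normalised to unit variance so stage-2 parameter estimates carry amplitude
information; stage 2 is per-voxel multiple OLS (optionally with confound
regressors, normalised the same way), yielding PE maps, residual standard
deviations and Z maps.  Single regression does the stage-2 fit one
regressor at a time, close in spirit to seed-based correlation.

Ordinary least squares overstates Z when residuals are autocorrelated (low
TR, physiological noise), so each Z image is renormalised with a
Gaussian + two-gamma mixture fitted by EM: a central Gaussian null and
positive/negative gamma activation components offset to the null mean.
Initialisation takes the null from the median and interquartile range and
the gammas from tail excess beyond two initial standard deviations; gamma
shapes are kept > 1 (zero density at the null centre) and gamma means at
≥ 2σ₀ — without the mean floor the gammas erode the null tail and bias σ₀
low by several percent on activation-free images.  The EM runs at most 500
iterations to 1e-6 log-likelihood tolerance and returns the best fit
flagged if unconverged.  Corrected Z = (Z − μ₀)/σ₀; the reporting threshold
is the smallest Z above the gamma mode where the weighted activation
density matches the weighted null density, +∞ if no positive component
survives.  Summary metrics per corrected map: peak Z, suprathreshold Z
mass, and PE / residual at the peak voxel in percent of the mean.

The closed-form sensitivity predictor multiplies the steady-state signal
ratio of two protocols by the square root of their timepoint-count ratio at
fixed duration.  With gray-matter T1 = 1.2 s (chosen from the 1.2–1.4 s
literature range; the shorter end reproduces the published prediction), the
(2.5 s, 90°) → (0.4 s, 50°) comparison predicts a ≈15% raw peak-Z gain,
and the synthetic single-regression sweep (known timecourses as regressors,
isolating the Bloch/thermal effect from regressor-estimation noise)
reproduces it within simulation error.

## Problem sizes and what the tests show

The simulation tests run at 64² matrices with 16 coils and 2–9 slices, the
resting-state acceptance sweep at a 10×32×32 grid with 4 networks
(multi-TR datasets of 240–1500 volumes, 50 seeds for the amplitude-bias
check, 100 noise replicas for the g-factor comparison) — sizes chosen so
the full suite completes in a few minutes while every Monte-Carlo margin
stays several standard errors wide.  The generator emulates the *structure*
of the study conditions (protocol timing, Bloch scaling, coil encoding,
physiological aliasing), not real-brain anatomy, motion, scanner drift or
measured coil covariance; passing tests therefore validate the algorithms
and their stated scalings, not in-vivo effect sizes.  In particular, the
published in-vivo peak-Z and sum-Z ratio tables, measured g-factor/SNR
tables and fibre-orientation results are outside what synthetic data can
reproduce and are not targets.

## Known limitations

- Discrete-object simulation shares its grid with the reconstruction; there
  is no sub-voxel or continuous k-space model, no ramp sampling, motion,
  or isochromat-level Bloch dynamics.
- The minimum-TR decomposition is a configurable model, not a vendor timing
  engine; absolute minimum TRs are approximate even though per-slice times
  and ratios are exact.
- The mixture-model threshold is undefined (infinite) when an image has no
  positive activation component; callers get an empty suprathreshold set.
- Dual regression on very small grids shows the known circularity bias of
  stage-1-estimated regressors; at the 32-scale grids used for acceptance
  it is within a few percent.
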