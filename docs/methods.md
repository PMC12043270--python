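# Methods

This note records the models implemented in `neodmri`, the defaults they
ship with, and the design choices made where several reasonable options
existed.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units and conventions

b-values in s/mm², diffusivities in μm²/ms, so the diffusion exponent is
`b·D·10⁻³` (dimensionless); the kurtosis term is `(1/6)·b²·D²·10⁻⁶·K`.
Voxel indices are 0-based with readout on axis 0, phase encoding (PE) on
axis 1 and slice on axis 2; NIfTI affines are diagonal with isotropic
spacing.  Positive off-resonance shifts signal along +PE; reversed-PE
acquisitions negate the shift.

## Echo-train timing, PSF and distortion (`epi_geometry`)

An EPI shot acquires `ceil(n_pe/R)` lines separated by the echo spacing
(default 188 lines, 0.4 ms).  Readout segmentation splits the
*frequency*-encoding axis across shots, so PE blurring and distortion
depend on R only; segments multiply per-volume time.

**PSF.** The k-space envelope over the acquired lines is
`w(n) = exp(-n·esp/T2*)` in linear (monotonic) PE ordering, decay measured
from the first acquired line; the ordering is not otherwise constrained
because the magnitude PSF of a real exponential envelope is
ordering-phase-invariant.  The profile is the magnitude of the zero-padded
(≥64×) DFT, and FWHM is read off by linearly interpolated half-maximum
crossings.  The axis is expressed per acquired-lattice resolution element
(1 bin = 1/oversample voxels), which coincides with the nominal voxel
whenever R divides n_pe and keeps FWHM(R) monotone; the alternative
rescaling by `n_pe/(R·lines)` differs by at most 0.5% (at R=3).  In the
no-decay limit the profile is the periodic sinc with FWHM 1.2067 voxels,
verified against an independent dense-search oracle.  At T2* = 83 ms the
model gives 1.245/1.216/1.211/1.209 voxels for R=1..4; published
simulations of the same protocol report 1.29/1.24/1.23/1.22.  The ~0.04
gap at R=1 is consistent with the reference simulation including effects
beyond pure T2* decay (e.g. field-map-induced local gradients); the
package treats ±0.05 voxels as the meaningful agreement band.

**Distortion.** `shift_voxels = f·T_eff` with `T_eff = n_pe·esp/R`.  The
*exact* `1/R` scaling (rather than `ceil(n_pe/R)·esp`, which would break it
at R=3) is deliberate: the acceleration comparison is defined by that
proportionality, and the integer line count is a timing detail of the
shot, not of the accumulated phase ramp per unit k.  Percentiles use
linear interpolation between order statistics so the 90th percentile is
reproducible.

## Synthetic phantom (`phantom_forge`)

Anatomy is schematic — nested ellipsoids with a 1–2 voxel cortical ribbon,
paired deep-grey nuclei, paired ventricles, and an optional dilated-
ventricle lesion ring — because every downstream check rests on parameter
recovery, not anatomical realism.  Per-tissue defaults model unfixed
post-mortem neonatal tissue at 7T and ~10 °C:

| tissue | T2 (ms) | T2* (ms) | MD (μm²/ms) | FA | MK |
| --- | --- | --- | --- | --- | --- |
| WM | 178 | 83 | 0.071 | 0.40 | 1.2 |
| cortical GM | 160 | 70 | 0.075 | 0.15 | 1.0 |
| deep GM | 150 | 60 | 0.080 | 0.10 | 0.9 |
| CSF | 1800 | 400 | 1.50 | 0 | 0 |
| lesion | 120 | 45 | 0.30 | 0 | 0.5 |

WM T2/T2*/MD are the anchored working-point values; GM/lesion values are
plausible interpolations (unpublished for this preparation) and CSF MD
sits near free water at 10 °C from the temperature law below.  The DWI
signal is the kurtosis representation with an axially symmetric tensor
built from (MD, FA, principal direction) — eigenvalues `MD(1+2δ)`,
`MD(1−δ)` with `δ = FA/√(3−2FA²)` — and a scalar kurtosis.  Noise is
independent complex Gaussian per channel; magnitudes are Rician.  A
per-volume multiplicative MD factor emulates slow ADC drift (thermal
settling) across a session.

Field maps are smoothed Gaussian noise rescaled so the masked 90th
percentile of |f| hits the requested value (exact up to floating point;
contract 0.1%) — a calibrated stand-in for a measured infant field map,
since linear scaling to another field strength scales the percentile
exactly.  Coils are two rings of 8 loop elements on an infant-coil former
(117×135×114 mm inner dimensions) with smooth `1/(r+d)` magnitude and
slowly varying phase; the real coil maps are unpublished.

k-space encoding applies `exp(-t/T2*)·exp(2πi f t)` per acquired PE line
before spatial encoding; MB slices (spaced `n_slices/MB` apart) are summed
without CAIPI shifts; in-plane undersampling keeps every R-th line; slices
are zero-padded (and the count recorded) when MB does not divide the slice
count.  Calibration is an ideal fully sampled low-resolution block per
slice — the scanner's actual calibration scheme is not modelled — and
segments are phase-consistent, so no navigator correction is needed.

## Parallel imaging (`parallel_recon`)

Split slice-GRAPPA fits one 5×5 (PE×RO) multi-coil kernel per collapsed
slice by regularized least squares over the stacked per-slice calibration
patches, with targets equal to the slice's own centre samples for its own
calibration and zero for the others — jointly penalizing target error and
inter-slice leakage.  In-plane GRAPPA uses 4×5 kernels per missing-line
offset.  Both use Tikhonov regularization at 1e-4 of the mean calibration
Gram eigenvalue; that level costs a ~1e-3 relative bias noiselessly and is
kept for noise robustness.  Magnitude images are root-sum-of-squares coil
combinations.  The analytic g-factor is the SENSE unmixing of the combined
MB×R aliasing pattern; the pseudo-multiple-replica estimate (default 200
seeded replicas) converges to it within 5% and is provided as a
cross-check.  NRMSE is RMS error over a mask divided by the reference RMS.
On the bundled 16-channel fixture the NRMSE ranking is MB2R2 < MB3R2 <
MB4R2 < MB2R3 and MB2R2 also minimizes median g; orderings, not absolute
fixture values, are the supported comparison surface.

## Feasibility and scheduling (`protocol_planner`)

Timing model: one volume costs `TR × n_segments`; one TR covers
`ceil(n_slices/MB)` slice blocks of `TE + half echo train + overhead` ms.
The overhead (34.35 ms) is calibrated once from the reference protocol
(TR 10.8 s at MB2, R2, 130 slices, TE 113 ms) and assumed MB/R-independent
— the minimal model consistent with the printed TRs; per-slice sequence
timing is not published.  The calibration pair is an exact fixed point.
With a 7 h session and 301 volumes the per-volume cap is 83 s and the TR
cap 11.96 s (12 s rounded); the same five protocols (all MB=1, plus MB2R1
at 12.02 s) are excluded under either budget convention.  The SAR model is
deliberately parametric (`fraction = E_vol/TR`, conservative cap 0.8,
energy constant supplied by the user): published SAR values are
figure-only, so exclusion counting uses the TR budget alone.

Shell partitioning caps subsets at 18 directions (the smallest cap that
splits 64/88/128 into 4/5/8) with balanced sizes.  Interleaving alternates
highest-b subsets with the remaining shells' subsets taken round-robin in
ascending b (duty-cycle balance; the round-robin order is a package
choice), errors when alternation is impossible, and degenerates to a
sequential list for a single shell.  Direction sets come from seeded
antipodally symmetric electrostatic-repulsion descent (200 iterations
default).

## Forecasts (`signal_forecast`)

T2 field scaling is linear in R2 = 1/T2 with the default slope 0.372
s⁻¹T⁻¹ calibrated on the (280 ms @ 1.5 T → 178 ms @ 7 T) white-matter
pair; the functional form is the package's choice of the simplest law
reproducing that pair.  Water diffusivity follows the Speedy–Angell power
law (D₀ = 16.35 μm²/ms, Tₛ = 215.05 K, γ = 2.063), which matches tabulated
free-water measurements at 5–35 °C within 3% and predicts a factor ≈2.0
between 37 °C and 10 °C.  Signal comparisons multiply `exp(-TE/T2)` by the
mono-exponential attenuation; SNR comparisons add the voxel-volume ratio
and the square root of the total-readout-time factor (7 segments vs single
shot → √7).  Both sides of a comparison must state TE/T2/b/ADC explicitly
and the full assumption set is echoed in the result; the headline 2.5-fold
signal / ≈3-fold SNR gains are reproduced as ranges over the reported
post-mortem ADC interval 0.2–0.3 μm²/ms with an assumed adult WM T2 of
47 ms at 7T (mid-range ADC 0.22 reproduces the point values).

## QA estimators (`shellwise_qa`)

Shell ADC uses the direction-averaged (powder) signal log-ratio against
b=0; kurtosis fitting uses per-direction signals — the distinction is
deliberate and both are documented because powder averaging biases
high-b anisotropic signals.  Non-positive magnitudes are excluded
voxel-wise from log fits and counted, never clamped.

Sub-group stability fits each interleaved subset's ADC from its own
opening b=0 and its shell members (nearest scheduled b=0 as fallback),
ordered by acquisition mid-time; the coefficient of variation is the
sample std/mean of the sub-group medians across the session (the
"across sub-groups per tissue" reading of session stability).  The drift
fixture uses an isotropic Gaussian phantom so the subset series isolates
drift: with anisotropic tissue, 16-direction subsets add powder-sampling
variation that is a property of the sub-sampling, not of the scanner.

The kurtosis fit estimates `ln S0`, six tensor elements and one scalar K
by iterated weighted linear least squares (signal-squared weights, 6
rounds), recomputing the directional diffusivity in the kurtosis regressor
from the current tensor each round; the generator's model is an exact
fixed point, and noiseless recovery is verified to well under 2%.  MO is
the tensor mode `3√6·det(deviatoric/|deviatoric|)`, reported as 0 with a
flag for isotropic voxels; negative-eigenvalue voxels are flagged.

BIC selection refits a model family with the axial diffusivity held fixed
at each grid point (default grid {0.01, 0.05, …, 1.0} μm²/ms — a strict
0.05 step from 0.01 would miss 0.25/0.30/0.35, the region of interest) and
averages the per-voxel `BIC = n·ln(RSS/n) + k·ln(n)` over the mask; the
averaged-BIC form is a package choice, as is the flatness flag (both
neighbours of the argmin within ΔBIC < 2) and the reporting of
neighbour-ΔBIC as a sensitivity field — parameters conditioned on a flat
selection valley should not be over-interpreted.  The bundled
three-compartment family (stick, tortuosity-linked hindered pool with
`d⊥ = d∥(1−φ)`, free isotropic water at 1.5 μm²/ms, restricted isotropic
"dot" pool) is dispersion-free by design: it makes the selection harness
testable end-to-end without Watson-dispersion integrals, which are out of
scope.  Fitting scans φ over a coarse grid with non-negative least squares
for the four amplitudes (5 effective parameters); the fibre axis comes
from a log-linear tensor fit.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale problems chosen to make every
check sharp while remaining cheap: 40–48 voxel in-plane phantoms, 12–16
slice slabs for reconstruction (in-plane 48 divisible by R=2,3,4; 12
slices divisible by MB=2,3,4), one-slice WM masks (~700 voxels) for DKI,
40–60 voxels × 25 seeded repeats for BIC selection, and the full
301-volume schedule for drift.  RSS values are floored at 1e-30 before
logs; percentile and FWHM interpolation are linear; all stochastic paths
take explicit integer seeds.

## Limitations

The phantom does not emulate susceptibility-induced fields from anatomy,
gradient nonlinearity, eddy currents, partial-Fourier readouts, CAIPI
shifts, inter-segment phase errors, multi-compartment exchange or fibre
dispersion; passing tests therefore demonstrate correctness of the
computations under their stated models, not performance on scanner data.
Absolute NRMSE/g values on the bundled coil fixture depend on its
synthetic geometry; only orderings are meaningful.  The SAR model is
calibratable but not verifiable against published numbers.
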