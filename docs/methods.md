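# Methods

This note documents the models implemented in `prfscotoma`, the
choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Stimulus model

The aperture is a bar of width 1.75° sweeping a circular 14° visual
field in discrete steps, one step per acquisition frame (TR).  Eight
crossings rotate clockwise in 45° increments starting from a
left-to-right sweep; 12 s blanks follow every second (diagonal)
crossing.  The number of positions per crossing is
`field/step + 1` when the ratio is integral, otherwise `ceil(field/step)`,
which yields the canonical 18 positions (0.8° steps, TR 2 s → 168
frames per run) and 36 positions (0.4° steps, TR 1 s → 336 frames).

Open choices, resolved once:

- **Bar position** refers to the bar *center*, starting at the field
  edge (−7° along the motion direction).  In the 0.8° case the 18
  positions therefore span −7.0° to +6.6°.
- **Raster**: 101 × 101 cell centers over [−7°, +7°]² (odd count puts
  a cell exactly at fixation); a cell is stimulated if its center is
  inside the bar and inside the field disc.  Resolution is
  configurable.
- **Scotoma mask**: cells with eccentricity ≤ the scotoma radius are
  never stimulated; a zero radius is exactly a no-op.
- The checkerboard carrier (contrast, 8 Hz flicker) is not modelled;
  the analysis consumes only the binary aperture.

## pRF forward model

A voxel's population receptive field is an isotropic 2D Gaussian with
center (x, y) and size σ (degrees).  The neural drive of frame *t* is
the inner product of the aperture with the Gaussian; the nonlinear
variant raises the drive to a compressive exponent *n* ∈ (0, 1]
before hemodynamics (compressive spatial summation).  The BOLD
prediction is `baseline + β · (drive ⊛ HRF)`, convolved at TR
resolution (bar steps are TR-locked, so supersampling would only
interpolate).

The HRF is a difference of two gamma densities in the peak-time
parameterization (shape = delay/dispersion + 1, scale = dispersion),
so the kernel's positive lobe peaks at `peak_delay_s`.  The canonical
kernel uses peak delay 6 s, undershoot delay 16 s, dispersions 1 s,
peak:undershoot ratio 6, and is normalized to unit peak.  The fitted
variant frees only the peak delay and peak dispersion — the
undershoot is poorly constrained by 168-frame runs, and run-to-run
hemodynamic variability is dominated by the first peak (position
±0.8 s, width ≈ 1 s).

## Synthetic data generator

A simulated subject is a set of abstract V1 voxels (no spatial
layout, matching the voxel-to-voxel design of the analysis):

- **Centers**: eccentricity uniform on [0°, 7°], polar angle uniform —
  per-area density falls as 1/ecc, a cortical-magnification-like
  foveal concentration.
- **Sizes**: σ = 0.5° + 0.1° · eccentricity, a linear V1-like
  size–eccentricity law (σ ∈ [0.5°, 1.2°]).
- **Amplitudes**: β is calibrated per voxel, once, against a
  *full-field* run so the noiseless response has unit standard
  deviation.  The same β then drives the scotoma condition — ground
  truth is condition-invariant, and partially masked voxels genuinely
  respond less.
- **Noise**: i.i.d. Gaussian, default sd 1.0, giving a median
  full-field single-run variance explained near 0.5 (realistic for
  high-field single runs).  An optional AR(1) flag adds temporal
  autocorrelation for robustness experiments; the analysis itself
  assumes none.
- **Sessions**: 2 sessions × 2 runs; each run draws its own HRF peak
  delay uniformly within ±0.8 s of 6 s.  Session averages are
  frame-wise means (noise sd shrinks by √2).  Run (s, r) uses seed
  `base_seed + 2(s−1) + (r−1)`.

What the generator does *not* emulate: head motion, fixation
instability, spatially correlated noise, draining veins, the
continuum of marginally responsive voxels found inside a real V1
mask, and receptive-field shapes beyond the isotropic Gaussian.
Passing tests therefore demonstrate the *machinery* (estimator
correctness, the scotoma-naive bias mechanism, coordinate-transform
effects) — not that real-data reliability magnitudes would be
reproduced.

## Fitting

Fitting is always scotoma-naive: predictions use the full-field
aperture regardless of how the data were acquired.  Five stages:

1. exhaustive coarse grid search under the canonical HRF — x, y on a
   0.5° lattice over the 7° disc, σ ∈ {0.25, 0.5, 1, 2, 4}°
   (exponent ∈ {0.25, 0.5, 0.75, 1} for the nonlinear variant);
2. per-run HRF fit (Nelder–Mead over peak delay ∈ [3, 10] s and peak
   dispersion ∈ [0.5, 2.5] s) on the 50 best-explained voxels above
   the gate, falling back to the canonical kernel when fewer than 50
   qualify;
3. coarse re-fit under the fitted HRF;
4. local refinement of (x, y, σ[, n]): a bounded coordinate pattern
   search with per-voxel geometrically shrinking steps (position step
   0.25° → 0.002°, σ multiplicative), evaluated in vectorized batches
   across all voxels.  This implements the same derivative-free
   local-optimization contract as a per-voxel simplex, but runs
   orders of magnitude faster as array operations; variance explained
   is non-decreasing by construction.
5. final amplitude/baseline/variance-explained computation.

Amplitude and baseline are profiled out analytically at every
candidate (β from the regression slope, so candidates are ranked by
squared positive correlation); candidates that would need β < 0 are
rejected, since pRFs model positive responses.  Ties resolve to the
smallest eccentricity, then smallest σ, making outputs deterministic.
Voxels whose coarse variance explained is below 0.02 skip stage 4: a
voxel that far under the 0.10 inclusion gate cannot be lifted across
it by a local polish, and the gate discards it downstream.

Noiseless recovery (matched HRF): median |Δecc| ≈ 0.001°, median
relative σ error ≈ 0.2% — comfortably inside the 0.05° / 5% contract.

The forward model may be evaluated on a coarser raster than the
simulation (default 61 × 61 for pipeline fits); the Gaussian–aperture
overlap converges quickly with resolution and this roughly halves to
quarters the fit cost with no measurable recovery penalty.

## Scotoma border estimation

Gated pRF centers (variance explained > 0.10) are reduced to
eccentricities r_vox and smoothed with Gaussian kernels,

    KDE_pRF(x) = 1/(n·√(2πw²)) · Σ_vox exp(−(x − r_vox)²/(2w²)),

with Scott's-rule bandwidth w = 3.5·σ_r·n^(−1/3), where σ_r is the
sample standard deviation of the eccentricities entering *that* curve
(computed per curve — the source dataset for σ_r is otherwise
ambiguous) and n their count.  The gate is what creates the central
density deficit: voxels inside a scotoma lack the characteristic
signal and cannot pass it.

Curves are evaluated from 0° to 8° in 0.01° steps (one degree beyond
the stimulated radius, to capture edge kernels).  The reference
density is the pointwise mean of the individual full-field reference
subjects' curves.  Each scotoma dataset is compared through

    comp(x) = (ref − scot) / (ref + scot) ∈ [−1, 1],

undefined (and excluded from scanning) where both densities are below
1e-12.  Scanning outward from x = 0, the border is the first downward
crossing of 0.1 after a region at or above it, linearly interpolated
between grid points.  Curves that never reach 0.1 flag "no scotoma";
curves that start below 0.1 but exceed it further out flag
"non-central" rather than returning a border.  Borders are reported
both per subject and from the group-averaged classification curve —
the two do not coincide in general.

## Reliability battery

Voxels are paired across two analyses by id and kept when variance
explained exceeds the threshold in both.  Spearman rank correlations
(mid-ranks for ties) are computed per parameter (x, y, eccentricity,
polar angle, σ), per subject, then group-averaged via Fisher z
(tanh of the mean atanh).  Mean within-voxel differences are absolute
differences, with polar angle wrapped to [0°, 180°]; an optional
eccentricity limit (e.g. < 7°, the stimulated field) applies to both
analyses.  Polar angle enters the correlation as a linear variable on
(−180°, 180°]; the branch-cut caveat this carries is discussed below.

The coordinate-bias simulation jitters a [−7°, 7°]² grid (1° spacing)
with isotropic Gaussian noise (default sd 0.5°), correlates true
versus jittered values in Cartesian and polar coordinates over many
repetitions (default 1000) and Fisher-averages the result; an
exclusion radius removes central grid points first.  Polar angle is
circular, so each jittered angle is unwrapped to the 360° branch
nearest its true value before ranking: without this, the arbitrary
position of the ±180° cut — not the geometry of the transform —
dominates the angle correlation and caps it near 0.92 at *any* noise
level.  With the unwrapping, the simulation isolates the genuine
effects: x and y behave identically; the radius correlation falls
below the angle correlation (radius compresses the noise into a
narrower, tie-heavy range); and excluding the central 2° widens that
gap by restricting the radius range further while removing the
noisiest angles.

## Known limitations

- The reliability-versus-threshold sweep on synthetic data does *not*
  reproduce the rising σ-reliability trend reported on real data.
  In an all-genuine synthetic population, tightening the gate mainly
  restricts parameter range and removes border voxels whose σ
  inflation is correlated between runs, so the trend is flat to
  negative.  The real-data trend evidently rides on the continuum of
  marginally responsive voxels in an anatomical V1 mask, which the
  generator deliberately does not emulate.  The sweep is provided as
  functionality; no synthetic test asserts the real-data direction.
- Real-data correlation magnitudes (e.g. position ≈ 0.95–0.99 vs
  size ≈ 0.4) are not reproduction targets; only the robust
  direction — position parameters more reliable than σ — is asserted.
- Surround suppression (difference of Gaussians) and elliptical pRFs
  are out of scope.

## Problem sizes used by the shipped experiments

The border-recovery experiment simulates 10 full-field reference
subjects and 5 scotoma subjects at 600 voxels each (within the
500–1000 range the analysis is designed for), fits on a 61 × 61
forward-model raster, and completes in a few minutes on one CPU; the
reliability tests use 3 subjects × 150 voxels.  These sizes were
chosen as the smallest cohorts at which the group-level border
estimate is stable across seeds.
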