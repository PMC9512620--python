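# prfscotoma

Simulation and analysis of population receptive field (pRF) mapping
with artificial central scotomas.

Visual-field losses (scotomas) can be measured objectively with fMRI:
each voxel of early visual cortex is modelled by a population
receptive field — an isotropic 2D Gaussian on the visual field with
center (x, y) and size σ — estimated from the response to a bar
sweeping across the visual field.  When the central stimulus region
is masked, voxels representing the masked area lose their driving
signal, fail the variance-explained inclusion gate, and the fitted
pRF centers of partially driven voxels shift outward and pile up just
beyond the mask border.  This package implements, end to end and on
purely synthetic data:

- **Stimulus simulation** — a 1.75°-wide bar crossing a 14° field in
  0.8° steps (TR 2 s, 168 frames) or 0.4° steps (TR 1 s, 336 frames),
  eight crossings rotating clockwise by 45°, 12 s blanks after the
  diagonal crossings, with an optional central mask (the artificial
  scotoma).
- **Forward model and fitting** — BOLD predictions via a two-gamma
  HRF; scotoma-naive five-stage coarse-to-fine estimation of
  (x, y, σ), with per-run HRF fitting, a canonical-HRF variant and a
  compressive spatial-summation (nonlinear) variant.
- **Scotoma border estimation** — pRF-center density over
  eccentricity by kernel density estimation with Scott's-rule
  bandwidth w = 3.5 σ_r n^(−1/3); the normalized comparison with a
  full-field reference cohort,
  KDE_comp = (KDE_ref − KDE_scotoma)/(KDE_ref + KDE_scotoma); border
  read-out at the first outward crossing of the 0.1 level.
- **Reliability statistics** — voxel matching with double
  variance-explained gating, Spearman correlations per parameter,
  Fisher-z group averaging, mean absolute voxelwise differences, and
  the Cartesian-versus-polar coordinate bias simulation.

Audience: vision scientists evaluating pRF-based scotoma mapping, and
methodologists who need a tested, fully synthetic sandbox for
perimetry-by-pRF analysis pipelines.

## Worked example

Simulate one subject's full-field run, fit it, and inspect recovery:

```python
import numpy as np
import prfscotoma as pf
from prfscotoma.fitting import FitConfig

seq = pf.build_sequence(pf.study_config(scotoma_radius_deg=0.0,
                                        grid_resolution=61))
pop = pf.sample_population(200, seed=7)
pop = pf.calibrate_amplitudes(pop, seq)          # unit signal sd
run = pf.simulate_run(pop, seq, noise_sd=1.0, seed=8)
table = pf.fit_run(run.timeseries, seq, FitConfig())

print("gated voxels:", (table.variance_explained > 0.10).sum(), "of", len(table))
print("median VE: %.3f" % table.variance_explained.median())
truth_ecc = np.array([v.params.eccentricity for v in pop])
print("median |ecc error|: %.3f deg"
      % np.median(np.abs(table.eccentricity - truth_ecc)))
print("fitted HRF peak delay: %.2f s" % table.hrf_peak_delay_s.iloc[0])
```

```
gated voxels: 200 of 200
median VE: 0.508
median |ecc error|: 0.142 deg
fitted HRF peak delay: 5.96 s
```

At the default signal-to-noise (unit signal sd, unit noise sd) every
genuine voxel clears the 10% variance-explained gate, the median
variance explained sits near 0.5, eccentricity is recovered to about
0.14° despite the noise, and the per-run HRF fit lands near the true
6 s peak delay.

The coordinate-bias simulation from the command line:

```bash
$ prfscotoma bias-sim --reps 200 --seed 7
{
  "x": 0.9937219330300533,
  "y": 0.9936696774351979,
  "radius": 0.9709527234404591,
  "angle": 0.9949745560223392
}
```

x and y behave identically; the radius (eccentricity) correlation is
systematically lower than the polar-angle correlation — a pure
artifact of the coordinate transform, not of the measurement.

Other entry points: `prfscotoma simulate stimulus|study`,
`prfscotoma fit`, `prfscotoma kde`, `prfscotoma run-study` (the full
multi-subject pipeline with tabular outputs), and
`prfscotoma border-benchmark`.

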