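"""Synthetic voxel populations and multi-run, multi-session datasets.

A simulated "subject" is a population of abstract V1 voxels, each with a
ground-truth pRF, measured in two sessions of two moving-bar runs each.
Centers are sampled uniformly in eccentricity (denser per unit area
foveally, emulating cortical magnification) with uniform polar angle,
and pRF size grows linearly with eccentricity.  Response amplitudes are
calibrated against a full-field run so that the noiseless signal has a
target standard deviation, which makes the signal-to-noise ratio — and
hence the fraction of voxels passing a variance-explained gate —
directly configurable through ``noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .prf_model import (
    CANONICAL_HRF,
    HRFParams,
    ModelVariant,
    PRFParams,
    predict_timecourse,
    two_gamma_hrf,
)
from .stimulus import ApertureSequence, StimulusConfig, build_sequence

__all__ = [
    "GroundTruthVoxel",
    "SimulatedRun",
    "StudyDataset",
    "sample_population",
    "calibrate_amplitudes",
    "simulate_run",
    "simulate_study",
    "population_frame",
]

#: default noiseless-signal standard deviation after amplitude calibration
DEFAULT_SIGNAL_SD = 1.0
#: default additive noise standard deviation; with unit signal sd this puts
#: the median full-field variance explained near 0.5
DEFAULT_NOISE_SD = 1.0
#: spread of the per-run HRF peak-delay jitter (seconds)
DEFAULT_HRF_JITTER_S = 0.8


@dataclass(frozen=True)
class GroundTruthVoxel:
    voxel_id: int
    params: PRFParams
    region: str = "V1"


@dataclass
class SimulatedRun:
    """Noisy simulated time series for one run of one subject."""

    timeseries: np.ndarray  # (n_voxels, n_frames)
    seq: ApertureSequence
    noise_sd: float
    hrf_used: HRFParams
    seed: int | None
    session_id: int = 1
    run_id: int = 1

    def __post_init__(self) -> None:
        if self.timeseries.shape[1] != self.seq.n_frames:
            raise ValueError("timeseries column count != frame count")


@dataclass
class StudyDataset:
    """Four runs (2 sessions × 2 runs) plus per-session averages."""

    population: list[GroundTruthVoxel]
    runs: dict[tuple[int, int], SimulatedRun]
    averages: dict[int, SimulatedRun] = field(default_factory=dict)

    def voxel_ids(self) -> np.ndarray:
        return np.array([v.voxel_id for v in self.population])


def sample_population(
    n_vox: int,
    field_radius_deg: float = 7.0,
    sigma_slope: float = 0.1,
    sigma_intercept: float = 0.5,
    seed: int | None = None,
) -> list[GroundTruthVoxel]:
    """Draw a ground-truth voxel population.

    Eccentricity is uniform on [0, field_radius_deg] (per-area density
    ∝ 1/ecc, i.e. foveally weighted), polar angle uniform, and
    σ = sigma_intercept + sigma_slope × eccentricity.  Amplitudes are
    left at 1 until :func:`calibrate_amplitudes` is applied.
    """
    if n_vox < 1:
        raise ValueError("n_vox must be >= 1")
    if sigma_slope < 0 or sigma_intercept <= 0:
        raise ValueError("sigma law must have slope >= 0 and intercept > 0")
    rng = np.random.default_rng(seed)
    ecc = rng.uniform(0.0, field_radius_deg, n_vox)
    ang = rng.uniform(-np.pi, np.pi, n_vox)
    voxels = []
    for i in range(n_vox):
        params = PRFParams(
            x=float(ecc[i] * np.cos(ang[i])),
            y=float(ecc[i] * np.sin(ang[i])),
            sigma=float(sigma_intercept + sigma_slope * ecc[i]),
        )
        voxels.append(GroundTruthVoxel(voxel_id=i, params=params))
    return voxels


def population_frame(pop: list[GroundTruthVoxel]):
    """Ground-truth table (one row per voxel) as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "voxel_id": [v.voxel_id for v in pop],
            "x": [v.params.x for v in pop],
            "y": [v.params.y for v in pop],
            "sigma": [v.params.sigma for v in pop],
            "eccentricity": [v.params.eccentricity for v in pop],
            "polar_angle_deg": [v.params.polar_angle_deg for v in pop],
            "beta": [v.params.beta for v in pop],
            "region": [v.region for v in pop],
        }
    )


def _noiseless_matrix(
    pop: list[GroundTruthVoxel], seq: ApertureSequence, h: HRFParams
) -> np.ndarray:
    """Noiseless prediction matrix (n_voxels, n_frames), vectorized."""
    from scipy import signal as _signal

    gx, gy = seq.cell_coordinates()
    xs = np.array([v.params.x for v in pop])
    ys = np.array([v.params.y for v in pop])
    sig = np.array([v.params.sigma for v in pop])
    # (n_cells, n_vox) Gaussian weights
    g = np.exp(
        -((gx[:, None] - xs[None, :]) ** 2 + (gy[:, None] - ys[None, :]) ** 2)
        / (2.0 * sig[None, :] ** 2)
    )
    drive = seq.flat @ g  # (n_frames, n_vox)
    kernel = two_gamma_hrf(h, seq.config.tr_s)
    resp = _signal.fftconvolve(drive, kernel[:, None], axes=0)[: seq.n_frames]
    beta = np.array([v.params.beta for v in pop])
    base = np.array([v.params.baseline for v in pop])
    return (resp * beta[None, :] + base[None, :]).T


def calibrate_amplitudes(
    pop: list[GroundTruthVoxel],
    seq: ApertureSequence,
    h: HRFParams = CANONICAL_HRF,
    target_sd: float = DEFAULT_SIGNAL_SD,
) -> list[GroundTruthVoxel]:
    """Set each voxel's beta so its noiseless response has sd ``target_sd``.

    Calibration is done once, against a full-field sequence, and the
    resulting betas are part of the ground truth: the same amplitudes
    drive the scotoma condition, where partially masked voxels then
    genuinely respond less.
    """
    unit_pop = [
        replace(v, params=replace(v.params, beta=1.0, baseline=0.0))
        for v in pop
    ]
    ts = _noiseless_matrix(unit_pop, seq, h)
    sds = ts.std(axis=1)
    out = []
    for v, sd in zip(pop, sds):
        beta = target_sd / sd if sd > 1e-12 else 0.0
        out.append(replace(v, params=replace(v.params, beta=float(beta))))
    return out


def simulate_run(
    pop: list[GroundTruthVoxel],
    seq: ApertureSequence,
    h: HRFParams = CANONICAL_HRF,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
    session_id: int = 1,
    run_id: int = 1,
    ar1_coef: float = 0.0,
) -> SimulatedRun:
    """One noisy run: noiseless predictions plus Gaussian noise.

    Noise is i.i.d. by default; ``ar1_coef`` adds optional first-order
    temporal autocorrelation (stationary AR(1) with marginal sd
    ``noise_sd``) for robustness experiments.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    clean = _noiseless_matrix(pop, seq, h)
    rng = np.random.default_rng(seed)
    if noise_sd == 0:
        noisy = clean
    elif ar1_coef == 0.0:
        noisy = clean + rng.normal(0.0, noise_sd, clean.shape)
    else:
        if not -1 < ar1_coef < 1:
            raise ValueError("ar1_coef must be in (-1, 1)")
        innov_sd = noise_sd * np.sqrt(1 - ar1_coef**2)
        eps = rng.normal(0.0, innov_sd, clean.shape)
        eps[:, 0] = rng.normal(0.0, noise_sd, clean.shape[0])
        noise = np.empty_like(eps)
        noise[:, 0] = eps[:, 0]
        for t in range(1, eps.shape[1]):
            noise[:, t] = ar1_coef * noise[:, t - 1] + eps[:, t]
        noisy = clean + noise
    return SimulatedRun(
        timeseries=noisy,
        seq=seq,
        noise_sd=noise_sd,
        hrf_used=h,
        seed=seed,
        session_id=session_id,
        run_id=run_id,
    )


def simulate_study(
    pop: list[GroundTruthVoxel],
    study_config: StimulusConfig,
    n_sessions: int = 2,
    n_runs: int = 2,
    noise_sd: float = DEFAULT_NOISE_SD,
    base_seed: int = 0,
    hrf_jitter_s: float = DEFAULT_HRF_JITTER_S,
    seq: ApertureSequence | None = None,
) -> StudyDataset:
    """Simulate one subject's full study: runs, sessions and averages.

    Run (session s, run r) gets seed ``base_seed + 2(s−1) + (r−1)`` and
    its own HRF whose peak delay is jittered uniformly within
    ±``hrf_jitter_s`` around the canonical 6 s (per-run hemodynamic
    variability).  Per-session averaged runs are the frame-wise mean of
    the session's runs, halving the noise variance.
    """
    if seq is None:
        seq = build_sequence(study_config)
    hrf_rng = np.random.default_rng(base_seed)
    runs: dict[tuple[int, int], SimulatedRun] = {}
    for s in range(1, n_sessions + 1):
        for r in range(1, n_runs + 1):
            delay = CANONICAL_HRF.peak_delay_s + hrf_rng.uniform(
                -hrf_jitter_s, hrf_jitter_s
            )
            h = CANONICAL_HRF.with_peak(delay, CANONICAL_HRF.peak_dispersion_s)
            seed = base_seed + n_runs * (s - 1) + (r - 1)
            runs[(s, r)] = simulate_run(
                pop, seq, h, noise_sd, seed=seed, session_id=s, run_id=r
            )
    averages: dict[int, SimulatedRun] = {}
    for s in range(1, n_sessions + 1):
        stack = np.stack(
            [runs[(s, r)].timeseries for r in range(1, n_runs + 1)]
        )
        averages[s] = SimulatedRun(
            timeseries=stack.mean(axis=0),
            seq=seq,
            noise_sd=noise_sd / np.sqrt(n_runs),
            hrf_used=runs[(s, 1)].hrf_used,
            seed=None,
            session_id=s,
            run_id=0,
        )
    return StudyDataset(population=pop, runs=runs, averages=averages)
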