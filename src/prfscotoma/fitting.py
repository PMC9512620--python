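"""Scotoma-naive pRF estimation with a five-stage coarse-to-fine search.

Fitting always assumes full-field stimulation: the forward model is
evaluated on an unmasked aperture sequence even when the data were
acquired (or simulated) with an artificial scotoma.  This is what
produces the characteristic displacement of fitted centers from inside
a scotoma toward its border.

The five stages are: (1) exhaustive coarse grid search with the
canonical HRF, (2) per-run HRF fit on the best-explained voxels,
(3) coarse re-fit under the fitted HRF, (4) derivative-free local
refinement of position and size (and exponent for the nonlinear
variant), and (5) final amplitude/baseline estimation.  Amplitude and
baseline are profiled out analytically at every candidate, so the
search only ever ranks candidates by variance explained; candidates
requiring a negative amplitude are rejected.

Stage 4 uses a bounded pattern search (coordinate-wise proposals with a
geometrically shrinking step), evaluated in vectorized batches across
all voxels simultaneously rather than voxel-by-voxel — the same
local-optimization contract as a simplex search, but orders of
magnitude faster in this array setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .prf_model import (
    CANONICAL_HRF,
    HRFParams,
    ModelVariant,
    PRFParams,
    polar_angle_deg,
    two_gamma_hrf,
)
from .stimulus import ApertureSequence

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "RESULT_COLUMNS",
    "variance_explained",
    "coarse_fit",
    "refine_fit",
    "fit_run_hrf",
    "fit_run",
    "fit_population",
]

#: canonical column set of a pRF result table
RESULT_COLUMNS = (
    "voxel_id",
    "x",
    "y",
    "sigma",
    "exponent",
    "beta",
    "baseline",
    "variance_explained",
    "eccentricity",
    "polar_angle_deg",
    "hrf_peak_delay_s",
    "hrf_peak_dispersion_s",
)


@dataclass(frozen=True)
class FitConfig:
    """Search-space and procedure settings for pRF fitting."""

    variant: ModelVariant = ModelVariant.GAUSSIAN_FITTED_HRF
    grid_spacing_deg: float = 0.5
    sigma_levels: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    exponent_levels: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    n_stages: int = 5
    ve_threshold: float = 0.10
    position_bound_deg: float = 9.0
    sigma_bounds: tuple[float, float] = (0.05, 8.0)
    exponent_bounds: tuple[float, float] = (0.1, 1.0)
    refine_initial_step_deg: float = 0.25
    refine_tolerance_deg: float = 2e-3
    refine_max_iter: int = 100
    refine_min_ve: float = 0.02
    hrf_n_voxels: int = 50
    hrf_min_gated: int = 50
    hrf_delay_bounds: tuple[float, float] = (3.0, 10.0)
    hrf_dispersion_bounds: tuple[float, float] = (0.5, 2.5)

    def __post_init__(self) -> None:
        if not 0 <= self.ve_threshold < 1:
            raise ValueError("ve_threshold must be in [0, 1)")
        if len(self.sigma_levels) == 0 or len(self.exponent_levels) == 0:
            raise ValueError("grids must be non-empty")


def variance_explained(observed: np.ndarray, predicted: np.ndarray) -> float:
    """1 − SS_residual / SS_total (about the observed mean).

    Returns NaN for a constant observed series, where the quantity is
    undefined.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length 1D, n >= 2")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot <= 0:
        return float("nan")
    ss_res = np.sum((obs - pred) ** 2)
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# internal vectorized machinery


def _candidate_grid(cfg: FitConfig, field_radius: float):
    """Coarse (x, y, sigma) candidates, sorted by (ecc, sigma)."""
    coords = np.arange(
        -field_radius, field_radius + 1e-9, cfg.grid_spacing_deg
    )
    xx, yy = np.meshgrid(coords, coords)
    keep = np.hypot(xx, yy) <= field_radius + 1e-9
    px, py = xx[keep], yy[keep]
    xs = np.repeat(px, len(cfg.sigma_levels))
    ys = np.repeat(py, len(cfg.sigma_levels))
    ss = np.tile(np.asarray(cfg.sigma_levels, dtype=float), len(px))
    order = np.lexsort((ss, np.round(np.hypot(xs, ys), 9)))
    return xs[order], ys[order], ss[order]


def _drives(
    seq: ApertureSequence,
    xs: np.ndarray,
    ys: np.ndarray,
    sigmas: np.ndarray,
    chunk: int = 1024,
) -> np.ndarray:
    """Neural drive matrix (n_frames, n_candidates) before the HRF."""
    gx, gy = seq.cell_coordinates()
    flat = seq.flat
    out = np.empty((seq.n_frames, len(xs)))
    for lo in range(0, len(xs), chunk):
        hi = min(lo + chunk, len(xs))
        g = np.exp(
            -(
                (gx[:, None] - xs[None, lo:hi]) ** 2
                + (gy[:, None] - ys[None, lo:hi]) ** 2
            )
            / (2.0 * sigmas[None, lo:hi] ** 2)
        )
        out[:, lo:hi] = flat @ g
    return out


def _convolve(drives: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    full = signal.fftconvolve(drives, kernel[:, None], axes=0)
    return full[: drives.shape[0]]


def _demean(a: np.ndarray):
    mean = a.mean(axis=0)
    centered = a - mean
    norm = np.sqrt(np.sum(centered**2, axis=0))
    return centered, norm, mean


def _score_all(preds: np.ndarray, yc: np.ndarray, ynorm: np.ndarray):
    """Correlation of every candidate with every voxel.

    Returns (r, pc, pnorm, pmean): r has shape (n_cand, n_vox); a
    negative r means the candidate would need a negative amplitude.
    """
    pc, pnorm, pmean = _demean(preds)
    denom = np.outer(pnorm, ynorm)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc.T @ yc) / denom
    r[~np.isfinite(r)] = 0.0
    return r, pc, pnorm, pmean


def _score_paired(
    preds: np.ndarray, yc: np.ndarray, ynorm: np.ndarray, vox_idx: np.ndarray
):
    """Correlation of candidate j with its own voxel vox_idx[j]."""
    pc, pnorm, pmean = _demean(preds)
    num = np.sum(pc * yc[:, vox_idx], axis=0)
    denom = pnorm * ynorm[vox_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    r[~np.isfinite(r)] = 0.0
    return r, pnorm, pmean


class _CoarseEngine:
    """Precomputed coarse-grid drives for one aperture sequence.

    Building the drive matrix is the expensive part of the coarse search
    and depends only on the sequence and the candidate grid, so it is
    shared across runs, HRF updates and (for the nonlinear variant)
    exponent levels.
    """

    def __init__(self, seq: ApertureSequence, cfg: FitConfig):
        self.seq = seq
        self.cfg = cfg
        radius = seq.config.field_radius_deg
        self.xs, self.ys, self.sigmas = _candidate_grid(cfg, radius)
        self.base_drives = _drives(seq, self.xs, self.ys, self.sigmas)
        if cfg.variant is ModelVariant.NONLINEAR:
            self.exponents = tuple(sorted(cfg.exponent_levels))
        else:
            self.exponents = (1.0,)

    def best_fit(self, Y: np.ndarray, h: HRFParams):
        """Best coarse candidate per voxel (positive-amplitude only).

        Y is (n_voxels, n_frames).  Returns a dict of per-voxel arrays:
        x, y, sigma, exponent, ve, beta, baseline.
        """
        kernel = two_gamma_hrf(h, self.seq.config.tr_s)
        yc, ynorm, ymean = _demean(Y.T)
        n_vox = Y.shape[0]
        best = {
            "x": np.zeros(n_vox),
            "y": np.zeros(n_vox),
            "sigma": np.full(n_vox, self.sigmas[0]),
            "exponent": np.ones(n_vox),
            "ve": np.zeros(n_vox),
            "beta": np.zeros(n_vox),
            "baseline": ymean.copy(),
        }
        best["x"][:] = self.xs[0]
        best["y"][:] = self.ys[0]
        best_score = np.full(n_vox, -np.inf)
        for expo in self.exponents:
            drives = (
                self.base_drives
                if expo == 1.0
                else np.power(self.base_drives, expo)
            )
            preds = _convolve(drives, kernel)
            r, pc, pnorm, pmean = _score_all(preds, yc, ynorm)
            score = np.square(np.clip(r, 0.0, None))
            idx = np.argmax(score, axis=0)  # first max -> smallest ecc/sigma
            sc = score[idx, np.arange(n_vox)]
            improve = sc > best_score + 1e-15
            if improve.any():
                ii = idx[improve]
                vv = np.flatnonzero(improve)
                rr = r[ii, vv]
                with np.errstate(invalid="ignore", divide="ignore"):
                    beta = rr * ynorm[vv] / pnorm[ii]
                beta[~np.isfinite(beta)] = 0.0
                best["x"][vv] = self.xs[ii]
                best["y"][vv] = self.ys[ii]
                best["sigma"][vv] = self.sigmas[ii]
                best["exponent"][vv] = expo
                best["ve"][vv] = sc[vv]
                best["beta"][vv] = np.clip(beta, 0.0, None)
                best["baseline"][vv] = ymean[vv] - beta * pmean[ii]
                best_score[vv] = sc[vv]
        # voxels with zero total variance have undefined ve
        best["ve"][ynorm <= 1e-12] = np.nan
        return best


def _refine_batch(
    Y: np.ndarray,
    start: dict,
    seq: ApertureSequence,
    cfg: FitConfig,
    h: HRFParams,
    which: np.ndarray | None = None,
):
    """Vectorized bounded pattern search around the coarse solutions.

    Proposals per iteration and voxel: x ± step, y ± step, sigma ×/÷
    factor (and exponent ×/÷ factor for the nonlinear variant).  A
    voxel's step halves whenever none of its proposals improves the
    variance explained; the voxel retires once the position step drops
    below ``refine_tolerance_deg``.  The result can never be worse than
    the starting point.
    """
    kernel = two_gamma_hrf(h, seq.config.tr_s)
    yc, ynorm, _ = _demean(Y.T)
    n_vox = Y.shape[0]

    x = start["x"].copy()
    y = start["y"].copy()
    sg = start["sigma"].copy()
    ex = start["exponent"].copy()
    ve = np.where(np.isnan(start["ve"]), 0.0, start["ve"]).copy()

    nonlinear = cfg.variant is ModelVariant.NONLINEAR
    step = np.full(n_vox, cfg.refine_initial_step_deg)
    sig_fac = np.full(n_vox, 2.0**0.5)
    active = np.ones(n_vox, dtype=bool)
    if which is not None:
        active &= which
    pb = cfg.position_bound_deg
    slo, shi = cfg.sigma_bounds
    elo, ehi = cfg.exponent_bounds

    for _ in range(cfg.refine_max_iter):
        av = np.flatnonzero(active)
        if av.size == 0:
            break
        n_prop = 8 if nonlinear else 6
        cx = np.repeat(x[av], n_prop)
        cy = np.repeat(y[av], n_prop)
        cs = np.repeat(sg[av], n_prop)
        ce = np.repeat(ex[av], n_prop)
        st = step[av]
        fc = sig_fac[av]
        cx[0::n_prop] += st
        cx[1::n_prop] -= st
        cy[2::n_prop] += st
        cy[3::n_prop] -= st
        cs[4::n_prop] *= fc
        cs[5::n_prop] /= fc
        if nonlinear:
            ce[6::n_prop] *= fc
            ce[7::n_prop] /= fc
        np.clip(cx, -pb, pb, out=cx)
        np.clip(cy, -pb, pb, out=cy)
        np.clip(cs, slo, shi, out=cs)
        np.clip(ce, elo, ehi, out=ce)

        drives = _drives(seq, cx, cy, cs)
        if nonlinear:
            drives = np.power(drives, ce[None, :])
        preds = _convolve(drives, kernel)
        vox_idx = np.repeat(av, n_prop)
        r, _, _ = _score_paired(preds, yc, ynorm, vox_idx)
        score = np.square(np.clip(r, 0.0, None)).reshape(av.size, n_prop)
        best_j = np.argmax(score, axis=1)
        best_sc = score[np.arange(av.size), best_j]
        improved = best_sc > ve[av] + 1e-12
        if improved.any():
            rows = av[improved]
            cols = best_j[improved]
            flatpos = (np.flatnonzero(improved)) * n_prop + cols
            x[rows] = cx[flatpos]
            y[rows] = cy[flatpos]
            sg[rows] = cs[flatpos]
            ex[rows] = ce[flatpos]
            ve[rows] = best_sc[improved]
        stuck = av[~improved]
        step[stuck] *= 0.5
        sig_fac[stuck] = np.sqrt(sig_fac[stuck])
        done = step < cfg.refine_tolerance_deg
        active &= ~done

    out = {
        "x": x,
        "y": y,
        "sigma": sg,
        "exponent": ex,
        "ve": np.where(np.isnan(start["ve"]), np.nan, ve),
    }
    return out


def _finalize(
    Y: np.ndarray,
    params: dict,
    seq: ApertureSequence,
    cfg: FitConfig,
    h: HRFParams,
):
    """Final amplitude/baseline/variance-explained pass (stage 5)."""
    kernel = two_gamma_hrf(h, seq.config.tr_s)
    drives = _drives(seq, params["x"], params["y"], params["sigma"])
    if cfg.variant is ModelVariant.NONLINEAR:
        drives = np.power(drives, params["exponent"][None, :])
    preds = _convolve(drives, kernel)
    yc, ynorm, ymean = _demean(Y.T)
    vox_idx = np.arange(Y.shape[0])
    r, pnorm, pmean = _score_paired(preds, yc, ynorm, vox_idx)
    r = np.clip(r, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = r * ynorm / pnorm
    beta[~np.isfinite(beta)] = 0.0
    ve = np.square(r)
    ve[ynorm <= 1e-12] = np.nan
    out = dict(params)
    out["beta"] = beta
    out["baseline"] = ymean - beta * pmean
    out["ve"] = ve
    return out


# ---------------------------------------------------------------------------
# public single-voxel operations


def _params_from_best(best: dict, i: int) -> PRFParams:
    return PRFParams(
        x=float(best["x"][i]),
        y=float(best["y"][i]),
        sigma=float(best["sigma"][i]),
        exponent=float(best["exponent"][i]),
        beta=float(best.get("beta", np.ones(i + 1))[i]),
        baseline=float(best.get("baseline", np.zeros(i + 1))[i]),
    )


def coarse_fit(
    ts: np.ndarray,
    seq: ApertureSequence,
    cfg: FitConfig = FitConfig(),
    h: HRFParams = CANONICAL_HRF,
) -> tuple[PRFParams, float]:
    """Exhaustive coarse-grid fit of a single voxel time course.

    Ties in variance explained resolve to the smallest eccentricity,
    then the smallest sigma.  The sequence must be a full-field one.
    """
    Y = np.asarray(ts, dtype=float)[None, :]
    engine = _CoarseEngine(seq, cfg)
    best = engine.best_fit(Y, h)
    return _params_from_best(best, 0), float(best["ve"][0])


def refine_fit(
    start: PRFParams,
    ts: np.ndarray,
    seq: ApertureSequence,
    cfg: FitConfig = FitConfig(),
    h: HRFParams = CANONICAL_HRF,
) -> tuple[PRFParams, float]:
    """Local derivative-free refinement from a coarse starting point."""
    Y = np.asarray(ts, dtype=float)[None, :]
    start_dict = {
        "x": np.array([start.x]),
        "y": np.array([start.y]),
        "sigma": np.array([start.sigma]),
        "exponent": np.array([start.exponent]),
        "ve": np.array([np.nan]),
    }
    # evaluate the true starting score first so refinement cannot regress
    fin0 = _finalize(Y, start_dict, seq, cfg, h)
    start_dict["ve"] = fin0["ve"]
    refined = _refine_batch(Y, start_dict, seq, cfg, h)
    fin = _finalize(Y, refined, seq, cfg, h)
    return _params_from_best(fin, 0), float(fin["ve"][0])


def fit_run_hrf(
    best: dict,
    Y: np.ndarray,
    seq: ApertureSequence,
    cfg: FitConfig = FitConfig(),
) -> HRFParams:
    """Fit the run's shared two-gamma HRF peak parameters.

    Optimizes peak delay and peak dispersion (undershoot fixed) over the
    top-variance-explained gated voxels with their current pRF
    parameters.  Falls back to the canonical HRF when fewer than
    ``hrf_min_gated`` voxels pass the gate, or for the canonical-HRF
    variant.
    """
    if cfg.variant is ModelVariant.GAUSSIAN_CANONICAL_HRF:
        return CANONICAL_HRF
    ve = np.where(np.isnan(best["ve"]), -np.inf, best["ve"])
    gated = np.flatnonzero(ve > cfg.ve_threshold)
    if gated.size < cfg.hrf_min_gated:
        logger.warning(
            "HRF fit skipped: only %d voxels above the gate (need %d); "
            "using the canonical HRF",
            gated.size,
            cfg.hrf_min_gated,
        )
        return CANONICAL_HRF
    top = gated[np.argsort(ve[gated])[::-1][: cfg.hrf_n_voxels]]
    drives = _drives(seq, best["x"][top], best["y"][top], best["sigma"][top])
    if cfg.variant is ModelVariant.NONLINEAR:
        drives = np.power(drives, best["exponent"][None, top])
    yc, ynorm, _ = _demean(Y[top].T)
    vox_idx = np.arange(top.size)
    tr = seq.config.tr_s
    dlo, dhi = cfg.hrf_delay_bounds
    plo, phi = cfg.hrf_dispersion_bounds

    def objective(theta: np.ndarray) -> float:
        delay = float(np.clip(theta[0], dlo, dhi))
        disp = float(np.clip(theta[1], plo, phi))
        kernel = two_gamma_hrf(CANONICAL_HRF.with_peak(delay, disp), tr)
        preds = _convolve(drives, kernel)
        r, _, _ = _score_paired(preds, yc, ynorm, vox_idx)
        return -float(np.mean(np.square(np.clip(r, 0.0, None))))

    res = optimize.minimize(
        objective,
        x0=np.array([CANONICAL_HRF.peak_delay_s, CANONICAL_HRF.peak_dispersion_s]),
        method="Nelder-Mead",
        options={"xatol": 0.01, "fatol": 1e-7, "maxiter": 200},
    )
    delay = float(np.clip(res.x[0], dlo, dhi))
    disp = float(np.clip(res.x[1], plo, phi))
    return CANONICAL_HRF.with_peak(delay, disp)


def fit_run(
    Y: np.ndarray,
    seq: ApertureSequence,
    cfg: FitConfig = FitConfig(),
    voxel_ids: np.ndarray | None = None,
    engine: "_CoarseEngine | None" = None,
) -> pd.DataFrame:
    """Fit every voxel of one run; returns a pRF result table.

    ``Y`` is (n_voxels, n_frames); ``seq`` must be the full-field
    aperture sequence (scotoma-naive fitting).  Voxels whose coarse
    variance explained falls below ``refine_min_ve`` skip the local
    refinement stage: a voxel that far under the inclusion gate cannot
    be lifted across it by a local polish, and the gate later discards
    it either way.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != seq.n_frames:
        raise ValueError("Y must be (n_voxels, n_frames) matching seq")
    if voxel_ids is None:
        voxel_ids = np.arange(Y.shape[0])
    if Y.shape[0] == 0:
        return pd.DataFrame(columns=list(RESULT_COLUMNS))
    if engine is None:
        engine = _CoarseEngine(seq, cfg)

    # stage 1: coarse grid under the canonical HRF
    best = engine.best_fit(Y, CANONICAL_HRF)
    # stage 2: run-specific HRF
    hrf = fit_run_hrf(best, Y, seq, cfg)
    # stage 3: coarse re-fit under the fitted HRF
    if hrf is not CANONICAL_HRF:
        best = engine.best_fit(Y, hrf)
    # stage 4: local refinement of the well-explained voxels
    ve0 = np.where(np.isnan(best["ve"]), -np.inf, best["ve"])
    refined = _refine_batch(
        Y, best, seq, cfg, hrf, which=ve0 >= cfg.refine_min_ve
    )
    # stage 5: final amplitude, baseline and variance explained
    fin = _finalize(Y, refined, seq, cfg, hrf)

    ecc = np.hypot(fin["x"], fin["y"])
    table = pd.DataFrame(
        {
            "voxel_id": voxel_ids,
            "x": fin["x"],
            "y": fin["y"],
            "sigma": fin["sigma"],
            "exponent": fin["exponent"],
            "beta": fin["beta"],
            "baseline": fin["baseline"],
            "variance_explained": fin["ve"],
            "eccentricity": ecc,
            "polar_angle_deg": polar_angle_deg(fin["x"], fin["y"]),
            "hrf_peak_delay_s": hrf.peak_delay_s,
            "hrf_peak_dispersion_s": hrf.peak_dispersion_s,
        }
    )
    return table


def fit_population(
    dataset,
    cfg: FitConfig = FitConfig(),
    fit_seq: ApertureSequence | None = None,
    include_averages: bool = True,
) -> dict[str, pd.DataFrame]:
    """Run the six per-subject analyses of a simulated study.

    Fits each of the four single runs plus the two per-session averaged
    runs (labels ``s{i}r{j}`` and ``s{i}avg``).  ``fit_seq`` is the
    full-field sequence used for prediction; when omitted it is derived
    from the dataset's stimulus configuration with the scotoma removed.
    """
    from .stimulus import build_sequence

    first = next(iter(dataset.runs.values()))
    if fit_seq is None:
        fit_seq = build_sequence(
            replace(first.seq.config, scotoma_radius_deg=0.0)
        )
    engine = _CoarseEngine(fit_seq, cfg)
    voxel_ids = dataset.voxel_ids()
    tables: dict[str, pd.DataFrame] = {}
    for (s, r), run in sorted(dataset.runs.items()):
        tables[f"s{s}r{r}"] = fit_run(
            run.timeseries, fit_seq, cfg, voxel_ids, engine=engine
        )
    if include_averages:
        for s, run in sorted(dataset.averages.items()):
            tables[f"s{s}avg"] = fit_run(
                run.timeseries, fit_seq, cfg, voxel_ids, engine=engine
            )
    return tables
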