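"""Test-retest reliability statistics for pRF result tables.

Voxels are matched one-to-one across two analyses (runs or sessions)
and kept only when the model explains more than a variance-explained
threshold in *both*; Spearman rank correlations are computed per pRF
parameter, averaged across subjects through the Fisher z transform, and
complemented by mean absolute within-voxel parameter differences.  A
separate grid simulation quantifies how transforming Cartesian pRF
positions to polar coordinates systematically deflates the radius
correlation relative to the polar-angle correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PARAM_COLUMNS",
    "CorrelationReport",
    "BiasSimResult",
    "match_voxels",
    "spearman_rho",
    "fisher_average",
    "mean_differences",
    "group_mean_differences",
    "correlation_report",
    "threshold_sweep",
    "coordinate_bias_simulation",
    "wrap_angle_difference_deg",
]

#: pRF parameters entering the reliability battery
PARAM_COLUMNS = ("eccentricity", "polar_angle_deg", "sigma", "x", "y")


def match_voxels(
    a: pd.DataFrame, b: pd.DataFrame, ve_threshold: float = 0.10
) -> pd.DataFrame:
    """Pair voxels present in both tables and gated in both.

    Inner join on ``voxel_id``; a pair survives only if variance
    explained exceeds the threshold in both analyses.  Columns come
    back suffixed ``_a`` and ``_b``.
    """
    merged = a.merge(b, on="voxel_id", suffixes=("_a", "_b"))
    ve_a = merged["variance_explained_a"]
    ve_b = merged["variance_explained_b"]
    keep = (ve_a > ve_threshold) & (ve_b > ve_threshold)
    return merged.loc[keep.fillna(False)].reset_index(drop=True)


def spearman_rho(u: np.ndarray, v: np.ndarray) -> float:
    """Spearman rank correlation (mid-ranks for ties).

    Returns NaN for constant input, where ranks carry no information.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 3:
        raise ValueError("u and v must be equal-length 1D with n >= 3")
    if np.all(u == u[0]) or np.all(v == v[0]):
        return float("nan")
    return float(stats.spearmanr(u, v).statistic)


def fisher_average(rhos) -> float:
    """Group-average correlation via the Fisher z transform.

    tanh(mean(atanh(ρ_i))); coefficients at ±1 are clipped just inside
    the open interval before the transform.
    """
    r = np.asarray(list(rhos), dtype=float)
    if r.size == 0:
        raise ValueError("need at least one coefficient")
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    return float(np.tanh(np.mean(np.arctanh(r))))


def wrap_angle_difference_deg(a, b) -> np.ndarray:
    """Absolute polar-angle difference wrapped to [0°, 180°]."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % 360.0
    return np.minimum(d, 360.0 - d)


def mean_differences(
    pairs: pd.DataFrame,
    params=PARAM_COLUMNS,
    ecc_limit: float | None = None,
) -> pd.Series:
    """Mean absolute within-voxel parameter difference.

    ``ecc_limit`` restricts to voxel pairs whose eccentricity is below
    the limit in both analyses (e.g. within the stimulated field of
    view).  Polar-angle differences are wrapped to [0°, 180°].
    """
    if len(pairs) == 0:
        raise ValueError("pairs must be non-empty")
    sel = pairs
    if ecc_limit is not None:
        keep = (sel["eccentricity_a"] < ecc_limit) & (
            sel["eccentricity_b"] < ecc_limit
        )
        sel = sel.loc[keep]
    out = {}
    for p in params:
        a = sel[f"{p}_a"].to_numpy(dtype=float)
        b = sel[f"{p}_b"].to_numpy(dtype=float)
        if p == "polar_angle_deg":
            d = wrap_angle_difference_deg(a, b)
        else:
            d = np.abs(a - b)
        out[p] = float(np.mean(d)) if d.size else float("nan")
    return pd.Series(out)


def group_mean_differences(
    pairs_by_subject: list[pd.DataFrame],
    params=PARAM_COLUMNS,
    ecc_limit: float | None = None,
) -> pd.DataFrame:
    """Across-subject mean and SEM of the per-subject mean differences."""
    rows = [
        mean_differences(p, params, ecc_limit) for p in pairs_by_subject
    ]
    per_subject = pd.DataFrame(rows)
    n = len(per_subject)
    return pd.DataFrame(
        {
            "mean": per_subject.mean(),
            "sem": per_subject.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
        }
    )


@dataclass
class CorrelationReport:
    """Group reliability summary for one run comparison."""

    label: str
    rho: dict[str, float]  # Fisher-z group means per parameter
    per_subject_rho: pd.DataFrame  # rows = subjects, columns = parameters
    n_voxels: list[int] = field(default_factory=list)


def correlation_report(
    pairs_by_subject: list[pd.DataFrame],
    label: str = "",
    params=PARAM_COLUMNS,
) -> CorrelationReport:
    """Per-subject Spearman correlations and their Fisher-z group mean."""
    rows = []
    counts = []
    for pairs in pairs_by_subject:
        row = {}
        for p in params:
            u = pairs[f"{p}_a"].to_numpy(dtype=float)
            v = pairs[f"{p}_b"].to_numpy(dtype=float)
            row[p] = spearman_rho(u, v) if len(pairs) >= 3 else float("nan")
        rows.append(row)
        counts.append(len(pairs))
    per_subject = pd.DataFrame(rows)
    group = {
        p: fisher_average(per_subject[p].dropna())
        if per_subject[p].notna().any()
        else float("nan")
        for p in params
    }
    return CorrelationReport(
        label=label, rho=group, per_subject_rho=per_subject, n_voxels=counts
    )


def threshold_sweep(
    a: pd.DataFrame,
    b: pd.DataFrame,
    thresholds,
    params=PARAM_COLUMNS,
) -> pd.DataFrame:
    """Reliability of one table pair across inclusion thresholds.

    One row per threshold with the surviving pair count and the
    Spearman correlation per parameter; correlations are NaN when fewer
    than three pairs survive.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in thresholds:
        pairs = match_voxels(a, b, t)
        row = {"threshold": t, "n_pairs": len(pairs)}
        for p in params:
            if len(pairs) >= 3:
                row[p] = spearman_rho(
                    pairs[f"{p}_a"].to_numpy(float),
                    pairs[f"{p}_b"].to_numpy(float),
                )
            else:
                row[p] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BiasSimResult:
    """Coordinate-system bias of Spearman reliability on a noisy grid."""

    rho: dict[str, float]  # keys: x, y, radius, angle
    n_reps: int
    noise_sd: float
    exclusion_radius: float


def _colwise_spearman(truth: np.ndarray, noisy: np.ndarray) -> np.ndarray:
    """Spearman rho between a fixed truth vector and each row of noisy."""
    rt = stats.rankdata(truth)
    rn = stats.rankdata(noisy, axis=1)
    rt_c = rt - rt.mean()
    rn_c = rn - rn.mean(axis=1, keepdims=True)
    num = rn_c @ rt_c
    denom = np.sqrt((rn_c**2).sum(axis=1) * (rt_c**2).sum())
    return num / denom


def coordinate_bias_simulation(
    grid_extent: float = 7.0,
    grid_spacing: float = 1.0,
    noise_sd: float = 0.5,
    n_reps: int = 1000,
    exclusion_radius: float = 0.0,
    seed: int | None = None,
) -> BiasSimResult:
    """Cartesian-vs-polar reliability bias on a jittered position grid.

    A square grid of pRF positions is perturbed with isotropic Gaussian
    noise; Spearman correlations between true and perturbed values are
    computed in Cartesian (x, y) and polar (radius, angle) coordinates
    for every repetition and Fisher-averaged.  ``exclusion_radius``
    removes grid points within a central disc before jittering,
    mimicking a foveal scotoma.

    Polar angle is a circular variable: each perturbed angle is
    unwrapped to the 360°-branch nearest its true value before
    ranking, so the comparison isolates the geometry of the
    coordinate transform rather than the arbitrary position of the
    ±180° branch cut.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    coords = np.arange(-grid_extent, grid_extent + 1e-9, grid_spacing)
    xx, yy = np.meshgrid(coords, coords)
    x = xx.ravel()
    y = yy.ravel()
    if exclusion_radius > 0:
        keep = np.hypot(x, y) >= exclusion_radius
        x, y = x[keep], y[keep]
    rng = np.random.default_rng(seed)
    nx = x[None, :] + rng.normal(0.0, noise_sd, (n_reps, x.size))
    ny = y[None, :] + rng.normal(0.0, noise_sd, (n_reps, y.size))
    true_r = np.hypot(x, y)
    true_a = np.degrees(np.arctan2(y, x))
    noisy_r = np.hypot(nx, ny)
    noisy_a = np.degrees(np.arctan2(ny, nx))
    # unwrap to the branch nearest the true angle (circular variable)
    noisy_a = true_a + ((noisy_a - true_a + 180.0) % 360.0 - 180.0)
    rho = {
        "x": fisher_average(_colwise_spearman(x, nx)),
        "y": fisher_average(_colwise_spearman(y, ny)),
        "radius": fisher_average(_colwise_spearman(true_r, noisy_r)),
        "angle": fisher_average(_colwise_spearman(true_a, noisy_a)),
    }
    return BiasSimResult(
        rho=rho,
        n_reps=n_reps,
        noise_sd=noise_sd,
        exclusion_radius=exclusion_radius,
    )
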