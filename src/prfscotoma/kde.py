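"""Scotoma border estimation from pRF-center density curves.

The pRF centers of one analysis are reduced to their eccentricities
(polar angle and size are discarded) and smoothed into a density curve
with a Gaussian kernel whose bandwidth follows Scott's rule,
w = 3.5 σ_r n^(−1/3).  A scotoma dataset's curve is compared with the
averaged curve of a full-field reference cohort through the normalized
difference

    comp(x) = (ref(x) − scot(x)) / (ref(x) + scot(x)) ∈ [−1, 1],

which is near +1 inside a central scotoma (reference density present,
scotoma density absent) and dips below zero just outside it, where
scotoma-naive fitting piles displaced centers.  The scotoma border is
read off at the first outward crossing of the 0.1 level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KDECurve",
    "ComparisonCurve",
    "BORDER_THRESHOLD",
    "DEFAULT_EVAL_GRID",
    "scotts_bandwidth",
    "kde_curve",
    "comparison_curve",
    "estimate_border",
    "classify_border",
    "group_average",
    "gated_eccentricities",
    "scotoma_border_analysis",
]

#: classification level of the normalized comparison curve
BORDER_THRESHOLD = 0.1

#: default eccentricity evaluation grid: 0° to 8° in 0.01° steps (one
#: degree beyond the stimulated radius, to capture edge kernels)
DEFAULT_EVAL_GRID = np.arange(0.0, 8.0 + 1e-9, 0.01)


def scotts_bandwidth(sigma_r: float, n: int) -> float:
    """Scott's-rule kernel bandwidth w = 3.5 · σ_r · n^(−1/3).

    ``sigma_r`` is the standard deviation of the eccentricity sample and
    ``n`` its size.
    """
    if sigma_r <= 0:
        raise ValueError("sigma_r must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 3.5 * sigma_r * n ** (-1.0 / 3.0)


@dataclass
class KDECurve:
    """pRF-center density over eccentricity for one analysis."""

    eval_ecc: np.ndarray
    density: np.ndarray
    bandwidth_w: float
    n_centers: int
    source_ecc: np.ndarray
    sigma_r: float

    def integral(self) -> float:
        """Trapezoidal integral of the density over the stored grid."""
        return float(np.trapezoid(self.density, self.eval_ecc))


@dataclass
class ComparisonCurve:
    """Normalized reference-vs-scotoma density difference."""

    eval_ecc: np.ndarray
    value: np.ndarray  # NaN where both densities are negligible
    threshold: float = BORDER_THRESHOLD
    ref_curve: KDECurve | None = field(default=None, repr=False)
    scotoma_curve: KDECurve | None = field(default=None, repr=False)


def kde_curve(
    source_ecc: np.ndarray,
    eval_grid: np.ndarray | None = None,
    w_override: float | None = None,
) -> KDECurve:
    """Gaussian-kernel density of pRF-center eccentricities.

    density(x) = (1 / (n √(2π w²))) Σ_vox exp(−(x − r_vox)² / (2w²)),
    with w from Scott's rule on the sample itself unless overridden.
    The curve integrates to 1 over the real line; over a finite grid a
    small amount of mass can sit outside (kernels near the grid edges).
    """
    ecc = np.asarray(source_ecc, dtype=float).ravel()
    if ecc.size == 0:
        raise ValueError("source_ecc must be non-empty")
    grid = DEFAULT_EVAL_GRID if eval_grid is None else np.asarray(eval_grid, float)
    n = ecc.size
    sigma_r = float(np.std(ecc, ddof=1)) if n > 1 else 0.0
    if w_override is not None:
        w = float(w_override)
        if w <= 0:
            raise ValueError("bandwidth override must be positive")
    else:
        w = scotts_bandwidth(sigma_r, n)
    z = (grid[:, None] - ecc[None, :]) / w
    density = np.exp(-0.5 * z**2).sum(axis=1) / (n * np.sqrt(2 * np.pi) * w)
    return KDECurve(
        eval_ecc=grid,
        density=density,
        bandwidth_w=w,
        n_centers=n,
        source_ecc=ecc,
        sigma_r=sigma_r,
    )


def comparison_curve(
    ref: KDECurve, scot: KDECurve, eps: float = 1e-12
) -> ComparisonCurve:
    """Pointwise (ref − scot)/(ref + scot); NaN where both are < eps."""
    if ref.eval_ecc.shape != scot.eval_ecc.shape or not np.allclose(
        ref.eval_ecc, scot.eval_ecc
    ):
        raise ValueError("curves must share the evaluation grid")
    r, s = ref.density, scot.density
    undefined = (r < eps) & (s < eps)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = (r - s) / (r + s)
    value[undefined] = np.nan
    return ComparisonCurve(
        eval_ecc=ref.eval_ecc.copy(),
        value=value,
        ref_curve=ref,
        scotoma_curve=scot,
    )


def classify_border(
    comp: ComparisonCurve, threshold: float | None = None
) -> tuple[float | None, str]:
    """Border radius and classification status for one comparison curve.

    Scanning outward from x = 0, the border is the eccentricity of the
    first downward crossing of the threshold after a region at or above
    it, linearly interpolated between grid points.  Status is one of
    ``"border"``, ``"no_scotoma"`` (the curve never reaches the
    threshold) or ``"non_central"`` (the curve starts below the
    threshold but exceeds it further out — not a central scotoma
    pattern).
    """
    t = comp.threshold if threshold is None else threshold
    x = np.asarray(comp.eval_ecc, float)
    v = np.asarray(comp.value, float)
    defined = np.isfinite(v)
    if not defined.any():
        raise ValueError("comparison curve is entirely undefined")
    x = x[defined]
    v = v[defined]
    if v[0] < t:
        if np.any(v >= t):
            return None, "non_central"
        return None, "no_scotoma"
    below = np.flatnonzero(v < t)
    if below.size == 0:
        return None, "no_scotoma"  # never drops below: no readable border
    i = below[0]
    x0, x1 = x[i - 1], x[i]
    v0, v1 = v[i - 1], v[i]
    border = x0 + (v0 - t) / (v0 - v1) * (x1 - x0)
    return float(border), "border"


def estimate_border(
    comp: ComparisonCurve, threshold: float | None = None
) -> float | None:
    """Scotoma border radius in degrees, or None when no central
    scotoma pattern is present."""
    border, _ = classify_border(comp, threshold)
    return border


def group_average(curves: list):
    """Pointwise mean of KDE or comparison curves on a shared grid.

    For comparison curves the mean ignores NaNs pointwise (a point is
    NaN only where every subject is undefined).
    """
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    grid = curves[0].eval_ecc
    for c in curves[1:]:
        if c.eval_ecc.shape != grid.shape or not np.allclose(c.eval_ecc, grid):
            raise ValueError("curves must share the evaluation grid")
    if isinstance(curves[0], KDECurve):
        density = np.mean([c.density for c in curves], axis=0)
        return KDECurve(
            eval_ecc=grid.copy(),
            density=density,
            bandwidth_w=float(np.mean([c.bandwidth_w for c in curves])),
            n_centers=int(sum(c.n_centers for c in curves)),
            source_ecc=np.concatenate([c.source_ecc for c in curves]),
            sigma_r=float(np.mean([c.sigma_r for c in curves])),
        )
    stack = np.vstack([c.value for c in curves])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        value = np.nanmean(stack, axis=0)
    return ComparisonCurve(
        eval_ecc=grid.copy(),
        value=value,
        threshold=curves[0].threshold,
    )


def gated_eccentricities(table, ve_threshold: float = 0.10) -> np.ndarray:
    """Eccentricities of the voxels passing the variance-explained gate.

    Only gated pRF centers enter the density curves — the gate is what
    empties the curve inside a scotoma, because unstimulated voxels
    cannot be fitted.
    """
    ve = table["variance_explained"].to_numpy()
    keep = np.isfinite(ve) & (ve > ve_threshold)
    return table.loc[keep, "eccentricity"].to_numpy(dtype=float)


def scotoma_border_analysis(
    reference_tables: list,
    scotoma_tables: list,
    ve_threshold: float = 0.10,
    threshold: float = BORDER_THRESHOLD,
    eval_grid: np.ndarray | None = None,
):
    """Full border-estimation pipeline on fitted result tables.

    Builds one KDE curve per reference subject and averages them into
    the reference density; builds one curve and one comparison curve
    per scotoma subject; reads each subject's border and the border of
    the group-averaged comparison curve.  Returns a dict with the
    curves, per-subject borders/statuses and the group results.
    """
    grid = DEFAULT_EVAL_GRID if eval_grid is None else eval_grid
    ref_curves = [
        kde_curve(gated_eccentricities(t, ve_threshold), grid)
        for t in reference_tables
    ]
    ref_mean = group_average(ref_curves)
    comp_curves = []
    borders = []
    statuses = []
    for t in scotoma_tables:
        scot = kde_curve(gated_eccentricities(t, ve_threshold), grid)
        comp = comparison_curve(ref_mean, scot)
        comp.threshold = threshold
        b, status = classify_border(comp)
        comp_curves.append(comp)
        borders.append(b)
        statuses.append(status)
    group_comp = group_average(comp_curves)
    group_border, group_status = classify_border(group_comp)
    found = [b for b in borders if b is not None]
    return {
        "reference_curves": ref_curves,
        "reference_mean": ref_mean,
        "comparison_curves": comp_curves,
        "subject_borders": borders,
        "subject_statuses": statuses,
        "mean_subject_border": float(np.mean(found)) if found else None,
        "group_curve": group_comp,
        "group_border": group_border,
        "group_status": group_status,
    }
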