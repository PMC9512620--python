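"""Population receptive field forward model.

A voxel's pRF is a 2D isotropic Gaussian on the visual field with
center (x, y) and size sigma, all in degrees of visual angle.  The
neural drive at each acquisition frame is the overlap between the
stimulus aperture and the Gaussian; an optional compressive exponent is
applied to the drive before convolution with a two-gamma hemodynamic
response function (HRF).  Three model variants are supported: the
standard Gaussian with a per-run fitted HRF, the same Gaussian with a
fixed canonical HRF, and a compressive spatial-summation (nonlinear)
variant with a free exponent.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.stats import gamma as gamma_dist

from .stimulus import ApertureSequence

__all__ = [
    "PRFParams",
    "HRFParams",
    "ModelVariant",
    "CANONICAL_HRF",
    "gaussian_field",
    "two_gamma_hrf",
    "predict_timecourse",
    "polar_angle_deg",
]


def polar_angle_deg(x: float | np.ndarray, y: float | np.ndarray) -> float | np.ndarray:
    """Polar angle in degrees on (−180°, 180°]; 0° = right horizontal
    meridian, counter-clockwise positive."""
    return np.degrees(np.arctan2(y, x))


@dataclass(frozen=True)
class PRFParams:
    """One voxel's receptive-field model parameters (degrees)."""

    x: float
    y: float
    sigma: float
    exponent: float = 1.0
    beta: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")

    @property
    def eccentricity(self) -> float:
        return math.hypot(self.x, self.y)

    @property
    def polar_angle_deg(self) -> float:
        return float(polar_angle_deg(self.x, self.y))


class ModelVariant(str, enum.Enum):
    GAUSSIAN_FITTED_HRF = "gaussian_fitted_hrf"
    GAUSSIAN_CANONICAL_HRF = "gaussian_canonical_hrf"
    NONLINEAR = "nonlinear"


@dataclass(frozen=True)
class HRFParams:
    """Two-gamma HRF: a peak gamma minus a scaled undershoot gamma.

    Delays are peak times: each gamma density has shape
    ``delay/dispersion + 1`` and scale ``dispersion``, so its mode sits
    exactly at ``delay`` (the common peak-time parameterization of the
    gamma-variate response).  ``kind`` records whether the kernel is
    the fixed canonical one or was fitted to a run.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kind: str = "canonical"

    def __post_init__(self) -> None:
        for name in (
            "peak_delay_s",
            "undershoot_delay_s",
            "peak_dispersion_s",
            "undershoot_dispersion_s",
            "peak_undershoot_ratio",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_peak(self, peak_delay_s: float, peak_dispersion_s: float) -> "HRFParams":
        return replace(
            self,
            peak_delay_s=peak_delay_s,
            peak_dispersion_s=peak_dispersion_s,
            kind="fitted",
        )


CANONICAL_HRF = HRFParams()


def gaussian_field(
    params: PRFParams, grid_x: np.ndarray, grid_y: np.ndarray
) -> np.ndarray:
    """Evaluate the pRF Gaussian on a raster.

    ``grid_x``/``grid_y`` are the 1D cell-center coordinate vectors of an
    aperture raster; the result has shape ``(len(grid_y), len(grid_x))``
    with value exp(−((cx−x)² + (cy−y)²) / (2σ²)), i.e. 1 at the center.
    """
    gx = np.asarray(grid_x, dtype=float)
    gy = np.asarray(grid_y, dtype=float)
    dx2 = (gx[None, :] - params.x) ** 2
    dy2 = (gy[:, None] - params.y) ** 2
    return np.exp(-(dx2 + dy2) / (2.0 * params.sigma**2))


def two_gamma_hrf(
    h: HRFParams, tr_s: float, duration_s: float = 32.0
) -> np.ndarray:
    """Sample the two-gamma HRF kernel at the acquisition rate.

    Returns the difference of two gamma densities (peak minus
    undershoot divided by ``peak_undershoot_ratio``) evaluated at
    ``t = 0, tr, 2·tr, …`` up to ``duration_s``, normalized so the
    kernel's maximum is 1.
    """
    if duration_s < 24.0:
        raise ValueError("duration_s must cover the undershoot (>= 24 s)")
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    t = np.arange(0.0, duration_s + 1e-9, tr_s)
    kernel = _two_gamma_values(h, t)
    peak = kernel.max()
    if peak <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return kernel / peak


def _two_gamma_values(h: HRFParams, t: np.ndarray) -> np.ndarray:
    shape1 = h.peak_delay_s / h.peak_dispersion_s + 1.0
    shape2 = h.undershoot_delay_s / h.undershoot_dispersion_s + 1.0
    pos = gamma_dist.pdf(t, a=shape1, scale=h.peak_dispersion_s)
    neg = gamma_dist.pdf(t, a=shape2, scale=h.undershoot_dispersion_s)
    return pos - neg / h.peak_undershoot_ratio


def predict_timecourse(
    params: PRFParams,
    seq: ApertureSequence,
    h: HRFParams = CANONICAL_HRF,
    variant: ModelVariant = ModelVariant.GAUSSIAN_FITTED_HRF,
) -> np.ndarray:
    """Predicted BOLD time course of one voxel for one run.

    drive(t) = (Σ_cells aperture_t · gaussian)^exponent, convolved with
    the HRF kernel and truncated to the frame count, then scaled by
    ``beta`` and shifted by ``baseline``.  Gaussian variants force
    exponent = 1 regardless of ``params.exponent``.
    """
    g = gaussian_field(params, seq.grid_x, seq.grid_y)
    drive = seq.flat @ g.ravel()
    exponent = params.exponent if variant is ModelVariant.NONLINEAR else 1.0
    if exponent != 1.0:
        drive = np.power(drive, exponent)
    kernel = two_gamma_hrf(h, seq.config.tr_s)
    response = signal.convolve(drive, kernel)[: seq.n_frames]
    return params.baseline + params.beta * response
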