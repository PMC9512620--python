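"""Moving-bar retinotopy stimulus apertures.

The stimulus is a bar of fixed width sweeping across a circular visual
field, rotating clockwise by a fixed angle after every crossing, with
blank (mean-luminance) periods inserted after the diagonal crossings.
An optional central circular mask emulates an artificial scotoma: cells
inside the mask are never stimulated.  Apertures are binary masks on a
square raster of visual-field positions; the checkerboard carrier is not
modelled because the receptive-field analysis only uses the aperture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StimulusConfig",
    "ApertureSequence",
    "study_config",
    "reference_config",
    "positions_per_crossing",
    "build_sequence",
    "masked_fraction",
]


@dataclass(frozen=True)
class StimulusConfig:
    """Geometry and timing of one moving-bar run.

    Defaults describe the scotoma-study acquisition: a 14° field crossed
    in 0.8° steps at a 2 s repetition time.  ``blank_after_crossings``
    holds 1-based crossing indices after which a blank block is shown.
    """

    field_diameter_deg: float = 14.0
    bar_width_deg: float = 1.75
    step_deg: float = 0.8
    tr_s: float = 2.0
    n_crossings: int = 8
    rotation_step_deg: float = 45.0
    blank_duration_s: float = 12.0
    blank_after_crossings: tuple[int, ...] = (2, 4, 6, 8)
    scotoma_radius_deg: float = 0.0
    grid_resolution: int = 101

    def __post_init__(self) -> None:
        if self.field_diameter_deg <= 0:
            raise ValueError("field_diameter_deg must be positive")
        if not 0 < self.bar_width_deg < self.field_diameter_deg:
            raise ValueError("bar_width_deg must be in (0, field_diameter_deg)")
        if self.step_deg <= 0:
            raise ValueError("step_deg must be positive")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.scotoma_radius_deg < 0:
            raise ValueError("scotoma_radius_deg must be >= 0")
        if self.grid_resolution < 3:
            raise ValueError("grid_resolution must be >= 3")
        n_blank = self.blank_duration_s / self.tr_s
        if abs(n_blank - round(n_blank)) > 1e-9:
            raise ValueError(
                "blank_duration_s must be an integer multiple of tr_s"
            )

    @property
    def field_radius_deg(self) -> float:
        return self.field_diameter_deg / 2.0

    @property
    def frames_per_blank(self) -> int:
        return int(round(self.blank_duration_s / self.tr_s))


def study_config(scotoma_radius_deg: float = 2.0, **kwargs) -> StimulusConfig:
    """Study acquisition: 0.8° steps, TR 2 s, central mask by default."""
    return StimulusConfig(scotoma_radius_deg=scotoma_radius_deg, **kwargs)


def reference_config(**kwargs) -> StimulusConfig:
    """Full-field reference acquisition: 0.4° steps at TR 1 s."""
    kwargs.setdefault("step_deg", 0.4)
    kwargs.setdefault("tr_s", 1.0)
    kwargs.setdefault("scotoma_radius_deg", 0.0)
    return StimulusConfig(**kwargs)


def positions_per_crossing(field_diameter_deg: float, step_deg: float) -> int:
    """Number of bar positions needed to cross the field once.

    When the field width is an exact multiple of the step, the bar visits
    both edges (``width/step + 1`` positions); otherwise the count is the
    ceiling of the ratio.  A 14° field gives 18 positions at 0.8° steps
    and 36 at 0.4° steps.
    """
    if field_diameter_deg <= 0 or step_deg <= 0:
        raise ValueError("field_diameter_deg and step_deg must be positive")
    ratio = field_diameter_deg / step_deg
    if abs(ratio - round(ratio)) < 1e-9:
        return int(round(ratio)) + 1
    return int(math.ceil(ratio))


@dataclass
class ApertureSequence:
    """Binary aperture frames plus the raster and timing they live on.

    ``frames`` has shape ``(n_frames, n, n)`` with 1 = stimulated.
    ``grid_x``/``grid_y`` give the cell-center coordinates in degrees of
    visual angle (x positive rightward, y positive upward, fixation at
    the origin).
    """

    frames: np.ndarray
    frame_times_s: np.ndarray
    grid_x: np.ndarray
    grid_y: np.ndarray
    config: StimulusConfig
    is_blank: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.frame_times_s):
            raise ValueError("frames and frame_times_s lengths differ")
        if self.is_blank is None:
            self.is_blank = ~self.frames.any(axis=(1, 2))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def flat(self) -> np.ndarray:
        """Frames flattened to (n_frames, n_cells), float64 (cached)."""
        cached = getattr(self, "_flat", None)
        if cached is None:
            cached = self.frames.reshape(self.n_frames, -1).astype(np.float64)
            self._flat = cached
        return cached

    def cell_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened x/y coordinate per raster cell."""
        xx, yy = np.meshgrid(self.grid_x, self.grid_y)
        return xx.ravel(), yy.ravel()


def _crossing_frames(
    cfg: StimulusConfig,
    crossing: int,
    xx: np.ndarray,
    yy: np.ndarray,
    in_field: np.ndarray,
) -> np.ndarray:
    """Binary frames for one crossing (0-based index)."""
    n_pos = positions_per_crossing(cfg.field_diameter_deg, cfg.step_deg)
    # Clockwise rotation: crossing k moves along direction rotated by
    # -k * rotation_step from the initial left-to-right sweep.
    theta = -math.radians(crossing * cfg.rotation_step_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    proj = xx * ux + yy * uy
    radius = cfg.field_radius_deg
    offsets = -radius + cfg.step_deg * np.arange(n_pos)
    half_w = cfg.bar_width_deg / 2.0
    frames = (
        np.abs(proj[None, :, :] - offsets[:, None, None]) <= half_w + 1e-12
    )
    frames &= in_field[None, :, :]
    return frames


def build_sequence(config: StimulusConfig) -> ApertureSequence:
    """Construct the full aperture sequence for one run.

    The bar center starts at the field edge (−radius along the motion
    direction) and advances one step per acquisition frame; after each
    crossing the motion direction rotates clockwise.  Blank blocks of
    all-zero frames follow the crossings listed in
    ``blank_after_crossings``.  With the study settings this yields
    8 × 18 + 4 × 6 = 168 frames and the reference settings 336.
    """
    n = config.grid_resolution
    radius = config.field_radius_deg
    coords = np.linspace(-radius, radius, n)
    xx, yy = np.meshgrid(coords, coords)
    ecc = np.hypot(xx, yy)
    in_field = ecc <= radius + 1e-12
    if config.scotoma_radius_deg > 0:
        in_field = in_field & (ecc > config.scotoma_radius_deg)

    blocks = []
    blank_block = np.zeros(
        (config.frames_per_blank, n, n), dtype=bool
    )
    for k in range(config.n_crossings):
        blocks.append(_crossing_frames(config, k, xx, yy, in_field))
        if (k + 1) in config.blank_after_crossings:
            blocks.append(blank_block)
    frames = np.concatenate(blocks, axis=0)
    times = config.tr_s * np.arange(len(frames), dtype=float)
    return ApertureSequence(
        frames=frames.astype(np.uint8),
        frame_times_s=times,
        grid_x=coords.copy(),
        grid_y=coords.copy(),
        config=config,
    )


def masked_fraction(seq: ApertureSequence) -> np.ndarray:
    """Per-frame fraction of bar pixels removed by the scotoma mask.

    Compares each frame against the same sequence rebuilt without the
    central mask.  Blank frames report 0.
    """
    if seq.config.scotoma_radius_deg == 0:
        return np.zeros(seq.n_frames)
    full = build_sequence(replace(seq.config, scotoma_radius_deg=0.0))
    n_full = full.frames.reshape(full.n_frames, -1).sum(axis=1)
    n_masked = seq.frames.reshape(seq.n_frames, -1).sum(axis=1)
    frac = np.zeros(seq.n_frames)
    nz = n_full > 0
    frac[nz] = (n_full[nz] - n_masked[nz]) / n_full[nz]
    return frac
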