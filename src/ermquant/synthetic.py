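"""Synthetic scenarios with known ground truth.

No SD-OCT study data ships with this package, so every pipeline stage is
exercised on generated inputs: an ERM region drawn directly in en face
coordinates and inverse-projected into per-B-scan detections, a smooth
radial thickness blob, and Likert ratings from a latent-score model.

Generating the ERM region in en face space first makes the projection
round-trip exactly checkable: the detections a scenario emits are the
bounding intervals a perfect detector would produce, so rebuilding the
EPI from them must recover (a band-aligned cover of) the original shape.

All randomness flows from ``ScenarioSpec.seed`` through independent
substreams per output, so identical specs give bit-identical scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .agreement import ObserverStudy
from .epi_projection import (
    BScanDetection,
    Orientation,
    ScanGeometry,
    scan_band,
)
from .thickness import ThicknessMap

__all__ = [
    "RectShape",
    "EllipseShape",
    "ThicknessBlob",
    "RatingModel",
    "ScenarioSpec",
    "rasterize_shape",
    "detections_from_mask",
    "gen_detections",
    "gen_thickness_map",
    "gen_ratings",
    "overlap_scenario",
]


@dataclass(frozen=True)
class RectShape:
    """Axis-aligned rectangle in en face pixels, half-open intervals."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("rectangle must have positive extent")


@dataclass(frozen=True)
class EllipseShape:
    """Filled ellipse in en face pixel coordinates."""

    center_row: float
    center_col: float
    radius_row: float
    radius_col: float

    def __post_init__(self) -> None:
        if self.radius_row <= 0 or self.radius_col <= 0:
            raise ValueError("ellipse radii must be positive")


Shape = Union[RectShape, EllipseShape]


@dataclass(frozen=True)
class ThicknessBlob:
    """Radial thickness bump: background + (peak−background)·max(0, 1−d²)."""

    center_row: float
    center_col: float
    radius_row: float
    radius_col: float
    peak_um: float
    background_um: float
    noise_sd_um: float = 0.0

    def __post_init__(self) -> None:
        for name in ("peak_um", "background_um"):
            v = getattr(self, name)
            if not 0 <= v <= 600:
                raise ValueError(f"{name} must be within [0, 600] μm, got {v}")
        if self.radius_row <= 0 or self.radius_col <= 0:
            raise ValueError("blob radii must be positive")
        if self.noise_sd_um < 0:
            raise ValueError("noise_sd_um must be non-negative")


@dataclass(frozen=True)
class RatingModel:
    """Latent-score Likert model for a panel of raters.

    Each case draws a shared latent offset ~ N(0, case_sd); rater r's
    score is mean_r + latent + N(0, noise_sd_r), rounded and clipped to
    {1..5}.  case_sd > 0 with small noise gives highly reliable raters;
    case_sd = 0 with large noise gives independent raters.
    """

    rater_means: tuple[float, ...] = (4.5, 4.5)
    rater_noise_sd: tuple[float, ...] = (0.4, 0.4)
    case_sd: float = 0.8

    def __post_init__(self) -> None:
        if len(self.rater_means) != len(self.rater_noise_sd):
            raise ValueError("rater_means and rater_noise_sd must align")
        if len(self.rater_means) < 2:
            raise ValueError("need at least 2 raters")
        for m in self.rater_means:
            if not 1 <= m <= 5:
                raise ValueError(f"rater mean {m} outside the Likert range [1, 5]")
        if self.case_sd < 0 or any(s < 0 for s in self.rater_noise_sd):
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to generate one synthetic eye + observer study."""

    seed: int
    erm_shape: Shape = field(
        default_factory=lambda: EllipseShape(248.0, 248.0, 120.0, 100.0)
    )
    thickness_blob: ThicknessBlob = field(
        default_factory=lambda: ThicknessBlob(248.0, 248.0, 160.0, 150.0, 480.0, 200.0)
    )
    overlap_target: float | None = None
    rating_model: RatingModel = field(default_factory=RatingModel)

    def __post_init__(self) -> None:
        if self.overlap_target is not None and not 0 <= self.overlap_target <= 1:
            raise ValueError("overlap_target must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for output substream *stream*."""
        return np.random.default_rng([self.seed, stream])


def rasterize_shape(shape: Shape, geometry: ScanGeometry | None = None) -> np.ndarray:
    """Boolean en face mask of a parametric shape; errors if it leaves the frame."""
    geometry = geometry or ScanGeometry()
    h, w = geometry.enface_shape
    if isinstance(shape, RectShape):
        if shape.row0 < 0 or shape.col0 < 0 or shape.row1 > h or shape.col1 > w:
            raise ValueError(f"rectangle {shape} outside {h}x{w} frame")
        mask = np.zeros((h, w), dtype=bool)
        mask[shape.row0 : shape.row1, shape.col0 : shape.col1] = True
        return mask
    if isinstance(shape, EllipseShape):
        if not (0 <= shape.center_row < h and 0 <= shape.center_col < w):
            raise ValueError(f"ellipse center {shape} outside {h}x{w} frame")
        rr, cc = np.ogrid[:h, :w]
        d2 = ((rr - shape.center_row) / shape.radius_row) ** 2 + (
            (cc - shape.center_col) / shape.radius_col
        ) ** 2
        return d2 <= 1.0
    raise TypeError(f"unsupported shape type {type(shape).__name__}")


def detections_from_mask(
    mask: np.ndarray, geometry: ScanGeometry | None = None
) -> list[BScanDetection]:
    """Perfect-detector detections for an en face mask.

    For each scan line whose band intersects the mask, emits one
    detection spanning the bounding interval of the intersection,
    inverse-mapped from en face pixels to B-scan pixels.
    """
    geometry = geometry or ScanGeometry()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != geometry.enface_shape:
        raise ValueError("mask shape does not match geometry")
    scale = geometry.bscan_width / geometry.enface_width
    v_scale = geometry.bscan_width / geometry.enface_height
    detections: list[BScanDetection] = []
    for k in range(geometry.n_scans_per_orientation):
        r0, r1 = scan_band(k, Orientation.HORIZONTAL, geometry)
        cols = np.flatnonzero(mask[r0:r1, :].any(axis=0))
        if cols.size:
            detections.append(
                BScanDetection(
                    scan_index=k,
                    orientation=Orientation.HORIZONTAL,
                    x0=float(cols[0]) * scale,
                    x1=float(cols[-1] + 1) * scale,
                    confidence=1.0,
                )
            )
        c0, c1 = scan_band(k, Orientation.VERTICAL, geometry)
        rows = np.flatnonzero(mask[:, c0:c1].any(axis=1))
        if rows.size:
            detections.append(
                BScanDetection(
                    scan_index=k,
                    orientation=Orientation.VERTICAL,
                    x0=float(rows[0]) * v_scale,
                    x1=float(rows[-1] + 1) * v_scale,
                    confidence=1.0,
                )
            )
    return detections


def gen_detections(
    spec: ScenarioSpec, geometry: ScanGeometry | None = None
) -> list[BScanDetection]:
    """Detections for the scenario's ERM shape (deterministic given spec)."""
    geometry = geometry or ScanGeometry()
    return detections_from_mask(rasterize_shape(spec.erm_shape, geometry), geometry)


def gen_thickness_map(
    spec: ScenarioSpec, geometry: ScanGeometry | None = None
) -> ThicknessMap:
    """Smooth radial thickness field, plus optional Gaussian noise."""
    geometry = geometry or ScanGeometry()
    blob = spec.thickness_blob
    h, w = geometry.enface_shape
    rr, cc = np.ogrid[:h, :w]
    d2 = ((rr - blob.center_row) / blob.radius_row) ** 2 + (
        (cc - blob.center_col) / blob.radius_col
    ) ** 2
    grid = blob.background_um + (blob.peak_um - blob.background_um) * np.maximum(
        0.0, 1.0 - d2
    )
    if blob.noise_sd_um > 0:
        grid = grid + spec.rng(1).normal(0.0, blob.noise_sd_um, size=grid.shape)
        grid = np.clip(grid, 0.0, None)
    return ThicknessMap(grid=grid, geometry=geometry)


def gen_ratings(spec: ScenarioSpec, n_cases: int = 30) -> ObserverStudy:
    """Integer Likert ratings from the scenario's latent-score model."""
    if n_cases < 2:
        raise ValueError("need at least 2 cases")
    model = spec.rating_model
    rng = spec.rng(2)
    latent = rng.normal(0.0, model.case_sd, size=n_cases)
    cols = []
    for mean, noise in zip(model.rater_means, model.rater_noise_sd):
        y = mean + latent + rng.normal(0.0, noise, size=n_cases)
        cols.append(np.clip(np.rint(y), 1, 5).astype(int))
    return ObserverStudy(ratings=np.column_stack(cols))


def overlap_scenario(
    overlap_target: float, geometry: ScanGeometry | None = None
) -> tuple[RectShape, ThicknessMap]:
    """ERM rectangle and thickness map with a programmed overlap fraction.

    The thickened region is a fixed band-aligned rectangle held at a
    uniform 490 μm (class 1) on a 200 μm background; the ERM rectangle
    has the same size and is shifted right so that the overlapping
    fraction of its area is ``overlap_target``.  Increasing the target
    strictly increases the true overlap, which must translate into a
    non-decreasing association score.
    """
    geometry = geometry or ScanGeometry()
    if not 0.0 <= overlap_target <= 1.0:
        raise ValueError("overlap_target must be in [0, 1]")
    n = geometry.n_scans_per_orientation
    lo_band, hi_band = n // 5, n // 2  # block left of center, room to shift right
    r0, _ = scan_band(lo_band, Orientation.HORIZONTAL, geometry)
    r1, _ = scan_band(hi_band, Orientation.HORIZONTAL, geometry)
    c0, _ = scan_band(lo_band, Orientation.VERTICAL, geometry)
    c1, _ = scan_band(hi_band, Orientation.VERTICAL, geometry)
    width = c1 - c0
    shift = round((1.0 - overlap_target) * width)
    if c1 + shift > geometry.enface_width:
        raise ValueError("programmed overlap would push the ERM outside the frame")
    erm = RectShape(row0=r0, row1=r1, col0=c0 + shift, col1=c1 + shift)
    grid = np.full(geometry.enface_shape, 200.0)
    grid[r0:r1, c0:c1] = 490.0
    return erm, ThicknessMap(grid=grid, geometry=geometry)
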