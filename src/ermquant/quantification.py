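"""Convert EPI pixel counts to physical ERM area and coverage ratio.

The device's en face frame has a fixed lateral sampling of 20 μm per
pixel (10 pixels per 200 μm), so each pixel covers 400 μm².  ERM area is
the count of true EPI pixels times the pixel area; the ERM ratio is that
area as a percentage of the full 496x496 frame area.

Ratios are reported truncated (not rounded) to two decimal places, the
convention that reproduces the reference quantification tables; the
untruncated value is kept alongside for downstream analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .epi_projection import EPIMask, ScanGeometry

__all__ = [
    "Calibration",
    "AreaReport",
    "pixel_area",
    "erm_area",
    "erm_ratio",
    "truncate_pct",
    "quantify",
]


@dataclass(frozen=True)
class Calibration:
    """Lateral pixel calibration of the en face frame, in μm per pixel."""

    um_per_pixel: float = 20.0

    def __post_init__(self) -> None:
        if not self.um_per_pixel > 0:
            raise ValueError(f"um_per_pixel must be positive, got {self.um_per_pixel}")

    @property
    def pixel_area_um2(self) -> float:
        return self.um_per_pixel**2

    def to_dict(self) -> dict:
        return {"um_per_pixel": self.um_per_pixel, "pixel_area_um2": self.pixel_area_um2}


@dataclass(frozen=True)
class AreaReport:
    """Physical quantification of one EPI."""

    erm_pixels: int
    erm_area_um2: float
    erm_ratio_pct: float  # truncated to 2 decimals
    erm_ratio_raw_pct: float  # full precision
    calibration: Calibration = field(default_factory=Calibration)

    def to_dict(self) -> dict:
        return {
            "erm_pixels": self.erm_pixels,
            "erm_area_um2": self.erm_area_um2,
            "erm_ratio_pct": self.erm_ratio_pct,
            "erm_ratio_raw_pct": self.erm_ratio_raw_pct,
            "calibration": self.calibration.to_dict(),
        }


def pixel_area(cal: Calibration) -> float:
    """Area covered by one en face pixel, in μm²."""
    return cal.pixel_area_um2


def erm_area(mask: EPIMask | np.ndarray, cal: Calibration | None = None) -> float:
    """Total ERM area in μm²: true-pixel count times the pixel area."""
    cal = cal or Calibration()
    grid = mask.grid if isinstance(mask, EPIMask) else np.asarray(mask, dtype=bool)
    return float(grid.sum()) * pixel_area(cal)


def truncate_pct(value: float, decimals: int = 2) -> float:
    """Truncate a percentage toward zero at *decimals* places.

    A tiny epsilon absorbs float representation error so that values that
    are exact at the cut (e.g. 100.00) are not pulled down a count.
    """
    scale = 10**decimals
    return math.floor(value * scale + 1e-9) / scale


def erm_ratio(
    area_um2: float,
    geometry: ScanGeometry | None = None,
    cal: Calibration | None = None,
) -> float:
    """ERM area as a percentage of the full en face frame, truncated to 2 dp."""
    geometry = geometry or ScanGeometry()
    cal = cal or Calibration()
    total = geometry.enface_pixels * pixel_area(cal)
    if area_um2 < 0:
        raise ValueError(f"area must be non-negative, got {area_um2}")
    if area_um2 > total:
        raise ValueError(f"area {area_um2} μm² exceeds frame area {total} μm²")
    return truncate_pct(100.0 * area_um2 / total)


def quantify(
    mask: EPIMask,
    cal: Calibration | None = None,
    geometry: ScanGeometry | None = None,
) -> AreaReport:
    """Full area report for one EPI mask."""
    cal = cal or Calibration()
    geometry = geometry or mask.geometry
    area = erm_area(mask, cal)
    total = geometry.enface_pixels * pixel_area(cal)
    raw = 100.0 * area / total
    return AreaReport(
        erm_pixels=mask.n_true,
        erm_area_um2=area,
        erm_ratio_pct=truncate_pct(raw),
        erm_ratio_raw_pct=raw,
        calibration=cal,
    )
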