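"""Project per-B-scan ERM detections onto an en face grid.

SD-OCT devices acquire a raster of cross-sectional B-scans (here 25
horizontal plus 25 vertical lines per eye).  An epiretinal membrane (ERM)
detector produces bounding boxes on each B-scan; only the box's extent
along the scan line carries en face information, because a B-scan is a
cut through the retina along that line.  This module maps those 1-D
extents into the 2-D en face frame and merges them into a single binary
mask, the Epiretinal Projection Image (EPI).

Coordinate conventions: pixels are 0-based and all intervals are
half-open ``[start, stop)``.  The B-scan x-axis (width 768 px by default)
maps linearly onto the en face axis (496 px) via

    x_enface = x_bscan / W_bscan * W_enface

Horizontal scans project onto en face columns, vertical scans onto rows.
Perpendicular to the scan line, each detection is painted across its
scan's full band of the frame (frame_extent / n_scans pixels), so the 25
bands of one orientation tile the frame exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Orientation",
    "ScanGeometry",
    "BScanDetection",
    "EPIMask",
    "PixelRegion",
    "normalize_coordinate",
    "scan_band",
    "project_detection",
    "build_epi",
]

#: Absolute tolerance for snapping a nearly integral coordinate to the
#: integer before floor/ceil discretization.  Guards against binary
#: floating-point artifacts in the 768 <-> 496 rescaling (relative error
#: of a multiply/divide pair is ~1e-16, far below this).
SNAP_TOL = 1e-6


class Orientation(str, Enum):
    """Direction of a B-scan line in the en face frame."""

    HORIZONTAL = "horizontal"
    VERTICAL = "vertical"


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition geometry of one SD-OCT raster volume.

    Defaults match the device used throughout: 768x496 B-scans,
    a 496x496 en face frame and 25 scan lines per orientation.
    """

    bscan_width: int = 768
    bscan_height: int = 496
    enface_width: int = 496
    enface_height: int = 496
    n_scans_per_orientation: int = 25

    def __post_init__(self) -> None:
        for name in (
            "bscan_width",
            "bscan_height",
            "enface_width",
            "enface_height",
            "n_scans_per_orientation",
        ):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")

    @property
    def enface_shape(self) -> tuple[int, int]:
        return (self.enface_height, self.enface_width)

    @property
    def enface_pixels(self) -> int:
        return self.enface_height * self.enface_width

    def to_dict(self) -> dict:
        return {
            "bscan_width": self.bscan_width,
            "bscan_height": self.bscan_height,
            "enface_width": self.enface_width,
            "enface_height": self.enface_height,
            "n_scans_per_orientation": self.n_scans_per_orientation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(**{k: int(v) for k, v in d.items()})


@dataclass(frozen=True)
class BScanDetection:
    """One ERM bounding box on one B-scan.

    Only the extent along the scan axis (``x0``..``x1``, B-scan pixels)
    is retained; the vertical extent of the box on the B-scan carries
    depth information that does not map to the en face plane.
    """

    scan_index: int
    orientation: Orientation
    x0: float
    x1: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "orientation", Orientation(self.orientation))
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        if self.x1 <= self.x0:
            raise ValueError(
                f"degenerate detection: x1 ({self.x1}) must exceed x0 ({self.x0})"
            )

    def validate(self, geometry: ScanGeometry) -> None:
        """Raise ValueError if the detection is out of range for *geometry*."""
        n = geometry.n_scans_per_orientation
        if not 0 <= self.scan_index < n:
            raise ValueError(
                f"scan_index {self.scan_index} out of range [0, {n}) for geometry"
            )
        if self.x0 < 0 or self.x1 > geometry.bscan_width:
            raise ValueError(
                f"detection extent [{self.x0}, {self.x1}] exceeds B-scan width "
                f"{geometry.bscan_width}"
            )


class PixelRegion(NamedTuple):
    """Half-open rectangular region on the en face grid."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    @property
    def n_pixels(self) -> int:
        return max(0, self.row_stop - self.row_start) * max(
            0, self.col_stop - self.col_start
        )


@dataclass
class EPIMask:
    """Merged en face ERM mask with per-pixel provenance counts.

    ``grid`` is the binary EPI; ``coverage`` counts how many projected
    detections contributed to each pixel (grid is true exactly where
    coverage >= 1).
    """

    grid: np.ndarray
    coverage: np.ndarray
    geometry: ScanGeometry = field(default_factory=ScanGeometry)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        self.coverage = np.asarray(self.coverage, dtype=np.int32)
        if self.grid.shape != self.geometry.enface_shape:
            raise ValueError(
                f"grid shape {self.grid.shape} does not match en face shape "
                f"{self.geometry.enface_shape}"
            )
        if self.coverage.shape != self.grid.shape:
            raise ValueError("coverage shape must match grid shape")
        if (self.coverage < 0).any():
            raise ValueError("coverage counts must be non-negative")
        if not np.array_equal(self.grid, self.coverage >= 1):
            raise ValueError("grid must be true exactly where coverage >= 1")

    @property
    def n_true(self) -> int:
        return int(self.grid.sum())


def _snap(value: float) -> float:
    nearest = round(value)
    return float(nearest) if abs(value - nearest) <= SNAP_TOL else value


def _snap_floor(value: float) -> int:
    return int(math.floor(_snap(value)))


def _snap_ceil(value: float) -> int:
    return int(math.ceil(_snap(value)))


def normalize_coordinate(x_bscan: float, geometry: ScanGeometry | None = None) -> float:
    """Map a B-scan x-coordinate onto the en face axis.

    Returns the real-valued coordinate ``x / W_bscan * W_enface``;
    callers discretize (floor for interval starts, ceil for stops).
    """
    geometry = geometry or ScanGeometry()
    if not 0 <= x_bscan <= geometry.bscan_width:
        raise ValueError(
            f"x_bscan={x_bscan} outside [0, {geometry.bscan_width}]"
        )
    return x_bscan / geometry.bscan_width * geometry.enface_width


def scan_band(
    scan_index: int,
    orientation: Orientation | str,
    geometry: ScanGeometry | None = None,
) -> tuple[int, int]:
    """Half-open pixel interval a scan occupies perpendicular to its line.

    Band *k* of *n* over a frame extent *E* is ``[floor(k*E/n),
    floor((k+1)*E/n))``, computed in exact integer arithmetic so the *n*
    bands tile the frame with no gaps or overlaps.  Horizontal scans band
    rows, vertical scans band columns.
    """
    geometry = geometry or ScanGeometry()
    orientation = Orientation(orientation)
    n = geometry.n_scans_per_orientation
    if not 0 <= scan_index < n:
        raise ValueError(f"scan_index {scan_index} out of range [0, {n})")
    extent = (
        geometry.enface_height
        if orientation is Orientation.HORIZONTAL
        else geometry.enface_width
    )
    return (scan_index * extent) // n, ((scan_index + 1) * extent) // n


def project_detection(
    det: BScanDetection, geometry: ScanGeometry | None = None
) -> PixelRegion:
    """Rectangular en face footprint of one detection.

    Along the scan axis the footprint is ``[floor(norm(x0)),
    ceil(norm(x1)))`` so no sub-pixel extent is lost; perpendicular to it,
    the footprint spans the scan's band.  For vertical scans the along-axis
    extent lands on en face rows (the y-axis).
    """
    geometry = geometry or ScanGeometry()
    det.validate(geometry)
    along_start = _snap_floor(normalize_coordinate(det.x0, geometry))
    along_stop = _snap_ceil(normalize_coordinate(det.x1, geometry))
    band_start, band_stop = scan_band(det.scan_index, det.orientation, geometry)
    if det.orientation is Orientation.HORIZONTAL:
        along_stop = min(along_stop, geometry.enface_width)
        return PixelRegion(band_start, band_stop, along_start, along_stop)
    along_stop = min(along_stop, geometry.enface_height)
    return PixelRegion(along_start, along_stop, band_start, band_stop)


def build_epi(
    detections: Iterable[BScanDetection],
    geometry: ScanGeometry | None = None,
    min_confidence: float = 0.25,
) -> EPIMask:
    """Merge projected detections into one EPI mask.

    Detections below *min_confidence* are dropped before projection; the
    remaining footprints are unioned, with ``coverage`` counting how many
    contributed to each pixel.  An empty input yields an all-false mask.
    """
    geometry = geometry or ScanGeometry()
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence must be in [0, 1], got {min_confidence}")
    coverage = np.zeros(geometry.enface_shape, dtype=np.int32)
    for det in detections:
        if det.confidence < min_confidence:
            continue
        region = project_detection(det, geometry)
        coverage[region.row_start : region.row_stop, region.col_start : region.col_stop] += 1
    return EPIMask(grid=coverage >= 1, coverage=coverage, geometry=geometry)
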