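"""Discretize a retinal-thickness map into ordered severity classes.

Clinically, the thickness range ophthalmologists scrutinize on a macular
thickness map is 220-500 μm; thicker retina within that range indicates
more severe traction.  The range is split into nine equal-width bands
(280/9 ≈ 31.1 μm each), numbered thickest-first: class 1 is
[500 − 280/9, 500], class 9 is [220, 220 + 280/9).

Intervals are inclusive at their lower edge and exclusive at the upper,
except class 1 which includes 500 exactly.  Pixels below 220 μm or above
500 μm are left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epi_projection import ScanGeometry

__all__ = [
    "THICKNESS_MIN_UM",
    "THICKNESS_MAX_UM",
    "N_CLASSES",
    "ThicknessMap",
    "ThicknessClasses",
    "class_bounds",
    "discretize",
    "cumulative_union",
]

THICKNESS_MIN_UM = 220.0
THICKNESS_MAX_UM = 500.0
N_CLASSES = 9


@dataclass
class ThicknessMap:
    """Retinal thickness in μm on the en face grid.

    ``valid_mask`` marks pixels with a measurement; it defaults to all
    pixels whose value is finite.
    """

    grid: np.ndarray
    valid_mask: np.ndarray | None = None
    geometry: ScanGeometry = field(default_factory=ScanGeometry)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != self.geometry.enface_shape:
            raise ValueError(
                f"thickness grid shape {self.grid.shape} does not match en face "
                f"shape {self.geometry.enface_shape}"
            )
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.grid)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.grid.shape:
                raise ValueError("valid_mask shape must match grid shape")
            self.valid_mask = self.valid_mask & np.isfinite(self.grid)
        if (self.grid[self.valid_mask] < 0).any():
            raise ValueError("thickness values must be non-negative where valid")


@dataclass
class ThicknessClasses:
    """Ordered thickness-class masks, index 0 = class 1 = thickest band.

    ``edges`` holds the 10 band boundaries in descending μm (500 ... 220).
    """

    masks: list[np.ndarray]
    edges: np.ndarray
    geometry: ScanGeometry = field(default_factory=ScanGeometry)

    def __post_init__(self) -> None:
        if len(self.masks) != len(self.edges) - 1:
            raise ValueError("need exactly one more edge than masks")
        self.edges = np.asarray(self.edges, dtype=float)
        if not (np.diff(self.edges) < 0).all():
            raise ValueError("edges must be strictly decreasing (thickest-first)")

    @property
    def n_classes(self) -> int:
        return len(self.masks)

    def mask(self, i: int) -> np.ndarray:
        """Mask of class *i* (1-based, 1 = thickest)."""
        if not 1 <= i <= self.n_classes:
            raise ValueError(f"class index {i} out of range [1, {self.n_classes}]")
        return self.masks[i - 1]

    def pixel_counts(self) -> list[int]:
        return [int(m.sum()) for m in self.masks]


def class_bounds(
    i: int,
    t_min: float = THICKNESS_MIN_UM,
    t_max: float = THICKNESS_MAX_UM,
    n_classes: int = N_CLASSES,
) -> tuple[float, float]:
    """μm interval ``[lower, upper)`` of class *i* (1-based, thickest-first).

    Class 1's upper bound (t_max) is inclusive.
    """
    if not 1 <= i <= n_classes:
        raise ValueError(f"class index {i} out of range [1, {n_classes}]")
    edges = np.linspace(t_max, t_min, n_classes + 1)
    return float(edges[i]), float(edges[i - 1])


def discretize(
    tmap: ThicknessMap,
    t_min: float = THICKNESS_MIN_UM,
    t_max: float = THICKNESS_MAX_UM,
    n_classes: int = N_CLASSES,
) -> ThicknessClasses:
    """Assign each in-range pixel to exactly one thickness class.

    Valid pixels with thickness in [t_min, t_max] land in one class;
    out-of-range pixels are unassigned.  The class masks are therefore
    pairwise disjoint and their union is the in-range valid pixel set.
    """
    edges = np.linspace(t_max, t_min, n_classes + 1)
    g, valid = tmap.grid, tmap.valid_mask
    masks = []
    for i in range(1, n_classes + 1):
        lower, upper = edges[i], edges[i - 1]
        with np.errstate(invalid="ignore"):
            if i == 1:
                m = valid & (g >= lower) & (g <= upper)
            else:
                m = valid & (g >= lower) & (g < upper)
        masks.append(m)
    return ThicknessClasses(masks=masks, edges=edges, geometry=tmap.geometry)


def cumulative_union(classes: ThicknessClasses, i: int) -> np.ndarray:
    """Union of class masks 1..i — the retina at least as thick as class i's floor."""
    if not 1 <= i <= classes.n_classes:
        raise ValueError(f"class index {i} out of range [1, {classes.n_classes}]")
    out = np.zeros_like(classes.masks[0], dtype=bool)
    for m in classes.masks[:i]:
        out |= m
    return out
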