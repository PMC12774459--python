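"""Weighted cumulative-IoU association between ERM and thickened retina.

The association score quantifies how strongly the projected ERM region
co-locates with retinal thickening.  With the nine thickness classes
ordered thickest-first, the score is

    score = (1/9) * Σ_{i=1..9}  W_i * IoU(A_ERM, ∪_{j<=i} A_class_j)

where W_i = −0.01·i² − 0.07·i + 1.666 decreases with i, so overlap with
the thickest retina dominates, and the cumulative union progressively
admits thinner retina.  The weights are used exactly as the polynomial
gives them (Σ W_i = 8.994, not 9), so the attainable maximum is
(1/9)·Σ W_i ≈ 0.99933, reached when the ERM mask coincides with class 1
and classes 2-9 are empty.

IoU of two empty sets is defined as 0 ("no association"), never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epi_projection import EPIMask
from .thickness import ThicknessClasses

__all__ = [
    "AssociationResult",
    "iou",
    "weight",
    "class_weights",
    "max_association_score",
    "association_score",
]

N_CLASSES = 9


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two boolean masks; 0 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum()) / union


def weight(i: int) -> float:
    """Severity weight of thickness class *i* (1 = thickest)."""
    if not 1 <= i <= N_CLASSES:
        raise ValueError(f"class index {i} out of range [1, {N_CLASSES}]")
    return -0.01 * i * i - 0.07 * i + 1.666


def class_weights() -> np.ndarray:
    return np.array([weight(i) for i in range(1, N_CLASSES + 1)])


def max_association_score() -> float:
    """Upper bound of the score: all nine IoU terms equal to 1."""
    return float(class_weights().sum()) / N_CLASSES


@dataclass(frozen=True)
class AssociationResult:
    score: float
    per_class_iou: tuple[float, ...]
    weights: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "per_class_iou": list(self.per_class_iou),
            "weights": list(self.weights),
            "weights_sum": float(np.sum(self.weights)),
            "max_score": max_association_score(),
        }


def association_score(
    erm: EPIMask | np.ndarray, classes: ThicknessClasses
) -> AssociationResult:
    """ERM-thickness association score over the nine class masks.

    The ERM operand is the binary EPI grid; provenance counts are
    ignored.  Each term i is the IoU of the ERM mask with the cumulative
    union of classes 1..i, weighted by W_i; the score averages the nine
    weighted terms.
    """
    grid = erm.grid if isinstance(erm, EPIMask) else np.asarray(erm, dtype=bool)
    if classes.n_classes != N_CLASSES:
        raise ValueError(
            f"association score is defined for {N_CLASSES} classes, "
            f"got {classes.n_classes}"
        )
    if classes.masks[0].shape != grid.shape:
        raise ValueError(
            f"geometry mismatch: ERM grid {grid.shape} vs class masks "
            f"{classes.masks[0].shape}"
        )
    ious = []
    cum = np.zeros_like(grid, dtype=bool)
    for mask in classes.masks:
        cum = cum | mask
        ious.append(iou(grid, cum))
    w = class_weights()
    score = float(np.dot(w, ious)) / N_CLASSES
    return AssociationResult(
        score=score, per_class_iou=tuple(ious), weights=tuple(w)
    )
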