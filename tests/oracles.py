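"""Independent reference implementations used only as test oracles.

These deliberately avoid the library's vectorized code paths: projection
is a per-pixel membership loop over real-valued intervals, the
association score is computed on Python sets, kappa/ICC come from
hand-written contingency-table and ANOVA arithmetic.
"""

from __future__ import annotations

import numpy as np


def pixel_in_band(row: int, scan_index: int, extent: int, n_scans: int) -> bool:
    """Row *row* lies in scan band k iff the unit pixel [row, row+1) sits
    inside the real interval [k*E/n, (k+1)*E/n] rounded to the tiling."""
    lo = scan_index * extent / n_scans
    hi = (scan_index + 1) * extent / n_scans
    return (row + 1) > lo and (row + 1) <= hi


def pixel_in_span(col: int, x0: float, x1: float, bscan_width: int, enface_extent: int) -> bool:
    """Column *col* is covered iff the unit pixel [col, col+1) intersects
    the normalized real interval [x0, x1) mapped onto the en face axis."""
    n0 = x0 / bscan_width * enface_extent
    n1 = x1 / bscan_width * enface_extent
    return (col + 1) > n0 and col < n1


def epi_bruteforce(detections, geometry, min_confidence=0.0):
    """Per-pixel union over all detection rectangles."""
    h, w = geometry.enface_height, geometry.enface_width
    n = geometry.n_scans_per_orientation
    grid = np.zeros((h, w), dtype=bool)
    kept = [d for d in detections if d.confidence >= min_confidence]
    for r in range(h):
        for c in range(w):
            for det in kept:
                if det.orientation.value == "horizontal":
                    ok = pixel_in_band(r, det.scan_index, h, n) and pixel_in_span(
                        c, det.x0, det.x1, geometry.bscan_width, w
                    )
                else:
                    ok = pixel_in_band(c, det.scan_index, w, n) and pixel_in_span(
                        r, det.x0, det.x1, geometry.bscan_width, h
                    )
                if ok:
                    grid[r, c] = True
                    break
    return grid


def association_bruteforce(erm_grid, class_masks):
    """Score from explicit cumulative unions as Python sets of pixel coords."""
    erm = {
        (r, c)
        for r in range(erm_grid.shape[0])
        for c in range(erm_grid.shape[1])
        if erm_grid[r, c]
    }
    cum: set = set()
    total = 0.0
    for i, mask in enumerate(class_masks, start=1):
        for r in range(mask.shape[0]):
            for c in range(mask.shape[1]):
                if mask[r, c]:
                    cum.add((r, c))
        union = len(erm | cum)
        iou_i = len(erm & cum) / union if union else 0.0
        w_i = -0.01 * i * i - 0.07 * i + 1.666
        total += w_i * iou_i
    return total / len(class_masks)


def qwk_bruteforce(a, b, n_levels=5):
    """Quadratic-weighted kappa from an explicitly built contingency table."""
    n = len(a)
    obs = np.zeros((n_levels, n_levels))
    for x, y in zip(a, b):
        obs[x - 1, y - 1] += 1
    obs /= n
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    exp = np.outer(row, col)
    penalty = np.array(
        [
            [(i - j) ** 2 / (n_levels - 1) ** 2 for j in range(n_levels)]
            for i in range(n_levels)
        ]
    )
    denom = (penalty * exp).sum()
    if denom == 0:
        return 1.0
    return 1.0 - (penalty * obs).sum() / denom


def kappa_2x2(a: int, b: int, c: int, d: int) -> float:
    """Unweighted Cohen's kappa from 2x2 cell counts (a=both+, d=both-)."""
    n = a + b + c + d
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    return (po - pe) / (1 - pe)


def icc21_anova(mat) -> float:
    """ICC(2,1) from hand-computed two-way ANOVA mean squares."""
    mat = np.asarray(mat, dtype=float)
    n, k = mat.shape
    grand = mat.mean()
    ss_rows = k * ((mat.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((mat.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((mat - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
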