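"""Dual-view baseline: tree delimitation and per-tree counting.

The dual-view method photographs each tree once from each side of the row
and counts detected fruit in the two images.  Trees are delimited
automatically: pixels below the Otsu threshold are zeroed, the remaining
intensity is summed per pixel column over the top two-thirds of the image
(the part carrying the canopy's sky silhouette and maximum width), and the
first near-zero columns on either side of the image centre are taken as the
boundaries between neighbouring canopies.  When a side has no near-zero
column — canopies touching — that side falls back to a fixed margin from
the centre.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "ColumnProfile",
    "TreeSegment",
    "otsu_threshold",
    "apply_otsu_zeroing",
    "column_profile",
    "segment_trees",
    "dualview_tree_count",
    "row_total",
    "assign_to_segment",
]


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column sums of post-threshold intensity over the top image rows."""

    values: np.ndarray  # length = image width; >= 0
    top_fraction: float = 2.0 / 3.0


@dataclass(frozen=True)
class TreeSegment:
    """Column bounds of one tree, half-open [left_col, right_col)."""

    left_col: int
    right_col: int
    method: str  # "profile" or "fixed_margin"

    def __post_init__(self):
        if not (0 <= self.left_col < self.right_col):
            raise ValueError("require 0 <= left_col < right_col")

    def contains(self, x: float) -> bool:
        return self.left_col <= x < self.right_col


def otsu_threshold(gray: np.ndarray) -> float:
    """Intensity level maximizing between-class variance of the histogram.

    Degenerate case: a constant image has no class split; its single value
    is returned, and zeroing pixels *strictly below* it then changes
    nothing.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty image")
    vals = np.unique(gray)
    if vals.size == 1:
        return float(vals[0])
    level = threshold_otsu(gray)
    if np.issubdtype(gray.dtype, np.integer):
        # threshold_otsu's convention keeps pixels > level; ours zeroes
        # pixels strictly below the returned level, so shift to the next
        # integer to make the two classes coincide
        return float(np.floor(level) + 1)
    return float(level)


def apply_otsu_zeroing(gray: np.ndarray) -> np.ndarray:
    """Zero pixels strictly below the Otsu level; returns a float copy."""
    gray = np.asarray(gray, dtype=float)
    level = otsu_threshold(gray)
    out = gray.copy()
    out[out < level] = 0.0
    return out


def column_profile(gray: np.ndarray, top_fraction: float = 2.0 / 3.0) -> ColumnProfile:
    """Column-intensity projection of the Otsu-zeroed top image rows.

    ``top_fraction`` of the rows (whole rows, rounded down, measured from
    the image top) enter the sum.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    n_rows = int(gray.shape[0] * top_fraction)
    if n_rows < 1:
        raise ValueError("top_fraction leaves no rows")
    zeroed = apply_otsu_zeroing(gray[:n_rows, :])
    return ColumnProfile(values=zeroed.sum(axis=0), top_fraction=top_fraction)


def segment_trees(
    gray: np.ndarray,
    center_col: int,
    near_zero_frac: float = 0.02,
    top_fraction: float = 2.0 / 3.0,
    fixed_margin: int | None = None,
) -> TreeSegment:
    """Delimit the tree centred at ``center_col`` from its neighbours.

    Scans the column profile leftward then rightward from the centre for the
    first column whose value is <= ``near_zero_frac`` x max(profile) — the
    canopy gap.  A side with no such column within the image falls back to a
    fixed margin (default: a quarter of the image width) from the centre.
    """
    gray = np.asarray(gray)
    width = gray.shape[1]
    if not (0 <= center_col < width):
        raise ValueError("center_col outside image")
    if fixed_margin is None:
        fixed_margin = width // 4
    profile = column_profile(gray, top_fraction).values
    peak = profile.max()
    if peak <= 0:
        raise ValueError("no canopy signal: column profile is all zero")
    cutoff = near_zero_frac * peak

    left = None
    for c in range(center_col, -1, -1):
        if profile[c] <= cutoff:
            left = c
            break
    right = None
    for c in range(center_col + 1, width):
        if profile[c] <= cutoff:
            right = c
            break

    method = "profile"
    if left is None:
        left = max(center_col - fixed_margin, 0)
        method = "fixed_margin"
    if right is None:
        right = min(center_col + fixed_margin, width)
        method = "fixed_margin"
    return TreeSegment(left_col=int(left), right_col=int(right), method=method)


def assign_to_segment(centroids: Sequence[tuple[float, float]], segment: TreeSegment) -> int:
    """Count fruit centroids falling inside a tree's column segment."""
    return sum(1 for x, _ in centroids if segment.contains(x))


def dualview_tree_count(side_a_count: int, side_b_count: int) -> int:
    """Per-tree dual-view count: one image per tree side, counts summed."""
    if side_a_count < 0 or side_b_count < 0:
        raise ValueError("counts must be >= 0")
    return side_a_count + side_b_count


def row_total(per_tree_counts: Sequence[int]) -> int:
    """Row yield estimate: sum of the per-tree dual-view counts."""
    counts = list(per_tree_counts)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    return sum(counts)
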