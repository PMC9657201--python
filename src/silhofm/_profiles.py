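"""Row-profile primitives shared by conditioning QC and geometry.

All helpers operate on a 2D boolean mask with row 0 at the top. They are
deliberately dependency-light: a silhouette is fully characterised, for our
purposes, by its per-row foreground widths and run counts.
"""
from __future__ import annotations

import numpy as np

from .errors import DegenerateInputError


def row_widths(mask: np.ndarray) -> np.ndarray:
    """Foreground pixel count per row (total run length, not extent)."""
    return mask.sum(axis=1).astype(np.int64)


def runs_per_row(mask: np.ndarray) -> np.ndarray:
    """Number of contiguous foreground runs in each row."""
    m = mask.astype(np.int8)
    starts = np.diff(m, axis=1, prepend=0) == 1
    return starts.sum(axis=1).astype(np.int64)


def body_bounds(mask: np.ndarray) -> tuple[int, int]:
    """(top_row, bottom_row) of the foreground, inclusive."""
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise DegenerateInputError("empty mask: no foreground rows")
    return int(rows[0]), int(rows[-1])


def extremum_row(widths: np.ndarray, lo: int, hi: int, mode: str) -> int:
    """Row of the width extremum in [lo, hi], midpoint of ties.

    Discretisation flattens smooth extrema into runs of equal width; the
    midpoint of the extremal run is the stable sub-row estimate.
    """
    lo = max(lo, 0)
    hi = min(hi, len(widths) - 1)
    if hi < lo:
        raise DegenerateInputError(f"empty search window [{lo}, {hi}]")
    seg = widths[lo : hi + 1]
    target = seg.max() if mode == "max" else seg.min()
    idx = np.flatnonzero(seg == target)
    # midpoint of the extremal run containing the median index of all ties
    return lo + int(round(idx.mean()))


def neck_row(mask: np.ndarray, top: int, bottom: int, search_frac: float = 0.25) -> int:
    """Row of minimum width in the top fraction of the body: the neck.

    The head-height convention used throughout the package is the span from
    the top foreground row to this minimum-width row.
    """
    widths = row_widths(mask)
    body_h = bottom - top + 1
    hi = top + int(round(search_frac * body_h))
    # skip the first few rows: the crown can be narrower than the neck
    lo = top + max(3, int(round(0.08 * body_h)))
    return extremum_row(widths, lo, hi, "min")


def eye_row_estimate(top: int, neck: int, eye_frac: float = 0.4) -> int:
    """Eye line as a fixed fraction of head height below the crown."""
    return top + int(round(eye_frac * (neck - top)))


def malleolus_row_estimate(top: int, bottom: int, offset_frac: float = 0.02) -> int:
    """Malleolus line at a small offset above the lowest foreground row."""
    body_h = bottom - top + 1
    return bottom - int(round(offset_frac * body_h))
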