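"""Landmark lines, virtual frame, and occupancy features on a silhouette.

The measurable geometry of the method: six transverse lines (eyes,
chest, belly, thigh, calf, malleolus) anchor a virtual frame whose
vertical span is the eye-to-malleolus pixel distance and whose width is a
preset fraction of that span. The shape features — pixel occupancy inside
the frame and normalised site widths — are dimensionless, which is what
makes them independent of camera distance and resolution.

Conventions: 0-based row-major coordinates with the origin at top-left;
row/column intervals are half-open for counting. On a featureless binary
mask the eye line cannot be seen, so it is placed at a fixed fraction of
head height (crown to neck minimum); site lines start at fixed fractions
of the eye-malleolus span and are refined to the nearest local width
maximum.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _profiles
from .conditioning import BinarySilhouette
from .errors import (
    DegenerateFrameError,
    DegenerateInputError,
    FrameOverflowError,
    InvalidArgumentError,
    LandmarkFailureError,
)

__all__ = [
    "GeometryConfig",
    "LandmarkSet",
    "VirtualFrame",
    "FeatureVector",
    "detect_landmarks",
    "build_virtual_frame",
    "occupancy_ratio",
    "site_widths",
    "extract_features",
    "FEATURE_ORDER",
]

SITES = ("chest", "belly", "thigh", "calf")
FEATURE_ORDER = (
    "occupancy_ratio",
    "width_chest",
    "width_belly",
    "width_thigh",
    "width_calf",
)


@dataclass(frozen=True)
class GeometryConfig:
    frame_fraction: float = 0.4
    occupancy_mode: str = "ratio"  # "ratio" (white/black) or "fraction" (white/all)
    eye_head_fraction: float = 0.4
    malleolus_offset_fraction: float = 0.02
    neck_search_fraction: float = 0.25
    site_fractions: tuple = (("chest", 0.22), ("belly", 0.38), ("thigh", 0.60), ("calf", 0.82))
    refine_window_fraction: float = 0.03
    min_rows: int = 50


@dataclass(frozen=True)
class LandmarkSet:
    """Transverse line rows, strictly ordered top to bottom."""

    eye_row: int
    chest_row: int
    belly_row: int
    thigh_row: int
    calf_row: int
    malleolus_row: int

    def __post_init__(self):
        rows = [self.eye_row, self.chest_row, self.belly_row,
                self.thigh_row, self.calf_row, self.malleolus_row]
        if any(r < 0 for r in rows):
            raise InvalidArgumentError("landmark rows must be non-negative")
        if not all(a < b for a, b in zip(rows, rows[1:])):
            raise LandmarkFailureError(f"landmark rows not strictly ordered: {rows}")

    @property
    def span(self) -> int:
        return self.malleolus_row - self.eye_row

    def site_row(self, site: str) -> int:
        return getattr(self, f"{site}_row")


@dataclass(frozen=True)
class VirtualFrame:
    """Counting region: rows [top_row, bottom_row), cols [left_col, right_col)."""

    top_row: int
    bottom_row: int
    left_col: int
    right_col: int

    @property
    def span(self) -> int:
        return self.bottom_row - self.top_row

    @property
    def width(self) -> int:
        return self.right_col - self.left_col

    @property
    def n_pixels(self) -> int:
        return self.span * self.width


@dataclass(frozen=True)
class FeatureVector:
    """The model's only predictors. Body weight is structurally excluded."""

    occupancy_ratio: float
    width_chest: float
    width_belly: float
    width_thigh: float
    width_calf: float
    span_px: int
    gender: str
    stature_cm: float | None = None

    def __post_init__(self):
        if self.occupancy_ratio <= 0:
            raise InvalidArgumentError("occupancy_ratio must be positive")
        for s in SITES:
            w = getattr(self, f"width_{s}")
            if not 0.0 < w < 1.0:
                raise InvalidArgumentError(f"width_{s}={w} outside (0, 1)")

    def as_array(self, use_stature: bool = False) -> np.ndarray:
        vals = [getattr(self, name) for name in FEATURE_ORDER]
        if use_stature:
            if self.stature_cm is None:
                raise InvalidArgumentError("stature requested but not carried")
            vals.append(self.stature_cm)
        return np.asarray(vals, dtype=float)


def detect_landmarks(
    sil: BinarySilhouette, config: GeometryConfig = GeometryConfig()
) -> LandmarkSet:
    """Locate the six transverse lines on a conditioned silhouette."""
    mask = sil.mask
    top, bottom = _profiles.body_bounds(mask)
    body_h = bottom - top + 1
    if body_h < config.min_rows:
        raise DegenerateInputError(
            f"silhouette spans {body_h} rows; need at least {config.min_rows}"
        )
    widths = _profiles.row_widths(mask)
    neck = _profiles.neck_row(mask, top, bottom, config.neck_search_fraction)
    eye = _profiles.eye_row_estimate(top, neck, config.eye_head_fraction)
    malleolus = _profiles.malleolus_row_estimate(
        top, bottom, config.malleolus_offset_fraction
    )
    span = malleolus - eye
    if span <= 0:
        raise LandmarkFailureError("non-positive eye-to-malleolus span")
    half_win = int(round(config.refine_window_fraction * span))
    rows = {"eye": eye, "malleolus": malleolus}
    for site, frac in config.site_fractions:
        guess = eye + int(round(frac * span))
        rows[site] = _profiles.extremum_row(
            widths, guess - half_win, guess + half_win, "max"
        )
    return LandmarkSet(
        eye_row=rows["eye"],
        chest_row=rows["chest"],
        belly_row=rows["belly"],
        thigh_row=rows["thigh"],
        calf_row=rows["calf"],
        malleolus_row=rows["malleolus"],
    )


def build_virtual_frame(
    lm: LandmarkSet, sil: BinarySilhouette, frame_fraction: float = 0.4
) -> VirtualFrame:
    """Frame spanning eye to malleolus, width a preset fraction of the span,
    horizontally centred on the silhouette centroid."""
    if not 0.0 < frame_fraction <= 1.0:
        raise InvalidArgumentError("frame_fraction must be in (0, 1]")
    mask = sil.mask
    if lm.malleolus_row >= sil.height:
        raise InvalidArgumentError("landmarks exceed image bounds")
    span = lm.span
    fw = int(round(frame_fraction * span))
    col_mass = mask.sum(axis=0)
    centroid = float(np.average(np.arange(sil.width), weights=col_mass))
    left = int(round(centroid - fw / 2.0))
    right = left + fw
    left_c, right_c = max(left, 0), min(right, sil.width)
    window = mask[lm.eye_row : lm.malleolus_row]
    occupied = np.flatnonzero(window.any(axis=0))
    if occupied.size and (occupied[0] < left_c or occupied[-1] >= right_c):
        raise FrameOverflowError(
            f"silhouette spans columns [{occupied[0]}, {occupied[-1]}] but frame "
            f"is [{left_c}, {right_c}); raise frame_fraction above {frame_fraction}"
        )
    return VirtualFrame(
        top_row=lm.eye_row, bottom_row=lm.malleolus_row,
        left_col=left_c, right_col=right_c,
    )


def occupancy_ratio(
    sil: BinarySilhouette, frame: VirtualFrame, mode: str = "ratio"
) -> float:
    """Pixel occupancy inside the frame.

    ``ratio``: foreground count / background count (white over black);
    ``fraction``: foreground count / all frame pixels.
    """
    if mode not in ("ratio", "fraction"):
        raise InvalidArgumentError("mode must be 'ratio' or 'fraction'")
    window = sil.mask[frame.top_row : frame.bottom_row, frame.left_col : frame.right_col]
    fg = int(window.sum())
    total = window.size
    if mode == "fraction":
        if total == 0:
            raise DegenerateFrameError("frame contains no pixels")
        return fg / total
    bg = total - fg
    if bg == 0:
        raise DegenerateFrameError("frame contains no background pixels")
    return fg / bg


def site_widths(sil: BinarySilhouette, lm: LandmarkSet) -> dict[str, float]:
    """Foreground run length at each site row, normalised by the span."""
    span = lm.span
    out = {}
    for site in SITES:
        w = int(sil.mask[lm.site_row(site)].sum())
        if w == 0:
            raise LandmarkFailureError(f"no foreground pixels on the {site} row")
        out[site] = w / span
    return out


def extract_features(
    sil: BinarySilhouette,
    lm: LandmarkSet,
    frame: VirtualFrame,
    gender: str,
    stature_cm: float | None = None,
    occupancy_mode: str = "ratio",
) -> FeatureVector:
    """Assemble the dimensionless shape features for one subject.

    Pure composition of the operations above; body weight cannot be
    attached (there is no field for it).
    """
    if frame.top_row != lm.eye_row or frame.bottom_row != lm.malleolus_row:
        raise InvalidArgumentError("frame was not built from these landmarks")
    widths = site_widths(sil, lm)
    return FeatureVector(
        occupancy_ratio=occupancy_ratio(sil, frame, occupancy_mode),
        width_chest=widths["chest"],
        width_belly=widths["belly"],
        width_thigh=widths["thigh"],
        width_calf=widths["calf"],
        span_px=lm.span,
        gender=gender,
        stature_cm=stature_cm,
    )


def features_from_mask(
    mask: np.ndarray,
    gender: str,
    stature_cm: float | None = None,
    config: GeometryConfig = GeometryConfig(),
) -> FeatureVector:
    """Convenience path: landmarks + frame + features from a raw mask."""
    sil = BinarySilhouette(mask=np.asarray(mask, dtype=bool))
    lm = detect_landmarks(sil, config)
    frame = build_virtual_frame(lm, sil, config.frame_fraction)
    return extract_features(
        sil, lm, frame, gender, stature_cm, config.occupancy_mode
    )
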