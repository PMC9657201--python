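"""Silhouette conditioning: resolution standardisation, binarisation, QC.

The input contract is a high-contrast raster (the synthetic renders, or
any photograph already reduced to figure-on-background). Conditioning
produces the canonical silhouette — a single, hole-free foreground
component on a clean background — and the acquisition quality-control
report. Arbitrary-background photographs are out of scope: segmentation
here is threshold-based and assumes separable intensities.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from . import _profiles
from .errors import (
    DegenerateInputError,
    FramingError,
    InvalidArgumentError,
    InvalidInputError,
    NoSubjectError,
)

__all__ = [
    "BinarySilhouette",
    "QCConfig",
    "QCReport",
    "standardize_resolution",
    "binarize",
    "quality_check",
    "read_image",
    "write_silhouette",
]

QC_CHECKS = (
    "head_not_horizontal",
    "arm_not_alongside",
    "legs_not_aligned",
    "subject_too_small",
    "touching_border",
    "multiple_bodies",
)


@dataclass(frozen=True)
class BinarySilhouette:
    """Conditioned white-on-black body mask (True = body, row 0 = top)."""

    mask: np.ndarray

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @classmethod
    def from_mask(
        cls, mask: np.ndarray, allow_bottom_contact: bool = False
    ) -> "BinarySilhouette":
        """Validate the silhouette invariants before wrapping the mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 2:
            raise InvalidInputError("mask must be 2D")
        if not mask.any():
            raise NoSubjectError("mask has no foreground")
        n_comp = int(label(mask, connectivity=2).max())
        if n_comp != 1:
            raise InvalidInputError(
                f"expected exactly one connected component, found {n_comp}"
            )
        if mask[0].any() or mask[:, 0].any() or mask[:, -1].any():
            raise FramingError("silhouette touches the top or a lateral border")
        if mask[-1].any() and not allow_bottom_contact:
            raise FramingError("silhouette touches the bottom border")
        return cls(mask=mask)


def read_image(path) -> np.ndarray:
    """Load a PNG/PGM image as 2D uint8 grayscale."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def write_silhouette(sil: BinarySilhouette, path) -> None:
    """Export the conditioned silhouette as 8-bit PNG (255 on 0)."""
    Image.fromarray(np.where(sil.mask, 255, 0).astype(np.uint8)).save(path)


def standardize_resolution(image: np.ndarray, target_pixels: int = 5_000_000) -> np.ndarray:
    """Rescale to the standard pixel count, preserving aspect ratio.

    The camera standardisation step: every input is brought to a single
    homogeneous resolution (default 5 MP) before analysis. Idempotent when
    the input already has the target size.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise InvalidInputError("expected a 2D grayscale image")
    h, w = img.shape
    if h == 0 or w == 0:
        raise InvalidInputError("zero-size image")
    scale = np.sqrt(target_pixels / (h * w))
    nh, nw = int(round(h * scale)), int(round(w * scale))
    if (nh, nw) == (h, w):
        return img
    pil = Image.fromarray(img.astype(np.uint8))
    return np.asarray(pil.resize((nw, nh), Image.LANCZOS))


def binarize(
    image: np.ndarray,
    threshold="otsu",
    foreground: str = "bright",
    allow_bottom_contact: bool = False,
) -> BinarySilhouette:
    """Threshold an image into the conditioned silhouette.

    After thresholding (fixed value or Otsu), only the largest 8-connected
    component is kept and its interior holes are filled, yielding the
    single homogeneous silhouette. ``foreground`` selects which intensity
    side is body ("bright" or "dark").
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.size == 0:
        raise InvalidInputError("empty image")
    if foreground not in ("bright", "dark"):
        raise InvalidArgumentError("foreground must be 'bright' or 'dark'")
    thr = threshold_otsu(img) if threshold == "otsu" else float(threshold)
    raw = img > thr if foreground == "bright" else img < thr
    if not raw.any():
        raise NoSubjectError("no foreground pixels after thresholding")
    labels, n = label(raw, connectivity=2, return_num=True)
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        raw = labels == (int(np.argmax(sizes)) + 1)
    filled = ndimage.binary_fill_holes(raw)
    if filled[0].any() or filled[:, 0].any() or filled[:, -1].any():
        raise FramingError("subject touches the top or a lateral image border")
    if filled[-1].any() and not allow_bottom_contact:
        raise FramingError("subject touches the bottom image border")
    return BinarySilhouette(mask=filled)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCConfig:
    """Acquisition-rule tolerances. The rules mirror an operator-facing
    checklist (head level, arms alongside, legs together, subject large
    enough, fully in frame); the numeric tolerances are package defaults,
    not published values."""

    max_head_tilt_deg: float = 8.0
    min_span_fraction: float = 0.5   # eye-to-malleolus span / image height
    arm_run_fraction: float = 0.10   # tolerated multi-run rows in the torso band
    leg_run_fraction: float = 0.15   # tolerated multi-run rows below the thigh
    allow_bottom_contact: bool = False


@dataclass(frozen=True)
class QCReport:
    passed: bool
    failures: tuple[str, ...]
    metrics: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"passed": self.passed, "failures": list(self.failures),
                 "metrics": self.metrics},
                fh, indent=2, sort_keys=True,
            )


def _head_tilt_deg(mask: np.ndarray, top: int, neck: int) -> float:
    """Angle of the head region's principal axis from vertical, degrees."""
    ys, xs = np.nonzero(mask[top : neck + 1])
    if ys.size < 10:
        return 0.0
    cov = np.cov(np.vstack([ys.astype(float), xs.astype(float)]))
    vals, vecs = np.linalg.eigh(cov)
    vy, vx = vecs[:, int(np.argmax(vals))]
    return float(np.degrees(np.arctan2(abs(vx), abs(vy))))


def quality_check(sil: BinarySilhouette, config: QCConfig = QCConfig()) -> QCReport:
    """Run all acquisition checks; every violated rule is reported.

    Checks never raise on degenerate input — a silhouette the checks
    cannot measure is itself a failure.
    """
    mask = np.asarray(sil.mask, dtype=bool)
    failures: list[str] = []
    metrics: dict[str, float] = {}

    n_comp = int(label(mask, connectivity=2).max())
    metrics["n_components"] = float(n_comp)
    if n_comp == 0:
        return QCReport(False, ("subject_too_small",), metrics)
    if n_comp > 1:
        failures.append("multiple_bodies")

    touches = bool(mask[0].any() or mask[:, 0].any() or mask[:, -1].any())
    if not config.allow_bottom_contact:
        touches = touches or bool(mask[-1].any())
    metrics["touching_border"] = float(touches)
    if touches:
        failures.append("touching_border")

    try:
        top, bottom = _profiles.body_bounds(mask)
        neck = _profiles.neck_row(mask, top, bottom)
        eye = _profiles.eye_row_estimate(top, neck)
        malleolus = _profiles.malleolus_row_estimate(top, bottom)
    except DegenerateInputError:
        failures.append("subject_too_small")
        return QCReport(False, tuple(failures), metrics)
    body_h = bottom - top + 1

    span_frac = (malleolus - eye) / mask.shape[0]
    metrics["span_fraction"] = float(span_frac)
    if span_frac < config.min_span_fraction:
        failures.append("subject_too_small")

    tilt = _head_tilt_deg(mask, top, neck)
    metrics["head_tilt_deg"] = tilt
    if tilt > config.max_head_tilt_deg:
        failures.append("head_not_horizontal")

    runs = _profiles.runs_per_row(mask)
    # torso band: below the neck, above the belly region
    band_lo = neck
    band_hi = top + int(round(0.45 * body_h))
    band = runs[band_lo:band_hi]
    arm_frac = float((band > 1).mean()) if band.size else 0.0
    metrics["arm_multirun_fraction"] = arm_frac
    if arm_frac > config.arm_run_fraction:
        failures.append("arm_not_alongside")

    leg_lo = top + int(round(0.62 * body_h))
    legs = runs[leg_lo : bottom + 1]
    leg_frac = float((legs > 1).mean()) if legs.size else 0.0
    metrics["leg_multirun_fraction"] = leg_frac
    if leg_frac > config.leg_run_fraction:
        failures.append("legs_not_aligned")

    return QCReport(passed=not failures, failures=tuple(failures), metrics=metrics)
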