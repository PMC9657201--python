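"""Parametric synthetic cohort of lateral body silhouettes.

This module generates everything a desk validation of the single-image
silhouette method needs: body-composition records drawn from configurable
per-gender distributions, rendered lateral silhouette images with exact
ground-truth landmark rows and shape features, and deliberately
non-compliant renders for exercising acquisition quality control.

The generative model is intentionally simple and fully documented:

* Fat mass and abdominal fat mass follow a truncated bivariate lognormal
  law (Gaussian copula on the log scale). The pre-truncation parameters
  are moment-calibrated so that the post-truncation mean and SD equal the
  configured targets.
* Stature and body weight are normals truncated at +/- 3 SD; weight is
  rank-correlated with fat mass through the same copula. Weight is carried
  on each record but is never a model predictor.
* Shape is a linear map from (fat mass, abdominal fat mass) to the
  sagittal depth of eight body segments, plus additive Gaussian segment
  noise representing individual build. Depths increase strictly with fat
  mass, and the belly depth additionally with abdominal fat mass.
* A body is rendered as a single vertical column whose per-row width
  follows a monotone (PCHIP) interpolation through segment keypoints, so
  the anatomical sites (chest, belly, thigh, calf) are exact local width
  extrema at known row positions.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
import numpy as np
from scipy import optimize, stats
from scipy.interpolate import PchipInterpolator

from .errors import InvalidArgumentError, RenderingBoundsError

__all__ = [
    "BodyParams",
    "RenderSpec",
    "GroundTruth",
    "GenderDistribution",
    "CohortConfig",
    "DEFAULT_COHORT_CONFIG",
    "segment_depths",
    "sample_cohort",
    "render_silhouette",
    "render_qc_violation",
    "synthesize_reference",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_ground_truth_csv",
    "QC_VIOLATIONS",
]

SEGMENTS = ("head", "neck", "chest", "belly", "hip", "thigh", "calf", "ankle")

# Linear shape map: segment sagittal depth [cm] =
#     base + c_fm * fm_total + c_ab * fm_abdominal
DEPTH_MAP: dict[str, tuple[float, float, float]] = {
    "head": (18.5, 0.02, 0.0),
    "neck": (10.0, 0.06, 0.0),
    "chest": (19.0, 0.22, 0.10),
    "belly": (15.0, 0.22, 1.20),
    "hip": (17.0, 0.20, 0.0),
    "thigh": (12.0, 0.16, 0.0),
    "calf": (9.5, 0.09, 0.0),
    "ankle": (6.5, 0.02, 0.0),
}

# Vertical anatomy in fractions of stature (0 = crown, 1 = sole).
NECK_T = 0.155          # minimum-width row defining head height
EYE_T = 0.4 * NECK_T    # eye line at 40% of head height
MALLEOLUS_T = 0.98      # 2% of body height above the sole
_SPAN_T = MALLEOLUS_T - EYE_T
SITE_FRACTIONS = {"chest": 0.22, "belly": 0.38, "thigh": 0.60, "calf": 0.82}
SITE_T = {s: EYE_T + f * _SPAN_T for s, f in SITE_FRACTIONS.items()}

QC_VIOLATIONS = (
    "tilted_head",
    "arm_raised",
    "legs_apart",
    "subject_too_small",
    "touching_border",
)


@dataclass(frozen=True)
class BodyParams:
    """One subject: composition record plus derived segment depths."""

    subject_id: str
    gender: str  # "female" | "male"
    stature: float  # cm
    weight: float  # kg, carried but never a predictor
    fm_total: float  # kg
    fm_abdominal: float  # kg, lumbar 2-5 region
    segment_thicknesses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.gender not in ("female", "male"):
            raise InvalidArgumentError(f"unknown gender {self.gender!r}")
        if not (self.fm_total > 0 and self.fm_abdominal > 0):
            raise InvalidArgumentError("fat masses must be strictly positive")
        if not self.fm_abdominal < self.fm_total:
            raise InvalidArgumentError("abdominal fat mass must be below total")
        if not self.stature > 0:
            raise InvalidArgumentError("stature must be positive")
        if not self.segment_thicknesses:
            object.__setattr__(
                self,
                "segment_thicknesses",
                segment_depths(self.fm_total, self.fm_abdominal),
            )
        for seg, d in self.segment_thicknesses.items():
            if not d > 0:
                raise InvalidArgumentError(f"segment {seg!r} depth must be positive")


def segment_depths(
    fm_total: float,
    fm_abdominal: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Sagittal segment depths [cm] from the linear shape map.

    ``noise_sd`` adds independent Gaussian build noise per segment,
    clipped so depths stay strictly positive.
    """
    out = {}
    noise = (
        rng.normal(0.0, noise_sd, size=len(SEGMENTS))
        if (noise_sd > 0 and rng is not None)
        else np.zeros(len(SEGMENTS))
    )
    for seg, eps in zip(SEGMENTS, noise):
        base, c_fm, c_ab = DEPTH_MAP[seg]
        d = base + c_fm * fm_total + c_ab * fm_abdominal + eps
        out[seg] = float(max(d, 1.0))
    return out


# ---------------------------------------------------------------------------
# cohort distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenderDistribution:
    """Marginal targets for one gender (means/SDs on the natural scale)."""

    stature_mean: float
    stature_sd: float
    weight_mean: float
    weight_sd: float
    fm_mean: float
    fm_sd: float
    fm_range: tuple[float, float]
    fm_abdominal_mean: float
    fm_abdominal_sd: float
    fm_abdominal_range: tuple[float, float]


@dataclass(frozen=True)
class CohortConfig:
    female: GenderDistribution
    male: GenderDistribution
    fm_abdominal_corr: float = 0.9   # latent (log-scale) correlation
    weight_fm_corr: float = 0.75     # latent correlation, weight vs fat mass
    segment_noise_sd: float = 0.25   # cm, per-segment build noise

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = json.load(fh)
        for g in ("female", "male"):
            d[g]["fm_range"] = tuple(d[g]["fm_range"])
            d[g]["fm_abdominal_range"] = tuple(d[g]["fm_abdominal_range"])
            d[g] = GenderDistribution(**d[g])
        return cls(**d)


DEFAULT_COHORT_CONFIG = CohortConfig(
    female=GenderDistribution(
        stature_mean=163.6, stature_sd=6.7,
        weight_mean=66.8, weight_sd=13.1,
        fm_mean=22.8, fm_sd=10.9, fm_range=(8.6, 59.2),
        fm_abdominal_mean=2.45, fm_abdominal_sd=2.0,
        fm_abdominal_range=(0.24, 6.9),
    ),
    male=GenderDistribution(
        stature_mean=178.8, stature_sd=7.0,
        weight_mean=80.1, weight_sd=11.5,
        fm_mean=17.0, fm_sd=7.5, fm_range=(6.2, 33.0),
        fm_abdominal_mean=1.94, fm_abdominal_sd=1.41,
        fm_abdominal_range=(0.35, 5.0),
    ),
)


def _log_ndtr_diff(b, a):
    """log(Phi(b) - Phi(a)) for b > a, stable in both tails."""
    from scipy.special import log_ndtr

    if a > 0.0:  # reflect: Phi(b) - Phi(a) = Phi(-a) - Phi(-b)
        big, small = log_ndtr(-a), log_ndtr(-b)
    else:
        big, small = log_ndtr(b), log_ndtr(a)
    d = min(small - big, -1e-17)
    return big + np.log1p(-np.exp(d))


def _trunc_lognorm_moments(mu, sigma, lo, hi):
    """Mean and SD of a lognormal truncated to [lo, hi] (closed form,
    evaluated in log space so extreme parameters stay finite)."""
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    log_z = _log_ndtr_diff(b, a)

    def raw(k):
        expo = (
            k * mu + 0.5 * k * k * sigma * sigma
            + _log_ndtr_diff(b - k * sigma, a - k * sigma) - log_z
        )
        return np.exp(expo)  # bounded in [lo**k, hi**k]

    m1 = raw(1)
    m2 = raw(2)
    return m1, np.sqrt(max(m2 - m1 * m1, 1e-12))


_CALIB_CACHE: dict[tuple, tuple[float, float]] = {}


def _calibrated_lognorm(mean, sd, lo, hi) -> tuple[float, float]:
    """(mu, sigma) whose [lo, hi]-truncated lognormal matches mean/sd."""
    key = (mean, sd, lo, hi)
    if key in _CALIB_CACHE:
        return _CALIB_CACHE[key]
    if not lo < mean < hi:
        raise InvalidArgumentError("target mean outside the truncation range")

    def mu_for_mean(sigma: float) -> float:
        # truncated mean is monotone increasing in mu with limits (lo, hi)
        return optimize.brentq(
            lambda mu: _trunc_lognorm_moments(mu, sigma, lo, hi)[0] - mean,
            np.log(lo) - 6.0 * sigma - 1.0,
            np.log(hi) + 6.0 * sigma + 1.0,
            xtol=1e-12,
        )

    def sd_at(sigma: float) -> float:
        return _trunc_lognorm_moments(mu_for_mean(sigma), sigma, lo, hi)[1]

    # the mean is matched exactly for every sigma; pick the smallest sigma
    # whose truncated SD reaches the target, or the SD-maximising sigma if
    # the target exceeds what the truncated family can produce
    grid = np.linspace(0.02, 3.0, 60)
    sds = np.array([sd_at(s) for s in grid])
    above = np.flatnonzero(sds >= sd)
    if above.size:
        i = above[0]
        sigma = (
            grid[0]
            if i == 0
            else optimize.brentq(lambda s: sd_at(s) - sd, grid[i - 1], grid[i],
                                 xtol=1e-12)
        )
    else:
        sigma = float(grid[int(np.argmax(sds))])
    mu = mu_for_mean(sigma)
    _CALIB_CACHE[key] = (mu, sigma)
    return mu, sigma


def _trunc_lognorm_ppf(u, mu, sigma, lo, hi):
    """Quantile function of the [lo, hi]-truncated lognormal."""
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    ca, cb = stats.norm.cdf(a), stats.norm.cdf(b)
    return np.exp(mu + sigma * stats.norm.ppf(ca + u * (cb - ca)))


def _sample_gender(
    n: int, gd: GenderDistribution, cfg: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """(n, 4) array of [stature, weight, fm_total, fm_abdominal].

    Gaussian copula with exact (inverse-CDF) truncated marginals: the
    configured marginal law holds by construction whatever the latent
    correlations. The only rejection is the rare fm_abdominal >= fm_total
    pair.
    """
    mu1, s1 = _calibrated_lognorm(gd.fm_mean, gd.fm_sd, *gd.fm_range)
    mu2, s2 = _calibrated_lognorm(
        gd.fm_abdominal_mean, gd.fm_abdominal_sd, *gd.fm_abdominal_range
    )
    r_ab = cfg.fm_abdominal_corr
    r_w = cfg.weight_fm_corr
    corr = np.array(
        [  # latent order: fm, fm_ab, weight
            [1.0, r_ab, r_w],
            [r_ab, 1.0, r_ab * r_w],
            [r_w, r_ab * r_w, 1.0],
        ]
    )
    chol = np.linalg.cholesky(corr)

    out = np.empty((n, 4))
    filled = 0
    while filled < n:
        m = max(n - filled, 64)
        z = rng.standard_normal((m, 3)) @ chol.T
        u = stats.norm.cdf(z)
        fm = _trunc_lognorm_ppf(u[:, 0], mu1, s1, *gd.fm_range)
        ab = _trunc_lognorm_ppf(u[:, 1], mu2, s2, *gd.fm_abdominal_range)
        weight = stats.truncnorm.ppf(
            u[:, 2], -3, 3, loc=gd.weight_mean, scale=gd.weight_sd
        )
        stature = stats.truncnorm.rvs(
            -3, 3, loc=gd.stature_mean, scale=gd.stature_sd,
            size=m, random_state=rng,
        )
        ok = ab < fm
        take = min(int(ok.sum()), n - filled)
        sel = np.flatnonzero(ok)[:take]
        out[filled : filled + take, 0] = stature[sel]
        out[filled : filled + take, 1] = weight[sel]
        out[filled : filled + take, 2] = fm[sel]
        out[filled : filled + take, 3] = ab[sel]
        filled += take
    return out


def sample_cohort(
    n: int,
    female_fraction: float = 0.53,
    seed: int = 0,
    config: CohortConfig = DEFAULT_COHORT_CONFIG,
) -> list[BodyParams]:
    """Draw ``n`` subjects with per-gender marginals from ``config``.

    Deterministic given ``seed``. The female count is ``round(n * female_fraction)``.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    if not 0.0 <= female_fraction <= 1.0:
        raise InvalidArgumentError(
            f"female_fraction must be in [0, 1], got {female_fraction}"
        )
    n_f = int(round(n * female_fraction))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cohort: list[BodyParams] = []
    for gender, count, prefix in (("female", n_f, "F"), ("male", n - n_f, "M")):
        if count == 0:
            continue
        gd = getattr(config, gender)
        vals = _sample_gender(count, gd, config, rng)
        for i in range(count):
            stature, weight, fm, ab = vals[i]
            depths = segment_depths(fm, ab, config.segment_noise_sd, rng)
            cohort.append(
                BodyParams(
                    subject_id=f"{prefix}{i + 1:04d}",
                    gender=gender,
                    stature=float(stature),
                    weight=float(weight),
                    fm_total=float(fm),
                    fm_abdominal=float(ab),
                    segment_thicknesses=depths,
                )
            )
    return cohort


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderSpec:
    """Raster geometry and perturbation scale for one render."""

    image_width: int
    image_height: int
    pixels_per_cm: float
    pose_jitter: float = 0.0  # SD of per-keypoint depth multipliers
    foreground_value: int = 255
    background_value: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.image_width < 8 or self.image_height < 8:
            raise InvalidArgumentError("image must be at least 8x8")
        if self.foreground_value == self.background_value:
            raise InvalidArgumentError("foreground and background values must differ")
        if self.pixels_per_cm <= 0:
            raise InvalidArgumentError("pixels_per_cm must be positive")

    @classmethod
    def for_megapixels(
        cls,
        megapixels: float,
        max_stature_cm: float = 205.0,
        fill: float = 0.9,
        aspect: float = 0.5,
        pose_jitter: float = 0.0,
        seed: int = 0,
    ) -> "RenderSpec":
        """Portrait spec sized so a ``max_stature_cm`` body fills ``fill`` of the height."""
        h = int(round(np.sqrt(megapixels * 1e6 / aspect)))
        w = int(round(aspect * h))
        return cls(
            image_width=w,
            image_height=h,
            pixels_per_cm=fill * h / max_stature_cm,
            pose_jitter=pose_jitter,
            seed=seed,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Exact landmark rows and features for one rendered silhouette."""

    eye_row: int
    chest_row: int
    belly_row: int
    thigh_row: int
    calf_row: int
    malleolus_row: int
    true_features: dict[str, float]

    def rows(self) -> dict[str, int]:
        return {
            "eye": self.eye_row,
            "chest": self.chest_row,
            "belly": self.belly_row,
            "thigh": self.thigh_row,
            "calf": self.calf_row,
            "malleolus": self.malleolus_row,
        }


def _keypoints(depths: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    """Knot positions (stature fraction) and widths (cm) of the outline."""
    d = depths
    pts = [
        (0.000, 0.55 * d["head"]),
        (0.028, 0.85 * d["head"]),
        (EYE_T, d["head"]),
        (0.105, 0.80 * d["head"]),
        (NECK_T, d["neck"]),
        (0.200, d["neck"] + 0.55 * (d["chest"] - d["neck"])),
        (SITE_T["chest"], d["chest"]),
        (0.335, 0.90 * min(d["chest"], d["belly"])),
        (SITE_T["belly"], d["belly"]),
        (0.447, 0.93 * min(d["belly"], d["hip"])),
        (0.480, d["hip"]),
        (0.545, 0.85 * min(d["hip"], d["thigh"])),
        (SITE_T["thigh"], d["thigh"]),
        (0.700, 0.72 * min(d["thigh"], d["calf"])),
        (SITE_T["calf"], d["calf"]),
        (0.930, d["ankle"]),
    ]
    # flank each measurement site so its width maximum is locally symmetric
    # (keeps the discrete extremal run centred on the true site row)
    for site in ("chest", "belly", "thigh", "calf"):
        for dt in (-0.018, 0.018):
            pts.append((SITE_T[site] + dt, 0.99 * d[site]))
    pts += [
        (MALLEOLUS_T, 1.02 * d["ankle"]),
        (1.000, 1.10 * d["ankle"]),
    ]
    pts.sort(key=lambda p: p[0])
    t = np.array([p[0] for p in pts])
    w = np.array([p[1] for p in pts])
    return t, w


_LEG_SPLIT_T = 0.55
_ARM_T0, _ARM_T1 = 0.21, 0.45


def _render_mask(
    params: BodyParams,
    spec: RenderSpec,
    *,
    head_shear_deg: float = 0.0,
    arm_raised: bool = False,
    legs_offset_cm: float = 0.0,
    scale: float = 1.0,
    top_margin_zero: bool = False,
) -> tuple[np.ndarray, float, float]:
    """Rasterize the body. Returns (mask, body_top, body_height_px)."""
    ppcm = spec.pixels_per_cm * scale
    h_px = params.stature * ppcm
    H, W = spec.image_height, spec.image_width
    if h_px > H - 2:
        raise RenderingBoundsError(
            f"body height {h_px:.0f}px exceeds image height {H}px"
        )
    body_top = 0.0 if top_margin_zero else (H - h_px) / 2.0

    t_knots, w_knots = _keypoints(params.segment_thicknesses)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    lean = 0.0
    if spec.pose_jitter > 0:
        w_knots = w_knots * (1.0 + spec.pose_jitter * rng.standard_normal(w_knots.size))
        lean = np.deg2rad(50.0 * spec.pose_jitter * rng.standard_normal())
    profile = PchipInterpolator(t_knots, np.maximum(w_knots, 0.5))

    rows = np.arange(H)
    t = (rows + 0.5 - body_top) / h_px
    inside = (t >= 0.0) & (t < 1.0)
    r_in = rows[inside]
    t_in = t[inside]
    hw = profile(t_in) * ppcm / 2.0
    cx = W / 2.0
    # lean pivots at the feet
    off = np.tan(lean) * (body_top + h_px - (r_in + 0.5))
    if head_shear_deg:
        shear = np.tan(np.deg2rad(head_shear_deg))
        head = t_in < NECK_T
        off = off + np.where(head, shear * (NECK_T - t_in) * h_px, 0.0)

    mask = np.zeros((H, W), dtype=bool)
    centers = cx + off

    def fill(row, c, half):
        # exact-width fill: the run length is round(2*half) so the
        # per-row quantisation error never exceeds half a pixel
        w_px = int(round(2.0 * half))
        lo = int(round(c - w_px / 2.0))
        mask[row, max(lo, 0) : max(lo + w_px, 0)] = True

    for r, c, half, tt in zip(r_in, centers, hw, t_in):
        if legs_offset_cm > 0 and tt >= _LEG_SPLIT_T:
            for leg_c in (c - legs_offset_cm * ppcm, c + legs_offset_cm * ppcm):
                fill(r, leg_c, 0.55 * half)
        else:
            fill(r, c, half)

    if arm_raised:
        # arm strip leaving the torso at the shoulder, angled forward/down
        shoulder_hw = profile(_ARM_T0) * ppcm / 2.0
        reach_px = 15.0 * ppcm
        sel = (t_in >= _ARM_T0) & (t_in <= _ARM_T1)
        frac = (t_in[sel] - _ARM_T0) / (_ARM_T1 - _ARM_T0)
        arm_c = centers[sel] + (shoulder_hw - 2.0 * ppcm) + frac * reach_px
        for r, c in zip(r_in[sel], arm_c):
            fill(r, c, 1.5 * ppcm)

    if mask[:, 0].any() or mask[:, -1].any():
        raise RenderingBoundsError("silhouette reaches a lateral image border")
    return mask, body_top, h_px


def _gt_row(body_top: float, h_px: float, t: float) -> int:
    return int(round(body_top + t * h_px - 0.5))


def _true_features(
    mask: np.ndarray, body_top: float, h_px: float, frame_fraction: float
) -> tuple[dict[str, int], dict[str, float]]:
    """Landmark rows and exact occupancy/width features of a rendered mask."""
    rows = {
        "eye": _gt_row(body_top, h_px, EYE_T),
        "malleolus": _gt_row(body_top, h_px, MALLEOLUS_T),
    }
    for site, tt in SITE_T.items():
        rows[site] = _gt_row(body_top, h_px, tt)
    span = rows["malleolus"] - rows["eye"]
    feats: dict[str, float] = {}
    for site in ("chest", "belly", "thigh", "calf"):
        feats[f"width_{site}"] = float(mask[rows[site]].sum()) / span
    # occupancy inside the eye-to-malleolus frame, centred on the centroid
    centroid = float(np.average(np.arange(mask.shape[1]), weights=mask.sum(axis=0)))
    fw = int(round(frame_fraction * span))
    left = int(round(centroid - fw / 2.0))
    right = left + fw
    window = mask[rows["eye"] : rows["malleolus"], left:right]
    fg = int(window.sum())
    bg = window.size - fg
    feats["occupancy_ratio"] = fg / bg
    return rows, feats


def render_silhouette(
    params: BodyParams,
    spec: RenderSpec,
    frame_fraction: float = 0.4,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one compliant lateral silhouette with exact ground truth.

    Returns an 8-bit image (``foreground_value`` on ``background_value``)
    and the GroundTruth holding landmark rows and the exact occupancy and
    site-width features of the rendered outline.
    """
    mask, body_top, h_px = _render_mask(params, spec)
    rows, feats = _true_features(mask, body_top, h_px, frame_fraction)
    gt = GroundTruth(
        eye_row=rows["eye"],
        chest_row=rows["chest"],
        belly_row=rows["belly"],
        thigh_row=rows["thigh"],
        calf_row=rows["calf"],
        malleolus_row=rows["malleolus"],
        true_features=feats,
    )
    img = np.where(mask, spec.foreground_value, spec.background_value).astype(np.uint8)
    return img, gt


def render_qc_violation(
    params: BodyParams, spec: RenderSpec, violation: str
) -> np.ndarray:
    """Render a silhouette violating exactly one acquisition rule."""
    if violation not in QC_VIOLATIONS:
        raise InvalidArgumentError(
            f"unknown violation {violation!r}; expected one of {QC_VIOLATIONS}"
        )
    kwargs = {
        "tilted_head": {"head_shear_deg": 15.0},
        "arm_raised": {"arm_raised": True},
        "legs_apart": {"legs_offset_cm": 6.0},
        "subject_too_small": {"scale": 0.5},
        "touching_border": {"top_margin_zero": True},
    }[violation]
    mask, _, _ = _render_mask(params, spec, **kwargs)
    return np.where(mask, spec.foreground_value, spec.background_value).astype(np.uint8)


# ---------------------------------------------------------------------------
# reference synthesis and IO
# ---------------------------------------------------------------------------


def synthesize_reference(
    feature_matrix: np.ndarray,
    coefficients: np.ndarray,
    intercept: float,
    noise_sd: float,
    seed: int = 0,
) -> np.ndarray:
    """Reference values that are exactly linear in the given features.

    Used by parameter-recovery studies: the returned vector is
    ``intercept + X @ coefficients + N(0, noise_sd)``, so an ordinary
    least-squares fit has a well-defined generating truth in feature
    space. ``noise_sd=0`` gives the exact-recovery limit.
    """
    X = np.asarray(feature_matrix, dtype=float)
    beta = np.asarray(coefficients, dtype=float)
    y = intercept + X @ beta
    if noise_sd > 0:
        y = y + np.random.default_rng(np.random.SeedSequence(seed)).normal(
            0.0, noise_sd, size=y.shape
        )
    return y


_COHORT_COLS = [
    "subject_id", "gender", "stature_cm", "weight_kg",
    "fm_total_kg", "fm_abdominal_kg", "image_path",
]


def write_cohort_csv(cohort, path, image_paths=None):
    """Cohort table with the standard column layout."""
    import pandas as pd

    if image_paths is None:
        image_paths = [""] * len(cohort)
    df = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in cohort],
            "gender": [p.gender for p in cohort],
            "stature_cm": [p.stature for p in cohort],
            "weight_kg": [p.weight for p in cohort],
            "fm_total_kg": [p.fm_total for p in cohort],
            "fm_abdominal_kg": [p.fm_abdominal for p in cohort],
            "image_path": list(image_paths),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return df


def read_cohort_csv(path):
    import pandas as pd

    df = pd.read_csv(path)
    missing = set(_COHORT_COLS) - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"cohort CSV missing columns: {sorted(missing)}")
    return df


def write_ground_truth_csv(subject_ids, truths, path):
    """Sidecar CSV of true landmark rows per subject."""
    import pandas as pd

    rows = []
    for sid, gt in zip(subject_ids, truths):
        rows.append(
            {
                "subject_id": sid,
                "eye_row": gt.eye_row,
                "chest_row": gt.chest_row,
                "belly_row": gt.belly_row,
                "thigh_row": gt.thigh_row,
                "calf_row": gt.calf_row,
                "malleolus_row": gt.malleolus_row,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
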