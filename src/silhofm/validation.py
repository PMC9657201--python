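"""Method-agreement statistics for predicted vs reference fat mass.

The battery compares a candidate measurement against a reference on
paired data: Lin's concordance correlation coefficient (agreement with
the identity line), Bland-Altman bias and limits of agreement with a
proportional-bias test, group-level absolute and percent error, the
linearity null (slope 1, intercept 0), a paired t-test, and the
technical error of measurement (TEM) for replicate reproducibility.

Conventions: Lin's CCC uses population (1/n) moments; Bland-Altman and
TEM summaries use the sample (n-1) SD; limits of agreement are
bias +/- 1.96 SD; all tests are two-sided.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "lin_ccc",
    "bland_altman",
    "error_metrics",
    "linearity_test",
    "paired_comparison",
    "reproducibility",
    "full_report",
    "AgreementReport",
    "ReproducibilityReport",
    "BlandAltmanResult",
    "LinearityResult",
    "PairedResult",
]


def _paired(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise InvalidInputError("inputs must be 1D vectors")
    if x.shape[0] != y.shape[0]:
        raise InvalidInputError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < min_n:
        raise InvalidInputError(f"need at least {min_n} pairs, got {x.shape[0]}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("inputs contain non-finite values")
    return x, y


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2) with population (1/n)
    moments. Symmetric in its arguments; 1 only for perfect agreement
    with the identity line.
    """
    x, y = _paired(x, y, 3)
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise InvalidInputError("zero denominator: no variance and equal means")
    return float(2.0 * sxy / denom)


class BlandAltmanResult(NamedTuple):
    bias: float
    loa_low: float
    loa_high: float
    proportional_bias_slope: float
    proportional_bias_p: float


def bland_altman(pred, ref) -> BlandAltmanResult:
    """Bias, 95% limits of agreement, and the proportional-bias test.

    Differences are pred - ref; the limits are bias +/- 1.96 sample SD.
    Proportional bias is the OLS slope of the differences on the pairwise
    means, with its two-sided p-value.
    """
    pred, ref = _paired(pred, ref, 3)
    d = pred - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    means = (pred + ref) / 2.0
    if sd == 0.0 or np.ptp(means) == 0.0:
        # constant differences, or no spread to regress on: no trend
        return BlandAltmanResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, 0.0, 1.0)
    fit = stats.linregress(means, d)
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        proportional_bias_slope=float(fit.slope),
        proportional_bias_p=float(fit.pvalue),
    )


def error_metrics(pred, ref, mode: str = "group_mean") -> tuple[float, float]:
    """(absolute error [kg], percent error [%]) of the prediction.

    ``group_mean``: |mean(pred) - mean(ref)|, the group-level accuracy
    index; ``rmse``: root-mean-square paired error. Percent error is the
    absolute error over the reference mean.
    """
    if mode not in ("group_mean", "rmse"):
        raise InvalidInputError("mode must be 'group_mean' or 'rmse'")
    pred, ref = _paired(pred, ref, 1)
    if np.any(ref <= 0):
        raise InvalidInputError("reference values must be positive")
    if mode == "group_mean":
        ape = float(abs(pred.mean() - ref.mean()))
    else:
        ape = float(np.sqrt(np.mean((pred - ref) ** 2)))
    return ape, 100.0 * ape / float(ref.mean())


class LinearityResult(NamedTuple):
    slope: float
    intercept: float
    see: float
    slope_eq1_p: float
    intercept_eq0_p: float
    r2: float


def linearity_test(pred, ref) -> LinearityResult:
    """OLS of predicted on reference with the identity-line null.

    Tests slope against 1 and intercept against 0 (t with n-2 df); SEE is
    the residual SD of the regression.
    """
    pred, ref = _paired(pred, ref, 3)
    if np.ptp(ref) == 0.0:
        raise InvalidInputError("reference has zero variance")
    n = pred.shape[0]
    fit = stats.linregress(ref, pred)
    resid = pred - (fit.intercept + fit.slope * ref)
    see = float(np.sqrt(resid @ resid / (n - 2)))
    if fit.stderr == 0.0:
        slope_p = 1.0 if fit.slope == 1.0 else 0.0
    else:
        t_slope = (fit.slope - 1.0) / fit.stderr
        slope_p = float(2.0 * stats.t.sf(abs(t_slope), n - 2))
    if fit.intercept_stderr == 0.0:
        int_p = 1.0 if fit.intercept == 0.0 else 0.0
    else:
        t_int = fit.intercept / fit.intercept_stderr
        int_p = float(2.0 * stats.t.sf(abs(t_int), n - 2))
    return LinearityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        see=see,
        slope_eq1_p=slope_p,
        intercept_eq0_p=int_p,
        r2=float(fit.rvalue**2),
    )


class PairedResult(NamedTuple):
    mean_diff: float
    p: float
    degenerate: bool  # identical-pairs case: SD of differences is zero


def paired_comparison(x, y) -> PairedResult:
    """Two-sided paired t-test on x - y with n-1 df."""
    x, y = _paired(x, y, 2)
    d = x - y
    mean_diff = float(d.mean())
    sd = d.std(ddof=1)
    n = d.shape[0]
    if sd == 0.0:
        return PairedResult(mean_diff, 1.0 if mean_diff == 0.0 else 0.0, True)
    t = mean_diff / (sd / np.sqrt(n))
    return PairedResult(mean_diff, float(2.0 * stats.t.sf(abs(t), n - 1)), False)


@dataclass(frozen=True)
class ReproducibilityReport:
    """Replicate precision summary: TEM, CV, and agreement indices."""

    n: int
    mean_test1: float
    mean_test2: float
    mean_diff: float
    sd_diff: float
    cv_percent: float
    tem: float
    r2: float
    ccc: float
    p_diff: float

    def to_dict(self) -> dict:
        return asdict(self)


def reproducibility(test1, test2) -> ReproducibilityReport:
    """Precision of paired replicate measurements.

    TEM = sqrt(sum(d^2) / 2n); CV is TEM over the grand mean of both
    replicates, in percent.
    """
    t1, t2 = _paired(test1, test2, 3)
    d = t1 - t2
    n = d.shape[0]
    tem = float(np.sqrt(np.sum(d**2) / (2.0 * n)))
    grand = float(np.concatenate([t1, t2]).mean())
    if grand == 0.0:
        raise InvalidInputError("zero grand mean: CV undefined")
    if np.ptp(t1) == 0.0 and np.ptp(t2) == 0.0:
        r2 = ccc_val = 1.0 if np.array_equal(t1, t2) else 0.0
    else:
        r2 = float(stats.pearsonr(t1, t2).statistic ** 2)
        ccc_val = lin_ccc(t1, t2)
    pc = paired_comparison(t1, t2)
    return ReproducibilityReport(
        n=n,
        mean_test1=float(t1.mean()),
        mean_test2=float(t2.mean()),
        mean_diff=float(d.mean()),
        sd_diff=float(d.std(ddof=1)),
        cv_percent=100.0 * tem / abs(grand),
        tem=tem,
        r2=r2,
        ccc=ccc_val,
        p_diff=pc.p,
    )


@dataclass(frozen=True)
class AgreementReport:
    """The full agreement battery between a prediction and its reference."""

    n: int
    mean_pred: float
    mean_ref: float
    paired_t_p: float
    r2: float
    ccc: float
    see: float
    ape: float
    percent_error: float
    slope: float
    intercept: float
    slope_eq1_p: float
    intercept_eq0_p: float
    bias: float
    loa_low: float
    loa_high: float
    proportional_bias_slope: float
    proportional_bias_p: float

    def to_dict(self) -> dict:
        return asdict(self)


def full_report(pred, ref, ape_mode: str = "group_mean") -> AgreementReport:
    """Assemble every agreement statistic for paired pred/ref vectors [kg]."""
    pred, ref = _paired(pred, ref, 3)
    lin = linearity_test(pred, ref)
    ba = bland_altman(pred, ref)
    ape, pct = error_metrics(pred, ref, ape_mode)
    pc = paired_comparison(pred, ref)
    return AgreementReport(
        n=pred.shape[0],
        mean_pred=float(pred.mean()),
        mean_ref=float(ref.mean()),
        paired_t_p=pc.p,
        r2=lin.r2,
        ccc=lin_ccc(pred, ref),
        see=lin.see,
        ape=ape,
        percent_error=pct,
        slope=lin.slope,
        intercept=lin.intercept,
        slope_eq1_p=lin.slope_eq1_p,
        intercept_eq0_p=lin.intercept_eq0_p,
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        proportional_bias_slope=ba.proportional_bias_slope,
        proportional_bias_p=ba.proportional_bias_p,
    )


def plot_agreement(pred, ref, scatter_path=None, bland_altman_path=None, label="FM"):
    """Identity-line scatter and Bland-Altman plot as PNG files."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pred, ref = _paired(pred, ref, 3)
    if scatter_path is not None:
        lin = linearity_test(pred, ref)
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(ref, pred, s=18, alpha=0.7, edgecolor="none")
        lims = [min(ref.min(), pred.min()), max(ref.max(), pred.max())]
        ax.plot(lims, lims, "k--", lw=1, label="identity")
        xs = np.linspace(lims[0], lims[1], 2)
        ax.plot(xs, lin.intercept + lin.slope * xs, "r-", lw=1,
                label=f"fit: y={lin.slope:.2f}x+{lin.intercept:.2f}")
        ax.set_xlabel(f"reference {label} (kg)")
        ax.set_ylabel(f"predicted {label} (kg)")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(scatter_path, dpi=110, metadata={"Software": None})
        plt.close(fig)
    if bland_altman_path is not None:
        ba = bland_altman(pred, ref)
        means = (pred + ref) / 2.0
        d = pred - ref
        fig, ax = plt.subplots(figsize=(5.5, 4))
        ax.scatter(means, d, s=18, alpha=0.7, edgecolor="none")
        for yv, ls in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
            ax.axhline(yv, color="r", ls=ls, lw=1)
        ax.set_xlabel(f"mean of methods (kg {label})")
        ax.set_ylabel("difference, predicted - reference (kg)")
        fig.tight_layout()
        fig.savefig(bland_altman_path, dpi=110, metadata={"Software": None})
        plt.close(fig)
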