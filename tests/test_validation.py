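"""Unit and property tests for the agreement-statistics battery.

Every statistic is checked against an independent brute-force evaluation
of its defining formula (explicit sums, no library shortcuts), plus the
hand-computed worked fixtures.
"""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from silhofm.errors import InvalidInputError
from silhofm.validation import (
    bland_altman,
    error_metrics,
    full_report,
    lin_ccc,
    linearity_test,
    paired_comparison,
    reproducibility,
)

# ---------------------------------------------------------------------------
# brute-force oracles: explicit two-pass formula evaluation
# ---------------------------------------------------------------------------


def ccc_brute(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx2 = sum((v - mx) ** 2 for v in x) / n
    sy2 = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def tem_brute(t1, t2):
    d = [a - b for a, b in zip(t1, t2)]
    return math.sqrt(sum(v * v for v in d) / (2 * len(d)))


def ols_brute(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((v - mx) ** 2 for v in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    slope = sxy / sxx
    return slope, my - slope * mx


def sample_sd(v):
    n = len(v)
    m = sum(v) / n
    return math.sqrt(sum((x - m) ** 2 for x in v) / (n - 1))


def _pairs(rng, n=None):
    n = n or rng.integers(3, 40)
    y = rng.uniform(5, 50, n)  # positive, like fat mass in kg
    x = y + rng.normal(0, 3, n)
    return x, y


# ---------------------------------------------------------------------------
# Lin CCC
# ---------------------------------------------------------------------------


class TestLinCCC:
    def test_worked_fixtures(self):
        assert lin_ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0, abs=1e-15)
        assert lin_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7, abs=1e-15)
        assert lin_ccc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0, abs=1e-15)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x, y = _pairs(rng)
            assert lin_ccc(x, y) == pytest.approx(
                ccc_brute(list(x), list(y)), rel=1e-12
            )

    def test_symmetry_and_reorder_invariance(self):
        rng = np.random.default_rng(8)
        x, y = _pairs(rng, 25)
        assert lin_ccc(x, y) == pytest.approx(lin_ccc(y, x), rel=1e-13)
        perm = rng.permutation(25)
        assert lin_ccc(x[perm], y[perm]) == pytest.approx(lin_ccc(x, y), rel=1e-13)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            lin_ccc([1, 2], [1, 2])
        with pytest.raises(InvalidInputError):
            lin_ccc([1, 2, 3], [1, 2])
        with pytest.raises(InvalidInputError):
            lin_ccc([5, 5, 5], [5, 5, 5])  # zero denominator

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=30),
        st.integers(0, 10_000),
    )
    def test_bounded_by_pearson(self, xs, seed):
        """|CCC| never exceeds |Pearson r|, with equality at matched moments."""
        x = np.asarray(xs)
        rng = np.random.default_rng(seed)
        y = x * rng.uniform(0.5, 2.0) + rng.normal(0, 1, x.size)
        if x.std() == 0 or y.std() == 0:
            return
        r = np.corrcoef(x, y)[0, 1]
        assert abs(lin_ccc(x, y)) <= abs(r) + 1e-12

    def test_equals_pearson_at_equal_moments(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 500)
        y = rng.normal(0, 1, 500)
        # force exactly equal means and variances
        y = (y - y.mean()) / y.std() * x.std() + x.mean()
        r = np.corrcoef(x, y)[0, 1]
        assert lin_ccc(x, y) == pytest.approx(r, rel=1e-10)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


class TestBlandAltman:
    def test_constant_offset(self):
        ref = np.array([10.0, 20.0, 30.0, 40.0])
        ba = bland_altman(ref + 1.0, ref)
        assert ba.bias == pytest.approx(1.0)
        assert ba.loa_low == pytest.approx(1.0)
        assert ba.loa_high == pytest.approx(1.0)
        assert ba.proportional_bias_slope == 0.0

    def test_hand_computed_sd(self):
        ref = np.array([10.0, 20.0, 30.0, 40.0])
        pred = ref + np.array([1.0, -1.0, 1.0, -1.0])
        ba = bland_altman(pred, ref)
        sd = 2 / math.sqrt(3)
        assert ba.bias == pytest.approx(0.0, abs=1e-12)
        assert ba.loa_high == pytest.approx(1.96 * sd, rel=1e-12)
        assert ba.loa_low == pytest.approx(-1.96 * sd, rel=1e-12)

    def test_detects_proportional_bias(self):
        rng = np.random.default_rng(10)
        ref = rng.uniform(5, 50, 50)
        ba = bland_altman(1.1 * ref, ref)
        assert ba.proportional_bias_slope > 0
        assert ba.proportional_bias_p < 0.05

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            pred, ref = _pairs(rng)
            ba = bland_altman(pred, ref)
            d = list(pred - ref)
            bias = sum(d) / len(d)
            sd = sample_sd(d)
            assert ba.bias == pytest.approx(bias, rel=1e-12, abs=1e-12)
            assert ba.loa_high == pytest.approx(bias + 1.96 * sd, rel=1e-12)
            assert ba.loa_low == pytest.approx(bias - 1.96 * sd, rel=1e-12)
            means = [(a + b) / 2 for a, b in zip(pred, ref)]
            slope, _ = ols_brute(means, d)
            assert ba.proportional_bias_slope == pytest.approx(
                slope, rel=1e-10, abs=1e-12
            )

    def test_midpoint_is_bias(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            pred, ref = _pairs(rng)
            ba = bland_altman(pred, ref)
            assert (ba.loa_low + ba.loa_high) / 2 == pytest.approx(
                ba.bias, rel=1e-12, abs=1e-12
            )


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------


class TestErrorMetrics:
    def test_identity(self):
        ref = np.array([10.0, 20.0, 30.0])
        assert error_metrics(ref, ref) == (0.0, 0.0)

    def test_group_mean_definition(self):
        ref = np.array([12.8, 22.8, 32.8])  # mean 22.8
        pred = np.array([12.6, 22.6, 32.6])  # mean 22.6
        ape, pct = error_metrics(pred, ref)
        assert ape == pytest.approx(0.2, abs=1e-12)
        assert pct == pytest.approx(100 * 0.2 / 22.8, rel=1e-12)

    def test_rmse_mode(self):
        ref = np.array([10.0, 20.0, 30.0])
        ape, _ = error_metrics(ref + 1.0, ref, mode="rmse")
        assert ape == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            error_metrics([1.0, 2.0], [1.0, 0.0])


# ---------------------------------------------------------------------------
# linearity
# ---------------------------------------------------------------------------


class TestLinearity:
    def test_identity_line(self):
        ref = np.array([5.0, 10.0, 20.0, 35.0])
        res = linearity_test(ref, ref)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.see == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0)

    def test_rejects_doubled_slope(self):
        rng = np.random.default_rng(13)
        ref = rng.uniform(5, 40, 20)
        res = linearity_test(2.0 * ref + rng.normal(0, 0.5, 20), ref)
        assert res.slope_eq1_p < 0.01

    def test_matches_brute_force(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            pred, ref = _pairs(rng)
            res = linearity_test(pred, ref)
            slope, intercept = ols_brute(list(ref), list(pred))
            assert res.slope == pytest.approx(slope, rel=1e-10)
            assert res.intercept == pytest.approx(intercept, rel=1e-8, abs=1e-10)
            resid = [p - (intercept + slope * r) for p, r in zip(pred, ref)]
            see = math.sqrt(sum(v * v for v in resid) / (len(pred) - 2))
            assert res.see == pytest.approx(see, rel=1e-10, abs=1e-12)

    def test_type_one_error_at_noise_scale(self):
        """Under a true identity relation with 2.3 kg noise the slope test
        keeps its nominal size."""
        rng = np.random.default_rng(15)
        keep = 0
        for _ in range(100):
            ref = rng.uniform(6, 50, 200)
            pred = ref + rng.normal(0, 2.3, 200)
            if linearity_test(pred, ref).slope_eq1_p > 0.05:
                keep += 1
        assert keep >= 90

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            linearity_test([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------


class TestPairedComparison:
    def test_identical_pairs_degenerate(self):
        res = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_diff == 0.0
        assert res.p == 1.0
        assert res.degenerate

    def test_large_effect(self):
        rng = np.random.default_rng(16)
        y = rng.normal(20, 5, 100)
        d = rng.normal(1.0, 1.0, 100)
        res = paired_comparison(y + d, y)
        assert res.p < 1e-10

    def test_matches_brute_force(self):
        from scipy import stats as ss

        rng = np.random.default_rng(17)
        for _ in range(100):
            x, y = _pairs(rng)
            res = paired_comparison(x, y)
            d = x - y
            n = d.size
            t = d.mean() / (sample_sd(list(d)) / math.sqrt(n))
            p = 2 * ss.t.sf(abs(t), n - 1)
            assert res.p == pytest.approx(p, rel=1e-10)

    def test_type_one_error(self):
        rng = np.random.default_rng(18)
        rejections = sum(
            paired_comparison(rng.normal(0, 1, 50) + base, base).p < 0.05
            for base in (rng.normal(20, 5, 50) for _ in range(1000))
        )
        assert 0.03 <= rejections / 1000 <= 0.07


# ---------------------------------------------------------------------------
# reproducibility
# ---------------------------------------------------------------------------


class TestReproducibility:
    def test_identical_replicates(self):
        t = np.array([10.0, 12.0, 14.0, 16.0])
        rep = reproducibility(t, t)
        assert rep.tem == 0.0
        assert rep.cv_percent == 0.0
        assert rep.ccc == pytest.approx(1.0)

    def test_hand_computed_tem(self):
        t1 = np.array([10.5, 10.5, 10.5, 10.5])
        t2 = np.array([9.5, 9.5, 9.5, 9.5])
        rep = reproducibility(t1, t2)
        assert rep.tem == pytest.approx(math.sqrt(4 / 8), rel=1e-12)
        assert rep.cv_percent == pytest.approx(100 * math.sqrt(0.5) / 10, rel=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            t1 = rng.normal(20, 8, int(rng.integers(3, 30)))
            t2 = t1 + rng.normal(0, 0.5, t1.size)
            rep = reproducibility(t1, t2)
            assert rep.tem == pytest.approx(
                tem_brute(list(t1), list(t2)), rel=1e-12
            )
            grand = (sum(t1) + sum(t2)) / (2 * t1.size)
            assert rep.cv_percent == pytest.approx(
                100 * rep.tem / grand, rel=1e-12
            )


# ---------------------------------------------------------------------------
# assembled report
# ---------------------------------------------------------------------------


class TestFullReport:
    def test_perfect_agreement(self):
        ref = np.array([8.0, 15.0, 22.0, 30.0, 41.0])
        rep = full_report(ref, ref)
        assert rep.ccc == pytest.approx(1.0)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.ape == 0.0
        assert rep.bias == 0.0
        assert rep.loa_low == rep.loa_high == 0.0

    def test_internal_consistency(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            pred, ref = _pairs(rng, 40)
            rep = full_report(pred, ref)
            r = np.corrcoef(pred, ref)[0, 1]
            assert abs(rep.ccc) <= abs(r) + 1e-12
            assert rep.loa_low <= rep.bias <= rep.loa_high
            assert (rep.loa_low + rep.loa_high) / 2 == pytest.approx(
                rep.bias, rel=1e-12, abs=1e-12
            )
            assert -1.0 <= rep.ccc <= 1.0
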