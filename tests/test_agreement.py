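import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpree.agreement import (
    CarstensenFit,
    ConversionDirection,
    ConversionEquation,
    DegenerateDataError,
    PairedMeasurements,
    bland_altman,
    carstensen_loa,
    compare_formulas_ccc,
    conversion_equations,
    convert,
    lin_ccc,
)

import pandas as pd


def brute_force_line(x, y):
    """Least squares of y on x via hand-coded normal-equation summation."""
    n = len(x)
    sx = sum(x); sy = sum(y)
    sxx = sum(v * v for v in x); sxy = sum(a * b for a, b in zip(x, y))
    det = n * sxx - sx * sx
    b = (n * sxy - sx * sy) / det
    a = (sy - b * sx) / n
    sse = sum((yi - a - b * xi) ** 2 for xi, yi in zip(x, y))
    return a, b, (sse / (n - 2)) ** 0.5


class TestBlandAltman:
    def test_symmetric_differences_have_zero_bias(self):
        pairs = PairedMeasurements(y1=[100, 200, 150], y2=[110, 190, 150])
        result = bland_altman(pairs)
        assert result.mean_bias == pytest.approx(0.0)
        assert result.classic_loa[0] < 0 < result.classic_loa[1]

    def test_identical_methods(self):
        pairs = PairedMeasurements(y1=[100, 200, 300], y2=[100, 200, 300])
        result = bland_altman(pairs)
        assert result.mean_bias == 0
        assert result.classic_loa == (0.0, 0.0)
        assert result.pearson_r_bias_vs_mean == 0.0
        assert not result.proportional_bias

    def test_constant_averages_rejected(self):
        with pytest.raises(DegenerateDataError):
            bland_altman(PairedMeasurements(y1=[10, 20, 30], y2=[30, 20, 10]))

    def test_proportional_bias_detected_in_simulation(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(500, 1500, 200)
        d = 50 - 0.4 * a + rng.normal(0, 30, 200)
        y1 = a + d / 2
        y2 = a - d / 2
        result = bland_altman(PairedMeasurements(y1=y1, y2=y2))
        assert result.pearson_r_bias_vs_mean < -0.5
        assert result.p_value < 1e-6
        assert result.proportional_bias


class TestCarstensen:
    def test_identical_methods_give_zero_fit(self):
        fit = carstensen_loa(PairedMeasurements(y1=[1.0, 2, 3, 4], y2=[1.0, 2, 3, 4]))
        assert fit.a == pytest.approx(0, abs=1e-12)
        assert fit.b == pytest.approx(0, abs=1e-12)
        assert fit.tau == pytest.approx(0, abs=1e-12)

    def test_doubling_relation_hand_algebra(self):
        y1 = np.arange(1.0, 11.0)
        fit = carstensen_loa(PairedMeasurements(y1=y1, y2=2 * y1))
        assert fit.a == pytest.approx(0, abs=1e-9)
        assert fit.b == pytest.approx(-2 / 3, abs=1e-12)
        assert fit.tau == pytest.approx(0, abs=1e-9)

    def test_sloped_loa_reduce_to_classic_at_zero_slope(self):
        fit = CarstensenFit(a=12.0, b=0.0, tau=30.0, n=50)
        lo, hi = fit.sloped_loa(900.0)
        assert lo == pytest.approx(12 - 60)
        assert hi == pytest.approx(12 + 60)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(1)
        a_true, b_true, tau_true = 560.0, -0.52, 60.0
        avg = rng.uniform(500, 1500, 1000)
        d = a_true + b_true * avg + rng.normal(0, tau_true, 1000)
        fit = carstensen_loa(PairedMeasurements(y1=avg + d / 2, y2=avg - d / 2))
        assert fit.a == pytest.approx(a_true, rel=0.05)
        assert fit.b == pytest.approx(b_true, rel=0.05)
        assert fit.tau == pytest.approx(tau_true, rel=0.05)

    def test_agrees_with_brute_force_normal_equations(self):
        rng = np.random.default_rng(2)
        for n in (3, 5, 8, 12):
            y1 = list(rng.uniform(500, 1200, n))
            y2 = list(rng.uniform(500, 1200, n))
            fit = carstensen_loa(PairedMeasurements(y1=y1, y2=y2))
            d = [a - b for a, b in zip(y1, y2)]
            avg = [(a + b) / 2 for a, b in zip(y1, y2)]
            a_o, b_o, tau_o = brute_force_line(avg, d)
            assert fit.a == pytest.approx(a_o, abs=1e-9)
            assert fit.b == pytest.approx(b_o, abs=1e-9)
            assert fit.tau == pytest.approx(tau_o, abs=1e-9)


class TestConversionEquations:
    def test_zero_fit_is_identity(self):
        c12, c21 = conversion_equations(CarstensenFit(a=0, b=0, tau=0, n=10))
        for eq in (c12, c21):
            assert eq.intercept == 0
            assert eq.slope == 1
            assert eq.halfwidth == 0

    def test_doubling_case_recovers_generating_relation(self):
        _, c21 = conversion_equations(CarstensenFit(a=0.0, b=-2 / 3, tau=0.0, n=10))
        assert c21.slope == pytest.approx(2.0)
        assert c21.intercept == pytest.approx(0.0)

    def test_published_harris_benedict_conversion_backsolved(self):
        """(a, b) = (560, -0.5185) reproduces the printed conversion
        intercept -756.1 and slope 1.70 for formula -> calorimetry."""
        _, c21 = conversion_equations(CarstensenFit(a=560.0, b=-0.5185, tau=60.0, n=95))
        assert c21.intercept == pytest.approx(-756.1, abs=0.5)
        assert c21.slope == pytest.approx(1.70, abs=0.005)

    def test_degenerate_slope_rejected(self):
        with pytest.raises(DegenerateDataError):
            conversion_equations(CarstensenFit(a=0, b=2.0, tau=1, n=10))

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=-500, max_value=500),
        st.floats(min_value=-1.9, max_value=1.9),
        st.floats(min_value=0, max_value=100),
    )
    def test_directions_are_mutually_inverse(self, a, b, tau):
        c12, c21 = conversion_equations(CarstensenFit(a=a, b=b, tau=tau, n=10))
        assert c12.slope * c21.slope == pytest.approx(1.0, rel=1e-9)
        assert c12.intercept + c12.slope * c21.intercept == pytest.approx(0.0, abs=1e-7)


class TestConvert:
    def test_published_worked_example(self):
        eq = ConversionEquation(ConversionDirection.Y2_FROM_Y1, -756.11, 1.70, 0.0)
        point, _ = convert(956.0, eq)
        assert point == pytest.approx(869.1, abs=0.05)

    def test_identity_leaves_value_unchanged(self):
        eq = ConversionEquation(ConversionDirection.Y1_FROM_Y2, 0.0, 1.0, 0.0)
        assert convert(812.3, eq)[0] == 812.3

    def test_interval_half_width(self):
        eq = ConversionEquation(ConversionDirection.Y2_FROM_Y1, 0.0, 2.0, 10.0)
        point, (lo, hi) = convert(100.0, eq)
        assert (point, lo, hi) == (200.0, 190.0, 210.0)


class TestLinCcc:
    def test_perfect_concordance(self):
        est, (lo, hi) = lin_ccc([1, 2, 3, 4], [1, 2, 3, 4])
        assert est == pytest.approx(1.0)

    def test_hand_computed_moment_formula(self):
        est, _ = lin_ccc([1, 2, 3], [2, 3, 4])
        assert est == pytest.approx(4 / 7, abs=1e-12)

    def test_anticorrelated_is_negative(self):
        est, _ = lin_ccc([1, 2, 3, 4], [4, 3, 2, 1])
        assert est < 0

    def test_zero_total_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            lin_ccc([2, 2, 2], [2, 2, 2])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_ccc_bounded_by_pearson(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 30)
        y = 0.5 * x + rng.normal(0, 1, 30) + rng.uniform(-1, 1)
        est, _ = lin_ccc(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(est) <= abs(r) + 1e-12

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(800, 150, 41)
        y = x + rng.normal(0, 120, 41)
        est, (lo, hi) = lin_ccc(x, y)
        assert lo < est < hi
        assert -1 <= lo and hi <= 1


class TestCompareFormulasCcc:
    def test_exact_formula_ranks_first(self):
        measured = pd.Series([700.0, 800, 900, 1000], index=list("abcd"), name="m")
        preds = pd.DataFrame(
            {"EXACT": measured.values, "NOISY": [750.0, 760, 950, 920]},
            index=measured.index,
        )
        table = compare_formulas_ccc(preds, measured)
        assert table.iloc[0]["formula"] == "EXACT"
        assert table.iloc[0]["ccc"] == pytest.approx(1.0)

    def test_rows_match_standalone_ccc(self):
        rng = np.random.default_rng(4)
        measured = pd.Series(rng.uniform(600, 1200, 20), index=[f"s{i}" for i in range(20)])
        preds = pd.DataFrame(
            {f"F{j}": measured.values + rng.normal(0, 50 * (j + 1), 20) for j in range(3)},
            index=measured.index,
        )
        table = compare_formulas_ccc(preds, measured).set_index("formula")
        for j in range(3):
            est, _ = lin_ccc(preds[f"F{j}"].values, measured.values)
            assert table.loc[f"F{j}", "ccc"] == pytest.approx(est)

    def test_mismatched_ids_rejected(self):
        measured = pd.Series([1.0, 2, 3], index=list("abc"))
        preds = pd.DataFrame({"F": [1.0, 2, 3]}, index=list("abd"))
        with pytest.raises(ValueError):
            compare_formulas_ccc(preds, measured)
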