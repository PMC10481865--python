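"""Method-comparison statistics: Bland-Altman, Carstensen LoA, conversions, CCC.

Given paired measurements of the same quantity by two methods — here a
prediction formula (y1) and indirect calorimetry (y2) — the difference
D = y1 - y2 is plotted against the average A = (y1 + y2)/2.  When D drifts
with A (proportional bias, detected by the Pearson correlation of D on A),
flat limits of agreement are misleading; Carstensen's single-measurement
procedure regresses D on A,

    D_i = a + b * A_i + e_i,   sd(e) = tau,

yielding sloped limits of agreement a + b*A ± 2*tau and, more usefully,
bidirectional conversion equations between the two methods with prediction
intervals:

    y1 | y2 = a/(1 - b/2) + (1 + b/2)/(1 - b/2) * y2  ±  2*tau/(1 - b/2)
    y2 | y1 = -a/(1 + b/2) + (1 - b/2)/(1 + b/2) * y1 ±  2*tau/(1 + b/2)

Lin's concordance correlation coefficient (CCC) summarises how far paired
values fall from the 45-degree identity line, combining precision (Pearson
correlation) with accuracy (bias from the line).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateDataError(ValueError):
    """The paired data lack the variance the statistic requires."""


@dataclass
class PairedMeasurements:
    """Paired single measurements by two methods on the same subjects."""

    y1: np.ndarray  # method under test (formula estimate), kcal/day
    y2: np.ndarray  # reference (indirect calorimetry), kcal/day
    ids: list[str] | None = None

    def __post_init__(self):
        self.y1 = np.asarray(self.y1, dtype=float)
        self.y2 = np.asarray(self.y2, dtype=float)
        if self.y1.shape != self.y2.shape or self.y1.ndim != 1:
            raise ValueError("y1 and y2 must be 1-d arrays of equal length")
        if len(self.y1) < 3:
            raise ValueError("need at least 3 pairs")
        if np.isnan(self.y1).any() or np.isnan(self.y2).any():
            raise ValueError("paired measurements must not contain missing values")
        if self.ids is not None and len(self.ids) != len(self.y1):
            raise ValueError("ids length mismatch")

    @property
    def differences(self) -> np.ndarray:
        return self.y1 - self.y2

    @property
    def averages(self) -> np.ndarray:
        return (self.y1 + self.y2) / 2.0


@dataclass
class BlandAltmanResult:
    mean_bias: float                     # kcal/day
    classic_loa: tuple[float, float]     # mean ± 1.96 SD
    pearson_r_bias_vs_mean: float
    p_value: float
    n: int

    @property
    def proportional_bias(self) -> bool:
        """Two-sided p < 0.05 on the bias-vs-mean correlation."""
        return self.p_value < 0.05


@dataclass
class CarstensenFit:
    a: float      # intercept of D on A, kcal/day
    b: float      # slope of D on A
    tau: float    # residual SD, kcal/day
    n: int

    def sloped_loa(self, avg: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Limits of agreement a + b*A ± 2*tau at given average value(s)."""
        centre = self.a + self.b * np.asarray(avg, dtype=float)
        return centre - 2.0 * self.tau, centre + 2.0 * self.tau


class ConversionDirection(str, Enum):
    Y1_FROM_Y2 = "y1_from_y2"
    Y2_FROM_Y1 = "y2_from_y1"


@dataclass
class ConversionEquation:
    direction: ConversionDirection
    intercept: float   # kcal/day
    slope: float
    halfwidth: float   # prediction-interval half width, kcal/day


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Classic Bland-Altman summary plus a proportional-bias test.

    Limits of agreement are mean(D) ± 1.96*SD(D); the association between the
    bias and the mean is tested with Pearson's product-moment correlation.
    A constant difference (zero-variance D) short-circuits to r = 0, p = 1.
    """
    d, a = pairs.differences, pairs.averages
    if np.var(a) == 0:
        raise DegenerateDataError("averages have zero variance; correlation undefined")
    mean_bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (mean_bias - 1.96 * sd, mean_bias + 1.96 * sd)
    if np.var(d) == 0:
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(a, d)
    return BlandAltmanResult(
        mean_bias=mean_bias, classic_loa=loa,
        pearson_r_bias_vs_mean=float(r), p_value=float(p), n=len(d),
    )


def carstensen_loa(pairs: PairedMeasurements) -> CarstensenFit:
    """Regress differences on averages; residual SD uses the n-2 denominator."""
    d, a = pairs.differences, pairs.averages
    n = len(d)
    if np.var(a) == 0:
        raise DegenerateDataError("averages are constant; slope not identifiable")
    x = np.column_stack([np.ones(n), a])
    coef, *_ = np.linalg.lstsq(x, d, rcond=None)
    resid = d - x @ coef
    tau = float(np.sqrt((resid @ resid) / (n - 2)))
    return CarstensenFit(a=float(coef[0]), b=float(coef[1]), tau=tau, n=n)


def conversion_equations(fit: CarstensenFit) -> tuple[ConversionEquation, ConversionEquation]:
    """Bidirectional method-conversion equations from a difference-on-average fit.

    Valid for |b| < 2 (both denominators 1 ± b/2 nonzero with consistent
    sign); the two point predictions are exact mutual inverses.
    """
    if abs(fit.b) >= 2:
        raise DegenerateDataError(f"|b| = {abs(fit.b):.3f} >= 2: conversion degenerate")
    lo = 1.0 - fit.b / 2.0
    hi = 1.0 + fit.b / 2.0
    y1_from_y2 = ConversionEquation(
        direction=ConversionDirection.Y1_FROM_Y2,
        intercept=fit.a / lo, slope=hi / lo, halfwidth=2.0 * fit.tau / lo,
    )
    y2_from_y1 = ConversionEquation(
        direction=ConversionDirection.Y2_FROM_Y1,
        intercept=-fit.a / hi, slope=lo / hi, halfwidth=2.0 * fit.tau / hi,
    )
    return y1_from_y2, y2_from_y1


def convert(value: float, eq: ConversionEquation) -> tuple[float, tuple[float, float]]:
    """Apply a conversion equation: point prediction and prediction interval."""
    point = eq.intercept + eq.slope * value
    return point, (point - eq.halfwidth, point + eq.halfwidth)


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with a 95% CI.

    Uses population (1/n) moments:
    CCC = 2*s_xy / (s_x^2 + s_y^2 + (mean x - mean y)^2).  The confidence
    interval is computed on the Fisher z-transform with Lin's (1989)
    asymptotic standard error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 3")
    n = len(x)
    mx, my = x.mean(), y.mean()
    sx2 = float(((x - mx) ** 2).mean())
    sy2 = float(((y - my) ** 2).mean())
    sxy = float(((x - mx) * (y - my)).mean())
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise DegenerateDataError("total variance is zero; CCC undefined")
    ccc = 2.0 * sxy / denom

    if sx2 == 0 or sy2 == 0 or abs(ccc) >= 1:
        return float(ccc), (float(ccc), float(ccc))
    r = sxy / np.sqrt(sx2 * sy2)
    u2 = (mx - my) ** 2 / np.sqrt(sx2 * sy2)
    z = np.arctanh(ccc)
    se_z2 = (
        (1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
        + 2 * ccc**3 * (1 - ccc) * u2 / (r * (1 - ccc**2) ** 2)
        - ccc**4 * u2**2 / (2 * r**2 * (1 - ccc**2) ** 2)
    ) / (n - 2)
    se_z = np.sqrt(max(se_z2, 0.0))
    lo, hi = np.tanh(z - 1.959964 * se_z), np.tanh(z + 1.959964 * se_z)
    return float(ccc), (float(lo), float(hi))


def compare_formulas_ccc(
    prediction_values: pd.DataFrame, measured: pd.Series
) -> pd.DataFrame:
    """Rank formulas by concordance with the measured values.

    ``prediction_values`` is the subject x formula table; ``measured`` is the
    calorimetry REE indexed by the same subject ids.  Rows with a missing
    prediction are dropped per formula.  Returns a dataframe with columns
    formula, ccc, ci_low, ci_high, n sorted by descending CCC.
    """
    if not prediction_values.index.equals(measured.index):
        missing = prediction_values.index.symmetric_difference(measured.index)
        raise ValueError(f"subject ids do not align; mismatched: {list(missing)[:5]}")
    rows = []
    for formula in prediction_values.columns:
        col = prediction_values[formula]
        mask = col.notna() & measured.notna()
        est, (lo, hi) = lin_ccc(col[mask].to_numpy(), measured[mask].to_numpy())
        rows.append(
            {"formula": formula, "ccc": est, "ci_low": lo, "ci_high": hi, "n": int(mask.sum())}
        )
    out = pd.DataFrame(rows).sort_values("ccc", ascending=False, ignore_index=True)
    return out
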