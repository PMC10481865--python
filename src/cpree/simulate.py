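"""Synthetic cohort and calorimetry-trace generators.

No subject-level data are deposited for this population, so every pipeline
stage is exercised on synthetic cohorts whose marginal summaries (medians
and interquartile ranges of weight, triceps skinfold, age, height) and whose
REE structure match the published study-population description: a cross
section of children with spastic quadriplegic cerebral palsy (GMFCS level V),
65% male, median age 9 years, median weight 19.45 kg, median TSF 7.7 mm,
with measured REE generated from the population-specific linear structure

    REE = intercept + b_w * weight + b_tsf * TSF + noise.

Anthropometric marginals are split log-normal (piecewise log-linear in the
normal deviate, skewed and strictly positive) with the configured median and
both quartiles matched exactly; a Gaussian copula adds realistic rank
correlation between measures.  All generation is deterministic under a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calorimetry import BreathSeries, WEIR_KCAL_PER_L_O2, WEIR_KCAL_PER_L_CO2
from .cohort import Cohort, SubjectRecord

_Z75 = stats.norm.ppf(0.75)  # 0.6745; spread of the standard normal IQR


class GeneratorConfigError(ValueError):
    """The generator configuration implies an impossible distribution."""


@dataclass
class GeneratorConfig:
    """Study-population parameters for :func:`generate_cohort`.

    Defaults reproduce the published cohort description: n=100, 65% male,
    median [IQR] weight 19.45 [14.43, 26.05] kg, TSF 7.70 [5.40, 9.20] mm,
    age 9 [6, 14] years, height 118 [107.55, 135.25] cm, median RQ 0.7144;
    REE built from the population-specific coefficients 28.43 kcal/day/kg
    (weight), -17 kcal/day/mm (TSF) and 398.2 kcal/day intercept with
    residual SD 200 kcal/day (the square root of the reported test MSE);
    caloric intake calibrated so that REE rises 163 kcal/day per 388 kcal/day
    of intake and 102 kcal/day per 4.75 years of age.
    """

    n: int = 100
    seed: int = 0
    male_fraction: float = 0.65
    weight_median: float = 19.45
    weight_iqr: tuple[float, float] = (14.43, 26.05)
    tsf_median: float = 7.70
    tsf_iqr: tuple[float, float] = (5.40, 9.20)
    age_median: float = 9.0
    age_iqr: tuple[float, float] = (6.0, 14.0)
    height_median: float = 118.0
    height_iqr: tuple[float, float] = (107.55, 135.25)
    arm_circ_median: float = 18.0
    arm_circ_iqr: tuple[float, float] = (15.20, 20.00)
    ree_coeff_weight: float = 28.43      # kcal/day per kg
    ree_coeff_tsf: float = -17.0         # kcal/day per mm
    ree_intercept: float = 398.2         # kcal/day
    ree_noise_sd: float = 200.0          # kcal/day
    ree_floor: float = 250.0             # kcal/day truncation
    intake_slope: float = 163.0 / 388.0  # kcal/day REE per kcal/day intake
    intake_age_slope: float = 102.0 / 4.75  # kcal/day REE per year
    intake_median: float = 1146.0        # kcal/day, centring constant
    intake_noise_sd: float = 250.0       # kcal/day of intake-specific variation
    rq_median: float = 0.7144
    rq_sd: float = 0.09
    weight_tsf_spearman: float = 0.3
    feeding_fractions: tuple[float, float, float] = (0.64, 0.29, 0.07)

    def validate(self) -> None:
        if self.n < 0:
            raise GeneratorConfigError(f"n must be >= 0, got {self.n}")
        for name in ("weight", "tsf", "age", "height", "arm_circ"):
            lo, hi = getattr(self, f"{name}_iqr")
            med = getattr(self, f"{name}_median")
            if not (0 < lo < hi):
                raise GeneratorConfigError(
                    f"{name}_iqr must satisfy 0 < lower < upper, got ({lo}, {hi})"
                )
            if not (lo < med < hi):
                raise GeneratorConfigError(
                    f"{name}_median {med} must lie inside the IQR ({lo}, {hi})"
                )
        if self.ree_noise_sd < 0 or self.intake_noise_sd < 0:
            raise GeneratorConfigError("noise SDs must be non-negative")
        if self.intake_slope * self.intake_noise_sd >= self.ree_noise_sd > 0:
            raise GeneratorConfigError(
                "intake-specific noise would exceed the total REE noise budget"
            )
        if not 0 <= self.male_fraction <= 1:
            raise GeneratorConfigError("male_fraction must be a proportion")


def _quantile_transform(median: float, iqr: tuple[float, float]):
    """Monotone map from a standard-normal deviate to a positive marginal.

    Piecewise log-linear (a "split log-normal"): below the median the log
    scale is set by the lower quartile, above by the upper quartile, so all
    three configured quantiles are matched exactly while each tail stays
    log-normal.  A single-sigma log-normal can only match the quartile
    *ratio* and misses asymmetric quartiles (e.g. the left-skewed TSF
    distribution) by far more than the calibration tolerance.
    """
    lo, hi = iqr
    b = math.log(median)
    slope_lo = (b - math.log(lo)) / _Z75
    slope_hi = (math.log(hi) - b) / _Z75

    def transform(z: np.ndarray) -> np.ndarray:
        return np.exp(b + np.where(z < 0, slope_lo, slope_hi) * z)

    return transform


def _copula_correlation(spearman: float) -> float:
    """Gaussian-copula correlation reproducing a target Spearman rho."""
    return 2.0 * math.sin(math.pi * spearman / 6.0)


def _nearest_correlation(matrix: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalise to unit diagonal."""
    w, v = np.linalg.eigh(matrix)
    if w.min() > 1e-10:
        return matrix
    w = np.clip(w, 1e-10, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    return m / np.outer(d, d)


# Copula order: weight, tsf, height, age, arm circumference.  Only the
# weight-TSF entry is a configured knob; the remaining entries are fixed,
# physiologically motivated rank correlations (children grow, so size
# measures co-vary strongly with age and with each other).
_BASE_SPEARMAN = np.array(
    [
        [1.00, 0.30, 0.85, 0.75, 0.70],
        [0.30, 1.00, 0.20, 0.10, 0.50],
        [0.85, 0.20, 1.00, 0.85, 0.50],
        [0.75, 0.10, 0.85, 1.00, 0.45],
        [0.70, 0.50, 0.50, 0.45, 1.00],
    ]
)


def generate_cohort(config: GeneratorConfig | None = None, *, inject_outlier: bool = False) -> Cohort:
    """Draw a synthetic cohort under ``config``.

    ``inject_outlier`` appends one extra subject with REE 209 kcal/day and a
    severe-malnutrition z-score, emulating the single implausible
    calorimetry value screened out by :func:`cpree.cohort.exclude_extreme_ree`.

    The caloric-intake column is constructed so that an OLS regression of
    measured REE on intake and age recovers ``intake_slope`` and
    ``intake_age_slope`` in expectation: the REE residual is decomposed into
    an intake-borne component (slope times an intake-specific normal
    deviate) plus an independent remainder, and intake carries the full
    weight/TSF structural signal divided by the slope.  See docs/methods.md.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    spearman = _BASE_SPEARMAN.copy()
    spearman[0, 1] = spearman[1, 0] = config.weight_tsf_spearman
    corr = _nearest_correlation(
        np.vectorize(_copula_correlation)(spearman) if n else spearman
    )
    z = rng.multivariate_normal(np.zeros(5), corr, size=n, method="cholesky") if n else np.empty((0, 5))

    names = ["weight", "tsf", "height", "age", "arm_circ"]
    draws = {}
    for j, name in enumerate(names):
        transform = _quantile_transform(
            getattr(config, f"{name}_median"), getattr(config, f"{name}_iqr")
        )
        draws[name] = transform(z[:, j])
    # age capped at the study's inclusion range
    draws["age"] = np.clip(draws["age"], 1.0, 19.0)

    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    feeding = rng.choice(
        ["oral", "enteral", "mixed"], size=n, p=list(config.feeding_fractions)
    )

    # REE: population-specific linear structure plus noise.  The noise is
    # split into an intake-borne part and an independent remainder so the
    # intake regression is exactly calibrated (see docstring).
    nu = rng.normal(0.0, config.intake_noise_sd, size=n)      # intake units
    rest_sd = math.sqrt(
        max(config.ree_noise_sd**2 - (config.intake_slope * config.intake_noise_sd) ** 2, 0.0)
    )
    rest = rng.normal(0.0, rest_sd, size=n)
    structural = (
        config.ree_intercept
        + config.ree_coeff_weight * draws["weight"]
        + config.ree_coeff_tsf * draws["tsf"]
    )
    ree = structural + config.intake_slope * nu + rest
    ree = np.maximum(ree, config.ree_floor)

    # intake = (structural signal + intake noise - age effect)/slope + centring
    b = config.intake_slope
    signal = (
        config.ree_coeff_weight * draws["weight"] + config.ree_coeff_tsf * draws["tsf"]
    )
    centre = config.intake_median - (
        config.ree_coeff_weight * config.weight_median
        + config.ree_coeff_tsf * config.tsf_median
        - config.intake_age_slope * config.age_median
    ) / b
    intake = centre + (signal + b * nu - config.intake_age_slope * draws["age"]) / b
    intake = np.maximum(intake, 100.0)

    # RQ: truncated normal inside the physiological fat-to-mixed band
    a_t = (0.62 - config.rq_median) / config.rq_sd
    b_t = (0.88 - config.rq_median) / config.rq_sd
    rq = stats.truncnorm.rvs(
        a_t, b_t, loc=config.rq_median, scale=config.rq_sd, size=n, random_state=rng
    )

    # BMI-for-age z-score anchored to the weight copula deviate: heavier
    # children (for the cohort) score higher; intercept targets the reported
    # ~52% moderate+severe malnutrition share.
    bmi_z = -2.1 + 1.2 * z[:, 0] + 0.6 * rng.normal(size=n)

    subjects = []
    for i in range(n):
        height = float(draws["height"][i])
        subjects.append(
            SubjectRecord(
                id=f"S{i + 1:04d}",
                sex=str(sex[i]),
                age=float(draws["age"][i]),
                weight=float(draws["weight"][i]),
                tsf=float(draws["tsf"][i]),
                feeding=str(feeding[i]),
                height=height,
                knee_height=(height - 24.2) / 2.69,
                arm_circumference=float(draws["arm_circ"][i]),
                bmi_zscore=float(bmi_z[i]),
                ree_measured=float(ree[i]),
                rq=float(rq[i]),
                caloric_intake=float(intake[i]),
            )
        )
    if inject_outlier:
        subjects.append(
            SubjectRecord(
                id=f"S{n + 1:04d}",
                sex="female",
                age=7.0,
                weight=9.8,
                tsf=3.1,
                feeding="enteral",
                height=96.0,
                knee_height=(96.0 - 24.2) / 2.69,
                arm_circumference=11.0,
                bmi_zscore=-4.63,
                ree_measured=209.0,
                rq=0.68,
                caloric_intake=620.0,
            )
        )
    return Cohort(subjects=subjects, provenance=f"generate_cohort(seed={config.seed}, n={n})")


def generate_breath_series(
    ree_true: float,
    rq_true: float,
    duration: float,
    unsteady_lead: float,
    seed: int,
    breaths_per_minute: float = 20.0,
) -> BreathSeries:
    """Construct a breath-by-breath gas-exchange trace with a known changepoint.

    The first ``unsteady_lead`` minutes oscillate strongly (VO2 coefficient
    of variation well above the steady-state tolerance); the remainder is
    stationary with ~1.5% breath-level noise whose segment means satisfy the
    abbreviated Weir equation at ``ree_true`` and a VCO2/VO2 ratio of
    ``rq_true``.
    """
    if not duration > unsteady_lead >= 0:
        raise ValueError("require duration > unsteady_lead >= 0")
    if not 0.6 <= rq_true <= 1.2:
        raise ValueError(f"rq_true must lie in [0.6, 1.2], got {rq_true}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * breaths_per_minute))
    dt = 1.0 / breaths_per_minute
    t = (np.arange(n) + 0.5) * dt + rng.uniform(-0.1 * dt, 0.1 * dt, size=n)
    t = np.maximum.accumulate(t)  # keep strictly increasing despite jitter
    t += np.arange(n) * 1e-9

    # steady-segment mean VO2 from the abbreviated Weir identity
    vo2_ss = ree_true / (1.44 * (WEIR_KCAL_PER_L_O2 + WEIR_KCAL_PER_L_CO2 * rq_true))

    lead = t < unsteady_lead
    vo2 = np.empty(n)
    # unsteady: 45% sinusoid (period 1.8 min) -> window CV far above 10%
    vo2[lead] = vo2_ss * (1.0 + 0.45 * np.sin(2 * np.pi * t[lead] / 1.8))
    vo2[~lead] = vo2_ss * (1.0 + rng.normal(0.0, 0.015, size=(~lead).sum()))
    vo2 = np.maximum(vo2, 1e-6)
    vco2 = rq_true * vo2 * (1.0 + rng.normal(0.0, 0.005, size=n))
    ve = 0.027 * vo2 * (1.0 + rng.normal(0.0, 0.01, size=n))
    return BreathSeries(time=t, vo2=vo2, vco2=np.maximum(vco2, 1e-6), ve=np.maximum(ve, 1e-9))
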