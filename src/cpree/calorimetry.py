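"""Indirect-calorimetry processing: steady-state detection and Weir REE.

A metabolic cart reports breath-by-breath oxygen consumption (VO2, ml/min),
carbon dioxide production (VCO2, ml/min) and minute ventilation (VE, L/min).
A measurement is usable only once the subject reaches a steady state —
conventionally, a window of at least 5 minutes in which the respiratory
quotient varies by less than 5% and VO2 and VE by less than 10% ("variation"
implemented as the within-window coefficient of variation, SD/mean).  Energy
expenditure is then obtained from the abbreviated Weir equation, which omits
the urinary-nitrogen (protein) term.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Abbreviated Weir coefficients: kcal per litre of O2 consumed / CO2 produced.
WEIR_KCAL_PER_L_O2 = 3.941
WEIR_KCAL_PER_L_CO2 = 1.106


class MeasurementError(RuntimeError):
    """The trace does not support a valid REE measurement."""


@dataclass
class BreathSeries:
    """Breath-by-breath gas-exchange series (times in minutes)."""

    time: np.ndarray   # minutes, strictly increasing
    vo2: np.ndarray    # ml/min
    vco2: np.ndarray   # ml/min
    ve: np.ndarray     # L/min

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        self.ve = np.asarray(self.ve, dtype=float)
        n = len(self.time)
        if n < 1 or any(len(a) != n for a in (self.vo2, self.vco2, self.ve)):
            raise ValueError("time, vo2, vco2, ve must have equal length >= 1")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.vo2 <= 0) or np.any(self.vco2 <= 0) or np.any(self.ve <= 0):
            raise ValueError("vo2, vco2 and ve must be positive")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class SteadyStateResult:
    found: bool
    start: float | None = None   # minutes
    end: float | None = None     # minutes
    rq_cv: float | None = None   # %, over the qualifying window
    vo2_cv: float | None = None  # %
    ve_cv: float | None = None   # %


def rq(vo2: float, vco2: float) -> float:
    """Respiratory quotient VCO2/VO2."""
    if vo2 is None or vo2 <= 0:
        raise ValueError(f"vo2 must be > 0, got {vo2}")
    return vco2 / vo2


def weir_ree(vo2: float, vco2: float) -> float:
    """Abbreviated Weir resting energy expenditure, kcal/day.

    ``1.44 * (3.941 * VO2 + 1.106 * VCO2)`` with VO2/VCO2 in ml/min; the
    1.44 factor converts kcal/min (per-litre coefficients over ml) to
    kcal/day.  The urinary-nitrogen term is omitted.
    """
    if vo2 is None or vo2 <= 0 or vco2 is None or vco2 <= 0:
        raise ValueError(f"vo2 and vco2 must be > 0, got {vo2}, {vco2}")
    return 1.44 * (WEIR_KCAL_PER_L_O2 * vo2 + WEIR_KCAL_PER_L_CO2 * vco2)


def _cv_percent(x: np.ndarray) -> float:
    m = x.mean()
    if m == 0:
        return float("inf")
    return float(x.std(ddof=1) / m * 100.0)


def detect_steady_state(
    series: BreathSeries,
    window: float = 5.0,
    rq_tol: float = 5.0,
    vo2_tol: float = 10.0,
    ve_tol: float = 10.0,
) -> SteadyStateResult:
    """Find the earliest window of length >= ``window`` minutes satisfying the
    steady-state coefficient-of-variation tolerances (percent).

    The window slides breath by breath; for each starting breath the end is
    the first breath at least ``window`` minutes later.  The earliest
    qualifying window wins.  Raises if the series is shorter than ``window``.
    """
    t = series.time
    span = t[-1] - t[0]
    if span < window:
        raise ValueError(
            f"series spans {span:.2f} min, shorter than the {window:.2f} min window"
        )
    rqs = series.vco2 / series.vo2
    # prefix sums for O(1) window moments
    def moments(x):
        s = np.concatenate([[0.0], np.cumsum(x)])
        s2 = np.concatenate([[0.0], np.cumsum(x * x)])
        return s, s2

    sums = {name: moments(x) for name, x in (("rq", rqs), ("vo2", series.vo2), ("ve", series.ve))}
    ends = np.searchsorted(t, t + window, side="left")  # first index with t[j] >= t[i]+window

    def window_cv(name: str, i: int, j: int) -> float:
        s, s2 = sums[name]
        m = j - i + 1
        mean = (s[j + 1] - s[i]) / m
        var = max((s2[j + 1] - s2[i]) / m - mean * mean, 0.0) * m / (m - 1)
        return float(np.sqrt(var) / mean * 100.0) if mean != 0 else float("inf")

    for i in range(len(t)):
        j = ends[i]
        if j >= len(t):
            break
        cv_rq = window_cv("rq", i, j)
        cv_vo2 = window_cv("vo2", i, j)
        cv_ve = window_cv("ve", i, j)
        if cv_rq < rq_tol and cv_vo2 < vo2_tol and cv_ve < ve_tol:
            return SteadyStateResult(
                found=True, start=float(t[i]), end=float(t[j]),
                rq_cv=cv_rq, vo2_cv=cv_vo2, ve_cv=cv_ve,
            )
    return SteadyStateResult(found=False)


def measure_ree(
    series: BreathSeries,
    measurement: float = 20.0,
    window: float = 5.0,
    rq_tol: float = 5.0,
    vo2_tol: float = 10.0,
    ve_tol: float = 10.0,
) -> tuple[float, float]:
    """Measure (REE kcal/day, RQ) over ``measurement`` minutes of data
    following steady-state onset.

    Raises :class:`MeasurementError` if no steady state is found or fewer
    than ``measurement`` minutes of trace follow its start.
    """
    ss = detect_steady_state(series, window=window, rq_tol=rq_tol, vo2_tol=vo2_tol, ve_tol=ve_tol)
    if not ss.found:
        raise MeasurementError("no steady state detected in the trace")
    t = series.time
    if t[-1] - ss.start < measurement:
        raise MeasurementError(
            f"only {t[-1] - ss.start:.1f} min of data follow steady-state onset; "
            f"{measurement:.1f} min required"
        )
    mask = (t >= ss.start) & (t <= ss.start + measurement)
    mean_vo2 = float(series.vo2[mask].mean())
    mean_vco2 = float(series.vco2[mask].mean())
    return weir_ree(mean_vo2, mean_vco2), mean_vco2 / mean_vo2


def read_breath_csv(path) -> BreathSeries:
    """Read a trace CSV with columns time_min, vo2_ml_min, vco2_ml_min, ve_l_min."""
    df = pd.read_csv(Path(path))
    required = ["time_min", "vo2_ml_min", "vco2_ml_min", "ve_l_min"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing trace column(s): {', '.join(missing)}")
    return BreathSeries(
        time=df["time_min"].to_numpy(),
        vo2=df["vo2_ml_min"].to_numpy(),
        vco2=df["vco2_ml_min"].to_numpy(),
        ve=df["ve_l_min"].to_numpy(),
    )


def write_breath_csv(series: BreathSeries, path) -> None:
    pd.DataFrame(
        {
            "time_min": series.time,
            "vo2_ml_min": series.vo2,
            "vco2_ml_min": series.vco2,
            "ve_l_min": series.ve,
        }
    ).to_csv(path, index=False)
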