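"""Points-based nomogram construction from a fitted linear model.

A nomogram turns a linear model into a paper calculator: each predictor gets
an axis mapping its value to "points" proportional to that predictor's
contribution span, scaled so the most influential predictor (largest
|coefficient| x range) spans exactly 0-100 points.  The reference end of
each axis is the value minimising the term's contribution (the minimum for a
positive coefficient, the maximum for a negative one, e.g. triceps skinfold
in the REE model), so points are always non-negative and increase with the
predicted response.  The total-points axis inverts the sum back to the
response scale, here REE in kcal/day; reading the nomogram is algebraically
identical to evaluating the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model_dev import ModelFit

logger = logging.getLogger(__name__)


class NomogramRangeError(ValueError):
    """A predictor value falls outside the nomogram's declared axis range."""


@dataclass
class NomogramAxis:
    predictor: str
    coefficient: float
    range: tuple[float, float]
    reference: float        # range end where points = 0
    points_per_unit: float  # signed: points = points_per_unit * (x - reference)

    def points(self, value: float) -> float:
        lo, hi = self.range
        if not lo <= value <= hi:
            raise NomogramRangeError(
                f"{self.predictor} = {value} outside the nomogram range [{lo}, {hi}]"
            )
        return self.points_per_unit * (value - self.reference)

    @property
    def max_points(self) -> float:
        lo, hi = self.range
        return max(self.points(lo), self.points(hi))


@dataclass
class Nomogram:
    axes: list[NomogramAxis]
    intercept: float
    base_value: float        # intercept + sum of reference contributions
    kcal_per_point: float    # response units per point

    def total_points_to_ree(self, total_points: float) -> float:
        return self.base_value + self.kcal_per_point * total_points

    def predict(self, **values: float) -> float:
        total = 0.0
        for axis in self.axes:
            if axis.predictor not in values:
                raise ValueError(f"missing value for predictor {axis.predictor!r}")
            total += axis.points(values[axis.predictor])
        return self.total_points_to_ree(total)


def build_nomogram(model: ModelFit, ranges: dict[str, tuple[float, float]]) -> Nomogram:
    """Construct a nomogram from a strictly linear model and per-predictor ranges.

    Zero-coefficient predictors are excluded with a warning; spline terms are
    unsupported (a nomogram axis must be a straight-line map).
    """
    for term in model.terms:
        if term not in ranges:
            raise ValueError(f"no range supplied for predictor {term!r}")
        if "rcs" in term or "spline" in term:
            raise ValueError("spline-term models are not supported by the nomogram")
        lo, hi = ranges[term]
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"range for {term!r} must be finite with min < max")

    spans = {
        t: abs(model.coefficients[t]) * (ranges[t][1] - ranges[t][0])
        for t in model.terms
        if model.coefficients[t] != 0
    }
    dropped = [t for t in model.terms if model.coefficients[t] == 0]
    for t in dropped:
        logger.warning("predictor %s has zero coefficient; excluded from the nomogram", t)
    if not spans:
        raise ValueError("no predictor with a nonzero coefficient")
    scale = max(spans.values())  # response units spanned by 100 points

    axes = []
    base = model.coefficients["intercept"]
    for t in model.terms:
        if t in dropped:
            continue
        beta = model.coefficients[t]
        lo, hi = ranges[t]
        reference = lo if beta > 0 else hi
        axes.append(
            NomogramAxis(
                predictor=t,
                coefficient=beta,
                range=(lo, hi),
                reference=reference,
                points_per_unit=beta / scale * 100.0,
            )
        )
        base += beta * reference
    return Nomogram(axes=axes, intercept=model.coefficients["intercept"],
                    base_value=base, kcal_per_point=scale / 100.0)


def nomogram_predict(nomogram: Nomogram, weight: float, tsf: float) -> float:
    """Predicted REE (kcal/day) for the weight + TSF nomogram.

    Values outside the declared axis ranges raise
    :class:`NomogramRangeError` — the instrument refuses clinical
    extrapolation.
    """
    return nomogram.predict(weight=weight, tsf=tsf)


def _nice_ticks(lo: float, hi: float, n: int = 8) -> np.ndarray:
    raw = (hi - lo) / n
    mag = 10 ** np.floor(np.log10(raw))
    step = min(s for s in (1 * mag, 2 * mag, 2.5 * mag, 5 * mag, 10 * mag) if s >= raw)
    start = np.ceil(lo / step) * step
    ticks = np.arange(start, hi + step / 2, step)
    return ticks[(ticks >= lo - 1e-9) & (ticks <= hi + 1e-9)]


def tick_table(nomogram: Nomogram) -> str:
    """Plain-text tick table: the canonical, testable rendering surface."""
    lines = []
    for axis in nomogram.axes:
        lines.append(f"axis: {axis.predictor}  (coefficient {axis.coefficient:g}, "
                     f"range {axis.range[0]:g}..{axis.range[1]:g})")
        lines.append(f"{'value':>10}  {'points':>8}")
        for v in _nice_ticks(*axis.range):
            lines.append(f"{v:>10.4g}  {axis.points(float(v)):>8.2f}")
        lines.append("")
    max_total = sum(a.max_points for a in nomogram.axes)
    lines.append("axis: total points -> REE (kcal/day)")
    lines.append(f"{'points':>10}  {'ree':>8}")
    for tp in _nice_ticks(0.0, max_total):
        lines.append(f"{tp:>10.4g}  {nomogram.total_points_to_ree(float(tp)):>8.1f}")
    lines.append("")
    return "\n".join(lines)


def render_nomogram(nomogram: Nomogram, path) -> None:
    """Write the nomogram to ``path``.

    A ``.txt`` path gets the tick table; any other suffix gets an
    aligned-axes matplotlib figure plus a ``<stem>.ticks.txt`` sidecar.
    """
    if not nomogram.axes:
        raise ValueError("cannot render a nomogram with no axes")
    path = Path(path)
    if path.suffix == ".txt":
        path.write_text(tick_table(nomogram))
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    max_total = sum(a.max_points for a in nomogram.axes)
    rows = [("Points", 0.0, max(a.max_points for a in nomogram.axes), None)]
    for a in nomogram.axes:
        rows.append((a.predictor, a.range[0], a.range[1], a))
    rows.append(("Total points", 0.0, max_total, "total"))

    fig, ax = plt.subplots(figsize=(8, 1.2 * (len(rows) + 1)))
    ax.set_xlim(-5, 105)
    ax.set_ylim(-0.5, len(rows) + 0.5)
    ax.axis("off")
    for i, (label, lo, hi, kind) in enumerate(rows):
        yy = len(rows) - i
        ax.text(-6, yy, label, ha="right", va="center", fontsize=10)
        if kind is None:  # points ruler
            ticks = _nice_ticks(lo, hi)
            pos = (ticks - lo) / (hi - lo) * 100
            labels = [f"{t:g}" for t in ticks]
        elif kind == "total":
            ticks = _nice_ticks(lo, hi)
            pos = (ticks - lo) / (hi - lo) * 100
            labels = [f"{t:g}\n{nomogram.total_points_to_ree(float(t)):.0f}" for t in ticks]
        else:
            ticks = _nice_ticks(lo, hi)
            pts = np.array([kind.points(float(t)) for t in ticks])
            span = max(a.max_points for a in nomogram.axes)
            pos = pts / span * 100 if span else pts
            labels = [f"{t:g}" for t in ticks]
        ax.hlines(yy, 0, 100, color="black", lw=0.8)
        for x, lab in zip(pos, labels):
            ax.vlines(x, yy - 0.07, yy + 0.07, color="black", lw=0.8)
            ax.text(x, yy - 0.32, lab, ha="center", va="top", fontsize=8)
    ax.set_title("REE nomogram (sum predictor points; read REE off the total axis)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    path.with_name(path.stem + ".ticks.txt").write_text(tick_table(nomogram))
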