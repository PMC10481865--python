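"""Resting-energy-expenditure prediction equations.

Implements the standard paediatric/adult formulas used in clinical practice
(WHO, Schofield weight, Schofield weight & height, Harris-Benedict, Oxford,
Mifflin-St Jeor) plus two population-specific equations for children with
spastic quadriplegic cerebral palsy:

* ``CP_PRELIMINARY`` — weight-only, ``REE = 24*W + 380`` (kcal/day);
* ``CP_FINAL``       — weight and triceps skinfold,
  ``REE = 28.43*W - 17*TSF + 398.2``.

Unit conventions differ by equation and are enforced here: Schofield
weight & height consumes height in metres (its height coefficients are on
the metre scale); Harris-Benedict and Mifflin consume height in centimetres;
all heights in :class:`PredictionInput` are centimetres and converted
internally.  Age bands for the banded equations are half-open —
[0,3), [3,10), [10,18), [18,30) — so a child of exactly 10.0 years uses the
10-18 equation; ages of 30 or more are out of range.

The published Schofield weight & height table prints the male <3 y weight
coefficient as 1.67; the original Schofield coefficient is 0.167 (which
yields physiological values at infant weights) and is the default here.
Pass ``as_printed=True`` to evaluate the table exactly as printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort


class FormulaId(str, Enum):
    WHO = "WHO"
    SCHOFIELD_W = "SCHOFIELD_W"
    SCHOFIELD_WH = "SCHOFIELD_WH"
    HARRIS_BENEDICT = "HARRIS_BENEDICT"
    OXFORD = "OXFORD"
    MIFFLIN = "MIFFLIN"
    CP_PRELIMINARY = "CP_PRELIMINARY"
    CP_FINAL = "CP_FINAL"


ALL_FORMULAS = tuple(FormulaId)

#: Formulas that require a height value.
HEIGHT_FORMULAS = {FormulaId.SCHOFIELD_WH, FormulaId.HARRIS_BENEDICT, FormulaId.MIFFLIN}
#: Formulas dispatched on age band.
BANDED_FORMULAS = {FormulaId.WHO, FormulaId.SCHOFIELD_W, FormulaId.SCHOFIELD_WH, FormulaId.OXFORD}

AGE_BANDS = ((0.0, 3.0), (3.0, 10.0), (10.0, 18.0), (18.0, 30.0))


@dataclass
class PredictionInput:
    sex: str            # "male" | "female"
    age: float          # years
    weight: float       # kg
    height: Optional[float] = None  # cm

    def validate(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.weight is None or self.weight <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        if self.age is None or self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.height is not None and self.height <= 0:
            raise ValueError(f"height must be > 0 when present, got {self.height}")


class AgeOutOfRangeError(ValueError):
    """Age falls outside every defined band of a banded formula."""


class MissingPredictorError(ValueError):
    """A required predictor (height or TSF) is absent."""


def _band_index(age: float) -> int:
    for k, (lo, hi) in enumerate(AGE_BANDS):
        if lo <= age < hi:
            return k
    raise AgeOutOfRangeError(
        f"age {age} y is outside the defined bands [0, 30) of this formula"
    )


# (male coefficients, female coefficients) per band: (a*wt + const)
_WHO = {
    "male": ((60.9, -54), (22.7, 495), (17.5, 651), (15.3, 679)),
    "female": ((61.0, -51), (22.5, 499), (12.2, 746), (14.7, 496)),
}
_SCHOFIELD_W = {
    "male": ((59.5, -30.4), (22.7, 504.3), (17.7, 658.2), (15.0, 692.1)),
    "female": ((58.3, -31.1), (20.3, 485.9), (13.4, 692.6), (14.8, 486.6)),
}
_OXFORD = {
    "male": ((61.0, -33.7), (23.3, 514), (18.4, 581), (16.0, 545)),
    "female": ((58.9, -23.1), (20.1, 507), (11.1, 761), (13.1, 558)),
}
# (a*wt + b*ht_m + const) per band
_SCHOFIELD_WH = {
    "male": ((0.167, 1517, -618), (19.6, 130, 415), (16.2, 137, 516), (15.0, -10, 706)),
    "female": ((16.2, 1023, -413), (17.0, 162, 317), (8.4, 466, 200), (13.6, 283, 98)),
}
#: male <3 y weight coefficient as printed in the source table (likely typo).
_SCHOFIELD_WH_MALE_INFANT_AS_PRINTED = 1.67


def predict_ree(
    formula: FormulaId | str,
    inp: PredictionInput,
    tsf: Optional[float] = None,
    *,
    as_printed: bool = False,
) -> float:
    """Evaluate one REE prediction equation (kcal/day) for one subject.

    ``tsf`` (triceps skinfold, mm) is required by ``CP_FINAL`` only.
    Raises :class:`MissingPredictorError` if a needed predictor is absent and
    :class:`AgeOutOfRangeError` for ages >= 30 under banded formulas.
    """
    formula = FormulaId(formula)
    inp.validate()
    w, age, sex = inp.weight, inp.age, inp.sex

    if formula in HEIGHT_FORMULAS and inp.height is None:
        raise MissingPredictorError(f"{formula.value} requires height")
    if formula is FormulaId.CP_FINAL and tsf is None:
        raise MissingPredictorError("CP_FINAL requires triceps skinfold (tsf)")
    if tsf is not None and tsf <= 0:
        raise ValueError(f"tsf must be > 0, got {tsf}")

    if formula is FormulaId.CP_PRELIMINARY:
        return 24.0 * w + 380.0
    if formula is FormulaId.CP_FINAL:
        return 28.43 * w - 17.0 * tsf + 398.2
    if formula is FormulaId.HARRIS_BENEDICT:
        ht = inp.height  # cm
        if sex == "male":
            return 66.47 + 13.75 * w + 5.0 * ht - 6.76 * age
        return 655.10 + 9.56 * w + 1.85 * ht - 4.68 * age
    if formula is FormulaId.MIFFLIN:
        ht = inp.height  # cm
        base = 9.99 * w + 6.25 * ht - 4.92 * age
        return base + 5.0 if sex == "male" else base - 161.0

    band = _band_index(age)
    if formula is FormulaId.WHO:
        a, c = _WHO[sex][band]
        return a * w + c
    if formula is FormulaId.SCHOFIELD_W:
        a, c = _SCHOFIELD_W[sex][band]
        return a * w + c
    if formula is FormulaId.OXFORD:
        a, c = _OXFORD[sex][band]
        return a * w + c
    if formula is FormulaId.SCHOFIELD_WH:
        a, b, c = _SCHOFIELD_WH[sex][band]
        if as_printed and sex == "male" and band == 0:
            a = _SCHOFIELD_WH_MALE_INFANT_AS_PRINTED
        return a * w + b * (inp.height / 100.0) + c  # height in metres
    raise AssertionError(f"unhandled formula {formula}")  # pragma: no cover


@dataclass
class PredictionTable:
    """Dense subject x formula table of predictions with per-cell failures.

    ``values`` is a dataframe indexed by subject id with one column per
    formula (NaN where the prediction is undefined); ``failures`` lists
    (id, formula, reason) for every absent cell.
    """

    values: pd.DataFrame
    failures: pd.DataFrame

    def get(self, subject_id: str, formula: FormulaId | str) -> float:
        return float(self.values.loc[subject_id, FormulaId(formula).value])


def predict_all(
    cohort: Cohort,
    formulas: tuple[FormulaId, ...] | list[FormulaId] | set[FormulaId] = ALL_FORMULAS,
    *,
    as_printed: bool = False,
) -> PredictionTable:
    """Evaluate a set of formulas over a cohort.

    Per-subject failures (missing height, out-of-band age, ...) are recorded
    as NaN cells with a reason, never as zeros.
    """
    formulas = [FormulaId(f) for f in formulas]
    if not formulas:
        raise ValueError("formula set must be non-empty")
    ids = cohort.ids()
    values = pd.DataFrame(
        np.nan, index=pd.Index(ids, name="id"), columns=[f.value for f in formulas]
    )
    failures = []
    for s in cohort:
        inp = PredictionInput(sex=s.sex, age=s.age, weight=s.weight, height=s.height)
        for f in formulas:
            try:
                values.loc[s.id, f.value] = predict_ree(f, inp, tsf=s.tsf, as_printed=as_printed)
            except (MissingPredictorError, AgeOutOfRangeError, ValueError) as exc:
                failures.append({"id": s.id, "formula": f.value, "reason": str(exc)})
    return PredictionTable(
        values=values,
        failures=pd.DataFrame(failures, columns=["id", "formula", "reason"]),
    )
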