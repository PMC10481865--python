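"""Domain types, cohort CSV I/O, anthropometric helpers and filtering rules.

The cohort is a flat table of one record per child: anthropometry (weight,
height or knee height, triceps skinfold, arm circumference), feeding mode,
an externally computed BMI-for-age z-score, and — where indirect calorimetry
and a dietary record are available — measured resting energy expenditure
(REE, kcal/day), respiratory quotient and daily caloric intake.

Heights are stored in centimetres throughout; individual prediction formulas
convert units as each equation requires.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
FEEDING_MODES = ("oral", "enteral", "mixed")
NUTRITION_GROUPS = ("group1", "group2", "unassigned")

#: Canonical CSV column order (comma-separated, UTF-8, "." decimals).
CSV_COLUMNS = [
    "id",
    "sex",
    "age_years",
    "weight_kg",
    "height_cm",
    "knee_height_cm",
    "tsf_mm",
    "arm_circumference_cm",
    "feeding",
    "bmi_zscore",
    "ree_kcal_day",
    "rq",
    "intake_kcal_day",
]

_FIELD_TO_COLUMN = {
    "id": "id",
    "sex": "sex",
    "age": "age_years",
    "weight": "weight_kg",
    "height": "height_cm",
    "knee_height": "knee_height_cm",
    "tsf": "tsf_mm",
    "arm_circumference": "arm_circumference_cm",
    "feeding": "feeding",
    "bmi_zscore": "bmi_zscore",
    "ree_measured": "ree_kcal_day",
    "rq": "rq",
    "caloric_intake": "intake_kcal_day",
}
_COLUMN_TO_FIELD = {v: k for k, v in _FIELD_TO_COLUMN.items()}

_REQUIRED_COLUMNS = ["id", "sex", "age_years", "weight_kg", "tsf_mm", "feeding"]


class CohortFormatError(ValueError):
    """A cohort file does not conform to the expected CSV layout."""


class CohortValidationError(ValueError):
    """One or more subject records violate a domain invariant."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass
class SubjectRecord:
    """One child's anthropometry, feeding, intake and calorimetry results.

    Optional measurements are ``None`` when absent.  ``validate`` returns the
    list of invariant violations rather than raising, so that file readers
    can collect problems across rows.
    """

    id: str
    sex: str                       # "male" | "female"
    age: float                     # years
    weight: float                  # kg
    tsf: float                     # triceps skinfold, mm
    feeding: str                   # "oral" | "enteral" | "mixed"
    height: Optional[float] = None          # cm
    knee_height: Optional[float] = None     # cm
    arm_circumference: Optional[float] = None  # cm
    bmi_zscore: Optional[float] = None      # BMI-for-age SDS (external)
    ree_measured: Optional[float] = None    # kcal/day, indirect calorimetry
    rq: Optional[float] = None              # respiratory quotient
    caloric_intake: Optional[float] = None  # kcal/day

    def validate(self) -> list[str]:
        problems: list[str] = []
        if not self.id:
            problems.append("id must be non-empty")
        if self.sex not in SEXES:
            problems.append(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.feeding not in FEEDING_MODES:
            problems.append(
                f"feeding must be one of {FEEDING_MODES}, got {self.feeding!r}"
            )
        if not (self.weight is not None and self.weight > 0):
            problems.append(f"weight must be > 0, got {self.weight}")
        if self.age is None or not (0 <= self.age <= 19):
            problems.append(f"age must be in [0, 19] years, got {self.age}")
        if self.tsf is not None and self.tsf <= 0:
            problems.append(f"tsf must be > 0 when present, got {self.tsf}")
        if self.height is not None and self.height <= 0:
            problems.append(f"height must be > 0 when present, got {self.height}")
        if self.knee_height is not None and self.knee_height <= 0:
            problems.append(f"knee_height must be > 0, got {self.knee_height}")
        if self.rq is not None and not (0.5 < self.rq < 1.3):
            problems.append(f"rq must lie in (0.5, 1.3), got {self.rq}")
        return problems


@dataclass
class Cohort:
    """An ordered collection of :class:`SubjectRecord` with unique ids."""

    subjects: list[SubjectRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def __getitem__(self, i):
        return self.subjects[i]

    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    def validate(self) -> list[str]:
        problems = []
        seen: set[str] = set()
        for i, s in enumerate(self.subjects):
            problems.extend(f"subject {i} ({s.id}): {p}" for p in s.validate())
            if s.id in seen:
                problems.append(f"duplicate id {s.id!r}")
            seen.add(s.id)
        return problems

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append({col: getattr(s, _COLUMN_TO_FIELD[col]) for col in CSV_COLUMNS})
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        return df


def _coerce_optional_float(value, column: str, row: int) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CohortFormatError(
            f"row {row}: could not parse {column}={value!r} as a number"
        ) from None


def cohort_from_dataframe(df: pd.DataFrame, provenance: str = "") -> Cohort:
    """Build a validated :class:`Cohort` from a dataframe in CSV layout."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing required column(s): {', '.join(missing)}")
    subjects = []
    problems: list[str] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        kwargs = {}
        for col in CSV_COLUMNS:
            if col not in df.columns:
                value = None
            else:
                value = rowd[col]
            name = _COLUMN_TO_FIELD[col]
            if col in ("id", "sex", "feeding"):
                kwargs[name] = "" if value is None or (isinstance(value, float) and math.isnan(value)) else str(value)
            else:
                kwargs[name] = _coerce_optional_float(value, col, row_idx)
        rec = SubjectRecord(**kwargs)
        row_problems = rec.validate()
        if row_problems:
            problems.extend(f"row {row_idx}: {p}" for p in row_problems)
        subjects.append(rec)
    cohort = Cohort(subjects=subjects, provenance=provenance)
    dup = [p for p in cohort.validate() if "duplicate id" in p]
    problems.extend(dup)
    if problems:
        raise CohortValidationError(problems)
    return cohort


def read_cohort_csv(path) -> Cohort:
    """Read a cohort CSV (see :data:`CSV_COLUMNS`) into a :class:`Cohort`.

    Raises :class:`CohortFormatError` for structural problems (missing
    required columns, unparseable numbers) and :class:`CohortValidationError`
    listing every row whose values violate a domain invariant.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"id": str})
    return cohort_from_dataframe(df, provenance=str(path))


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write the cohort in the canonical column order; absent optionals as empty cells."""
    df = cohort.to_dataframe()
    df.to_csv(path, index=False, float_format="%.10g")


def height_from_knee_height(kh: float) -> float:
    """Estimate standing height (cm) from knee height (cm).

    Uses the segmental equation for non-ambulant children,
    ``height = 2.69 * knee_height + 24.2``.
    """
    if kh is None or kh <= 0:
        raise ValueError(f"knee height must be > 0 cm, got {kh}")
    return 2.69 * kh + 24.2


def bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m^2, from weight in kg and height in cm."""
    if weight is None or weight <= 0 or height is None or height <= 0:
        raise ValueError(f"weight and height must be positive, got {weight}, {height}")
    return weight / (height / 100.0) ** 2


def classify_nutrition_group(bmi_zscore: float) -> str:
    """Assign a nutritional-status group from a BMI-for-age z-score.

    ``group1`` is moderate plus severe malnutrition (z <= -2); ``group2``
    pools mild malnutrition, normal status and overweight/obesity (z >= -1).
    Scores in the open gap (-2, -1) are ``unassigned`` and are dropped from
    group comparisons.
    """
    if bmi_zscore is None or not math.isfinite(bmi_zscore):
        raise ValueError(f"bmi z-score must be finite, got {bmi_zscore}")
    if bmi_zscore <= -2:
        return "group1"
    if bmi_zscore >= -1:
        return "group2"
    return "unassigned"


def exclude_extreme_ree(cohort: Cohort, min_ree: float = 300.0) -> Cohort:
    """Drop subjects whose measured REE falls below ``min_ree`` kcal/day.

    Physiologically implausible calorimetry values (e.g. from a severely
    malnourished child with an unusable trace) distort both the conversion
    equations and the model fit, so they are screened out before analysis.
    Subjects without a measured REE are kept.  Removals are logged with ids.
    """
    if min_ree < 0:
        raise ValueError(f"min_ree must be >= 0, got {min_ree}")
    kept, removed = [], []
    for s in cohort.subjects:
        if s.ree_measured is not None and s.ree_measured < min_ree:
            removed.append(s.id)
        else:
            kept.append(s)
    if removed:
        logger.warning(
            "excluded %d subject(s) with REE < %.0f kcal/day: %s",
            len(removed), min_ree, ", ".join(removed),
        )
    if not kept:
        logger.warning("all subjects excluded by the REE floor of %.0f kcal/day", min_ree)
    return Cohort(subjects=kept, provenance=cohort.provenance)
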