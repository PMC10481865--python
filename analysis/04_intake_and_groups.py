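#!/usr/bin/env python
"""Descriptive analyses: nutrition-group REE quantiles and the intake model.

Splits the cohort by BMI-for-age z-score into moderate-plus-severe
malnutrition (z <= -2) and mild-to-normal-or-above (z >= -1), compares the
REE distributions at the 25th/50th/75th percentiles with bootstrap
confidence intervals, then fits the multivariable linear model
REE ~ caloric intake + age (+ sex, dropped when not evident) and reports
the clinically scaled effects.
"""

import json
from pathlib import Path

from cpree.cohort import classify_nutrition_group, read_cohort_csv
from cpree.model_dev import intake_model, quantile_group_diff

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 404


def main() -> None:
    cohort = read_cohort_csv(RESULTS / "cohort_screened.csv")
    groups = [classify_nutrition_group(s.bmi_zscore) for s in cohort]
    ree = [s.ree_measured for s in cohort]
    assigned = [(r, g) for r, g in zip(ree, groups) if g != "unassigned"]
    print(f"group sizes: group1={sum(g == 'group1' for _, g in assigned)}, "
          f"group2={sum(g == 'group2' for _, g in assigned)}, "
          f"unassigned={sum(g == 'unassigned' for g in groups)} (dropped)")
    qc = quantile_group_diff(
        [r for r, _ in assigned], [g for _, g in assigned], n_boot=2000, seed=SEED
    )
    print("REE difference group2 - group1 (kcal/day):")
    for t in qc.taus:
        lo, hi = qc.ci95[t]
        sig = "evident" if lo > 0 or hi < 0 else "not evident"
        print(f"  tau={t:.2f}: {qc.differences[t]:7.1f}  95% CI [{lo:.1f}, {hi:.1f}]  ({sig})")

    im = intake_model(
        ree,
        [s.caloric_intake for s in cohort],
        [s.age for s in cohort],
        [s.sex for s in cohort],
    )
    print(f"\nintake model on {im.n_complete} complete cases "
          f"(sex {'dropped' if im.sex_dropped else 'retained'}):")
    print(f"  +388 kcal/day intake -> REE {im.effect_per_388_kcal_intake:+.1f} kcal/day")
    print(f"  +4.75 years of age   -> REE {im.effect_per_4_75_years:+.1f} kcal/day")

    (RESULTS / "intake_and_groups.json").write_text(
        json.dumps(
            {
                "quantile_differences": {str(t): qc.differences[t] for t in qc.taus},
                "quantile_ci95": {str(t): qc.ci95[t] for t in qc.taus},
                "n_group1": qc.n_group1,
                "n_group2": qc.n_group2,
                "intake_effect_per_388": im.effect_per_388_kcal_intake,
                "age_effect_per_4_75y": im.effect_per_4_75_years,
                "intake_model_coefficients": im.fit.coefficients,
                "n_complete": im.n_complete,
            },
            indent=2,
        )
    )
    print(f"wrote {RESULTS / 'intake_and_groups.json'}")


if __name__ == "__main__":
    main()
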