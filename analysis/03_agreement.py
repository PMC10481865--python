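#!/usr/bin/env python
"""Method comparison: each formula against indirect calorimetry.

For every prediction formula, runs the Bland-Altman analysis with a
proportional-bias test, and — since the bias drifts with the magnitude —
fits Carstensen's difference-on-average regression to obtain sloped limits
of agreement and the bidirectional conversion equations between formula
estimates and calorimetry.  Writes results/agreement/<formula>.json and a
one-line-per-formula summary table.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from cpree.agreement import (
    PairedMeasurements,
    bland_altman,
    carstensen_loa,
    conversion_equations,
)
from cpree.cohort import read_cohort_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort_csv(RESULTS / "cohort_screened.csv")
    measured = pd.Series({s.id: s.ree_measured for s in cohort})
    preds = pd.read_csv(RESULTS / "predictions.csv").pivot(
        index="id", columns="formula", values="ree_kcal_day"
    )
    out_dir = RESULTS / "agreement"
    out_dir.mkdir(exist_ok=True)

    rows = []
    for formula in preds.columns:
        col = preds[formula].dropna()
        pairs = PairedMeasurements(
            y1=col.to_numpy(), y2=measured.loc[col.index].to_numpy(), ids=list(col.index)
        )
        ba = bland_altman(pairs)
        cf = carstensen_loa(pairs)
        conv_to_ic, conv_from_ic = None, None
        if ba.proportional_bias:
            c12, c21 = conversion_equations(cf)
            conv_to_ic = c21  # formula value -> calorimetry scale
            conv_from_ic = c12
        report = {
            "formula": formula,
            "bland_altman": dataclasses.asdict(ba),
            "carstensen": dataclasses.asdict(cf),
            "conversion_to_calorimetry": dataclasses.asdict(conv_to_ic) if conv_to_ic else None,
            "conversion_from_calorimetry": dataclasses.asdict(conv_from_ic) if conv_from_ic else None,
        }
        (out_dir / f"{formula}.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        rows.append(
            {
                "formula": formula,
                "mean_bias": ba.mean_bias,
                "pearson_r_bias_vs_mean": ba.pearson_r_bias_vs_mean,
                "p": ba.p_value,
                "proportional_bias": ba.proportional_bias,
                "carstensen_b": cf.b,
                "conversion": (
                    f"{conv_to_ic.intercept:+.2f} {conv_to_ic.slope:+.3f}*x" if conv_to_ic else "-"
                ),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "agreement_summary.csv", index=False)
    print("proportional-bias assessment (difference = formula - calorimetry):")
    print(table.round(3).to_string(index=False))
    print(f"wrote per-formula reports under {out_dir}")


if __name__ == "__main__":
    main()
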