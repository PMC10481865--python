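#!/usr/bin/env python
"""Develop and validate the population-specific weight + TSF model.

On the training split (first 54 subjects, mirroring the historical design):
test the weight effect for nonlinearity with a 3-knot restricted cubic
spline and a likelihood-ratio test; run the limited backward selection with
weight forced in; fit the final linear model; bootstrap (3,000 resamples)
the optimism correction of R^2-adjusted and MSE.  Then compare the model's
test-split predictions against every formula by Lin's concordance
correlation coefficient.
"""

import json
from pathlib import Path

import pandas as pd

from cpree.agreement import compare_formulas_ccc, lin_ccc
from cpree.cohort import read_cohort_csv
from cpree.formulas import ALL_FORMULAS, predict_all
from cpree.model_dev import (
    backward_select,
    bootstrap_validate,
    fit_linear,
    lrt_nonlinearity,
    rcs_basis,
    train_test_split_validate,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 505
TRAIN_N = 54
N_BOOT = 3000


def main() -> None:
    cohort = read_cohort_csv(RESULTS / "cohort_screened.csv")
    split = train_test_split_validate(cohort, train_n=TRAIN_N)
    train = [s for s in cohort if s.id in set(split.train_ids)]
    df = pd.DataFrame(
        {
            "ree": [s.ree_measured for s in train],
            "weight": [s.weight for s in train],
            "tsf": [s.tsf for s in train],
            "height": [s.height for s in train],
            "age": [s.age for s in train],
            "sex": [1.0 if s.sex == "male" else 0.0 for s in train],
        }
    )

    basis = rcs_basis(df["weight"].to_numpy())
    lin = fit_linear(df[["weight"]], df["ree"])
    spl = fit_linear(basis.transform(df["weight"].to_numpy()).set_index(df.index), df["ree"])
    stat, p = lrt_nonlinearity(lin, spl)
    print(f"nonlinearity of weight (3-knot RCS, LRT): chi2 = {stat:.2f}, p = {p:.3f} "
          f"-> {'keep spline' if p < 0.05 else 'linear weight retained'}")

    selected = backward_select(df, "ree")
    print(f"backward selection retained: {selected.terms}")

    final = split.fit
    c = final.coefficients
    print(f"final model (n={final.n}): REE = {c['weight']:.2f}*weight "
          f"{c['tsf']:+.2f}*TSF {c['intercept']:+.1f}   "
          f"R2adj = {final.r2adj:.4f}, MSE = {final.mse:.1f}")

    vr_r2, vr_mse = bootstrap_validate(df[["weight", "tsf"]], df["ree"],
                                       n_boot=N_BOOT, seed=SEED)
    print(f"\noptimism correction over {N_BOOT} bootstrap resamples:")
    for vr in (vr_r2, vr_mse):
        print(f"  {vr.index:>3}: original {vr.original:.4f}  training {vr.training:.4f}  "
              f"test {vr.test:.4f}  optimism {vr.optimism:+.4f}  corrected {vr.corrected:.4f}")

    preds = predict_all(cohort, ALL_FORMULAS)
    test_values = preds.values.loc[split.test_ids].copy()
    test_values["NEW_MODEL"] = split.predictions
    ccc = compare_formulas_ccc(test_values, split.measured)
    ccc.to_csv(RESULTS / "ccc_table.csv", index=False)
    print(f"\nconcordance with calorimetry on the {len(split.test_ids)}-subject test split:")
    print(ccc.round(3).to_string(index=False))

    (RESULTS / "model.json").write_text(
        json.dumps(
            {
                "final_model": {"terms": final.terms, "coefficients": c,
                                "r2adj": final.r2adj, "mse": final.mse, "n": final.n},
                "selected_terms": selected.terms,
                "weight_nonlinearity_lrt": {"statistic": stat, "p": p},
                "rcs_knots": list(basis.knots),
                "validation": {
                    vr.index: {
                        "original": vr.original, "training": vr.training, "test": vr.test,
                        "optimism": vr.optimism, "corrected": vr.corrected, "n_boot": vr.n_boot,
                    }
                    for vr in (vr_r2, vr_mse)
                },
            },
            indent=2,
        )
    )
    print(f"wrote {RESULTS / 'model.json'} and {RESULTS / 'ccc_table.csv'}")


if __name__ == "__main__":
    main()
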