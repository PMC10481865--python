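"""End-to-end orchestration of the REE analysis.

``run_all`` sequences the full study workflow on one cohort: ingest or
simulate, screen implausible calorimetry values, evaluate every prediction
formula, run the method-comparison statistics (Bland-Altman, Carstensen
limits of agreement, conversion equations) per formula, develop and validate
the population-specific weight + TSF model, and emit the nomogram.  Each
stage writes a diffable JSON/CSV artifact; stage failures are recorded and
independent later stages still run.  Everything is deterministic under the
configured seed (one global seed fanned out to per-stage substreams).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    PairedMeasurements,
    bland_altman,
    carstensen_loa,
    compare_formulas_ccc,
    conversion_equations,
)
from .cohort import Cohort, exclude_extreme_ree, read_cohort_csv, write_cohort_csv
from .formulas import ALL_FORMULAS, FormulaId, predict_all
from .model_dev import (
    backward_select,
    bootstrap_validate,
    fit_linear,
    lrt_nonlinearity,
    rcs_basis,
    train_test_split_validate,
)
from .nomogram import build_nomogram, render_nomogram
from .simulate import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for :func:`run_all`."""

    output_dir: Path
    cohort_path: Optional[Path] = None          # read this cohort ...
    generator: Optional[GeneratorConfig] = None  # ... or simulate one
    formulas: tuple[FormulaId, ...] = ALL_FORMULAS
    min_ree: float = 300.0      # kcal/day exclusion floor
    train_n: int = 54
    n_boot: int = 3000
    seed: int = 0
    nomogram_ranges: dict = field(
        default_factory=lambda: {"weight": (5.0, 60.0), "tsf": (2.0, 20.0)}
    )

    def validate(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.train_n < 10:
            raise ValueError("train_n must be >= 10")
        if self.cohort_path is None and self.generator is None:
            raise ValueError("either cohort_path or generator must be given")


@dataclass
class RunReport:
    outputs: dict[str, Path] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, default=_json_default, indent=2, sort_keys=True) + "\n")


def run_all(config: RunConfig) -> RunReport:
    """Run the full analysis; see the module docstring for stage order."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] % 2**31) for s in seeds]

    # --- cohort -----------------------------------------------------------
    if config.cohort_path is not None:
        cohort = read_cohort_csv(config.cohort_path)
    else:
        gen = dataclasses.replace(config.generator, seed=stage_seed[0])
        cohort = generate_cohort(gen)
    write_cohort_csv(cohort, out / "cohort.csv")
    report.outputs["cohort"] = out / "cohort.csv"

    cohort = exclude_extreme_ree(cohort, min_ree=config.min_ree)

    # --- formula predictions ---------------------------------------------
    table = None
    try:
        table = predict_all(cohort, config.formulas)
        pred_long = (
            table.values.reset_index()
            .melt(id_vars="id", var_name="formula", value_name="ree_kcal_day")
            .sort_values(["id", "formula"], ignore_index=True)
        )
        pred_long["status"] = np.where(pred_long["ree_kcal_day"].notna(), "ok", "failed")
        pred_long.to_csv(out / "predictions.csv", index=False)
        report.outputs["predictions"] = out / "predictions.csv"
    except Exception as exc:  # noqa: BLE001 - stage isolation
        report.errors["predictions"] = str(exc)
        logger.exception("prediction stage failed")

    measured = pd.Series(
        {s.id: s.ree_measured for s in cohort}, name="measured", dtype=float
    )
    measured.index.name = "id"

    # --- agreement per formula -------------------------------------------
    if table is not None:
        agree_dir = out / "agreement"
        agree_dir.mkdir(exist_ok=True)
        for f in config.formulas:
            try:
                col = table.values[f.value]
                mask = col.notna() & measured.notna()
                pairs = PairedMeasurements(
                    y1=col[mask].to_numpy(),
                    y2=measured[mask].to_numpy(),
                    ids=list(col[mask].index),
                )
                ba = bland_altman(pairs)
                cf = carstensen_loa(pairs)
                conv12, conv21 = conversion_equations(cf)
                _dump(
                    {
                        "formula": f.value,
                        "bland_altman": ba,
                        "carstensen": {"a": cf.a, "b": cf.b, "tau": cf.tau, "n": cf.n},
                        "conversion_y1_from_y2": conv12,
                        "conversion_y2_from_y1": conv21,
                    },
                    agree_dir / f"{f.value}.json",
                )
                report.outputs[f"agreement/{f.value}"] = agree_dir / f"{f.value}.json"
            except Exception as exc:  # noqa: BLE001
                report.errors[f"agreement/{f.value}"] = str(exc)
                logger.exception("agreement stage failed for %s", f.value)

    # --- model development -------------------------------------------------
    split = None
    try:
        split = train_test_split_validate(cohort, train_n=config.train_n)
        train_ids = set(split.train_ids)
        rows = [s for s in cohort if s.id in train_ids]
        train_df = pd.DataFrame(
            {
                "ree": [s.ree_measured for s in rows],
                "weight": [s.weight for s in rows],
                "tsf": [s.tsf for s in rows],
                "height": [s.height for s in rows],
                "age": [s.age for s in rows],
                "sex": [1.0 if s.sex == "male" else 0.0 for s in rows],
            }
        )
        # nonlinearity check on weight
        basis = rcs_basis(train_df["weight"].to_numpy())
        spline_X = basis.transform(train_df["weight"].to_numpy())
        spline_X.index = train_df.index
        lin = fit_linear(train_df[["weight"]], train_df["ree"])
        spl = fit_linear(spline_X, train_df["ree"])
        lrt_stat, lrt_p = lrt_nonlinearity(lin, spl)
        selected = backward_select(
            train_df, "ree", forced=("weight",), candidates=("height", "age", "sex", "tsf")
        )
        final = split.fit
        vr_r2, vr_mse = bootstrap_validate(
            train_df[["weight", "tsf"]], train_df["ree"],
            n_boot=config.n_boot, seed=stage_seed[1],
        )
        _dump(
            {
                "final_model": {
                    "terms": final.terms,
                    "coefficients": final.coefficients,
                    "r2adj": final.r2adj,
                    "mse": final.mse,
                    "n": final.n,
                },
                "selected_terms": selected.terms,
                "weight_nonlinearity_lrt": {"statistic": lrt_stat, "p": lrt_p},
                "rcs_knots": basis.knots,
                "train_n": len(split.train_ids),
                "test_n": len(split.test_ids),
            },
            out / "model.json",
        )
        _dump({"r2": vr_r2, "mse": vr_mse}, out / "validation.json")
        report.outputs["model"] = out / "model.json"
        report.outputs["validation"] = out / "validation.json"
    except Exception as exc:  # noqa: BLE001
        report.errors["model"] = str(exc)
        logger.exception("model-development stage failed")

    # --- concordance comparison on the test set ---------------------------
    if table is not None and split is not None:
        try:
            test_values = table.values.loc[split.test_ids].copy()
            test_values["NEW_MODEL"] = split.predictions
            ccc = compare_formulas_ccc(test_values, split.measured)
            ccc.to_csv(out / "ccc_table.csv", index=False)
            report.outputs["ccc_table"] = out / "ccc_table.csv"
        except Exception as exc:  # noqa: BLE001
            report.errors["ccc_table"] = str(exc)
            logger.exception("concordance stage failed")

    # --- nomogram ----------------------------------------------------------
    if split is not None:
        try:
            nom = build_nomogram(split.fit, config.nomogram_ranges)
            render_nomogram(nom, out / "nomogram.txt")
            report.outputs["nomogram"] = out / "nomogram.txt"
        except Exception as exc:  # noqa: BLE001
            report.errors["nomogram"] = str(exc)
            logger.exception("nomogram stage failed")

    # --- run log -----------------------------------------------------------
    (out / "run.log").write_text(
        "\n".join(
            [
                f"cpree version: {__version__}",
                f"seed: {config.seed}",
                f"stage seeds: {stage_seed}",
                f"min_ree: {config.min_ree}",
                f"train_n: {config.train_n}",
                f"n_boot: {config.n_boot}",
                f"stages failed: {sorted(report.errors) or 'none'}",
            ]
        )
        + "\n"
    )
    return report
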