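import numpy as np
import pandas as pd
import pytest

from cpree.model_dev import (
    FitError,
    backward_select,
    bootstrap_validate,
    fit_linear,
    intake_model,
    lrt_nonlinearity,
    quantile_group_diff,
    rcs_basis,
    train_test_split_validate,
)
from cpree.simulate import GeneratorConfig, generate_cohort


def brute_force_ols(X, y):
    """Normal equations by hand-coded summation (independent oracle)."""
    n = len(y)
    cols = [[1.0] * n] + [list(map(float, X[c])) for c in X.columns]
    p = len(cols)
    A = [[sum(cols[i][k] * cols[j][k] for k in range(n)) for j in range(p)] for i in range(p)]
    b = [sum(cols[i][k] * y[k] for k in range(n)) for i in range(p)]
    beta = np.linalg.solve(np.array(A), np.array(b))
    return beta


class TestFitLinear:
    def test_noiseless_identity_recovery(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"weight": rng.uniform(5, 60, 40), "tsf": rng.uniform(2, 20, 40)})
        y = 28.43 * X["weight"] - 17 * X["tsf"] + 398.2
        fit = fit_linear(X, y)
        assert fit.coefficients["weight"] == pytest.approx(28.43, abs=1e-9)
        assert fit.coefficients["tsf"] == pytest.approx(-17.0, abs=1e-9)
        assert fit.coefficients["intercept"] == pytest.approx(398.2, abs=1e-8)
        assert fit.r2adj == pytest.approx(1.0, abs=1e-12)

    def test_constant_response(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        fit = fit_linear(X, np.full(10, 7.0))
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-10)
        assert fit.r2adj <= 0.0

    def test_rank_deficient_design_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        with pytest.raises(FitError):
            fit_linear(X, np.arange(10.0))

    def test_agrees_with_brute_force_normal_equations(self):
        rng = np.random.default_rng(1)
        for n in (5, 8, 12):
            X = pd.DataFrame({"w": rng.uniform(5, 60, n), "t": rng.uniform(2, 20, n)})
            y = list(rng.uniform(300, 1500, n))
            fit = fit_linear(X, y)
            beta = brute_force_ols(X, y)
            assert fit.coefficients["intercept"] == pytest.approx(beta[0], abs=1e-9)
            assert fit.coefficients["w"] == pytest.approx(beta[1], abs=1e-9)
            assert fit.coefficients["t"] == pytest.approx(beta[2], abs=1e-9)

    def test_mse_and_residual_sd_denominators(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.uniform(0, 1, 30)})
        y = rng.uniform(0, 1, 30)
        fit = fit_linear(X, y)
        assert fit.mse == pytest.approx(fit.sse / 30)
        assert fit.residual_sd == pytest.approx(np.sqrt(fit.sse / (30 - 2)))


class TestRcsBasis:
    def test_restricted_term_zero_below_first_knot_and_continuous(self):
        x = np.linspace(0, 100, 200)
        basis = rcs_basis(x)
        grid = np.linspace(-10, 110, 2000)
        vals = basis.transform(grid)["rcs"].to_numpy()
        assert np.all(vals[grid <= basis.knots[0]] == 0)
        assert np.all(np.abs(np.diff(vals)) < 1.0)  # no jumps on a fine grid

    def test_linear_beyond_boundary_knots(self):
        x = np.linspace(0, 100, 200)
        basis = rcs_basis(x)
        grid = np.linspace(basis.knots[2] + 1, basis.knots[2] + 50, 500)
        vals = basis.transform(grid)["rcs"].to_numpy()
        second_diff = np.diff(vals, 2)
        assert np.max(np.abs(second_diff)) < 1e-6

    def test_all_equal_input_rejected(self):
        with pytest.raises(FitError):
            rcs_basis(np.full(50, 3.0))


class TestLrtNonlinearity:
    def _fits(self, x, y):
        basis = rcs_basis(x)
        lin = fit_linear(pd.DataFrame({"x": x}), y)
        spl = fit_linear(basis.transform(x), y)
        return lin, spl

    def test_identical_models_give_null_result(self):
        lin = fit_linear(pd.DataFrame({"x": np.arange(20.0)}), np.arange(20.0) * 2 + 1)
        stat, p = lrt_nonlinearity(lin, lin_spline := fit_linear(
            rcs_basis(np.arange(20.0)).transform(np.arange(20.0)), np.arange(20.0) * 2 + 1
        ))
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_detects_strong_quadratic_effect(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(5, 60, 500)
        y = 0.5 * (x - 30) ** 2 + rng.normal(0, 20, 500)
        stat, p = lrt_nonlinearity(*self._fits(x, y))
        assert p < 0.01

    def test_mismatched_sample_sizes_rejected(self):
        a = fit_linear(pd.DataFrame({"x": np.arange(20.0)}), np.arange(20.0))
        b = fit_linear(pd.DataFrame({"x": np.arange(30.0), "z": np.arange(30.0) ** 2}), np.arange(30.0))
        with pytest.raises(ValueError):
            lrt_nonlinearity(a, b)


class TestBackwardSelect:
    def make_data(self, n=1000, seed=4, null=False):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "weight": rng.uniform(5, 60, n),
                "tsf": rng.uniform(2, 20, n),
                "height": rng.uniform(80, 170, n),
                "age": rng.uniform(1, 19, n),
                "sex": rng.integers(0, 2, n).astype(float),
            }
        )
        signal = 398.2 + 28.43 * df["weight"]
        if not null:
            signal = signal - 17 * df["tsf"]
        df["ree"] = signal + rng.normal(0, 200, n)
        return df

    def test_retains_only_true_effects(self):
        # each null candidate survives w.p. ~5%, so require a clear majority
        hits = sum(
            set(backward_select(self.make_data(seed=s), "ree").terms) == {"weight", "tsf"}
            for s in range(5)
        )
        assert hits >= 3

    def test_null_candidates_reduce_to_forced_model(self):
        hits = 0
        for seed in range(5):
            fit = backward_select(self.make_data(seed=100 + seed, null=True), "ree")
            hits += set(fit.terms) == {"weight"}
        assert hits >= 3  # majority over seeds; each null term is kept w.p. ~0.05

    def test_empty_candidates_returns_forced_model(self):
        df = self.make_data(n=100)
        fit = backward_select(df, "ree", candidates=())
        assert fit.terms == ["weight"]

    def test_forced_term_never_removed_even_if_null(self):
        df = self.make_data(n=500, seed=6, null=True)
        df["ree"] = 500 + np.random.default_rng(7).normal(0, 100, 500)  # weight truly null
        fit = backward_select(df, "ree")
        assert "weight" in fit.terms


class TestBootstrapValidate:
    def test_noiseless_model_has_no_optimism(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"w": rng.uniform(5, 60, 54), "t": rng.uniform(2, 20, 54)})
        y = 28.43 * X["w"] - 17 * X["t"] + 398.2
        vr_r2, vr_mse = bootstrap_validate(X, y, n_boot=200, seed=1)
        assert vr_r2.original == pytest.approx(1.0, abs=1e-12)
        assert abs(vr_r2.optimism) < 1e-9
        assert vr_r2.corrected == pytest.approx(1.0, abs=1e-9)

    def test_optimism_identities_hold_exactly(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"w": rng.uniform(5, 60, 54), "t": rng.uniform(2, 20, 54)})
        y = 28.43 * X["w"] - 17 * X["t"] + 398.2 + rng.normal(0, 200, 54)
        for vr in bootstrap_validate(X, y, n_boot=300, seed=2):
            assert vr.optimism == vr.training - vr.test
            assert vr.corrected == vr.original - vr.optimism

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"w": rng.uniform(5, 60, 40)})
        y = 24 * X["w"] + 380 + rng.normal(0, 150, 40)
        a = bootstrap_validate(X, y, n_boot=100, seed=5)
        b = bootstrap_validate(X, y, n_boot=100, seed=5)
        assert a == b

    def test_overfit_model_shows_positive_r2_optimism(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({f"x{i}": rng.normal(size=30) for i in range(5)})
        y = rng.normal(size=30)
        vr_r2, vr_mse = bootstrap_validate(X, y, n_boot=300, seed=3)
        assert vr_r2.optimism > 0
        assert vr_mse.optimism < 0  # apparent MSE is optimistically small


class TestTrainTestSplit:
    def test_split_sizes(self):
        cohort = generate_cohort(GeneratorConfig(n=95, seed=12))
        sv = train_test_split_validate(cohort, train_n=54)
        assert len(sv.train_ids) == 54
        assert len(sv.test_ids) == 41

    def test_noiseless_data_gives_perfect_test_concordance(self):
        from cpree.agreement import lin_ccc

        cohort = generate_cohort(GeneratorConfig(n=95, seed=13, ree_noise_sd=0.0,
                                                 intake_noise_sd=0.0))
        sv = train_test_split_validate(cohort, train_n=54)
        est, _ = lin_ccc(sv.predictions.values, sv.measured.values)
        assert est == pytest.approx(1.0, abs=1e-9)

    def test_shuffle_is_reproducible(self):
        cohort = generate_cohort(GeneratorConfig(n=80, seed=14))
        a = train_test_split_validate(cohort, train_n=54, shuffle_seed=3)
        b = train_test_split_validate(cohort, train_n=54, shuffle_seed=3)
        assert a.train_ids == b.train_ids

    def test_insufficient_subjects_rejected(self):
        cohort = generate_cohort(GeneratorConfig(n=40, seed=15))
        with pytest.raises(FitError):
            train_test_split_validate(cohort, train_n=54)


class TestQuantileGroupDiff:
    def test_simple_median_difference(self):
        g1 = [700, 750, 800, 850, 900]
        g2 = [800, 850, 900, 950, 1000]
        qc = quantile_group_diff(g1 + g2, ["group1"] * 5 + ["group2"] * 5, n_boot=200)
        assert qc.differences[0.5] == pytest.approx(100.0)

    def test_median_tau_equals_difference_of_sample_medians(self):
        rng = np.random.default_rng(16)
        g1 = rng.uniform(500, 900, 37)
        g2 = rng.uniform(600, 1100, 48)
        qc = quantile_group_diff(
            np.concatenate([g1, g2]), ["group1"] * 37 + ["group2"] * 48, n_boot=100
        )
        assert qc.differences[0.5] == pytest.approx(np.median(g2) - np.median(g1))

    def test_identical_groups_cover_zero(self):
        rng = np.random.default_rng(17)
        vals = rng.uniform(600, 1000, 60)
        qc = quantile_group_diff(
            np.concatenate([vals, vals]), ["group1"] * 60 + ["group2"] * 60,
            n_boot=500, seed=1,
        )
        for t in qc.taus:
            assert qc.differences[t] == 0
            lo, hi = qc.ci95[t]
            assert lo <= 0 <= hi

    def test_known_shift_recovered(self):
        rng = np.random.default_rng(18)
        g1 = rng.normal(750, 150, 200)
        g2 = rng.normal(870, 150, 200)
        qc = quantile_group_diff(
            np.concatenate([g1, g2]), ["group1"] * 200 + ["group2"] * 200,
            n_boot=1000, seed=2,
        )
        lo, hi = qc.ci95[0.5]
        assert lo <= 120 <= hi

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            quantile_group_diff([1, 2, 3, 4, 5, 6], ["group1"] * 2 + ["group2"] * 4)


class TestIntakeModel:
    def test_recovers_scaled_effects(self):
        rng = np.random.default_rng(19)
        n = 1000
        intake = rng.uniform(800, 1600, n)
        age = rng.uniform(1, 19, n)
        ree = 100 + (163 / 388) * intake + (102 / 4.75) * age + rng.normal(0, 80, n)
        result = intake_model(ree, intake, age)
        assert result.effect_per_388_kcal_intake == pytest.approx(163, rel=0.05)
        assert result.effect_per_4_75_years == pytest.approx(102, rel=0.05)

    def test_scaled_effect_is_exact_multiple_of_coefficient(self):
        rng = np.random.default_rng(20)
        intake = rng.uniform(800, 1600, 50)
        age = rng.uniform(1, 19, 50)
        ree = 0.4 * intake + 20 * age + rng.normal(0, 50, 50)
        result = intake_model(ree, intake, age)
        assert result.effect_per_388_kcal_intake == pytest.approx(
            result.fit.coefficients["intake"] * 388.0, abs=1e-12
        )

    def test_constant_intake_rejected(self):
        with pytest.raises(FitError):
            intake_model([1.0] * 20, [500.0] * 20, np.arange(20.0))

    def test_incomplete_cases_dropped(self):
        rng = np.random.default_rng(21)
        n = 100
        intake = rng.uniform(800, 1600, n).astype(object)
        intake[:16] = None
        age = rng.uniform(1, 19, n)
        ree = rng.uniform(500, 1200, n)
        result = intake_model(ree, pd.array(intake, dtype="float64"), age)
        assert result.n_complete == 84

    def test_nonevident_sex_effect_dropped(self):
        rng = np.random.default_rng(22)
        n = 400
        intake = rng.uniform(800, 1600, n)
        age = rng.uniform(1, 19, n)
        sex = np.where(rng.random(n) < 0.65, "male", "female")
        ree = 0.42 * intake + 21 * age + rng.normal(0, 120, n)  # no true sex effect
        result = intake_model(ree, intake, age, sex)
        assert result.sex_dropped
        assert "sex" not in result.fit.terms
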