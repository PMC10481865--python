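"""Population-specific model development and validation.

Covers the modelling workflow around the weight + triceps-skinfold REE model:

* restricted cubic spline basis (3 knots) and a Gaussian likelihood-ratio
  test for a nonlinear weight effect;
* limited backward selection with weight forced into the model;
* ordinary least squares fitting with adjusted R^2 and MSE;
* Harrell bootstrap optimism correction of the fit indices;
* a historical train/test split (first n subjects train, remainder test)
  feeding a concordance comparison against the standard formulas;
* descriptive analyses: quantile differences in REE between nutrition
  groups, and the multivariable caloric-intake model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort


class FitError(ValueError):
    """The design matrix does not support the requested fit."""


@dataclass
class ModelFit:
    """An ordinary-least-squares linear model summary.

    ``coefficients`` maps "intercept" plus each term name to its estimate.
    ``mse`` is SSE/n (the mean squared error of the estimate);
    ``residual_sd`` uses the unbiased denominator n - p - 1.
    """

    response: str
    terms: list[str]
    coefficients: dict[str, float]
    r2adj: float
    mse: float
    n: int
    residual_sd: float
    sse: float
    r2: float
    pvalues: dict[str, float] = field(default_factory=dict)
    bse: dict[str, float] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.terms) + 1

    def params_array(self) -> np.ndarray:
        return np.array([self.coefficients["intercept"]] +
                        [self.coefficients[t] for t in self.terms])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Evaluate the fitted linear predictor on new data."""
        beta = self.params_array()
        mat = np.column_stack([np.ones(len(X))] + [np.asarray(X[t], dtype=float) for t in self.terms])
        return mat @ beta

    def loglik(self) -> float:
        """Gaussian maximum-likelihood log-likelihood (sigma^2 = SSE/n)."""
        s2 = self.sse / self.n
        return -0.5 * self.n * (np.log(2 * np.pi * s2) + 1.0)


def fit_linear(X: pd.DataFrame, y, response: str = "ree") -> ModelFit:
    """Fit ``response ~ X`` by OLS.

    ``X`` holds one column per term (no intercept column); a constant is
    added internally.  Raises :class:`FitError` on a rank-deficient design
    or when n <= p + 2.
    """
    y = np.asarray(y, dtype=float)
    n, p = len(y), X.shape[1]
    if len(X) != n:
        raise FitError("X and y lengths differ")
    if n <= p + 2:
        raise FitError(f"n = {n} too small for {p} terms")
    design = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("design matrix is rank deficient")
    res = sm.OLS(y, design).fit()
    sse = float(res.ssr)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    names = ["intercept"] + list(X.columns)
    return ModelFit(
        response=response,
        terms=list(X.columns),
        coefficients=dict(zip(names, map(float, res.params))),
        r2adj=float(r2adj),
        mse=sse / n,
        n=n,
        residual_sd=float(np.sqrt(sse / (n - p - 1))),
        sse=sse,
        r2=float(r2),
        pvalues=dict(zip(names, map(float, res.pvalues))),
        bse=dict(zip(names, map(float, res.bse))),
    )


# ---------------------------------------------------------------------------
# Restricted cubic spline (3 knots)
# ---------------------------------------------------------------------------

@dataclass
class RcsBasis:
    """Restricted-cubic-spline basis with three knots for one predictor.

    The basis is the linear term plus one restricted cubic term that is zero
    below the first knot and exactly linear beyond the last knot (the cubic
    and quadratic pieces cancel), normalised by (t3 - t1)^2 as in Harrell's
    parameterisation.
    """

    knots: np.ndarray  # strictly increasing, length 3

    def transform(self, x) -> pd.DataFrame:
        x = np.asarray(x, dtype=float)
        t1, t2, t3 = self.knots
        def cube(u):
            return np.maximum(u, 0.0) ** 3
        term = (
            cube(x - t1)
            - cube(x - t2) * (t3 - t1) / (t3 - t2)
            + cube(x - t3) * (t2 - t1) / (t3 - t2)
        ) / (t3 - t1) ** 2
        return pd.DataFrame({"linear": x, "rcs": term})


def rcs_basis(x, n_knots: int = 3) -> RcsBasis:
    """Place three knots at the 0.10 / 0.50 / 0.90 quantiles of ``x``."""
    if n_knots != 3:
        raise ValueError("only the 3-knot restricted cubic spline is supported")
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 10:
        raise FitError("need at least 10 distinct values to place spline knots")
    knots = np.quantile(x, [0.10, 0.50, 0.90])
    if not (knots[0] < knots[1] < knots[2]):
        raise FitError(f"degenerate knots {knots}")
    return RcsBasis(knots=knots)


def lrt_nonlinearity(linear_fit: ModelFit, spline_fit: ModelFit) -> tuple[float, float]:
    """Likelihood-ratio test of the spline model against its linear reduction.

    Both models must be fitted to the same data (same n); the statistic is
    2 * (loglik_spline - loglik_linear) = n * ln(SSE_linear / SSE_spline)
    under the Gaussian likelihood, referred to a chi-square with df equal to
    the parameter-count difference.
    """
    if linear_fit.n != spline_fit.n:
        raise ValueError("models were fitted to different data (n differs)")
    df = spline_fit.n_params - linear_fit.n_params
    if df < 1:
        raise ValueError("spline model must have more parameters than the linear model")
    stat = max(2.0 * (spline_fit.loglik() - linear_fit.loglik()), 0.0)
    p = 1.0 if stat == 0.0 else float(stats.chi2.sf(stat, df))
    return float(stat), p


def backward_select(
    data: pd.DataFrame,
    response: str,
    forced: Sequence[str] = ("weight",),
    candidates: Sequence[str] = ("height", "age", "sex", "tsf"),
    alpha: float = 0.05,
    criterion: str = "pvalue",
) -> ModelFit:
    """Limited stepwise backward selection with forced terms.

    Starts from forced + all candidates and iteratively removes the
    non-forced term with the largest partial-F p-value above ``alpha``
    (equivalently the largest t-test p-value for single-df terms); forced
    terms are never removed.  ``criterion='aic'`` removes terms while AIC
    improves instead.
    """
    missing = [c for c in (*forced, *candidates, response) if c not in data.columns]
    if missing:
        raise ValueError(f"columns not in data: {missing}")
    current = list(candidates)
    y = data[response]

    def fit(terms):
        return fit_linear(data[list(forced) + terms], y, response=response)

    model = fit(current)
    while current:
        if criterion == "pvalue":
            pvals = {t: model.pvalues[t] for t in current}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] <= alpha:
                break
            current.remove(worst)
            model = fit(current)
        elif criterion == "aic":
            def aic(m):
                return 2 * m.n_params - 2 * m.loglik()
            trials = {t: fit([c for c in current if c != t]) for t in current}
            best_t = min(trials, key=lambda t: aic(trials[t]))
            if aic(trials[best_t]) >= aic(model):
                break
            current.remove(best_t)
            model = trials[best_t]
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    return model


# ---------------------------------------------------------------------------
# Bootstrap optimism correction (Harrell)
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    """Optimism-corrected fit index.

    ``optimism = training - test`` and ``corrected = original - optimism``
    hold as exact arithmetic identities by construction.
    """

    index: str            # "r2" or "mse"
    original: float
    training: float
    test: float
    optimism: float
    corrected: float
    n_boot: int
    n_skipped: int = 0


def _index_values(beta, Xmat, y, sst):
    resid = y - Xmat @ beta
    sse = float(resid @ resid)
    return 1.0 - sse / sst, sse / len(y)


def bootstrap_validate(
    X: pd.DataFrame,
    y,
    n_boot: int = 3000,
    seed: int = 0,
) -> tuple[ValidationResult, ValidationResult]:
    """Harrell optimism-corrected R^2 and MSE for an OLS model.

    For each bootstrap resample (with replacement, size n) the model is
    refitted; ``training`` is the mean apparent index on the resamples and
    ``test`` the mean index of resample-fitted models evaluated on the
    original data.  Degenerate (rank-deficient) resamples are skipped and
    counted.  Deterministic under a fixed seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xmat = np.column_stack([np.ones(n), np.asarray(X, dtype=float)])
    p = Xmat.shape[1]
    sst = float(((y - y.mean()) ** 2).sum())
    beta_full, *_ = np.linalg.lstsq(Xmat, y, rcond=None)
    orig_r2, orig_mse = _index_values(beta_full, Xmat, y, sst)

    rng = np.random.default_rng(seed)
    tr_r2, te_r2, tr_mse, te_mse = [], [], [], []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb, yb = Xmat[idx], y[idx]
        if np.linalg.matrix_rank(Xb) < p:
            skipped += 1
            continue
        beta_b, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
        sst_b = float(((yb - yb.mean()) ** 2).sum())
        if sst_b == 0:
            skipped += 1
            continue
        r2_b, mse_b = _index_values(beta_b, Xb, yb, sst_b)
        r2_o, mse_o = _index_values(beta_b, Xmat, y, sst)
        tr_r2.append(r2_b)
        te_r2.append(r2_o)
        tr_mse.append(mse_b)
        te_mse.append(mse_o)
    if not tr_r2:
        raise FitError("every bootstrap resample was degenerate")

    def make(index, original, training, test):
        optimism = training - test
        return ValidationResult(
            index=index, original=original, training=training, test=test,
            optimism=optimism, corrected=original - optimism,
            n_boot=n_boot, n_skipped=skipped,
        )

    return (
        make("r2", orig_r2, float(np.mean(tr_r2)), float(np.mean(te_r2))),
        make("mse", orig_mse, float(np.mean(tr_mse)), float(np.mean(te_mse))),
    )


# ---------------------------------------------------------------------------
# Train/test split validation
# ---------------------------------------------------------------------------

@dataclass
class SplitValidation:
    fit: ModelFit
    train_ids: list[str]
    test_ids: list[str]
    predictions: pd.Series   # model predictions on the test subjects
    measured: pd.Series      # calorimetry REE on the test subjects


def train_test_split_validate(
    cohort: Cohort,
    train_n: int = 54,
    terms: Sequence[str] = ("weight", "tsf"),
    shuffle_seed: Optional[int] = None,
) -> SplitValidation:
    """Fit on the first ``train_n`` subjects (cohort order, historically the
    earlier study's sample) and predict the remainder for concordance checks.

    ``shuffle_seed`` applies a reproducible permutation before splitting.
    """
    subjects = [s for s in cohort if s.ree_measured is not None]
    if len(subjects) < train_n + 3:
        raise FitError(
            f"cohort has {len(subjects)} usable subjects; need >= {train_n + 3}"
        )
    order = np.arange(len(subjects))
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(order)
    subjects = [subjects[i] for i in order]
    train, test = subjects[:train_n], subjects[train_n:]

    def frame(group):
        return pd.DataFrame(
            {
                "weight": [s.weight for s in group],
                "tsf": [s.tsf for s in group],
                "height": [s.height for s in group],
                "age": [s.age for s in group],
                "sex": [1.0 if s.sex == "male" else 0.0 for s in group],
            },
            index=pd.Index([s.id for s in group], name="id"),
        )

    X_train = frame(train)[list(terms)]
    y_train = np.array([s.ree_measured for s in train])
    fit = fit_linear(X_train, y_train)
    X_test = frame(test)[list(terms)]
    preds = pd.Series(fit.predict(X_test), index=X_test.index, name="predicted")
    measured = pd.Series(
        [s.ree_measured for s in test], index=X_test.index, name="measured"
    )
    return SplitValidation(
        fit=fit,
        train_ids=[s.id for s in train],
        test_ids=[s.id for s in test],
        predictions=preds,
        measured=measured,
    )


# ---------------------------------------------------------------------------
# Descriptive analyses
# ---------------------------------------------------------------------------

@dataclass
class QuantileComparison:
    taus: tuple[float, ...]
    differences: dict[float, float]          # group2 - group1, kcal/day
    ci95: dict[float, tuple[float, float]]
    n_group1: int
    n_group2: int


def quantile_group_diff(
    ree: Sequence[float],
    group: Sequence[str],
    taus: tuple[float, ...] = (0.25, 0.5, 0.75),
    n_boot: int = 2000,
    seed: int = 0,
) -> QuantileComparison:
    """Differences in REE quantiles between nutrition groups (group2 - group1).

    Point estimates are differences of sample quantiles (linear / type-7
    interpolation); 95% confidence intervals come from a stratified
    nonparametric bootstrap resampling subjects within each group.
    """
    ree = np.asarray(ree, dtype=float)
    group = np.asarray(group)
    g1 = ree[group == "group1"]
    g2 = ree[group == "group2"]
    if len(g1) < 5 or len(g2) < 5:
        raise ValueError(f"both groups need n >= 5, got {len(g1)} and {len(g2)}")
    if any(not (0 < t < 1) for t in taus):
        raise ValueError("taus must lie in (0, 1)")

    diffs = {t: float(np.quantile(g2, t) - np.quantile(g1, t)) for t in taus}
    rng = np.random.default_rng(seed)
    boots = {t: np.empty(n_boot) for t in taus}
    for i in range(n_boot):
        b1 = g1[rng.integers(0, len(g1), len(g1))]
        b2 = g2[rng.integers(0, len(g2), len(g2))]
        for t in taus:
            boots[t][i] = np.quantile(b2, t) - np.quantile(b1, t)
    ci = {
        t: (float(np.quantile(boots[t], 0.025)), float(np.quantile(boots[t], 0.975)))
        for t in taus
    }
    return QuantileComparison(
        taus=tuple(taus), differences=diffs, ci95=ci,
        n_group1=len(g1), n_group2=len(g2),
    )


@dataclass
class IntakeModelResult:
    fit: ModelFit
    effect_per_388_kcal_intake: float   # kcal/day REE per +388 kcal/day intake
    effect_per_4_75_years: float        # kcal/day REE per +4.75 years (+1 SD)
    sex_dropped: bool
    n_complete: int


def intake_model(
    ree: Sequence[float],
    intake: Sequence[float],
    age: Sequence[float],
    sex: Optional[Sequence[str]] = None,
) -> IntakeModelResult:
    """Multivariable linear model REE ~ caloric intake + age (+ sex).

    Complete cases only.  Sex (male=1) is included when supplied but dropped
    and the model refitted if its effect is not evident (p > 0.05), mirroring
    the reported analysis.  Effects are also reported on the scaled units
    used clinically: per +388 kcal/day of intake and per +4.75 years of age.
    """
    df = pd.DataFrame({"ree": ree, "intake": intake, "age": age})
    if sex is not None:
        df["sex"] = [1.0 if s == "male" else 0.0 for s in sex]
    df = df.dropna()
    if len(df) < 10:
        raise FitError(f"only {len(df)} complete cases; need >= 10")
    if df["intake"].nunique() == 1:
        raise FitError("caloric intake is constant; its coefficient is not identifiable")
    terms = ["intake", "age"] + (["sex"] if sex is not None else [])
    fit = fit_linear(df[terms], df["ree"])
    sex_dropped = False
    if sex is not None and fit.pvalues.get("sex", 0.0) > 0.05:
        fit = fit_linear(df[["intake", "age"]], df["ree"])
        sex_dropped = True
    return IntakeModelResult(
        fit=fit,
        effect_per_388_kcal_intake=fit.coefficients["intake"] * 388.0,
        effect_per_4_75_years=fit.coefficients["age"] * 4.75,
        sex_dropped=sex_dropped,
        n_complete=len(df),
    )
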