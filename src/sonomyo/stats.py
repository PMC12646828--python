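"""Cohort statistics: normality-gated two-group comparisons, one-way
ANOVA with Bonferroni post hoc tests, correlations, and binary logistic
regression with odds ratios and 95% Wald confidence intervals.

Routing mirrors standard clinical-statistics practice: each group is
first screened with a Lilliefors-style Kolmogorov-Smirnov test (Gaussian
null with estimated mean/SD, alpha = 0.05); two groups that both pass
are compared with the unpaired Student's t-test, otherwise with the
Mann-Whitney U-test.  Logistic models are fitted by Newton/IRLS maximum
likelihood (statsmodels) with convergence at max |dbeta| < 1e-8 within
50 iterations; non-convergence and perfect separation raise instead of
returning silent estimates.  Odds ratios are exp(beta) with
exp(beta +/- 1.96 SE) intervals, SEs from the inverse observed
information.

Sex is coded female = 0, male = 1 throughout, so a "male" odds ratio
above 1 means male excess risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import (ConvergenceError, InsufficientDataError,
                     MissingDataError, UndefinedCorrelationError)
from .score import MALE, compute_cutoffs, score_cohort

NORMALITY_ALPHA = 0.05
_Z975 = 1.96

MODEL_DESIGNS = {
    1: ["age", "male", "rfma_cm2", "rfmt_cm", "mit_pct"],
    2: ["age", "male", "mass_score", "quality_score"],
}


@dataclass(frozen=True)
class GroupComparison:
    test_used: str              # "t" or "mann_whitney"
    statistic: float
    p_value: float
    group_summaries: tuple      # per group: dict of location/dispersion


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class LogisticFit:
    """Per-predictor estimates of a fitted binary logistic model.

    ``table`` is indexed by predictor name (plus ``const``) with columns
    beta, se, odds_ratio, ci_low, ci_high, p_value.
    """

    table: pd.DataFrame
    converged: bool
    n_iterations: int
    log_likelihood: float
    n_obs: int


def normality_gate(sample) -> str:
    """"normal" / "non_normal" via Lilliefors KS at alpha = 0.05.

    A zero-variance sample is non-normal by definition (the Gaussian
    null is degenerate).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"normality test needs n >= 3, got {x.size}")
    if np.std(x) == 0:
        return "non_normal"
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return "normal" if p >= NORMALITY_ALPHA else "non_normal"


def _summarise(x: np.ndarray, parametric: bool) -> dict:
    if parametric:
        return {"n": x.size, "mean": float(x.mean()), "sd": float(x.std(ddof=1))}
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"n": x.size, "median": float(med), "iqr": float(q3 - q1)}


def compare_groups(x, y) -> GroupComparison:
    """Two-sided two-group comparison routed through the normality gate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise InsufficientDataError("each group needs n >= 3")
    parametric = (normality_gate(x) == "normal"
                  and normality_gate(y) == "normal")
    if parametric:
        stat, p = sps.ttest_ind(x, y, equal_var=True)
        test = "t"
    else:
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            stat, p = x.size * y.size / 2.0, 1.0  # all values tied
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic")
            stat, p = res.statistic, res.pvalue
            if np.isnan(p):  # fully tied samples: no evidence either way
                stat, p = x.size * y.size / 2.0, 1.0
        test = "mann_whitney"
    return GroupComparison(test_used=test, statistic=float(stat),
                           p_value=float(p),
                           group_summaries=(_summarise(x, parametric),
                                            _summarise(y, parametric)))


def anova_bonferroni(groups) -> dict:
    """One-way ANOVA omnibus p plus Bonferroni-adjusted pairwise t-tests."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise InsufficientDataError(
            "ANOVA needs >= 3 groups; use compare_groups for two")
    if any(a.size < 2 for a in arrays):
        raise InsufficientDataError("each group needs n >= 2")
    if all(np.std(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        f_stat, omnibus_p = 0.0, 1.0
    else:
        f_stat, omnibus_p = sps.f_oneway(*arrays)
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    pairwise = {}
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            if np.std(arrays[i]) == 0 and np.std(arrays[j]) == 0 \
                    and arrays[i][0] == arrays[j][0]:
                raw = 1.0
            else:
                _, raw = sps.ttest_ind(arrays[i], arrays[j], equal_var=True)
            pairwise[(i, j)] = min(1.0, float(raw) * n_pairs)
    return {"f_statistic": float(f_stat), "p_value": float(omnibus_p),
            "pairwise_p": pairwise}


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("correlation needs paired n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InsufficientDataError("correlation requires finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero-variance variable")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise InsufficientDataError(f"unknown method {method!r}")
    return CorrelationResult(method=method, r=float(r), p_value=float(p),
                             n=int(x.size))


def logistic_fit(design: pd.DataFrame, outcome) -> LogisticFit:
    """Maximum-likelihood binary logistic regression with Wald inference.

    ``design`` holds the predictor columns (no constant; one is added).
    Raises ConvergenceError on non-convergence or perfect separation and
    MissingDataError for a single-class outcome.
    """
    X = pd.DataFrame(design).astype(float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise MissingDataError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise MissingDataError("outcome has a single class")
    if len(X) <= X.shape[1] + 1:
        raise InsufficientDataError("need n > number of predictors + 1")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, Xc)
            res = model.fit(method="newton", maxiter=50, tol=1e-8, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge in 50 iterations")
    beta = res.params
    se = res.bse
    if not np.isfinite(se).all():
        raise ConvergenceError("singular information matrix (separation?)")
    table = pd.DataFrame({
        "beta": beta,
        "se": se,
        "odds_ratio": np.exp(beta),
        "ci_low": np.exp(beta - _Z975 * se),
        "ci_high": np.exp(beta + _Z975 * se),
        "p_value": res.pvalues,
    })
    return LogisticFit(table=table, converged=True,
                       n_iterations=int(res.mle_retvals.get("iterations", 0)),
                       log_likelihood=float(res.llf), n_obs=int(len(X)))


def run_model(cohort: pd.DataFrame, model_id: int, outcome: str) -> LogisticFit:
    """Fit one of the two pre-registered designs to a cohort table.

    Model 1 regresses the outcome on age, sex and the absolute
    ultrasound variables (RFMA, RFMT, MiT); Model 2 on age, sex and the
    two ultrasound scores (computed from per-sex cohort medians when the
    columns are absent).  ``outcome`` is "sarcopenia" or "dynapenia".
    """
    if model_id not in MODEL_DESIGNS:
        raise MissingDataError(f"model_id must be 1 or 2, got {model_id}")
    df = cohort.copy()
    if "male" not in df.columns:
        if "sex" not in df.columns:
            raise MissingDataError("cohort lacks a sex column")
        df["male"] = (df["sex"] == MALE).astype(int)
    if model_id == 2 and not {"mass_score", "quality_score"} <= set(df.columns):
        df = score_cohort(df, compute_cutoffs(df))
    if outcome not in df.columns:
        if {"handgrip_kg", "asmi"} <= set(df.columns):
            df = score_cohort(df, compute_cutoffs(df)) \
                if "sarcopenia" not in df.columns else df
        if outcome not in df.columns:
            raise MissingDataError(f"cohort lacks outcome column {outcome!r}")
    cols = MODEL_DESIGNS[model_id]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise MissingDataError(f"cohort lacks columns: {', '.join(missing)}")
    return logistic_fit(df[cols], df[outcome].astype(float))
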