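"""Statistical stage: normality screening, covariate-adjusted regressions,
and condition × visit linear mixed models.

Each maze-navigation outcome is screened with the Shapiro–Wilk test and
natural-log transformed when non-normal (and strictly positive).  The
association of an outcome with one cognitive test is estimated by
ordinary least squares adjusted for age, sex, education, height and
weight — one model per (outcome, test) pair, complete-case.  Condition
(no-wall vs wall) and repetition (immediate vs delayed visit) effects
are estimated with a linear mixed model with a condition × visit
interaction and a subject random intercept, fitted by REML; significant
interactions are followed up with the four simple-effect contrasts
(visit within each condition, condition within each visit) with
Bonferroni correction (×4).  Significance is assessed at α = 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cohort import COVARIATE_COLUMNS, SCORE_COLUMNS

logger = logging.getLogger(__name__)

ALPHA = 0.05
MIN_COMPLETE_CASES = 15
N_PAIRWISE = 4  # the four simple-effect contrasts of the 2x2 design

TRANSFORM_NONE = "none"
TRANSFORM_LOG = "log"
TRANSFORM_REFUSED = "untransformable"


def screen_and_transform(
    values: np.ndarray, alpha: float = ALPHA
) -> tuple[np.ndarray, str]:
    """Shapiro–Wilk screen; natural-log transform when non-normal.

    Returns ``(values, flag)`` where flag is ``"none"`` (normal enough),
    ``"log"`` (transformed, all values were positive) or
    ``"untransformable"`` (non-normal but contains non-positive values;
    returned unchanged with a logged warning).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values for a normality screen")
    p = float(sps.shapiro(values).pvalue)
    if p >= alpha:
        return values, TRANSFORM_NONE
    if np.all(values > 0):
        return np.log(values), TRANSFORM_LOG
    logger.warning(
        "non-normal sample contains non-positive values; refusing a shift-based "
        "log transform and leaving the data unchanged"
    )
    return values, TRANSFORM_REFUSED


@dataclass
class RegressionResult:
    """Adjusted association of one outcome with one cognitive test."""

    outcome: str
    test: str
    coef: float
    se: float
    pvalue: float
    conf_int: tuple[float, float]
    n: int
    transform: str

    @property
    def significant(self) -> bool:
        return self.pvalue < ALPHA


def _design_matrix(df: pd.DataFrame, test_col: str) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            test_col: df[test_col].astype(float),
            "age": df["age"].astype(float),
            "sex_male": (df["sex"].astype(str) == "M").astype(float),
            "education": df["education"].astype(float),
            "height": df["height"].astype(float),
            "weight": df["weight"].astype(float),
        },
        index=df.index,
    )
    return sm.add_constant(X)


def adjusted_regression(
    outcome_col: str,
    test_col: str,
    cohort: pd.DataFrame,
    alpha: float = ALPHA,
    min_cases: int = MIN_COMPLETE_CASES,
    transform: bool = True,
) -> RegressionResult:
    """OLS of the (possibly log-transformed) outcome on one cognitive score,
    adjusted for age, sex, education, height and weight (complete-case)."""
    if test_col not in SCORE_COLUMNS:
        raise ValueError(f"unknown cognitive test {test_col!r}")
    cols = [outcome_col, test_col, *COVARIATE_COLUMNS]
    df = cohort[cols].dropna()
    if len(df) < min_cases:
        raise ValueError(
            f"only {len(df)} complete cases for {outcome_col!r} ~ {test_col!r}; "
            f"need at least {min_cases}"
        )
    y = df[outcome_col].to_numpy(dtype=float)
    flag = TRANSFORM_NONE
    if transform:
        y, flag = screen_and_transform(y, alpha)
    X = _design_matrix(df, test_col)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design matrix (rank {rank} < {X.shape[1]} columns) "
            f"for {outcome_col!r} ~ {test_col!r}; column variances: "
            f"{X.var().round(6).to_dict()}"
        )
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int().loc[test_col]
    return RegressionResult(
        outcome=outcome_col,
        test=test_col,
        coef=float(fit.params[test_col]),
        se=float(fit.bse[test_col]),
        pvalue=float(fit.pvalues[test_col]),
        conf_int=(float(ci[0]), float(ci[1])),
        n=len(df),
        transform=flag,
    )


@dataclass
class PairwiseContrast:
    label: str
    estimate: float
    pvalue_raw: float
    pvalue_bonferroni: float


@dataclass
class MixedModelResult:
    """Condition × visit mixed model for one outcome."""

    outcome: str
    fixed_effects: dict[str, float]
    pvalues: dict[str, float]
    random_intercept_var: float
    n_subjects: int
    n_obs: int
    converged: bool
    pairwise: list[PairwiseContrast] = field(default_factory=list)

    @property
    def interaction_pvalue(self) -> float:
        return self.pvalues["condition:visit"]


def condition_visit_mixed_model(
    outcome_col: str,
    long_table: pd.DataFrame,
    alpha: float = ALPHA,
    always_pairwise: bool = False,
) -> MixedModelResult:
    """Fit outcome ~ condition + visit + condition:visit, subject random
    intercept, by REML; Bonferroni pairwise follow-up of a significant
    interaction.

    The pairwise family is the four simple effects — visit within each
    condition and condition within each visit — each a Wald test on a
    linear combination of the fixed effects, with p-values multiplied by
    four (capped at 1).
    """
    df = long_table[["subject_id", "condition", "visit", outcome_col]].dropna()
    counts = df.groupby("subject_id").size()
    if (counts >= 2).sum() < 10:
        raise ValueError(
            f"need at least 10 subjects with 2+ sessions for {outcome_col!r}; "
            f"have {(counts >= 2).sum()}"
        )
    work = df.copy()
    # treatment coding: reference cell = no_wall / immediate
    work["wall"] = (work["condition"] == "wall").astype(float)
    work["delayed"] = (work["visit"] == "delayed").astype(float)
    work["wall_x_delayed"] = work["wall"] * work["delayed"]
    exog = sm.add_constant(work[["wall", "delayed", "wall_x_delayed"]])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(work[outcome_col].astype(float), exog, groups=work["subject_id"])
        try:
            fit = model.fit(reml=True)
            converged = bool(fit.converged)
        except Exception:  # singular fit: refit with the variance floored at ~0
            logger.warning(
                "mixed-model fit failed for %s; refitting with free random-effect scale",
                outcome_col,
            )
            fit = model.fit(reml=True, method="powell")
            converged = False

    params = fit.fe_params
    pvals = fit.pvalues
    fixed = {
        "intercept": float(params["const"]),
        "condition": float(params["wall"]),
        "visit": float(params["delayed"]),
        "condition:visit": float(params["wall_x_delayed"]),
    }
    pv = {
        "condition": float(pvals["wall"]),
        "visit": float(pvals["delayed"]),
        "condition:visit": float(pvals["wall_x_delayed"]),
    }
    re_var = float(np.squeeze(fit.cov_re.to_numpy())) if fit.cov_re.size else 0.0

    result = MixedModelResult(
        outcome=outcome_col,
        fixed_effects=fixed,
        pvalues=pv,
        random_intercept_var=max(re_var, 0.0),
        n_subjects=int(counts.shape[0]),
        n_obs=len(work),
        converged=converged,
    )
    if result.interaction_pvalue < alpha or always_pairwise:
        # columns: const, wall, delayed, wall_x_delayed
        contrasts = {
            "delayed_vs_immediate_within_no_wall": [0.0, 0.0, 1.0, 0.0],
            "delayed_vs_immediate_within_wall": [0.0, 0.0, 1.0, 1.0],
            "wall_vs_no_wall_within_immediate": [0.0, 1.0, 0.0, 0.0],
            "wall_vs_no_wall_within_delayed": [0.0, 1.0, 0.0, 1.0],
        }
        for label, row in contrasts.items():
            L = np.array([row])
            tt = fit.t_test(L)
            p_raw = float(np.squeeze(tt.pvalue))
            result.pairwise.append(
                PairwiseContrast(
                    label=label,
                    estimate=float(np.squeeze(tt.effect)),
                    pvalue_raw=p_raw,
                    pvalue_bonferroni=min(1.0, N_PAIRWISE * p_raw),
                )
            )
    return result


def build_association_table(
    cohort: pd.DataFrame,
    outcomes: list[str],
    tests: list[str] | None = None,
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Association report: one regression per (outcome, test) pair.

    Returns ``(coefs, pvalues)`` DataFrames with outcomes as rows and
    tests as columns, matching the shape of a per-stratum report; no
    correction across cells is applied (each cell is tested at α).
    """
    tests = list(tests) if tests is not None else list(SCORE_COLUMNS)
    coefs = pd.DataFrame(index=outcomes, columns=tests, dtype=float)
    pvals = pd.DataFrame(index=outcomes, columns=tests, dtype=float)
    for outcome in outcomes:
        for test in tests:
            r = adjusted_regression(outcome, test, cohort, alpha=alpha)
            coefs.loc[outcome, test] = r.coef
            pvals.loc[outcome, test] = r.pvalue
    return coefs, pvals


def association_tables_by_stratum(
    long_table: pd.DataFrame,
    cohort: pd.DataFrame,
    outcomes: list[str],
    tests: list[str] | None = None,
) -> dict[tuple[str, str], tuple[pd.DataFrame, pd.DataFrame]]:
    """Per condition × visit stratum association tables.

    Merges each stratum's outcome rows with the cohort covariates and
    scores, then builds the per-stratum report.
    """
    out = {}
    for (condition, visit), grp in long_table.groupby(["condition", "visit"]):
        merged = grp.merge(cohort, on="subject_id", how="left")
        out[(condition, visit)] = build_association_table(merged, outcomes, tests)
    return out
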