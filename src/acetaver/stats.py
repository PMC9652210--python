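"""Cohort statistics: group summaries, t-tests, and the pose-bias OLS.

The scientific question this layer answers: how large is the systematic
2D−3D discrepancy Δ = AV³ᴰ − AV²ᴰ, and how much of it is explained by
pelvis pose (AP tilt λ, lateral tilt ρ)? The analyses are per side, with
single regressions Δ~λ and Δ~ρ, the main-effects model Δ~λ+ρ, and the
interaction model Δ~λ+ρ+λ·ρ, plus the paired 3D-vs-2D comparison and
sex-group t-tests.

t-tests use Welch's unequal-variance form by default (a pooled-variance
Student variant is available); OLS goes through statsmodels. No
multiple-testing correction is applied, and the two hemipelvises of a
subject are treated as independent within their side — a documented
simplification of the per-side analysis design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError

log = logging.getLogger(__name__)

#: Columns a cohort table must carry. delta_deg is always derived.
COHORT_COLUMNS = (
    "subject_id",
    "side",
    "sex",
    "bmi_class",
    "av3d_deg",
    "av2d_deg",
    "lambda_deg",
    "rho_deg",
)


def cohort_with_delta(table: pd.DataFrame) -> pd.DataFrame:
    """Validated copy of a cohort table with delta_deg (re)computed.

    The difference column is always recomputed from av3d_deg − av2d_deg so
    it can never be stored inconsistently.
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table missing column(s): {', '.join(missing)}")
    bad_sides = set(table["side"].unique()) - {"left", "right"}
    if bad_sides:
        raise ValidationError(f"unknown side value(s): {sorted(bad_sides)}")
    out = table.copy()
    out["delta_deg"] = out["av3d_deg"] - out["av2d_deg"]
    return out


@dataclass(frozen=True)
class TTestResult:
    mean_difference: float
    t_statistic: float
    df: float
    p_value: float
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    equal_variance: bool

    def __post_init__(self):
        if not (self.df > 0):
            raise ValidationError("t-test degrees of freedom must be positive")


@dataclass(frozen=True)
class RegressionResult:
    names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    r_squared: float
    n: int

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError("R² must lie in [0, 1]")

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def conf_int(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided (1−alpha) confidence interval for one coefficient."""
        i = self.names.index(name)
        df = self.n - len(self.names)
        half = sps.t.ppf(1 - alpha / 2, df) * self.standard_errors[i]
        return float(self.coefficients[i] - half), float(self.coefficients[i] + half)


def summarize(
    table: pd.DataFrame,
    group_by: str,
    measures: tuple[str, ...] = ("av3d_deg", "av2d_deg", "delta_deg"),
) -> pd.DataFrame:
    """Per-group mean and sample SD (n−1) of the chosen measures.

    Groups are ordered deterministically (sorted); a group with a single
    observation reports its SD as missing; empty groups are omitted (with
    a warning when the grouping column is categorical with unused levels).
    """
    if group_by not in table.columns:
        raise ValidationError(f"no grouping column {group_by!r}")
    present = [m for m in measures if m in table.columns]
    if not present:
        raise ValidationError("none of the requested measures are in the table")
    grouped = table.groupby(group_by, sort=True, observed=True)
    if hasattr(table[group_by], "cat"):
        unused = set(table[group_by].cat.categories) - set(grouped.groups)
        if unused:
            log.warning("empty group(s) omitted: %s", sorted(unused))
    agg = grouped[present].agg(["count", "mean", "std"])
    return agg


def t_test_independent(a, b, equal_variance: bool = False) -> TTestResult:
    """Two-sided independent-samples t-test (Welch by default)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("each sample needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=equal_variance)
    return TTestResult(
        mean_difference=float(a.mean() - b.mean()),
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
        group_sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        equal_variance=equal_variance,
    )


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify (nearly) collinear columns: R² of each column on the rest
    offenders = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        denom = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        if denom == 0 or np.sum(resid**2) < 1e-10 * max(denom, 1.0):
            offenders.append(names[j])
    raise DegenerateInputError(
        f"design matrix is rank deficient (rank {rank} of {X.shape[1]}); "
        f"collinear column(s): {', '.join(offenders) or 'unidentified'}"
    )


def ols(
    response,
    predictors: dict[str, np.ndarray],
    interactions: list[tuple[str, str]] | None = None,
) -> RegressionResult:
    """Ordinary least squares with named predictors and optional interactions.

    Interaction columns are elementwise products of the named predictor
    pairs. An intercept is always included. Raises on rank deficiency,
    naming the collinear columns.
    """
    y = np.asarray(response, dtype=np.float64).reshape(-1)
    names = ["intercept"] + list(predictors)
    cols = [np.ones(len(y))] + [
        np.asarray(v, dtype=np.float64).reshape(-1) for v in predictors.values()
    ]
    for pair in interactions or []:
        a, b = pair
        if a not in predictors or b not in predictors:
            raise ValidationError(f"interaction names unknown: {pair}")
        names.append(f"{a}:{b}")
        cols.append(
            np.asarray(predictors[a], dtype=np.float64)
            * np.asarray(predictors[b], dtype=np.float64)
        )
    X = np.column_stack(cols)
    if len(y) <= X.shape[1]:
        raise DegenerateInputError("need more observations than coefficients")
    if any(len(c) != len(y) for c in cols):
        raise ValidationError("predictor lengths do not match the response")
    _check_full_rank(X, names)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        names=tuple(names),
        coefficients=np.asarray(fit.params),
        standard_errors=np.asarray(fit.bse),
        t_statistics=np.asarray(fit.tvalues),
        p_values=np.asarray(fit.pvalues),
        r_squared=float(fit.rsquared),
        n=int(len(y)),
    )


def run_bias_analysis(table: pd.DataFrame) -> dict:
    """The full per-side pose-bias analysis of a cohort table.

    For each side: single regressions Δ~λ and Δ~ρ, the main-effects model
    Δ~λ+ρ, the interaction model Δ~λ+ρ+λ·ρ, and the paired AV³ᴰ-vs-AV²ᴰ
    comparison (mean difference, SD, paired t-test). Requires at least 10
    hemipelvises per side.
    """
    df = cohort_with_delta(table)
    report: dict = {}
    for side, sub in df.groupby("side", sort=True):
        if len(sub) < 10:
            raise ValidationError(
                f"side {side!r} has only {len(sub)} rows; need at least 10"
            )
        delta = sub["delta_deg"].to_numpy()
        lam = sub["lambda_deg"].to_numpy()
        rho = sub["rho_deg"].to_numpy()
        paired = sps.ttest_rel(sub["av3d_deg"], sub["av2d_deg"])
        report[side] = {
            "n": int(len(sub)),
            "single_lambda": ols(delta, {"lambda": lam}),
            "single_rho": ols(delta, {"rho": rho}),
            "multiple": ols(delta, {"lambda": lam, "rho": rho}),
            "interaction": ols(
                delta,
                {"lambda": lam, "rho": rho},
                interactions=[("lambda", "rho")],
            ),
            "paired_mean_difference": float(delta.mean()),
            "paired_sd": float(delta.std(ddof=1)),
            "paired_t": float(paired.statistic),
            "paired_p": float(paired.pvalue),
        }
    return report
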