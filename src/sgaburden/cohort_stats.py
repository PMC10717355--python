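"""Group-comparison statistics for cohort characteristic tables.

Categorical traits are compared with the Pearson chi-square test *without*
continuity correction, falling back to Fisher's exact test when any expected
cell count drops below 5 or a margin is empty; continuous traits use Welch's
unequal-variance t-test or the Wilcoxon rank-sum test.  Uni- and
multivariable logistic regressions give odds ratios with Wald confidence
intervals.  Missing values are excluded pairwise and reported, matching how
clinical baseline tables handle incomplete chart data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) = group-1 yes/no, (c, d) = group-2 yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def expected(self) -> np.ndarray:
        t = self.as_array()
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / self.n


@dataclass
class ComparisonResult:
    variable: str
    test: str  # chisq | fisher | welch_t | wilcoxon
    statistic: float
    p_value: float
    effect: float | None = None  # difference of proportions or odds ratio
    group1_summary: str = ""
    group2_summary: str = ""
    n_missing: int = 0


def two_proportion_chisq(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, df = 1.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).  A zero margin leaves the
    statistic undefined; returns (0, 1) with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        warnings.warn("zero margin in 2x2 table; chi-square undefined, returning p = 1")
        return 0.0, 1.0
    chi2 = table.n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def fisher_exact_2x2(table: ContingencyTable2x2, alternative: str = "two-sided") -> float:
    """Fisher's exact p (two-sided: sum of hypergeometric probabilities <= observed)."""
    return float(stats.fisher_exact(table.as_array().astype(int), alternative=alternative)[1])


def choose_categorical_test(table: ContingencyTable2x2) -> str:
    """'fisher' if any expected cell count < 5 (or a margin is zero), else 'chisq'."""
    exp = table.expected()
    if not np.isfinite(exp).all() or (exp < 5).any():
        return "fisher"
    return "chisq"


def categorical_compare(variable: str, table: ContingencyTable2x2) -> ComparisonResult:
    test = choose_categorical_test(table)
    if test == "chisq":
        statistic, p = two_proportion_chisq(table)
    else:
        statistic, p = np.nan, fisher_exact_2x2(table)
    p1 = table.a / max(table.a + table.b, 1)
    p2 = table.c / max(table.c + table.d, 1)
    return ComparisonResult(
        variable=variable,
        test=test,
        statistic=statistic,
        p_value=p,
        effect=p1 - p2,
        group1_summary=f"{table.a} ({100 * p1:.1f})",
        group2_summary=f"{table.c} ({100 * p2:.1f})",
    )


def continuous_compare(values1, values2, method: str = "welch_t", variable: str = "") -> ComparisonResult:
    """Welch t-test or two-sided Wilcoxon rank-sum (normal approximation with
    tie correction) between two samples."""
    x = np.asarray(pd.Series(values1).dropna(), dtype=float)
    y = np.asarray(pd.Series(values2).dropna(), dtype=float)
    if method == "welch_t":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("welch_t requires n >= 2 per group")
        if np.var(x) == 0 and np.var(y) == 0:
            # degenerate: no within-group variation
            stat, p = (0.0, 1.0) if np.mean(x) == np.mean(y) else (np.inf, 0.0)
        else:
            stat, p = stats.ttest_ind(x, y, equal_var=False)
    elif method == "wilcoxon":
        if len(x) < 1 or len(y) < 1:
            raise ValueError("wilcoxon requires n >= 1 per group")
        # exact null distribution for small untied samples, tie-corrected
        # normal approximation otherwise
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonResult(
        variable=variable,
        test=method,
        statistic=float(stat),
        p_value=float(p),
        group1_summary=f"{np.mean(x):.2f} ({np.std(x, ddof=1) if len(x) > 1 else 0:.2f})",
        group2_summary=f"{np.mean(y):.2f} ({np.std(y, ddof=1) if len(y) > 1 else 0:.2f})",
    )


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


def _logit_fit(y: np.ndarray, X: np.ndarray):
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises PerfectSeparationError
            raise SeparationError(str(exc)) from exc
    fitted = fit.predict(X)
    if np.any(fitted < 1e-10) or np.any(fitted > 1 - 1e-10) or not np.isfinite(fit.bse).all():
        raise SeparationError("complete or quasi-complete separation detected")
    return fit


def univariable_logistic(outcome, predictor) -> dict:
    """ML logistic fit of a binary outcome on one predictor.

    Returns {'or', 'ci_low', 'ci_high', 'p', 'coef'} (Wald inference).
    """
    df = pd.DataFrame({"y": outcome, "x": predictor}).dropna()
    y = df["y"].to_numpy(dtype=float)
    X = sm.add_constant(df["x"].to_numpy(dtype=float), has_constant="add")
    fit = _logit_fit(y, X)
    coef, se = fit.params[1], fit.bse[1]
    z = stats.norm.ppf(0.975)
    return {
        "or": float(np.exp(coef)),
        "ci_low": float(np.exp(coef - z * se)),
        "ci_high": float(np.exp(coef + z * se)),
        "p": float(fit.pvalues[1]),
        "coef": float(coef),
    }


def multivariable_logistic(outcome, predictors: pd.DataFrame) -> pd.DataFrame:
    """Joint ML logistic fit; one row of (or, ci_low, ci_high, p) per predictor."""
    df = pd.concat([pd.Series(outcome, name="_y").reset_index(drop=True),
                    predictors.reset_index(drop=True)], axis=1).dropna()
    y = df["_y"].to_numpy(dtype=float)
    X = sm.add_constant(df.drop(columns="_y").to_numpy(dtype=float), has_constant="add")
    fit = _logit_fit(y, X)
    z = stats.norm.ppf(0.975)
    rows = []
    for i, name in enumerate(predictors.columns, start=1):
        coef, se = fit.params[i], fit.bse[i]
        rows.append(
            {
                "predictor": name,
                "or": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - z * se)),
                "ci_high": float(np.exp(coef + z * se)),
                "p": float(fit.pvalues[i]),
            }
        )
    return pd.DataFrame(rows)


def group_comparison_table(
    samples: pd.DataFrame,
    group_col: str,
    variables: list[str],
    continuous_method: str = "welch_t",
) -> pd.DataFrame:
    """Baseline-characteristics comparison of two groups, one row per variable.

    Boolean/binary variables are routed through :func:`choose_categorical_test`;
    numeric ones through :func:`continuous_compare`.  Missing values are
    dropped pairwise and counted per variable.
    """
    groups = samples[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"group column {group_col!r} must have exactly 2 levels, got {len(groups)}")
    g1, g2 = sorted(groups, key=str)
    rows = []
    for var in variables:
        if var not in samples.columns:
            raise KeyError(f"variable {var!r} not in sample table")
        col = samples[var]
        n_missing = int(col.isna().sum())
        sub = samples[[group_col, var]].dropna()
        v1 = sub.loc[sub[group_col] == g1, var]
        v2 = sub.loc[sub[group_col] == g2, var]
        if pd.api.types.is_bool_dtype(col) or str(col.dtype) == "boolean" or set(col.dropna().unique()) <= {0, 1, True, False}:
            a, b = int(v1.astype(bool).sum()), int((~v1.astype(bool)).sum())
            c, d = int(v2.astype(bool).sum()), int((~v2.astype(bool)).sum())
            if (a + b == 0) or (c + d == 0):
                res = ComparisonResult(var, "fisher", np.nan, 1.0)
            elif a + c == 0 or b + d == 0:
                # trait constant in both groups
                res = ComparisonResult(var, "chisq", 0.0, 1.0)
            else:
                res = categorical_compare(var, ContingencyTable2x2(a, b, c, d))
        else:
            res = continuous_compare(v1, v2, method=continuous_method, variable=var)
        res.n_missing = n_missing
        rows.append(
            {
                "variable": var,
                "test": res.test,
                "statistic": res.statistic,
                "p_value": res.p_value,
                f"{g1}_summary": res.group1_summary,
                f"{g2}_summary": res.group2_summary,
                "n_missing": n_missing,
                "p_display": format_p(res.p_value),
            }
        )
    return pd.DataFrame(rows)


def format_p(p: float) -> str:
    """Report-style p formatting: 2 significant figures, scientific below 0.001."""
    if not np.isfinite(p):
        return "NA"
    if p >= 0.001:
        return f"{p:.2g}"
    return f"{p:.1e}"
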