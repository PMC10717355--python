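"""Propensity-score matching of cases to controls with balance diagnostics.

The propensity score is the fitted probability of case status from a logistic
regression on the matching covariates (by default gestational age, sex, and
maternal gestational hypertension).  Matching is greedy nearest-neighbour
without replacement on the logit of the propensity score: cases are processed
in descending propensity order and each takes the closest unused control(s),
optionally subject to a caliper.  Standardised mean differences before and
after matching quantify the covariate balance achieved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_stats import SeparationError, _logit_fit

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["gestational_age", "sex", "maternal_hypertension"]


@dataclass
class MatchResult:
    scores: pd.Series  # propensity per sample id (rows used in the fit)
    pairs: pd.DataFrame  # case_id, control_id, pair_distance
    ratio: int
    caliper: float | None
    balance: pd.DataFrame = field(default_factory=pd.DataFrame)  # covariate, smd_before, smd_after

    @property
    def matched_case_ids(self) -> list:
        return list(pd.unique(self.pairs["case_id"]))

    @property
    def matched_control_ids(self) -> list:
        return list(self.pairs["control_id"])


def _design_matrix(samples: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=samples.index)
    for cov in covariates:
        col = samples[cov]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.dropna().unique(), key=str)
            # binary encode against the first level; multi-level gets dummies
            for lev in levels[1:]:
                X[f"{cov}[{lev}]"] = (col == lev).astype(float)
                X.loc[col.isna(), f"{cov}[{lev}]"] = np.nan
        else:
            X[cov] = pd.to_numeric(col.astype("Float64"), errors="coerce").astype(float)
    return X


def estimate_propensity(
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    case_col: str = "group",
    case_value: str = "SGA",
) -> pd.Series:
    """Fitted case-probabilities from a logistic model of case status.

    Rows with missing covariates are excluded (logged) and absent from the
    returned Series.  Complete separation aborts with
    :class:`~sgaburden.cohort_stats.SeparationError`.
    """
    covariates = covariates or DEFAULT_COVARIATES
    X = _design_matrix(samples, covariates)
    y = (samples[case_col] == case_value).astype(float)
    keep = ~X.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("estimate_propensity: excluding %d row(s) with missing covariates", n_dropped)
    X, y = X[keep], y[keep]
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 samples per group to fit the propensity model")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        logger.warning("estimate_propensity: dropping constant covariate(s): %s", constant)
        X = X.drop(columns=constant)
    import statsmodels.api as sm

    design = np.column_stack([np.ones(len(X)), X.to_numpy()]) if len(X.columns) else np.ones((len(X), 1))
    fit = _logit_fit(y.to_numpy(), design)
    scores = pd.Series(fit.predict(design),
                       index=samples.loc[keep, "sample_id"].to_numpy(), name="propensity")
    return scores


def nearest_neighbor_match(
    scores: pd.Series,
    is_case: pd.Series,
    ratio: int = 1,
    caliper: float | None = None,
    seed: int = 0,
) -> MatchResult:
    """Greedy 1:ratio nearest-neighbour matching without replacement.

    Distances are absolute differences on the logit scale.  Cases are
    processed in descending propensity order; exact distance ties go to the
    smallest control id (after a seeded shuffle fixes the scan order, so the
    rule is deterministic).  With a caliper, a case whose nearest eligible
    control is farther than ``caliper`` logit units keeps fewer (possibly
    zero) partners, with a warning.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    is_case = is_case.reindex(scores.index)
    eps = 1e-12
    logit = np.log(np.clip(scores, eps, 1 - eps) / (1 - np.clip(scores, eps, 1 - eps)))
    case_ids = scores.index[is_case.astype(bool)]
    control_ids = scores.index[~is_case.astype(bool)]
    if len(case_ids) == 0 or len(control_ids) == 0:
        raise ValueError("both groups must be non-empty")

    rng = np.random.default_rng(seed)
    control_ids = pd.Index(rng.permutation(control_ids))
    c_logit = logit[control_ids].to_numpy()
    available = np.ones(len(control_ids), dtype=bool)

    order = scores[case_ids].sort_values(ascending=False, kind="stable").index
    rows = []
    for cid in order:
        target = logit[cid]
        for _ in range(ratio):
            idx = np.flatnonzero(available)
            if len(idx) == 0:
                break
            dist = np.abs(c_logit[idx] - target)
            best = dist.min()
            if caliper is not None and best > caliper:
                warnings.warn(f"case {cid}: nearest control beyond caliper ({best:.3g} > {caliper})")
                break
            tied = idx[dist <= best + eps]
            pick = tied[np.argmin([str(control_ids[t]) for t in tied])] if len(tied) > 1 else tied[0]
            available[pick] = False
            rows.append({"case_id": cid, "control_id": control_ids[pick], "pair_distance": float(best)})
    pairs = pd.DataFrame(rows, columns=["case_id", "control_id", "pair_distance"])
    return MatchResult(scores=scores, pairs=pairs, ratio=ratio, caliper=caliper)


def _smd(case_vals: np.ndarray, control_vals: np.ndarray, pooled_sd: float) -> float:
    diff = np.nanmean(case_vals) - np.nanmean(control_vals)
    if pooled_sd == 0:
        if abs(diff) < 1e-12:
            return 0.0
        raise ZeroDivisionError("zero pooled SD with unequal means")
    return float(diff / pooled_sd)


def balance_diagnostics(
    match: MatchResult,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    case_col: str = "group",
    case_value: str = "SGA",
) -> pd.DataFrame:
    """Standardised mean differences per covariate, before and after matching.

    SMD = (mean_case - mean_control) / pooled SD, with the pooled SD taken
    from the full (pre-match) groups so before/after values share a scale.
    """
    covariates = covariates or DEFAULT_COVARIATES
    if len(match.pairs) == 0:
        raise ValueError("no matched pairs")
    X = _design_matrix(samples, covariates)
    X.index = samples["sample_id"].to_numpy()
    is_case = pd.Series((samples[case_col] == case_value).to_numpy(), index=X.index)
    matched_cases = set(match.matched_case_ids)
    matched_controls = set(match.matched_control_ids)
    rows = []
    for col in X.columns:
        v = X[col]
        case_all = v[is_case].to_numpy()
        ctrl_all = v[~is_case].to_numpy()
        s1, s2 = np.nanvar(case_all, ddof=1), np.nanvar(ctrl_all, ddof=1)
        pooled = float(np.sqrt((s1 + s2) / 2.0))
        before = _smd(case_all, ctrl_all, pooled)
        after = _smd(
            v[v.index.isin(matched_cases)].to_numpy(),
            v[v.index.isin(matched_controls)].to_numpy(),
            pooled,
        )
        rows.append({"covariate": col, "smd_before": before, "smd_after": after})
    match.balance = pd.DataFrame(rows)
    return match.balance


def match_cohort(
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    ratio: int = 1,
    caliper: float | None = None,
    seed: int = 0,
    case_col: str = "group",
    case_value: str = "SGA",
) -> MatchResult:
    """Propensity estimation + matching + balance diagnostics in one call."""
    covariates = covariates or DEFAULT_COVARIATES
    scores = estimate_propensity(samples, covariates, case_col=case_col, case_value=case_value)
    is_case = pd.Series(
        (samples.set_index("sample_id")[case_col] == case_value).reindex(scores.index).to_numpy(),
        index=scores.index,
    )
    result = nearest_neighbor_match(scores, is_case, ratio=ratio, caliper=caliper, seed=seed)
    balance_diagnostics(result, samples, covariates, case_col=case_col, case_value=case_value)
    return result
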