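"""Poor-prognosis prediction: burden features, clinical-factor screening,
gradient-boosted models, and DeLong AUC comparison.

Genetic predictors are per-risk-gene 2/1/0 burden scores (2 = carries a
protein-truncating variant in the gene, 1 = missense only, 0 = otherwise).
Clinical factors are the organ-system flags that pass a univariable logistic
screen (p < alpha) on the *training* data.  Two gradient-boosting classifiers
are trained — clinical factors only, and clinical + genetic — with
hyperparameters picked by repeated stratified k-fold cross-validated AUC, and
compared on held-out data with DeLong's paired test.  Everything downstream
of the train/test split sees training data only, so held-out and external
validation estimates are leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold, train_test_split

from .cohort_stats import SeparationError, univariable_logistic
from .simulate import FLAG_COLUMNS
from .variants import GeneTypeCountMatrix, VariantType


@dataclass
class GbmConfig:
    """Cross-validation and hyperparameter grid for the boosted models."""

    cv_folds: int = 10
    cv_repeats: int = 3
    grid: dict = field(
        default_factory=lambda: {
            "n_estimators": [50, 100, 150],
            "max_depth": [1, 2, 3],
            "learning_rate": [0.1],
            "min_samples_leaf": [10],
        }
    )
    seed: int = 0


def burden_features(
    matrix: GeneTypeCountMatrix,
    risk_genes: list[str],
    mode: str = "per_gene",
) -> pd.DataFrame:
    """2/1/0 rare-variant burden per sample for each risk gene.

    mode='per_gene' gives one column per risk gene; mode='sum' a single
    summed score.  Scores: 2 if the sample carries any PTV in the gene, 1 if
    any missense (and no PTV), else 0.
    """
    gene_idx = {g: i for i, g in enumerate(matrix.genes)}
    missing = [g for g in risk_genes if g not in gene_idx]
    if missing:
        raise KeyError(f"risk gene(s) absent from matrix: {', '.join(missing[:5])}")
    cols = {}
    ptv = matrix.carriers(VariantType.PTV)
    mis = matrix.carriers(VariantType.MIS)
    for g in risk_genes:
        i = gene_idx[g]
        cols[f"burden_{g}"] = np.where(ptv[i], 2, np.where(mis[i], 1, 0))
    out = pd.DataFrame(cols, index=matrix.samples)
    if mode == "sum":
        out = out.sum(axis=1).to_frame("burden_sum")
    elif mode != "per_gene":
        raise ValueError(f"unknown genetic feature mode {mode!r}")
    out.index.name = "sample_id"
    return out


def select_clinical_factors(
    samples: pd.DataFrame,
    outcome_col: str = "poor_prognosis",
    candidates: list[str] | None = None,
    alpha: float = 0.05,
) -> list[str]:
    """Organ-system flags whose univariable logistic p-value is < alpha.

    Flags that separate perfectly (or are constant) are skipped — they cannot
    be screened by a Wald test and would destabilise the fit.
    """
    candidates = candidates if candidates is not None else FLAG_COLUMNS
    y = samples[outcome_col].astype(int)
    if y.nunique() < 2:
        raise ValueError("training outcome must contain both classes")
    selected = []
    for flag in candidates:
        x = samples[flag].astype(int)
        if x.nunique() < 2:
            continue
        try:
            fit = univariable_logistic(y, x)
        except (SeparationError, ValueError):
            continue
        if fit["p"] < alpha:
            selected.append(flag)
    if not selected:
        import warnings

        warnings.warn("no clinical factor passed the univariable screen")
    return selected


def split_train_test(samples: pd.DataFrame, ratio: float = 0.7, seed: int = 0,
                     outcome_col: str = "poor_prognosis", stratify: bool = True):
    """Disjoint, exhaustive train/test split (default 7:3), stratified by outcome."""
    if len(samples) < 10:
        raise ValueError("need at least 10 samples to split")
    strat = samples[outcome_col] if stratify else None
    train, test = train_test_split(
        samples, train_size=ratio, random_state=seed, stratify=strat, shuffle=True
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def train_gbm(features: pd.DataFrame, labels, config: GbmConfig | None = None):
    """Gradient-boosted trees with the grid point maximising repeated-CV AUC.

    The winning hyperparameters are refit on all training data.  Fully seeded:
    same inputs, same model.
    """
    config = config or GbmConfig()
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if not config.grid:
        raise ValueError("empty hyperparameter grid")
    cv = RepeatedStratifiedKFold(
        n_splits=config.cv_folds, n_repeats=config.cv_repeats, random_state=config.seed
    )
    search = GridSearchCV(
        GradientBoostingClassifier(random_state=config.seed),
        param_grid=config.grid,
        scoring="roc_auc",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(features.to_numpy(dtype=float), y)
    return search.best_estimator_


# ---------------------------------------------------------------------------
# DeLong AUC machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(labels: np.ndarray, scores: np.ndarray):
    """AUC and the DeLong placement components V10 (cases), V01 (controls)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def auc_ci_delong(labels, scores, level: float = 0.95):
    """AUC (Mann-Whitney) with a DeLong confidence interval, truncated to [0, 1]."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    auc, v10, v01 = _delong_components(labels, scores)

    def _v(x):  # single observation contributes no estimable variance
        return np.var(x, ddof=1) / len(x) if len(x) > 1 else 0.0

    var = _v(v10) + _v(v01)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def delong_paired_test(labels, scores1, scores2) -> float:
    """Two-sided p for a difference in AUC between two models scored on the
    same samples, using the paired DeLong covariance."""
    labels = np.asarray(labels, dtype=int)
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    if s1.shape != s2.shape or s1.shape != labels.shape:
        raise ValueError("labels and both score vectors must be aligned")
    auc1, v10_1, v01_1 = _delong_components(labels, s1)
    auc2, v10_2, v01_2 = _delong_components(labels, s2)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 1.0
    z = (auc1 - auc2) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


class _ConstantModel:
    """Fallback intercept-only classifier when no feature survives screening."""

    def __init__(self, prevalence: float):
        self.prevalence = prevalence

    def predict_proba(self, X):
        p = np.full(len(X), self.prevalence)
        return np.column_stack([1 - p, p])


@dataclass
class ModelEvaluation:
    model_id: str  # clinical | clinical_genetic
    dataset_id: str  # test | validation
    auc: float
    ci_low: float
    ci_high: float
    paired_p: float | None = None  # vs the other model on the same dataset


def evaluate_two_models(
    train: pd.DataFrame,
    test: pd.DataFrame,
    validation: pd.DataFrame | None,
    clinical_factors: list[str],
    genetic_columns: list[str],
    outcome_col: str = "poor_prognosis",
    config: GbmConfig | None = None,
) -> tuple[list[ModelEvaluation], dict]:
    """Train clinical-only and clinical+genetic boosted models and evaluate both
    on the held-out test set (and an external validation set, if given).

    All tables must carry the clinical factor and genetic burden columns.
    Returns the evaluations plus the fitted models and score vectors.
    """
    config = config or GbmConfig()
    feats = {"clinical": list(clinical_factors), "clinical_genetic": list(clinical_factors) + list(genetic_columns)}
    datasets = {"test": test} | ({"validation": validation} if validation is not None else {})
    for name, df in {"train": train, **datasets}.items():
        missing = [c for c in feats["clinical_genetic"] if c not in df.columns]
        if missing:
            raise KeyError(f"{name} dataset lacks feature column(s): {', '.join(missing[:5])}")

    models, scores = {}, {}
    for model_id, cols in feats.items():
        if cols:
            models[model_id] = train_gbm(train[cols].astype(float), train[outcome_col], config)
        else:
            # nothing passed the screen: an intercept-only model (constant
            # predicted risk = training prevalence)
            models[model_id] = _ConstantModel(float(np.mean(train[outcome_col])))
        for ds_id, df in datasets.items():
            X = df[cols].to_numpy(dtype=float) if cols else np.zeros((len(df), 1))
            scores[(model_id, ds_id)] = models[model_id].predict_proba(X)[:, 1]

    evaluations = []
    for ds_id, df in datasets.items():
        y = df[outcome_col].astype(int).to_numpy()
        p = delong_paired_test(y, scores[("clinical_genetic", ds_id)], scores[("clinical", ds_id)])
        for model_id in feats:
            auc, (lo, hi) = auc_ci_delong(y, scores[(model_id, ds_id)])
            evaluations.append(ModelEvaluation(model_id, ds_id, auc, lo, hi, paired_p=p))
    return evaluations, {"models": models, "scores": scores}
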