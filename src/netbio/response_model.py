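"""Immunotherapy-response classification.

An L2-regularized logistic regression with balanced class weights is trained
on z-standardized pathway-activity (or gene-expression) features.  The
regularization strength C is chosen by stratified 5-fold cross-validation
over the grid {0.1, 0.2, ..., 1.0}.  Evaluation protocols: leave-one-out
cross-validation (LOOCV), Monte-Carlo cross-validation (repeated stratified
80/20 splits), and across-study prediction (train on one cohort, test on an
independent one over shared features).  A data-driven ANOVA-F SelectKBest
baseline is provided for comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import (
    GridSearchCV,
    LeaveOneOut,
    StratifiedKFold,
    train_test_split,
)

logger = logging.getLogger("netbio")

__all__ = [
    "RECIST_RESPONDER",
    "ModelSpec",
    "FittedModel",
    "PredictionResult",
    "MetricReport",
    "binarize_recist",
    "fit_classifier",
    "predict",
    "loocv",
    "monte_carlo_cv",
    "across_study_predict",
    "anova_f_scores",
    "anova_select_k",
    "compute_metrics",
    "feature_importance",
    "compare_groups",
]

#: RECIST best-overall-response classes mapped to the binary responder label.
RECIST_RESPONDER = {"CR": 1, "PR": 1, "SD": 0, "PD": 0, "R": 1, "NR": 0}


def binarize_recist(recist: Sequence[str]) -> np.ndarray:
    """CR/PR -> responder (1); SD/PD -> non-responder (0)."""
    try:
        return np.array([RECIST_RESPONDER[r] for r in recist], dtype=int)
    except KeyError as e:
        raise ValueError(f"unknown RECIST class {e.args[0]!r}") from None


@dataclass
class ModelSpec:
    """Hyperparameters of the response classifier and its inner model selection."""

    C_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))
    inner_folds: int = 5
    class_weight: str = "balanced"
    inner_scoring: str = "accuracy"
    rng_seed: int = 0
    max_iter: int = 2000

    def __post_init__(self) -> None:
        if not self.C_grid or any(c <= 0 for c in self.C_grid):
            raise ValueError("C_grid must be non-empty and positive")


@dataclass
class FittedModel:
    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    chosen_C: float
    estimator: LogisticRegression = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("one coefficient per feature required")


@dataclass
class PredictionResult:
    """Per-sample responder probability; predicted label = probability >= 0.5."""

    probabilities: pd.Series  # index: sample identifiers

    def __post_init__(self) -> None:
        p = self.probabilities.to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def labels(self) -> pd.Series:
        return (self.probabilities >= 0.5).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probability": self.probabilities, "predicted_label": self.labels}
        ).rename_axis("sample")


@dataclass
class MetricReport:
    accuracy: float
    f1: float
    auc_roc: float
    auprc: float
    fisher_p: float
    confusion: np.ndarray  # 2×2, rows pred R/NR, cols observed R/NR

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc_roc": self.auc_roc,
            "auprc": self.auprc,
            "fisher_p": self.fisher_p,
            "confusion": np.asarray(self.confusion).tolist(),
        }


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def fit_classifier(X, y, spec: ModelSpec | None = None) -> FittedModel:
    """Grid-search C by stratified inner CV, then refit on all data.

    Ties on the inner score go to the smallest C (strongest regularization).
    With too few minority samples for the requested folds, the fold count is
    reduced (with a warning); below 2 usable folds the smallest grid C is used
    directly.
    """
    spec = spec or ModelSpec()
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present to fit the classifier")
    n_minority = int(counts.min())

    # default penalty is the ridge (L2) one
    base = LogisticRegression(
        solver="lbfgs",
        class_weight=spec.class_weight,
        max_iter=spec.max_iter,
        random_state=spec.rng_seed,
    )
    folds = min(spec.inner_folds, n_minority)
    if folds < spec.inner_folds:
        warnings.warn(
            f"minority class has {n_minority} samples; inner CV reduced to {folds} folds",
            stacklevel=2,
        )
    if folds >= 2:
        search = GridSearchCV(
            base,
            param_grid={"C": list(spec.C_grid)},
            scoring=spec.inner_scoring,
            cv=StratifiedKFold(n_splits=folds, shuffle=False),
            n_jobs=None,
        )
        search.fit(Xf.to_numpy(dtype=float), y)
        chosen_C = float(search.best_params_["C"])
    else:
        chosen_C = float(min(spec.C_grid))
    est = base.set_params(C=chosen_C)
    est.fit(Xf.to_numpy(dtype=float), y)
    return FittedModel(
        feature_names=[str(c) for c in Xf.columns],
        coefficients=est.coef_.ravel().copy(),
        intercept=float(est.intercept_[0]),
        chosen_C=chosen_C,
        estimator=est,
    )


def predict(model: FittedModel, X) -> PredictionResult:
    Xf = _as_frame(X)
    probs = model.estimator.predict_proba(Xf.to_numpy(dtype=float))[:, 1]
    return PredictionResult(pd.Series(probs, index=Xf.index, name="probability"))


def loocv(X, y, spec: ModelSpec | None = None) -> tuple[PredictionResult, MetricReport]:
    """Leave-one-out CV: inner grid search on each training fold, held-out
    probability per sample, metrics computed once over all held-out predictions."""
    spec = spec or ModelSpec()
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 10:
        warnings.warn(f"LOOCV on only {n} samples", stacklevel=2)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 10:
        warnings.warn("fewer than 10 samples in a class", stacklevel=2)
    probs = np.empty(n)
    arr = Xf.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # repeated small-fold warnings
        for train_idx, test_idx in LeaveOneOut().split(arr):
            model = fit_classifier(Xf.iloc[train_idx], y[train_idx], spec)
            probs[test_idx[0]] = model.estimator.predict_proba(arr[test_idx])[0, 1]
    pred = PredictionResult(pd.Series(probs, index=Xf.index, name="probability"))
    return pred, compute_metrics(y, probs)


def monte_carlo_cv(
    X,
    y,
    spec: ModelSpec | None = None,
    n_iter: int = 100,
    train_frac: float = 0.8,
    return_splits: bool = False,
):
    """Repeated stratified random 80/20 splits; one MetricReport per iteration.

    Split i uses random state ``rng_seed + i``, so two feature sets evaluated
    with the same spec and labels see identical splits (paired comparison).
    """
    spec = spec or ModelSpec()
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=int)
    idx = np.arange(len(y))
    reports: list[MetricReport] = []
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    n_resampled = 0
    for i in range(n_iter):
        state = spec.rng_seed + i
        while True:
            tr, te = train_test_split(
                idx, train_size=train_frac, random_state=state, stratify=y
            )
            if np.unique(y[tr]).size == 2 and np.unique(y[te]).size == 2:
                break
            n_resampled += 1
            state += 10_000_019  # resample with a shifted state
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_classifier(Xf.iloc[tr], y[tr], spec)
        probs = model.estimator.predict_proba(Xf.iloc[te].to_numpy(dtype=float))[:, 1]
        reports.append(compute_metrics(y[te], probs))
        splits.append((tr, te))
    if n_resampled:
        logger.info("%d degenerate splits were resampled", n_resampled)
    if return_splits:
        return reports, splits
    return reports


def across_study_predict(
    train_X, train_y, test_X, spec: ModelSpec | None = None
) -> PredictionResult:
    """Fit on the full training cohort; predict an independent cohort over the
    intersection of feature names.  Each cohort must be z-scored independently
    beforehand."""
    train_X, test_X = _as_frame(train_X), _as_frame(test_X)
    common = sorted(set(train_X.columns) & set(test_X.columns))
    if not common:
        raise ValueError("no shared features between cohorts")
    dropped = (len(train_X.columns) - len(common)) + (len(test_X.columns) - len(common))
    if dropped:
        logger.info("across-study: %d non-shared feature columns dropped", dropped)
    model = fit_classifier(train_X[common], train_y, spec)
    return predict(model, test_X[common])


def anova_f_scores(X, y) -> pd.Series:
    """One-way ANOVA F statistic per feature between the two classes.

    Zero within-group variance with differing group means gives +inf;
    a feature constant overall scores 0.
    """
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f_classif(Xf.to_numpy(dtype=float), y)
    F = np.asarray(F, dtype=float)
    n_inf = int(np.isinf(F).sum())
    if n_inf:
        logger.info("%d features with zero within-group variance ranked first", n_inf)
    return pd.Series(np.nan_to_num(F, nan=0.0), index=[str(c) for c in Xf.columns])


def anova_select_k(X, y, k: int) -> list[str]:
    """Top-k features by one-way ANOVA F between the two classes.

    Zero within-group variance (with group means differing) gives F = +inf and
    ranks first; a feature constant overall scores 0.  Ties break by ascending
    feature name.  Must be called on training data only.
    """
    Xf = _as_frame(X)
    if k > Xf.shape[1]:
        raise ValueError(f"k={k} exceeds {Xf.shape[1]} features")
    scores = anova_f_scores(Xf, y)
    names = list(scores.index)
    order = sorted(range(len(names)), key=lambda i: (-scores.iloc[i], names[i]))
    return [names[i] for i in order[:k]]


def compute_metrics(y_true, probabilities) -> MetricReport:
    """Threshold-free (ROC AUC, AUPRC) and threshold-0.5 (accuracy, F1,
    Fisher-exact) metrics of responder predictions."""
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined: only one class present in y_true")
    pred = (p >= 0.5).astype(int)
    # rows: predicted R / predicted NR; cols: observed R / observed NR
    confusion = np.array(
        [
            [int(((pred == 1) & (y == 1)).sum()), int(((pred == 1) & (y == 0)).sum())],
            [int(((pred == 0) & (y == 1)).sum()), int(((pred == 0) & (y == 0)).sum())],
        ]
    )
    _, fisher_p = stats.fisher_exact(confusion, alternative="two-sided")
    return MetricReport(
        accuracy=float(accuracy_score(y, pred)),
        f1=float(f1_score(y, pred, pos_label=1, zero_division=0)),
        auc_roc=float(roc_auc_score(y, p)),
        auprc=float(average_precision_score(y, p)),
        fisher_p=float(fisher_p),
        confusion=confusion,
    )


def feature_importance(
    model: FittedModel, top_n: int = 10, sign: str = "positive"
) -> list[tuple[str, float]]:
    """Features ranked by |coefficient| within the requested sign
    (``positive``, ``negative`` or ``both``); ties break by name."""
    if sign not in ("positive", "negative", "both"):
        raise ValueError(f"unknown sign {sign!r}")
    pairs = list(zip(model.feature_names, model.coefficients))
    if sign == "positive":
        pairs = [(n, c) for n, c in pairs if c > 0]
    elif sign == "negative":
        pairs = [(n, c) for n, c in pairs if c < 0]
    else:
        pairs = [(n, c) for n, c in pairs if c != 0]
    if not pairs:
        warnings.warn("no nonzero coefficients with the requested sign", stacklevel=2)
    pairs.sort(key=lambda nc: (-abs(nc[1]), nc[0]))
    return [(n, float(c)) for n, c in pairs[:top_n]]


def compare_groups(
    values_a, values_b, test: str = "t_test", welch: bool = False
) -> tuple[float, float]:
    """Two-sided group comparison: Student's t (pooled variance by default,
    Welch optional) or the Mann–Whitney U test.  Returns (statistic, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "t_test":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test requires >= 2 values per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError("zero variance in both groups")
        stat, p = stats.ttest_ind(a, b, equal_var=not welch)
    elif test == "mann_whitney":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("Mann-Whitney requires >= 1 value per group")
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(stat), float(p)
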