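"""Capped forward selection, cross-validated regression, and classification.

The analysis mirrors a small-cohort clinical ML workflow: greedy forward
feature selection on the full dataset capped at three terms (a deliberate
small-n concession — selection is not nested inside the folds), ordinary
least squares for the filling-pressure regression scored by pooled
fivefold-CV R^2, and a panel of standard classifiers (LDA, logistic
regression, KNN, depth-limited tree, RBF-SVM) benchmarked against a
majority-class dummy and a BNP-only comparator.

CV metrics are pooled: held-out predictions from all folds are
concatenated and each metric is computed once, which keeps the dummy
baseline's identities exact (recall 0, specificity 1, AUROC 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ModelingError, UsageError
from .feature_table import FeatureMatrix, final_model_features

__all__ = [
    "RegressionFit",
    "ClassifierMetrics",
    "SelectionTrace",
    "CLASSIFIER_METHODS",
    "fit_ols",
    "forward_select",
    "cv_regress",
    "label_overload",
    "cv_classify",
    "dummy_classify",
    "bnp_only_model",
    "auroc_score",
    "evaluate_case",
]

_COLLINEAR_TOL = 1e-10

CLASSIFIER_METHODS = ("lda", "logistic", "knn", "tree", "svm_rbf")


@dataclass
class RegressionFit:
    feature_names: list[str]
    intercept: float
    coefficients: np.ndarray
    r2: float
    adj_r2: float
    f_pvalue: float
    fitted: np.ndarray  # in-sample predictions, mmHg
    residuals: np.ndarray
    cv_r2: Optional[float] = None
    cv_predictions: Optional[np.ndarray] = None  # pooled held-out, mmHg
    dropped_collinear: list[str] = field(default_factory=list)


@dataclass
class ClassifierMetrics:
    method: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    auroc: float
    scores: np.ndarray  # pooled held-out scores
    labels: np.ndarray
    predictions: np.ndarray


@dataclass
class SelectionTrace:
    selected: list[str]
    criteria: list[float]  # criterion value after each addition

    def __post_init__(self) -> None:
        if len(self.selected) != len(self.criteria):
            raise UsageError("trace lengths must match")


# ---------------------------------------------------------------------------
# regression


def _drop_collinear(
    X: np.ndarray, names: Sequence[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedily keep columns while the design (with intercept) stays
    numerically full rank; singular values below 1e-10 x max are rank 0."""
    n = X.shape[0]
    kept_idx: list[int] = []
    dropped: list[str] = []
    ones = np.ones((n, 1))
    for j in range(X.shape[1]):
        trial = np.hstack([ones, X[:, kept_idx + [j]]])
        s = np.linalg.svd(trial, compute_uv=False)
        if s[-1] > _COLLINEAR_TOL * s[0]:
            kept_idx.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        warnings.warn(
            f"dropping exactly-collinear columns: {dropped}", stacklevel=3
        )
    return X[:, kept_idx], [names[j] for j in kept_idx], dropped


def fit_ols(
    X: np.ndarray, y: np.ndarray, feature_names: Optional[Sequence[str]] = None
) -> RegressionFit:
    """Ordinary least squares with intercept; R^2, adjusted R^2, F-test p."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(y) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    feature_names = list(feature_names)
    Xk, names, dropped = _drop_collinear(X, feature_names)
    if Xk.shape[1] == 0:
        raise ModelingError("design is rank deficient after dropping columns")
    if n <= Xk.shape[1] + 1:
        raise ModelingError(
            f"need n > p + 1 (n={n}, p={Xk.shape[1]}) for OLS with intercept"
        )
    model = sm.OLS(y, sm.add_constant(Xk, has_constant="add")).fit()
    fitted = np.asarray(model.fittedvalues)
    return RegressionFit(
        feature_names=names,
        intercept=float(model.params[0]),
        coefficients=np.asarray(model.params[1:]),
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        f_pvalue=float(model.f_pvalue) if Xk.shape[1] > 0 else float("nan"),
        fitted=fitted,
        residuals=y - fitted,
        dropped_collinear=dropped,
    )


def cv_regress(
    X: np.ndarray, y: np.ndarray, folds: int = 5, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Pooled fivefold-CV R^2 for a fixed feature set.

    Folds are a seeded shuffle; the model is refit per training fold and
    cv_r2 = 1 - sum((y - yhat_heldout)^2) / sum((y - ybar)^2) over the
    pooled held-out predictions.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and len(y) > 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < folds:
        raise ModelingError(f"n={n} smaller than {folds} folds")
    pred = np.empty(n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        if len(train) < p + 2:
            raise ModelingError(
                f"training fold of {len(train)} rows cannot support {p} features; "
                "use fewer features or more data"
            )
        reg = LinearRegression().fit(X[train], y[train])
        pred[test] = reg.predict(X[test])
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ModelingError("target has zero variance")
    return 1.0 - ss_res / ss_tot, pred


# ---------------------------------------------------------------------------
# forward selection


def _make_classifier(method: str, seed: int = 0):
    """Fixed-hyperparameter estimators; scale-sensitive ones standardize
    internally (the scaler is refit on each training fold by clone)."""
    if method == "lda":
        return LinearDiscriminantAnalysis()
    if method == "logistic":
        return Pipeline(
            [("scale", StandardScaler()),
             ("clf", LogisticRegression(max_iter=2000))]
        )
    if method == "knn":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", KNeighborsClassifier(n_neighbors=5))]
        )
    if method == "tree":
        return DecisionTreeClassifier(max_depth=3, random_state=seed)
    if method == "svm_rbf":
        return Pipeline(
            [("scale", StandardScaler()),
             ("clf", SVC(C=1.0, kernel="rbf", gamma="scale"))]
        )
    raise UsageError(f"unknown classifier method {method!r}")


def forward_select(
    matrix_or_X: Union[FeatureMatrix, np.ndarray],
    y: Optional[np.ndarray] = None,
    k: int = 3,
    task: str = "regression",
    method: str = "lda",
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> SelectionTrace:
    """Greedy forward selection on the full dataset, capped at ``k`` terms.

    At each step the candidate maximizing the in-sample criterion
    (regression: OLS R^2; classification: refit accuracy of ``method``)
    joins the model; ties break toward the earlier column; selection
    stops early once no candidate improves the criterion.  Performing
    selection outside the CV folds deliberately reproduces the published
    small-cohort workflow and is a known source of optimism — the cap at
    three features is its mitigation.
    """
    if isinstance(matrix_or_X, FeatureMatrix):
        X = matrix_or_X.values
        names = list(matrix_or_X.feature_names)
        if y is None:
            y = matrix_or_X.target
    else:
        X = np.asarray(matrix_or_X, dtype=float)
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )
        if y is None:
            raise UsageError("y is required when passing a bare array")
    y = np.asarray(y)
    n, p = X.shape
    if p == 0:
        raise UsageError("candidate pool is empty")
    if k < 1 or k > p:
        raise UsageError(f"k={k} outside [1, {p}]")
    if task not in ("regression", "classification"):
        raise UsageError("task must be regression or classification")

    def criterion(cols: list[int]) -> float:
        Xs = X[:, cols]
        if task == "regression":
            return LinearRegression().fit(Xs, y).score(Xs, y)
        est = _make_classifier(method, seed=seed)
        est.fit(Xs, y)
        return float(np.mean(est.predict(Xs) == y))

    selected: list[int] = []
    criteria: list[float] = []
    current = -np.inf
    for _ in range(k):
        best_j, best_c = None, current
        for j in range(p):
            if j in selected:
                continue
            try:
                c = criterion(selected + [j])
            except np.linalg.LinAlgError:
                continue
            if c > best_c + 1e-12:
                best_j, best_c = j, c
        if best_j is None:
            break
        selected.append(best_j)
        criteria.append(best_c)
        current = best_c
    if not selected:
        raise ModelingError("no candidate feature improved the criterion")
    return SelectionTrace(selected=[names[j] for j in selected], criteria=criteria)


# ---------------------------------------------------------------------------
# classification


def label_overload(pressure, threshold: float = 15.0):
    """Volume-overload label: strictly greater than the cutoff (mmHg)."""
    pressure = np.asarray(pressure, dtype=float)
    if np.any(pressure <= 0):
        raise UsageError("pressures must be positive")
    if threshold <= 0:
        raise UsageError("threshold must be positive")
    out = pressure > threshold
    return bool(out) if out.ndim == 0 else out


def auroc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUROC via the Mann-Whitney U statistic (ties count one half)."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ModelingError("AUROC needs both classes")
    ranks = rankdata(scores)
    u = float(ranks[labels].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def _pooled_metrics(
    method: str, labels: np.ndarray, preds: np.ndarray, scores: np.ndarray
) -> ClassifierMetrics:
    labels = np.asarray(labels, dtype=bool)
    preds = np.asarray(preds, dtype=bool)
    tp = int(np.sum(preds & labels))
    fp = int(np.sum(preds & ~labels))
    tn = int(np.sum(~preds & ~labels))
    fn = int(np.sum(~preds & labels))
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    specificity = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return ClassifierMetrics(
        method=method,
        accuracy=float(np.mean(preds == labels)),
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=specificity,
        auroc=auroc_score(labels, scores),
        scores=np.asarray(scores, dtype=float),
        labels=labels,
        predictions=preds,
    )


def _positive_scores(est, X: np.ndarray) -> np.ndarray:
    """Positive-class score: posterior probability where available,
    signed decision values otherwise (the probability-free SVM)."""
    try:
        proba = est.predict_proba(X)
    except AttributeError:
        return np.asarray(est.decision_function(X), dtype=float)
    classes = np.asarray(est.classes_)
    pos_col = int(np.nonzero(classes)[0][0]) if classes.dtype == bool else 1
    return np.asarray(proba[:, pos_col], dtype=float)


def _stratified_folds(labels: np.ndarray, folds: int, seed: int):
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ModelingError("both classes must be present")
    if min(labels.sum(), (~labels).sum()) < folds:
        raise ModelingError(
            f"minority class of {min(labels.sum(), (~labels).sum())} cannot "
            f"populate {folds} stratified folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(np.zeros(len(labels)), labels):
        if len(np.unique(labels[train])) < 2:
            raise ModelingError("a training fold contains a single class")
        yield train, test


def cv_classify(
    X: np.ndarray,
    labels: np.ndarray,
    method: str = "lda",
    folds: int = 5,
    seed: int = 0,
) -> ClassifierMetrics:
    """Stratified seeded CV; metrics on pooled held-out predictions.

    Scores are posterior probabilities of the positive class (signed
    decision values for the SVM), pooled across folds before a single
    metric computation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and len(labels) > 1:
        X = X.T
    labels = np.asarray(labels, dtype=bool)
    n = len(labels)
    if n < folds:
        raise ModelingError(f"n={n} smaller than {folds} folds")
    preds = np.empty(n, dtype=bool)
    scores = np.empty(n, dtype=float)
    for train, test in _stratified_folds(labels, folds, seed):
        est = _make_classifier(method, seed=seed)
        est.fit(X[train], labels[train])
        preds[test] = est.predict(X[test]).astype(bool)
        scores[test] = _positive_scores(est, X[test])
    return _pooled_metrics(method, labels, preds, scores)


def dummy_classify(
    labels: np.ndarray, folds: int = 5, seed: int = 0
) -> ClassifierMetrics:
    """Majority-class baseline under the same CV machinery.

    Each held-out row receives the training-fold majority class and a
    constant score, so when the majority is the negative class the pooled
    metrics are exactly recall 0, precision 0, F1 0, specificity 1, and
    AUROC 0.5 (all score pairs tied).
    """
    labels = np.asarray(labels, dtype=bool)
    n = len(labels)
    preds = np.empty(n, dtype=bool)
    scores = np.full(n, 0.5)
    for train, test in _stratified_folds(labels, folds, seed):
        majority = labels[train].sum() > len(train) / 2.0
        preds[test] = majority
    return _pooled_metrics("dummy", labels, preds, scores)


def bnp_only_model(
    bnp: np.ndarray,
    y: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
    method: str = "lda",
    folds: int = 5,
    seed: int = 0,
):
    """BNP-as-sole-feature comparator through the same CV machinery.

    Returns a :class:`RegressionFit` when ``y`` (pressure) is given, else
    :class:`ClassifierMetrics` for ``labels``.
    """
    bnp = np.asarray(bnp, dtype=float).reshape(-1, 1)
    if np.any(bnp <= 0):
        raise UsageError("BNP values must be positive")
    if (y is None) == (labels is None):
        raise UsageError("provide exactly one of y or labels")
    if y is not None:
        y = np.asarray(y, dtype=float)
        if np.ptp(bnp) > 0:
            fit = fit_ols(bnp, y, feature_names=["bnp"])
        else:
            # constant BNP: intercept-only comparator with no skill
            fitted = np.full(len(y), y.mean())
            fit = RegressionFit(
                feature_names=[], intercept=float(y.mean()),
                coefficients=np.empty(0), r2=0.0, adj_r2=0.0,
                f_pvalue=float("nan"), fitted=fitted, residuals=y - fitted,
                dropped_collinear=["bnp"],
            )
        fit.cv_r2, fit.cv_predictions = cv_regress(bnp, y, folds=folds, seed=seed)
        return fit
    return cv_classify(bnp, labels, method=method, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# case runner


def evaluate_case(
    pool: FeatureMatrix,
    case: str,
    feature_mode: str = "search",
    method: str = "lda",
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Run one analysis case end to end on a candidate pool.

    ``case``: ``regression``, ``classify_15``, or ``classify_10``;
    ``feature_mode``: ``search`` (fresh forward selection) or
    ``published`` (the fixed three-term constructions).  Returns a dict
    with the selected features, the model fit/metrics, and the dummy and
    BNP comparators where defined.
    """
    if case not in ("regression", "classify_15", "classify_10"):
        raise UsageError(f"unknown case {case!r}")
    if feature_mode not in ("search", "published"):
        raise UsageError("feature_mode must be 'search' or 'published'")
    out: dict = {"case": case, "feature_mode": feature_mode}
    if case == "regression":
        target: np.ndarray = pool.target
        if feature_mode == "published":
            sub = final_model_features(pool, case)
            names = sub.feature_names
            trace = None
        else:
            trace = forward_select(pool, target, k=3, task="regression", seed=seed)
            names = trace.selected
            sub = pool.select(names)
        fit = fit_ols(sub.values, target, feature_names=names)
        fit.cv_r2, fit.cv_predictions = cv_regress(
            sub.values, target, folds=folds, seed=seed
        )
        out.update(features=names, trace=trace, fit=fit)
        if pool.bnp is not None:
            out["bnp"] = bnp_only_model(pool.bnp, y=target, folds=folds, seed=seed)
        return out
    labels = pool.labels_15 if case == "classify_15" else pool.labels_10
    if feature_mode == "published":
        sub = final_model_features(pool, case)
        names = sub.feature_names
        trace = None
    else:
        trace = forward_select(
            pool, labels, k=3, task="classification", method=method, seed=seed
        )
        names = trace.selected
        sub = pool.select(names)
    metrics = cv_classify(sub.values, labels, method=method, folds=folds, seed=seed)
    out.update(
        features=names,
        trace=trace,
        metrics=metrics,
        dummy=dummy_classify(labels, folds=folds, seed=seed),
    )
    if pool.bnp is not None:
        out["bnp"] = bnp_only_model(
            pool.bnp, labels=labels, method=method, folds=folds, seed=seed
        )
    return out
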