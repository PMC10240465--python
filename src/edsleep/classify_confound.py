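"""Stratified 5-fold kNN classification and GLM confound control.

The classifier is k-nearest neighbours on the selected features, validated
with stratified k-fold cross-validation; hyperparameters (neighbour count,
metric, vote weighting) are chosen per training fold by an inner stratified
3-fold grid search. Standardization and median imputation are fit on each
training fold only, so no test subject leaks into its own fold's
preprocessing.

The confound analysis refits, on each held-out fold, binomial generalized
linear models for the group label under three scenarios — ML score only,
confounds (age, BMI, gender) only, and both — and aggregates McFadden
pseudo-R² (1 − deviance/null deviance) and Wald p-values across folds. This
compares how much the trained prediction itself explains the outcome versus
what the confounds alone explain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .io_preprocess import ConfigurationError, DataError

__all__ = [
    "CvPlan",
    "CvReport",
    "ConfoundReport",
    "DEFAULT_GRID",
    "stratified_kfold",
    "knn_fit_predict",
    "grid_search",
    "cross_validate",
    "evaluate",
    "glm_logistic",
    "pseudo_r2",
    "confound_analysis",
]

POSITIVE = "high"

DEFAULT_GRID = {
    "k_neighbors": tuple(range(1, 16, 2)),
    "metric": ("euclidean", "manhattan"),
    "weighting": ("uniform", "distance"),
}


@dataclass
class CvPlan:
    k: int
    fold_of: pd.Series  # subject -> fold id
    seed: int

    def test_index(self, fold: int):
        return self.fold_of.index[self.fold_of == fold]

    def train_index(self, fold: int):
        return self.fold_of.index[self.fold_of != fold]


@dataclass
class CvReport:
    scores: pd.Series  # out-of-fold P(high)
    predicted: pd.Series  # out-of-fold labels
    truth: pd.Series
    fold_of: pd.Series
    metrics: dict
    confusion: dict  # tp, fp, tn, fn
    hyperparams: list = field(default_factory=list)  # per fold


@dataclass
class ConfoundReport:
    pseudo_r2: dict  # scenario -> mean over folds
    p_values: dict  # scenario -> {variable: mean p}
    variant: str
    per_fold: list = field(default_factory=list)
    excluded_folds: list = field(default_factory=list)
    ridge_escalated: bool = False


# ---------------------------------------------------------------------------
# cross-validation plumbing


def stratified_kfold(labels: pd.Series, k: int = 5, seed: int = 0) -> CvPlan:
    """Deterministic stratified fold assignment; per-fold class counts differ
    by at most 1 from perfect stratification."""
    from sklearn.model_selection import StratifiedKFold

    labels = pd.Series(labels)
    if k < 2:
        raise ConfigurationError("need at least 2 folds")
    counts = labels.value_counts()
    if (counts < k).any():
        raise ConfigurationError(
            f"smallest class ({counts.min()}) has fewer members than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = pd.Series(index=labels.index, dtype=int)
    for fold, (_, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_of.iloc[test] = fold
    return CvPlan(k=k, fold_of=fold_of, seed=seed)


def _fold_transform(X_train: np.ndarray):
    """Median imputation + standardization fit on the training fold only."""
    median = np.nanmedian(X_train, axis=0)
    median = np.where(np.isnan(median), 0.0, median)
    filled = np.where(np.isnan(X_train), median, X_train)
    mean = filled.mean(axis=0)
    sd = filled.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)

    def apply(X):
        filled = np.where(np.isnan(X), median, X)
        return (filled - mean) / sd

    return apply


def knn_fit_predict(X_train, y_train, X_test, hyperparams: dict):
    """Fit kNN and score the test points.

    Score = (weighted) fraction of the k nearest training neighbours labelled
    positive; predicted label = score >= 0.5 (ties toward positive).
    """
    from sklearn.neighbors import KNeighborsClassifier

    k = int(hyperparams["k_neighbors"])
    if k > len(y_train):
        raise ConfigurationError(
            f"k_neighbors={k} exceeds training size {len(y_train)}"
        )
    clf = KNeighborsClassifier(
        n_neighbors=k,
        metric=hyperparams.get("metric", "euclidean"),
        weights=hyperparams.get("weighting", "uniform"),
    )
    y = np.asarray(y_train)
    clf.fit(np.asarray(X_train), y == POSITIVE)
    proba = clf.predict_proba(np.asarray(X_test))
    pos_col = list(clf.classes_).index(True)
    scores = proba[:, pos_col]
    labels = np.where(scores >= 0.5, POSITIVE, "low")
    return scores, labels


def grid_search(
    X_train,
    y_train,
    grid: dict = None,
    seed: int = 0,
    inner_k: int = 3,
) -> dict:
    """Inner stratified cross-validated grid search on a training fold.

    Best mean accuracy wins; ties broken by smaller neighbour count, then grid
    order. Returns the winning hyperparameter dict (with its inner score under
    ``"inner_accuracy"``).
    """
    from sklearn.model_selection import StratifiedKFold

    grid = grid or DEFAULT_GRID
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    combos = [
        dict(zip(grid.keys(), values)) for values in product(*grid.values())
    ]
    max_k = max(int(c["k_neighbors"]) for c in combos)
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = None
    for order, combo in enumerate(combos):
        accs = []
        for tr, te in splits:
            if int(combo["k_neighbors"]) > len(tr):
                accs = None
                break
            transform = _fold_transform(X[tr])
            _, labels = knn_fit_predict(
                transform(X[tr]), y[tr], transform(X[te]), combo
            )
            accs.append(float(np.mean(labels == y[te])))
        if accs is None:
            continue
        score = float(np.mean(accs))
        key = (-score, int(combo["k_neighbors"]), order)
        if best is None or key < best[0]:
            best = (key, dict(combo, inner_accuracy=score))
    if best is None:
        raise ConfigurationError("no feasible hyperparameter combination")
    return best[1]


def cross_validate(
    X: pd.DataFrame,
    labels: pd.Series,
    k: int = 5,
    seed: int = 0,
    grid: dict = None,
    search_mode: str = "nested",
) -> CvReport:
    """Out-of-fold kNN predictions under stratified k-fold CV.

    ``search_mode="nested"`` (default) re-runs the hyperparameter grid search
    inside every training fold; ``"global"`` searches once on the full data
    (the optimistic variant, exposed for comparison).
    """
    plan = stratified_kfold(labels, k=k, seed=seed)
    scores = pd.Series(index=X.index, dtype=float)
    predicted = pd.Series(index=X.index, dtype=object)
    hyper = []
    global_hp = None
    if search_mode == "global":
        transform = _fold_transform(X.to_numpy(dtype=float))
        global_hp = grid_search(
            transform(X.to_numpy(dtype=float)), labels.to_numpy(), grid, seed=seed
        )
    for fold in range(k):
        tr = plan.train_index(fold)
        te = plan.test_index(fold)
        X_tr = X.loc[tr].to_numpy(dtype=float)
        X_te = X.loc[te].to_numpy(dtype=float)
        transform = _fold_transform(X_tr)
        hp = global_hp or grid_search(
            transform(X_tr), labels.loc[tr].to_numpy(), grid, seed=seed + fold
        )
        hyper.append(hp)
        s, lab = knn_fit_predict(
            transform(X_tr), labels.loc[tr].to_numpy(), transform(X_te), hp
        )
        scores.loc[te] = s
        predicted.loc[te] = lab
    report = evaluate(labels, scores, predicted, plan.fold_of)
    report.hyperparams = hyper
    return report


def _rank_auc(truth_pos: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the rank statistic (Mann–Whitney with ties averaged)."""
    ranks = pd.Series(scores).rank(method="average").to_numpy()
    n_pos = int(truth_pos.sum())
    n_neg = len(truth_pos) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC needs both classes in the truth")
    u = ranks[truth_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate(truth, scores, predicted, fold_of) -> CvReport:
    """Pooled out-of-fold confusion matrix and summary metrics."""
    truth = pd.Series(truth)
    scores = pd.Series(scores).reindex(truth.index)
    predicted = pd.Series(predicted).reindex(truth.index)
    if scores.isna().any() or predicted.isna().any():
        raise DataError("every subject must be predicted exactly once")
    t = (truth == POSITIVE).to_numpy()
    p = (predicted == POSITIVE).to_numpy()
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))
    metrics = {
        "accuracy": (tp + tn) / len(t),
        "precision": tp / (tp + fp) if tp + fp else np.nan,
        "recall": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "auc_roc": _rank_auc(t, scores.to_numpy(dtype=float)),
    }
    return CvReport(
        scores=scores,
        predicted=predicted,
        truth=truth,
        fold_of=pd.Series(fold_of).reindex(truth.index),
        metrics=metrics,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )


# ---------------------------------------------------------------------------
# GLM confound analysis


def glm_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-6,
    max_iter: int = 200,
    tol: float = 1e-12,
):
    """Binomial GLM (logit link) by iteratively reweighted least squares with
    a small ridge penalty on the non-intercept coefficients.

    Returns a dict with coefficients, deviance, Wald p-values, and flags. If
    the fit diverges (complete separation in a small fold) the ridge is
    escalated to 1e-2 and the fit is flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    design = np.column_stack([np.ones(n), X])
    penalty = np.diag([0.0] + [ridge] * d)

    def fit(lam_matrix):
        beta = np.zeros(d + 1)
        for _ in range(max_iter):
            eta = np.clip(design @ beta, -30, 30)
            mu = expit(eta)
            w = np.maximum(mu * (1 - mu), 1e-10)
            z = eta + (y - mu) / w
            wx = design * w[:, None]
            lhs = design.T @ wx + lam_matrix
            rhs = design.T @ (w * z)
            new = np.linalg.solve(lhs, rhs)
            step = np.max(np.abs(new - beta))
            beta = new
            if step < tol:
                return beta, True
        return beta, False

    beta, converged = fit(penalty)
    escalated = False
    if not converged or np.max(np.abs(beta)) > 20:
        escalated = True
        beta, converged = fit(np.diag([0.0] + [1e-2] * d))

    eta = np.clip(design @ beta, -30, 30)
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    deviance = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    w = np.maximum(mu * (1 - mu), 1e-10)
    info = design.T @ (design * w[:, None]) + (
        np.diag([0.0] + [1e-2] * d) if escalated else penalty
    )
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pvals = 2.0 * (1.0 - norm.cdf(np.abs(zstat)))
    return {
        "beta": beta,
        "deviance": deviance,
        "p": pvals,
        "converged": converged,
        "ridge_escalated": escalated,
    }


def pseudo_r2(deviance: float, null_deviance: float, variant: str = "mcfadden",
              n: int = None) -> float:
    """Pseudo-R² of a binomial GLM fit relative to the intercept-only model."""
    if null_deviance <= 0:
        return 0.0
    if variant == "mcfadden":
        return max(0.0, 1.0 - deviance / null_deviance)
    if variant == "cox_snell":
        if n is None:
            raise ValueError("cox_snell needs the sample size")
        return max(0.0, 1.0 - np.exp((deviance - null_deviance) / n))
    if variant == "nagelkerke":
        if n is None:
            raise ValueError("nagelkerke needs the sample size")
        cs = 1.0 - np.exp((deviance - null_deviance) / n)
        denom = 1.0 - np.exp(-null_deviance / n)
        return max(0.0, cs / denom) if denom > 0 else 0.0
    raise ValueError(f"unknown pseudo-R² variant {variant!r}")


SCENARIOS = ("ml_only", "confounds_only", "ml_plus_confounds")
CONFOUND_VARS = ("age", "bmi", "gender")


def confound_analysis(
    report: CvReport,
    covariates: pd.DataFrame,
    variant: str = "mcfadden",
    ridge: float = 1e-6,
) -> ConfoundReport:
    """Three-scenario GLM analysis on the out-of-fold predictions.

    ``covariates`` must contain ``age``, ``bmi`` and ``gender`` (0/1,
    female = 1) indexed like the CV report. Per fold the group label of the
    held-out subjects is regressed on (a) the ML score, (b) the confounds,
    (c) both; fold-mean pseudo-R² per scenario and fold-mean Wald p-values per
    coefficient are reported. Single-class test folds are excluded and listed.
    """
    covariates = covariates.loc[report.truth.index]
    y_all = (report.truth == POSITIVE).astype(float)
    folds = sorted(report.fold_of.unique())
    per_fold = []
    excluded = []
    escalated = False
    for fold in folds:
        idx = report.fold_of[report.fold_of == fold].index
        y = y_all.loc[idx].to_numpy()
        if y.min() == y.max():
            excluded.append(int(fold))
            continue
        ml = report.scores.loc[idx].to_numpy()[:, None]
        conf = covariates.loc[idx, list(CONFOUND_VARS)].to_numpy(dtype=float)
        designs = {
            "ml_only": (ml, ("ml_prediction",)),
            "confounds_only": (conf, CONFOUND_VARS),
            "ml_plus_confounds": (
                np.column_stack([conf, ml]),
                CONFOUND_VARS + ("ml_prediction",),
            ),
        }
        null_fit = glm_logistic(np.empty((len(y), 0)), y, ridge=ridge)
        entry = {"fold": int(fold), "n": len(y), "null_deviance": null_fit["deviance"]}
        for scen, (X, names) in designs.items():
            fit = glm_logistic(X, y, ridge=ridge)
            escalated |= fit["ridge_escalated"]
            entry[scen] = {
                "deviance": fit["deviance"],
                "pseudo_r2": pseudo_r2(
                    fit["deviance"], null_fit["deviance"], variant, n=len(y)
                ),
                "p": dict(zip(names, fit["p"][1:])),
                "ridge_escalated": fit["ridge_escalated"],
            }
        per_fold.append(entry)
    if not per_fold:
        raise DataError("all test folds were single-class; nothing to analyse")
    mean_r2 = {
        scen: float(np.mean([f[scen]["pseudo_r2"] for f in per_fold]))
        for scen in SCENARIOS
    }
    mean_p = {}
    for scen in SCENARIOS:
        names = per_fold[0][scen]["p"].keys()
        mean_p[scen] = {
            name: float(np.mean([f[scen]["p"][name] for f in per_fold]))
            for name in names
        }
    return ConfoundReport(
        pseudo_r2=mean_r2,
        p_values=mean_p,
        variant=variant,
        per_fold=per_fold,
        excluded_folds=excluded,
        ridge_escalated=escalated,
    )
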