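"""The four classifier families and their hyperparameter grids.

Families: support vector machines (linear / polynomial / Gaussian kernels,
box constraint 1..50), Gaussian naive Bayes (no tuning), ensembles (bagged
random forest and AdaBoost with depth-1 stumps, 100 learners) and logistic
regression (stepwise or plain GLM).  Responder is the positive class; scores
are posterior probabilities (SVM margins are Platt-calibrated) so thresholds
and AUCs are comparable across families.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .selection import NormalizationParams


def effective_folds(y: np.ndarray, cv_folds: int) -> int:
    """Stratified folds cannot outnumber the smaller class."""
    counts = np.bincount(np.asarray(y).astype(int), minlength=2)
    return max(2, min(cv_folds, int(counts[counts > 0].min())))

__all__ = [
    "ClassifierSpec",
    "TrainedModel",
    "family_grid",
    "train",
    "stepwise_logistic",
    "predict",
    "grid_search",
    "BOX_CONSTRAINT_GRID",
]

log = logging.getLogger(__name__)

FAMILIES = ("svm", "naive_bayes", "ensemble", "logistic")

#: discretization of the box-constraint range 1..50
BOX_CONSTRAINT_GRID = (1, 2, 5, 8, 10, 15, 20, 30, 40, 50)


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family with resolved hyperparameters.

    ``params`` keys by family:
      svm      — kernel in {linear, polynomial, gaussian}, box_constraint
      ensemble — aggregation in {bagging_random_forest, adaboost}, n_learners
      logistic — mode in {stepwise, glm}, p_enter, p_remove
      naive_bayes — none
    """

    family: str
    params: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def describe(self) -> str:
        inner = ", ".join(f"{k}={v}" for k, v in self.params)
        return f"{self.family}({inner})"

    @staticmethod
    def make(family: str, **params: object) -> "ClassifierSpec":
        return ClassifierSpec(family=family, params=tuple(sorted(params.items())))


#: complexity order used for tie-breaking toward simpler models
_KERNEL_ORDER = {"linear": 0, "polynomial": 1, "gaussian": 2}


def family_grid(family: str) -> list[ClassifierSpec]:
    """The hyperparameter grid searched for one family, simplest first."""
    if family == "svm":
        return [
            ClassifierSpec.make("svm", kernel=k, box_constraint=c)
            for k in ("linear", "polynomial", "gaussian")
            for c in BOX_CONSTRAINT_GRID
        ]
    if family == "naive_bayes":
        return [ClassifierSpec.make("naive_bayes")]
    if family == "ensemble":
        return [
            ClassifierSpec.make("ensemble", aggregation=a, n_learners=100)
            for a in ("bagging_random_forest", "adaboost")
        ]
    if family == "logistic":
        grid = [ClassifierSpec.make("logistic", mode="glm")]
        grid += [
            ClassifierSpec.make("logistic", mode="stepwise", p_enter=pe, p_remove=pr)
            for pe in (0.05, 0.1)
            for pr in (0.2, 0.3)
        ]
        return grid
    raise ValueError(f"unknown classifier family {family!r}")


@dataclass
class TrainedModel:
    """A fitted classifier bound to its feature subset and normalization."""

    spec: ClassifierSpec
    selected_features: list[str]
    estimator: object
    normalization: NormalizationParams | None = None
    decision_threshold: float = 0.5
    construction_performance: object = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.selected_features)


def _median_heuristic_gamma(x: np.ndarray) -> float:
    """Gaussian kernel scale 1 / (2 m^2) with m the median pairwise distance."""
    n = x.shape[0]
    if n < 2:
        return 1.0
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    med = float(np.sqrt(np.median(d2[np.triu_indices(n, k=1)])))
    return 1.0 / (2.0 * med * med) if med > 0 else 1.0


def _build_estimator(spec: ClassifierSpec, x: np.ndarray, seed: int):
    p = spec.param_dict
    if spec.family == "svm":
        kernel = {"linear": "linear", "polynomial": "poly", "gaussian": "rbf"}[p["kernel"]]
        gamma = _median_heuristic_gamma(x) if kernel == "rbf" else "scale"
        return SVC(
            kernel=kernel, C=float(p["box_constraint"]), degree=3, coef0=1.0,
            gamma=gamma, probability=True, random_state=seed,
        )
    if spec.family == "naive_bayes":
        return GaussianNB()
    if spec.family == "ensemble":
        if p["aggregation"] == "bagging_random_forest":
            return RandomForestClassifier(
                n_estimators=int(p["n_learners"]), max_features="sqrt",
                bootstrap=True, random_state=seed,
            )
        return AdaBoostClassifier(n_estimators=int(p["n_learners"]), learning_rate=1.0,
                                  random_state=seed)
    if spec.family == "logistic":
        # plain GLM; the stepwise variant is handled by stepwise_logistic
        return LogisticRegression(penalty=None, max_iter=2000, solver="lbfgs")
    raise ValueError(f"unknown classifier family {spec.family!r}")


def train(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    labels: np.ndarray,
    features: Sequence[str],
    normalization: NormalizationParams | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit one classifier on (normalized) construction rows."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training data")
    features = list(features)
    x = table[features].to_numpy(dtype=float)
    if spec.family == "logistic" and spec.param_dict.get("mode") == "stepwise":
        return stepwise_logistic(
            table, y, features,
            p_enter=float(spec.param_dict.get("p_enter", 0.05)),
            p_remove=float(spec.param_dict.get("p_remove", 0.2)),
            normalization=normalization,
        )
    if spec.family == "naive_bayes":
        for j, f in enumerate(features):
            if x[:, j].std() == 0:
                log.warning("naive Bayes: feature %s has zero variance; variance floored", f)
    est = _build_estimator(spec, x, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(x, y)
    return TrainedModel(spec=spec, selected_features=features, estimator=est,
                        normalization=normalization)


def _irls_logistic(x: np.ndarray, y: np.ndarray, max_iter: int = 50):
    """Unpenalized logistic fit by iteratively reweighted least squares.

    Returns (params, deviance, stable) where params = [intercept, coefs].
    ``stable`` is False under (quasi-)perfect separation, detected as
    divergent coefficients or non-convergence.
    """
    n = len(y)
    design = np.column_stack([np.ones(n), x]) if x.shape[1] else np.ones((n, 1))
    beta = np.zeros(design.shape[1])
    stable = True
    for _ in range(max_iter):
        eta = np.clip(design @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        wd = design * w[:, None]
        try:
            beta_new = np.linalg.solve(design.T @ wd, wd.T @ z)
        except np.linalg.LinAlgError:
            stable = False
            break
        if not np.all(np.isfinite(beta_new)):
            stable = False
            break
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    else:
        stable = False
    if np.abs(beta).max() > 1e4:
        stable = False
    eta = np.clip(design @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    deviance = -2.0 * float((y * np.log(mu) + (1 - y) * np.log(1 - mu)).sum())
    return beta, deviance, stable


class _GLMLogistic:
    """Unpenalized logistic fit (IRLS) with a ridge fallback under separation.

    Exposes the sklearn predict / predict_proba surface used by the rest of
    the pipeline.  ``terms`` is the retained feature subset (stepwise) or all
    features (plain GLM).
    """

    def __init__(self, terms: list[str], all_features: list[str]):
        self.terms = terms
        self.all_features = all_features
        self._params: np.ndarray | None = None  # intercept + term coefficients
        self.used_ridge_fallback = False

    def fit(self, x_terms: np.ndarray, y: np.ndarray) -> "_GLMLogistic":
        params, _, stable = _irls_logistic(x_terms, y)
        if stable:
            self._params = params
        else:
            # (quasi-)perfect separation: ridge-regularized fallback, lambda = 1e-6
            log.warning("logistic fit unstable (separation?); using ridge fallback")
            self.used_ridge_fallback = True
            if x_terms.shape[1] == 0:
                p1 = max(min(y.mean(), 1 - 1e-9), 1e-9)
                self._params = np.array([np.log(p1 / (1 - p1))])
            else:
                ridge = LogisticRegression(C=1e6, max_iter=5000)
                ridge.fit(x_terms, y)
                self._params = np.concatenate([ridge.intercept_, ridge.coef_[0]])
        return self

    def _proba1(self, x_terms: np.ndarray) -> np.ndarray:
        eta = self._params[0] + (
            x_terms @ self._params[1:] if x_terms.shape[1] else 0.0
        )
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p1 = self._proba1(x)
        return np.column_stack([1 - p1, p1])

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self._proba1(x) >= 0.5).astype(int)


def _deviance(y: np.ndarray, x: np.ndarray) -> float:
    return _irls_logistic(x, y)[1]


def stepwise_logistic(
    table: pd.DataFrame,
    labels: np.ndarray,
    features: Sequence[str],
    p_enter: float = 0.05,
    p_remove: float = 0.2,
    normalization: NormalizationParams | None = None,
) -> TrainedModel:
    """Forward-backward stepwise logistic regression from the intercept-only model.

    At each round the candidate whose deviance-based F-approximation gives
    the smallest p-value below ``p_enter`` is added, then any retained term
    with p above ``p_remove`` is removed; the loop stops when neither move
    changes the model.
    """
    from scipy.stats import f as f_dist

    if not p_enter < p_remove:
        raise ValueError("p_enter must be smaller than p_remove")
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training data")
    features = list(features)
    n = len(y)

    def term_p(dev_small: float, dev_big: float, n_terms_big: int) -> float:
        # F-approximation of the single-term deviance test
        df2 = max(n - (n_terms_big + 1), 1)
        fstat = max(dev_small - dev_big, 0.0) / max(dev_big / df2, 1e-12)
        return float(f_dist.sf(fstat, 1, df2))

    current: list[str] = []
    dev_cur = _deviance(y, np.empty((n, 0)))
    changed = True
    while changed:
        changed = False
        # forward step
        candidates = [f for f in features if f not in current]
        best_p, best_f, best_dev = 1.0, None, dev_cur
        for f in candidates:
            dev = _deviance(y, table[current + [f]].to_numpy(dtype=float))
            p = term_p(dev_cur, dev, len(current) + 1)
            if p < best_p or (p == best_p and best_f is not None and f < best_f):
                best_p, best_f, best_dev = p, f, dev
        if best_f is not None and best_p < p_enter:
            current.append(best_f)
            dev_cur = best_dev
            changed = True
        # backward step
        removed = True
        while removed and current:
            removed = False
            worst_p, worst_f = -1.0, None
            for f in current:
                others = [g for g in current if g != f]
                dev_wo = _deviance(y, table[others].to_numpy(dtype=float))
                p = term_p(dev_wo, dev_cur, len(current))
                if p > worst_p:
                    worst_p, worst_f = p, f
            if worst_f is not None and worst_p > p_remove:
                current.remove(worst_f)
                dev_cur = _deviance(y, table[current].to_numpy(dtype=float))
                removed = True
                changed = True

    est = _GLMLogistic(terms=current, all_features=features)
    est.fit(table[current].to_numpy(dtype=float), y)
    spec = ClassifierSpec.make("logistic", mode="stepwise", p_enter=p_enter, p_remove=p_remove)
    model = TrainedModel(spec=spec, selected_features=features, estimator=est,
                         normalization=normalization)
    model.diagnostics["stepwise_terms"] = list(current)
    return model


def predict(model: TrainedModel, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (1 = responder) and posterior scores for rows of ``table``."""
    missing = [f for f in model.selected_features if f not in table.columns]
    if missing:
        raise KeyError(f"feature vector missing model features: {missing}")
    est = model.estimator
    if isinstance(est, _GLMLogistic):
        x = table[est.terms].to_numpy(dtype=float)
    else:
        x = table[model.selected_features].to_numpy(dtype=float)
    scores = est.predict_proba(x)[:, 1]
    labels = (scores >= model.decision_threshold).astype(int)
    return labels, scores


def grid_search(
    family: str,
    table: pd.DataFrame,
    labels: np.ndarray,
    features: Sequence[str],
    cv_folds: int = 6,
    seed: int = 0,
    normalization: NormalizationParams | None = None,
) -> TrainedModel:
    """Best model of one family by mean stratified k-fold CV accuracy.

    Ties go to the simpler candidate (the grid is ordered simplest first and
    improvement must be strict).  The returned model is refitted on all rows;
    ``diagnostics['eligible']`` is False when no candidate beat 0.5 CV
    accuracy, flagging the family for exclusion downstream.
    """
    y = np.asarray(labels).astype(int)
    features = list(features)
    grid = family_grid(family)
    if family == "svm":
        grid = sorted(
            grid,
            key=lambda s: (_KERNEL_ORDER[s.param_dict["kernel"]], s.param_dict["box_constraint"]),
        )
    skf = StratifiedKFold(n_splits=effective_folds(y, cv_folds), shuffle=True,
                          random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    x = table[features].to_numpy(dtype=float)
    best_spec, best_acc = None, -np.inf
    for spec in grid:
        stepwise = spec.family == "logistic" and spec.param_dict.get("mode") == "stepwise"
        accs = []
        for tr, te in folds:
            if stepwise:
                model = train(spec, table.iloc[tr], y[tr], features, seed=seed)
                pred, _ = predict(model, table.iloc[te])
            else:
                # hard-label CV: skip probability calibration for speed
                est = _build_estimator(spec, x[tr], seed)
                if isinstance(est, SVC):
                    est.probability = False
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(x[tr], y[tr])
                pred = est.predict(x[te])
            accs.append(float((pred == y[te]).mean()))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_acc, best_spec = acc, spec
    model = train(best_spec, table, y, features, normalization=normalization, seed=seed)
    model.diagnostics["cv_accuracy"] = best_acc
    model.diagnostics["eligible"] = bool(best_acc > 0.5)
    if not model.diagnostics["eligible"]:
        log.warning("family %s: best CV accuracy %.3f <= 0.5; flagged ineligible", family, best_acc)
    return model
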