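"""Feature normalization and the three feature-selection procedures.

All selection runs on construction-set rows only.  Min-max scaling is
anchored on the construction set and applied, unclipped, to validation rows.
The three selectors are

* **ranking** — per-feature Mann-Whitney AUC with correlation pruning,
  stability-resampled 100 times; survivors ordered by construction AUC and
  cut at the overfitting point;
* **affinity propagation** — exemplar features from message passing over a
  feature-similarity matrix;
* **mRMR (MIQ)** — greedy mutual-information-quotient ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "NormalizationParams",
    "RankingConfig",
    "SelectionResult",
    "fit_minmax",
    "apply_minmax",
    "feature_auc",
    "correlation_prune",
    "stability_ranking",
    "overfitting_point",
    "affinity_propagation_select",
    "mrmr_rank",
]

log = logging.getLogger(__name__)


@dataclass
class NormalizationParams:
    """Per-feature (min, max) computed on construction rows."""

    minima: pd.Series
    maxima: pd.Series

    @property
    def features(self) -> list[str]:
        return list(self.minima.index)


def fit_minmax(table: pd.DataFrame, features: Sequence[str]) -> NormalizationParams:
    """Min and max of each feature over construction rows."""
    if len(table) == 0:
        raise ValueError("construction rows are empty")
    sub = table[list(features)]
    return NormalizationParams(minima=sub.min(axis=0), maxima=sub.max(axis=0))


def apply_minmax(params: NormalizationParams, table: pd.DataFrame) -> pd.DataFrame:
    """x' = (x - min) / (max - min); constant features map to 0.

    Values are NOT clipped: rows outside the construction range (e.g.
    validation cases) may leave [0, 1], which is logged.
    """
    out = table.copy()
    span = params.maxima - params.minima
    for feat in params.features:
        if span[feat] == 0:
            out[feat] = 0.0
        else:
            out[feat] = (table[feat] - params.minima[feat]) / span[feat]
    scaled = out[params.features].to_numpy(dtype=float)
    n_outside = int(((scaled < 0) | (scaled > 1)).any(axis=1).sum())
    if n_outside:
        log.info("min-max scaling: %d rows have values outside [0, 1]", n_outside)
    return out


def feature_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Direction-folded Mann-Whitney AUC, in [0.5, 1].

    Tie-corrected via midranks; folded to max(a, 1-a) so a feature that
    discriminates in either direction scores above 0.5.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(values)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return float(max(auc, 1.0 - auc))


def _unfolded_auc_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise unfolded Mann-Whitney AUC of a feature matrix (fast path)."""
    n, p = x.shape
    n1 = int(y.sum())
    n0 = n - n1
    ranks = np.empty_like(x)
    for j in range(p):
        ranks[:, j] = rankdata(x[:, j])
    return (ranks[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * n0)


def correlation_prune(
    table: pd.DataFrame,
    aucs: dict[str, float] | pd.Series,
    threshold: float = 0.85,
) -> list[str]:
    """Iteratively drop the lower-AUC member of the most-correlated pair.

    Among all pairs with \\|Pearson r\\| >= threshold the currently
    most-correlated pair is resolved first; AUC ties drop the
    lexicographically later name.  Returns retained feature names in the
    table's column order.
    """
    names = list(table.columns)
    if len(names) < 2:
        return names
    aucs = pd.Series(aucs)
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(table.to_numpy(dtype=float), rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)  # constant features correlate with nothing
    np.fill_diagonal(corr, 0.0)
    alive = np.ones(len(names), dtype=bool)
    while True:
        masked = np.where(np.outer(alive, alive), corr, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] < threshold:
            break
        a_i, a_j = aucs[names[i]], aucs[names[j]]
        if a_i < a_j:
            drop = i
        elif a_j < a_i:
            drop = j
        else:
            drop = max(i, j, key=lambda k: names[k])  # tie: later name removed
        alive[drop] = False
    return [n for n, keep in zip(names, alive) if keep]


@dataclass(frozen=True)
class RankingConfig:
    """Knobs of the stability-resampled AUC ranking."""

    correlation_threshold: float = 0.85
    resamples: int = 100
    resample_fraction: float = 0.70
    min_selections: int = 70
    cv_folds: int = 6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation threshold must be in (0, 1]")
        if self.min_selections > self.resamples:
            raise ValueError("min_selections cannot exceed resamples")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class SelectionResult:
    """Outcome of one feature-selection method."""

    method: str
    ordered_features: list[str]
    per_feature_auc: dict[str, float] = field(default_factory=dict)
    selection_counts: dict[str, int] = field(default_factory=dict)
    cv_curves: list[tuple[int, float, float]] = field(default_factory=list)
    chosen_size: int = 0

    @property
    def selected(self) -> list[str]:
        k = self.chosen_size or len(self.ordered_features)
        return self.ordered_features[:k]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "ordered_features": self.ordered_features,
            "per_feature_auc": self.per_feature_auc,
            "selection_counts": self.selection_counts,
            "cv_curves": [list(c) for c in self.cv_curves],
            "chosen_size": self.chosen_size,
        }


def _stratified_subsample(y: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Indices of a label-stratified subsample (without replacement)."""
    idx = []
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        k = max(1, int(round(fraction * len(members))))
        idx.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(idx))


def stability_ranking(
    table: pd.DataFrame,
    labels: np.ndarray,
    cfg: RankingConfig = RankingConfig(),
) -> SelectionResult:
    """Stability-resampled AUC ranking with correlation pruning.

    Each of ``cfg.resamples`` label-stratified 70% resamples computes
    per-feature AUCs and runs correlation pruning; features surviving at
    least ``cfg.min_selections`` resamples are kept and ordered by their AUC
    on the full construction set, descending (ties broken by name).
    """
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(cfg.rng_seed)
    names = list(table.columns)
    x = table.to_numpy(dtype=float)
    counts = dict.fromkeys(names, 0)
    for _ in range(cfg.resamples):
        idx = _stratified_subsample(y, cfg.resample_fraction, rng)
        sub = table.iloc[idx]
        aucs_arr = _unfolded_auc_matrix(x[idx], y[idx])
        aucs = pd.Series(np.maximum(aucs_arr, 1 - aucs_arr), index=names)
        for feat in correlation_prune(sub, aucs, cfg.correlation_threshold):
            counts[feat] += 1
    survivors = [n for n in names if counts[n] >= cfg.min_selections]
    if not survivors:
        raise ValueError(
            f"no feature was selected in >= {cfg.min_selections}/{cfg.resamples} resamples; "
            "consider relaxing min_selections or the correlation threshold"
        )
    full_arr = _unfolded_auc_matrix(x, y)
    full_auc = {n: float(max(a, 1 - a)) for n, a in zip(names, full_arr)}
    ordered = sorted(survivors, key=lambda n: (-full_auc[n], n))
    return SelectionResult(
        method="ranking",
        ordered_features=ordered,
        per_feature_auc={n: full_auc[n] for n in ordered},
        selection_counts=counts,
        chosen_size=len(ordered),
    )


def overfitting_point(
    ordered: Sequence[str],
    classifier_factory: Callable[[], object],
    train_table: pd.DataFrame,
    train_labels: np.ndarray,
    test_table: pd.DataFrame,
    test_labels: np.ndarray,
    cv_folds: int = 6,
    seed: int = 0,
) -> tuple[int, list[tuple[int, float, float]]]:
    """Feature-count cutoff at the point of overfitting.

    For each k, a fresh classifier on the top-k features yields (a) the mean
    accuracy over the 6 cross-validation sub-training sets of the
    construction-train split and (b) the accuracy on the held-out
    construction-test split.  The chosen size is the largest k whose test
    accuracy is non-decreasing up to k while at k+1 the train accuracy keeps
    rising (non-strictly) and the test accuracy strictly falls; if that
    pattern never occurs, the smallest k maximizing test accuracy is used.
    """
    from sklearn.base import clone
    from sklearn.model_selection import StratifiedKFold

    if not ordered:
        raise ValueError("ordered feature list is empty")
    y_tr = np.asarray(train_labels).astype(int)
    y_te = np.asarray(test_labels).astype(int)
    curves: list[tuple[int, float, float]] = []
    counts = np.bincount(y_tr, minlength=2)
    cv_folds = max(2, min(cv_folds, int(counts[counts > 0].min())))
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y_tr)), y_tr))
    for k in range(1, len(ordered) + 1):
        feats = list(ordered[:k])
        x_tr = train_table[feats].to_numpy(dtype=float)
        x_te = test_table[feats].to_numpy(dtype=float)
        accs = []
        for tr_idx, _ in folds:
            clf = clone(classifier_factory())
            clf.fit(x_tr[tr_idx], y_tr[tr_idx])
            accs.append(float((clf.predict(x_tr[tr_idx]) == y_tr[tr_idx]).mean()))
        clf = clone(classifier_factory())
        clf.fit(x_tr, y_tr)
        test_acc = float((clf.predict(x_te) == y_te).mean())
        curves.append((k, float(np.mean(accs)), test_acc))

    train = [c[1] for c in curves]
    test = [c[2] for c in curves]
    return choose_overfitting_size(train, test), curves


def choose_overfitting_size(train: Sequence[float], test: Sequence[float]) -> int:
    """The overfitting-point rule on accuracy curves indexed by subset size.

    Chosen size = the largest k whose test accuracy is non-decreasing up to k
    while at k+1 train accuracy keeps rising (non-strictly) and test accuracy
    strictly falls; if the pattern never occurs, the smallest k maximizing
    test accuracy.
    """
    for k in range(len(test) - 1, 0, -1):  # k is the 1-based subset size
        i = k - 1
        nondecr = all(test[j] >= test[j - 1] for j in range(1, i + 1))
        if nondecr and train[i + 1] >= train[i] and test[i + 1] < test[i]:
            return k
    return int(np.argmax(test)) + 1  # argmax returns the smallest tie


def affinity_propagation_select(
    table: pd.DataFrame,
    labels: np.ndarray | None = None,
    damping: float = 0.7,
    max_iter: int = 500,
    convergence_iter: int = 30,
    preference: float | None = None,
) -> SelectionResult:
    """Exemplar features by affinity-propagation message passing.

    Similarity is the negative squared Euclidean distance between
    standardized feature columns; the shared preference defaults to the
    median off-diagonal similarity, so the cluster count is not set a priori.
    Responsibilities and availabilities are damped at ``damping``; the run
    stops when the exemplar set is stable for ``convergence_iter`` sweeps.
    """
    names = list(table.columns)
    if len(names) < 2:
        raise ValueError("need at least 2 features")
    x = table.to_numpy(dtype=float)

    # exactly identical columns carry zero distance and break the symmetry of
    # message passing; collapse each identical group onto its first member
    unique_cols: list[int] = []
    for j in range(x.shape[1]):
        if not any(np.array_equal(x[:, j], x[:, k]) for k in unique_cols):
            unique_cols.append(j)
    if len(unique_cols) == 1:
        only = names[unique_cols[0]]
        return SelectionResult(method="affinity_propagation", ordered_features=[only],
                               chosen_size=1)
    if len(unique_cols) < len(names):
        sub = table.iloc[:, unique_cols]
        result = affinity_propagation_select(sub, labels, damping, max_iter,
                                             convergence_iter, preference)
        return result

    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    diff = z.T[:, None, :] - z.T[None, :, :]
    s = -np.einsum("ijk,ijk->ij", diff, diff)
    p = len(names)
    off = s[~np.eye(p, dtype=bool)]
    pref = float(np.median(off)) if preference is None else preference
    np.fill_diagonal(s, pref)

    r = np.zeros((p, p))
    a = np.zeros((p, p))
    stable = 0
    exemplars: np.ndarray = np.array([], dtype=int)
    converged = False
    for _ in range(max_iter):
        # responsibilities
        as_ = a + s
        idx_max = np.argmax(as_, axis=1)
        first_max = as_[np.arange(p), idx_max]
        as_[np.arange(p), idx_max] = -np.inf
        second_max = as_.max(axis=1)
        r_new = s - first_max[:, None]
        r_new[np.arange(p), idx_max] = s[np.arange(p), idx_max] - second_max
        r = damping * r + (1 - damping) * r_new
        # availabilities
        rp = np.maximum(r, 0)
        np.fill_diagonal(rp, np.diag(r))
        col_sums = rp.sum(axis=0)
        a_new = np.minimum(0, col_sums[None, :] - rp)
        a_new[np.diag_indices(p)] = (col_sums - np.diag(rp))
        a = damping * a + (1 - damping) * a_new
        # boundary inclusive: at exact message symmetry (e.g. two equidistant
        # features at median preference) both points count as exemplars
        new_exemplars = np.flatnonzero(np.diag(r) + np.diag(a) >= 0)
        if new_exemplars.size and np.array_equal(new_exemplars, exemplars):
            stable += 1
            if stable >= convergence_iter:
                converged = True
                break
        else:
            stable = 0
        exemplars = new_exemplars
    if exemplars.size == 0:
        exemplars = np.array([int(np.argmax(np.diag(r) + np.diag(a)))])
    if not converged:
        log.warning("affinity propagation did not converge; returning last stable exemplar set")

    chosen = [names[i] for i in exemplars]
    aucs: dict[str, float] = {}
    if labels is not None:
        y = np.asarray(labels).astype(int)
        aucs = {n: feature_auc(table[n].to_numpy(), y) for n in chosen}
        chosen = sorted(chosen, key=lambda n: (-aucs[n], n))
    return SelectionResult(
        method="affinity_propagation",
        ordered_features=chosen,
        per_feature_auc=aucs,
        chosen_size=len(chosen),
    )


def _equal_frequency_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right")


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two discrete codes."""
    ja = np.unique(a, return_inverse=True)[1]
    jb = np.unique(b, return_inverse=True)[1]
    counts = np.zeros((ja.max() + 1, jb.max() + 1))
    np.add.at(counts, (ja, jb), 1.0)
    pxy = counts / counts.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())


def mrmr_rank(
    table: pd.DataFrame,
    labels: np.ndarray,
    n_bins_mi: int = 4,
) -> SelectionResult:
    """Greedy minimum-redundancy maximum-relevance (MIQ) ranking.

    Relevance I(f; y) and redundancy I(f; s) are plug-in mutual informations
    after equal-frequency binning of each feature into ``n_bins_mi`` bins.
    The first pick maximizes relevance; subsequent picks maximize
    relevance / mean redundancy with the already-selected set.  The full
    ordering is returned; the subset size is chosen downstream.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    names = list(table.columns)
    binned = {n: _equal_frequency_bins(table[n].to_numpy(dtype=float), n_bins_mi) for n in names}
    relevance = {n: _mutual_information(binned[n], y) for n in names}

    eps = 1e-12
    remaining = list(names)
    selected: list[str] = []
    red_sum = dict.fromkeys(names, 0.0)  # sum of I(f; s) over selected s
    while remaining:
        if not selected:
            scores = {n: relevance[n] for n in remaining}
        else:
            scores = {
                n: relevance[n] / max(red_sum[n] / len(selected), eps) for n in remaining
            }
        best = min(remaining, key=lambda n: (-scores[n], n))
        selected.append(best)
        remaining.remove(best)
        for n in remaining:
            red_sum[n] += _mutual_information(binned[n], binned[best])
    return SelectionResult(
        method="mrmr",
        ordered_features=selected,
        per_feature_auc={n: float(relevance[n]) for n in selected},
        chosen_size=len(selected),
    )
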