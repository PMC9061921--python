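"""Performance metrics, model selection, validation and error analysis.

Responder is the positive class throughout.  Percentages are rounded to the
nearest integer, half away from zero (the rounding under which the printed
rates and percentages of a confusion table are mutually consistent, e.g.
10/16 -> 63%).  Proportion confidence intervals are Clopper-Pearson; AUC
intervals come from a seeded stratified bootstrap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricValue",
    "PerformanceReport",
    "confusion",
    "metrics",
    "roc_auc",
    "select_best",
    "validate",
    "mann_whitney",
    "error_analysis",
    "compare_models",
    "OVERFITTING_AUC_THRESHOLD",
    "MIN_ACCURACY",
]

log = logging.getLogger(__name__)

#: construction AUC at or above this marks clear overfitting
OVERFITTING_AUC_THRESHOLD = 0.99
#: eligibility floor on construction accuracy
MIN_ACCURACY = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predictions: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    """Confusion counts with responder (1) positive."""
    pred = np.asarray(predictions).astype(int)
    lab = np.asarray(labels).astype(int)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels differ in length")
    return ConfusionCounts(
        tp=int(((pred == 1) & (lab == 1)).sum()),
        fp=int(((pred == 1) & (lab == 0)).sum()),
        tn=int(((pred == 0) & (lab == 0)).sum()),
        fn=int(((pred == 0) & (lab == 1)).sum()),
    )


def round_half_away(x: float) -> int:
    """Round to nearest integer, half away from zero (62.5 -> 63)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class MetricValue:
    """One proportion metric: raw fraction, printed percent, rate and 95% CI."""

    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> int:
        return round_half_away(100.0 * self.fraction)

    @property
    def rate(self) -> str:
        return f"{self.numerator}/{self.denominator}"

    @property
    def ci_percent(self) -> tuple[int, int]:
        lo, hi = clopper_pearson(self.numerator, self.denominator)
        return round_half_away(100 * lo), round_half_away(100 * hi)

    def __str__(self) -> str:
        lo, hi = self.ci_percent
        return f"{self.percent}({lo}-{hi})[{self.rate}]"


@dataclass
class PerformanceReport:
    """ACC / SE / SP / NPV / PPV (+ optional AUC) of one model on one split."""

    accuracy: MetricValue
    sensitivity: MetricValue | None
    specificity: MetricValue | None
    npv: MetricValue | None
    ppv: MetricValue | None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    counts: ConfusionCounts | None = None

    def metric(self, name: str) -> MetricValue | None:
        return getattr(self, {"acc": "accuracy", "se": "sensitivity", "sp": "specificity",
                              "npv": "npv", "ppv": "ppv"}[name])

    def to_dict(self) -> dict:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "npv", "ppv"):
            m = getattr(self, name)
            out[name] = None if m is None else {
                "percent": m.percent, "rate": m.rate, "ci_percent": list(m.ci_percent),
            }
        out["auc"] = self.auc
        out["auc_ci"] = list(self.auc_ci) if self.auc_ci else None
        return out

    def to_text(self) -> str:
        auc = f"{self.auc:.2f}" if self.auc is not None else "--"
        if self.auc_ci:
            auc += f"({round_half_away(100 * self.auc_ci[0])}-{round_half_away(100 * self.auc_ci[1])})"
        cols = [auc] + [
            str(m) if m is not None else "undefined"
            for m in (self.accuracy, self.sensitivity, self.specificity, self.npv, self.ppv)
        ]
        return " / ".join(cols)


def metrics(c: ConfusionCounts) -> PerformanceReport:
    """Accuracy, sensitivity, specificity, NPV and PPV from confusion counts.

    A metric with a zero denominator is reported as undefined (None), never 0.
    """

    def mk(num: int, den: int) -> MetricValue | None:
        return MetricValue(num, den) if den > 0 else None

    if c.n == 0:
        raise ValueError("empty confusion table")
    return PerformanceReport(
        accuracy=MetricValue(c.tp + c.tn, c.n),
        sensitivity=mk(c.tp, c.tp + c.fn),
        specificity=mk(c.tn, c.tn + c.fp),
        npv=mk(c.tn, c.tn + c.fn),
        ppv=mk(c.tp, c.tp + c.fp),
        counts=c,
    )


def _auc_point(scores: np.ndarray, labels: np.ndarray) -> float:
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC (positive-class orientation, unfolded) with bootstrap CI.

    The CI resamples cases stratified within each class, 2000 replicates.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc = _auc_point(scores, labels)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([
            rng.choice(pos, size=len(pos), replace=True),
            rng.choice(neg, size=len(neg), replace=True),
        ])
        boots[b] = _auc_point(scores[idx], labels[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, (float(lo), float(hi))


def select_best(candidates: list[tuple[object, PerformanceReport]]):
    """The paper-rule model choice on construction performance.

    Candidates whose construction AUC reaches the overfitting threshold
    (>= 0.99) are excluded; among the rest the highest accuracy wins, ties
    broken by PPV, then by fewer selected features.  Returns
    (model, report, exclusion_log).
    """
    if not candidates:
        raise ValueError("no candidate models")
    exclusions = []
    eligible = []
    for model, report in candidates:
        if report.auc is not None and report.auc >= OVERFITTING_AUC_THRESHOLD:
            exclusions.append(
                {"model": getattr(model.spec, "describe", lambda: str(model))(),
                 "reason": f"overfitting: construction AUC {report.auc:.2f} >= "
                           f"{OVERFITTING_AUC_THRESHOLD}"}
            )
            continue
        eligible.append((model, report))
    if not eligible:
        raise ValueError("all candidate models excluded as overfitting (AUC >= 0.99)")

    def key(item):
        model, report = item
        ppv = report.ppv.fraction if report.ppv is not None else -1.0
        return (-report.accuracy.fraction, -ppv, model.n_features)

    best = min(eligible, key=key)
    return best[0], best[1], exclusions


def validate(
    model,
    table: pd.DataFrame,
    split: str = "validation",
    auc_seed: int = 0,
) -> tuple[PerformanceReport, pd.DataFrame]:
    """Frozen-model evaluation on the rows of a named held-out split.

    Refuses construction rows (leakage guard).  Applies the model's stored
    min-max normalization before predicting; hybrid validation is achieved
    simply by passing feature rows of the other mask provenance.
    """
    from .classify import predict
    from .selection import apply_minmax

    if split.startswith("construction"):
        raise ValueError("refusing to validate on construction rows (leakage)")
    rows = table[table["split"] == split]
    if len(rows) == 0:
        raise ValueError(f"no rows tagged {split!r}")
    if model.normalization is not None:
        rows = apply_minmax(model.normalization, rows)
    y = rows["label"].to_numpy().astype(int)
    pred, scores = predict(model, rows)
    report = metrics(confusion(pred, y))
    if len(np.unique(y)) == 2:
        report.auc, report.auc_ci = roc_auc(scores, y, seed=auc_seed)
    per_case = pd.DataFrame(
        {"id": rows["id"].to_numpy(), "label": y, "prediction": pred, "score": scores}
    )
    per_case["correct"] = per_case["label"] == per_case["prediction"]
    return report, per_case


def mann_whitney(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when both groups have <= 8 observations and no ties;
    normal approximation with tie and continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


@dataclass
class ErrorAnalysisReport:
    """Per-case correctness of the two pipelines plus the Mann-Whitney contrasts."""

    per_case: pd.DataFrame
    n_misclassified_manual: int
    n_misclassified_automatic: int
    n_misclassified_both: int
    pvalues: dict[str, float | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_misclassified_manual": self.n_misclassified_manual,
            "n_misclassified_automatic": self.n_misclassified_automatic,
            "n_misclassified_both": self.n_misclassified_both,
            "pvalues": self.pvalues,
        }


def error_analysis(
    preds_manual: pd.DataFrame,
    preds_auto: pd.DataFrame,
    dsc_by_case: dict[str, float],
    volume_by_case: dict[str, float],
) -> ErrorAnalysisReport:
    """Misclassification overlap and volume / DSC contrasts between pipelines.

    ``preds_*`` are the per-case prediction frames produced by
    :func:`validate` (aligned on ``id``).  Tests (two-sided Mann-Whitney):
    tumour volume correct vs misclassified per pipeline, DSC correct vs
    misclassified for the automatic pipeline, and volume of manual vs
    automatic misclassified tumours.  Empty groups give p = None.
    """
    merged = preds_manual.merge(
        preds_auto, on="id", suffixes=("_manual", "_automatic"), validate="one_to_one"
    )
    merged["dsc"] = merged["id"].map(dsc_by_case)
    merged["volume"] = merged["id"].map(volume_by_case)
    wrong_man = merged[~merged["correct_manual"]]
    wrong_auto = merged[~merged["correct_automatic"]]
    both = merged[~merged["correct_manual"] & ~merged["correct_automatic"]]

    def mw(a, b):
        a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
        if len(a) == 0 or len(b) == 0:
            return None
        return mann_whitney(a, b)

    pvals = {
        "volume_correct_vs_misclassified_manual": mw(
            merged.loc[merged["correct_manual"], "volume"], wrong_man["volume"]),
        "volume_correct_vs_misclassified_automatic": mw(
            merged.loc[merged["correct_automatic"], "volume"], wrong_auto["volume"]),
        "dsc_correct_vs_misclassified_automatic": mw(
            merged.loc[merged["correct_automatic"], "dsc"], wrong_auto["dsc"]),
        "volume_misclassified_manual_vs_automatic": mw(
            wrong_man["volume"], wrong_auto["volume"]),
    }
    return ErrorAnalysisReport(
        per_case=merged,
        n_misclassified_manual=len(wrong_man),
        n_misclassified_automatic=len(wrong_auto),
        n_misclassified_both=len(both),
        pvalues=pvals,
    )


def compare_models(
    preds_a: np.ndarray, preds_b: np.ndarray, labels: np.ndarray
) -> dict[str, float | None | dict]:
    """Compare two models' paired predictions on the same cases.

    Reports (a) per-metric two-proportion z-tests (the study-style unpaired
    comparison of printed proportions) and (b) McNemar's exact test on the
    paired correctness disagreements, the statistically appropriate primary
    test for paired designs.
    """
    from statsmodels.stats.contingency_tables import mcnemar
    from statsmodels.stats.proportion import proportions_ztest

    a = np.asarray(preds_a).astype(int)
    b = np.asarray(preds_b).astype(int)
    y = np.asarray(labels).astype(int)
    ca, cb = confusion(a, y), confusion(b, y)
    ra, rb = metrics(ca), metrics(cb)

    two_prop: dict[str, float | None] = {}
    for name in ("acc", "se", "sp", "npv", "ppv"):
        ma, mb = ra.metric(name), rb.metric(name)
        if ma is None or mb is None:
            two_prop[name] = None
            continue
        if ma.numerator + mb.numerator in (0, ma.denominator + mb.denominator):
            two_prop[name] = 1.0  # identical degenerate proportions
            continue
        _, p = proportions_ztest(
            [ma.numerator, mb.numerator], [ma.denominator, mb.denominator]
        )
        two_prop[name] = float(p)

    correct_a = a == y
    correct_b = b == y
    n01 = int((correct_a & ~correct_b).sum())
    n10 = int((~correct_a & correct_b).sum())
    table = [[int((correct_a & correct_b).sum()), n01], [n10, int((~correct_a & ~correct_b).sum())]]
    mc = mcnemar(table, exact=True)
    return {
        "two_proportion": two_prop,
        "mcnemar_p": float(mc.pvalue),
        "discordant": {"a_only_correct": n01, "b_only_correct": n10},
    }
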