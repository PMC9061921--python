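"""End-to-end orchestration: extract -> select -> train -> validate -> compare.

The pipeline runs two parallel provenance tracks (manual and automatic
masks).  Automatic-track construction cases whose automatic mask overlaps
the manual reference at DSC < 0.20 are treated as segmentation failures and
excluded from training.  Each track normalizes on its construction rows,
runs the three feature-selection methods, grid-searches the four classifier
families on each selected subset, applies the best-model rule (highest
construction accuracy then PPV, overfitting candidates with AUC >= 0.99
excluded), and validates externally; hybrid validation swaps the provenance
of the validation feature rows.  All randomness derives from the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .catalogue import catalogue_names
from .classify import FAMILIES, grid_search, predict, train
from .evaluate import (
    PerformanceReport,
    compare_models,
    confusion,
    error_analysis,
    metrics,
    roc_auc,
    select_best,
    validate,
)
from .features import extract_case_features
from .imaging import StudyCase, dice, load_cohort, roi_volume_mm3
from .matrices import NeighbourhoodConfig
from .preprocessing import DiscretizationConfig, ResegmentationConfig
from .selection import (
    RankingConfig,
    SelectionResult,
    affinity_propagation_select,
    apply_minmax,
    fit_minmax,
    mrmr_rank,
    overfitting_point,
    stability_ranking,
)
from .synthetic import generate_study_cohort

__all__ = ["PipelineConfig", "run_pipeline", "build_feature_table", "run_track", "run_selection"]

log = logging.getLogger(__name__)

META_COLUMNS = ["id", "centre", "trg", "label", "split", "provenance"]
FS_METHODS = ("ranking", "affinity_propagation", "mrmr")


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    # input: either a clinical CSV or a simulation block
    clinical_csv: str | None = None
    simulate: dict = field(default_factory=dict)
    # preprocessing
    low_percentile: float = 1.0
    high_percentile: float = 99.0
    bin_count: int = 64
    min_slice_pixels: int = 2
    # selection / classification
    fs_methods: tuple[str, ...] = FS_METHODS
    families: tuple[str, ...] = FAMILIES
    cv_folds: int = 6
    ranking: dict = field(default_factory=dict)
    # global
    seed: int = 0
    out_dir: str | None = None

    @staticmethod
    def from_yaml(path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = PipelineConfig(**raw)
        cfg.fs_methods = tuple(cfg.fs_methods)
        cfg.families = tuple(cfg.families)
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["fs_methods"] = list(self.fs_methods)
        out["families"] = list(self.families)
        return out


def _feature_configs(cfg: PipelineConfig):
    return (
        ResegmentationConfig(cfg.low_percentile, cfg.high_percentile),
        DiscretizationConfig(cfg.bin_count),
        NeighbourhoodConfig(),
    )


def build_feature_table(
    cases: list[StudyCase], provenance: str, cfg: PipelineConfig,
    exclude_ids: set[str] | None = None,
) -> pd.DataFrame:
    """One row of 157 features plus metadata per case for one mask provenance."""
    reseg, disc, nbh = _feature_configs(cfg)
    rows = []
    for case in cases:
        if exclude_ids and case.id in exclude_ids:
            continue
        if provenance not in case.masks:
            continue
        feats = extract_case_features(
            case, provenance, reseg=reseg, disc=disc, nbh=nbh,
            min_slice_pixels=cfg.min_slice_pixels,
        )
        rows.append({
            "id": case.id, "centre": case.centre, "trg": case.trg,
            "label": int(case.is_responder), "split": case.split,
            "provenance": provenance, **feats,
        })
    table = pd.DataFrame(rows, columns=META_COLUMNS + catalogue_names())
    return table


def _sizing_classifier():
    # reference classifier for the overfitting-point curves
    return SVC(kernel="linear", C=1.0)


def _cv_construction_report(
    spec, table: pd.DataFrame, labels: np.ndarray, features: list[str],
    cv_folds: int, seed: int, repeats: int = 2,
) -> PerformanceReport:
    """Construction performance from repeated stratified k-fold CV predictions.

    Out-of-fold scores are averaged over ``repeats`` fold layouts to stabilise
    the construction AUC estimate at small n.
    """
    from .classify import effective_folds

    y = np.asarray(labels).astype(int)
    scores = np.zeros(len(y), dtype=float)
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=effective_folds(y, cv_folds), shuffle=True,
                              random_state=seed + rep)
        for tr, te in skf.split(np.zeros(len(y)), y):
            model = train(spec, table.iloc[tr], y[tr], features, seed=seed)
            _, s = predict(model, table.iloc[te])
            scores[te] += s
    scores /= repeats
    pred = (scores >= 0.5).astype(int)
    report = metrics(confusion(pred, y))
    report.auc, report.auc_ci = roc_auc(scores, y, seed=seed)
    return report


def run_selection(
    method: str,
    constr: pd.DataFrame,
    cfg: PipelineConfig,
    seed: int,
) -> SelectionResult:
    """One FS method on normalized construction rows, sized at the overfitting point."""
    feature_cols = catalogue_names()
    y = constr["label"].to_numpy().astype(int)
    x = constr[feature_cols]
    if method == "ranking":
        rank_cfg = RankingConfig(rng_seed=seed, **cfg.ranking)
        result = stability_ranking(x, y, rank_cfg)
    elif method == "affinity_propagation":
        result = affinity_propagation_select(x, y)
    elif method == "mrmr":
        result = mrmr_rank(x, y)
    else:
        raise ValueError(f"unknown FS method {method!r}")

    is_train = constr["split"] == "construction-train"
    tr, te = constr[is_train], constr[~is_train]
    if len(te) == 0 or len(tr) == 0:
        log.info("%s: no construction-train/test partition; keeping full ordering", method)
        return result
    # candidate subset sizes are capped at the training sample size
    max_k = min(len(result.ordered_features), int(is_train.sum()))
    chosen, curves = overfitting_point(
        result.ordered_features[:max_k], _sizing_classifier,
        tr[feature_cols], tr["label"].to_numpy(),
        te[feature_cols], te["label"].to_numpy(),
        cv_folds=cfg.cv_folds, seed=seed,
    )
    result.chosen_size = chosen
    result.cv_curves = curves
    return result


def run_track(
    table: pd.DataFrame, cfg: PipelineConfig, seed: int
) -> dict:
    """Selection, training and best-model choice for one provenance track."""
    feature_cols = catalogue_names()
    constr_mask = table["split"].str.startswith("construction")
    constr_raw = table[constr_mask].reset_index(drop=True)
    if constr_raw.empty:
        raise ValueError("no construction rows in feature table")
    norm = fit_minmax(constr_raw, feature_cols)
    constr = apply_minmax(norm, constr_raw)
    y = constr["label"].to_numpy().astype(int)

    selections: dict[str, SelectionResult] = {}
    candidates = []
    skipped = []
    for method in cfg.fs_methods:
        sel = run_selection(method, constr, cfg, seed)
        selections[method] = sel
        feats = sel.selected
        for family in cfg.families:
            model = grid_search(
                family, constr, y, feats, cv_folds=cfg.cv_folds, seed=seed,
                normalization=norm,
            )
            if not model.diagnostics.get("eligible", True):
                skipped.append({"fs": method, "family": family,
                                "reason": "construction CV accuracy <= 0.5"})
                continue
            report = _cv_construction_report(
                model.spec, constr, y, feats, cfg.cv_folds, seed
            )
            model.construction_performance = report
            model.diagnostics["fs_method"] = method
            candidates.append((model, report))
    if not candidates:
        raise ValueError("no eligible candidate models in this track")
    best_model, best_report, exclusions = select_best(candidates)
    return {
        "normalization": norm,
        "selections": selections,
        "candidates": candidates,
        "best_model": best_model,
        "best_report": best_report,
        "exclusions": exclusions,
        "skipped": skipped,
    }


def _load_cases(cfg: PipelineConfig) -> list[StudyCase]:
    if cfg.clinical_csv:
        return load_cohort(cfg.clinical_csv)
    if cfg.simulate:
        sim = dict(cfg.simulate)
        n_constr = tuple(sim.pop("n_construction", (10, 10)))
        n_val = tuple(sim.pop("n_validation", (5, 5)))
        return generate_study_cohort(n_constr, n_val, seed=cfg.seed, **sim)
    raise ValueError("config provides neither clinical_csv nor a simulate block")


def run_pipeline(cfg: PipelineConfig, cases: list[StudyCase] | None = None) -> dict:
    """Run both provenance tracks end to end; returns (and optionally writes) results.

    ``cases`` bypasses loading/simulation when a cohort is already in memory.
    """
    if cases is None:
        cases = _load_cases(cfg)

    dsc_by_case: dict[str, float] = {}
    volume_by_case: dict[str, float] = {}
    excluded_auto: set[str] = set()
    for case in cases:
        volume_by_case[case.id] = roi_volume_mm3(case.masks["manual"], case.t2w.spacing)
        if "automatic" in case.masks:
            d = dice(case.masks["manual"], case.masks["automatic"])
            dsc_by_case[case.id] = d.value
            if d.excluded and case.split.startswith("construction"):
                excluded_auto.add(case.id)
                log.warning("case %s excluded from automatic-track construction "
                            "(DSC %.2f < 0.20)", case.id, d.value)

    have_auto = all("automatic" in c.masks for c in cases)
    tracks = ["manual"] + (["automatic"] if have_auto else [])
    tables = {"manual": build_feature_table(cases, "manual", cfg)}
    if have_auto:
        tables["automatic"] = build_feature_table(
            cases, "automatic", cfg, exclude_ids=excluded_auto
        )

    results: dict = {
        "config": cfg.to_dict(),
        "n_cases": len(cases),
        "excluded_automatic_construction": sorted(excluded_auto),
        "tracks": {},
    }
    track_out: dict[str, dict] = {}
    for i, prov in enumerate(tracks):
        track_out[prov] = run_track(tables[prov], cfg, seed=cfg.seed + 101 * i)

    has_validation = (tables["manual"]["split"] == "validation").any()
    per_case_val: dict[str, pd.DataFrame] = {}
    for prov in tracks:
        best = track_out[prov]["best_model"]
        entry = {
            "best_model": best.spec.describe(),
            "fs_method": best.diagnostics.get("fs_method"),
            "n_selected_features": len(track_out[prov]["selections"][
                best.diagnostics.get("fs_method")].selected),
            "construction": track_out[prov]["best_report"].to_dict(),
            "excluded_candidates": track_out[prov]["exclusions"],
            "skipped": track_out[prov]["skipped"],
        }
        if has_validation:
            report, per_case = validate(best, tables[prov], auc_seed=cfg.seed)
            entry["validation"] = report.to_dict()
            per_case_val[prov] = per_case
            other = {"manual": "automatic", "automatic": "manual"}[prov]
            if other in tables:
                hybrid_report, _ = validate(best, tables[other], auc_seed=cfg.seed)
                entry["hybrid_validation"] = hybrid_report.to_dict()
        else:
            log.warning("no validation split: validation and hybrid stages skipped")
        results["tracks"][prov] = entry

    if has_validation and len(per_case_val) == 2:
        err = error_analysis(
            per_case_val["manual"], per_case_val["automatic"], dsc_by_case, volume_by_case
        )
        merged = per_case_val["manual"].merge(
            per_case_val["automatic"], on="id", suffixes=("_m", "_a")
        )
        results["error_analysis"] = err.to_dict()
        results["model_comparison"] = compare_models(
            merged["prediction_m"].to_numpy(), merged["prediction_a"].to_numpy(),
            merged["label_m"].to_numpy(),
        )

    results["_objects"] = {"tracks": track_out, "tables": tables, "per_case": per_case_val}
    if cfg.out_dir:
        _write_artifacts(results, tables, track_out, cfg)
    return results


def _write_artifacts(results: dict, tables, track_out, cfg: PipelineConfig) -> None:
    os.makedirs(cfg.out_dir, exist_ok=True)
    for prov, table in tables.items():
        table.to_csv(os.path.join(cfg.out_dir, f"features_{prov}.csv"), index=False)
    for prov, out in track_out.items():
        sel = {m: r.to_dict() for m, r in out["selections"].items()}
        with open(os.path.join(cfg.out_dir, f"selection_{prov}.json"), "w") as fh:
            json.dump(sel, fh, indent=2)
    serializable = {k: v for k, v in results.items() if k != "_objects"}
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(serializable, fh, indent=2)
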