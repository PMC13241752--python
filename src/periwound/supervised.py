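"""Supervised reproduction of rater labels: geometry-only vs full features.

One model is trained per rater (no consensus label is invented) under
repeated stratified cross-validation; agreement with that rater is measured
as Cohen's kappa on pooled out-of-fold predictions, once per repeat.  The
geometry-only and full-feature runs share fold assignments for a given seed,
and their pooled per-run kappa samples are compared with a two-sample
Student's t-test.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import (
    accuracy_score,
    precision_recall_fscore_support,
)
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from . import agreement
from .io_config import AnnotationTable, RunConfig

logger = logging.getLogger("periwound")

FEATURE_SETS = ("geometry", "full")


@dataclasses.dataclass(frozen=True)
class RaterMetrics:
    kappa_per_repeat: list[float]
    kappa_mean: float
    kappa_sd: float
    accuracy: float
    precision: float  # macro
    recall: float  # macro
    f1: float  # macro


@dataclasses.dataclass(frozen=True)
class ClassifierReport:
    feature_set: str
    columns: list[str]
    raters: list[str]
    per_rater: dict[str, RaterMetrics]
    runs: np.ndarray  # per-run kappa values, repeats x raters flattened
    kappa_mean: float
    kappa_sd: float
    importances: dict[str, float]
    seed: int


def make_classifier(name: str, seed: int):
    if name == "hist_gradient_boosting":
        return HistGradientBoostingClassifier(random_state=seed, class_weight="balanced")
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=200, class_weight="balanced", random_state=seed, n_jobs=1
        )
    raise ValueError(f"unknown classifier {name!r}")


def select_columns(
    features: pd.DataFrame, groups: dict[str, str], feature_set: str
) -> list[str]:
    if feature_set == "full":
        return list(features.columns)
    if feature_set == "geometry":
        return [c for c in features.columns if groups[c] == "geometry"]
    raise ValueError(f"feature_set must be one of {FEATURE_SETS}")


def train_eval(
    features: pd.DataFrame,
    groups: dict[str, str],
    table: AnnotationTable,
    feature_set: str,
    config: RunConfig = RunConfig(),
    seed: int = 0,
    compute_importances: bool = True,
) -> ClassifierReport:
    """Repeated stratified CV of one model per rater on the chosen columns."""
    if list(features.index) != table.image_ids:
        raise ValueError("feature rows and annotation rows are not aligned")
    cols = select_columns(features, groups, feature_set)
    x = features[cols].to_numpy(dtype=float)
    per_rater: dict[str, RaterMetrics] = {}
    runs: list[float] = []
    importance_sum = np.zeros(len(cols))
    n_importance = 0

    for rater in table.raters:
        y = table.labels(rater)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            logger.warning("rater %s uses < 2 classes; skipped", rater)
            continue
        n_splits = int(min(config.cv_folds, counts.min()))
        if n_splits < 2:
            logger.warning(
                "rater %s: rarest class has %d items; skipped", rater, counts.min()
            )
            continue
        cv = RepeatedStratifiedKFold(
            n_splits=n_splits, n_repeats=config.cv_repeats, random_state=seed
        )
        kappas = []
        all_true, all_pred = [], []
        pred = np.empty(len(y), dtype=object)
        for i, (tr, te) in enumerate(cv.split(x, y)):
            clf = make_classifier(config.classifier, seed)
            clf.fit(x[tr], y[tr])
            pred[te] = clf.predict(x[te])
            if (i + 1) % n_splits == 0:  # repeat complete: pooled out-of-fold kappa
                kappas.append(agreement.cohen_kappa(pred, y))
                all_true.append(y.copy())
                all_pred.append(pred.copy())
                pred = np.empty(len(y), dtype=object)
        yt = np.concatenate(all_true)
        yp = np.concatenate(all_pred)
        prec, rec, f1, _ = precision_recall_fscore_support(
            yt, yp, average="macro", zero_division=0
        )
        kap = np.array(kappas)
        per_rater[rater] = RaterMetrics(
            kappa_per_repeat=[float(v) for v in kappas],
            kappa_mean=float(kap.mean()),
            kappa_sd=float(kap.std(ddof=1)) if len(kap) > 1 else 0.0,
            accuracy=float(accuracy_score(yt, yp)),
            precision=float(prec),
            recall=float(rec),
            f1=float(f1),
        )
        runs.extend(kappas)

        if compute_importances:
            xtr, xte, ytr, yte = train_test_split(
                x, y, test_size=0.25, random_state=seed, stratify=y
            )
            clf = make_classifier(config.classifier, seed)
            clf.fit(xtr, ytr)
            imp = permutation_importance(
                clf, xte, yte, n_repeats=10, random_state=seed
            )
            importance_sum += imp.importances_mean
            n_importance += 1

    if not per_rater:
        raise ValueError("no rater had enough class diversity to train on")
    runs_arr = np.array(runs)
    if n_importance:
        imp_mean = np.clip(importance_sum / n_importance, 0.0, None)
        total = imp_mean.sum()
        importances = dict(
            zip(cols, (imp_mean / total) if total > 0 else imp_mean)
        )
    else:
        importances = {}
    return ClassifierReport(
        feature_set=feature_set,
        columns=cols,
        raters=list(per_rater),
        per_rater=per_rater,
        runs=runs_arr,
        kappa_mean=float(runs_arr.mean()),
        kappa_sd=float(runs_arr.std(ddof=1)) if len(runs_arr) > 1 else 0.0,
        importances={k: float(v) for k, v in importances.items()},
        seed=seed,
    )


def compare_feature_sets(
    report_geo: ClassifierReport, report_full: ClassifierReport
) -> dict[str, float]:
    """Two-sample Student's t on the pooled per-run kappas of the two models."""
    if len(report_geo.runs) != len(report_full.runs):
        raise ValueError("reports have different numbers of validation runs")
    if report_geo.raters != report_full.raters:
        raise ValueError("reports cover different raters")
    t, p = agreement.two_sample_t(report_geo.runs, report_full.runs)
    return {
        "t": t,
        "p": p,
        "geometry_mean": report_geo.kappa_mean,
        "geometry_sd": report_geo.kappa_sd,
        "full_mean": report_full.kappa_mean,
        "full_sd": report_full.kappa_sd,
    }
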