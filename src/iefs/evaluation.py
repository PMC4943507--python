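"""Cross-validated evaluation: stratified folds, accuracy, macro AUC,
and the benchmark grid over selectors x samplers x T x signature sizes.

The fold count follows the benchmark convention for small classes:
``'auto'`` picks 3 folds when the smallest class has fewer than 10 samples
and 10 folds otherwise.  If the smallest class is smaller than the fold
count itself, evaluation falls back to leave-one-out with a warning
(stratification cannot place such a class in every fold).

Accuracy and AUC are reported in percent.  Multiclass AUC is the
unweighted (macro) mean of per-class one-vs-rest ROC AUCs, rank-based with
ties counted half, so minority classes weigh equally with majority ones.
Sampling and selection happen inside the training folds only; test folds
keep their original distribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .core import derive_seed, ova_fit, ova_predict
from .datasets import ExpressionDataset, RunConfig
from .exceptions import ValidationError

__all__ = [
    "stratified_folds",
    "accuracy",
    "multiclass_auc",
    "per_class_recall",
    "cross_validate",
    "run_benchmark",
    "plot_report",
    "DEFAULT_SIGNATURE_GRID",
]

#: benchmark signature sizes: 5..100 step 5
DEFAULT_SIGNATURE_GRID = tuple(range(5, 101, 5))


def stratified_folds(labels, k: int | str = "auto", seed: int = 0):
    """Stratified train/test index partitions.

    Returns a list of ``(train_idx, test_idx)`` pairs.  ``k='auto'`` uses
    3 folds if the smallest class has < 10 samples, else 10.
    """
    labels = np.asarray(labels).astype(str)
    n = len(labels)
    _, counts = np.unique(labels, return_counts=True)
    min_class = int(counts.min())
    if k == "auto":
        k = 3 if min_class < 10 else 10
        if min_class < k:
            warnings.warn(
                f"smallest class has {min_class} samples < {k} folds; "
                f"falling back to leave-one-out",
                stacklevel=2,
            )
            return [(np.setdiff1d(np.arange(n), [i]), np.array([i]))
                    for i in range(n)]
    else:
        k = int(k)
        if k < 2:
            raise ValidationError("need at least 2 folds")
        if min_class < k:
            raise ValidationError(
                f"smallest class has {min_class} samples, fewer than k={k} "
                f"folds; use k='auto'"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(n), labels)]


def accuracy(y_true, y_pred) -> float:
    """Percent of exactly correct predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred differ in length")
    return 100.0 * float(np.mean(y_true.astype(str) == y_pred.astype(str)))


def multiclass_auc(y_true, confidences, class_order) -> float:
    """Macro one-vs-rest ROC AUC in percent (rank-based, ties half).

    Classes absent from ``y_true`` are skipped with a warning and the
    average runs over the present classes only.
    """
    y_true = np.asarray(y_true).astype(str)
    confidences = np.asarray(confidences, dtype=float)
    if confidences.shape != (len(y_true), len(class_order)):
        raise ValidationError("confidence matrix must be n_samples x n_classes")
    aucs = []
    for k, cls in enumerate(class_order):
        pos = y_true == str(cls)
        if not pos.any() or pos.all():
            warnings.warn(f"class {cls!r} absent from one side of y_true; "
                          f"skipped in macro AUC", stacklevel=2)
            continue
        aucs.append(roc_auc_score(pos.astype(int), confidences[:, k]))
    if not aucs:
        raise ValidationError("no class with both positives and negatives")
    return 100.0 * float(np.mean(aucs))


def per_class_recall(y_true, y_pred, class_order) -> dict[str, float]:
    """Fraction of each class's samples predicted correctly (in percent)."""
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    out = {}
    for cls in class_order:
        mask = y_true == str(cls)
        out[str(cls)] = (100.0 * float(np.mean(y_pred[mask] == str(cls)))
                         if mask.any() else float("nan"))
    return out


def cross_validate(dataset: ExpressionDataset, config: RunConfig,
                   seed: int | None = None) -> dict:
    """Full stratified CV of one IEFS configuration.

    IEFS (sampling + selection + classifiers) is fit on each training fold
    only and scored on the held-out fold.  Returns fold-mean accuracy and
    macro AUC (percent), pooled per-class recall, and the pooled
    out-of-fold predictions.
    """
    seed = config.seed if seed is None else seed
    folds = stratified_folds(dataset.labels, config.cv_folds, seed=seed)
    class_order = dataset.classes
    accs, aucs = [], []
    pooled_true, pooled_pred = [], []
    for f, (train, test) in enumerate(folds):
        train_ds = dataset.subset_samples(train)
        fold_config = config.replace(seed=derive_seed(seed, f))
        model = ova_fit(train_ds, fold_config)
        y_pred, conf = ova_predict(model, dataset.matrix[test],
                                   feature_ids=dataset.feature_ids)
        y_true = dataset.labels[test].astype(str)
        accs.append(accuracy(y_true, y_pred))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                aucs.append(multiclass_auc(y_true, conf, model.class_order))
            except ValidationError:
                pass  # single-class fold (leave-one-out); AUC undefined
        pooled_true.extend(y_true.tolist())
        pooled_pred.extend(np.asarray(y_pred).astype(str).tolist())
    if not aucs:
        # leave-one-out: score the pooled out-of-fold confidences instead
        aucs = [float("nan")]
    return {
        "accuracy": float(np.mean(accs)),
        "auc": float(np.mean(aucs)),
        "per_class_recall": per_class_recall(pooled_true, pooled_pred, class_order),
        "y_true": pooled_true,
        "y_pred": pooled_pred,
        "n_folds": len(folds),
    }


REPORT_COLUMNS = ["selector", "sampler", "T", "n_features", "classifier",
                  "fold_scheme", "accuracy_mean", "auc_mean",
                  "per_class_recall", "seed", "error"]


def run_benchmark(
    dataset: ExpressionDataset,
    selectors=("ranking",),
    samplers=("none", "oversample"),
    T_values=(1,),
    n_features_grid=DEFAULT_SIGNATURE_GRID,
    classifiers=("knn",),
    cv_folds: int | str = "auto",
    seed: int = 0,
    include_baseline: bool = True,
    base_config: RunConfig | None = None,
) -> pd.DataFrame:
    """Benchmark grid: one row per configuration, plus an all-features
    baseline row (sampler none, every feature kept).

    Per-cell failures are recorded in the row's ``error`` column and the
    run continues.  Each cell gets a hierarchical sub-seed so any single
    cell is independently reproducible.
    """
    base = base_config or RunConfig()
    rows = []
    grid = list(itertools.product(selectors, samplers, T_values,
                                  n_features_grid, classifiers))
    if include_baseline:
        for clf in classifiers:
            grid.append(("ranking", "none", 1, dataset.n_features, clf))
    for cell, (sel, sam, T, nf, clf) in enumerate(grid):
        cfg = base.replace(selector=sel, sampler=sam, T=T, n_features=int(nf),
                           classifier=clf, cv_folds=cv_folds,
                           seed=derive_seed(seed, cell))
        row = {"selector": sel, "sampler": sam, "T": T, "n_features": int(nf),
               "classifier": clf, "seed": cfg.seed, "error": ""}
        try:
            res = cross_validate(dataset, cfg)
            row.update({
                "fold_scheme": f"stratified-{res['n_folds']}",
                "accuracy_mean": round(res["accuracy"], 6),
                "auc_mean": round(res["auc"], 6),
                "per_class_recall": ";".join(
                    f"{c}={v:.2f}" for c, v in res["per_class_recall"].items()
                ),
            })
        except Exception as exc:  # noqa: BLE001 - fail-soft per cell
            row.update({"fold_scheme": "", "accuracy_mean": np.nan,
                        "auc_mean": np.nan, "per_class_recall": "",
                        "error": f"{type(exc).__name__}: {exc}"})
        rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6f")


def plot_report(report: pd.DataFrame, metric: str = "accuracy_mean", ax=None):
    """Accuracy/AUC versus signature size, one line per method combination."""
    import matplotlib.pyplot as plt  # optional dependency

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    body = report[report["error"] == ""]
    for (sel, sam, T, clf), grp in body.groupby(
            ["selector", "sampler", "T", "classifier"]):
        grp = grp.sort_values("n_features")
        label = f"{sel}/{sam}/T={T}/{clf}"
        ax.plot(grp["n_features"], grp[metric], marker="o", label=label)
    ax.set_xlabel("number of selected gene signatures")
    ax.set_ylabel(metric.replace("_mean", " (%)"))
    ax.legend(fontsize=7)
    return ax
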