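"""Metric tables, nested-CV classification, statistics and DMR ranking.

The benchmarking workflow: compute one or more read-level metrics for every
(sample, region) pair into a long-format MetricTable; pivot one metric into
a samples x regions feature matrix; filter heavily missing features and
samples; classify with a linear maximum-margin model (SVM) under nested
cross-validation (stratified 5-fold outer for performance, 3-fold inner for
the cost parameter C); pool predicted probabilities across outer folds for
an aggregated ROC; and compare metrics with rank tests under
Benjamini-Hochberg correction.  For biomarker prioritisation, per-region
differential scores (group-mean differences) feed top-k ranking, top-k
intersection and quadrant partitioning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from . import haplotype, heterogeneity, mpci
from .pat_io import PatRecord, RegionSpec, build_read_matrix

__all__ = [
    "METRICS",
    "compute_metric_table",
    "assemble_features",
    "filter_missing",
    "nested_cv_classify",
    "pooled_roc",
    "bh_adjust",
    "compare_metric_runs",
    "dmr_differential_score",
    "rank_top_k",
    "top_k_intersection",
    "quadrant_partition",
    "BenchmarkReport",
    "SPIKEIN_C_GRID",
    "WIDE_C_GRID",
]

# decade-step cost grids: spike-in experiments use 1e-3..10, wider runs 1e-3..1e3
SPIKEIN_C_GRID: tuple[float, ...] = tuple(10.0**e for e in range(-3, 2))
WIDE_C_GRID: tuple[float, ...] = tuple(10.0**e for e in range(-3, 4))


def _metric_dispatch(seed: int, mpci_config: "mpci.MpciConfig | None" = None) -> dict[str, Callable]:
    cfg = mpci_config or mpci.DEFAULT_CONFIG
    return {
        "mpci": lambda R: mpci.compute_mpci(R, seed=seed, config=cfg),
        "mhl": haplotype.compute_mhl,
        "umhl": haplotype.compute_umhl,
        "dmhl": haplotype.compute_dmhl,
        "me": heterogeneity.compute_me,
        "ep": heterogeneity.compute_ep,
        "pdr": heterogeneity.compute_pdr,
        "fdrp": lambda R: heterogeneity.compute_fdrp(R, seed=seed),
        "qfdrp": lambda R: heterogeneity.compute_qfdrp(R, seed=seed),
    }


METRICS: tuple[str, ...] = tuple(_metric_dispatch(0))


def compute_metric_table(
    samples: Mapping[str, Sequence[PatRecord]],
    regions: Sequence[RegionSpec],
    metrics: Sequence[str] = ("mpci",),
    seed: int = 0,
    min_overlap: int = 1,
    max_reads: int | None = None,
    mpci_config: "mpci.MpciConfig | None" = None,
) -> pd.DataFrame:
    """Long-format (sample, region, metric, value) table; NaN = missing."""
    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    dispatch = _metric_dispatch(seed, mpci_config)
    rows = []
    for sample_id, records in samples.items():
        for region in regions:
            R = build_read_matrix(
                records, region, min_overlap=min_overlap, max_reads=max_reads, seed=seed
            )
            for name in metrics:
                rows.append((sample_id, region.name, name, dispatch[name](R)))
    return pd.DataFrame(rows, columns=["sample", "region", "metric", "value"])


def assemble_features(
    metric_table: pd.DataFrame,
    metric: str,
    samples: Sequence[str] | None = None,
    regions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pivot one metric into a samples x regions matrix (NaN preserved)."""
    if metric not in set(metric_table["metric"]):
        raise ValueError(f"metric {metric!r} not present in the table")
    sub = metric_table[metric_table["metric"] == metric]
    if samples is not None:
        sub = sub[sub["sample"].isin(samples)]
    if regions is not None:
        if len(regions) == 0:
            raise ValueError("empty region list")
        sub = sub[sub["region"].isin(regions)]
    if sub.duplicated(["sample", "region"]).any():
        raise ValueError("duplicated (sample, region) rows in metric table")
    X = sub.pivot(index="sample", columns="region", values="value")
    if samples is not None:
        X = X.reindex(samples)
    if regions is not None:
        X = X.reindex(columns=regions)
    return X


def filter_missing(
    X: pd.DataFrame,
    max_feature_missing: float = 0.10,
    max_sample_missing: float = 0.80,
    impute: bool = True,
) -> pd.DataFrame:
    """Drop features with >10% and samples with >80% missing, then impute.

    Thresholds are strict (>).  Remaining NaNs are filled with the feature
    median unless ``impute=False``.
    """
    feat_missing = X.isna().mean(axis=0)
    X = X.loc[:, feat_missing <= max_feature_missing]
    if X.shape[1] == 0:
        raise ValueError("all features removed by missingness filter")
    samp_missing = X.isna().mean(axis=1)
    X = X.loc[samp_missing <= max_sample_missing, :]
    if X.shape[0] == 0:
        raise ValueError("all samples removed by missingness filter")
    if impute:
        X = X.fillna(X.median(axis=0))
    return X


@dataclass
class BenchmarkReport:
    fold_auc: list[float]
    fold_accuracy: list[float]
    fold_sensitivity: list[float]
    fold_specificity: list[float]
    chosen_c: list[float]
    pooled_scores: np.ndarray  # probability of the positive class, all folds
    pooled_labels: np.ndarray
    pooled_fpr: np.ndarray
    pooled_tpr: np.ndarray
    pooled_auc: float

    def summary(self) -> dict:
        return {
            "mean_auc": float(np.mean(self.fold_auc)),
            "mean_accuracy": float(np.mean(self.fold_accuracy)),
            "mean_sensitivity": float(np.mean(self.fold_sensitivity)),
            "mean_specificity": float(np.mean(self.fold_specificity)),
            "pooled_auc": self.pooled_auc,
            "chosen_c": list(self.chosen_c),
        }


def nested_cv_classify(
    X,
    y,
    outer_folds: int = 5,
    inner_folds: int = 3,
    c_grid: Sequence[float] = SPIKEIN_C_GRID,
    seed: int = 0,
) -> BenchmarkReport:
    """Nested-CV linear SVM: outer folds estimate performance, inner folds
    pick C; probabilities from all outer test folds are pooled for the
    aggregated ROC.  Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    y01 = (y == classes[1]).astype(int)  # positive = second class in sort order
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    fold_auc, fold_acc, fold_sens, fold_spec, chosen = [], [], [], [], []
    scores_all, labels_all = [], []
    for k, (tr, te) in enumerate(outer.split(X, y01)):
        assert len(set(tr) & set(te)) == 0
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed + k)
        search = GridSearchCV(
            SVC(kernel="linear", probability=True, random_state=seed),
            param_grid={"C": list(c_grid)},
            cv=inner,
            scoring="roc_auc",
        )
        with warnings.catch_warnings():
            # sklearn 1.9 deprecates SVC(probability=True); Platt-scaled
            # probabilities are exactly what fold pooling needs here
            warnings.simplefilter("ignore", FutureWarning)
            search.fit(X[tr], y01[tr])
            chosen.append(float(search.best_params_["C"]))
            prob = search.predict_proba(X[te])[:, 1]
        pred = (prob >= 0.5).astype(int)
        yt = y01[te]
        fold_auc.append(_rank_auc(yt, prob))
        fold_acc.append(float(np.mean(pred == yt)))
        tp = int(np.sum((pred == 1) & (yt == 1)))
        tn = int(np.sum((pred == 0) & (yt == 0)))
        fn = int(np.sum((pred == 0) & (yt == 1)))
        fp = int(np.sum((pred == 1) & (yt == 0)))
        fold_sens.append(tp / (tp + fn) if tp + fn else math.nan)
        fold_spec.append(tn / (tn + fp) if tn + fp else math.nan)
        scores_all.append(prob)
        labels_all.append(yt)
    scores = np.concatenate(scores_all)
    labels = np.concatenate(labels_all)
    fpr, tpr, pooled = pooled_roc(labels, scores)
    return BenchmarkReport(
        fold_auc=fold_auc,
        fold_accuracy=fold_acc,
        fold_sensitivity=fold_sens,
        fold_specificity=fold_spec,
        chosen_c=chosen,
        pooled_scores=scores,
        pooled_labels=labels,
        pooled_fpr=fpr,
        pooled_tpr=tpr,
        pooled_auc=pooled,
    )


def _rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    if len(np.unique(y)) < 2:
        return math.nan
    fpr, tpr, _ = roc_curve(y, scores)
    return float(_trapezoid_auc(fpr, tpr))


def pooled_roc(labels, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical ROC over pooled fold predictions; AUC by trapezoid rule."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("pooled ROC needs both classes")
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, >= raw p)."""
    _, adjusted, _, _ = multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")
    return adjusted


def compare_metric_runs(
    runs_a: Mapping[str, Sequence[float]],
    runs_b: Mapping[str, Sequence[float]],
    paired: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-test A vs B per performance measure, BH-adjusted across measures.

    ``paired`` uses the Wilcoxon signed-rank test on fold-matched values
    (identical vectors give p = 1); unpaired uses the exact two-sided
    Mann-Whitney rank-sum test.
    """
    measures = list(runs_a)
    if set(measures) != set(runs_b):
        raise ValueError("A and B must report the same measures")
    raw = []
    for mname in measures:
        a = np.asarray(runs_a[mname], dtype=float)
        b = np.asarray(runs_b[mname], dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 observations per measure")
        if paired:
            if len(a) != len(b):
                raise ValueError("paired mode needs equal-length vectors")
            if np.allclose(a, b):
                raw.append((mname, 0.0, 1.0))
                continue
            res = stats.wilcoxon(a, b)
            raw.append((mname, float(res.statistic), float(res.pvalue)))
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            raw.append((mname, float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(raw, columns=["measure", "statistic", "p_raw"])
    df["p_adjusted"] = bh_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["p_adjusted"] < alpha
    return df


def dmr_differential_score(
    metric_table: pd.DataFrame,
    metric: str,
    group_a: Sequence[str],
    group_b: Sequence[str],
    scale_factor: float = 1.0,
) -> pd.Series:
    """Per-region (mean over group A) - (mean over group B), scaled.

    Means ignore missing values; a region missing in an entire group scores
    NaN.  ``scale_factor=2`` puts an MHL differential (range 0-1 per group)
    on the MPCI differential scale (range 0-2).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    X = assemble_features(metric_table, metric)
    mean_a = X.loc[X.index.intersection(group_a)].mean(axis=0)
    mean_b = X.loc[X.index.intersection(group_b)].mean(axis=0)
    return (mean_a - mean_b) * scale_factor


def rank_top_k(scores: pd.Series, k: int) -> list[str]:
    """Top-k region ids by descending score; ties keep input order."""
    s = scores.dropna()
    if k > len(s):
        raise ValueError(f"k={k} exceeds {len(s)} scored regions")
    order = s.sort_values(ascending=False, kind="stable")
    return list(order.index[:k])


def top_k_intersection(list_a: Sequence[str], list_b: Sequence[str]) -> int:
    return len(set(list_a) & set(list_b))


def quadrant_partition(
    scores_a: pd.Series,
    scores_b: pd.Series,
    threshold_a: float,
    threshold_b: float,
) -> dict[str, list[str]]:
    """Split regions by (A high/low) x (B high/low); boundaries count low.

    Quadrant names follow the high-A/low-B = "region1", high/high =
    "region2", low/low = "region3", low-A/high-B = "region4" convention.
    """
    common = scores_a.index.intersection(scores_b.index)
    out: dict[str, list[str]] = {"region1": [], "region2": [], "region3": [], "region4": []}
    for rid in common:
        a_high = scores_a[rid] > threshold_a
        b_high = scores_b[rid] > threshold_b
        if a_high and not b_high:
            out["region1"].append(rid)
        elif a_high and b_high:
            out["region2"].append(rid)
        elif not a_high and not b_high:
            out["region3"].append(rid)
        else:
            out["region4"].append(rid)
    return out
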