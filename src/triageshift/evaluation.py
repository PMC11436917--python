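"""Metrics, bootstrap confidence intervals, paired-bootstrap comparison,
and subgroup error analysis.

Point estimates come with 95% percentile confidence intervals from 1000
seeded bootstrap resamples of the test set.  Two models are compared with a
*paired* bootstrap: the same resample indices drive both models in each of
the 1000 pairs, and the p-value for "A better than B" is the add-one-
smoothed fraction of pairs in which B does at least as well as A (ties
count against rejection).

AUROC is the Mann-Whitney pairwise ranking probability (ties count 1/2);
AUPRC is the step-wise precision envelope (average precision, no
interpolation).  PPV and NPV are reported as ``nan`` (not 0) when their
confusion-cell denominator is empty, and they are prevalence-dependent by
construction — a fact the subgroup and cross-site analyses rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .exceptions import MetricError, SchemaError


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: tuple[str, ...] = ()


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> ConfusionMetrics:
    """Confusion-table ratios at ``threshold`` (score >= threshold is positive).

    A ratio with an empty denominator is reported as ``nan`` and named in
    ``undefined`` rather than silently coerced to 0.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))

    undefined = []
    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    return ConfusionMetrics(
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        undefined=tuple(undefined),
    )


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve = P(score_pos > score_neg) + P(tie)/2.

    Computed as the normalized Mann-Whitney U statistic from average ranks
    (exactly the trapezoidal ROC area, with ties counted 1/2); this form is
    much faster inside the bootstrap loops than generic curve construction.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise MetricError("AUROC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step-wise precision envelope)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise MetricError("AUPRC requires both classes")
    return float(average_precision_score(labels, scores))


@dataclass(frozen=True)
class MetricCI:
    metric: str
    point: float
    ci_lower: float
    ci_upper: float
    B: int
    seed: int
    n_redrawn: int = 0  # single-class resamples redrawn


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    scores: np.ndarray,
    labels: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    metric_name: str = "metric",
) -> MetricCI:
    """Point estimate + 95% percentile CI from B seeded row resamples.

    Resamples are drawn with replacement at the original size; a resample
    containing a single label class is redrawn (the count is logged in the
    result).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if B < 1:
        raise ValueError(f"B={B} must be >= 1")
    point = metric_fn(scores, labels)
    rng = np.random.default_rng(seed)
    n = len(scores)
    values = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            lb = labels[idx]
            if lb.min() != lb.max():
                break
            n_redrawn += 1
        values[b] = metric_fn(scores[idx], lb)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return MetricCI(
        metric=metric_name, point=float(point), ci_lower=float(lo),
        ci_upper=float(hi), B=B, seed=seed, n_redrawn=n_redrawn,
    )


@dataclass(frozen=True)
class MetricReport:
    """All six evaluation metrics with bootstrap CIs, plus cohort prevalence."""

    metrics: dict[str, MetricCI]
    prevalence: float
    threshold: float
    B: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": m.metric, "point": m.point,
             "ci_lower": m.ci_lower, "ci_upper": m.ci_upper, "B": m.B}
            for m in self.metrics.values()
        ]
        return pd.DataFrame(rows).set_index("metric")


def evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    B: int = 1000,
    seed: int = 0,
) -> MetricReport:
    """Full metric report: sensitivity/specificity/PPV/NPV/AUROC/AUPRC with CIs."""
    labels = np.asarray(labels, dtype=int)

    def at_threshold(attr):
        def fn(s, l):
            return getattr(confusion_metrics(s, l, threshold), attr)
        return fn

    metric_fns = {
        "sensitivity": at_threshold("sensitivity"),
        "specificity": at_threshold("specificity"),
        "ppv": at_threshold("ppv"),
        "npv": at_threshold("npv"),
        "auroc": auroc,
        "auprc": auprc,
    }
    metrics = {
        name: bootstrap_ci(fn, scores, labels, B=B, seed=seed, metric_name=name)
        for name, fn in metric_fns.items()
    }
    return MetricReport(
        metrics=metrics,
        prevalence=float(labels.mean()),
        threshold=threshold, B=B, seed=seed,
    )


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    model_a: str
    model_b: str
    B: int
    p_value: float
    direction: str  # "a_better" | "b_better" | "tied"
    point_a: float
    point_b: float


def compare_models(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    metric_fn: Callable[[np.ndarray, np.ndarray], float] = auroc,
    B: int = 1000,
    seed: int = 0,
    metric_name: str = "auroc",
    model_a: str = "A",
    model_b: str = "B",
) -> ComparisonResult:
    """Paired-bootstrap test of "A better than B" on a shared test set.

    Each of the B resamples uses the *same* row indices for both models;
    p = (1 + #{resamples where metric_B >= metric_A}) / (B + 1), so ties
    count against rejection and p lies in (0, 1].
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise SchemaError(
            f"length mismatch: scores_a={len(scores_a)}, scores_b={len(scores_b)}, "
            f"labels={len(labels)}"
        )
    rng = np.random.default_rng(seed)
    n = len(labels)
    b_wins = 0
    for _ in range(B):
        while True:
            idx = rng.integers(0, n, n)
            lb = labels[idx]
            if lb.min() != lb.max():
                break
        if metric_fn(scores_b[idx], lb) >= metric_fn(scores_a[idx], lb):
            b_wins += 1
    point_a = metric_fn(scores_a, labels)
    point_b = metric_fn(scores_b, labels)
    direction = (
        "a_better" if point_a > point_b else "b_better" if point_b > point_a else "tied"
    )
    return ComparisonResult(
        metric=metric_name, model_a=model_a, model_b=model_b, B=B,
        p_value=(1 + b_wins) / (B + 1), direction=direction,
        point_a=float(point_a), point_b=float(point_b),
    )


def subgroup_error_analysis(
    cohort: pd.DataFrame,
    scores: np.ndarray,
    threshold: float,
    feature: str,
    bins: int = 10,
) -> pd.DataFrame:
    """Distribution of a feature within each confusion cell (TP/FP/TN/FN).

    Returns, per cell: n, median, Q1, Q3 and histogram counts over shared
    bins — the device used to ask, e.g., whether false negatives concentrate
    among low white-cell-count patients.  Empty cells are reported with
    n = 0 and blank statistics.
    """
    if feature not in cohort.columns:
        raise SchemaError(f"feature {feature!r} absent from cohort")
    scores = np.asarray(scores, dtype=float)
    labels = cohort["label"].to_numpy(dtype=int)
    pred = scores >= threshold
    cells = {
        "TP": pred & (labels == 1),
        "FP": pred & (labels == 0),
        "TN": ~pred & (labels == 0),
        "FN": ~pred & (labels == 1),
    }
    values = cohort[feature].to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    edges = (
        np.histogram_bin_edges(finite, bins=bins) if len(finite) else np.linspace(0, 1, bins + 1)
    )
    rows = []
    for cell, mask in cells.items():
        v = values[mask]
        v = v[np.isfinite(v)]
        if len(v) == 0:
            rows.append({"cell": cell, "n": 0, "median": np.nan, "q1": np.nan,
                         "q3": np.nan, "histogram": [0] * bins})
        else:
            rows.append({
                "cell": cell, "n": len(v),
                "median": float(np.median(v)),
                "q1": float(np.quantile(v, 0.25)),
                "q3": float(np.quantile(v, 0.75)),
                "histogram": np.histogram(v, bins=edges)[0].tolist(),
            })
    return pd.DataFrame(rows).set_index("cell")


def report_to_csv(report: MetricReport, path) -> None:
    """Flat CSV of a metric report, suitable for plotting."""
    frame = report.to_frame()
    frame["prevalence"] = report.prevalence
    frame["threshold"] = report.threshold
    frame.to_csv(path)
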