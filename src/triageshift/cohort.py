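"""Cohort assembly: age-matched controls, temporal splits, cohort contrasts.

Two devices from the study design live here.  First, because early-pandemic
testing left negative labels uncertain, the training cohort is built by
pairing each PCR-confirmed positive presentation with a fixed number of
age-matched pre-pandemic controls (default 20:1, which engineers a cohort
prevalence of 1/21 ~ 4.76%, close to the ~5% observed at general emergency
departments).  Second, site-local model adaptation uses a temporal split:
the earliest 40% of presentations (20% adaptation training + 20% threshold
calibration) with prospective validation on the remaining 60%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, SizingError
from .schema import DEFAULT_SCHEMA, FeatureSchema


@dataclass(frozen=True)
class SplitSpec:
    """Temporal split fractions, earliest-first (adapt_train, adapt_threshold, test)."""

    fractions: tuple[float, float, float] = (0.2, 0.2, 0.6)

    def __post_init__(self):
        if any(f < 0 for f in self.fractions):
            raise ValueError(f"fractions {self.fractions} must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions {self.fractions} must sum to 1")


@dataclass(frozen=True)
class MatchSpec:
    """Control-matching specification: ``ratio`` controls per positive, matched on age."""

    ratio: int = 20
    match_variable: str = "age"
    replacement: bool = False

    def __post_init__(self):
        if int(self.ratio) != self.ratio or self.ratio < 1:
            raise ValueError(f"ratio {self.ratio} must be an integer >= 1")


def match_controls(
    positives: pd.DataFrame,
    control_pool: pd.DataFrame,
    spec: MatchSpec = MatchSpec(),
    seed: int = 0,
) -> pd.DataFrame:
    """Pair each positive presentation with ``ratio`` nearest-age controls.

    Greedy per positive in input order; each control is the available pool
    member with smallest absolute age difference, removed from the pool once
    used (without replacement).  Ties in age distance are broken by a seeded
    random choice.  The returned cohort is positives + selected controls, so
    its prevalence is exactly ``1 / (ratio + 1)``.
    """
    if (control_pool["label"] != 0).any():
        raise DataError("control_pool contains rows with label != 0")
    n_needed = spec.ratio * len(positives)
    if not spec.replacement and len(control_pool) < n_needed:
        raise SizingError(
            f"control pool too small: need {n_needed} controls "
            f"({spec.ratio} x {len(positives)} positives), have {len(control_pool)}"
        )
    rng = np.random.default_rng(seed)
    pool_ages = control_pool[spec.match_variable].to_numpy(dtype=float)
    available = np.ones(len(control_pool), dtype=bool)
    chosen: list[int] = []
    for age in positives[spec.match_variable].to_numpy(dtype=float):
        dist_base = np.abs(pool_ages - age)
        for _ in range(spec.ratio):
            dist = dist_base if spec.replacement else np.where(available, dist_base, np.inf)
            best = dist.min()
            ties = np.flatnonzero(dist == best)
            pick = ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]
            chosen.append(pick)
            if not spec.replacement:
                available[pick] = False
    controls = control_pool.iloc[chosen]
    return pd.concat([positives, controls], ignore_index=True)


def temporal_split(
    cohort: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split earliest-first into (adapt_train, adapt_threshold, test).

    Rows are stably sorted by timestamp (input order breaks ties); the first
    ``floor(f1 * n)`` rows go to adaptation training, the next
    ``floor(f2 * n)`` to threshold calibration, and the remainder to test.
    The partition is exhaustive and disjoint.
    """
    n = len(cohort)
    if n == 0:
        raise SizingError("cannot split an empty cohort")
    ordered = cohort.sort_values("timestamp", kind="stable")
    f1, f2, _ = spec.fractions
    n1 = math.floor(f1 * n)
    n2 = math.floor(f2 * n)
    return (
        ordered.iloc[:n1],
        ordered.iloc[n1 : n1 + n2],
        ordered.iloc[n1 + n2 :],
    )


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def prevalence(cohort: pd.DataFrame) -> float:
    """Percentage of positive labels, reported to 3 significant figures."""
    if len(cohort) == 0:
        raise SizingError("prevalence of an empty cohort is undefined")
    return _round_sig(100.0 * cohort["label"].sum() / len(cohort))


def compare_prevalence(cohort_a: pd.DataFrame, cohort_b: pd.DataFrame) -> float:
    """Two-sided Fisher exact p-value for the prevalence contrast between cohorts."""
    if len(cohort_a) == 0 or len(cohort_b) == 0:
        raise SizingError("both cohorts must be non-empty")
    table = [
        [int(cohort_a["label"].sum()), int((cohort_a["label"] == 0).sum())],
        [int(cohort_b["label"].sum()), int((cohort_b["label"] == 0).sum())],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def compare_feature_medians(cohorts: list[pd.DataFrame], feature: str) -> float:
    """Kruskal-Wallis p-value for a feature's location across >= 2 cohorts.

    Missing values are excluded.  The ties-only degenerate case (every value
    identical) is reported as p = 1.0 rather than an error.
    """
    if len(cohorts) < 2:
        raise DataError("need at least two cohorts to compare")
    groups = []
    for i, cohort in enumerate(cohorts):
        values = cohort[feature].dropna().to_numpy()
        if len(values) == 0:
            raise DataError(f"feature {feature!r} is all-missing in cohort {i}")
        groups.append(values)
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.kruskal(*groups).pvalue)
    except ValueError:  # all values identical
        return 1.0
    return 1.0 if np.isnan(p) else p


def summarize_features(
    cohort: pd.DataFrame, schema: FeatureSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Per-feature n, median, Q1, Q3 (linear-interpolation quantiles).

    All-missing features are reported with n = 0 and blank (NaN) statistics.
    """
    rows = []
    for feat in schema.names:
        if feat not in cohort.columns:
            continue
        values = cohort[feat].dropna()
        if len(values) == 0:
            rows.append({"feature": feat, "n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan})
        else:
            rows.append({
                "feature": feat,
                "n": len(values),
                "median": values.quantile(0.5, interpolation="linear"),
                "q1": values.quantile(0.25, interpolation="linear"),
                "q3": values.quantile(0.75, interpolation="linear"),
            })
    return pd.DataFrame(rows).set_index("feature")
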