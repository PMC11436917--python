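"""Preprocessing: unit harmonization, standardization, median imputation,
and kNN+GATS completion of wholly missing feature columns.

The pipeline order is fixed and documented: harmonize units -> impute
population medians on the raw scale (so the medians stay unit-interpretable)
-> standardize to zero mean / unit variance with statistics fitted on
training data only.

GATS (Geometrically-Aggregated Training Samples) fills feature columns that
are entirely absent at a site: each target row is matched to its *k* nearest
donor rows (Euclidean distance on standardized shared features), and the
missing columns are filled with a convex combination of the donors' values.
Because the combination is convex, every filled cell lies within the
componentwise [min, max] of its donors, so the completed data stay inside
the donor data space; and because a convex combination commutes with the
affine standardization map, combining on the standardized scale and
inverting equals combining the raw donor values directly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import pairwise_distances

from .exceptions import ConfigurationError, DataError, SizingError
from .schema import DEFAULT_SCHEMA, UNIT_CONVERSIONS, FeatureSchema

# ---------------------------------------------------------------------------
# Unit harmonization
# ---------------------------------------------------------------------------

def canonical_units(schema: FeatureSchema = DEFAULT_SCHEMA) -> dict[str, str]:
    """Declared-unit map asserting every feature is already canonical."""
    return {f: schema.unit(f) for f in schema.names}


def harmonize_units(
    cohort: pd.DataFrame,
    declared_units: dict[str, str],
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> pd.DataFrame:
    """Convert every present feature into the schema's canonical unit.

    ``declared_units`` maps feature name -> the unit the site records it in.
    Every feature column with at least one non-missing value must be declared;
    a declaration equal to the canonical unit is the identity.
    """
    out = cohort.copy()
    for feat in schema.names:
        if feat not in out.columns or out[feat].notna().sum() == 0:
            continue
        if feat not in declared_units:
            raise ConfigurationError(f"no declared unit for present feature {feat!r}")
        declared = declared_units[feat]
        if declared == schema.unit(feat):
            continue
        conv = UNIT_CONVERSIONS.get((feat, declared))
        if conv is None:
            raise ConfigurationError(
                f"unknown unit {declared!r} for feature {feat!r} "
                f"(canonical: {schema.unit(feat)!r})"
            )
        out[feat] = conv(out[feat]) if callable(conv) else out[feat] * conv
    return out


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizationStats:
    """Training means and population standard deviations (ddof = 0)."""

    means: dict[str, float]
    sds: dict[str, float]
    fitted_on: str = ""

    @property
    def features(self) -> list[str]:
        return list(self.means)


def fit_standardizer(
    train: pd.DataFrame, features: list[str], fitted_on: str = ""
) -> StandardizationStats:
    """Fit per-feature mean/sd on training data (non-missing values only)."""
    means, sds = {}, {}
    for feat in features:
        values = train[feat].dropna().to_numpy(dtype=float)
        if len(values) == 0:
            raise DataError(f"feature {feat!r} has no non-missing training values")
        sd = float(np.std(values, ddof=0))
        if sd == 0.0:
            raise DataError(f"feature {feat!r} is constant in training data")
        means[feat] = float(np.mean(values))
        sds[feat] = sd
    return StandardizationStats(means=means, sds=sds, fitted_on=fitted_on)


def apply_standardizer(cohort: pd.DataFrame, stats: StandardizationStats) -> pd.DataFrame:
    out = cohort.copy()
    for feat in stats.features:
        out[feat] = (out[feat] - stats.means[feat]) / stats.sds[feat]
    return out


def invert_standardizer(cohort: pd.DataFrame, stats: StandardizationStats) -> pd.DataFrame:
    out = cohort.copy()
    for feat in stats.features:
        out[feat] = out[feat] * stats.sds[feat] + stats.means[feat]
    return out


# ---------------------------------------------------------------------------
# Median imputation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImputationMedians:
    """Population medians fitted on training data, one per imputable feature."""

    medians: dict[str, float]
    fitted_on: str = ""


def fit_imputer(
    train: pd.DataFrame, features: list[str], fitted_on: str = ""
) -> ImputationMedians:
    """Compute training medians; features missing everywhere are omitted."""
    medians = {}
    for feat in features:
        values = train[feat].dropna()
        if len(values) > 0:
            medians[feat] = float(values.median())
    return ImputationMedians(medians=medians, fitted_on=fitted_on)


def median_impute(
    cohort: pd.DataFrame, medians: ImputationMedians, features: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing cells with training medians; return (filled, missingness mask).

    The mask marks the cells that were imputed, for audit.  A feature that is
    missing in the cohort but has no fitted median is an error.
    """
    features = features if features is not None else list(medians.medians)
    out = cohort.copy()
    mask = pd.DataFrame(False, index=cohort.index, columns=cohort.columns)
    for feat in features:
        if feat not in out.columns:
            continue
        missing = out[feat].isna()
        if not missing.any():
            continue
        if feat not in medians.medians:
            raise DataError(
                f"feature {feat!r} has missing cells but no fitted median "
                f"(all-missing in training data)"
            )
        out.loc[missing, feat] = medians.medians[feat]
        mask.loc[missing, feat] = True
    return out, mask


# ---------------------------------------------------------------------------
# kNN matching and GATS fill
# ---------------------------------------------------------------------------

def knn_match(
    target_rows: pd.DataFrame,
    source: pd.DataFrame,
    shared_features: list[str],
    k: int,
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray]:
    """For each target row, the k nearest source rows on shared features.

    Returns ``(indices, distances)``, each of shape ``(n_target, k)``,
    ascending by distance; ties broken by source row order (stable sort).
    ``shared_features`` must be non-missing in both tables.
    """
    if k > len(source):
        raise SizingError(f"k={k} exceeds source size {len(source)}")
    if k < 1:
        raise SizingError(f"k={k} must be >= 1")
    X_t = target_rows[shared_features].to_numpy(dtype=float)
    X_s = source[shared_features].to_numpy(dtype=float)
    if np.isnan(X_t).any() or np.isnan(X_s).any():
        raise DataError("shared_features contain missing values; impute first")
    dist = pairwise_distances(X_t, X_s, metric=metric)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    return order, np.take_along_axis(dist, order, axis=1)


@dataclass
class GATSFill:
    """kNN+GATS fill configuration and, after running, the audit record.

    ``weight_scheme``: ``uniform`` (1/k each), ``inverse-distance``
    (w_i proportional to 1/(d_i + eps); exact matches absorb all weight), or
    ``random-convex`` (a seeded flat-Dirichlet draw per target row).
    ``records`` holds, per target row: neighbor source indices, the convex
    weight vector, and the filled feature names.
    """

    k: int = 10
    distance_metric: str = "euclidean"
    weight_scheme: str = "uniform"
    seed: int = 0
    records: list[dict] = field(default_factory=list)

    _SCHEMES = ("uniform", "inverse-distance", "random-convex")

    def validate(self) -> None:
        if self.weight_scheme not in self._SCHEMES:
            raise ConfigurationError(
                f"unknown weight_scheme {self.weight_scheme!r}; choose from {self._SCHEMES}"
            )
        if self.k < 1:
            raise ConfigurationError(f"k={self.k} must be >= 1")


def _convex_weights(
    scheme: str, distances: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One convex weight vector per target row; shape matches ``distances``."""
    n, k = distances.shape
    if scheme == "uniform":
        w = np.full((n, k), 1.0 / k)
    elif scheme == "inverse-distance":
        exact = distances == 0.0
        with np.errstate(divide="ignore"):
            w = 1.0 / (distances + 1e-12)
        # rows with exact matches give all weight to the zero-distance donors
        any_exact = exact.any(axis=1)
        w[any_exact] = exact[any_exact].astype(float)
        w = w / w.sum(axis=1, keepdims=True)
    else:  # random-convex
        w = rng.dirichlet(np.ones(k), size=n)
    if (w < 0).any() or np.abs(w.sum(axis=1) - 1.0).max() > 1e-9:
        raise AssertionError("internal invariant violated: weight vector not convex")
    return w


def gats_fill(
    target: pd.DataFrame,
    source: pd.DataFrame,
    missing_features: list[str],
    config: GATSFill | None = None,
    shared_features: list[str] | None = None,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> tuple[pd.DataFrame, GATSFill]:
    """Fill wholly missing target columns with convex donor combinations.

    Each target row is matched to its ``config.k`` nearest source rows by
    Euclidean distance on ``shared_features`` standardized with
    source-fitted statistics (defaults to the schema's matched set); its
    ``missing_features`` are then set to the convex combination of the
    donors' values under ``config.weight_scheme``.  Returns the completed
    table and the config with its per-row audit records populated.
    """
    config = config or GATSFill()
    config.validate()
    if not missing_features:
        warnings.warn("gats_fill called with no missing_features; returning input unchanged")
        return target.copy(), config
    for feat in missing_features:
        if target[feat].notna().any():
            raise DataError(f"feature {feat!r} is not wholly missing in target")
        if source[feat].isna().any():
            raise DataError(f"feature {feat!r} has missing values in source; impute first")
    shared = shared_features if shared_features is not None else schema.matched

    stats = fit_standardizer(source, shared, fitted_on="gats-source")
    idx, dist = knn_match(
        apply_standardizer(target, stats),
        apply_standardizer(source, stats),
        shared,
        config.k,
        metric=config.distance_metric,
    )
    rng = np.random.default_rng(config.seed)
    weights = _convex_weights(config.weight_scheme, dist, rng)

    out = target.copy()
    donor_values = source[missing_features].to_numpy(dtype=float)  # (n_source, m)
    filled = np.einsum("nk,nkm->nm", weights, donor_values[idx])
    out[missing_features] = filled
    config.records = [
        {
            "row": int(target.index[i]),
            "neighbors": [int(source.index[j]) for j in idx[i]],
            "weights": [float(w) for w in weights[i]],
            "filled_features": list(missing_features),
        }
        for i in range(len(target))
    ]
    return out, config


def write_fill_records(config: GATSFill, path) -> None:
    """Serialize fill audit records as JSON lines, one record per target row."""
    with open(path, "w") as fh:
        for record in config.records:
            fh.write(json.dumps(record) + "\n")
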