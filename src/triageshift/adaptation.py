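"""Decision-threshold calibration and the three deployment strategies.

A site that adopts a triage classifier can (i) use the source site's model
*ready-made*, (ii) *transfer-learn* — warm-start the network from the source
weights and update it on the earliest 40% of local presentations (20% for
weight updates, 20% for threshold calibration), or (iii) train a *local*
model from scratch on that same 20%.  Prospective validation uses the
remaining 60% of local presentations; external validation uses the entirety
of another site's cohort.

The decision threshold is calibrated by grid search to a target sensitivity
of 0.85 (±0.05) — comparable to PCR's 80-90% and above lateral-flow tests —
choosing, among thresholds inside the band, the one that maximizes
specificity.

Every orchestrated run enforces a leakage guard: the rows used for fitting
or calibration never intersect the rows used for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SplitSpec, temporal_split
from .exceptions import CalibrationError, ConfigurationError, ProtocolError
from .models import ModelBundle, fine_tune, predict_scores, train_model
from .preprocess import (
    apply_standardizer,
    fit_imputer,
    fit_standardizer,
    gats_fill,
    median_impute,
)
from .schema import DEFAULT_SCHEMA, FeatureSchema

# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationSpec:
    """Grid-search calibration target: sensitivity ``target`` within ``±band``."""

    target_sensitivity: float = 0.85
    band: float = 0.05
    grid_resolution: float = 0.001

    def __post_init__(self):
        if not 0.0 < self.target_sensitivity < 1.0:
            raise ConfigurationError(
                f"target_sensitivity {self.target_sensitivity} outside (0, 1)"
            )
        if self.band < 0:
            raise ConfigurationError(f"band {self.band} must be >= 0")


@dataclass(frozen=True)
class CalibrationResult:
    """Selected threshold with the sensitivity/specificity it attains on the
    calibration data, and whether the target band was achievable."""

    threshold: float
    sensitivity: float
    specificity: float
    in_band: bool
    note: str = ""


def calibrate_threshold(
    scores: np.ndarray, labels: np.ndarray, spec: CalibrationSpec = CalibrationSpec()
) -> CalibrationResult:
    """Grid-search the decision threshold for the target sensitivity band.

    Scans thresholds 0, step, 2*step, ..., 1.  Among thresholds whose
    sensitivity lies inside [target - band, target + band], returns the one
    maximizing specificity (smallest such threshold on ties).  If the band is
    unachievable, falls back to the threshold whose sensitivity is closest to
    the target, preferring the higher sensitivity on ties, and flags the
    decision path in ``note``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    if not pos.any():
        raise CalibrationError("no positive labels; sensitivity is undefined")
    neg = ~pos

    step = spec.grid_resolution
    grid = np.arange(0.0, 1.0 + step / 2, step)
    pred = scores[:, None] >= grid[None, :]  # (n, n_grid)
    sens = pred[pos].mean(axis=0)
    if neg.any():
        spec_ = (~pred[neg]).mean(axis=0)
    else:
        spec_ = np.ones_like(sens)

    in_band = np.abs(sens - spec.target_sensitivity) <= spec.band + 1e-12
    if in_band.any():
        idx_band = np.flatnonzero(in_band)
        best = idx_band[np.argmax(spec_[idx_band])]  # argmax -> smallest index on ties
        return CalibrationResult(
            threshold=float(grid[best]),
            sensitivity=float(sens[best]),
            specificity=float(spec_[best]),
            in_band=True,
            note="band achievable; specificity-maximizing threshold selected",
        )
    gap = np.abs(sens - spec.target_sensitivity)
    best_gap = gap.min()
    candidates = np.flatnonzero(gap <= best_gap + 1e-12)
    best = candidates[np.argmax(sens[candidates])]
    return CalibrationResult(
        threshold=float(grid[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec_[best]),
        in_band=False,
        note="target band unachievable; closest-sensitivity fallback used",
    )


# ---------------------------------------------------------------------------
# Experiment plans and orchestration
# ---------------------------------------------------------------------------

STRATEGIES = ("ready_made", "transfer", "local")


@dataclass
class ExperimentPlan:
    """One head-to-head deployment experiment."""

    strategy: str
    training_site: str
    adaptation_site: str | None = None
    external_site: str | None = None
    feature_set: str = "reduced"  # reduced(14) | comprehensive(25)
    split: SplitSpec = field(default_factory=SplitSpec)
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    model_kind: str = "neural_net"
    recalibrate: bool = False  # ready_made: recalibrate threshold at the target site
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(
                f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}"
            )
        if self.strategy in ("transfer", "local") and self.adaptation_site is None:
            raise ConfigurationError(f"strategy {self.strategy!r} requires an adaptation_site")
        if self.feature_set not in ("reduced", "comprehensive"):
            raise ConfigurationError(f"unknown feature_set {self.feature_set!r}")


@dataclass
class EvalSet:
    """Scores and labels for one evaluation cohort, plus its row ids."""

    scores: np.ndarray
    labels: np.ndarray
    row_ids: set


@dataclass
class StrategyResult:
    plan: ExperimentPlan
    bundle: ModelBundle
    calibration: CalibrationResult | None
    evaluations: dict[str, EvalSet]
    fitted_row_ids: set


def preprocess_with_bundle(bundle: ModelBundle, cohort: pd.DataFrame) -> pd.DataFrame:
    """Impute and standardize a cohort with the bundle's own statistics."""
    out = cohort
    if bundle.medians is not None:
        out, _ = median_impute(out, bundle.medians, features=bundle.features)
    if bundle.stats is not None:
        out = apply_standardizer(out, bundle.stats)
    return out


def score_cohort(bundle: ModelBundle, cohort: pd.DataFrame) -> np.ndarray:
    """Preprocess with the bundle's stats and score; one value in [0,1] per row."""
    return predict_scores(bundle, preprocess_with_bundle(bundle, cohort))


def fit_site_model(
    train: pd.DataFrame,
    features: list[str],
    kind: str = "neural_net",
    seed: int = 0,
    hyperparams: dict | None = None,
    cohort_id: str = "",
) -> ModelBundle:
    """Fit imputation medians + standardizer on ``train``, then train a model.

    Median imputation runs on the raw scale before standardization; the
    fitted statistics travel with the returned bundle.
    """
    medians = fit_imputer(train, features, fitted_on=cohort_id)
    imputed, _ = median_impute(train, medians, features=features)
    stats = fit_standardizer(imputed, features, fitted_on=cohort_id)
    prepared = apply_standardizer(imputed, stats)
    return train_model(
        kind, prepared, features, hyperparams=hyperparams, seed=seed,
        stats=stats, medians=medians, provenance={"cohort_id": cohort_id},
    )


def train_source_model(
    cohort: pd.DataFrame,
    features: list[str],
    kind: str = "neural_net",
    seed: int = 0,
    calibration: CalibrationSpec = CalibrationSpec(),
    hyperparams: dict | None = None,
    cohort_id: str = "source",
) -> tuple[ModelBundle, CalibrationResult]:
    """Develop a source-site model: train on the earliest 60%, calibrate on
    the next 20% (the final 20% stays untouched as a source-side holdout)."""
    dev, cal, _ = temporal_split(cohort, SplitSpec((0.6, 0.2, 0.2)))
    bundle = fit_site_model(dev, features, kind, seed, hyperparams, cohort_id)
    result = calibrate_threshold(
        score_cohort(bundle, cal), cal["label"].to_numpy(), calibration
    )
    bundle.threshold = result.threshold
    return bundle, result


def _row_ids(frame: pd.DataFrame) -> set:
    """Globally unique row identifiers: (site, positional index) pairs."""
    sites = frame["site_id"].astype(str) if "site_id" in frame.columns else "?"
    return set(zip(sites, frame.index))


def _guard(fitted: set, evaluations: dict[str, EvalSet]) -> None:
    for name, ev in evaluations.items():
        overlap = fitted & ev.row_ids
        if overlap:
            raise ProtocolError(
                f"leakage: {len(overlap)} rows shared between fitting/calibration "
                f"and evaluation set {name!r}"
            )


def complete_comprehensive(
    target: pd.DataFrame,
    donor: pd.DataFrame,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    k: int = 10,
    weight_scheme: str = "uniform",
    seed: int = 0,
) -> pd.DataFrame:
    """GATS-complete a reduced-schema site up to the comprehensive feature set.

    The donor pool must exclude the model-training cohort so that training
    and test data stay independent.  Donor rows are median-imputed with
    donor-fitted medians before matching and combination.
    """
    from .preprocess import GATSFill  # local import to keep module surfaces flat

    missing = [f for f in schema.uk_only if target[f].isna().all()]
    if not missing:
        return target.copy()
    medians = fit_imputer(donor, schema.comprehensive, fitted_on="donor")
    donor_complete, _ = median_impute(donor, medians, features=schema.comprehensive)
    tgt = target.copy()
    tgt_imputed, _ = median_impute(tgt, medians, features=schema.matched)
    tgt[schema.matched] = tgt_imputed[schema.matched]
    filled, _ = gats_fill(
        tgt, donor_complete, missing,
        config=GATSFill(k=k, weight_scheme=weight_scheme, seed=seed),
        shared_features=schema.matched, schema=schema,
    )
    # keep the original (pre-imputation) matched values; only the wholly
    # missing columns gain donor-derived values
    filled[schema.matched] = target[schema.matched]
    return filled


def run_strategy(
    plan: ExperimentPlan,
    cohorts: dict[str, pd.DataFrame],
    source_bundle: ModelBundle | None = None,
    donor: pd.DataFrame | None = None,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    hyperparams: dict | None = None,
) -> StrategyResult:
    """Execute one deployment strategy end to end.

    ``cohorts`` maps site id -> presentation table (raw scale, harmonized
    units).  For ``transfer``/``ready_made`` a trained ``source_bundle`` may
    be supplied; otherwise one is trained from the ``training_site`` cohort.
    For the comprehensive feature set at a reduced-schema site, ``donor``
    supplies the GATS completion pool (it must exclude the training cohort).
    """
    features = schema.matched if plan.feature_set == "reduced" else schema.comprehensive
    target_site = plan.adaptation_site or plan.external_site
    fitted: set = set()

    def _maybe_complete(df: pd.DataFrame) -> pd.DataFrame:
        if plan.feature_set == "comprehensive" and any(
            df[f].isna().all() for f in schema.uk_only
        ):
            if donor is None:
                raise ConfigurationError(
                    "comprehensive feature set at a reduced-schema site requires a donor pool"
                )
            return complete_comprehensive(df, donor, schema=schema, seed=plan.seed)
        return df

    if plan.strategy in ("ready_made", "transfer") and source_bundle is None:
        source = _maybe_complete(cohorts[plan.training_site])
        source_bundle, _ = train_source_model(
            source, features, plan.model_kind, plan.seed, plan.calibration,
            hyperparams, cohort_id=plan.training_site,
        )
        fitted |= _row_ids(source)  # entire source site is development data

    evaluations: dict[str, EvalSet] = {}

    if plan.strategy == "ready_made":
        target = _maybe_complete(cohorts[target_site])
        cal_result = None
        bundle = source_bundle
        if plan.recalibrate:
            adapt_train, adapt_cal, test = temporal_split(target, plan.split)
            cal_result = calibrate_threshold(
                score_cohort(bundle, adapt_cal), adapt_cal["label"].to_numpy(),
                plan.calibration,
            )
            bundle.threshold = cal_result.threshold
            fitted |= _row_ids(adapt_train) | _row_ids(adapt_cal)
            eval_frames = {"prospective": test}
        else:
            eval_frames = {"full_target": target}
    elif plan.strategy == "transfer":
        target = _maybe_complete(cohorts[plan.adaptation_site])
        adapt_train, adapt_cal, test = temporal_split(target, plan.split)
        prepared = preprocess_with_bundle(source_bundle, adapt_train)
        bundle = fine_tune(source_bundle, prepared, hyperparams, seed=plan.seed)
        cal_result = calibrate_threshold(
            score_cohort(bundle, adapt_cal), adapt_cal["label"].to_numpy(),
            plan.calibration,
        )
        bundle.threshold = cal_result.threshold
        fitted |= _row_ids(adapt_train) | _row_ids(adapt_cal)
        eval_frames = {"prospective": test}
    else:  # local
        target = _maybe_complete(cohorts[plan.adaptation_site])
        adapt_train, adapt_cal, test = temporal_split(target, plan.split)
        bundle = fit_site_model(
            adapt_train, features, plan.model_kind, plan.seed, hyperparams,
            cohort_id=plan.adaptation_site,
        )
        cal_result = calibrate_threshold(
            score_cohort(bundle, adapt_cal), adapt_cal["label"].to_numpy(),
            plan.calibration,
        )
        bundle.threshold = cal_result.threshold
        fitted |= _row_ids(adapt_train) | _row_ids(adapt_cal)
        eval_frames = {"prospective": test}

    if plan.external_site and plan.external_site != target_site:
        eval_frames["external"] = _maybe_complete(cohorts[plan.external_site])

    for name, frame in eval_frames.items():
        evaluations[name] = EvalSet(
            scores=score_cohort(bundle, frame),
            labels=frame["label"].to_numpy(dtype=int),
            row_ids=_row_ids(frame),
        )
    _guard(fitted, evaluations)
    return StrategyResult(
        plan=plan, bundle=bundle, calibration=cal_result,
        evaluations=evaluations, fitted_row_ids=fitted,
    )
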