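"""Classifier families and the deployable model bundle.

Three architectures are compared throughout the analysis: logistic
regression (the clinical-community baseline), gradient-boosted trees
(strong tabular performance; can consume missing values natively), and a
deliberately simple fully connected network — one hidden ReLU layer and a
sigmoid output, trained with the Adam optimizer.  Only the network supports
transfer learning: its weights can be carried to a new site and updated on
a small local sample (the tree ensemble requires the full dataset, and the
linear model has no useful notion of warm-started fine-tuning).

The network is implemented directly in numpy because the adaptation
protocol needs exact weight-level control: warm starts from a source
bundle, a zero-epoch identity guarantee, a reduced fine-tuning learning
rate, and optional freezing of the hidden layer.

A :class:`ModelBundle` packages the fitted classifier together with the
standardization statistics, imputation medians, feature list, and (once
calibrated) decision threshold — the unit one would actually deploy.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.linear_model import LogisticRegression

from .exceptions import (
    DataError,
    SchemaError,
    TrainingError,
    UnsupportedOperationError,
)
from .preprocess import ImputationMedians, StandardizationStats

MODEL_KINDS = ("logistic", "boosted_trees", "neural_net")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLPBinaryClassifier:
    """One-hidden-layer ReLU network with sigmoid output, trained by Adam.

    Mini-batch binary cross-entropy; optional early stopping on the loss of
    a held-out validation fraction with best-weight restoration.  Fully
    deterministic given the seed.  ``init_weights`` warm-starts training
    from an existing parameter set (the transfer-learning path); with
    ``epochs=0`` the warm-started weights are returned untouched.
    """

    def __init__(
        self,
        hidden: int = 16,
        lr: float = 1e-3,
        batch_size: int = 64,
        epochs: int = 200,
        early_stopping: bool = True,
        validation_fraction: float = 0.1,
        patience: int = 10,
        freeze_hidden: bool = False,
        seed: int = 0,
    ):
        self.hidden = hidden
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.freeze_hidden = freeze_hidden
        self.seed = seed
        self.weights_: dict[str, np.ndarray] | None = None

    # -- parameter plumbing -------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.weights_.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        self.weights_ = {k: np.asarray(v, dtype=float).copy() for k, v in weights.items()}

    def _init_weights(self, n_features: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        return {
            "W1": rng.normal(0.0, np.sqrt(2.0 / n_features), (n_features, self.hidden)),
            "b1": np.zeros(self.hidden),
            "W2": rng.normal(0.0, np.sqrt(2.0 / self.hidden), (self.hidden, 1)),
            "b2": np.zeros(1),
        }

    # -- forward / loss -----------------------------------------------------
    def _forward(self, X: np.ndarray, w: dict[str, np.ndarray]):
        z1 = X @ w["W1"] + w["b1"]
        a1 = np.maximum(z1, 0.0)
        z2 = (a1 @ w["W2"] + w["b2"]).ravel()
        return z1, a1, _sigmoid(z2)

    @staticmethod
    def _bce(p: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    # -- training -----------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        init_weights: dict[str, np.ndarray] | None = None,
    ) -> "MLPBinaryClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(self.seed)
        w = (
            {k: v.copy() for k, v in init_weights.items()}
            if init_weights is not None
            else self._init_weights(X.shape[1], rng)
        )
        self.weights_ = w
        if self.epochs == 0:
            return self

        use_val = self.early_stopping and len(X) >= 20
        if use_val:
            perm = rng.permutation(len(X))
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X_tr, y_tr = X[tr_idx], y[tr_idx]
        else:
            X_tr, y_tr = X, y

        m = {k: np.zeros_like(v) for k, v in w.items()}
        v_ = {k: np.zeros_like(v) for k, v in w.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_loss, best_w, bad_epochs = np.inf, None, 0
        frozen = {"W1", "b1"} if self.freeze_hidden else set()

        for _ in range(self.epochs):
            order = rng.permutation(len(X_tr))
            for start in range(0, len(X_tr), self.batch_size):
                batch = order[start : start + self.batch_size]
                Xb, yb = X_tr[batch], y_tr[batch]
                z1, a1, p = self._forward(Xb, w)
                dz2 = ((p - yb) / len(Xb))[:, None]
                grads = {
                    "W2": a1.T @ dz2,
                    "b2": dz2.sum(axis=0),
                }
                da1 = dz2 @ w["W2"].T
                dz1 = da1 * (z1 > 0)
                grads["W1"] = Xb.T @ dz1
                grads["b1"] = dz1.sum(axis=0)
                t += 1
                for k in w:
                    if k in frozen:
                        continue
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v_[k] = beta2 * v_[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1**t)
                    vhat = v_[k] / (1 - beta2**t)
                    w[k] = w[k] - self.lr * mhat / (np.sqrt(vhat) + eps)
            if use_val:
                _, _, p_val = self._forward(X_val, w)
                loss = self._bce(p_val, y_val)
                if loss < best_loss - 1e-6:
                    best_loss, bad_epochs = loss, 0
                    best_w = {k: v.copy() for k, v in w.items()}
                else:
                    bad_epochs += 1
                    if bad_epochs >= self.patience:
                        break
        if use_val and best_w is not None:
            w = best_w
        self.weights_ = w
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise TrainingError("network is not fitted")
        _, _, p = self._forward(np.asarray(X, dtype=float), self.weights_)
        return p


@dataclass
class ModelBundle:
    """A deployable unit: classifier + preprocessing stats + threshold."""

    kind: str
    model: Any
    features: list[str]
    stats: StandardizationStats | None = None
    medians: ImputationMedians | None = None
    threshold: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise TrainingError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")
        if self.threshold is not None and not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold {self.threshold} outside [0, 1]")


DEFAULT_HYPERPARAMS = {
    "logistic": {"C": 1.0, "max_iter": 2000},
    "boosted_trees": {
        "n_estimators": 100,
        "max_depth": 3,
        "learning_rate": 0.1,
        "allow_missing": False,
    },
    "neural_net": {
        "hidden": 16,
        "lr": 1e-2,
        "batch_size": 64,
        "epochs": 200,
        "early_stopping": True,
        "validation_fraction": 0.1,
        "patience": 10,
    },
}


def _design_matrix(cohort: pd.DataFrame, features: list[str], allow_missing: bool) -> np.ndarray:
    for feat in features:
        if feat not in cohort.columns:
            raise SchemaError(f"required feature column {feat!r} is absent")
    X = cohort[features].to_numpy(dtype=float)
    if not allow_missing and np.isnan(X).any():
        bad = [f for f in features if cohort[f].isna().any()]
        raise DataError(f"missing values in features {bad}; preprocess first")
    return X


def train_model(
    kind: str,
    train: pd.DataFrame,
    features: list[str],
    hyperparams: dict | None = None,
    seed: int = 0,
    stats: StandardizationStats | None = None,
    medians: ImputationMedians | None = None,
    provenance: dict | None = None,
) -> ModelBundle:
    """Train one classifier on a preprocessed cohort and wrap it as a bundle.

    ``train`` must already be harmonized/imputed/standardized (boosted trees
    may keep missing values when ``allow_missing`` is set).  Labels must
    contain both classes.
    """
    if kind not in MODEL_KINDS:
        raise TrainingError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")
    hp = {**DEFAULT_HYPERPARAMS[kind], **(hyperparams or {})}
    y = train["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    allow_missing = bool(hp.get("allow_missing", False)) and kind == "boosted_trees"
    X = _design_matrix(train, features, allow_missing)

    if kind == "logistic":
        model = LogisticRegression(C=hp["C"], max_iter=hp["max_iter"], random_state=seed)
        model.fit(X, y)
    elif kind == "boosted_trees":
        model = xgb.XGBClassifier(
            n_estimators=hp["n_estimators"],
            max_depth=hp["max_depth"],
            learning_rate=hp["learning_rate"],
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
        model.fit(X, y)
    else:
        model = MLPBinaryClassifier(
            hidden=hp["hidden"],
            lr=hp["lr"],
            batch_size=hp["batch_size"],
            epochs=hp["epochs"],
            early_stopping=hp["early_stopping"],
            validation_fraction=hp["validation_fraction"],
            patience=hp["patience"],
            seed=seed,
        )
        model.fit(X, y)

    prov = {"seed": seed, "hyperparameters": hp, **(provenance or {})}
    return ModelBundle(
        kind=kind, model=model, features=list(features),
        stats=stats, medians=medians, provenance=prov,
    )


def predict_scores(bundle: ModelBundle, cohort: pd.DataFrame) -> np.ndarray:
    """One score in [0, 1] per row; deterministic given the bundle."""
    allow_missing = (
        bundle.kind == "boosted_trees"
        and bool(bundle.provenance.get("hyperparameters", {}).get("allow_missing", False))
    )
    X = _design_matrix(cohort, bundle.features, allow_missing)
    if bundle.kind == "neural_net":
        scores = bundle.model.predict_proba(X)
    else:
        scores = bundle.model.predict_proba(X)[:, 1]
    return np.clip(np.asarray(scores, dtype=float), 0.0, 1.0)


def fine_tune(
    bundle: ModelBundle,
    adapt_train: pd.DataFrame,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> ModelBundle:
    """Warm-start the network from a source bundle and update it locally.

    All weights are updated at the source learning rate for a fixed epoch
    budget; early stopping is off by default because adaptation sets are
    small (a held-out fraction of ~100-250 rows carries almost no signal).
    Pass a smaller ``lr``, ``freeze_hidden=True`` (output layer only), or
    ``early_stopping=True`` to restrict the update.  ``epochs=0`` returns a
    bundle whose scores equal the source's exactly.  Only the network
    supports this operation.
    """
    if bundle.kind != "neural_net":
        raise UnsupportedOperationError(
            f"transfer learning is not supported for kind {bundle.kind!r}"
        )
    source_hp = bundle.provenance.get("hyperparameters", DEFAULT_HYPERPARAMS["neural_net"])
    hp = {**source_hp, "early_stopping": False, **(hyperparams or {})}
    model = MLPBinaryClassifier(
        hidden=bundle.model.hidden,
        lr=hp["lr"],
        batch_size=hp.get("batch_size", 64),
        epochs=hp.get("epochs", 200),
        early_stopping=hp.get("early_stopping", True),
        validation_fraction=hp.get("validation_fraction", 0.1),
        patience=hp.get("patience", 10),
        freeze_hidden=hp.get("freeze_hidden", False),
        seed=seed,
    )
    if hp.get("epochs", 200) == 0:
        model.set_weights(bundle.model.get_weights())
    else:
        y = adapt_train["label"].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise TrainingError("fine-tuning labels contain a single class")
        X = _design_matrix(adapt_train, bundle.features, allow_missing=False)
        model.fit(X, y, init_weights=bundle.model.get_weights())
    prov = {
        "seed": seed,
        "hyperparameters": hp,
        "fine_tuned_from": bundle.provenance.get("cohort_id", "source"),
    }
    return ModelBundle(
        kind="neural_net", model=model, features=list(bundle.features),
        stats=bundle.stats, medians=bundle.medians, provenance=prov,
    )


# ---------------------------------------------------------------------------
# Bundle serialization (versioned JSON archive)
# ---------------------------------------------------------------------------

_ARCHIVE_VERSION = 1


def save_bundle(bundle: ModelBundle, path) -> None:
    """Serialize a bundle (parameters + preprocessing stats + provenance) as JSON."""
    doc: dict[str, Any] = {
        "version": _ARCHIVE_VERSION,
        "kind": bundle.kind,
        "features": bundle.features,
        "threshold": bundle.threshold,
        "provenance": bundle.provenance,
        "stats": None if bundle.stats is None else {
            "means": bundle.stats.means, "sds": bundle.stats.sds,
            "fitted_on": bundle.stats.fitted_on,
        },
        "medians": None if bundle.medians is None else {
            "medians": bundle.medians.medians, "fitted_on": bundle.medians.fitted_on,
        },
    }
    if bundle.kind == "logistic":
        doc["model"] = {
            "coef": bundle.model.coef_.tolist(),
            "intercept": bundle.model.intercept_.tolist(),
            "classes": bundle.model.classes_.tolist(),
            "params": bundle.model.get_params(),
        }
    elif bundle.kind == "boosted_trees":
        doc["model"] = {
            "booster_json": bundle.model.get_booster().save_raw(raw_format="json").decode(),
            "params": {k: v for k, v in bundle.model.get_params().items()
                       if isinstance(v, (int, float, str, bool, type(None)))},
        }
    else:
        doc["model"] = {
            "weights": {k: v.tolist() for k, v in bundle.model.get_weights().items()},
            "hidden": bundle.model.hidden,
        }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_bundle(path) -> ModelBundle:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("version") != _ARCHIVE_VERSION:
        raise DataError(f"unsupported bundle archive version {doc.get('version')}")
    kind = doc["kind"]
    if kind == "logistic":
        model = LogisticRegression(**doc["model"]["params"])
        model.coef_ = np.asarray(doc["model"]["coef"])
        model.intercept_ = np.asarray(doc["model"]["intercept"])
        model.classes_ = np.asarray(doc["model"]["classes"])
    elif kind == "boosted_trees":
        model = xgb.XGBClassifier(**doc["model"]["params"])
        model.load_model(bytearray(doc["model"]["booster_json"].encode()))
    else:
        model = MLPBinaryClassifier(hidden=doc["model"]["hidden"])
        model.set_weights(doc["model"]["weights"])
    stats = doc["stats"] and StandardizationStats(**doc["stats"])
    medians = doc["medians"] and ImputationMedians(**doc["medians"])
    bundle = ModelBundle(
        kind=kind, model=model, features=doc["features"],
        stats=stats or None, medians=medians or None,
        provenance=doc["provenance"],
    )
    bundle.threshold = doc["threshold"]
    return bundle


def clone_bundle(bundle: ModelBundle) -> ModelBundle:
    return copy.deepcopy(bundle)
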