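"""Clinical predictor schema for the COVID-19 triage classifier.

The analysis distinguishes two feature sets:

* the **matched** set — 14 vital-sign and blood-test predictors recorded at
  every participating hospital, including the two Vietnamese ICU registries;
* the **uk_only** set — 11 additional laboratory predictors (differential
  white-cell counts, liver panel, C-reactive protein, eGFR) that are routine
  on admission only at the UK emergency departments.

``matched + uk_only`` together form the 25-predictor *comprehensive* set.
Every feature carries a canonical unit; per-site unit harmonization converts
declared site units into these before any modelling.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Feature:
    """One clinical predictor: name, canonical unit, panel group, set membership."""

    name: str
    unit: str
    group: str  # vital | blood | liver/CRP | urea&electrolytes
    set_membership: str  # matched | uk_only


_FEATURES = [
    # --- matched set: vital signs ---
    Feature("heart_rate", "beats/min", "vital", "matched"),
    Feature("respiratory_rate", "breaths/min", "vital", "matched"),
    Feature("systolic_bp", "mmHg", "vital", "matched"),
    Feature("diastolic_bp", "mmHg", "vital", "matched"),
    Feature("temperature", "degC", "vital", "matched"),
    # --- matched set: full blood count ---
    Feature("hemoglobin", "g/L", "blood", "matched"),
    Feature("hematocrit", "L/L", "blood", "matched"),
    Feature("white_cell_count", "1e9/L", "blood", "matched"),
    Feature("platelets", "1e9/L", "blood", "matched"),
    # --- matched set: liver function ---
    Feature("bilirubin", "umol/L", "liver/CRP", "matched"),
    # --- matched set: urea & electrolytes ---
    Feature("sodium", "mmol/L", "urea&electrolytes", "matched"),
    Feature("potassium", "mmol/L", "urea&electrolytes", "matched"),
    Feature("creatinine", "umol/L", "urea&electrolytes", "matched"),
    Feature("urea", "mmol/L", "urea&electrolytes", "matched"),
    # --- uk_only set: differential counts / red-cell indices ---
    Feature("mean_cell_volume", "fL", "blood", "uk_only"),
    Feature("neutrophil_count", "1e9/L", "blood", "uk_only"),
    Feature("lymphocyte_count", "1e9/L", "blood", "uk_only"),
    Feature("monocyte_count", "1e9/L", "blood", "uk_only"),
    Feature("eosinophil_count", "1e9/L", "blood", "uk_only"),
    Feature("basophil_count", "1e9/L", "blood", "uk_only"),
    # --- uk_only set: liver panel & CRP ---
    Feature("albumin", "g/L", "liver/CRP", "uk_only"),
    Feature("alkaline_phosphatase", "U/L", "liver/CRP", "uk_only"),
    Feature("alanine_aminotransferase", "U/L", "liver/CRP", "uk_only"),
    Feature("c_reactive_protein", "mg/L", "liver/CRP", "uk_only"),
    # --- uk_only set: renal ---
    Feature("egfr", "mL/min/1.73m2", "urea&electrolytes", "uk_only"),
]


class FeatureSchema:
    """Ordered collection of the 25 clinical predictors.

    Attributes
    ----------
    features : list[Feature]
        All predictors in canonical column order.
    """

    #: non-feature columns every cohort table carries
    META_COLUMNS = ["site_id", "timestamp", "age", "label"]

    def __init__(self, features: list[Feature] | None = None):
        self.features = list(features) if features is not None else list(_FEATURES)
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def matched(self) -> list[str]:
        """The 14 predictors shared by all sites (reduced feature set)."""
        return [f.name for f in self.features if f.set_membership == "matched"]

    @property
    def uk_only(self) -> list[str]:
        """The 11 predictors recorded only at the UK sites."""
        return [f.name for f in self.features if f.set_membership == "uk_only"]

    @property
    def comprehensive(self) -> list[str]:
        """All 25 predictors (matched + uk_only)."""
        return self.names

    def unit(self, name: str) -> str:
        return self[name].unit

    def __getitem__(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def __len__(self) -> int:
        return len(self.features)


#: module-level default schema used throughout the pipeline
DEFAULT_SCHEMA = FeatureSchema()

#: declared-unit -> (canonical unit, conversion) table for harmonization.
#: Keyed by (feature, declared unit); value is a multiplicative factor or a
#: callable for non-linear conversions (temperature).
UNIT_CONVERSIONS: dict[tuple[str, str], object] = {
    ("hemoglobin", "g/dL"): 10.0,
    ("hemoglobin", "g/L"): 1.0,
    ("hematocrit", "%"): 0.01,
    ("hematocrit", "L/L"): 1.0,
    ("temperature", "degF"): lambda v: (v - 32.0) * 5.0 / 9.0,
    ("temperature", "degC"): 1.0,
    ("bilirubin", "mg/dL"): 17.1,
    ("bilirubin", "umol/L"): 1.0,
    ("creatinine", "mg/dL"): 88.4,
    ("creatinine", "umol/L"): 1.0,
    ("albumin", "g/dL"): 10.0,
    ("albumin", "g/L"): 1.0,
    ("urea", "mg/dL"): 0.357,  # BUN mg/dL -> urea mmol/L
    ("urea", "mmol/L"): 1.0,
}
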