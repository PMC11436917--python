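"""Synthetic multi-site patient-presentation cohorts.

Real emergency-department and ICU admission data of the kind this pipeline
analyses are managed-access; the simulator here produces tables with the same
statistical structure so that every downstream stage (cohort assembly,
preprocessing, cross-site completion, model adaptation, evaluation) is
testable end to end.

Each :class:`SiteProfile` describes one hospital site:

* outcome prevalence (infectious-disease referral centres run far higher
  COVID-19 prevalence than general emergency departments — the default site
  library spans 4.27% to 74.7%);
* class-conditional feature distributions — normal for vital signs,
  moment-matched log-normal for blood counts and analytes (positivity, right
  skew);
* an affine per-feature covariate shift (offset + scale) emulating
  differences in assays, devices and case mix between sites;
* random per-feature missingness plus wholly missing feature columns
  (laboratory panels that are simply not routine at a site);
* data-entry artifacts: unit-conversion errors (hemoglobin recorded in g/dL
  where g/L is expected, a /10 corruption) and extreme values
  (lymphoma-like white-cell counts of 100-300 x 10^9/L).

Cohorts are plain :class:`pandas.DataFrame` objects with columns
``site_id, timestamp, age, label`` followed by the 25 schema features;
missing cells are ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .schema import DEFAULT_SCHEMA, FeatureSchema

# ---------------------------------------------------------------------------
# Default class-conditional feature distributions
# ---------------------------------------------------------------------------
# (mean negative class, mean positive class, sd, distribution family).
# Values are typical adult admission figures in the schema's canonical units;
# the positive-class shifts follow the familiar COVID-19 laboratory signature
# (lymphopenia, eosinopenia, raised CRP and transaminases, mild fever and
# tachypnoea).
_DEFAULT_PARAMS: dict[str, tuple[float, float, float, str]] = {
    "heart_rate": (88.0, 95.0, 16.0, "normal"),
    "respiratory_rate": (18.0, 22.0, 4.0, "normal"),
    "systolic_bp": (125.0, 121.0, 18.0, "normal"),
    "diastolic_bp": (74.0, 72.0, 12.0, "normal"),
    "temperature": (36.9, 37.6, 0.7, "normal"),
    "hemoglobin": (133.0, 129.0, 18.0, "lognormal"),
    "hematocrit": (0.40, 0.39, 0.05, "lognormal"),
    "white_cell_count": (9.5, 6.8, 3.5, "lognormal"),
    "platelets": (260.0, 210.0, 80.0, "lognormal"),
    "bilirubin": (10.0, 12.0, 6.0, "lognormal"),
    "sodium": (138.0, 136.0, 4.0, "normal"),
    "potassium": (4.2, 4.3, 0.5, "lognormal"),
    "creatinine": (85.0, 95.0, 35.0, "lognormal"),
    "urea": (5.5, 6.5, 2.5, "lognormal"),
    "mean_cell_volume": (90.0, 89.5, 6.0, "normal"),
    "neutrophil_count": (6.5, 5.2, 2.8, "lognormal"),
    "lymphocyte_count": (1.8, 1.0, 0.7, "lognormal"),
    "monocyte_count": (0.70, 0.50, 0.30, "lognormal"),
    "eosinophil_count": (0.18, 0.04, 0.12, "lognormal"),
    "basophil_count": (0.05, 0.02, 0.03, "lognormal"),
    "albumin": (40.0, 36.0, 5.0, "normal"),
    "alkaline_phosphatase": (85.0, 92.0, 35.0, "lognormal"),
    "alanine_aminotransferase": (28.0, 42.0, 20.0, "lognormal"),
    "c_reactive_protein": (20.0, 70.0, 40.0, "lognormal"),
    "egfr": (85.0, 78.0, 20.0, "normal"),
}


def default_feature_params(
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Return (means_neg, means_pos, sds) for every schema feature."""
    means_neg = {f: _DEFAULT_PARAMS[f][0] for f in schema.names}
    means_pos = {f: _DEFAULT_PARAMS[f][1] for f in schema.names}
    sds = {f: _DEFAULT_PARAMS[f][2] for f in schema.names}
    return means_neg, means_pos, sds


@dataclass
class ArtifactConfig:
    """Rates for data-entry artifact injection.

    ``hemoglobin_unit_error_rate`` — fraction of non-missing hemoglobin values
    divided by 10 (a g/dL value entered where g/L is expected).
    ``wbc_extreme_rate`` — fraction of non-missing white-cell counts replaced
    by a uniform draw from ``wbc_extreme_range`` (hematological-malignancy
    magnitudes).
    """

    hemoglobin_unit_error_rate: float = 0.0
    wbc_extreme_rate: float = 0.0
    wbc_extreme_range: tuple[float, float] = (100.0, 300.0)

    def validate(self) -> None:
        for name in ("hemoglobin_unit_error_rate", "wbc_extreme_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"artifact rate {name}={rate} outside [0, 1]")
        lo, hi = self.wbc_extreme_range
        if not 0 < lo <= hi:
            raise ConfigurationError(f"wbc_extreme_range {self.wbc_extreme_range} invalid")


@dataclass
class SiteProfile:
    """Simulator configuration for one hospital site."""

    site_id: str
    n_presentations: int
    prevalence: float
    feature_means_neg: dict[str, float] = field(default_factory=dict)
    feature_means_pos: dict[str, float] = field(default_factory=dict)
    feature_sds: dict[str, float] = field(default_factory=dict)
    site_shift: dict[str, tuple[float, float]] = field(default_factory=dict)  # feature -> (offset, scale)
    missing_rate: dict[str, float] = field(default_factory=dict)
    missing_columns: frozenset[str] = frozenset()
    artifact_config: ArtifactConfig = field(default_factory=ArtifactConfig)
    time_span: tuple[str, str] = ("2020-12-01", "2021-12-01")
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self):
        defaults = default_feature_params(self.schema)
        self.feature_means_neg = {**defaults[0], **self.feature_means_neg}
        self.feature_means_pos = {**defaults[1], **self.feature_means_pos}
        self.feature_sds = {**defaults[2], **self.feature_sds}
        self.missing_columns = frozenset(self.missing_columns)
        self.validate()

    def validate(self) -> None:
        if self.n_presentations <= 0:
            raise ConfigurationError(f"n_presentations={self.n_presentations} must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError(f"prevalence={self.prevalence} outside (0, 1)")
        for feat, sd in self.feature_sds.items():
            if sd <= 0:
                raise ConfigurationError(f"feature_sds[{feat}]={sd} must be > 0")
        for feat, rate in self.missing_rate.items():
            if not 0.0 <= rate < 1.0:
                raise ConfigurationError(f"missing_rate[{feat}]={rate} outside [0, 1)")
        unknown = self.missing_columns - set(self.schema.names)
        if unknown:
            raise ConfigurationError(f"missing_columns {sorted(unknown)} not in schema")
        start, end = pd.Timestamp(self.time_span[0]), pd.Timestamp(self.time_span[1])
        if end <= start:
            raise ConfigurationError(f"time_span {self.time_span} has end <= start")
        self.artifact_config.validate()


def _draw_feature(
    rng: np.random.Generator, mean: np.ndarray, sd: float, family: str
) -> np.ndarray:
    """Draw values with the given per-row mean and common sd.

    Log-normal draws are moment-matched: parameters are chosen so the
    natural-scale mean and sd equal the configured ones.
    """
    if family == "normal":
        return rng.normal(mean, sd)
    sigma2 = np.log1p(sd**2 / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2))


def generate_cohort(profile: SiteProfile, seed: int) -> pd.DataFrame:
    """Generate one site's presentation table.

    Labels are Bernoulli(prevalence); features are drawn from the
    class-conditional distribution, then the site's affine covariate shift
    (``value * scale + offset``) is applied, then random missingness and the
    site's wholly missing columns are masked.  Identical ``(profile, seed)``
    yields an identical table.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    n = profile.n_presentations
    schema = profile.schema

    labels = (rng.random(n) < profile.prevalence).astype(int)
    ages = np.clip(np.round(rng.normal(55.0, 18.0, n)), 18, 100).astype(int)
    start = pd.Timestamp(profile.time_span[0])
    end = pd.Timestamp(profile.time_span[1])
    offsets = rng.random(n) * (end - start).total_seconds()
    timestamps = start + pd.to_timedelta(np.round(offsets), unit="s")

    data: dict[str, object] = {
        "site_id": np.full(n, profile.site_id, dtype=object),
        "timestamp": timestamps,
        "age": ages,
        "label": labels,
    }
    for feat in schema.names:
        family = _DEFAULT_PARAMS.get(feat, (0, 0, 0, "normal"))[3]
        mean = np.where(
            labels == 1, profile.feature_means_pos[feat], profile.feature_means_neg[feat]
        )
        values = _draw_feature(rng, mean, profile.feature_sds[feat], family)
        offset, scale = profile.site_shift.get(feat, (0.0, 1.0))
        values = values * scale + offset
        rate = profile.missing_rate.get(feat, 0.0)
        if rate > 0:
            values = np.where(rng.random(n) < rate, np.nan, values)
        if feat in profile.missing_columns:
            values = np.full(n, np.nan)
        data[feat] = values
    return pd.DataFrame(data)


def inject_artifacts(
    cohort: pd.DataFrame, artifact_config: ArtifactConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject data-entry artifacts; return (corrupted cohort, provenance mask).

    The mask is a boolean frame of the cohort's shape; ``True`` marks cells
    altered by an artifact.  All other cells are byte-identical to the input.
    """
    artifact_config.validate()
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    mask = pd.DataFrame(False, index=cohort.index, columns=cohort.columns)

    rate = artifact_config.hemoglobin_unit_error_rate
    if rate > 0 and "hemoglobin" in out.columns:
        eligible = out["hemoglobin"].notna().to_numpy()
        hit = eligible & (rng.random(len(out)) < rate)
        out.loc[hit, "hemoglobin"] = out.loc[hit, "hemoglobin"] / 10.0
        mask.loc[hit, "hemoglobin"] = True

    rate = artifact_config.wbc_extreme_rate
    if rate > 0 and "white_cell_count" in out.columns:
        eligible = out["white_cell_count"].notna().to_numpy()
        hit = eligible & (rng.random(len(out)) < rate)
        lo, hi = artifact_config.wbc_extreme_range
        out.loc[hit, "white_cell_count"] = rng.uniform(lo, hi, int(hit.sum()))
        mask.loc[hit, "white_cell_count"] = True

    return out, mask


# ---------------------------------------------------------------------------
# Default site library and shifted-pair scenario
# ---------------------------------------------------------------------------

def default_site_library(schema: FeatureSchema = DEFAULT_SCHEMA) -> dict[str, SiteProfile]:
    """Six site profiles loosely patterned on a four-UK / two-Vietnam study.

    Prevalences span general emergency departments (4.27%-12.2%) and
    infectious-disease referral ICUs (65.4%, 74.7%).  The two high-prevalence
    sites lack the 11 UK-only laboratory columns, carry a moderate covariate
    shift, more random missingness, and data-entry artifacts.  Shift
    magnitudes are scenario parameters, not estimates of any real site.
    """
    uk_missing = {f: 0.05 for f in schema.names}
    icu_missing = {f: 0.12 for f in schema.matched}
    icu_shift = {
        "white_cell_count": (1.0, 1.15),
        "platelets": (-20.0, 1.0),
        "c_reactive_protein": (10.0, 1.2),
        "respiratory_rate": (2.0, 1.0),
        "sodium": (-1.0, 1.0),
    }
    icu_artifacts = ArtifactConfig(hemoglobin_unit_error_rate=0.002, wbc_extreme_rate=0.002)
    return {
        "uhb": SiteProfile("uhb", 3000, 0.0427, missing_rate=dict(uk_missing),
                           time_span=("2019-12-01", "2020-10-29"), schema=schema),
        "puh": SiteProfile("puh", 3000, 0.0529, missing_rate=dict(uk_missing),
                           time_span=("2020-03-01", "2021-02-28"), schema=schema),
        "ouh_wave_two": SiteProfile("ouh_wave_two", 3000, 0.0880, missing_rate=dict(uk_missing),
                                    time_span=("2020-10-01", "2021-03-06"), schema=schema),
        "bh": SiteProfile("bh", 1177, 0.122, missing_rate=dict(uk_missing),
                          time_span=("2021-01-01", "2021-03-31"), schema=schema),
        "htd": SiteProfile("htd", 1820, 0.747, missing_rate=dict(icu_missing),
                           missing_columns=frozenset(schema.uk_only),
                           site_shift=dict(icu_shift), artifact_config=icu_artifacts,
                           time_span=("2020-12-10", "2022-12-30"), schema=schema),
        "nhtd": SiteProfile("nhtd", 1611, 0.654, missing_rate=dict(icu_missing),
                            missing_columns=frozenset(schema.uk_only),
                            site_shift=dict(icu_shift), artifact_config=icu_artifacts,
                            time_span=("2020-11-01", "2022-12-21"), schema=schema),
    }


def make_shifted_pair(
    n_source: int = 4000,
    n_target: int = 600,
    source_prevalence: float = 0.25,
    target_prevalence: float = 0.65,
    shift_strength: float = 1.0,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> tuple[SiteProfile, SiteProfile]:
    """Source/target profile pair under a strong distribution shift.

    The target site emulates a high-prevalence infectious-disease referral
    ICU receiving a model developed at a general emergency department:

    * **case-mix change** — its negative class is other severe (often
      febrile) infections, so the class-conditional contrasts survive with
      *non-uniform* attenuation (alternating 0.2x / 0.7x across the matched
      features, misallocating a source model's learned weighting) and the
      platelet contrast reverses at half strength;
    * **affine covariate shift** — per-feature offsets of
      ``shift_strength`` source standard deviations (alternating sign) and
      scale changes of 2.0x / 0.6x, emulating assay and device differences
      that inflate noise on weak predictors and damp strong ones;
    * **prevalence shift** — 0.65 against the source's 0.25;
    * the 11 UK-only laboratory columns are wholly missing.

    The target is also small (600 presentations, so an earliest-20% split
    leaves ~120 rows for local training): the regime where a warm start
    from the source site helps, a from-scratch local model is data-starved,
    and the unadapted source model is misled by the shift.
    """
    source = SiteProfile("source", n_source, source_prevalence, schema=schema)
    means_neg, means_pos, sds = default_feature_params(schema)

    matched = schema.matched
    t_neg, t_pos = dict(means_neg), dict(means_pos)
    site_shift: dict[str, tuple[float, float]] = {}
    for i, f in enumerate(matched):
        attenuation = 0.2 if i % 2 == 0 else 0.7
        t_pos[f] = t_neg[f] + attenuation * (means_pos[f] - means_neg[f])
        offset = shift_strength * sds[f] * (1 if i % 3 == 0 else -1)
        site_shift[f] = (offset, 2.0 if i % 2 == 0 else 0.6)
    t_pos["platelets"] = t_neg["platelets"] - 0.5 * (
        means_pos["platelets"] - means_neg["platelets"]
    )
    target = SiteProfile(
        "target", n_target, target_prevalence,
        feature_means_neg=t_neg, feature_means_pos=t_pos,
        site_shift=site_shift, missing_columns=frozenset(schema.uk_only),
        schema=schema,
    )
    return source, target


# ---------------------------------------------------------------------------
# Config & table I/O
# ---------------------------------------------------------------------------

def profiles_from_yaml(path) -> dict[str, SiteProfile]:
    """Read site profiles from a YAML file (one document per site)."""
    profiles: dict[str, SiteProfile] = {}
    with open(path) as fh:
        for doc in yaml.safe_load_all(fh):
            if doc is None:
                continue
            if "artifact_config" in doc:
                doc["artifact_config"] = ArtifactConfig(**doc["artifact_config"])
            if "site_shift" in doc:
                doc["site_shift"] = {k: tuple(v) for k, v in doc["site_shift"].items()}
            if "missing_columns" in doc:
                doc["missing_columns"] = frozenset(doc["missing_columns"])
            if "time_span" in doc:
                doc["time_span"] = tuple(doc["time_span"])
            try:
                profile = SiteProfile(**doc)
            except TypeError as exc:
                raise ConfigurationError(f"bad profile document: {exc}") from exc
            profiles[profile.site_id] = profile
    return profiles


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as delimited text; missing cells empty."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["timestamp"])
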