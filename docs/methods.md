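# Methods

This note records the models, assumptions, parameter choices and
conventions implemented in `triageshift`, and their limitations.

## Synthetic cohorts

Real multi-hospital COVID-19 triage data are managed-access, so all
experiments run on simulated presentation tables. A `SiteProfile` fixes,
per site: the number of presentations, outcome prevalence, per-feature
class-conditional means and standard deviations, an affine covariate shift
(per-feature offset and scale), random per-cell missingness rates, wholly
missing columns, data-entry artifacts, and a time span for uniformly drawn
presentation timestamps.

* Features are drawn class-conditionally and independently, either normal
  or moment-matched lognormal (for right-skewed labs such as white-cell
  count and C-reactive protein): given target mean m and sd s, the log-
  scale parameters are `sigma^2 = log(1 + s^2/m^2)`,
  `mu = log(m) - sigma^2/2`.
* The default feature panel has 14 "matched" predictors available at every
  site (vitals, full blood count, urea and electrolytes) and 11
  source-site-only laboratory features (differential white-cell counts,
  liver panel, CRP, eGFR); 25 in total.
* Artifacts implemented: hemoglobin unit errors (value/10, the g/dL vs g/L
  confusion) and extreme white-cell-count entries (uniform in 100–300).
* `make_shifted_pair()` freezes the scenario used for the strategy-ordering
  analysis: a 4000-row, 25%-prevalence source and a 600-row,
  65%-prevalence target whose class-conditional contrasts are non-uniformly
  attenuated (alternating 0.2x/0.7x, platelets reversed at half strength),
  whose features carry offsets of ±1 source sd and scale changes of
  2.0x/0.6x, and which lacks the 11 source-only columns. The target is
  deliberately small so that the earliest-20% adaptation window (~120 rows)
  is enough to steer a warm-started network but too little to train a good
  model from scratch.

Independence of features given the class is a simplification; real labs
are correlated, which would make kNN completion and subgroup analyses
richer than here.

## Cohort construction

* **Age-matched controls**: each positive presentation is paired with
  `ratio` (default 20) nearest-age controls, greedily in input order and
  without replacement; age-distance ties are broken by a seeded random
  choice. The resulting cohort has prevalence exactly `1/(ratio+1)`
  (4.76% at 20:1, emulating a ~5% emergency-department rate).
* **Temporal split**: rows are stably sorted by timestamp; the earliest
  `floor(0.2 n)` rows form the adaptation-training window, the next
  `floor(0.2 n)` the threshold-calibration window, and the remainder the
  prospective test set.
* Cohort contrasts use two-sided Fisher exact tests for prevalence and
  Kruskal–Wallis for feature locations (all-tied degenerate inputs are
  reported as p = 1). Prevalences are reported to 3 significant figures.

## Preprocessing

Order: unit harmonization → median imputation → standardization. Unit
conversions must be declared for every present feature (fail-loud).
Imputation medians and standardization statistics (population sd,
`ddof=0`) are always fitted on training data only and travel inside the
model bundle; constant features are rejected rather than silently zeroed.

**Missing-column completion (GATS)**: for a site lacking whole columns,
each row is matched to its k = 10 nearest donor rows by Euclidean distance
on the standardized shared features (donor-fitted statistics; stable-sort
tie-breaking), and the missing values are filled with a convex combination
of the donors' values — uniform, inverse-distance, or seeded random-convex
(Dirichlet) weights. Every filled cell therefore lies in the componentwise
min–max envelope of its donors (asserted by tests), and each fill is
audited (row, neighbors, weights) to a JSON-lines record.

## Models

* **Logistic regression** — scikit-learn, C = 1, as the clinical baseline.
* **Gradient-boosted trees** — XGBoost, 100 trees of depth 3; can consume
  missing values natively (`allow_missing`).
* **Neural network** — one hidden ReLU layer (width 16) with sigmoid
  output, written directly in numpy: mini-batch (64) binary cross-entropy
  with Adam, up to 200 epochs, early stopping (patience 10) on a 10%
  validation split when n ≥ 20, with best-weight restoration. It is
  hand-written because the adaptation protocol needs exact weight-level
  control: warm starts, a zero-epoch identity guarantee, and optional
  hidden-layer freezing.
* The network's learning rate defaults to 1e-2. Fine-tuning updates all
  weights at the source learning rate for the full epoch budget with early
  stopping off: with only ~100–250 adaptation rows, a tiny held-out split
  is mostly noise, and a 10x-reduced rate moves the weights too little to
  counteract a strong shift (both regimes remain reachable by passing
  `lr`, `early_stopping=True`, or `freeze_hidden=True`).
* A `ModelBundle` packages classifier, feature list, imputation medians,
  standardization statistics and the calibrated threshold — the unit one
  would deploy — and serializes to a versioned JSON archive.

## Threshold calibration

The decision threshold is grid-searched (step 0.001 over [0, 1]) for
sensitivity 0.85 ± 0.05 on the calibration window — comparable to PCR's
sensitivity and above lateral-flow tests. Among in-band thresholds the
specificity-maximizing one is selected (which typically lands sensitivity
at the bottom edge of the band); if the band is unachievable the threshold
closest in sensitivity is used, preferring the higher sensitivity on ties,
and the result is flagged (`in_band=False`).

## Deployment strategies

* **ready-made**: the source bundle is deployed unchanged (optionally with
  local threshold recalibration).
* **transfer**: network weights are warm-started from the source bundle
  and updated on the target's adaptation-training window; the threshold is
  recalibrated on the calibration window.
* **local**: a model of the same family is trained from scratch on the
  adaptation-training window alone.

Prospective validation uses the target's final 60%; external validation
uses the entirety of another site. Every orchestrated run asserts a
leakage guard: the (site, row) identifiers used for fitting or calibration
must not intersect any evaluation set.

## Evaluation

Sensitivity, specificity, PPV and NPV are confusion-table ratios at the
calibrated threshold (score ≥ threshold is positive); empty denominators
give NaN, never 0. AUROC is the tie-aware Mann–Whitney ranking
probability, computed from average ranks (exactly the trapezoidal ROC
area; verified against brute-force pair counting and scikit-learn). AUPRC
is average precision (step-wise envelope, no interpolation). Confidence
intervals are 95% percentile intervals from B = 1000 seeded bootstrap
resamples; single-class resamples are redrawn and counted. Two models are
compared with a paired bootstrap (shared resample indices), reporting
`p = (1 + #{resamples with metric_B >= metric_A}) / (B + 1)`, so ties
count against rejection. Subgroup error analysis reports the distribution
(n, median, quartiles, histogram) of any feature within each confusion
cell, e.g. to ask whether false negatives concentrate among low
white-cell-count patients.

## Parameter summary

| parameter | default | where |
| --- | --- | --- |
| control matching ratio | 20:1, on age | `MatchSpec` |
| temporal split | 0.2 / 0.2 / 0.6 | `SplitSpec` |
| source development split | 0.6 train / 0.2 calibrate / 0.2 holdout | `train_source_model` |
| calibration target | sensitivity 0.85 ± 0.05, grid 0.001 | `CalibrationSpec` |
| GATS | k = 10, uniform weights | `GATSFill` |
| network | 16 hidden units, lr 1e-2, batch 64, ≤200 epochs | `DEFAULT_HYPERPARAMS` |
| bootstrap | B = 1000, 95% percentile | `bootstrap_ci` |

## Limitations

* Features are simulated independently given the class; correlation
  structure, nonlinear shifts and label noise are not modelled.
* The calibration-band and strategy-ordering results are properties of the
  synthetic scenarios; no empirical claim is made about any real hospital
  system, and real-data performance numbers are out of scope.
* The greedy nearest-age matcher is order-dependent (as in practice for
  sequential matching); it does not solve the optimal assignment problem.
* Transfer learning is implemented for the network only; warm-starting
  boosted trees (e.g. by continued boosting) is not supported.
* The simulator draws timestamps uniformly; it does not model epidemic
  waves, so temporal splits differ from calendar-defined waves only in
  label arrival order.
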