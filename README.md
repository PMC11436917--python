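# triageshift

Cross-site generalizability analysis for clinical triage classifiers.

## The scientific problem

A machine-learning triage model (here: a COVID-19 screening classifier built
from routine vital signs and blood tests) is usually developed at one
hospital and deployed at others. Between sites, three things change at once:

* **prevalence shift** — the outcome base rate can range from ~4% at a
  general emergency department to ~75% at an infectious-disease referral ICU,
  which moves PPV/NPV even when discrimination is unchanged;
* **covariate shift** — assays, devices and case mix move the predictor
  distributions (offsets, scale changes, unit errors, and feature–outcome
  contrasts that attenuate or even reverse);
* **schema mismatch** — whole laboratory panels recorded at the development
  site may simply not exist at the deployment site.

`triageshift` implements the full analysis pipeline for studying this
problem on synthetic multi-site electronic-health-record cohorts: a cohort
simulator with controllable shift, case–control cohort construction,
preprocessing and kNN-based completion of wholly missing columns (GATS:
convex combinations of nearest-neighbor donor records), three classifier
families, decision-threshold calibration to a target sensitivity, the
three-way deployment comparison (**ready-made** vs **transfer-learned** vs
**locally trained**), and bootstrap-based evaluation with paired
significance tests.

## Worked example

Simulate a strongly shifted source/target pair (a 25%-prevalence emergency
department and a small 65%-prevalence referral ICU missing 11 lab columns),
develop a source model, and compare the three deployment strategies on the
target site's prospective test window:

```python
import triageshift as ts

# 1. simulate a strongly shifted source/target site pair
source_profile, target_profile = ts.make_shifted_pair()
source = ts.generate_cohort(source_profile, seed=0)
target = ts.generate_cohort(target_profile, seed=1000)

# 2. develop the source model (train on earliest 60%, calibrate on next 20%)
features = ts.DEFAULT_SCHEMA.matched
bundle, cal = ts.train_source_model(source, features, kind="neural_net", seed=0)

# 3. the three deployment strategies, on the target's prospective 60%
cohorts = {"source": source, "target": target}
_, _, test = ts.temporal_split(target)
y = test["label"].to_numpy()

auc_rm = ts.auroc(ts.score_cohort(bundle, test), y)
tr = ts.run_strategy(ts.ExperimentPlan("transfer", "source", "target", seed=0),
                     cohorts, source_bundle=bundle)
lo = ts.run_strategy(ts.ExperimentPlan("local", "source", "target", seed=0), cohorts)
auc_tr = ts.auroc(tr.evaluations["prospective"].scores, y)
auc_lo = ts.auroc(lo.evaluations["prospective"].scores, y)

# 4. bootstrap CI and paired comparison
ci = ts.bootstrap_ci(ts.auroc, tr.evaluations["prospective"].scores, y,
                     B=1000, seed=0)
cmp = ts.compare_models(tr.evaluations["prospective"].scores,
                        ts.score_cohort(bundle, test), y, B=1000, seed=0,
                        model_a="transfer", model_b="ready_made")
```

Output (deterministic for these seeds):

```
source: 4000 rows, prevalence 25.4 %
target: 600 rows, prevalence 65.3 %
source threshold 0.332 (calibration sensitivity 0.803)
AUROC  ready-made 0.655 | transfer 0.688 | local 0.653
transfer AUROC 0.688 (95% CI 0.628-0.745)
paired bootstrap p (transfer > ready-made): 0.0759
```

On a single seed the ordering is noisy; over 30 seeds of this scenario the
median AUROCs are ready-made 0.595, local 0.667, transfer 0.732 — warm-
starting the network from the source site and updating it on ~120 local
rows beats both shipping the source model unchanged and training from
scratch on the same small sample (this is asserted by the acceptance test
suite, criterion 6).

## Command line

```bash
triageshift simulate --out data/                    # built-in six-site library
triageshift train --kind neural_net --train data/ouh_wave_two.csv --out bundle.json
triageshift evaluate --bundle bundle.json --data data/bh.csv
triageshift run --plan plan.yaml --data-dir data/ --out results/
```

where `plan.yaml` holds an `ExperimentPlan`, e.g.

```yaml
strategy: transfer
training_site: ouh_wave_two
adaptation_site: htd
seed: 0
```

## Reproduction

```bash
python -m pytest -q tests/                    # full suite, ~1 minute
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` carries one test per acceptance criterion:
exact cohort-prevalence worked examples, the 1/21 matched-cohort
prevalence, the calibration band, oracle-equivalence checks (AUROC vs
pair counting, kNN vs an all-pairs distance oracle, Fisher vs
hypergeometric enumeration), GATS convexity, strategy-ordering recovery
over 30 seeds, leakage/determinism guards, and bootstrap CI coverage /
paired-bootstrap type-I error. The acceptance script recomputes targets
t1–t8 from scratch and writes them as JSON.

## Package layout

| module | contents |
| --- | --- |
| `triageshift.schema` | 14 matched + 11 source-site-only predictors, units |
| `triageshift.synthetic` | site profiles, cohort simulator, shift/artifact injection |
| `triageshift.cohort` | age-matched controls, temporal splits, cohort contrasts |
| `triageshift.preprocess` | unit harmonization, median imputation, standardization, kNN + GATS completion |
| `triageshift.models` | logistic / boosted trees / numpy MLP, fine-tuning, bundle serialization |
| `triageshift.adaptation` | threshold calibration, the three deployment strategies, leakage guard |
| `triageshift.evaluation` | confusion metrics, AUROC/AUPRC, bootstrap CIs, paired comparison, subgroup error analysis |

See `docs/methods.md` for the statistical conventions, model details and
limitations.
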