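# esotox

Esophageal radiosensitivity from longitudinal CT, and its value in
esophagitis prediction modelling.

Acute radiation esophagitis is a dose-limiting toxicity of thoracic
chemoradiation for non-small-cell lung cancer. Symptom-based toxicity grades
(CTCAE) are subjective and coarse; the radiation-induced swelling of the
esophagus visible on serial CT — *esophageal expansion* — is an objective
imaging biomarker of the same response. `esotox` is a research package for
biostatisticians and medical physicists that implements, end to end:

1. **Expansion quantification.** Per axial slice,
   `e(z) = 100 · (A_follow(z) − A_base(z)) / A_base(z)`; each patient is
   summarized by the mean expansion and the mean delivered dose
   (planned dose × fraction of treatment delivered) over an isotropic 20 mm
   subvolume centered at the maximum-expansion slice, at the weekly scan
   nearest fraction 30.
2. **Radiosensitivity stratification.** Patients with delivered subvolume
   dose < 20 Gy are excluded; the rest are clustered with K-Means (k = 3,
   squared-Euclidean distance) in (dose, expansion) space. The cluster with
   the highest expansion-per-dose ratio is *radiosensitive*; of the other
   two the higher-dose one is *radioresistant* and the last *radionormal*.
   Radiosensitive membership becomes a dichotomous tag.
3. **NTCP modelling.** Lasso (L1-penalized) logistic regression for the
   grade ≥ 3 esophagitis endpoint over a 49/50-predictor catalogue
   (clinical indicators, DVH metrics MED/Dmax/V10–V70, dose-length metrics
   LEx_25%/LEx_100%, optional radiosensitivity tag), evaluated by 1000
   iterations of seeded 75/25 repeated cross-validation with inner 10-fold
   penalty selection. The with-tag and without-tag model families share
   splits and are compared by AUC, Brier score, scaled Brier, a paired
   t-test, and predictor recurrence.

Because no patient data are deposited for this setting, the package includes
a seeded synthetic-cohort generator (`esotox.simulate`) that reproduces the
statistical structure the analysis assumes — a three-component
radiosensitivity mixture in dose-response space, dose-localized swelling,
~30% within-dose-bin expansion variability, a 33/75/26 grade-0/2/3
composition, and exactly 8 constructed sub-20-Gy patients per 134.
Everything below runs on generated data.

## Worked example

```python
import numpy as np
from esotox import simulate, expansion, clustering, features, modelling

cohort = simulate.generate_cohort(simulate.GeneratorConfig.informative_tag(seed=1))
responses = expansion.quantify_cohort(cohort)          # 134 expansion-responses
result = clustering.cluster_responses(responses)       # 20 Gy exclusion + k=3
print(len(result.patient_ids), len(result.excluded_ids))
print({c: r for c, r in result.role_map.items()})

analyzed = [s for s in cohort if s.patient_id in set(result.patient_ids)]
tag = clustering.make_tag(result, [s.patient_id for s in analyzed])
grades = np.array([s.max_grade for s in analyzed])
fm_with = features.assemble_features(analyzed, tag)      # 50 predictors
fm_without = features.assemble_features(analyzed)        # 49 predictors

cfg = modelling.CVConfig(n_iterations=200, seed=7)
report = modelling.compare_families(
    modelling.repeated_cv(fm_with, grades, cfg),
    modelling.repeated_cv(fm_without, grades, cfg),
)
w, wo = report.summary["with_tag"], report.summary["without_tag"]
print(f"AUC_test {w['auc_test'][0]:.3f} vs {wo['auc_test'][0]:.3f}, "
      f"p = {report.auc_test_ttest[1]:.2e}")
print("top with-tag predictors:", report.top_predictors["with_tag"][:3])
```

Output (seed 1 cohort, 200 iterations):

```
126 8
{2: 'radiosensitive', 1: 'radioresistant', 0: 'radionormal'}
AUC_test 0.835 vs 0.505, p = 1.08e-102
top with-tag predictors: [50, 29, 43]
```

126 of 134 patients survive the 20 Gy exclusion. On this synthetic cohort
the radiosensitivity structure is latent — dose and clinical predictors
alone carry little signal (mean test AUC 0.505) — and the cluster-derived
tag (predictor index 50) lifts mean test AUC to 0.835 with an
overwhelmingly significant paired difference, recurring in essentially
every iteration: the pattern the method is designed to expose when a
genuine radiosensitivity subgroup exists.

A command-line interface wraps the same pipeline:

```bash
esotox all --seed 1 --iterations 200 --out-dir run1
esotox report --out-dir run1
```

writing per-stage CSVs, a versioned `summary.json` and a provenance
manifest (config echo, content hashes, timings) under `run1/`.

## Layout

- `esotox.simulate` — synthetic serial-CT cohort generator + cohort I/O
- `esotox.expansion` — expansion profiles and subvolume dose-response
- `esotox.clustering` — exclusion filter, `RadiosensitivityKMeans`, roles, tag
- `esotox.features` — predictor catalogue, DVH/dose-length metrics,
  standardization
- `esotox.modelling` — lasso-logistic path solver, `LassoLogisticNTCP`,
  repeated CV, family comparison
- `esotox.pipeline` / `esotox.cli` — end-to-end wiring and the `esotox`
  command

See `docs/methods.md` for the model, its assumptions, parameter defaults and
limitations.
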