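# aptrisk

Construction and honest validation of survival signatures from two-colour
array profiles — the workflow used to build serum aptamer-array prognostic
models for stage IIA colon cancer: array preprocessing, univariate Cox
screening, gradient-lasso Cox fitting, leave-one-out cross-validated risk
classification at an optimal log-rank cutpoint, and a permutation p-value
that removes the cutpoint scan's selection bias.

It is written for biostatisticians and computational biologists who need
the *validation engine* as much as the model: dichotomizing a
cross-validated risk score at the most significant cutpoint produces
spectacular but meaningless log-rank p-values, and the only honest summary
re-runs the entire pipeline on outcome-permuted data.

## The model

Disease-free survival follows a Cox proportional-hazards model
h(t | x) = h₀(t)·exp(xᵀβ) on array expression values x. The signature is
fitted by maximizing the partial likelihood l(β) under an L1 constraint,

    max l(β)   s.t.   ‖β‖₁ ≤ s,

with a coordinate-wise gradient ("gradient lasso") algorithm: each step
moves toward the signed vertex s·sign(g_k)·e_k of the largest gradient
coordinate with an exact line search, paired with a deletion move that
shrinks sign-opposed coefficients to exact zeros. Validation is
leave-one-out: sample i's risk score η_i = x_iᵀβ̂₍₋ᵢ₎ comes from a model
screened (univariate Cox, p < 0.01) and fitted on the other n−1 samples
only. The n scores are split at the cutpoint c minimizing the log-rank
p-value over all possible splits, and the bias of that minimization is
measured by B full-pipeline reruns on permuted outcomes:

    p_perm = #{ b : min-p(permuted data b) < min-p(observed) } / B.

## Worked example

Simulate a 60-patient cohort profiled on 100 features, 3 of them truly
prognostic, and run the full pipeline:

```python
import numpy as np
from aptrisk import (CohortConfig, generate_expression_cohort,
                     SurvivalOutcome, run_risk_pipeline,
                     selection_frequency)
from aptrisk.reporting import dfs_report

cfg = CohortConfig(n_samples=60, n_features=100, n_informative=3,
                   beta_true=np.array([1.0, 1.0, -1.0]),
                   censor_rate_target=0.55, baseline_scale=0.03, seed=11)
mat, clinical, truth = generate_expression_cohort(cfg)
outcome = SurvivalOutcome.from_clinical(clinical)

result = run_risk_pipeline(mat, outcome, B=100, seed=2)
cls = result["classification"]
print(selection_frequency(result["scores"]).head(4))
print(f"n_low={cls.n_low} n_high={cls.n_high}")
print(f"naive log-rank p = {cls.naive_p:.3g}, "
      f"permutation p = {cls.permutation_p:.3g}")
rep = dfs_report(clinical, cls.labels)
print({g: round(100 * s, 1) for g, s in rep["survival_at_horizon"].items()})
```

prints

```
APT0001    60
APT0002    60
APT0013    60
APT0048    51
Name: frequency, dtype: int64
n_low=51 n_high=9
naive log-rank p = 3.69e-14, permutation p = 0.03
{'low': 54.4, 'high': 0.0}
```

Two of the three injected features (`APT0001`, `APT0002`) enter every one
of the 60 fold models; `APT0013` is a noise feature that happens to
correlate with the 27 recurrence events in this draw and is selected just
as consistently — at this sample size the data genuinely support it, which
is why exact signature recovery is hard (see `docs/methods.md`). The scan
splits the cohort 51/9 with 5-year disease-free survival 54% vs 0%. Note
the two p-values: the naive scanned log-rank p (3.7e-14) is meaningless —
leave-one-out folds share almost all their samples, so cross-validated
scores inherit nearly the full overfit of screening and fitting, and on
*null* data this pipeline routinely scans its way to p ≈ 1e-7 — while the
permutation-corrected p = 0.03 is the defensible summary.

Spot-level workflows start from GenePix-style tables instead:

```bash
aptrisk simulate  --config cohort.yaml --out cohort/
aptrisk normalize --spots cohort/spots --out matrix.tsv
aptrisk loocv     --matrix matrix.tsv --clinical cohort/clinical.csv --out run/
aptrisk permute   --matrix matrix.tsv --clinical cohort/clinical.csv \
                  --out run/ --B 500 --seed 7
aptrisk report    --clinical cohort/clinical.csv --labels run/labels.tsv \
                  --out report/ --plots
```

`normalize` applies MA transform → per-print-tip-block loess → scale
normalization → kNN imputation (k = 10) → per-array standardization.

## Layout

| module | contents |
| --- | --- |
| `aptrisk.simulate` | synthetic cohorts: expression matrices or spot-level two-channel tables with dye bias, block offsets, missingness |
| `aptrisk.preprocess` | MA transform, print-tip loess, scale normalization, kNN imputation, standardization |
| `aptrisk.survival` | Cox partial likelihood (Breslow/Efron), Newton fitting, vectorized univariate screen, Kaplan–Meier, log-rank |
| `aptrisk.gradlasso` | L1-bounded Cox solver, path fitting, CV bound selection |
| `aptrisk.pipeline` | LOOCV scores, cutpoint scan, classification, permutation p-value |
| `aptrisk.reporting` | cross-tabs with chi-square/Fisher tests, multivariate Cox table, DFS/KM summaries and plots |
| `aptrisk.validation` | independent SLSQP oracle for the constrained Cox problem |
| `aptrisk.cli` | `aptrisk` command: simulate / normalize / loocv / permute / report |

See `docs/methods.md` for the statistical details, numerical conventions
and the design of the simulation studies.
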