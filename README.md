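# pcw — integrated evaluation of physician comprehensive workload

`pcw` implements an integrated evaluation model for the comprehensive
workload of physicians in outpatient practice, for health-services
researchers and hospital workforce analysts. Single indicators — patients
seen per day, or a subjective mental-workload score — each miss part of the
burden; this model combines task-level mental workload with per-visit time,
then adjusts for caseload, served-patient complexity and service quality.

## The model

For physician *i*,

```
PCW_i = (PMW_comm_i · T_comm_i + PMW_noncomm_i · T_noncomm_i) · R_ov_i · R_pc_i · R_ps_i
```

- **PMW** — mental workload per task group (physician–patient communication
  tasks vs. paperwork-type tasks), scored with a hybrid NASA-TLX/SWAT
  instrument: 12 items on a 0–100 scale feed six dimensions (MD, PD, TD,
  PR, FL, Pe); per-respondent dimension weights are pairwise-comparison win
  counts divided by 15, so `PMW = Σ_d score_d · w_d` is a convex
  combination of dimension scores.
- **T** — minutes per outpatient visit spent on each task group.
- **R_ov** — objective workload: daily outpatient count, normalized by the
  sample mean (1 = average caseload).
- **R_pc** — patient complexity: the admitted-to-seen ratio, min–max
  normalized over the sample plus 1, so zero-admission physicians sit at
  the reference value 1.
- **R_ps** — service quality: self-rated outpatient satisfaction / 100.

Each sample is stratified at M−SD, M, M+SD of its PCW distribution into
four relative groups — low (I), medium (II), high (III), very high (IV) —
and analyzed with Pearson chi-square cross-tabs, OLS on ln(PCW) with VIF
diagnostics, and multinomial logistic regression (relative risk ratios
against the very-high group).

Because the original survey data are not public, the package ships a
synthetic-cohort generator that reproduces the published marginal structure
(category frequencies, measurement means/SDs) and can inject known
covariate effects on the log-workload scale for parameter-recovery studies.

## Worked example

```python
import pcw
from pcw.synthetic_data import GeneratorConfig, EFFECTS_PRESET, sample_population

cfg = GeneratorConfig(n=1934, seed=1,
                      effect_spec={k: dict(v) for k, v in EFFECTS_PRESET.items()})
results = pcw.PCWModel(sample_population(cfg)).fit()
print(results.summary())
```

```
Physician comprehensive workload, n = 1934
coefficient scheme: {'r_ov': 'sample_mean', 'r_pc': 'minmax_plus1', 'r_ps': 'scale_max'}
PCW mean = 575.15, SD = 523.81, range [3.95, 4811.60]
cut points (M-SD, M, M+SD): 51.34, 575.15, 1098.96
        low:     53 (2.7%)
     medium:   1177 (60.9%)
       high:    471 (24.4%)
  very high:    233 (12.0%)
```

The cohort was generated with the preset log-scale effects (for example
+0.115 for female physicians); the regression stage recovers them:

```python
reg = results.regress_ln_pcw(["gender", "area", "hours_per_week_band",
                              "outpatient_hours_band"])
print(reg.summary())
```

```
ln(PCW) OLS: n=1934, df=1924, R^2=0.015, residual SD=0.953
Constant  beta=5.798 (SE 0.061)
gender [Female vs Male]  beta= 0.1137  SE=0.0435  t= 2.61  p=0.009  VIF=1.00 **
area [Eastern vs Central]  beta= 0.1145  SE=0.0508  t= 2.25  p=0.024  VIF=1.26 **
...
```

The estimate 0.1137 sits one standard error from the injected truth 0.115;
the VIF column shows the dummy-coded design is far from collinear.
`results.crosstab_chi2("gender")`, `results.distribution()` and
`results.multinomial([...])` produce the cross-tab, score-distribution and
relative-risk-ratio tables in the same style.

The same pipeline is scriptable from a shell:

```bash
pcw simulate --n 1934 --seed 1 --effects --out survey.csv
pcw run --input survey.csv --out report/
```

which writes `characteristics.csv`, `distribution.csv`, `group_tests.csv`,
`regression.csv`, `multinomial.csv` and `summary.json`.

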