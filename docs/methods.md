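# Methods

## Model

The comprehensive workload score for respondent *i* is

    PCW_i = (PMW_comm,i · T_comm,i + PMW_noncomm,i · T_noncomm,i)
            · R_ov,i · R_pc,i · R_ps,i

Task-level workload is mental resource consumption (the PMW score of the
hybrid NASA-TLX/SWAT instrument, 0–100) multiplied by time resource
consumption (minutes per outpatient visit). The product of the three
adjustment coefficients then rescales this subjective·time core by how much
work is done, how difficult the served patients are, and how well the
service is rated.

### Instrument scoring

Twelve items on a 0–100 bipolar scale (administered in steps of 10) map to
six dimensions — mental, physical and temporal demands, perceived risk,
frustration, performance. A dimension score is the unweighted mean of its
items. Weights come from the instrument's 15 pairwise comparisons: the
weight of a dimension is its win count divided by 15, per respondent and
per task group. Consequences used as test invariants: weights are multiples
of 1/15 summing to 1; PMW is a convex combination of dimension scores,
bounded by their extremes, permutation-invariant, and monotone in every
item rating.

The item-to-dimension assignment of the source instrument is not public;
the package defaults to two consecutive items per dimension and accepts any
assignment through `ScaleDefinition`. Scoring accepts any real rating in
[0, 100] — the 10-point discretization is a property of administration, not
of the arithmetic. Ties in a comparison are not representable; the
instrument forces a pick.

### Adjustment coefficients

Only the patient-complexity coefficient has a published construction
("normalize the admitted-to-seen ratio and add 1, so 1 is the reference
value"). Min–max normalization over the analysis sample is the default
because it maps zero-admission physicians exactly onto the reference value
1 and bounds R_pc in [1, 2]. For R_ov and R_ps no construction is
published; raw values (≈43 patients, ≈80 satisfaction points) would inflate
the score by three orders of magnitude, so the defaults are
divide-by-sample-mean for R_ov and divide-by-100 for R_ps. All three
normalizations are selectable per coefficient (`raw`, `sample_mean`,
`scale_max`, `minmax_plus1`) and the scheme used is recorded in every
report's metadata. A consequence of the sample-dependent defaults is that
the *absolute* PCW scale is not comparable across samples or schemes; the
published sample mean (811.30) is therefore treated as non-reproducible,
and analyses that matter (classification, regressions) are invariant to
the overall scale.

Zero daily outpatients makes the complexity ratio undefined; such records
are flagged, the ratio is taken as 0 (hence R_pc = 1), and the record's
PCW is 0 through R_ov.

### Classification

Cut points at M−SD, M and M+SD of the sample PCW distribution, sample SD
with n−1 denominator, boundaries closed on the left of each cut (score ≤
M−SD is type I). Records of a degenerate sample (SD = 0) are all type II,
with a warning. Types I–IV are reported as low / medium / high / very-high
groups.

### Inference

- Pearson chi-square without continuity correction, asymptotic p-values,
  df = (r−1)(c−1). Expected cells below 5 trigger a warning. The group
  cross-tab analysis excludes characteristic levels whose expected counts
  fall below 5 (`drop_sparse_levels`); the published statistics for
  hospital level, education and professional title are reproducible only
  under that convention, and the same sparse levels are the ones the
  published multinomial table reports as N/A.
- OLS on ln(PCW) with indicator coding and the published reference levels;
  VIF per non-reference term as 1/(1−R²) from auxiliary regressions on the
  fitted design. Zero-PCW records are excluded from the log-scale stages
  with a warning rather than floored — the +1 construction of R_pc shows
  the intent was to avoid zeros, not transform them.
- Multinomial logit by maximum likelihood with the very-high group as base
  outcome; Wald 95% CIs exponentiated into RRR bounds. Predictor levels
  with an empty outcome cell would separate the likelihood; they are
  collapsed into the reference and reported N/A for every contrast,
  mirroring how such levels appear in the published table. Newton is tried
  first; a BFGS pass with a larger iteration budget covers near-separated
  designs, and persistent non-convergence raises with the optimizer
  diagnostics.
- Significance flagged at p < 0.10 and p < 0.05; no multiple-testing
  correction is applied (none was in the source analysis).

## Synthetic cohorts

The original survey is not public, so the generator emulates its marginal
structure:

- Characteristics drawn independently from the published category
  frequencies (N = 1,934; income uses the cross-tab totals, N = 1,931).
- Measurements match the published mean ± SD *as realized moments*:
  truncated normals (times at 0, satisfaction on [0, 100]) have their
  parent parameters solved numerically so the truncated distribution hits
  the target moments; satisfaction is rounded to steps of 5. The daily
  caseload is negative binomial matched by moments (mean 43.20, SD 24.81),
  realized as a gamma–Poisson mixture; admissions are binomial given the
  caseload with rate 4.22/43.20, which matches the published admissions
  mean and guarantees admissions never exceed patients seen (its SD is
  consequently smaller than the published 3.85 — the published dispersion
  would require correlation structure the survey does not document).
- Item ratings: each respondent has a latent log-workload
  η = Σ configured covariate effects + N(0, 0.25²). Ratings are dimension
  base levels multiplied by exp(η + item noise), rounded to steps of 10
  and clipped to [0, 100]. Because η scales both task groups alike, a
  configured effect shifts ln(PCW) one-for-one, making recovery
  well-posed. Pairwise picks follow a noisy ranking of the respondent's
  realized dimension means (perception noise SD 8 rating points).
- This latent-effect construction is an artifact design choice: no
  generative model is published, only the regression fitted to the data.

The latent noise SD of 0.25 is deliberately smaller than the ln(PCW)
residual it induces: times, caseloads and satisfaction add their own
variation, and the fitted ln(PCW) regressions on default cohorts show
residual SDs around 0.85–0.95, in line with a weakly-determined individual
log-workload. No residual SD is published, so this parameter is unanchored;
it is a free knob of the generator, not an estimate.

Randomness: one global seed keys independent Philox (counter-based)
streams per field, each consumed in record order through inverse-CDF
transforms, so a cohort of size n is a prefix of any larger cohort with the
same seed.

What passing tests show — and don't: the generator reproduces published
*marginals* but draws characteristics independently, so joint structure in
the real data (e.g. region × hospital-level correlation, caseload–
satisfaction dependence) is absent unless configured. Recovery results
certify the pipeline's statistical correctness under this generative
model, not the field validity of the instrument.

## Problem sizes and numerical choices

Test-suite simulations use cohorts of 200–50,000 records: marginal-fidelity
checks at n = 20,000–50,000, full-pipeline recovery of the 0.115 gender
coefficient over 200 replicates at n = 2,000 (tolerance 0.01 on the mean
estimate, ≈4.5 Monte-Carlo SEs), CI-coverage at n = 800, and the √n
SE-scaling check at n = 500 vs 1,000 with 600 replicates. The acceptance
script repeats the direct and full-pipeline recoveries at 200 and 100
replicates respectively. Chi-square equivalence against a brute-force
two-loop oracle is checked to 1e−9 on 500 random tables.

Weight sums are validated to 1e−12; classification boundary membership is
evaluated on the computed cut values (floating-point subtraction means a
decimal literal like 316.32 may differ from M−SD in the last ulp).
Distribution tables use left-open, right-closed bins with the terminal bin
widened to cover the sample maximum when the published edges would not.

## Known limitations

- Absolute PCW values are sample-relative under the default scheme; only
  within-sample comparisons are meaningful.
- The eligibility screen is complete-case; no imputation is offered.
- The generator's independence assumptions understate real-world
  confounding between characteristics.
- Instrument reliability (e.g. Cronbach's alpha) belongs to the source
  instrument's validation data and is out of scope here.
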