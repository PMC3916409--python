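# Methods

## Model and procedure

The analysis pipeline mirrors a small-n case/control microarray study of
bronchial tissue (6 cases with primary ciliary dyskinesia, 9 controls):

1. **Preprocessing.** Linear intensities below a detection floor
   (default 5, in scanner intensity units) are raised to the floor and
   the matrix is log2-scaled.  Optional quantile normalization (applied
   on the linear scale, before flooring, matching the upstream position
   it occupies in array pipelines) forces all sample distributions onto
   the across-sample mean of order statistics, ties receiving the mean
   of the reference values they span.  Probes are collapsed to genes by
   the per-sample arithmetic mean of log2 values — a geometric mean of
   intensities, the convention that reproduces the packaged tables'
   group-mean columns.
2. **Per-gene screen.** Group means x̄_case and x̄_control on the log2
   scale; log2FC = x̄_control − x̄_case (so "down" = lower in cases);
   FC = 2^log2FC; Welch two-sample t-test (pooled-variance Student
   available via `equal_var=True`).  The screen keeps |effect| ≥ 2-fold
   with raw p < 0.05.  No multiple-testing correction is applied inside
   the screen — the fold-change floor plays that stabilising role, and
   an information-only Benjamini–Hochberg column can be attached.
3. **Set test.** For each predefined gene set, each member gene
   contributes a one-tailed Wilcoxon–Mann–Whitney p-value (alternative:
   case below control), combined by the unweighted Z-method:
   Z = Σ Φ⁻¹(1−p_i)/√k, p_set = 1 − Φ(Z).
4. **Robustness.** Leave-one-out over case samples (controls behind a
   flag) re-runs screen and set tests once per dropped sample; a set is
   called stable when every drop stays below the chosen α.

## Exact rank-sum test

With 6+9 samples the rank-sum null must be exact.  The null pmf of the
case rank sum is computed by dynamic programming over the pooled
midranks (doubled to integers), equivalent to complete enumeration of
all C(n₁+n₂, n₁) assignments and valid under arbitrary tie structure;
the test suite verifies exact agreement with a brute-force enumeration
oracle for every configuration up to n₁+n₂ = 12.  Above a pooled size
of 25 (`exact_threshold`) the implementation switches to the normal
approximation with tie-corrected variance and continuity correction —
the study scale (15) always uses the exact path; the cutoff only keeps
large synthetic runs fast.  The null pmf is cached by (n₁, midrank
multiset), which makes repeated 6v9 tests cheap.

Two p-value conventions are exposed:

- **inclusive** (default of `wilcoxon_one_tailed`): p = P(W ≤ w_obs).
  This is the classical exact test and what the per-gene p-values in the
  packaged tables resemble; it satisfies
  p(case_less) + p(case_greater) = 1 + P(W = w_obs).
- **mid-p** (`mid_p=True`; default inside `set_downregulation_test`):
  p = P(W < w) + P(W = w)/2 (Lancaster's correction).  Stouffer's
  combination assumes null p-values uniform on (0,1); the inclusive p of
  a discrete statistic has null mean 1/2 + E[P(W=w)]/2 > 1/2, which at
  6v9 biases the combined Z downward by ≈0.18 and deflates the nominal
  5% rejection rate to ≈3.4%.  The mid-p restores E[Φ⁻¹(1−p)] ≈ 0; the
  simulation harness measures the resulting type-I error at ≈5.1%.
  Combining the inclusive p-values remains available (`mid_p=False`)
  and is deliberately conservative.

p-values are clipped into [1e-16, 1−1e-16] before the inverse-normal
transform: degenerate inputs map to finite deviates (|Z| ≈ 8.2) rather
than ±∞, far beyond any value arising at the study's printed precision.

## Parameters that matter

| parameter | where | default | why |
|---|---|---|---|
| `floor_threshold` | preprocess / SimConfig | 5 (linear intensity) | detection floor of the array pipeline; log2(5) ≈ 2.32 |
| `fc_min`, `p_max` | diffexpr | 2, 0.05 | the screen's fold-change floor and raw-p cutoff |
| `equal_var` | diffexpr | False (Welch) | the safer default when group variances are unknown |
| `alternative` | setstats | `case_less` | the directional down-regulation hypothesis |
| `exact_threshold` | setstats | 25 pooled samples | exact null below, normal approximation above |
| `mid_p` | setstats | True for combination | calibration of the combined Z (see above) |
| `n_case`, `n_control` | SimConfig | 6, 9 | the study's sample sizes |
| `baseline_lo..hi` | SimConfig | 2.4–11.5 log2 units | empirical range of the ciliary genes' log2 means; deliberately spans the floor |
| `baseline_sigma` | SimConfig | 0.5 log2 units | typical within-group SD for array data at this scale |
| `correlation_rho` | SimConfig | 0 | within-set latent-factor correlation; stress-tests independence |

## Synthetic data: what it emulates, what it does not

Each gene's log2 expression is `mu_g − delta·[case & affected] +
sigma·(√rho·F_set + √(1−rho)·eps)` with mu_g uniform over the baseline
range, one shared standard-normal factor F per declared set, and
independent Gaussian noise; matrices are exported as linear intensities
(2^x) so preprocessing genuinely exercises the floor.  One master seed
drives everything; the harness derives per-replicate seeds by a fixed
affine offset, so studies are reproducible and replicates independent.

The generator captures the features the inference machinery is
sensitive to — sample sizes, a detection floor, coordinated directional
shifts, within-set correlation — and deliberately omits probe-level
noise, array spatial artifacts, batch effects, and heavy-tailed or
sample-specific technical variation.  Passing calibration and power
checks on this generator therefore validates the statistics under the
stated model, not the upstream array processing of real data.

## Monte-Carlo harness

`run_simulation_study` re-runs the full pipeline (generate → floor →
log2 → rank tests → combination) per replicate and reports, per grid
cell, the rejection rate of the combined test and the mean estimated
log2FC of the affected set.  The recovery average is restricted to set
genes whose shifted mean clears the detection floor
(mu_g − delta ≥ log2(floor) + 2σ): below the floor the signal is
censored by construction, and unrestricted averaging would conflate
estimator bias with that censoring.  (This mirrors the "stably
expressed" detection filtering that array studies apply before
interpreting fold changes.)  Floor censoring also attenuates the
per-gene screen near the floor, which is why the screen-recovery test
places its injected signals above it.

Reported problem sizes: null calibration 2000 replicates (rejection
0.04–0.06 at α = 0.05), power 400 replicates at delta = 1.5σ (power
> 0.9), recovery 1000 replicates at delta = 1 (±0.05), correlation
sensitivity 1000 replicates at rho = 0.5 — sizes at which binomial
Monte-Carlo error is a few parts per thousand to a percent, adequate
for the bands asserted.

Under within-set correlation (rho > 0) with no shift, the combined-Z
test rejects well above nominal — at rho = 0.5 several-fold above 5%.
This is a real property of the unweighted Z-method applied to
co-regulated genes ("coordinated expression" is precisely such
correlation), and the harness demonstrates it rather than hiding it:
set-level p-values from correlated modules overstate the evidence.

## Numerical and design choices

- Fold change is the ratio of geometric means, 2^(Δ of log2 means):
  this is the only convention that reproduces the packaged tables' fold
  changes from their group means (arithmetic-mean ratios do not).
- The screen's direction convention: "down" = lower in cases, i.e.
  log2FC > 0 under control−case; swapping labels flips the partition
  and negates log2FC while leaving t-test p-values unchanged.
- Fixture gene symbols are the printed ones (including legacy aliases
  such as RSHL3 for RSPH4A); aliases are retained in a separate column
  rather than resolved, since symbol resolution is unstable over time
  and the fixtures must match the printed tables verbatim.
- Tables are written with nine significant digits — the precision of
  the printed source tables (fixed decimal places cannot express the
  combined p-values' magnitudes).
- Missing values are rejected at read time; imputation is out of scope.
- Degenerate t-test inputs (zero variance in both groups) return p = 1
  when means agree, p = 0 otherwise, instead of NaN.

## Known limitations

- The combined test assumes independent genes; for co-expressed modules
  its p-values are anti-conservative (quantified above).  No
  correlation-adjusted variant is provided.
- Genome-wide quantities of the original study (total DE counts,
  ciliome proportions, annotation-cluster enrichments) require the raw
  array data and are out of scope; the packaged fixtures carry only the
  two printed result tables.
- The exact test's p-values are discrete; single-gene p-values at 6v9
  cannot fall below 1/5005 ≈ 2e-4.
- Leave-one-out stability is a qualitative check with a user-chosen α,
  not a formal jackknife.
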