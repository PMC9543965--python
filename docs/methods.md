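# Methods

This note records the statistical model behind each stage, the defaults and
their rationale, and what the synthetic cohorts do and do not emulate.

## 1. Synthetic cohorts

**What is emulated.** The generator reproduces the *marginal* distributional
structure the analysis assumes, parameterised entirely by published
per-group summaries:

- Plasma biomarkers (23 with published parameters) are log10-normal:
  log₁₀x ~ N(μ_g, σ_g) per group g ∈ {control, t2d}, emitted on the natural
  (pg/ml) scale. The defaults are the printed log10 mean ± SD pairs.
- Continuous clinical/MRI variables reported as mean ± SD are normal;
  variables reported as median (IQR) (eGFR, LV mass:volume, indexed LA
  volume, aortic distensibility, E/e′) are log10-normal with (μ, σ)
  back-solved in closed form from the median and IQR under log-normality
  (median = 10^μ; IQR/median = t − 1/t with t = 10^(z₀.₇₅σ)). This
  preserves the reported skew without inventing a new family.
- Categorical variables (sex, ethnicity, smoking, hypertension, late
  gadolinium enhancement) are Bernoulli with the printed count/percent.
- Diabetes duration is omitted: it is undefined for controls, and every
  generated variable must cover both groups.
- HbA1c is generated on the IFCC scale (mmol/mol); the NGSP % is obtained
  deterministically by the master equation when needed, never sampled
  separately.

Default sizes are the study's: 36 controls vs 83 cases; RCT completers
30/24/22 across standard care / MRP / exercise, two rows per completer.

**Pre/post dependence.** Within-subject correlation is a bivariate Gaussian
with ρ = 0.7 per variable on the modelled scale. The source reports no
within-subject correlations; 0.7 is a typical 12-week test–retest value for
anthropometric and biochemical measures. Follow-up adds the arm effect as a
constant shift on the modelled scale.

**Arm effects.** Printed per-arm changes are the defaults: MRP weight
−13.6 kg, systolic BP −13 mmHg, fasting glucose −1.9 mmol/L; exercise
weight −1.6 kg, glucose −0.8 mmol/L. Two classes of effects are not printed
and are declared assumptions: (i) MRP HbA1c −12 mmol/mol, a realistic
response to an ~810 kcal/day plan producing 13.6 kg weight loss and
consistent with the glucose normalisation; (ii) responsive biomarkers move
a fraction of the control-minus-case gap toward the control location on the
log10 scale — 0.6 for the ten MRP-responsive panel biomarkers, 0.4 for
MMP8 under exercise — reflecting the reported significant-but-incomplete
normalisation.

**What is not emulated.** Variables are mutually independent by default
(an optional Gaussian-copula correlation hook exists for stress tests); the
published between-variable correlation matrices are not available. Two
consequences matter when interpreting results on synthetic data:

- The PCA spectrum is flatter beyond PC1 than in real data (observed
  ≈16/4/4% for PC1–3 versus the reported 13.60/9.71/7.62%), because there
  is no shared covariance for PC2/PC3 to capture.
- kNN imputation has no cross-variable signal to exploit, so its advantage
  over column means appears only in tests that induce correlated structure
  deliberately.

Missingness is MCAR only (each eligible continuous cell masked i.i.d.);
the source states nothing about its missingness mechanism, so no MAR/MNAR
machinery is pretended. Label columns are never masked. Passing tests on
these cohorts demonstrate that the pipeline's arithmetic and decision rules
are correct under the declared generative model — not that the model
captures real biological covariance.

**No medication variable** is generated. The remission rule's "without
glucose-lowering agents" clause is therefore evaluated with the medication
requirement waived in the analysis drivers, which overstates "remission" in
arms whose members would in reality remain on therapy (standard care,
exercise). The rule itself accepts a medication flag and is tested with it.

## 2. Scale handling and standardization

Biomarkers are analysed as log₁₀x and reported back-transformed:
(10^mean, 10^SD) = (geometric mean, geometric SD). Printed back-transformed
cells are reproduced to printed precision, with a propagated-rounding
allowance of a factor 10^0.005 (the printed log10 inputs are themselves
rounded to 2 dp); three cells in the source table appear to have been
back-transformed from unrounded values and differ in the final digit.

Standardization subtracts the column mean and divides by the sample
(n−1) SD, fitted ignoring missing entries. Zero-variance columns are
reported and dropped, never divided by. The (n−1) convention matches
standard statistics-package output throughout the package.

## 3. kNN imputation

Distance between rows is the mean squared difference over columns observed
in both rows — dividing by the shared-column count keeps rows with
different missingness patterns comparable. Donors must have the target
column observed; the k nearest eligible donors (default k = 5) contribute
an unweighted mean; ties in distance break toward the lowest row index,
deterministically. Fewer than k eligible donors → use all; none → column
mean, counted as a fallback in the report; a fully missing row falls back
to column means and is flagged; a fully missing column is an error. The
implementation operates on the standardized matrix (Euclidean-type
distances are meaningless across mixed units) and never alters observed
entries. k and the unweighted mean are this package's declared choices —
the referenced imputation software's internals are not specified in the
source — with distance weighting available as an option. A brute-force
all-pairs oracle in the test suite pins the exact semantics.

## 4. Group statistics

- Normality flags come from Shapiro–Wilk at α = 0.05, a deterministic
  surrogate for visual histogram/Q-Q assessment, overridable per variable.
  Biomarkers are flagged parametric on the log10 scale by construction.
- The two-group t-test defaults to Welch's unequal-variance form — the
  source does not disambiguate, and recomputation from rounded summaries
  cannot either — with the pooled form available (`equal_var=True`).
- Bonferroni: p_adj = min(1, m·p); m defaults to the number of variables in
  the run.
- Change models are change-score regressions with mean-centered covariates,
  so the intercept is the covariate-adjusted mean change; Model 1 reduces
  algebraically to the paired t-test (asserted, not assumed). A two-occasion
  repeated-measures ANOVA engine would add machinery without changing any
  reported number for these within-arm contrasts. When all changes are
  exactly zero the statistic/p are defined as 0/1 rather than 0/0.
- Printed p-values are *not* reproduction targets: recomputing, e.g.,
  galectin-3's case–control p from the rounded summaries (3.79 ± 0.17 vs
  3.74 ± 0.13 at n = 36/83) gives ≈ 0.08–0.12, not the printed 0.052;
  summary rounding is the presumed cause. Direction-of-difference checks
  are used instead.

## 5. Low-dimensional views

**PCA.** Columns are centered (they are already standardized);
λᵢ = sᵢ²/(n−1) from the SVD; variance explained λᵢ/Σλⱼ; scores are
projections onto the top right-singular vectors. Components beyond the
third are computed but not plotted. The best-fit plane through the 3-D
scores is the least-squares plane: centroid plus the top-2 principal span
(for PCA scores this is the PC1–PC2 plane by construction; the function is
general and tested on arbitrary 3-D clouds).

**Fisher plane.** w ∝ (S_w + λI)⁻¹(m₂ − m₁) with S_w the pooled
within-class scatter. λ defaults to 10⁻³·trace(S_w)/p because p ≈ 50
variables exceeds the per-class n (22–30 pairs), making S_w singular;
λ = 0 requests the exact solve and errors on singularity. Sign conventions
are fixed for reproducible plots: the post/second class projects to the
larger u-mean, and +v points from healthy toward pre. The vertical axis
orthogonalizes the healthy-to-pre center vector against u and errors if
the two are numerically parallel (‖a − (a·u)u‖ < 1e-12). Accuracy is
resubstitution — no cross-validation, matching the single reported
accuracy per group — with ties at the threshold assigned to the class
whose projected mean is nearer. With p of order n, resubstitution accuracy
is optimistic (near 1.0 on synthetic cohorts); the reported per-arm
accuracies of the original subject-level data are not recoverable from
summaries, so the tests assert distributional properties (oracle
equivalence, permutation-null behaviour, separation rates over seeds)
rather than those numbers.

Both the full 51-variable set and the biomarkers+demographics sensitivity
set are supported (`variable_set` configuration); the source states the
membership of each visualization only coarsely.

## 6. Numerical conventions

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  (specs, config, seed) give bit-identical tables.
- Orthonormality and eigen-ordering are asserted to 1e-8; exact identities
  (Model 1 vs paired t, imputation oracle) to 1e-10–1e-12.
- Monte-Carlo tests use 4-standard-error bands at their stated n; seed-rate
  assertions (e.g. ≥95% of 100 seeds) use fixed seed sets.
- Problem sizes in tests and the acceptance script are the study's own
  (n = 36/83, 30/24/22 pairs) except parameter-recovery checks, which use
  n = 5,000 per group, and oracle checks on small matrices (20×5) where
  exhaustive search is the point.

## 7. Known limitations

- Independence between variables is the largest departure from real data
  (see §1); all multivariate results on synthetic cohorts inherit it.
- Only the 23 biomarkers with published parameters are simulated, not the
  full 51-marker assay panel; "m" for Bonferroni consequently defaults to
  the simulated panel size.
- The remission analysis on synthetic data waives the medication clause
  (no medication variable is modelled).
- Single imputation only; no MICE/EM, no MAR/MNAR mechanisms.
- No inferential claims attach to the visualizations; accuracies are
  resubstitution by design.
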