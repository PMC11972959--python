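# Methods

This note documents the models implemented in `mrtraj`, the synthetic
cohort the tests run on, the numerical choices, and the known limitations.

## The synthetic cohort generator

The generator (`mrtraj.simulate.generate_cohort`) produces the statistical
structure the downstream analyses assume. Its defaults describe a
middle-aged East-Asian-style biennial cohort: 8,500 subjects aged 40–69
(uniform), 47.4% male, FBS centered at 4.9 mmol/L, SBP at 117.4 mmHg,
eight visits two years apart, administrative censoring 16 years after
baseline, and baseline disease-history fractions of 892/8510 (diabetes),
1293/8510 (hypertension) and 34/8510 (stroke). Covariates without a
published distribution use documented defaults: BMI ~ Normal(24.5, 3)
kg/m², smoking never/former/current at 60/15/25%, alcohol yes at 50%,
regular exercise at 40%.

### Genotypes

Each of the 91 FBS-associated and 68 SBP-associated variants (one variant
belonging to both sets) is drawn as an additive dosage
G ~ Binomial(2, MAF) with MAF uniform on (0.05, 0.5] — Hardy–Weinberg
equilibrium holds by construction. Per-allele effects are
Normal(0, 0.05 mmol/L) for FBS and Normal(0, 1.5 mmHg) for SBP; the
shared variant's effects are tripled, making it a large-effect
pleiotropic outlier by design (the analog of an aldehyde-dehydrogenase
variant with effects on both traits). Genotype missingness is uniform at
rate `missing_rate` and applied only to the released matrix, never to the
phenotype-generating dosages. Variants sit ≥ 5 Mb apart, so instrument
independence holds and LD clumping is exercised through its r² machinery
rather than through physical linkage.

These per-allele effect sizes are far larger than real GWAS effects; they
are the price of making instrument discovery possible at a few thousand
subjects instead of the hundreds of thousands a biobank provides. A
consequence worth knowing: because the planted causal effects are large
on the standardized scale, an internally run GWAS of one phenotype also
detects the other phenotype's variants through the causal path, so
internally selected instrument sets overlap across traits much more than
the single shared variant. The clean-recovery analyses therefore use the
generating effects as *external* weights (the analog of weights estimated
in a separate biobank) with the shared variant excluded; the pipeline's
internal GWAS→clump→wGRS route remains available and is exercised by the
end-to-end tests.

### The bidirectional structural model

Baseline phenotypes solve the 2×2 linear simultaneous system

    F = μ_F + F0 + b·(S − μ_S),   S = μ_S + S0 + a·(F − μ_F)

in reduced form, F − μ_F = (F0 + b·S0)/(1 − ab), so both causal
parameters hold at once: a = 3.26 mmHg per mmol/L (1.63 mmHg per
0.5 mmol/L) and b = 0.063 mmol/L per mmHg (0.63 mmol/L per 10 mmHg).
Configurations with |a·b| ≥ 1 are rejected as singular. F0 and S0 collect
centered genetic effects, a shared latent confounder U ~ Normal(0, 1)
with loadings (0.15 mmol/L, 4.0 mmHg), a small age trend, and Gaussian
noise (0.30 mmol/L, 12 mmHg). Dosages enter centered at 2·MAF so the
configured phenotype means are exact. Optional horizontal pleiotropy adds
Normal(mean, sd) direct effects of each trait's instruments on the other
trait (mean forced to 0 in `balanced` mode — the InSIDE regime).

Note that with both causal effects planted, marginal phenotype SDs exceed
the per-equation noise figures (the b·S0 term imports blood-pressure-scale
variance into FBS); the configured SDs describe the structural equations,
not the marginal distributions.

### Visits, latent classes, events

A latent trajectory class z_i ~ Categorical(0.8, 0.2) drives visit-level
phenotypes: y_it = baseline_i + poly_{z_i}(t) + Normal(0, visit noise).
The minority class follows a reverse-U (rise-then-fall) quadratic and
sits at a higher level; the class whose curve spans the widest range is
the generator's "uncontrolled" class. Event times for incident diabetes
and hypertension are Weibull (default exponential) with per-year baseline
hazards 0.075 and 0.125 and log hazard ratios on the uncontrolled class
(ln 1.25 for T2D, ln 1.30 for HTN), age, sex and BMI; times beyond the
censoring horizon are administratively censored. Latent classes are
independent of genotype; the hazard acts on the class, which is what the
survival stage estimates.

## Instrument selection

The Hardy–Weinberg test is the exact conditional test (full enumeration
of heterozygote counts given the minor-allele count, summing all
configurations no more probable than the observed one), computed in log
space — well defined at any MAF, unlike the χ² approximation. QC drops
subjects with > 5% missing genotypes first, then variants by call rate
(< 0.96), MAF (< 0.01) and HWE (p < 1e−4), recording the failing rule;
the 0.96 cut-off is a parameter because genotyping-accuracy conventions
vary across platforms. GWAS is per-SNP OLS with age and sex, t-based
p-values, and per-SNP complete-case exclusion. Clumping is greedy in
ascending p (ties broken lexicographically by variant id, making the
result order-invariant), with r² computed from the analyzed panel's
dosages, a 1 Mb inclusive window on 1-based coordinates, and an optional
relaxation ladder (0.01 → 0.02 → 0.03) that stops once a requested
instrument count is reached. The wGRS orients every variant to its
trait-increasing allele (so all weights are nonnegative after
normalization), imputes missing dosages at twice the oriented
effect-allele frequency, and accepts external weight tables so scores can
be built from independently estimated effects.

## MR estimators

* **2SLS** — stage 1 regresses exposure on the wGRS and covariates,
  stage 2 the outcome on the fitted exposure; SEs use the structural
  residual evaluated at the observed exposure. The first-stage partial F
  (t² of the instrument) flags weak instruments below 10; Wu–Hausman is
  the control-function t-test. Effects are reported per exposure unit,
  per exposure SD, and per clinical increment (0.5 mmol/L FBS, 10 mmHg
  SBP).
* **IVW** — fixed-effect weighted regression through the origin; weights
  1/se²_Y (equivalently β²_X/se²_Y on the Wald ratios); normal p-values.
* **Medians** — simple median of Wald ratios, and the cumulative-weight
  interpolation weighted median with weights β²_X/se²_Y. Exactly tied
  ratios are merged (weights summed) so the estimator depends only on the
  weighted empirical measure — this makes weight-splitting duplication an
  exact invariance. SEs come from a seeded parametric bootstrap of both
  association vectors; the simple median's bootstrap CI is conservative
  (coverage ≈ 98% at nominal 95% in the calibration suite), a known
  property of that construction — it never undercovers.
* **MR-Egger** — weighted regression with intercept after orienting all
  exposure associations nonnegative; multiplicative overdispersion
  estimated from the fit and floored at 1; t inference on m − 2 df. The
  intercept estimates average directional pleiotropy; leave-one-out
  re-fitting flags variants whose exclusion moves the intercept test
  across 0.05 — the shared large-effect variant is the designed positive
  case.

The bidirectional driver estimates exposure associations on odd-indexed
subjects and outcome associations on even-indexed subjects, respecting
the two-sample assumption within a single cohort; 2SLS runs on the full
panel, overall and within sex strata (instruments are not re-selected per
stratum). Estimators whose preconditions fail after shared-variant
exclusion (< 3 variants for medians/Egger) are skipped with a warning
rather than aborting the report.

## Trajectories

`predict_series` fits one phenotype ~ wGRS regression per visit and
assigns every subject the fitted value at their score, yielding a
predicted value per visit even for missed visits (prediction needs only
the score). Observed-mode series are also supported; which mode a given
scientific claim needs is the analyst's choice, and both feed the same
mixture machinery. The default grid is one value per visit (8 biennial
values over 14 years); annual grids up to 14 points are configurable.

GBTM maximizes the normal mixture by EM: E-step responsibilities in log
space, M-step weighted polynomial least squares per class over observed
cells, shared residual σ (per-class σ behind a flag, PROC-TRAJ-style
censored-normal reduced to plain normal since predicted values are
unbounded), π_k as mean responsibility. A σ floor of 1e−6 keeps
zero-noise fixtures finite; empty classes trigger a restart; 10 random
multi-starts (seeded, spawned from one SeedSequence) keep the best
likelihood; classes are canonically ordered by intercept so relabeling
cannot change a reported model. BIC = −2 logL + p log(n subjects) with
p = Σ(order_k + 1) + (K − 1) + 1. Model selection excludes fits whose
smallest assigned class holds < 5% of subjects; if every candidate
violates the rule the best-BIC violator is returned with a warning — the
pragmatic path when a small class is scientifically expected. The class
with the largest fitted-curve range is labeled "uncontrolled"; average
posterior ≥ 0.7 is the adequacy convention. On observed cohort data with
continuous between-subject level variation, BIC often prefers extra level
classes — a structural property of approximating a random intercept with
discrete classes, shown honestly in the examples.

## Survival

Person-time runs from baseline (or the second visit as left truncation,
in which case pre-entry events are rejected with a reason) to onset or
administrative censoring; an option discretizes onsets to the midpoint
between the last disease-free and first diseased visit. Incidence CIs are
exact Poisson (Garwood, χ² form). The Cox model maximizes the Efron
partial likelihood with risk sets honoring delayed entry, computed via
suffix sums over entry and exit orderings (untied event times vectorized,
tie groups handled exactly); Newton–Raphson with step-halving, internal
covariate standardization, convergence when the score norm falls below
1e−9 × the number of events (an absolute 1e−9 is below the float64
summation floor at thousands of events), a cap of 50 iterations, and a
monotone-likelihood guard (|log HR| > 20 names the offending covariate).
Constant covariates are dropped with a note. Staged models: age/sex;
+ BMI, smoking, alcohol, exercise and medication flags; + wGRS quartiles
computed on the analysis cohort after exclusions. Hazard ratios are
invariant to time-unit rescaling; −2 log partial likelihood is reported
for model comparison.

## Problem sizes in the test and acceptance suites

Oracle-equivalence tests run on ≤ 50-subject or ≤ 30-variant fixtures at
1e−10/1e−6 tolerances against closed forms, statsmodels and lifelines.
Recovery suites use 200 replicates of n = 2,000 (bidirectional 2SLS,
median-of-replicates summary since a just-identified IV ratio is
heavy-tailed), 500 summary-level replicates at 60 variants (Egger
intercept type-I error), 50 seeds of 300 subjects (two-class trajectory
recovery and BIC selection), and 200 replicates of n = 5,000 (Cox hazard
ratio 1.25). The CI-calibration suite runs 500 replicates at n = 2,000
with 30 variants and 300 bootstrap draws. These sizes keep the full suite
within a couple of minutes per heavy module while leaving Monte-Carlo
error well inside the asserted bands.

## Limitations

* No LD structure beyond what dosage correlation measures on the panel;
  no population stratification, relatedness or imputation — instrument
  validity threats of real cohorts that the generator does not emulate.
  Passing tests demonstrate correctness of the estimators under their
  assumptions, not robustness to those threats.
* Latent trajectory classes are independent of genotype, so
  "genetically predicted" grouping on synthetic data stratifies genetic
  burden rather than recovering the classes; class recovery is tested on
  observed-mode series where the classes are identifiable.
* The two-sample split reuses one simulated population; real two-sample
  MR adds between-cohort heterogeneity not modeled here.
* Event generation uses proportional hazards with exponential/Weibull
  baselines; no competing risks or time-varying covariates.
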