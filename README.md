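# mrtraj

Bidirectional Mendelian randomization between fasting blood sugar (FBS)
and systolic blood pressure (SBP), genetically predicted trajectory
modeling, and incidence/survival linkage — a reusable, tested pipeline
exercised end to end on synthetic longitudinal cohorts.

## Who this is for

Genetic epidemiologists who want the full chain of a biobank-style
causal analysis — instrument selection from genotypes, weighted genetic
risk scores, five MR estimators with pleiotropy diagnostics, group-based
trajectory modeling (GBTM), and Cox regression of trajectory groups on
incident disease — as importable, oracle-tested components rather than a
patchwork of PLINK/STATA/SAS/R steps. Because cohort genotype data of
this kind are not publicly redistributable, the package ships a
first-class synthetic cohort generator that reproduces the statistical
structure the analysis assumes (a middle-aged biennial cohort: ~8,500
subjects aged 40–69, 91 FBS- and 68 SBP-associated instruments sharing
one large-effect variant, 8 biennial visits, incident type 2 diabetes and
hypertension), so every stage is testable without any data access.

## The models

**Instruments.** Variants pass QC (call rate ≥ 0.96, Hardy–Weinberg exact
test p ≥ 1e−4, MAF ≥ 0.01), get per-SNP additive-model effects from
age/sex-adjusted least squares, and are thinned by greedy LD clumping
(r² < 0.01 within 1 Mb, p < 5e−8). The weighted genetic risk score is

    wGRS_i = Σ_k β_k · G_ik

with each variant oriented to its trait-increasing allele and missing
dosages imputed at twice the effect-allele frequency.

**MR estimators.** With the wGRS as instrument Z, two-stage least squares
estimates the causal slope of outcome Y on exposure X (SEs from the
structural residual; first-stage partial F and the Wu–Hausman endogeneity
test as diagnostics). On per-variant summary statistics (β̂_Xj, β̂_Yj):
IVW is the fixed-effect weighted regression through the origin (weights
β̂²_Xj/se²_Yj on the Wald ratios); the simple and weighted medians use the
cumulative-weight interpolation estimator with parametric-bootstrap SEs;
MR-Egger adds an intercept whose deviation from zero estimates average
directional pleiotropy. All five run in both directions, with a
shared-variant-excluded re-analysis mirroring outlier removal.

**Trajectories.** Per-visit regression of the phenotype on the wGRS turns
genetic burden into a predicted series per subject; GBTM maximizes the
K-class normal mixture Π_i Σ_k π_k Π_t φ(y_it; poly_k(t), σ) by EM with
multi-start, selects K by BIC = −2 logL + p log n subject to a 5%
minimum-group-share rule, and labels the wider-ranging class
"uncontrolled".

**Survival.** Incidence per 1,000 person-years carries exact (Garwood)
Poisson intervals; Cox proportional hazards maximizes the Efron partial
likelihood by Newton–Raphson, supports delayed entry and staged covariate
sets (age/sex; + lifestyle/medications; + wGRS quartiles).

## Worked example

```python
from mrtraj import SimulationConfig, build_wgrs, fit_2sls, generate_cohort

cfg = SimulationConfig(n_subjects=4000, missing_rate=0.0, seed=3)
panel = generate_cohort(cfg)
vm = panel.variant_meta
inst = vm[vm.affects_sbp & ~vm.is_shared][
    ["snp_id", "effect_allele", "true_beta_sbp"]
].rename(columns={"true_beta_sbp": "beta"})
wgrs = build_wgrs(panel, inst)
ph = panel.baseline_phenotypes()
est, diag = fit_2sls(ph.sbp, ph.fbs, wgrs)
print(f"{10 * est.effect:+.2f} mmol/L FBS per 10 mmHg SBP "
      f"(p={est.p_value:.1e}, F={diag.first_stage_F:.0f})")
```

prints

    +0.62 mmol/L FBS per 10 mmHg SBP (p=2.2e-308, F=835)

a genetically instrumented estimate of the SBP→FBS effect — the
configured truth is 0.063 mmol/L per mmHg (0.63 per 10 mmHg) and the
first-stage F far exceeds the weak-instrument cut-off of 10. The
`examples/` directory walks through each capability (simulation,
instrument selection, bidirectional MR, trajectory groups, incidence and
Cox models, the one-call pipeline); `mrtraj simulate` and `mrtraj run`
expose the generator and the full pipeline on the command line.

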