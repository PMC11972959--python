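"""Synthetic cohort generator.

Implements the structural model the downstream analyses assume:

* genotypes ``G ~ Binomial(2, maf)`` per SNP (Hardy-Weinberg by construction),
  with optional uniform missingness;
* baseline phenotypes from a bidirectional linear structural system

      FBS = mu_F + G_x b_x + lam_F U + age-effect + e_F + b_yx * (SBP - mu_S)
      SBP = mu_S + G_y b_y + lam_S U + age-effect + e_S + b_xy * (FBS - mu_F)

  solved in reduced form (a 2x2 simultaneous system) so both causal
  coefficients hold at once; the system is rejected as singular when
  ``|b_xy * b_yx| >= 1``;
* optional horizontal pleiotropy: instrument SNPs of one phenotype receive
  direct Normal(mean, sd) effects on the other (``balanced`` forces mean 0);
* visit-level phenotypes = subject baseline + latent-class polynomial in
  years since baseline + visit noise;
* incident T2D/hypertension times from Weibull (default exponential)
  proportional hazards with administrative censoring.

Everything is driven by one ``numpy`` Generator, so a fixed seed yields a
bit-identical panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortPanel
from .config import SimulationConfig

_ALLELES = ("A", "C", "G", "T")


def _polynomial(coefs, t):
    """Evaluate intercept + c1 t + c2 t^2 + c3 t^3 (coefs low -> high)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for k, c in enumerate(coefs):
        out = out + c * t ** k
    return out


def _true_uncontrolled_group(config: SimulationConfig, phenotype: str) -> int:
    """Latent class whose mean curve spans the widest range ("uncontrolled")."""
    span = (config.n_visits - 1) * config.visit_spacing_years
    t = np.linspace(0.0, span, 64)
    ranges = [float(np.ptp(_polynomial(c, t)))
              for c in config.traj_coefficients[phenotype]]
    return int(np.argmax(ranges))


def generate_cohort(config: SimulationConfig,
                    seed: int | None = None) -> CohortPanel:
    """Draw one synthetic cohort; deterministic given ``seed``.

    ``seed=None`` uses ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    n_fbs, n_sbp, n_sh = config.n_snps_fbs, config.n_snps_sbp, config.n_shared
    m = n_fbs + n_sbp - n_sh + config.n_snps_null

    # ---- variants ----------------------------------------------------
    mafs = rng.uniform(*config.maf_range, size=m)
    idx = np.arange(m)
    chrom = 1 + idx % 22
    pos = 1_000_000 + (idx // 22) * 5_000_000  # >= 5 Mb apart per chromosome
    pairs = [rng.choice(4, size=2, replace=False) for _ in range(m)]
    eff = [_ALLELES[p[0]] for p in pairs]
    oth = [_ALLELES[p[1]] for p in pairs]

    fbs_idx = np.arange(n_fbs)
    sbp_idx = np.arange(n_fbs - n_sh, n_fbs + n_sbp - n_sh)
    shared_idx = np.arange(n_fbs - n_sh, n_fbs)

    beta_fbs = np.zeros(m)
    beta_sbp = np.zeros(m)
    beta_fbs[fbs_idx] = rng.normal(0.0, config.beta_scale_x, size=n_fbs)
    beta_sbp[sbp_idx] = rng.normal(0.0, config.beta_scale_y, size=n_sbp)
    # the shared variant is a large-effect outlier affecting both traits
    beta_fbs[shared_idx] *= config.shared_effect_multiplier
    beta_sbp[shared_idx] *= config.shared_effect_multiplier

    variant_meta = pd.DataFrame({
        "snp_id": [f"snp{j:05d}" for j in idx],
        "chrom": chrom, "pos": pos,
        "effect_allele": eff, "other_allele": oth,
        "true_maf": mafs,
        "true_beta_fbs": beta_fbs, "true_beta_sbp": beta_sbp,
        "affects_fbs": np.isin(idx, fbs_idx),
        "affects_sbp": np.isin(idx, sbp_idx),
        "is_shared": np.isin(idx, shared_idx),
    })

    genotypes_full = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)

    # ---- baseline covariates ----------------------------------------
    age = rng.uniform(40.0, 70.0, size=n)
    male = rng.random(n) < 0.474
    bmi = rng.normal(24.5, 3.0, size=n)
    smoking = rng.choice(["never", "former", "current"], size=n,
                         p=[0.60, 0.15, 0.25])
    alcohol = rng.choice(["no", "yes"], size=n, p=[0.50, 0.50])
    exercise = rng.choice(["no", "yes"], size=n, p=[0.60, 0.40])

    # ---- structural phenotypes --------------------------------------
    u = rng.normal(0.0, config.confounder_sd, size=n)
    e_f = rng.normal(0.0, config.fbs_noise_sd, size=n)
    e_s = rng.normal(0.0, config.sbp_noise_sd, size=n)
    age_c = age - 55.0

    # centered dosages keep the configured phenotype means exact; slopes
    # are unaffected (the shift is absorbed in the intercept)
    geno_c = genotypes_full - 2.0 * mafs[None, :]
    f0 = (geno_c @ beta_fbs + config.confounder_loading_fbs * u
          + config.age_effect_fbs * age_c + e_f)
    s0 = (geno_c @ beta_sbp + config.confounder_loading_sbp * u
          + config.age_effect_sbp * age_c + e_s)

    if config.pleiotropy_mode != "none":
        mean = 0.0 if config.pleiotropy_mode == "balanced" \
            else config.pleiotropy_mean
        alpha_on_sbp = np.zeros(m)
        alpha_on_fbs = np.zeros(m)
        alpha_on_sbp[fbs_idx] = rng.normal(mean, config.pleiotropy_sd, n_fbs)
        alpha_on_fbs[sbp_idx] = rng.normal(mean, config.pleiotropy_sd, n_sbp)
        s0 = s0 + geno_c @ alpha_on_sbp
        f0 = f0 + geno_c @ alpha_on_fbs

    a = config.causal_fbs_to_sbp   # FBS -> SBP, mmHg per mmol/L
    b = config.causal_sbp_to_fbs   # SBP -> FBS, mmol/L per mmHg
    den = 1.0 - a * b
    if abs(a * b) >= 1:
        raise ValueError("structural system singular (|a*b| >= 1)")
    f_dev = (f0 + b * s0) / den
    s_dev = (s0 + a * f0) / den
    fbs_base = config.fbs_mean + f_dev
    sbp_base = config.sbp_mean + s_dev

    # ---- latent trajectory classes and visits -----------------------
    shares = np.asarray(config.traj_group_shares)
    labels = rng.choice(len(shares), size=n, p=shares)
    t_visits = np.arange(config.n_visits) * config.visit_spacing_years
    coef_f = np.asarray(config.traj_coefficients["fbs"], dtype=float)
    coef_s = np.asarray(config.traj_coefficients["sbp"], dtype=float)
    curves_f = np.stack([_polynomial(c, t_visits) for c in coef_f])  # K x T
    curves_s = np.stack([_polynomial(c, t_visits) for c in coef_s])

    fbs_vis = (fbs_base[:, None] + curves_f[labels]
               + rng.normal(0.0, config.visit_noise_sd_fbs,
                            size=(n, config.n_visits)))
    sbp_vis = (sbp_base[:, None] + curves_s[labels]
               + rng.normal(0.0, config.visit_noise_sd_sbp,
                            size=(n, config.n_visits)))
    if config.visit_missing_rate > 0:
        # baseline visit is always observed; later visits drop out at random
        drop = rng.random((n, config.n_visits)) < config.visit_missing_rate
        drop[:, 0] = False
        fbs_vis[drop] = np.nan
        sbp_vis[drop] = np.nan

    subject_ids = [f"S{i:06d}" for i in range(n)]
    visits = pd.DataFrame({
        "subject_id": np.repeat(subject_ids, config.n_visits),
        "visit": np.tile(np.arange(config.n_visits), n),
        "time_years": np.tile(t_visits, n),
        "fbs": fbs_vis.ravel(),
        "sbp": sbp_vis.ravel(),
    })

    # ---- prevalent disease at baseline ------------------------------
    prevalent = {}
    for cond in ("t2d", "htn", "stroke"):
        spec_val = config.prevalence.get(cond, 0.0)
        flag = np.zeros(n, dtype=bool)
        if isinstance(spec_val, (int, np.integer)) and not isinstance(
                spec_val, bool):
            k = int(spec_val)
            if k > n:
                raise ValueError(f"prevalence count for {cond} exceeds n")
            flag[rng.choice(n, size=k, replace=False)] = True
        else:
            flag = rng.random(n) < float(spec_val)
        prevalent[cond] = flag

    med_dm = prevalent["t2d"] & (rng.random(n) < 0.8)
    med_ht = prevalent["htn"] & (rng.random(n) < 0.8)

    baseline = pd.DataFrame({
        "subject_id": subject_ids,
        "age": age,
        "sex": np.where(male, "male", "female"),
        "bmi": bmi,
        "smoking": smoking,
        "alcohol": alcohol,
        "exercise": exercise,
        "med_antidiabetic": med_dm.astype(int),
        "med_antihypertensive": med_ht.astype(int),
        "prevalent_t2d": prevalent["t2d"].astype(int),
        "prevalent_htn": prevalent["htn"].astype(int),
        "prevalent_stroke": prevalent["stroke"].astype(int),
    })

    # ---- event times -------------------------------------------------
    em = config.event_model
    unc = {ph: _true_uncontrolled_group(config, ph) for ph in ("fbs", "sbp")}
    events = {"subject_id": subject_ids}
    for outcome, pheno in (("t2d", "sbp"), ("htn", "fbs")):
        loghr = em.log_hr.get(outcome, {})
        eta = np.zeros(n)
        if "uncontrolled" in loghr:
            eta += loghr["uncontrolled"] * (labels == unc[pheno])
        if "age" in loghr:
            eta += loghr["age"] * age_c
        if "male" in loghr:
            eta += loghr["male"] * male
        if "bmi" in loghr:
            eta += loghr["bmi"] * (bmi - 24.5)
        rate = em.baseline_hazard[outcome] * np.exp(eta)
        e_unit = rng.exponential(1.0, size=n)
        t_event = (e_unit / rate) ** (1.0 / em.shape)
        observed = t_event <= config.censor_date_years
        events[f"{outcome}_time"] = np.where(
            observed, t_event, config.censor_date_years)
        events[f"{outcome}_event"] = observed.astype(int)
    events_df = pd.DataFrame(events)

    # apply genotype missingness to the released matrix only
    genotypes = genotypes_full.copy()
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        genotypes[mask] = np.nan

    meta = {
        "seed": int(config.seed if seed is None else seed),
        "shared_snp_ids": variant_meta.loc[variant_meta.is_shared,
                                           "snp_id"].tolist(),
        "uncontrolled_group": unc,
        "causal_fbs_to_sbp": a,
        "causal_sbp_to_fbs": b,
    }
    return CohortPanel(subject_ids=subject_ids, genotypes=genotypes,
                       variant_meta=variant_meta, baseline=baseline,
                       visits=visits, true_labels=labels, events=events_df,
                       meta=meta)


def simulate_summary_statistics(
    n_variants: int,
    causal_effect: float,
    *,
    beta_exposure_sd: float = 0.1,
    se_exposure: float = 0.01,
    se_outcome: float = 0.02,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    seed: int | None = None,
    direction: str = "X->Y",
):
    """Draw per-variant two-sample summary statistics directly.

    The generating model is ``beta_Y = causal_effect * beta_X + alpha + e``
    with pleiotropic effects ``alpha ~ Normal(pleiotropy_mean,
    pleiotropy_sd)`` independent of instrument strength (the InSIDE
    condition). Useful for calibration studies of the summary-data
    estimators without building a full cohort.
    """
    from .mr import TwoSampleInput

    rng = np.random.default_rng(seed)
    # instruments come pre-oriented to the exposure-increasing allele,
    # so true exposure associations are positive
    true_bx = np.abs(rng.normal(0.0, beta_exposure_sd, size=n_variants))
    alpha = rng.normal(pleiotropy_mean, pleiotropy_sd, size=n_variants) \
        if pleiotropy_sd > 0 or pleiotropy_mean != 0 else np.zeros(n_variants)
    bx = true_bx + rng.normal(0.0, se_exposure, size=n_variants)
    by = (causal_effect * true_bx + alpha
          + rng.normal(0.0, se_outcome, size=n_variants))
    return TwoSampleInput(
        beta_exposure=bx,
        se_exposure=np.full(n_variants, se_exposure),
        beta_outcome=by,
        se_outcome=np.full(n_variants, se_outcome),
        snp_id=np.array([f"snp{j:05d}" for j in range(n_variants)]),
        direction=direction,
    )
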