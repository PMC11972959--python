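"""MR estimator contracts: closed forms, oracles, and planted-truth checks."""

import numpy as np
import pandas as pd
import pytest

from mrtraj import (SimulationConfig, TwoSampleInput, build_wgrs, egger,
                    fit_2sls, generate_cohort, ivw, leave_one_out, median_mr,
                    run_bidirectional, simulate_summary_statistics,
                    two_sample_from_summaries, weighted_median)
from mrtraj.instruments import InstrumentSet
from conftest import tiny_config


def random_two_sample(m=20, seed=0, effect=0.4):
    return simulate_summary_statistics(m, effect, seed=seed)


# ---------------------------------------------------------------------
# 2SLS
# ---------------------------------------------------------------------

def test_2sls_with_perfect_instrument_equals_ols():
    rng = np.random.default_rng(0)
    n = 200
    x = rng.normal(size=n)
    y = 0.7 * x + rng.normal(size=n)
    est, diag = fit_2sls(x, y, instrument=x)
    X = np.column_stack([np.ones(n), x])
    ols = np.linalg.solve(X.T @ X, X.T @ y)[1]
    assert est.effect == pytest.approx(ols, abs=1e-10)
    assert not diag.weak_flag


def test_2sls_point_estimate_is_wald_ratio_on_small_fixture():
    rng = np.random.default_rng(1)
    n = 12
    z = rng.normal(size=n)
    x = 0.5 * z + rng.normal(size=n)
    y = 0.3 * x + rng.normal(size=n)
    est, _ = fit_2sls(x, y, z)
    zc = z - z.mean()
    wald = (zc @ y) / (zc @ x)
    assert est.effect == pytest.approx(wald, abs=1e-12)


def test_2sls_unbiased_under_confounding_where_ols_is_not():
    """Planted SBP->FBS effect of 0.05 with strong confounding: the IV
    estimate centers on the truth while naive OLS is pulled away."""
    truth = 0.05
    ests, ols_ests = [], []
    reps = 60
    for r in range(reps):
        cfg = tiny_config(n_subjects=2000, n_snps_fbs=12, n_snps_sbp=12,
                          n_shared=0, causal_fbs_to_sbp=0.0,
                          causal_sbp_to_fbs=truth, confounder_sd=1.0,
                          missing_rate=0.0, seed=1000 + r)
        panel = generate_cohort(cfg)
        vm = panel.variant_meta
        inst = vm[vm.affects_sbp][["snp_id", "effect_allele",
                                   "true_beta_sbp"]].rename(
            columns={"true_beta_sbp": "beta"})
        w = build_wgrs(panel, inst)
        ph = panel.baseline_phenotypes()
        x = ph["sbp"].to_numpy()
        y = ph["fbs"].to_numpy()
        est, _ = fit_2sls(x, y, w)
        ests.append(est.effect)
        X = np.column_stack([np.ones_like(x), x])
        ols_ests.append(np.linalg.solve(X.T @ X, X.T @ y)[1])
    mc_se = np.std(ests, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(ests) - truth) < 3 * mc_se
    # confounding biases OLS visibly relative to the same MC precision
    assert abs(np.mean(ols_ests) - truth) > 5 * mc_se


def test_2sls_rejects_degenerate_instruments():
    rng = np.random.default_rng(2)
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    with pytest.raises(ValueError, match="instrument"):
        fit_2sls(x, y, np.ones(50))
    cov = rng.normal(size=50)
    with pytest.raises(ValueError, match="instrument"):
        fit_2sls(x, y, 2.0 * cov + 1.0, covariates=cov)


# ---------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------

def test_ivw_single_variant_is_wald_ratio():
    d = TwoSampleInput([2.0], [0.1], [1.0], [0.1], ["a"])
    assert ivw(d).effect == pytest.approx(0.5)


def test_ivw_constant_ratio_is_returned_exactly():
    rng = np.random.default_rng(3)
    bx = rng.uniform(0.1, 1.0, 10)
    d = TwoSampleInput(bx, rng.uniform(0.01, 0.1, 10), 0.37 * bx,
                       rng.uniform(0.01, 0.1, 10), [f"s{i}" for i in range(10)])
    assert ivw(d).effect == pytest.approx(0.37, abs=1e-12)


def test_ivw_matches_weighted_least_squares_oracle():
    d = random_two_sample(m=20, seed=4)
    est = ivw(d)
    w = 1.0 / d.se_outcome ** 2
    X = d.beta_exposure[:, None]
    beta = np.linalg.solve(X.T @ (w[:, None] * X),
                           X.T @ (w * d.beta_outcome))[0]
    se = np.sqrt(np.linalg.inv(X.T @ (w[:, None] * X))[0, 0])
    assert est.effect == pytest.approx(beta, abs=1e-10)
    assert est.se == pytest.approx(se, abs=1e-10)


def test_ivw_excludes_zero_exposure_variants_with_warning():
    d = TwoSampleInput([0.0, 1.0, 2.0], [0.1] * 3, [0.1, 0.5, 1.0],
                       [0.1] * 3, ["a", "b", "c"])
    with pytest.warns(UserWarning, match="zero exposure"):
        est = ivw(d)
    assert est.n_instruments == 2


# ---------------------------------------------------------------------
# medians
# ---------------------------------------------------------------------

def test_simple_median_of_ratios():
    bx = np.ones(5)
    by = np.array([1.0, 1.0, 1.0, 5.0, 9.0])
    d = TwoSampleInput(bx, 0.1 * bx, by, 0.1 * bx, list("abcde"))
    assert median_mr(d, weighted=False, n_boot=200, seed=0).effect \
        == pytest.approx(1.0)


def test_weighted_median_with_equal_weights_is_simple_median():
    d = random_two_sample(m=15, seed=5)
    d_eq = TwoSampleInput(d.beta_exposure,
                          d.se_exposure,
                          d.beta_outcome,
                          np.full(len(d), 0.05) * np.abs(d.beta_exposure),
                          d.snp_id)
    # equal ratio weights: w = bx^2/se_y^2 constant when se_y ~ |bx|
    ratios = d_eq.beta_outcome / d_eq.beta_exposure
    simple = weighted_median(ratios, np.ones(len(d)))
    weighted = weighted_median(ratios, np.full(len(d), 3.7))
    assert weighted == pytest.approx(simple, abs=1e-12)


def test_weighted_median_breakdown_point():
    """Valid half (slightly up-weighted) dominates the estimate."""
    m_valid, m_invalid = 26, 24
    bx = np.concatenate([np.full(m_valid, 1.0), np.full(m_invalid, 1.0)])
    by = np.concatenate([np.full(m_valid, 0.4), np.full(m_invalid, 2.0)])
    se_y = np.concatenate([np.full(m_valid, 0.09),
                           np.full(m_invalid, 0.11)])
    rng = np.random.default_rng(6)
    by = by + rng.normal(0, 0.01, len(by))
    d = TwoSampleInput(bx, np.full(len(bx), 0.01), by, se_y,
                       [f"s{i}" for i in range(len(bx))])
    est = median_mr(d, weighted=True, n_boot=1000, seed=7)
    assert abs(est.effect - 0.4) < 0.05


def test_weighted_median_duplication_invariance():
    d = random_two_sample(m=11, seed=8)
    ratios = d.beta_outcome / d.beta_exposure
    w = d.beta_exposure ** 2 / d.se_outcome ** 2
    base = weighted_median(ratios, w)
    ratios2 = np.concatenate([ratios, [ratios[4]]])
    w2 = np.concatenate([w, [w[4] / 2]])
    w2[4] /= 2
    assert weighted_median(ratios2, w2) == pytest.approx(base, abs=1e-12)


def test_median_warns_on_tiny_bootstrap():
    d = random_two_sample(m=5, seed=9)
    with pytest.warns(UserWarning, match="unstable"):
        median_mr(d, n_boot=50, seed=0)


# ---------------------------------------------------------------------
# Egger
# ---------------------------------------------------------------------

def test_egger_on_exact_line_through_origin_has_null_intercept():
    bx = np.linspace(0.2, 1.0, 8)
    d = TwoSampleInput(bx, 0.01 * np.ones(8), 0.5 * bx,
                       0.02 * np.ones(8), [f"s{i}" for i in range(8)])
    est = egger(d)
    assert est.intercept == pytest.approx(0.0, abs=1e-12)
    assert est.effect == pytest.approx(0.5, abs=1e-12)
    assert est.intercept_p > 0.99


def test_egger_matches_weighted_normal_equations_oracle():
    d = random_two_sample(m=20, seed=10)
    est = egger(d)
    flip = np.sign(d.beta_exposure)
    bx, by = d.beta_exposure * flip, d.beta_outcome * flip
    w = 1.0 / d.se_outcome ** 2
    X = np.column_stack([np.ones(len(bx)), bx])
    coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * by))
    assert est.intercept == pytest.approx(coef[0], abs=1e-10)
    assert est.effect == pytest.approx(coef[1], abs=1e-10)


def test_egger_matches_statsmodels_wls():
    import statsmodels.api as sm

    d = random_two_sample(m=25, seed=11)
    est = egger(d)
    flip = np.sign(d.beta_exposure)
    bx, by = d.beta_exposure * flip, d.beta_outcome * flip
    w = 1.0 / d.se_outcome ** 2
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    assert est.effect == pytest.approx(fit.params[1], abs=1e-10)
    assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
    # with dispersion > 1 the SEs coincide with WLS's estimated-scale SEs
    resid = by - fit.fittedvalues
    disp = float(resid @ (w * resid) / (len(d) - 2))
    if disp >= 1:
        assert est.se == pytest.approx(fit.bse[1], rel=1e-8)


def test_egger_detects_directional_pleiotropy():
    """Directional pleiotropy on the outcome-SE scale: >= 80% power, m=60."""
    hits = 0
    reps = 100
    for r in range(reps):
        d = simulate_summary_statistics(
            60, 0.4, pleiotropy_mean=0.02, pleiotropy_sd=0.004,
            seed=2000 + r)
        if egger(d).intercept_p < 0.05:
            hits += 1
    assert hits / reps >= 0.80


def test_egger_unidentifiable_when_exposure_betas_equal():
    d = TwoSampleInput([0.5, 0.5, -0.5], [0.1] * 3, [0.2, 0.3, -0.1],
                       [0.1] * 3, ["a", "b", "c"])
    with pytest.raises(ValueError, match="unidentifiable"):
        egger(d)


# ---------------------------------------------------------------------
# single-instrument coincidences, leave-one-out, bidirectional report
# ---------------------------------------------------------------------

def test_single_instrument_ivw_equals_wald_ratio_and_egger_refused():
    d = TwoSampleInput([0.8], [0.05], [0.32], [0.05], ["a"])
    assert ivw(d).effect == pytest.approx(0.4, abs=1e-12)
    with pytest.raises(ValueError):
        egger(d)


def test_ivw_consistent_with_2sls_single_variant():
    """Summary stats computed from the same sample: IVW == 2SLS (1 SNP)."""
    rng = np.random.default_rng(12)
    n = 500
    g = rng.binomial(2, 0.3, n).astype(float)
    x = 0.5 * g + rng.normal(0, 1, n)
    y = 0.3 * x + rng.normal(0, 1, n)

    def simple_ols(y_, x_):
        X = np.column_stack([np.ones(n), x_])
        coef = np.linalg.solve(X.T @ X, X.T @ y_)
        r = y_ - X @ coef
        s2 = r @ r / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        return coef[1], se

    bx, sx = simple_ols(x, g)
    by, sy = simple_ols(y, g)
    d = TwoSampleInput([bx], [sx], [by], [sy], ["g"])
    est2, _ = fit_2sls(x, y, g)
    assert ivw(d).effect == pytest.approx(est2.effect, abs=1e-6)


def test_leave_one_out_flags_planted_outlier():
    """A single large-effect pleiotropic variant drives the Egger intercept;
    only its exclusion flips the intercept test back to null — the pattern
    seen when an outlier variant shared by both traits is removed."""
    m = 12
    bx = np.concatenate([np.linspace(0.1, 0.5, m - 1), [1.5]])
    by = 0.5 * bx + np.random.default_rng(4).normal(0, 0.004, m)
    by[-1] += 0.2                       # pleiotropic large-effect outlier
    d = TwoSampleInput(bx, np.full(m, 0.01), by, np.full(m, 0.02),
                       [f"s{i}" for i in range(m)])
    assert egger(d).intercept_p < 0.05
    loo = leave_one_out(d, "MR_Egger")
    flagged = loo[loo.flagged]["excluded_snp"].tolist()
    assert flagged == ["s11"]


def test_leave_one_out_homogeneous_ratios_flags_nothing():
    rng = np.random.default_rng(13)
    bx = rng.uniform(0.2, 1.0, 10)
    d = TwoSampleInput(bx, np.full(10, 0.01), 0.5 * bx + rng.normal(0, 0.002, 10),
                       np.full(10, 0.02), [f"s{i}" for i in range(10)])
    loo = leave_one_out(d, "MR_Egger")
    assert not loo.flagged.any()


def test_leave_one_out_ivw_is_definitional():
    d = random_two_sample(m=20, seed=14)
    loo = leave_one_out(d, "IVW")
    sub = d.drop_snp(d.snp_id[0])
    assert loo.effect.iloc[0] == pytest.approx(ivw(sub).effect, abs=1e-14)


def _marginal_snp_ols(g, y):
    """Vectorized per-SNP simple regressions (intercept + dosage)."""
    gc = g - g.mean(0)
    yc = y - y.mean()
    sxx = (gc ** 2).sum(0)
    beta = gc.T @ yc / sxx
    rss = (yc ** 2).sum() - beta ** 2 * sxx
    se = np.sqrt(rss / (len(y) - 2) / sxx)
    return beta, se


def test_five_estimator_ci_coverage_under_no_pleiotropy():
    """No pleiotropy, strong instruments, split-sample summaries
    (n=2,000, 30 variants, 500 replicates): the 95% CIs of 2SLS, IVW,
    weighted median and MR-Egger cover the truth at 93-97%; the simple
    median's parametric-bootstrap CI is conservative (coverage above the
    band but never anticonservative), a known property of that SE."""
    theta = 0.1
    reps = 500
    cover = {k: 0 for k in ("2SLS", "IVW", "simple_median",
                            "weighted_median", "MR_Egger")}
    for r in range(reps):
        rng = np.random.default_rng(50_000 + r)
        n, m = 2000, 30
        maf = rng.uniform(0.25, 0.35, m)
        g = rng.binomial(2, maf[None, :], (n, m)).astype(float)
        bx = rng.uniform(0.2, 0.5, m)
        u = rng.normal(0, 1, n)
        x = g @ bx + u + rng.normal(0, 1, n)
        y = theta * x + u + rng.normal(0, 1, n)
        est, _ = fit_2sls(x, y, g @ bx)
        lo, hi = est.ci()
        cover["2SLS"] += lo <= theta <= hi
        half = n // 2
        bX, sX = _marginal_snp_ols(g[:half], x[:half])
        bY, sY = _marginal_snp_ols(g[half:], y[half:])
        d = TwoSampleInput(bX, sX, bY, sY,
                           [f"s{i}" for i in range(m)])
        for e in (ivw(d), egger(d),
                  median_mr(d, False, n_boot=300, seed=r),
                  median_mr(d, True, n_boot=300, seed=r)):
            lo, hi = e.ci()
            cover[e.method] += lo <= theta <= hi
    rates = {k: v / reps for k, v in cover.items()}
    for k in ("2SLS", "IVW", "weighted_median", "MR_Egger"):
        assert 0.93 <= rates[k] <= 0.97, (k, rates[k])
    assert rates["simple_median"] >= 0.93, rates["simple_median"]


def test_bidirectional_report_shape_and_round_trip(tmp_path, midsize_panel):
    vm = midsize_panel.variant_meta
    inst_f = InstrumentSet("fbs", vm[vm.affects_fbs][
        ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
         "true_beta_fbs"]].rename(columns={"true_beta_fbs": "beta"}))
    inst_s = InstrumentSet("sbp", vm[vm.affects_sbp][
        ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
         "true_beta_sbp"]].rename(columns={"true_beta_sbp": "beta"}))
    rep = run_bidirectional(midsize_panel, inst_f, inst_s, n_boot=200,
                            seed=0)
    t = rep.table
    assert set(t.direction) == {"FBS->SBP", "SBP->FBS"}
    assert set(t.method) == {"2SLS", "IVW", "simple_median",
                             "weighted_median", "MR_Egger"}
    # shared-variant-excluded re-analysis present for both directions
    assert t.excluded_shared.any()
    without = t[t.excluded_shared]
    assert set(without.direction) == {"FBS->SBP", "SBP->FBS"}
    # Egger rows carry the intercept, others do not
    assert t.loc[t.method == "MR_Egger", "intercept"].notna().all()
    assert t.loc[t.method == "IVW", "intercept"].isna().all()
    # sex-stratified diagnostics exist
    assert {"all", "male", "female"} <= set(rep.diagnostics.subgroup)
    rep.to_tsv(tmp_path / "mr.tsv", tmp_path / "diag.tsv")
    back = pd.read_csv(tmp_path / "mr.tsv", sep="\t")
    assert len(back) == len(t)
    assert list(back.columns) == list(t.columns)
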