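"""QC, GWAS, clumping and wGRS contracts against independent oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from mrtraj import (bonferroni_threshold, build_wgrs, hwe_exact_test,
                    ld_clump, qc_filter, run_gwas)
from conftest import manual_panel


# ---------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------

def hwe_oracle(n_het, n_hom_minor, n_hom_major):
    """Full enumeration with exact rational arithmetic."""
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n - n_minor
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    if n_minor == 0:
        return 1.0
    from math import factorial

    probs = {}
    for h in range(n_minor % 2, min(n_minor, n_major) + 1, 2):
        hm = (n_minor - h) // 2
        hM = n - h - hm
        # exact probability: n! 2^h n_minor! n_major! / (hm! h! hM! (2n)!)
        probs[h] = Fraction(factorial(n) * 2 ** h * factorial(n_minor)
                            * factorial(n_major),
                            factorial(hm) * factorial(h) * factorial(hM)
                            * factorial(2 * n))
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


@pytest.mark.parametrize("het,hom_min,hom_maj", [
    (489, 213, 298),   # kept example: p ~ 0.64-0.66, well above 1e-4
    (57, 14, 50), (3, 0, 100), (0, 10, 10), (21, 10, 69), (100, 5, 5),
])
def test_hwe_exact_matches_rational_enumeration(het, hom_min, hom_maj):
    assert hwe_exact_test(het, hom_min, hom_maj) == pytest.approx(
        hwe_oracle(het, hom_min, hom_maj), abs=1e-10)


def test_hwe_example_genotype_table_is_kept():
    """counts (AA=298, Aa=489, aa=213) at n=1000: p well above the QC cut."""
    p = hwe_exact_test(489, 213, 298)
    assert 0.6 < p < 0.7
    assert p > 1e-4


# ---------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------

def test_qc_drops_monomorphic_low_callrate_and_hwe_failures():
    rng = np.random.default_rng(0)
    n = 1000
    good = rng.binomial(2, 0.3, n).astype(float)
    mono = np.zeros(n)
    lowcall = good.copy()
    lowcall[: n // 20] = np.nan          # call rate 0.95 < 0.96 boundary
    het_excess = np.ones(n)              # all heterozygous: extreme HWE
    geno = np.column_stack([good, mono, lowcall, het_excess, good])
    panel = manual_panel(geno)
    # keep all subjects so the per-variant call-rate rule is what bites
    res = qc_filter(panel, subject_missing=0.5)
    rep = res.variant_report.set_index("snp_id")
    assert rep.loc["rs0", "kept"]
    assert rep.loc["rs1", "reason"] == "maf"
    assert rep.loc["rs2", "reason"] == "call_rate"
    assert rep.loc["rs3", "reason"] == "hwe"
    assert res.kept_variants == ["rs0", "rs4"]


def test_qc_all_missing_variant_reported_not_crashed():
    geno = np.column_stack([np.full(50, np.nan),
                            np.random.default_rng(1).binomial(2, 0.4, 50)])
    res = qc_filter(manual_panel(geno), subject_missing=0.6)
    assert res.variant_report.set_index("snp_id").loc["rs0", "reason"] \
        == "no_calls"


def test_qc_subjects_with_excess_missingness_dropped_first():
    rng = np.random.default_rng(2)
    geno = rng.binomial(2, 0.3, size=(40, 20)).astype(float)
    geno[0, :5] = np.nan                  # 25% missing -> dropped
    res = qc_filter(manual_panel(geno))
    assert res.n_subjects_dropped == 1
    assert "S000" not in res.kept_subjects


def test_qc_is_idempotent(tiny_panel):
    first = qc_filter(tiny_panel)
    sub = tiny_panel.subset_subjects(
        np.isin(tiny_panel.subject_ids, first.kept_subjects))
    second = qc_filter(sub)
    assert second.kept_variants == first.kept_variants


# ---------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------

def test_gwas_exact_linear_phenotype_recovers_slope():
    rng = np.random.default_rng(3)
    dos = rng.binomial(2, 0.4, 60).astype(float)
    panel = manual_panel(dos[:, None], fbs=0.5 * dos)
    summ = run_gwas(panel, "fbs", covariates=())
    assert summ.beta[0] == pytest.approx(0.5, abs=1e-12)
    assert summ.se[0] == pytest.approx(0.0, abs=1e-10)


def test_gwas_matches_normal_equations_oracle():
    rng = np.random.default_rng(4)
    n, m = 30, 6
    geno = rng.binomial(2, 0.35, size=(n, m)).astype(float)
    age = rng.uniform(40, 70, n)
    sex = rng.permutation(["male"] * 15 + ["female"] * 15)
    y = (0.3 * geno[:, 0] + 0.01 * age + rng.normal(0, 0.4, n))
    panel = manual_panel(geno, age=age, sex=list(sex), fbs=y)
    summ = run_gwas(panel, "fbs")
    male = (np.asarray(sex) == "male").astype(float)
    for j in range(m):
        X = np.column_stack([np.ones(n), geno[:, j], age, male])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert summ.beta[j] == pytest.approx(beta[1], abs=1e-10)


def test_gwas_matches_statsmodels(midsize_panel):
    import statsmodels.api as sm

    summ = run_gwas(midsize_panel, "sbp").head(4)
    base = midsize_panel.baseline
    phen = midsize_panel.baseline_phenotypes()
    for row in summ.itertuples():
        dos = midsize_panel.dosage(row.snp_id)
        mask = ~np.isnan(dos)
        X = sm.add_constant(np.column_stack([
            dos[mask], base.age[mask],
            (base.sex == "male").to_numpy(dtype=float)[mask]]))
        fit = sm.OLS(phen.sbp.to_numpy()[mask], X).fit()
        assert row.beta == pytest.approx(fit.params[1], abs=1e-8)
        assert row.se == pytest.approx(fit.bse[1], abs=1e-8)
        assert row.p_value == pytest.approx(fit.pvalues[1], abs=1e-8)


def test_gwas_null_calibration_permuted_phenotype():
    rng = np.random.default_rng(5)
    n, m = 300, 400
    geno = rng.binomial(2, rng.uniform(0.1, 0.5, m)[None, :],
                        size=(n, m)).astype(float)
    y = rng.permutation(np.linspace(-1, 1, n))
    panel = manual_panel(geno, fbs=y)
    summ = run_gwas(panel, "fbs", covariates=())
    frac = (summ.p_value < 0.05).mean()
    assert abs(frac - 0.05) < 0.03


def test_gwas_zero_variance_dosage_flagged():
    geno = np.column_stack([np.full(30, 1.0),
                            np.random.default_rng(6).binomial(2, 0.4, 30)])
    summ = run_gwas(manual_panel(geno), "fbs", covariates=())
    assert summ.note[0] == "zero_variance"
    assert np.isnan(summ.beta[0]) and summ.p_value[0] == 1.0


# ---------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------

def _clump_certificate(kept, summaries, panel, r2, window):
    """Certificate check: kept is exactly the greedy-admissible set."""
    from mrtraj.instruments import _dosage_r2
    info = summaries.set_index("snp_id")
    kept = list(kept)
    for i, a in enumerate(kept):
        for b in kept[:i]:
            if info.at[a, "chrom"] == info.at[b, "chrom"] and \
                    abs(info.at[a, "pos"] - info.at[b, "pos"]) <= window:
                assert _dosage_r2(panel.dosage(a), panel.dosage(b)) < r2
    return True


def test_clump_prefers_smaller_p_among_correlated_pair():
    dos = np.random.default_rng(7).binomial(2, 0.3, 200).astype(float)
    geno = np.column_stack([dos, dos])  # perfect LD, 1 kb apart
    panel = manual_panel(geno, pos=[1000, 2000])
    summ = pd.DataFrame({
        "snp_id": ["rs0", "rs1"], "chrom": [1, 1], "pos": [1000, 2000],
        "beta": [0.2, 0.2], "se": [0.02, 0.02],
        "p_value": [1e-10, 1e-9]})
    inst = ld_clump(summ, panel, p_threshold=5e-8)
    assert inst.snp_ids == ["rs0"]


def test_clump_ignores_correlation_across_chromosomes():
    dos = np.random.default_rng(8).binomial(2, 0.3, 200).astype(float)
    panel = manual_panel(np.column_stack([dos, dos]),
                         chrom=[1, 2], pos=[1000, 2000])
    summ = pd.DataFrame({
        "snp_id": ["rs0", "rs1"], "chrom": [1, 2], "pos": [1000, 2000],
        "beta": [0.2, 0.2], "se": [0.02, 0.02],
        "p_value": [1e-10, 1e-9]})
    inst = ld_clump(summ, panel, p_threshold=5e-8)
    assert inst.snp_ids == ["rs0", "rs1"]


def test_clump_10_snp_fixture_matches_certificate_and_is_order_invariant():
    rng = np.random.default_rng(9)
    n, m = 400, 10
    base = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
    cols = []
    for j in range(m):
        src = base[:, j % 4].copy()
        flip = rng.random(n) < 0.15 * (j % 3)
        src[flip] = rng.binomial(2, 0.3, flip.sum())
        cols.append(src)
    geno = np.column_stack(cols)
    panel = manual_panel(geno, pos=[1000 * (j + 1) for j in range(m)])
    summ = pd.DataFrame({
        "snp_id": panel.snp_ids, "chrom": [1] * m,
        "pos": panel.variant_meta.pos, "beta": rng.normal(size=m),
        "se": np.full(m, 0.02),
        "p_value": rng.uniform(1e-12, 1e-9, m)})
    inst = ld_clump(summ, panel, r2_threshold=0.2, p_threshold=5e-8)
    assert _clump_certificate(inst.snp_ids, summ, panel, 0.2, 1_000_000)
    shuffled = summ.sample(frac=1.0, random_state=1).reset_index(drop=True)
    inst2 = ld_clump(shuffled, panel, r2_threshold=0.2, p_threshold=5e-8)
    assert inst2.snp_ids == inst.snp_ids


def test_clump_empty_result_warns_not_raises(tiny_panel):
    summ = run_gwas(tiny_panel, "fbs")
    with pytest.warns(UserWarning, match="no variants"):
        inst = ld_clump(summ, tiny_panel, p_threshold=1e-300)
    assert len(inst) == 0


# ---------------------------------------------------------------------
# wGRS
# ---------------------------------------------------------------------

def test_wgrs_trivial_weights():
    dos = np.array([[0.0], [1.0], [2.0]])
    panel = manual_panel(dos)
    w = build_wgrs(panel, pd.DataFrame({"snp_id": ["rs0"], "beta": [0.3]}))
    assert np.allclose(w, [0.0, 0.3, 0.6])
    z = build_wgrs(panel, pd.DataFrame({"snp_id": ["rs0"], "beta": [0.0]}))
    assert np.allclose(z, 0.0)


def test_wgrs_hand_computed_fixture_with_missing_call():
    geno = np.array([
        [0, 1, 2, 0, 1],
        [1, 1, 0, 2, 0],
        [2, np.nan, 1, 1, 1],
        [0, 2, 2, 1, 2],
    ], dtype=float)
    betas = np.array([0.1, -0.2, 0.3, 0.05, 0.4])
    panel = manual_panel(geno)
    inst = pd.DataFrame({"snp_id": panel.snp_ids, "beta": betas})
    scores = build_wgrs(panel, inst)
    # hand computation: rs1 has beta < 0 -> flip dosage to 2-d, weight 0.2;
    # the missing call at (2, rs1) is imputed with 2*freq of flipped allele
    flipped = 2.0 - geno[:, 1]
    freq = np.nanmean(flipped) / 2.0        # (1+1+0)/3 / 2 = 1/3
    d_imp = np.where(np.isnan(flipped), 2 * freq, flipped)
    expected = (0.1 * geno[:, 0] + 0.2 * d_imp + 0.3 * geno[:, 2]
                + 0.05 * geno[:, 3] + 0.4 * geno[:, 4])
    assert np.allclose(scores, expected, atol=1e-12)
    assert freq == pytest.approx(1 / 3)


def test_wgrs_missing_instrument_is_hard_error(tiny_panel):
    inst = pd.DataFrame({"snp_id": ["nope1", "nope2"], "beta": [0.1, 0.2]})
    with pytest.raises(KeyError, match="nope1"):
        build_wgrs(tiny_panel, inst)


def test_wgrs_allele_flip_invariance():
    rng = np.random.default_rng(10)
    geno = rng.binomial(2, 0.4, size=(50, 3)).astype(float)
    panel = manual_panel(geno)
    inst = pd.DataFrame({"snp_id": panel.snp_ids,
                         "effect_allele": ["A"] * 3,
                         "beta": [0.2, 0.5, 0.1]})
    w1 = build_wgrs(panel, inst)
    # flip coded allele of rs1 (A->G) and negate its beta
    inst2 = inst.copy()
    inst2.loc[1, "effect_allele"] = "G"
    inst2.loc[1, "beta"] = -0.5
    w2 = build_wgrs(panel, inst2)
    assert np.allclose(w1, w2, atol=1e-12)


def test_wgrs_is_calibrated_predictor():
    """Regressing the phenotype on the true-beta wGRS gives slope ~ 1.

    With the causal coupling off, the per-SNP weights are the total genetic
    effects, so the score predicts the phenotype on its own scale.
    """
    from conftest import tiny_config
    from mrtraj import generate_cohort

    panel = generate_cohort(tiny_config(
        n_subjects=2500, causal_fbs_to_sbp=0.0, causal_sbp_to_fbs=0.0,
        missing_rate=0.0, seed=13))
    vm = panel.variant_meta
    inst = vm[vm.affects_fbs][["snp_id", "effect_allele",
                               "true_beta_fbs"]].rename(
        columns={"true_beta_fbs": "beta"})
    w = build_wgrs(panel, inst)
    y = panel.baseline_phenotypes()["fbs"].to_numpy()
    X = np.column_stack([np.ones_like(w), w])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    se = np.sqrt(resid @ resid / (len(y) - 2)
                 / np.sum((w - w.mean()) ** 2))
    assert abs(coef[1] - 1.0) < 3 * se


# ---------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------

@pytest.mark.parametrize("alpha,m,expected", [
    (0.05, 91, 0.0005), (0.05, 68, 0.0007), (0.05, 1, 0.05)])
def test_bonferroni_matches_reported_thresholds(alpha, m, expected):
    assert round(bonferroni_threshold(alpha, m), 4) == expected


def test_bonferroni_rejects_zero_tests():
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)
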