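"""Variant QC, per-SNP GWAS, LD clumping and weighted genetic risk scores.

This stage turns a genotyped panel into an instrument set: variants are
filtered on call rate, Hardy-Weinberg equilibrium (exact test) and minor
allele frequency; per-SNP additive-model least squares (adjusted for age
and sex by default) yields effect sizes; greedy p-value-ordered LD clumping
thins them to approximately independent instruments; and the weighted
genetic risk score wGRS_i = sum_k beta_k * dosage_ik aggregates them into
one instrumental variable per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy import stats

SUMMARY_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                   "beta", "se", "p_value", "n_used", "maf", "hwe_p",
                   "call_rate"]


# ---------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------

def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg p-value by full enumeration of heterozygote counts.

    Conditions on the observed minor-allele count and sums the probabilities
    of all genotype configurations no more probable than the observed one
    (two-sided, Wigginton-style). Well defined at any MAF; returns 1.0 for
    degenerate (monomorphic or empty) tables.
    """
    n_het, n_hom_minor, n_hom_major = int(n_het), int(n_hom_minor), int(n_hom_major)
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:  # caller swapped the homozygote classes
        n_minor, n_major = n_major, n_minor
    if n == 0 or n_minor == 0:
        return 1.0

    # enumerate all het counts with the parity of n_minor
    h = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    hom_min = (n_minor - h) // 2
    hom_maj = (n - h - hom_min)
    logp = (h * np.log(2.0)
            + gammaln(n + 1) - gammaln(h + 1) - gammaln(hom_min + 1)
            - gammaln(hom_maj + 1)
            + gammaln(n_minor + 1) + gammaln(n_major + 1) - gammaln(2 * n + 1))
    p = np.exp(logp)
    p_obs = p[np.nonzero(h == n_het)[0][0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _variant_qc_stats(dosages: np.ndarray) -> dict:
    obs = dosages[~np.isnan(dosages)]
    n_used = obs.size
    call_rate = n_used / dosages.size if dosages.size else 0.0
    if n_used == 0:
        return {"call_rate": 0.0, "maf": np.nan, "hwe_p": np.nan,
                "n_used": 0}
    freq = obs.mean() / 2.0
    maf = min(freq, 1.0 - freq)
    counts = [int((obs == g).sum()) for g in (0.0, 1.0, 2.0)]
    # orient to minor allele for the exact test
    if freq <= 0.5:
        hom_minor, het, hom_major = counts[2], counts[1], counts[0]
    else:
        hom_minor, het, hom_major = counts[0], counts[1], counts[2]
    return {"call_rate": call_rate, "maf": maf,
            "hwe_p": hwe_exact_test(het, hom_minor, hom_major),
            "n_used": n_used}


# ---------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------

@dataclass
class QCResult:
    kept_variants: list[str]
    kept_subjects: list[str]
    variant_report: pd.DataFrame
    n_subjects_dropped: int


def qc_filter(panel, *, call_rate: float = 0.96, hwe_p: float = 1e-4,
              maf: float = 0.01, subject_missing: float = 0.05) -> QCResult:
    """Drop subjects with excess missingness, then filter variants.

    Subjects with more than ``subject_missing`` missing genotypes are
    removed first; variants then fail, in order of precedence, on
    ``no_calls``, ``call_rate``, ``maf`` or ``hwe``. The report records one
    row per variant with its statistics and the failing rule, if any.
    """
    geno = panel.genotypes
    subj_missing = np.isnan(geno).mean(axis=1)
    subj_keep = subj_missing <= subject_missing
    geno = geno[subj_keep]
    kept_subjects = [s for s, k in zip(panel.subject_ids, subj_keep) if k]

    rows = []
    for j, snp in enumerate(panel.snp_ids):
        st = _variant_qc_stats(geno[:, j])
        reason = ""
        if st["n_used"] == 0:
            reason = "no_calls"
        elif st["call_rate"] < call_rate:
            reason = "call_rate"
        elif st["maf"] < maf:
            reason = "maf"
        elif st["hwe_p"] < hwe_p:
            reason = "hwe"
        rows.append({"snp_id": snp, **st, "kept": reason == "",
                     "reason": reason})
    report = pd.DataFrame(rows)
    return QCResult(
        kept_variants=report.loc[report.kept, "snp_id"].tolist(),
        kept_subjects=kept_subjects,
        variant_report=report,
        n_subjects_dropped=int((~subj_keep).sum()),
    )


# ---------------------------------------------------------------------
# per-SNP GWAS
# ---------------------------------------------------------------------

def run_gwas(panel, phenotype: str, covariates=("age", "sex"),
             variant_ids: list[str] | None = None,
             subject_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-SNP additive-model least squares of a baseline phenotype.

    For each SNP, ordinary least squares of the visit-0 phenotype on dosage
    plus covariates, excluding subjects with a missing call at that SNP.
    Two-sided p-values come from the t distribution with n-k df. A SNP whose
    dosage has zero variance after exclusions gets an undefined beta and
    p = 1, flagged in the ``note`` column.

    Returns a summary-statistics table in the package's TSV dialect
    (snp, position, alleles, beta, se, p, n, maf, hwe_p, call_rate).
    """
    pheno_df = panel.baseline_phenotypes().merge(panel.baseline,
                                                 on="subject_id")
    if phenotype not in pheno_df.columns:
        raise KeyError(f"phenotype column {phenotype!r} not present")
    if subject_ids is not None:
        sel = pheno_df.subject_id.isin(set(subject_ids)).to_numpy()
    else:
        sel = np.ones(len(pheno_df), dtype=bool)

    y_all = pheno_df[phenotype].to_numpy(dtype=float)
    cov_cols = []
    for c in covariates:
        if c == "sex":
            cov_cols.append((pheno_df["sex"] == "male").to_numpy(dtype=float))
        else:
            cov_cols.append(pheno_df[c].to_numpy(dtype=float))
    covmat = np.column_stack(cov_cols) if cov_cols else \
        np.empty((len(pheno_df), 0))

    vm = panel.variant_meta.set_index("snp_id")
    snp_list = variant_ids if variant_ids is not None else panel.snp_ids
    rows = []
    for snp in snp_list:
        j = panel.snp_index(snp)
        dos = panel.genotypes[:, j]
        mask = sel & ~np.isnan(dos) & ~np.isnan(y_all)
        d, y = dos[mask], y_all[mask]
        X = np.column_stack([np.ones(mask.sum()), d, covmat[mask]])
        st = _variant_qc_stats(dos[sel])
        base = {
            "snp_id": snp, "chrom": vm.at[snp, "chrom"],
            "pos": int(vm.at[snp, "pos"]),
            "effect_allele": vm.at[snp, "effect_allele"],
            "other_allele": vm.at[snp, "other_allele"],
            "n_used": int(mask.sum()), "maf": st["maf"],
            "hwe_p": st["hwe_p"], "call_rate": st["call_rate"],
        }
        if mask.sum() <= X.shape[1] or np.nanstd(d) == 0:
            rows.append({**base, "beta": np.nan, "se": np.nan,
                         "p_value": 1.0, "note": "zero_variance"})
            continue
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = mask.sum() - X.shape[1]
        sigma2 = resid @ resid / dof
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
        beta = float(coef[1])
        if se == 0:
            p = 0.0 if beta != 0 else 1.0
        else:
            p = float(2 * stats.t.sf(abs(beta) / se, dof))
        rows.append({**base, "beta": beta, "se": se,
                     "p_value": max(p, np.finfo(float).tiny), "note": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------

@dataclass
class InstrumentSet:
    """QC-passing, clumped instruments for one phenotype."""

    phenotype: str
    table: pd.DataFrame                  # VariantSummary rows
    clump_r2: float = 0.01
    window_bp: int = 1_000_000
    p_threshold: float = 5e-8

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def without(self, snp_ids) -> "InstrumentSet":
        drop = set(snp_ids if not isinstance(snp_ids, str) else [snp_ids])
        return InstrumentSet(self.phenotype,
                             self.table[~self.table.snp_id.isin(drop)]
                             .reset_index(drop=True),
                             self.clump_r2, self.window_bp, self.p_threshold)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, phenotype: str = "",
                 **kw) -> "InstrumentSet":
        return cls(phenotype, pd.read_csv(path, sep="\t"), **kw)


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    mask = ~np.isnan(a) & ~np.isnan(b)
    if mask.sum() < 3:
        return 0.0
    x, y = a[mask], b[mask]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def ld_clump(summaries: pd.DataFrame, panel, *, r2_threshold: float = 0.01,
             window_bp: int = 1_000_000, p_threshold: float = 5e-8,
             phenotype: str = "", target_count: int | None = None,
             relax_schedule=(0.01, 0.02, 0.03)) -> InstrumentSet:
    """Greedy p-value-ordered clumping on dosage correlation.

    Variants with p below ``p_threshold`` are visited in ascending p order
    (ties broken by snp_id); one is retained iff no already-retained variant
    on the same chromosome within ``window_bp`` (inclusive, 1-based
    coordinates) has squared dosage correlation >= ``r2_threshold``. When
    ``target_count`` is given, the r-squared threshold is relaxed along
    ``relax_schedule`` until that many instruments are retained (or the
    schedule is exhausted).
    """
    thresholds = [r2_threshold]
    if target_count is not None:
        thresholds = [t for t in relax_schedule if t >= r2_threshold] \
            or [r2_threshold]
    chosen = pd.DataFrame(columns=summaries.columns)
    used_r2 = thresholds[0]
    for thr in thresholds:
        chosen = _clump_once(summaries, panel, thr, window_bp, p_threshold)
        used_r2 = thr
        if target_count is None or len(chosen) >= target_count:
            break
    if len(chosen) == 0:
        warnings.warn("LD clumping retained no variants", stacklevel=2)
    return InstrumentSet(phenotype, chosen.reset_index(drop=True),
                         clump_r2=used_r2, window_bp=window_bp,
                         p_threshold=p_threshold)


def _clump_once(summaries, panel, r2_threshold, window_bp, p_threshold):
    cand = summaries[(summaries.p_value < p_threshold)
                     & summaries.beta.notna()].copy()
    cand = cand.sort_values(["p_value", "snp_id"], kind="mergesort")
    kept_rows = []
    kept_meta: list[tuple[int, int, np.ndarray]] = []  # chrom, pos, dosages
    for row in cand.itertuples(index=False):
        dos = panel.dosage(row.snp_id)
        ok = True
        for chrom, pos, other in kept_meta:
            if chrom == row.chrom and abs(int(row.pos) - pos) <= window_bp:
                if _dosage_r2(dos, other) >= r2_threshold:
                    ok = False
                    break
        if ok:
            kept_rows.append(row)
            kept_meta.append((row.chrom, int(row.pos), dos))
    return pd.DataFrame(kept_rows, columns=cand.columns)


# ---------------------------------------------------------------------
# weighted genetic risk score
# ---------------------------------------------------------------------

def build_wgrs(panel, instruments, return_details: bool = False):
    """Per-subject weighted genetic risk score.

    ``instruments`` may be an :class:`InstrumentSet` or any DataFrame with
    ``snp_id``, ``beta`` and (optionally) ``effect_allele`` columns, so
    externally estimated weights can be applied to the panel's genotypes.

    Each SNP is oriented to its trait-increasing allele: a negative weight
    flips the coded allele (dosage -> 2 - dosage) and negates beta, so all
    weights are nonnegative after normalization. Missing dosages are imputed
    with twice the oriented effect-allele frequency observed in the panel.
    """
    table = instruments.table if isinstance(instruments, InstrumentSet) \
        else instruments
    missing = [s for s in table["snp_id"] if s not in set(panel.snp_ids)]
    if missing:
        raise KeyError(f"instrument SNPs absent from panel: {missing}")

    vm = panel.variant_meta.set_index("snp_id")
    scores = np.zeros(panel.n_subjects)
    details = []
    for row in table.itertuples(index=False):
        dos = panel.dosage(row.snp_id).copy()
        beta = float(row.beta)
        if np.isnan(beta):
            continue
        eff = getattr(row, "effect_allele", None)
        panel_eff = vm.at[row.snp_id, "effect_allele"]
        flipped_allele = False
        if eff is not None and eff != panel_eff:
            if eff != vm.at[row.snp_id, "other_allele"]:
                raise ValueError(
                    f"{row.snp_id}: effect allele {eff!r} matches neither "
                    f"panel allele")
            dos = 2.0 - dos
            flipped_allele = True
        if beta < 0:  # orient to the trait-increasing allele
            dos = 2.0 - dos
            beta = -beta
            flipped_allele = not flipped_allele
        freq = np.nanmean(dos) / 2.0 if np.any(~np.isnan(dos)) else 0.0
        dos = np.where(np.isnan(dos), 2.0 * freq, dos)
        scores += beta * dos
        details.append({"snp_id": row.snp_id, "weight": beta,
                        "oriented_freq": freq, "flipped": flipped_allele})
    if return_details:
        return scores, pd.DataFrame(details)
    return scores


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise corrected per-test threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
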