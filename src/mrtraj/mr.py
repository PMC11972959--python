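"""Mendelian randomization estimators and diagnostics.

Five estimators, run bidirectionally between fasting blood sugar (FBS,
mmol/L) and systolic blood pressure (SBP, mmHg):

* two-stage least squares (2SLS) on individual-level data with the wGRS as
  the single instrument, with the first-stage partial F and the Wu-Hausman
  endogeneity test;
* inverse-variance weighted (IVW), simple median, weighted median and
  MR-Egger on per-variant summary statistics, with leave-one-out
  pleiotropy diagnostics and a shared-variant-excluded re-analysis.

IVW is the fixed-effect no-intercept weighted regression of outcome on
exposure associations; MR-Egger adds an intercept estimating average
directional pleiotropy. Median estimators use the cumulative-weight
interpolation form with parametric-bootstrap standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import InstrumentSet, build_wgrs, run_gwas

CLINICAL_INCREMENT = {"fbs": 0.5, "sbp": 10.0}  # mmol/L, mmHg


@dataclass
class TwoSampleInput:
    """Per-variant exposure/outcome associations for summary-data MR."""

    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    snp_id: np.ndarray
    direction: str = ""

    def __post_init__(self):
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.beta_exposure, self.se_exposure,
                   self.beta_outcome, self.se_outcome)]
        (self.beta_exposure, self.se_exposure,
         self.beta_outcome, self.se_outcome) = arrays
        self.snp_id = np.asarray(self.snp_id)
        n = len(self.beta_exposure)
        if not all(len(a) == n for a in arrays) or len(self.snp_id) != n:
            raise ValueError("all per-variant arrays must share one length")
        if n < 1:
            raise ValueError("need at least one variant")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("all standard errors must be positive")

    def __len__(self) -> int:
        return len(self.beta_exposure)

    def subset(self, mask) -> "TwoSampleInput":
        mask = np.asarray(mask)
        return TwoSampleInput(self.beta_exposure[mask],
                              self.se_exposure[mask],
                              self.beta_outcome[mask],
                              self.se_outcome[mask],
                              self.snp_id[mask], self.direction)

    def drop_snp(self, snp_id: str) -> "TwoSampleInput":
        return self.subset(self.snp_id != snp_id)


def two_sample_from_summaries(exposure: pd.DataFrame, outcome: pd.DataFrame,
                              direction: str = "") -> TwoSampleInput:
    """Align exposure/outcome GWAS tables on snp_id and effect allele."""
    merged = exposure.merge(outcome, on="snp_id", suffixes=("_x", "_y"))
    merged = merged[merged.beta_x.notna() & merged.beta_y.notna()]
    by = merged.beta_y.to_numpy(dtype=float)
    if "effect_allele_x" in merged and "effect_allele_y" in merged:
        flip = merged.effect_allele_x != merged.effect_allele_y
        by = np.where(flip, -by, by)
    return TwoSampleInput(merged.beta_x.to_numpy(dtype=float),
                          merged.se_x.to_numpy(dtype=float),
                          by,
                          merged.se_y.to_numpy(dtype=float),
                          merged.snp_id.to_numpy(), direction)


@dataclass
class MREstimate:
    method: str
    effect: float
    se: float
    p_value: float
    n_instruments: int
    direction: str = ""
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    df: float | None = None     # t reference when inference is t-based

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        q = 0.5 + level / 2
        z = stats.t.ppf(q, self.df) if self.df else stats.norm.ppf(q)
        return self.effect - z * self.se, self.effect + z * self.se


@dataclass
class TSLSDiagnostics:
    first_stage_F: float
    weak_flag: bool
    wu_hausman_stat: float
    wu_hausman_p: float
    n: int


# ---------------------------------------------------------------------
# individual-level: two-stage least squares
# ---------------------------------------------------------------------

def fit_2sls(exposure, outcome, instrument, covariates=None,
             direction: str = "") -> tuple[MREstimate, TSLSDiagnostics]:
    """2SLS of ``outcome`` on ``exposure`` using one instrument.

    Stage 1 regresses the exposure on the instrument and covariates; stage 2
    regresses the outcome on the fitted exposure and covariates. Standard
    errors use the structural residual (outcome minus the structural fit
    evaluated at the *observed* exposure), not the naive stage-2 residual.
    Also returns the first-stage partial F for the instrument and the
    Wu-Hausman endogeneity test from the control-function augmented
    regression.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    z = np.asarray(instrument, dtype=float)
    n = len(x)
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
    mask = ~(np.isnan(x) | np.isnan(y) | np.isnan(z)
             | (np.isnan(C).any(axis=1) if C.size else np.zeros(n, bool)))
    x, y, z, C = x[mask], y[mask], z[mask], C[mask]
    n = len(x)
    if n < C.shape[1] + 3:
        raise ValueError("too few observations for 2SLS")
    if np.std(z) == 0:
        raise ValueError("weak/collinear instrument, F undefined")

    W = np.column_stack([np.ones(n), C])          # exogenous regressors
    Z1 = np.column_stack([W, z])                  # stage-1 design

    # stage 1 and its partial F for the instrument
    g1, *_ = np.linalg.lstsq(Z1, x, rcond=None)
    xhat = Z1 @ g1
    r1 = x - xhat
    dof1 = n - Z1.shape[1]
    sigma1 = r1 @ r1 / dof1
    z1_inv = np.linalg.pinv(Z1.T @ Z1)
    se_g = np.sqrt(sigma1 * z1_inv[-1, -1])
    if not np.isfinite(se_g) or se_g == 0:
        raise ValueError("weak/collinear instrument, F undefined")
    first_stage_F = float((g1[-1] / se_g) ** 2)

    # residualize the instrument on covariates to detect collinearity
    w_coef, *_ = np.linalg.lstsq(W, z, rcond=None)
    z_resid = z - W @ w_coef
    if np.sqrt(z_resid @ z_resid / n) < 1e-10 * max(np.std(z), 1.0):
        raise ValueError("weak/collinear instrument, F undefined")

    # stage 2 with fitted exposure
    X2 = np.column_stack([W, xhat])
    b2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    effect = float(b2[-1])

    # proper 2SLS covariance: residual from observed exposure
    X_struct = np.column_stack([W, x])
    resid = y - X_struct @ b2
    k = X2.shape[1]
    sigma2 = resid @ resid / (n - k)
    cov = sigma2 * np.linalg.pinv(X2.T @ X2)
    se = float(np.sqrt(cov[-1, -1]))
    p = float(2 * stats.t.sf(abs(effect) / se, n - k)) if se > 0 else 0.0
    p = max(p, np.finfo(float).tiny)

    # Wu-Hausman by the control-function augmented regression
    A = np.column_stack([W, x, r1])
    ca, *_ = np.linalg.lstsq(A, y, rcond=None)
    ra = y - A @ ca
    dof_a = n - A.shape[1]
    sig_a = max(ra @ ra / dof_a, 0.0)
    a_inv = np.linalg.pinv(A.T @ A)
    se_rho = np.sqrt(max(sig_a * a_inv[-1, -1], 0.0))
    t_rho = ca[-1] / se_rho if se_rho > 0 else np.inf
    wh_stat = float(t_rho ** 2)
    wh_p = float(stats.f.sf(wh_stat, 1, dof_a))

    est = MREstimate(method="2SLS", effect=effect, se=se, p_value=p,
                     n_instruments=1, direction=direction, df=n - k)
    diag = TSLSDiagnostics(first_stage_F=first_stage_F,
                           weak_flag=first_stage_F < 10,
                           wu_hausman_stat=wh_stat, wu_hausman_p=wh_p, n=n)
    return est, diag


# ---------------------------------------------------------------------
# summary-data estimators
# ---------------------------------------------------------------------

def _drop_null_exposure(data: TwoSampleInput) -> TwoSampleInput:
    zero = data.beta_exposure == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} variant(s) with zero "
                      f"exposure association", stacklevel=3)
        data = data.subset(~zero)
    return data


def ivw(data: TwoSampleInput) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    Equivalent to the no-intercept regression of beta_outcome on
    beta_exposure with weights 1/se_outcome^2, i.e. the weighted mean of
    per-variant Wald ratios with weights beta_exposure^2/se_outcome^2.
    """
    data = _drop_null_exposure(data)
    bx, by, sy = data.beta_exposure, data.beta_outcome, data.se_outcome
    w = 1.0 / sy ** 2
    denom = float(np.sum(w * bx ** 2))
    effect = float(np.sum(w * bx * by) / denom)
    se = float(np.sqrt(1.0 / denom))
    p = float(2 * stats.norm.sf(abs(effect) / se))
    return MREstimate("IVW", effect, se, p, len(data), data.direction)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Cumulative-weight interpolation weighted median.

    Supports batched input: with 2-D ``values`` (and matching or
    broadcastable weights) the median is taken along the last axis.
    """
    values = np.asarray(values, dtype=float)
    weights = np.broadcast_to(np.asarray(weights, dtype=float), values.shape)
    if values.ndim == 1:
        # merge exact ties so splitting a variant's weight across
        # duplicates leaves the estimate unchanged
        uniq, inv = np.unique(values, return_inverse=True)
        if len(uniq) < len(values):
            values = uniq
            weights = np.bincount(inv, weights=weights)
    order = np.argsort(values, axis=-1)
    v = np.take_along_axis(values, order, axis=-1)
    w = np.take_along_axis(weights, order, axis=-1)
    cw = np.cumsum(w, axis=-1)
    tot = cw[..., -1:]
    s = (cw - 0.5 * w) / tot  # centered cumulative weight in (0, 1)
    # interpolate to s = 0.5
    out = np.empty(values.shape[:-1])
    flat_v = v.reshape(-1, values.shape[-1])
    flat_s = s.reshape(-1, values.shape[-1])
    flat_o = out.reshape(-1)
    for i in range(flat_v.shape[0]):
        flat_o[i] = np.interp(0.5, flat_s[i], flat_v[i])
    return out if out.ndim else float(out)


def median_mr(data: TwoSampleInput, weighted: bool = False,
              n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Simple or weighted median of per-variant Wald ratios.

    The weighted form uses weights beta_exposure^2/se_outcome^2 through the
    cumulative-weight interpolation estimator; standard errors come from a
    seeded parametric bootstrap resampling both association estimates from
    normal distributions with their reported SEs.
    """
    data = _drop_null_exposure(data)
    if len(data) < 3:
        raise ValueError("median estimators need at least 3 variants")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives an unstable SE", stacklevel=2)
    bx, by = data.beta_exposure, data.beta_outcome
    sx, sy = data.se_exposure, data.se_outcome
    ratios = by / bx
    if weighted:
        weights = bx ** 2 / sy ** 2
        est = float(weighted_median(ratios, weights))
    else:
        est = float(np.median(ratios))

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, len(bx)))
    by_b = rng.normal(by, sy, size=(n_boot, len(by)))
    bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
    ratios_b = by_b / bx_b
    if weighted:
        w_b = bx_b ** 2 / sy ** 2
        boots = weighted_median(ratios_b, w_b)
    else:
        boots = np.median(ratios_b, axis=-1)
    se = float(np.std(boots, ddof=1))
    p = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else 0.0
    tag = "weighted_median" if weighted else "simple_median"
    return MREstimate(tag, est, se, p, len(data), data.direction)


def egger(data: TwoSampleInput) -> MREstimate:
    """MR-Egger: weighted regression with an intercept.

    Variants are oriented so every exposure association is nonnegative;
    the slope estimates the causal effect and the intercept the average
    directional pleiotropy. Weights are 1/se_outcome^2; inference uses a
    multiplicative overdispersion parameter (floored at 1) and the t
    distribution with m - 2 df.
    """
    data = _drop_null_exposure(data)
    m = len(data)
    if m < 3:
        raise ValueError("MR-Egger needs at least 3 variants")
    flip = np.sign(data.beta_exposure)
    bx = data.beta_exposure * flip
    by = data.beta_outcome * flip
    w = 1.0 / data.se_outcome ** 2
    if np.allclose(bx, bx[0]):
        raise ValueError("all exposure associations equal after orientation; "
                         "slope and intercept unidentifiable")
    X = np.column_stack([np.ones(m), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    dof = m - 2
    disp = max(1.0, float(resid @ (w * resid) / dof))
    cov = disp * np.linalg.inv(xtx)
    se_slope = float(np.sqrt(cov[1, 1]))
    se_int = float(np.sqrt(cov[0, 0]))
    p_slope = float(2 * stats.t.sf(abs(coef[1]) / se_slope, dof))
    p_int = float(2 * stats.t.sf(abs(coef[0]) / se_int, dof))
    return MREstimate("MR_Egger", float(coef[1]), se_slope, p_slope, m,
                      data.direction, intercept=float(coef[0]),
                      intercept_se=se_int, intercept_p=p_int, df=dof)


_METHODS = {"IVW": ivw,
            "simple_median": lambda d, **kw: median_mr(d, False, **kw),
            "weighted_median": lambda d, **kw: median_mr(d, True, **kw),
            "MR_Egger": lambda d, **kw: egger(d)}


def leave_one_out(data: TwoSampleInput, method: str = "MR_Egger",
                  **kwargs) -> pd.DataFrame:
    """Re-fit excluding each variant in turn.

    For MR-Egger, variants whose exclusion moves the intercept p-value
    across 0.05 are flagged as candidate pleiotropic outliers.
    """
    if len(data) < 4:
        raise ValueError("leave-one-out needs at least 4 variants")
    fn = _METHODS[method]
    full = fn(data, **kwargs) if method != "MR_Egger" else egger(data)
    rows = []
    for snp in data.snp_id:
        sub = data.drop_snp(snp)
        est = fn(sub, **kwargs) if method != "MR_Egger" else egger(sub)
        row = {"excluded_snp": snp, "effect": est.effect, "se": est.se,
               "p_value": est.p_value}
        if method == "MR_Egger":
            row.update(intercept=est.intercept,
                       intercept_p=est.intercept_p,
                       flagged=(est.intercept_p > 0.05) !=
                               (full.intercept_p > 0.05))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# bidirectional report
# ---------------------------------------------------------------------

@dataclass
class MRReport:
    """Method x direction effect table plus instrument diagnostics."""

    table: pd.DataFrame
    diagnostics: pd.DataFrame
    seed: int | None = None

    def to_tsv(self, table_path, diagnostics_path=None) -> None:
        self.table.to_csv(table_path, sep="\t", index=False)
        if diagnostics_path is not None:
            self.diagnostics.to_csv(diagnostics_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, table_path, diagnostics_path=None) -> "MRReport":
        diag = pd.read_csv(diagnostics_path, sep="\t") \
            if diagnostics_path else pd.DataFrame()
        return cls(pd.read_csv(table_path, sep="\t"), diag)


def _covariate_matrix(baseline: pd.DataFrame, names=("age", "sex")):
    cols = []
    for c in names:
        if c == "sex":
            cols.append((baseline["sex"] == "male").to_numpy(dtype=float))
        else:
            cols.append(baseline[c].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else None


def run_bidirectional(panel, instruments_fbs: InstrumentSet,
                      instruments_sbp: InstrumentSet, *,
                      n_boot: int = 1000, seed: int | None = 0,
                      exclude_shared: bool = True,
                      two_sample_split: bool = True) -> MRReport:
    """All five estimators in both directions, with diagnostics.

    Summary-data inputs respect the two-sample assumption by estimating
    exposure associations on odd-indexed subjects and outcome associations
    on even-indexed subjects (``two_sample_split=True``); 2SLS uses the full
    panel with the wGRS instrument adjusted for age and sex, overall and
    within sex strata. Shared variants (present in both instrument sets)
    are re-analyzed excluded when ``exclude_shared`` is set, mirroring an
    outlier-removal sensitivity analysis.

    Effects are reported per exposure unit and rescaled per 1 SD of the
    exposure and per clinical increment (0.5 mmol/L FBS, 10 mmHg SBP).
    """
    if len(instruments_fbs) == 0 or len(instruments_sbp) == 0:
        raise ValueError("both instrument sets must be nonempty")
    shared = sorted(set(instruments_fbs.snp_ids)
                    & set(instruments_sbp.snp_ids))
    base = panel.baseline.set_index("subject_id").loc[panel.subject_ids] \
        .reset_index()
    phen = panel.baseline_phenotypes()
    n = panel.n_subjects
    odd = [panel.subject_ids[i] for i in range(1, n, 2)]
    even = [panel.subject_ids[i] for i in range(0, n, 2)]

    table_rows, diag_rows = [], []
    for direction, instr, expo, outc in (
            ("FBS->SBP", instruments_fbs, "fbs", "sbp"),
            ("SBP->FBS", instruments_sbp, "sbp", "fbs")):
        for drop_shared in ([False, True] if (exclude_shared and shared)
                            else [False]):
            inst = instr.without(shared) if drop_shared else instr
            if len(inst) == 0:
                continue
            snps = inst.snp_ids
            if two_sample_split:
                g_exp = run_gwas(panel, expo, variant_ids=snps,
                                 subject_ids=odd)
                g_out = run_gwas(panel, outc, variant_ids=snps,
                                 subject_ids=even)
            else:
                g_exp = run_gwas(panel, expo, variant_ids=snps)
                g_out = run_gwas(panel, outc, variant_ids=snps)
            ts = two_sample_from_summaries(
                g_exp[["snp_id", "effect_allele", "beta", "se"]],
                g_out[["snp_id", "effect_allele", "beta", "se"]],
                direction)

            wgrs = build_wgrs(panel, inst)
            x = phen[expo].to_numpy(dtype=float)
            y = phen[outc].to_numpy(dtype=float)
            cov = _covariate_matrix(base)
            est2, diag = fit_2sls(x, y, wgrs, cov, direction)
            sd_x = float(np.nanstd(x, ddof=1))
            incr = CLINICAL_INCREMENT[expo]

            ests = [est2, ivw(ts)]
            for maker in (lambda: median_mr(ts, False, n_boot=n_boot,
                                            seed=seed),
                          lambda: median_mr(ts, True, n_boot=n_boot,
                                            seed=seed),
                          lambda: egger(ts)):
                try:
                    ests.append(maker())
                except ValueError as exc:
                    warnings.warn(f"{direction}: {exc}", stacklevel=2)
            for e in ests:
                table_rows.append({
                    "direction": direction,
                    "excluded_shared": drop_shared,
                    "method": e.method,
                    "n_instruments": len(inst) if e.method != "2SLS"
                    else len(inst),
                    "effect": e.effect, "se": e.se, "p_value": e.p_value,
                    "effect_per_sd": e.effect * sd_x,
                    "effect_per_increment": e.effect * incr,
                    "intercept": e.intercept,
                    "intercept_se": e.intercept_se,
                    "intercept_p": e.intercept_p,
                })
            diag_rows.append({
                "direction": direction, "excluded_shared": drop_shared,
                "subgroup": "all", "n": diag.n,
                "first_stage_F": diag.first_stage_F,
                "weak_flag": diag.weak_flag,
                "wu_hausman_p": diag.wu_hausman_p,
                "effect_2sls": est2.effect, "se_2sls": est2.se,
                "p_2sls": est2.p_value,
            })
            if not drop_shared:
                # sex-stratified 2SLS with shared instruments
                for sex in ("male", "female"):
                    sel = (base["sex"] == sex).to_numpy()
                    try:
                        e_s, d_s = fit_2sls(
                            x[sel], y[sel], wgrs[sel],
                            base.loc[sel, "age"].to_numpy(dtype=float),
                            direction)
                    except ValueError:
                        continue
                    diag_rows.append({
                        "direction": direction, "excluded_shared": False,
                        "subgroup": sex, "n": d_s.n,
                        "first_stage_F": d_s.first_stage_F,
                        "weak_flag": d_s.weak_flag,
                        "wu_hausman_p": d_s.wu_hausman_p,
                        "effect_2sls": e_s.effect, "se_2sls": e_s.se,
                        "p_2sls": e_s.p_value,
                    })
    return MRReport(pd.DataFrame(table_rows), pd.DataFrame(diag_rows),
                    seed=seed)
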