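"""Person-time accounting, exact-Poisson incidence rates, and Cox models.

Follow-up runs from baseline (optionally from the second visit, honored as
left truncation) to disease onset or administrative censoring. Incidence
rates per 1,000 person-years carry exact Poisson confidence intervals.
The Cox model maximizes the Efron partial likelihood by Newton-Raphson
with risk sets that respect delayed entry, and reports hazard ratios with
Wald confidence intervals for the covariate sets used in staged adjustment
(age/sex; + lifestyle and medications; + genetic risk score quartiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASE_EXCLUSIONS = ("t2d", "htn", "stroke")

MODEL_COVARIATES = {
    "model1": ["age", "sex"],
    "model2": ["age", "sex", "bmi", "smoking", "alcohol", "exercise",
               "med_antidiabetic", "med_antihypertensive"],
    "model2c": ["age", "sex", "bmi", "smoking", "alcohol", "exercise",
                "med_antidiabetic", "med_antihypertensive", "wgrs_quartile"],
}


@dataclass
class IncidenceSummary:
    n_persons: int
    n_events: int
    person_years: float
    rate_per_1000: float
    rate_ci_low: float
    rate_ci_high: float


@dataclass
class CoxFit:
    model: str
    coefficients: pd.DataFrame   # term, log_hr, se, hr, ci_low, ci_high, p
    partial_log_likelihood: float
    n_events: int
    n_subjects: int
    dropped_terms: list[str] = field(default_factory=list)
    n_iter: int = 0

    @property
    def minus_2_log_l(self) -> float:
        return -2.0 * self.partial_log_likelihood

    def hr(self, term: str) -> float:
        row = self.coefficients.set_index("term").loc[term]
        return float(row["hr"])


# ---------------------------------------------------------------------
# record construction
# ---------------------------------------------------------------------

def build_records(panel, outcome: str,
                  exclusions=BASE_EXCLUSIONS,
                  entry_at_second_visit: bool = False,
                  onset_at_visit_midpoint: bool = False):
    """Survival records for one outcome, excluding prevalent disease.

    Subjects with a baseline history of any condition in ``exclusions``
    are removed; the exclusion report counts each condition separately and
    the union. With ``entry_at_second_visit`` the entry time is the second
    visit (left truncation); subjects whose event or censoring precedes
    entry are rejected with a reason rather than given nonpositive
    follow-up. ``onset_at_visit_midpoint`` discretizes event times to the
    midpoint between the last disease-free visit and the first diseased
    one — the convention for onsets known only to visit resolution.

    Returns ``(records, report)`` where records has entry_time, exit_time,
    event and the baseline covariates.
    """
    if panel.events is None:
        raise ValueError("panel has no event table")
    base = panel.baseline.set_index("subject_id").loc[panel.subject_ids]
    ev = panel.events.set_index("subject_id").loc[panel.subject_ids]

    report = {"n_total": panel.n_subjects}
    excluded = np.zeros(panel.n_subjects, dtype=bool)
    for cond in exclusions:
        flag = base[f"prevalent_{cond}"].to_numpy(dtype=bool)
        report[f"n_prevalent_{cond}"] = int(flag.sum())
        excluded |= flag
    report["n_excluded"] = int(excluded.sum())

    entry = 0.0
    if entry_at_second_visit:
        t = np.sort(panel.visits["time_years"].unique())
        if len(t) < 2:
            raise ValueError("left truncation requires at least 2 visits")
        entry = float(t[1])

    time = ev[f"{outcome}_time"].to_numpy(dtype=float)
    event = ev[f"{outcome}_event"].to_numpy(dtype=int)
    if onset_at_visit_midpoint:
        grid = np.sort(panel.visits["time_years"].unique())
        spacing = grid[1] - grid[0] if len(grid) > 1 else 1.0
        idx = np.searchsorted(grid, time, side="right") - 1
        last_free = grid[np.clip(idx, 0, len(grid) - 1)]
        mid = last_free + spacing / 2.0
        time = np.where(event == 1, mid, time)
    keep = ~excluded
    short = keep & (time <= entry)
    report["n_rejected_followup"] = int(short.sum())
    keep &= ~short

    records = base.loc[keep].reset_index()
    records["entry_time"] = entry
    records["exit_time"] = time[keep]
    records["event"] = event[keep]
    records["outcome"] = outcome
    report["n_analyzed"] = int(keep.sum())
    return records, report


# ---------------------------------------------------------------------
# incidence
# ---------------------------------------------------------------------

def poisson_exact_ci(k: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence bounds for a Poisson count."""
    a = 1.0 - level
    low = 0.0 if k == 0 else stats.chi2.ppf(a / 2, 2 * k) / 2.0
    high = stats.chi2.ppf(1 - a / 2, 2 * k + 2) / 2.0
    return low, high


def incidence_from_counts(n_events: int, person_years: float,
                          n_persons: int | None = None) -> IncidenceSummary:
    """Rate per 1,000 person-years with an exact Poisson CI."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    lo, hi = poisson_exact_ci(int(n_events))
    scale = 1000.0 / person_years
    return IncidenceSummary(
        n_persons=int(n_persons) if n_persons is not None else int(n_events),
        n_events=int(n_events), person_years=float(person_years),
        rate_per_1000=n_events * scale,
        rate_ci_low=lo * scale, rate_ci_high=hi * scale)


def incidence(records: pd.DataFrame) -> IncidenceSummary:
    """Events, person-years and rate per 1,000 for a record set."""
    if len(records) == 0:
        raise ValueError("no records")
    py = float((records["exit_time"] - records["entry_time"]).sum())
    return incidence_from_counts(int(records["event"].sum()), py,
                                 n_persons=len(records))


# ---------------------------------------------------------------------
# Cox proportional hazards (Efron ties, delayed entry)
# ---------------------------------------------------------------------

def _design_matrix(records: pd.DataFrame, covariates):
    cols, names = [], []
    for c in covariates:
        s = records[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(dtype=float))
                names.append(dc)
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols) if cols else np.empty((len(records), 0))
    dropped = [nm for j, nm in enumerate(names) if X[:, j].std() == 0]
    keep = [j for j in range(X.shape[1]) if names[j] not in dropped]
    return X[:, keep], [names[j] for j in keep], dropped


def _efron_quantities(beta, X, entry, exit_, event):
    """Efron partial log-likelihood, gradient and Hessian."""
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard overflow; cancels in all ratios below
    theta = np.exp(eta)
    tx = theta[:, None] * X
    txx = theta[:, None, None] * (X[:, :, None] * X[:, None, :])

    def suffix_sums(times):
        order = np.argsort(times, kind="mergesort")
        st = times[order]
        s0 = np.concatenate([np.cumsum(theta[order][::-1])[::-1], [0.0]])
        s1 = np.vstack([np.cumsum(tx[order][::-1], axis=0)[::-1],
                        np.zeros((1, p))])
        s2 = np.concatenate([np.cumsum(txx[order][::-1], axis=0)[::-1],
                             np.zeros((1, p, p))])
        return st, s0, s1, s2

    ex_t, ex0, ex1, ex2 = suffix_sums(exit_)
    en_t, en0, en1, en2 = suffix_sums(entry)

    ev_idx = np.flatnonzero(event)
    ev_order = ev_idx[np.argsort(exit_[ev_idx], kind="mergesort")]
    ev_times = exit_[ev_order]
    uniq, starts, cnt = np.unique(ev_times, return_index=True,
                                  return_counts=True)
    i_ex = np.searchsorted(ex_t, uniq, side="left")
    i_en = np.searchsorted(en_t, uniq, side="left")
    S0a = ex0[i_ex] - en0[i_en]                 # (E,)
    S1a = ex1[i_ex] - en1[i_en]                 # (E, p)
    S2a = ex2[i_ex] - en2[i_en]                 # (E, p, p)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    single = cnt == 1
    if single.any():
        rows = ev_order[starts[single]]
        S0 = S0a[single]
        ratio1 = S1a[single] / S0[:, None]
        ll += eta[rows].sum() - np.log(S0).sum()
        grad += X[rows].sum(axis=0) - ratio1.sum(axis=0)
        hess -= (S2a[single] / S0[:, None, None]).sum(axis=0)
        hess += np.einsum("lp,lq->pq", ratio1, ratio1)

    for j in np.flatnonzero(~single):           # tied event times
        rows = ev_order[starts[j]:starts[j] + cnt[j]]
        d = int(cnt[j])
        S0, S1, S2 = S0a[j], S1a[j], S2a[j]
        D0 = theta[rows].sum()
        D1 = tx[rows].sum(axis=0)
        D2 = txx[rows].sum(axis=0)
        frac = np.arange(d) / d
        denom = S0 - frac * D0                      # (d,)
        num1 = S1[None, :] - frac[:, None] * D1     # (d, p)
        num2 = S2[None, :, :] - frac[:, None, None] * D2
        ll += eta[rows].sum() - np.log(denom).sum()
        ratio1 = num1 / denom[:, None]
        grad += X[rows].sum(axis=0) - ratio1.sum(axis=0)
        hess -= (num2 / denom[:, None, None]).sum(axis=0)
        hess += np.einsum("lp,lq->pq", ratio1, ratio1)
    return ll, grad, hess


def fit_cox(records: pd.DataFrame, covariates, *, ties: str = "efron",
            tol: float = 1e-9, max_iter: int = 50,
            model_tag: str = "cox") -> CoxFit:
    """Maximize the Efron partial likelihood by Newton-Raphson.

    Risk sets respect ``entry_time`` (delayed entry). Constant covariates
    are excluded and the fit proceeds on the rest. Convergence is declared
    when the score norm falls below ``tol``; monotone likelihood (perfect
    separation) raises an error naming the covariate.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is implemented")
    if records["event"].sum() < 1:
        raise ValueError("need at least one event")
    bad = records["exit_time"] <= records["entry_time"]
    if bad.any():
        raise ValueError("exit_time must exceed entry_time for all records")
    X, names, dropped = _design_matrix(records, covariates)
    if X.shape[1] == 0:
        raise ValueError("no non-constant covariates remain")
    # standardize internally for Newton stability; back-transform after
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mu) / sd
    entry = records["entry_time"].to_numpy(dtype=float)
    exit_ = records["exit_time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)

    beta = np.zeros(Xs.shape[1])
    ll, grad, hess = _efron_quantities(beta, Xs, entry, exit_, event)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular information matrix: {exc}") from exc
        # step-halving line search
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, h_new = _efron_quantities(
                cand, Xs, entry, exit_, event)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if np.abs(beta / sd).max() > 20:
            # a log-hazard-ratio beyond e^20 only arises when the partial
            # likelihood is monotone in that coefficient
            j = int(np.abs(beta / sd).argmax())
            raise ValueError(
                f"monotone likelihood (perfect separation) in {names[j]!r}")
        # score norm scaled by the event count (its natural magnitude)
        if np.linalg.norm(grad) < tol * max(1.0, float(event.sum())):
            break
    else:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(|score| = {np.linalg.norm(grad):.3g})")

    cov_s = np.linalg.inv(-hess)
    beta_raw = beta / sd
    se_raw = np.sqrt(np.diag(cov_s)) / sd
    z = beta_raw / se_raw
    coef = pd.DataFrame({
        "term": names,
        "log_hr": beta_raw,
        "se": se_raw,
        "hr": np.exp(beta_raw),
        "ci_low": np.exp(beta_raw - 1.959963984540054 * se_raw),
        "ci_high": np.exp(beta_raw + 1.959963984540054 * se_raw),
        "p_value": 2 * stats.norm.sf(np.abs(z)),
    })
    return CoxFit(model=model_tag, coefficients=coef,
                  partial_log_likelihood=float(ll),
                  n_events=int(event.sum()), n_subjects=len(records),
                  dropped_terms=dropped, n_iter=n_iter)


# ---------------------------------------------------------------------
# the trajectory-to-incidence report
# ---------------------------------------------------------------------

@dataclass
class Table2Report:
    outcome: str
    grouping_phenotype: str
    incidence_rows: pd.DataFrame
    cox_rows: pd.DataFrame
    fits: dict[str, CoxFit] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        inc = self.incidence_rows.assign(section="incidence")
        cox = self.cox_rows.assign(section="cox")
        pd.concat([inc, cox], ignore_index=True).to_csv(
            path, sep="\t", index=False)


def wgrs_quartiles(scores: np.ndarray) -> np.ndarray:
    """Quartile labels Q1..Q4 computed on the provided (analysis) cohort."""
    q = np.quantile(scores, [0.25, 0.5, 0.75])
    return np.array([f"Q{1 + np.searchsorted(q, s, side='right')}"
                     for s in scores])


def table2_report(panel, assignments: pd.DataFrame, wgrs,
                  outcome: str, *, grouping_phenotype: str = "",
                  models=("model1", "model2", "model2c"),
                  entry_at_second_visit: bool = False) -> Table2Report:
    """Incidence and staged Cox models by trajectory group.

    ``assignments`` must carry subject_id and a ``label`` column
    (controlled/uncontrolled). wGRS quartiles are computed on the analysis
    cohort after exclusions. Each Cox model adds the uncontrolled-group
    indicator to its covariate set and reports the group hazard ratio plus
    -2 log partial likelihood.
    """
    records, report = build_records(
        panel, outcome, entry_at_second_visit=entry_at_second_visit)
    score_map = dict(zip(panel.subject_ids, np.asarray(wgrs, dtype=float)))
    records = records.merge(
        assignments[["subject_id", "label"]], on="subject_id", how="inner")
    records["wgrs"] = records["subject_id"].map(score_map)
    records["wgrs_quartile"] = wgrs_quartiles(records["wgrs"].to_numpy())
    records["uncontrolled"] = (records["label"] == "uncontrolled").astype(float)

    inc_rows = []
    for label, grp in records.groupby("label"):
        s = incidence(grp)
        inc_rows.append({
            "group": label, "n_persons": s.n_persons, "n_events": s.n_events,
            "person_years": round(s.person_years, 2),
            "rate_per_1000": round(s.rate_per_1000, 2),
            "rate_ci_low": round(s.rate_ci_low, 2),
            "rate_ci_high": round(s.rate_ci_high, 2),
        })

    cox_rows, fits = [], {}
    for tag in models:
        covs = ["uncontrolled"] + MODEL_COVARIATES[tag]
        fit = fit_cox(records, covs, model_tag=tag)
        fits[tag] = fit
        row = fit.coefficients.set_index("term").loc["uncontrolled"]
        cox_rows.append({
            "model": tag, "hr": row["hr"], "ci_low": row["ci_low"],
            "ci_high": row["ci_high"], "p_value": row["p_value"],
            "minus_2_log_l": fit.minus_2_log_l,
            "n_events": fit.n_events,
        })
    rep = Table2Report(outcome=outcome,
                       grouping_phenotype=grouping_phenotype,
                       incidence_rows=pd.DataFrame(inc_rows),
                       cox_rows=pd.DataFrame(cox_rows), fits=fits)
    rep.exclusion_report = report  # type: ignore[attr-defined]
    return rep
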