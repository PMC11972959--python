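"""Genetically predicted phenotype series and group-based trajectory models.

``predict_series`` regresses each visit's phenotype on the wGRS and takes
the fitted values as that subject's genetically predicted level, giving a
per-visit predicted series even for subjects who missed a visit.

``fit_gbtm`` maximizes the finite-mixture likelihood

    prod_i sum_k pi_k prod_t Normal(y_it; poly_k(t), sigma)

by EM with weighted polynomial least squares in the M step, a shared
residual sigma (per-group behind a flag), multi-start initialization, and
canonical ordering of groups by intercept. ``select_model`` scans (K, order)
combinations, computes BIC = -2 logL + p log(n_subjects), and applies the
5%-minimum-group-share admissibility rule before choosing the best BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

SIGMA_FLOOR = 1e-6


@dataclass
class PredictedSeries:
    """One subject's per-visit phenotype values (predicted or observed)."""

    subject_id: str
    times: np.ndarray
    values: np.ndarray
    source: str = "wgrs_predicted"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def predict_series(panel, wgrs, phenotype: str,
                   mode: str = "wgrs_predicted") -> list[PredictedSeries]:
    """Genetically predicted per-visit series from the wGRS.

    For each visit time, the observed phenotype is regressed on the wGRS
    across subjects by least squares, and every subject's predicted value is
    the fitted value of that regression at their score. ``mode="observed"``
    bypasses the regression and returns each subject's observed series.
    """
    wgrs = np.asarray(wgrs, dtype=float)
    visits = panel.visits
    if mode == "observed":
        out = []
        for sid, grp in visits.groupby("subject_id", sort=False):
            grp = grp.dropna(subset=[phenotype])
            if len(grp) == 0:
                continue
            out.append(PredictedSeries(sid, grp["time_years"].to_numpy(),
                                       grp[phenotype].to_numpy(),
                                       source="observed"))
        return out

    if np.std(wgrs) == 0:
        raise ValueError("wGRS has zero variance; prediction undefined")
    times = np.sort(visits["time_years"].unique())
    if len(times) < 2:
        raise ValueError("need at least 2 visits")
    score_by_subject = dict(zip(panel.subject_ids, wgrs))
    pred = np.empty((panel.n_subjects, len(times)))
    wide = visits.pivot_table(index="subject_id", columns="time_years",
                              values=phenotype)
    wide = wide.reindex(panel.subject_ids)
    for j, t in enumerate(times):
        y = wide[t].to_numpy(dtype=float) if t in wide.columns \
            else np.full(panel.n_subjects, np.nan)
        mask = ~np.isnan(y)
        X = np.column_stack([np.ones(mask.sum()), wgrs[mask]])
        coef, *_ = np.linalg.lstsq(X, y[mask], rcond=None)
        pred[:, j] = coef[0] + coef[1] * wgrs
    return [PredictedSeries(sid, times, pred[i],
                            source="wgrs_predicted")
            for i, sid in enumerate(panel.subject_ids)]


@dataclass
class TrajectoryModelFit:
    n_groups: int
    polynomial_orders: list[int]
    coefficients: list[np.ndarray]       # per group, low -> high order
    residual_sd: float
    mixing_proportions: np.ndarray
    log_likelihood: float
    bic: float
    posterior: np.ndarray                # [subjects, K]
    assignment: np.ndarray               # argmax class per subject
    avg_posterior: np.ndarray            # mean max-posterior per group
    min_group_share: float
    subject_ids: list[str]
    times: np.ndarray | None = None
    loglik_history: list[float] = field(default_factory=list)

    def group_labels(self) -> dict[int, str]:
        """'uncontrolled' = group whose fitted curve spans the widest range."""
        if self.times is None:
            t = np.linspace(0.0, 14.0, 64)
        else:
            t = np.linspace(float(self.times.min()),
                            float(self.times.max()), 64)
        ranges = [np.ptp(np.polyval(c[::-1], t)) for c in self.coefficients]
        unc = int(np.argmax(ranges))
        return {k: ("uncontrolled" if k == unc else "controlled")
                for k in range(self.n_groups)}

    def assignments_frame(self) -> pd.DataFrame:
        labels = self.group_labels()
        return pd.DataFrame({
            "subject_id": self.subject_ids,
            "group": self.assignment,
            "posterior": self.posterior[np.arange(len(self.assignment)),
                                        self.assignment],
            "label": [labels[g] for g in self.assignment],
        })

    def to_dict(self) -> dict:
        return {
            "n_groups": self.n_groups,
            "polynomial_orders": list(self.polynomial_orders),
            "coefficients": [c.tolist() for c in self.coefficients],
            "residual_sd": self.residual_sd,
            "mixing_proportions": self.mixing_proportions.tolist(),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "avg_posterior": self.avg_posterior.tolist(),
            "min_group_share": self.min_group_share,
            "group_labels": {str(k): v
                             for k, v in self.group_labels().items()},
        }


def _series_matrix(series: list[PredictedSeries]):
    """Stack series on the union time grid; NaN marks unobserved visits."""
    times = np.unique(np.concatenate([s.times for s in series]))
    Y = np.full((len(series), len(times)), np.nan)
    pos = {t: j for j, t in enumerate(times)}
    for i, s in enumerate(series):
        for t, v in zip(s.times, s.values):
            Y[i, pos[t]] = v
    return Y, times, [s.subject_id for s in series]


def _n_params(orders, K: int, shared_sigma: bool) -> int:
    return sum(o + 1 for o in orders) + (K - 1) + (1 if shared_sigma else K)


def fit_gbtm(series: list[PredictedSeries], K: int,
             orders: int | list[int] = 2, *, max_iter: int = 500,
             tol: float = 1e-6, seed: int | None = None,
             n_restarts: int = 10,
             shared_sigma: bool = True) -> TrajectoryModelFit:
    """Fit a K-group polynomial-trajectory normal mixture by EM.

    Each restart initializes responsibilities from a random Dirichlet draw;
    the best converged likelihood wins. Groups are canonically reordered by
    intercept (ascending), so relabeling never changes the reported model.
    EM iterations never decrease the log-likelihood; the history is kept on
    the returned fit.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if any(len(s.values[~np.isnan(s.values)]) < 2 for s in series):
        raise ValueError("every subject needs at least 2 observations")
    orders = [orders] * K if np.isscalar(orders) else list(orders)
    if len(orders) != K or any(o < 0 or o > 3 for o in orders):
        raise ValueError("orders must give one value in 0..3 per group")

    Y, times, subject_ids = _series_matrix(series)
    n, T = Y.shape
    obs = ~np.isnan(Y)
    Y0 = np.where(obs, Y, 0.0)
    n_obs_i = obs.sum(axis=1)
    designs = [np.vander(times, o + 1, increasing=True) for o in orders]

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(max(n_restarts, 1))
    best = None
    for r in range(max(n_restarts, 1)):
        rng = np.random.default_rng(child_seeds[r])
        try:
            fit = _em_once(Y0, obs, n_obs_i, designs, K, rng,
                           max_iter, tol, shared_sigma)
        except _DegenerateFit:
            continue
        if best is None or fit["loglik"] > best["loglik"]:
            best = fit
    if best is None:
        raise RuntimeError("all EM restarts degenerated to an empty group")

    # canonical order: ascending intercept
    intercepts = np.array([c[0] for c in best["coefs"]])
    order_idx = np.argsort(intercepts, kind="mergesort")
    coefs = [best["coefs"][k] for k in order_idx]
    pi = best["pi"][order_idx]
    post = best["post"][:, order_idx]
    orders_sorted = [orders[k] for k in order_idx]

    assignment = post.argmax(axis=1)
    shares = np.bincount(assignment, minlength=K) / n
    avg_post = np.array([
        post[assignment == k, k].mean() if (assignment == k).any() else np.nan
        for k in range(K)])
    p = _n_params(orders_sorted, K, shared_sigma)
    bic = -2.0 * best["loglik"] + p * np.log(n)
    return TrajectoryModelFit(
        n_groups=K, polynomial_orders=orders_sorted, coefficients=coefs,
        residual_sd=best["sigma"], mixing_proportions=pi,
        log_likelihood=best["loglik"], bic=float(bic), posterior=post,
        assignment=assignment, avg_posterior=avg_post,
        min_group_share=float(shares.min()), subject_ids=subject_ids,
        times=times, loglik_history=best["history"],
    )


class _DegenerateFit(Exception):
    pass


def _em_once(Y0, obs, n_obs_i, designs, K, rng, max_iter, tol, shared_sigma):
    n, T = Y0.shape
    resp = rng.dirichlet(np.ones(K), size=n)
    pi = np.full(K, 1.0 / K)
    sigma = None
    coefs = [np.zeros(X.shape[1]) for X in designs]
    history: list[float] = []
    loglik = -np.inf
    for it in range(max_iter):
        # M step (first pass uses the random responsibilities)
        new_coefs = []
        sse = 0.0
        wtot = 0.0
        sigmas = np.empty(K)
        for k, X in enumerate(designs):
            w = resp[:, k]
            if w.max() < 1e-8:
                raise _DegenerateFit
            # weighted normal equations over observed cells:
            # A = sum_{i,t obs} w_i x_t x_t'
            wm = w[:, None] * obs                     # n x T
            col_w = wm.sum(axis=0)                    # per-time total weight
            A = (X.T * col_w) @ X
            rhs = X.T @ (wm * Y0).sum(axis=0)
            c = np.linalg.solve(A + 1e-12 * np.eye(A.shape[0]), rhs)
            new_coefs.append(c)
            mu = X @ c
            r2 = ((Y0 - mu[None, :]) ** 2) * obs
            sk = float((w[:, None] * r2).sum())
            nk = float((w * n_obs_i).sum())
            sigmas[k] = np.sqrt(max(sk / max(nk, 1e-12), SIGMA_FLOOR ** 2))
            sse += sk
            wtot += nk
        coefs = new_coefs
        if shared_sigma:
            sigma = float(np.sqrt(max(sse / wtot, SIGMA_FLOOR ** 2)))
            sig_k = np.full(K, sigma)
        else:
            sig_k = np.maximum(sigmas, SIGMA_FLOOR)
            sigma = float(np.exp(np.mean(np.log(sig_k))))
        pi = resp.mean(axis=0)
        pi = np.clip(pi, 1e-12, None)
        pi /= pi.sum()

        # E step
        ll_ik = np.empty((n, K))
        for k, X in enumerate(designs):
            mu = X @ coefs[k]
            r2 = ((Y0 - mu[None, :]) ** 2) * obs
            ll_ik[:, k] = (-0.5 * np.log(2 * np.pi * sig_k[k] ** 2) * n_obs_i
                           - r2.sum(axis=1) / (2 * sig_k[k] ** 2))
        log_num = np.log(pi)[None, :] + ll_ik
        log_den = logsumexp(log_num, axis=1)
        resp = np.exp(log_num - log_den[:, None])
        new_loglik = float(log_den.sum())
        history.append(new_loglik)
        if new_loglik - loglik < tol and it > 0:
            loglik = new_loglik
            break
        loglik = new_loglik
    if resp.max(axis=0).min() < 1e-8:
        raise _DegenerateFit
    return {"coefs": coefs, "pi": pi, "sigma": sigma, "post": resp,
            "loglik": loglik, "history": history}


MIN_GROUP_SHARE = 0.05


def select_model(series: list[PredictedSeries], k_range=(1, 2, 3, 4),
                 order_range=(2,), *, seed: int | None = None,
                 n_restarts: int = 10,
                 min_group_share: float = MIN_GROUP_SHARE,
                 **fit_kwargs):
    """Fit all (K, order) combinations and select by BIC.

    Models whose smallest assigned group holds less than ``min_group_share``
    of subjects are flagged as violating the minimum-share assumption and
    excluded from selection — unless every candidate violates it, in which
    case the best-BIC violator is returned with a warning (the pragmatic
    fallback when small latent groups are scientifically expected).

    Returns ``(best_fit, selection_table)``.
    """
    if not len(tuple(k_range)):
        raise ValueError("k_range must be nonempty")
    fits, rows = {}, []
    ss = np.random.SeedSequence(seed)
    combos = [(K, o) for K in k_range for o in order_range]
    child = ss.spawn(len(combos))
    for (K, order), cs in zip(combos, child):
        try:
            fit = fit_gbtm(series, K, order, seed=cs.entropy % (2 ** 31),
                           n_restarts=n_restarts, **fit_kwargs)
        except (RuntimeError, ValueError) as exc:
            rows.append({"K": K, "order": order, "log_likelihood": np.nan,
                         "bic": np.nan, "min_group_share": np.nan,
                         "min_share_violation": True, "error": str(exc)})
            continue
        viol = fit.min_group_share < min_group_share
        fits[(K, order)] = fit
        rows.append({"K": K, "order": order,
                     "log_likelihood": fit.log_likelihood, "bic": fit.bic,
                     "min_group_share": fit.min_group_share,
                     "min_share_violation": viol, "error": ""})
    table = pd.DataFrame(rows)
    ok = table[~table.min_share_violation & table.bic.notna()]
    if len(ok):
        best_row = ok.loc[ok.bic.idxmin()]
    else:
        warnings.warn("every candidate model violates the minimum group "
                      "share; returning the best BIC among violators",
                      stacklevel=2)
        valid = table[table.bic.notna()]
        if not len(valid):
            raise RuntimeError("no trajectory model could be fitted")
        best_row = valid.loc[valid.bic.idxmin()]
    best = fits[(int(best_row.K), int(best_row.order))]
    return best, table
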