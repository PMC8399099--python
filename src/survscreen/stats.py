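"""Core survival estimators: Kaplan-Meier, log-rank, Cox proportional hazards.

The Cox fitter maximizes the partial likelihood with Newton iterations and
handles tied event times with the Efron correction (Breslow available by
flag).  Inference is Wald-based: HR = exp(beta), 95% CI = exp(beta +/- 1.96 se),
two-sided normal p per coefficient, matching how hazard-ratio tables are
conventionally reported.  Non-convergence (e.g. monotone likelihood under
separation) is an explicit result state, never a silent answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import OneGroupError
from .cohort import AnalysisDataset, COVARIATE_NAMES

__all__ = [
    "KMCurve",
    "LogrankResult",
    "CoxResult",
    "km_estimate",
    "survival_at",
    "logrank",
    "cox_fit",
    "univariate_table",
    "multivariate_fit",
    "DAYS_5_YEARS",
]

#: Five-year landmark used for survival-rate readouts, in days.
DAYS_5_YEARS = 1826

Z_95 = 1.959963984540054  # standard normal 97.5% quantile


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored-only input yields an empty curve (S identically 1).
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if t.size == 0 or t.size != e.size:
        raise ValueError("times and events must be non-empty and equal length")
    if (t < 0).any():
        raise ValueError("negative survival time")
    ev_times = np.unique(t[e == 1])
    if ev_times.size == 0:
        empty = np.array([], float)
        return KMCurve(empty, empty.copy(), np.array([], int))
    at_risk = (t[:, None] >= ev_times[None, :]).sum(axis=0)
    deaths = ((t[:, None] == ev_times[None, :]) & (e[:, None] == 1)).sum(axis=0)
    surv = np.cumprod(1.0 - deaths / at_risk)
    return KMCurve(ev_times, surv, at_risk.astype(int))


def survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step-function readout of S(t)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    idx = int(np.searchsorted(curve.event_times, t, side="right"))
    return 1.0 if idx == 0 else float(curve.survival[idx - 1])


# ---------------------------------------------------------------------------
# log-rank


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p: float
    df: int = 1


def _logrank_grid(times: np.ndarray, events: np.ndarray, ks: np.ndarray):
    """Log-rank statistics for every prefix split of an *already ordered* cohort.

    Group 1 at cut ``k`` is the first k patients in the given order.  Returns
    (chi_square, p, variance, low-group events, high-group events) arrays;
    chi/p are NaN where the hypergeometric variance vanishes.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    ks = np.asarray(ks, int)
    total_events = int(e.sum())
    low_events = np.cumsum(e)[ks - 1]
    high_events = total_events - low_events
    ev = np.unique(t[e == 1])
    if ev.size == 0:
        nan = np.full(ks.shape, np.nan)
        return nan, nan.copy(), np.zeros(ks.shape), low_events, high_events
    at_risk = t[:, None] >= ev[None, :]
    death = (t[:, None] == ev[None, :]) & (e[:, None] == 1)
    d = death.sum(axis=0).astype(float)
    n_at = at_risk.sum(axis=0).astype(float)
    n1 = np.cumsum(at_risk, axis=0)[ks - 1].astype(float)
    o1 = np.cumsum(death, axis=0)[ks - 1].astype(float)
    frac = n1 / n_at
    expected = d * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        var = d * frac * (1.0 - frac) * (n_at - d) / (n_at - 1.0)
    var[:, n_at <= 1] = 0.0
    u = (o1 - expected).sum(axis=1)
    v = var.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(v > 0, u * u / v, np.nan)
    p = sps.chi2.sf(chi, 1)
    return chi, p, v, low_events, high_events


def logrank(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test (observed minus expected over pooled event
    times, hypergeometric variance), chi-square with 1 df."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise OneGroupError("one-group-logrank", "both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise OneGroupError("one-group-logrank", "no events in either group")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    chi, p, v, _, _ = _logrank_grid(t, e, np.array([ta.size]))
    if not np.isfinite(chi[0]) or v[0] <= 0:
        raise OneGroupError("one-group-logrank", "log-rank variance is zero")
    return LogrankResult(float(chi[0]), float(p[0]))


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxResult:
    """Per-covariate Wald summary of one Cox fit."""

    summary: pd.DataFrame  # index: covariate; columns: coef, se, hr, ci_low, ci_high, p
    converged: bool
    n: int
    n_events: int
    tie_method: str
    warnings: list[str] = dc_field(default_factory=list)

    def hr(self, name: str) -> float:
        return float(self.summary.loc[name, "hr"])

    def ci(self, name: str) -> tuple[float, float]:
        row = self.summary.loc[name]
        return float(row["ci_low"]), float(row["ci_high"])


def _cox_quantities(X, t, e, beta, tie_method):
    """Partial log-likelihood, score and observed information at ``beta``."""
    order = np.argsort(-t, kind="stable")
    ts, es, Xs = t[order], e[order], X[order]
    n, p = Xs.shape
    eta = np.clip(Xs @ beta, -200, 200)
    w = np.exp(eta)
    cw = np.cumsum(w)
    cwx = np.cumsum(w[:, None] * Xs, axis=0)
    cwxx = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)

    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        deaths = np.arange(i, j)[es[i:j] == 1]
        if deaths.size:
            d = deaths.size
            last = j - 1  # all rows 0..last have time >= ts[i]
            s0, s1, s2 = cw[last], cwx[last], cwxx[last]
            wd = w[deaths]
            xd = Xs[deaths]
            s0d, s1d = wd.sum(), (wd[:, None] * xd).sum(axis=0)
            s2d = (wd[:, None, None] * (xd[:, :, None] * xd[:, None, :])).sum(axis=0)
            loglik += eta[deaths].sum()
            score += xd.sum(axis=0)
            if tie_method == "efron":
                phis = np.arange(d) / d
            else:  # breslow
                phis = np.zeros(d)
            for phi in phis:
                s0l = s0 - phi * s0d
                s1l = s1 - phi * s1d
                s2l = s2 - phi * s2d
                loglik -= np.log(s0l)
                m1 = s1l / s0l
                score -= m1
                info += s2l / s0l - np.outer(m1, m1)
        i = j
    return loglik, score, info


def cox_fit(
    covariates,
    times,
    events,
    tie_method: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxResult:
    """Fit a Cox proportional-hazards model h(t) = h0(t) * exp(X @ beta).

    ``covariates`` is a DataFrame (or 2-D array) of numeric columns; every
    column must vary (a constant column makes the coefficient unidentifiable
    and is rejected with the one-group-cox category).
    """
    if tie_method not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {tie_method!r}")
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        X = covariates.to_numpy(float)
    else:
        X = np.asarray(covariates, float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if X.shape[0] != t.size or t.size != e.size:
        raise ValueError("covariates, times and events must align")
    if not np.isfinite(X).all():
        raise ValueError("covariates contain non-finite values")
    if e.sum() == 0:
        raise OneGroupError("one-group-cox", "no events in the cohort")
    for k, name in enumerate(names):
        if np.ptp(X[:, k]) == 0:
            raise OneGroupError("one-group-cox", f"covariate {name!r} is constant")

    beta = np.zeros(X.shape[1])
    loglik, score, info = _cox_quantities(X, t, e, beta, tie_method)
    converged = False
    warnings: list[str] = []
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            warnings.append("singular information matrix")
            break
        # step-halving keeps the partial likelihood non-decreasing
        factor = 1.0
        for _ in range(25):
            candidate = beta + factor * step
            new_ll, new_score, new_info = _cox_quantities(X, t, e, candidate, tie_method)
            if new_ll >= loglik - 1e-12:
                break
            factor /= 2.0
        beta, loglik, score, info = candidate, new_ll, new_score, new_info
        if np.max(np.abs(factor * step)) < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 50:
        converged = False
        warnings.append("monotone partial likelihood (possible separation)")
    if not converged and not warnings:
        warnings.append("Newton iterations did not converge")

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(beta.shape, np.nan)
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    pvals = 2 * sps.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):
        summary = pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hr": np.exp(beta),
                "ci_low": np.exp(beta - Z_95 * se),
                "ci_high": np.exp(beta + Z_95 * se),
                "p": pvals,
            },
            index=pd.Index(names, name="covariate"),
        )
    return CoxResult(summary, converged, int(t.size), int(e.sum()), tie_method, warnings)


# ---------------------------------------------------------------------------
# per-gene model tables


def _gene_subset(dataset: AnalysisDataset, gene_groups: pd.Series):
    groups = gene_groups.reindex(dataset.patients)
    keep = groups.notna()
    clin = dataset.clinical.loc[keep]
    return clin, groups[keep].astype(float)


def univariate_table(
    dataset: AnalysisDataset, gene_groups: pd.Series, tie_method: str = "efron"
) -> tuple[pd.DataFrame, list[dict]]:
    """One single-covariate Cox fit per clinical feature plus the gene group.

    Patients with a null expression value for the gene (NaN in
    ``gene_groups``) are excluded from every fit so all nine rows describe
    the same analysis subset.  Per-feature failures are logged and the
    remaining rows returned.
    """
    clin, groups = _gene_subset(dataset, gene_groups)
    t, e = clin["time"].to_numpy(float), clin["event"].to_numpy(int)
    rows, failures = [], []
    features = {name: clin[name] for name in COVARIATE_NAMES}
    features["gene"] = groups
    for name, series in features.items():
        try:
            res = cox_fit(series.to_frame(name), t, e, tie_method=tie_method)
            row = res.summary.loc[name]
            rows.append(
                {
                    "feature": name,
                    "hr": row["hr"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "p": row["p"],
                    "converged": res.converged,
                }
            )
        except OneGroupError as exc:
            failures.append({"feature": name, "category": exc.category, "reason": str(exc)})
    return pd.DataFrame(rows), failures


def multivariate_fit(
    dataset: AnalysisDataset,
    gene_groups: pd.Series,
    tie_method: str = "efron",
    small_group_warning: int = 5,
) -> CoxResult:
    """Joint Cox fit of all clinical covariates plus the gene indicator.

    Clinical covariates that are constant in the analysis subset are dropped
    with a warning (they carry no information); a constant gene indicator is
    an error.  Covariates whose minority level holds fewer than
    ``small_group_warning`` patients are flagged: their hazard ratios rest on
    almost no data and should be ignored.
    """
    clin, groups = _gene_subset(dataset, gene_groups)
    t, e = clin["time"].to_numpy(float), clin["event"].to_numpy(int)
    if groups.nunique() < 2:
        raise OneGroupError("one-group-cox", "gene indicator is constant")
    X = clin[list(COVARIATE_NAMES)].astype(float).copy()
    dropped = [c for c in X.columns if X[c].nunique() < 2]
    X = X.drop(columns=dropped)
    X["gene"] = groups.to_numpy(float)
    result = cox_fit(X, t, e, tie_method=tie_method)
    for c in dropped:
        result.warnings.append(f"covariate {c!r} constant in subset; dropped from joint fit")
    for c in X.columns:
        minority = int(min((X[c] == 1).sum(), (X[c] == 0).sum()))
        if minority < small_group_warning:
            result.warnings.append(
                f"covariate {c!r} has a near-empty subgroup ({minority} patients); "
                "its hazard ratio should be ignored"
            )
    return result
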