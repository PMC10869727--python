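"""Cox partial-likelihood machinery built from first principles.

Under the proportional-hazards model h(t | x_i) = h0(t) * exp(f(x_i)) the
baseline hazard cancels out of the ranking of event times, leaving the log
partial likelihood

    log L = sum_i delta_i * [ f_i - log sum_{j in R(t_i)} exp(f_j) ],

where R(t_i) = {j : t_j >= t_i} is the risk set at subject i's event time.
This module provides that objective and its analytic gradient with respect to
the scores (the training signal for the deep scorer), a Newton-Raphson
maximum-partial-likelihood fitter for tabular covariates with Breslow tie
handling, and per-subgroup hazard-ratio fits for forest-plot style analyses.

Tied event times share the full risk set (Breslow); each risk-set
log-sum-exp subtracts the running maximum score for stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import RiskScore, SubjectOutcome

Z95 = 1.959964  # normal quantile for the fixed 95% CI level


def _times_events(outcomes: Sequence[SubjectOutcome]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([o.time_days for o in outcomes], dtype=np.float64)
    d = np.array([o.event for o in outcomes], dtype=np.float64)
    return t, d


def _check_scores(scores: np.ndarray, n: int) -> np.ndarray:
    f = np.asarray(scores, dtype=np.float64).reshape(-1)
    if f.shape[0] != n:
        raise ValueError(f"scores ({f.shape[0]}) and outcomes ({n}) differ in length")
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite score")
    return f


def _tie_group_ends(t_sorted: np.ndarray) -> np.ndarray:
    """For ascending times, the index of the last member of each tie group."""
    n = t_sorted.shape[0]
    ends = np.empty(n, dtype=np.intp)
    i = n - 1
    while i >= 0:
        j = i
        while j > 0 and t_sorted[j - 1] == t_sorted[i]:
            j -= 1
        ends[j:i + 1] = i
        i = j - 1
    return ends


def risk_set_index(outcomes: Sequence[SubjectOutcome]) -> dict[int, np.ndarray]:
    """Explicit risk sets R(t_i) for every event subject i (original indices).

    Quadratic and intended for inspection and small problems; the likelihood
    routines below use sorted suffix sums instead.
    """
    t, d = _times_events(outcomes)
    return {
        int(i): np.flatnonzero(t >= t[i])
        for i in np.flatnonzero(d == 1)
    }


def partial_log_likelihood(scores: np.ndarray | Sequence[float],
                           outcomes: Sequence[SubjectOutcome]) -> float:
    """Breslow log partial likelihood of the scores; 0 when there are no events."""
    if len(outcomes) == 0:
        raise ValueError("at least one subject required")
    t, d = _times_events(outcomes)
    f = _check_scores(scores, len(outcomes))
    if d.sum() == 0:
        return 0.0
    order = np.argsort(t, kind="stable")
    ts, ds, fs = t[order], d[order], f[order]
    fmax = fs.max()
    w = np.exp(fs - fmax)
    # suffix sums: denom at i covers all j with t_j >= t_i (ties included)
    suffix = np.cumsum(w[::-1])[::-1]
    # suffix at the *first* member of i's tie group == sum over {t_j >= t_i}
    starts = np.empty(len(ts), dtype=np.intp)
    s = 0
    for i in range(len(ts)):
        if i > 0 and ts[i] != ts[i - 1]:
            s = i
        starts[i] = s
    ev = ds == 1
    log_denom = np.log(suffix[starts[ev]]) + fmax
    return float(np.sum(fs[ev] - log_denom))


def partial_likelihood_gradient(scores: np.ndarray | Sequence[float],
                                outcomes: Sequence[SubjectOutcome]) -> np.ndarray:
    """d log L / d f_k = delta_k - exp(f_k) * sum_{events i: t_i <= t_k} 1/D_i."""
    if len(outcomes) == 0:
        raise ValueError("at least one subject required")
    t, d = _times_events(outcomes)
    f = _check_scores(scores, len(outcomes))
    n = len(outcomes)
    if d.sum() == 0:
        return np.zeros(n)
    order = np.argsort(t, kind="stable")
    ts, ds, fs = t[order], d[order], f[order]
    fmax = fs.max()
    w = np.exp(fs - fmax)
    suffix = np.cumsum(w[::-1])[::-1]
    starts = np.empty(n, dtype=np.intp)
    s = 0
    for i in range(n):
        if i > 0 and ts[i] != ts[i - 1]:
            s = i
        starts[i] = s
    inv_d = np.where(ds == 1, 1.0 / suffix[starts], 0.0)
    cum_inv = np.cumsum(inv_d)
    ends = _tie_group_ends(ts)
    # k is in R(t_i) iff t_i <= t_k, i.e. events up to the end of k's tie group
    g_sorted = ds - w * cum_inv[ends]
    grad = np.empty(n)
    grad[order] = g_sorted
    return grad


# ---------------------------------------------------------------------------
# Newton-Raphson proportional-hazards fitter
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Maximum-partial-likelihood fit of a proportional-hazards model."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    hazard_ratios: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    wald_p: np.ndarray
    log_partial_likelihood: float
    converged: bool
    n_subjects: int
    n_events: int
    names: tuple[str, ...] = ()


def _cox_derivatives(X: np.ndarray, t: np.ndarray, d: np.ndarray,
                     beta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow log partial likelihood, score vector and observed information."""
    n, p = X.shape
    eta = X @ beta
    order = np.argsort(t, kind="stable")
    ts, ds, Xs = t[order], d[order], X[order]
    etas = eta[order]
    emax = etas.max()
    w = np.exp(etas - emax)                       # (n,)
    wx = w[:, None] * Xs                          # (n, p)
    wxx = wx[:, :, None] * Xs[:, None, :]         # (n, p, p)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        grp = slice(i, j + 1)
        dcount = ds[grp].sum()
        if dcount > 0:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            mean = s1 / s0
            ll += float(np.sum((etas[grp] - emax - np.log(s0)) * ds[grp]))
            grad += (Xs[grp] * ds[grp, None]).sum(axis=0) - dcount * mean
            info += dcount * (s2 / s0 - np.outer(mean, mean))
        i = j + 1
    return ll, grad, info


def fit_cox(covariates: np.ndarray, outcomes: Sequence[SubjectOutcome], *,
            max_iter: int = 100, tol: float = 1e-9, ridge: float = 0.0,
            names: Sequence[str] | None = None) -> CoxFit:
    """Newton-Raphson Breslow-tie proportional-hazards fit.

    Covariates are centered internally (coefficients are unaffected).
    Convergence is declared when the score norm drops below ``tol``; a
    diverging coefficient norm flags separation and the fit is returned with
    ``converged=False`` rather than raising.  ``ridge`` adds an optional
    l2 penalty (default 0) that can rescue separated data.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
    if X.shape[0] != len(outcomes):
        X = X.T
    if X.shape[0] != len(outcomes):
        raise ValueError("covariate rows must match outcomes")
    t, d = _times_events(outcomes)
    n, p = X.shape
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError("no events: partial likelihood is uninformative")
    Xc = X - X.mean(axis=0)

    beta = np.zeros(p)
    ll, grad, info = _cox_derivatives(Xc, t, d, beta)
    converged = False
    for _ in range(max_iter):
        g = grad - ridge * beta
        H = info + ridge * np.eye(p)
        if np.linalg.norm(g) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step halving on penalized objective decrease
        pen_ll = ll - 0.5 * ridge * beta @ beta
        for _ in range(30):
            cand = beta + step
            ll_c, grad_c, info_c = _cox_derivatives(Xc, t, d, cand)
            if ll_c - 0.5 * ridge * cand @ cand >= pen_ll - 1e-12:
                break
            step *= 0.5
        beta, ll, grad, info = cand, ll_c, grad_c, info_c
        if np.max(np.abs(beta)) > 20:  # separation guard
            break
    else:
        pass
    if np.max(np.abs(beta)) > 20:
        converged = False

    H = info + ridge * np.eye(p)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # separated fits can overflow the CI
        hr = np.exp(beta)
        ci_lo = np.exp(beta - Z95 * se)
        ci_hi = np.exp(beta + Z95 * se)
    return CoxFit(
        coefficients=beta,
        standard_errors=se,
        hazard_ratios=hr,
        ci95_low=ci_lo,
        ci95_high=ci_hi,
        wald_p=pvals,
        log_partial_likelihood=float(ll),
        converged=converged,
        n_subjects=n,
        n_events=n_events,
        names=tuple(names) if names is not None else tuple(f"x{i}" for i in range(p)),
    )


# ---------------------------------------------------------------------------
# subgroup hazard-ratio (forest) analysis
# ---------------------------------------------------------------------------

@dataclass
class ForestRow:
    """One subgroup's single-covariate hazard-ratio fit."""

    subgroup: str
    n: int
    n_events: int
    estimable: bool
    fit: CoxFit | None


SCORE_CODINGS = ("standardized_continuous", "binary_top_quartile")


def subgroup_forest(scores: Iterable[RiskScore],
                    outcomes: Sequence[SubjectOutcome],
                    subgroup_labels: Mapping[str, str],
                    score_coding: str = "standardized_continuous",
                    ) -> list[ForestRow]:
    """Per-subgroup Cox fits of the risk score, forest-plot style.

    The score is coded once on the full cohort — z-scored
    (``standardized_continuous``) or dichotomized at the empirical 75th
    percentile (``binary_top_quartile``) — then a single-covariate
    proportional-hazards model is fit within each subgroup.  Subgroups
    without events (or with a constant coded score) are reported as not
    estimable rather than raising.
    """
    if score_coding not in SCORE_CODINGS:
        raise ValueError(f"unknown coding {score_coding!r}; "
                         f"expected one of {SCORE_CODINGS}")
    score_by_id = {s.subject_id: s.score for s in scores}
    ids = [o.subject_id for o in outcomes]
    missing = [s for s in ids if s not in score_by_id]
    if missing:
        raise ValueError(f"no score for subject(s): {missing[:5]}")
    raw = np.array([score_by_id[s] for s in ids])
    if score_coding == "standardized_continuous":
        sd = raw.std(ddof=0)
        coded = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    else:
        q75 = np.sort(raw)[int(np.ceil(0.75 * len(raw))) - 1]
        coded = (raw > q75).astype(float)

    groups = sorted({subgroup_labels.get(s, None) for s in ids} - {None})
    rows: list[ForestRow] = []
    for g in groups:
        mask = np.array([subgroup_labels.get(s) == g for s in ids])
        sub_out = [o for o, m in zip(outcomes, mask) if m]
        sub_x = coded[mask]
        n_ev = sum(o.event for o in sub_out)
        if n_ev == 0 or np.ptp(sub_x) == 0:
            rows.append(ForestRow(g, len(sub_out), n_ev, False, None))
            continue
        fit = fit_cox(sub_x[:, None], sub_out, names=("risk_score",))
        rows.append(ForestRow(g, len(sub_out), n_ev, True, fit))
    return rows


def write_forest_tsv(rows: Sequence[ForestRow], path: str | Path) -> None:
    """Write the forest table: subgroup, n, n_events, hr, ci_low, ci_high, p, estimable."""
    with open(path, "w") as fh:
        fh.write("subgroup\tn\tn_events\thr\tci_low\tci_high\tp\testimable\n")
        for r in rows:
            if r.estimable and r.fit is not None:
                fh.write(
                    f"{r.subgroup}\t{r.n}\t{r.n_events}\t"
                    f"{r.fit.hazard_ratios[0]:.6g}\t{r.fit.ci95_low[0]:.6g}\t"
                    f"{r.fit.ci95_high[0]:.6g}\t{r.fit.wald_p[0]:.6g}\ttrue\n"
                )
            else:
                fh.write(f"{r.subgroup}\t{r.n}\t{r.n_events}\tNA\tNA\tNA\tNA\tfalse\n")
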