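"""Risk-stratification and survival evaluation protocol.

Implements the full evaluation stack for a scored cohort: Harrell's
concordance (optionally truncated at a horizon), the Kaplan-Meier
product-limit estimator, the k-group log-rank test, empirical-quantile
stratification (median split and median + upper-quartile three-level split),
horizon-based binary labels, threshold-sweep ROC curves, the three-segment
ROC induced by an ordered three-level stratification, and event-rate
summaries with half-away-from-zero percentage rounding.

Quantile thresholds use the type-1 empirical inverse CDF, so a cohort of 388
distinct scores splits exactly 194/194 at the median and 194/97/97 with cuts
at (0.5, 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import RiskScore, SubjectOutcome


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def concordance_index(scores: Sequence[float] | np.ndarray,
                      outcomes: Sequence[SubjectOutcome],
                      horizon_days: float | None = None) -> float:
    """Harrell's C over comparable pairs, higher score = higher risk.

    A pair (i, j) is comparable when i has an event and either t_i < t_j, or
    t_i <= t_j with j censored.  It is concordant when score_i > score_j;
    score ties count 1/2.  With ``horizon_days``, pairs whose earlier
    (event) time exceeds the horizon are excluded — the truncated C-index
    used for per-horizon model selection.
    """
    f = np.asarray(scores, dtype=np.float64).reshape(-1)
    t = np.array([o.time_days for o in outcomes])
    d = np.array([o.event for o in outcomes])
    if f.shape[0] != t.shape[0]:
        raise ValueError("scores and outcomes differ in length")
    ev = d == 1
    if horizon_days is not None:
        ev = ev & (t <= horizon_days)
    # comparable[i, j]: i the event case
    lt = t[:, None] < t[None, :]
    le_cens = (t[:, None] <= t[None, :]) & (d[None, :] == 0)
    comp = ev[:, None] & (lt | le_cens)
    np.fill_diagonal(comp, False)
    n_comp = comp.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    gt = f[:, None] > f[None, :]
    eq = f[:, None] == f[None, :]
    n_conc = (comp & gt).sum() + 0.5 * (comp & eq).sum()
    return float(n_conc / n_comp)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate reported at event times."""

    event_times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(outcomes: Sequence[SubjectOutcome]) -> KMCurve:
    """Kaplan-Meier estimator; censored subjects leave the risk set after their time."""
    if len(outcomes) == 0:
        raise ValueError("empty input")
    t = np.array([o.time_days for o in outcomes])
    d = np.array([o.event for o in outcomes])
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    times, surv, at_risk, n_ev = [], [], [], []
    s = 1.0
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        dcount = int(d[i:j + 1].sum())
        risk = n - i
        if dcount > 0:
            s *= 1.0 - dcount / risk
            times.append(float(t[i]))
            surv.append(s)
            at_risk.append(risk)
            n_ev.append(dcount)
        i = j + 1
    return KMCurve(np.array(times), np.array(surv),
                   np.array(at_risk, dtype=int), np.array(n_ev, dtype=int))


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


def logrank_test(group_labels: Sequence[str],
                 outcomes: Sequence[SubjectOutcome]) -> LogRankResult:
    """k-group log-rank test with the hypergeometric variance.

    At every distinct event time the observed events per group are compared
    with the expectation under exchangeability; ties across groups at one
    time are handled jointly.  The statistic is quadratic in (O - E) over
    the first k-1 groups with the estimated covariance; p from the
    chi-square upper tail with k-1 degrees of freedom.
    """
    labels = np.asarray([str(g) for g in group_labels])
    if labels.shape[0] != len(outcomes):
        raise ValueError("labels and outcomes differ in length")
    groups = sorted(set(labels))
    k = len(groups)
    if k < 2:
        raise ValueError("log-rank test requires at least two groups")
    t = np.array([o.time_days for o in outcomes])
    d = np.array([o.event for o in outcomes])
    if d.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    gidx = np.array([groups.index(g) for g in labels])

    event_times = np.unique(t[d == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        N = at_risk.sum()
        if N <= 1:
            dd = int(((t == et) & (d == 1)).sum())
            O[gidx[(t == et) & (d == 1)]] += 1  # degenerate, no variance
            E[gidx[at_risk]] += dd / max(N, 1)
            continue
        Ng = np.bincount(gidx[at_risk], minlength=k).astype(float)
        dead = (t == et) & (d == 1)
        dd = dead.sum()
        Og = np.bincount(gidx[dead], minlength=k).astype(float)
        O += Og
        E += dd * Ng / N
        frac = Ng / N
        factor = dd * (N - dd) / (N - 1)
        V += factor * (np.diag(frac) - np.outer(frac, frac))
    z = (O - E)[:-1]
    Vr = V[:-1, :-1]
    try:
        chi2 = float(z @ np.linalg.solve(Vr, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(Vr) @ z)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi2, df, max(p, np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# quantile stratification
# ---------------------------------------------------------------------------

@dataclass
class StratumAssignment:
    """Mapping of subjects to ordered risk strata with the cut quantiles used."""

    assignments: dict[str, str]
    strata: tuple[str, ...]          # ordered low -> high risk
    cut_quantiles: tuple[float, ...]

    def members(self, stratum: str) -> list[str]:
        return sorted(s for s, g in self.assignments.items() if g == stratum)

    def sizes(self) -> dict[str, int]:
        return {g: sum(1 for v in self.assignments.values() if v == g)
                for g in self.strata}


def _stratum_names(n_cuts: int) -> tuple[str, ...]:
    if n_cuts == 1:
        return ("below_median", "above_median")
    if n_cuts == 2:
        return ("low", "intermediate", "high")
    return tuple(f"stratum_{i + 1}" for i in range(n_cuts + 1))


def stratify_by_quantiles(scores: Iterable[RiskScore],
                          cut_quantiles: Sequence[float],
                          tie_policy: str = "strict") -> StratumAssignment:
    """Assign subjects to risk strata at empirical-quantile score thresholds.

    Thresholds are type-1 empirical quantiles (the ceil(n*q)-th order
    statistic), so n = 388 with cuts (0.5, 0.75) yields strata of exactly
    194 / 97 / 97 subjects when scores are distinct.  Tied scores straddling
    a cut raise under the default strict policy; ``tie_policy="stable_order"``
    breaks them by stable sort order instead.
    """
    items = [(s.subject_id, s.score) for s in scores]
    cuts = tuple(float(q) for q in cut_quantiles)
    if not cuts or any(not (0 < q < 1) for q in cuts) or list(cuts) != sorted(set(cuts)):
        raise ValueError("cut_quantiles must be strictly increasing in (0, 1)")
    if tie_policy not in ("strict", "stable_order"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    n = len(items)
    if n < len(cuts) + 1:
        raise ValueError("too few subjects for the requested cuts")
    vals = np.array([v for _, v in items])
    order = np.argsort(vals, kind="stable")
    boundaries = [int(np.ceil(n * q)) for q in cuts]  # rank counts per stratum edge
    if tie_policy == "strict":
        if np.unique(vals).size != n:
            # only a problem when ties straddle a boundary, but the contract
            # asks to reject degenerate distributions outright at the cuts
            for b in boundaries:
                if b < n and vals[order[b - 1]] == vals[order[b]]:
                    raise ValueError(
                        "degenerate score distribution: tied scores at a "
                        "quantile cut (use tie_policy='stable_order')"
                    )
    names = _stratum_names(len(cuts))
    assignments: dict[str, str] = {}
    edges = [0] + boundaries + [n]
    for level, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        for pos in order[lo:hi]:
            assignments[items[pos][0]] = names[level]
    return StratumAssignment(assignments, names, cuts)


# ---------------------------------------------------------------------------
# horizon labels and ROC
# ---------------------------------------------------------------------------

HORIZON_POLICIES = ("exclude_censored_before_horizon", "censored_as_negative")


def horizon_labels(outcomes: Sequence[SubjectOutcome], horizon_days: float,
                   policy: str = "exclude_censored_before_horizon",
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Binary event-by-horizon labels plus an inclusion mask.

    Positive: event at or before the horizon.  Negative: followed beyond the
    horizon event-free.  Subjects censored before the horizon are masked out
    under the default policy, or kept as negatives under
    ``censored_as_negative`` (the "disregard censoring" all-time variant).
    """
    if horizon_days <= 0:
        raise ValueError("horizon must be positive")
    if policy not in HORIZON_POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    t = np.array([o.time_days for o in outcomes])
    d = np.array([o.event for o in outcomes])
    pos = (d == 1) & (t <= horizon_days)
    beyond = t > horizon_days
    labels = pos.astype(int)
    if policy == "exclude_censored_before_horizon":
        mask = pos | beyond
    else:
        mask = np.ones_like(pos, dtype=bool)
    return labels, mask


@dataclass
class ROCCurve:
    """An ROC polyline from (0,0) to (1,1) with its trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    kind: str  # "threshold_sweep" | "stratified_3level"


def roc_curve(scores: Sequence[float] | np.ndarray,
              labels: Sequence[int] | np.ndarray) -> ROCCurve:
    """Threshold-sweep ROC; trapezoidal AUC equals the normalized Mann-Whitney U."""
    f = np.asarray(scores, dtype=np.float64).reshape(-1)
    y = np.asarray(labels, dtype=int).reshape(-1)
    if f.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    npos = int((y == 1).sum())
    nneg = int((y == 0).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-f, kind="stable")
    fs, ys = f[order], y[order]
    # collapse tied scores into single sweep points
    distinct = np.r_[np.flatnonzero(np.diff(fs)) , fs.size - 1]
    tp = np.cumsum(ys == 1)[distinct]
    fp = np.cumsum(ys == 0)[distinct]
    tpr = np.r_[0.0, tp / npos]
    fpr = np.r_[0.0, fp / nneg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr, tpr, auc, "threshold_sweep")


def stratified_roc(strata: StratumAssignment,
                   labels: Mapping[str, int]) -> ROCCurve:
    """Three-segment ROC of an ordered low/intermediate/high stratification.

    The two interior vertices are the operating points of the "high only
    positive" and "high + intermediate positive" rules — i.e. thresholding
    at the upper-quartile cut and at the median cut.  The AUC is the
    trapezoid over the four vertices and equals the threshold-sweep AUC of
    the ordinal stratum index used as a score.
    """
    if len(strata.strata) != 3:
        raise ValueError("stratified ROC requires exactly three ordered strata")
    low, mid, high = strata.strata
    ids = sorted(strata.assignments)
    missing = [s for s in ids if s not in labels]
    if missing:
        raise ValueError(f"no label for subject(s): {missing[:5]}")
    y = np.array([labels[s] for s in ids], dtype=int)
    g = np.array([strata.assignments[s] for s in ids])
    npos = int((y == 1).sum())
    nneg = int((y == 0).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("both classes must be present")

    def vertex(call_high: np.ndarray) -> tuple[float, float]:
        tp = int((call_high & (y == 1)).sum())
        fp = int((call_high & (y == 0)).sum())
        return fp / nneg, tp / npos

    v1 = vertex(g == high)
    v2 = vertex((g == high) | (g == mid))
    fpr = np.array([0.0, v1[0], v2[0], 1.0])
    tpr = np.array([0.0, v1[1], v2[1], 1.0])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr, tpr, auc, "stratified_3level")


# ---------------------------------------------------------------------------
# event-rate summaries
# ---------------------------------------------------------------------------

def percent(count: int, size: int) -> float:
    """100*count/size rounded half away from zero to two decimals."""
    if count > size:
        raise ValueError(f"count {count} exceeds cohort size {size}")
    if size <= 0:
        raise ValueError("cohort size must be positive")
    q = Decimal(100 * count) / Decimal(size)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def event_rate_summary(endpoint_counts: Sequence[tuple[str, int, int]] | pd.DataFrame,
                       ) -> pd.DataFrame:
    """Tabulate per-endpoint event counts as `count (percent)` summaries.

    Accepts (endpoint, count, size) triples or a DataFrame with those
    columns; returns a DataFrame adding the percentage, rounded half away
    from zero to two decimals.
    """
    if isinstance(endpoint_counts, pd.DataFrame):
        rows = [(str(r["endpoint"]), int(r["count"]), int(r["size"]))
                for _, r in endpoint_counts.iterrows()]
    else:
        rows = [(str(e), int(c), int(s)) for e, c, s in endpoint_counts]
    data = [(e, c, s, percent(c, s)) for e, c, s in rows]
    return pd.DataFrame(data, columns=["endpoint", "count", "size", "percent"])


# ---------------------------------------------------------------------------
# TSV writers
# ---------------------------------------------------------------------------

def write_km_tsv(curve: KMCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("time\tsurvival\tn_at_risk\tn_events\n")
        for t, s, r, e in zip(curve.event_times, curve.survival,
                              curve.n_at_risk, curve.n_events):
            fh.write(f"{t:.6g}\t{s:.8g}\t{r}\t{e}\n")


def write_roc_tsv(curve: ROCCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for x, y in zip(curve.fpr, curve.tpr):
            fh.write(f"{x:.8g}\t{y:.8g}\n")
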