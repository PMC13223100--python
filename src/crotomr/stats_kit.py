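"""Classical statistical tests shared by the expression, spatial and clinical
stages: Pearson chi-square, two-sided Fisher's exact test, Mann-Whitney U /
Wilcoxon rank-sum, Wilcoxon signed-rank, Kruskal-Wallis, Spearman correlation,
Kaplan-Meier curves and the two-group log-rank test.

All test statistics are computed here from first principles; only reference
distribution tails (normal, chi-square, t) come from scipy. Rank tests use
average ranks for ties and tie-corrected normal approximations — exact
enumeration is reserved for test oracles.

Test-selection policy for contingency tables (as used by the clinical stage):
Fisher's exact test for 2x2 tables, Pearson chi-square without continuity
correction otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln


class DegenerateTableError(ValueError):
    """A contingency table has a zero margin."""


@dataclass
class ContingencyResult:
    observed: np.ndarray
    test: str  # pearson_chi2 | fisher_exact
    statistic: Optional[float]
    df: Optional[int]
    pvalue: float


def _as_count_table(table) -> np.ndarray:
    t = np.asarray(table)
    if np.any(t < 0) or not np.all(np.equal(np.mod(t, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    return t.astype(np.int64)


def pearson_chi2(table) -> ContingencyResult:
    """Pearson chi-square test of independence, no continuity correction."""
    obs = _as_count_table(table)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if np.any(row == 0) or np.any(col == 0) or n == 0:
        raise DegenerateTableError("zero margin in contingency table")
    expected = row * col / n
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return ContingencyResult(obs, "pearson_chi2", stat, df, max(p, 1e-300))


def _log_hypergeom_pmf(a: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(A = a) for the free cell of a 2x2 table with margins fixed."""
    n = r1 + r2
    c2 = n - c1

    def lchoose(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    return lchoose(r1, a) + lchoose(r2, c1 - a) - lchoose(n, c1)


def fisher_exact_2x2(table) -> ContingencyResult:
    """Two-sided Fisher's exact test by the point-probability method.

    The two-sided p-value sums the hypergeometric probabilities of every
    table (with the observed margins) whose point probability does not
    exceed that of the observed table, compared with relative tolerance
    1e-7. A zero margin gives the degenerate p-value 1.
    """
    obs = _as_count_table(table)
    if obs.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    r1, r2 = int(obs[0].sum()), int(obs[1].sum())
    c1 = int(obs[:, 0].sum())
    if min(r1, r2, c1, obs[:, 1].sum()) == 0:
        return ContingencyResult(obs, "fisher_exact", None, None, 1.0)
    a_min = max(0, c1 - r2)
    a_max = min(r1, c1)
    support = np.arange(a_min, a_max + 1)
    logp = _log_hypergeom_pmf(support, r1, r2, c1)
    pmf = np.exp(logp - logp.max())
    pmf /= pmf.sum()
    p_obs = pmf[int(obs[0, 0]) - a_min]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return ContingencyResult(obs, "fisher_exact", None, None, min(p, 1.0))


def contingency_test(table) -> ContingencyResult:
    """Policy dispatcher: Fisher for 2x2 tables, Pearson chi-square otherwise."""
    obs = _as_count_table(table)
    if obs.shape == (2, 2):
        return fisher_exact_2x2(obs)
    return pearson_chi2(obs)


def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average ranks plus the tie-group sizes (for variance corrections)."""
    ranks = sps.rankdata(values, method="average")
    _, counts = np.unique(values, return_counts=True)
    return ranks, counts


def mann_whitney_u(x, y, continuity: bool = True) -> tuple[float, float]:
    """Mann-Whitney U from rank sums with average ranks for ties; two-sided
    p by normal approximation with tie-corrected variance and (by default)
    continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks, ties = _rank_with_ties(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    tie_term = ((ties**3 - ties).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u1), 1.0
    cc = 0.5 if continuity else 0.0
    z = (abs(u1 - mu) - cc) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return float(u1), float(max(p, 1e-300))


def wilcoxon_rank_sum(x, y) -> float:
    """Wilcoxon rank-sum p-value; identical to :func:`mann_whitney_u`."""
    return mann_whitney_u(x, y)[1]


def wilcoxon_signed_rank(paired_diffs) -> float:
    """Paired Wilcoxon signed-rank test (zeros dropped, average ranks,
    tie-corrected normal approximation with continuity correction)."""
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks, ties = _rank_with_ties(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    var = n * (n + 1) * (2 * n + 1) / 24 - ((ties**3 - ties).sum()) / 48
    if var <= 0:
        return 1.0
    z = (abs(w_plus - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return float(max(p, 1e-300))


def kruskal_wallis(groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square(g-1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks, ties = _rank_with_ties(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    correction = 1 - ((ties**3 - ties).sum()) / (n**3 - n) if n > 1 else 1.0
    if correction <= 0:
        return 0.0, 1.0
    h /= correction
    p = float(sps.chi2.sf(h, len(groups) - 1))
    return float(h), max(p, 1e-300)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation: Pearson correlation of average ranks, with
    a t-approximation p-value. Returns (nan, nan) flagged via nan when either
    variable has zero rank variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    sx, sy_ = rx.std(), ry.std()
    if sx == 0 or sy_ == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        return rho, 0.0 if n > 2 else 1.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = min(1.0, 2.0 * sps.t.sf(abs(t), n - 2))
    return rho, float(max(p, 1e-300))


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate over distinct event times."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times, events) -> SurvivalCurve:
    """Product-limit estimator. ``events`` is 1 for death, 0 for censoring."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("no subjects")
    if np.any(t < 0) or not np.all(np.isin(e, [0, 1])):
        raise ValueError("times must be >= 0 and events binary")
    event_times = np.unique(t[e == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for et in event_times:
        n_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        n_ev.append(d)
    return SurvivalCurve(event_times, np.array(surv), np.array(at_risk), np.array(n_ev))


def logrank(groups: Sequence[tuple]) -> tuple[float, float]:
    """Two-group log-rank test.

    ``groups`` is a sequence of two (times, events) tuples. The statistic is
    the squared standardized difference between observed and expected events
    in group 1, with hypergeometric variance at each distinct event time,
    referred to chi-square(1).
    """
    if len(groups) != 2:
        raise ValueError("logrank compares exactly two groups")
    data = []
    for times, events in groups:
        t = np.asarray(times, dtype=float)
        e = np.asarray(events, dtype=int)
        if t.size == 0:
            raise ValueError("a group has no subjects")
        data.append((t, e))
    all_t = np.concatenate([d[0] for d in data])
    all_e = np.concatenate([d[1] for d in data])
    grp = np.concatenate([np.zeros(data[0][0].size, int), np.ones(data[1][0].size, int)])
    event_times = np.unique(all_t[all_e == 1])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = all_t >= et
        n = int(at_risk.sum())
        n1 = int((at_risk & (grp == 0)).sum())
        d = int(((all_t == et) & (all_e == 1)).sum())
        d1 = int(((all_t == et) & (all_e == 1) & (grp == 0)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(max(sps.chi2.sf(chi2, 1), 1e-300))
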