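"""Nonparametric cohort tests, clinicopathological grouping, and survival.

The Wilcoxon signed-rank and Mann-Whitney U tests are implemented from their
defining null distributions so that small-sample p-values are *exact*:

* Wilcoxon: zero differences are dropped (Wilcoxon's convention), tied
  absolute differences get midranks, and for up to ``exact_limit`` effective
  pairs the two-tailed p-value is computed from the full sign-flip null —
  the distribution of W+ over all 2^n sign assignments, evaluated by
  subset-sum counting (equivalent to complete enumeration).  Beyond that, a
  normal approximation with tie and continuity corrections is used.
* Mann-Whitney: exact when the pooled sample is small and tie-free, from the
  distribution of the rank sum over all C(nA+nB, nA) group labelings
  (again via subset-sum counting); tie-corrected normal approximation
  otherwise.

Two-tailed p-values are symmetric-tail probabilities,
``P(|T - center| >= |t_obs - center|)``, which reduces to twice the smaller
tail for these symmetric nulls and is never larger than 1.

Survival uses the Kaplan-Meier product-limit estimator with right censoring
and the standard two-group log-rank chi-square (1 df).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedTestResult",
    "GroupComparisonResult",
    "SurvivalCurve",
    "LogRankResult",
    "SurvivalStratification",
    "DegenerateDataError",
    "InsufficientDataError",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "compare_by_covariate",
    "median_split",
    "kaplan_meier",
    "log_rank_test",
    "survival_stratification",
]


class DegenerateDataError(ValueError):
    """Input has no information for the requested test (e.g. all-zero differences)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested analysis."""


@dataclass(frozen=True)
class PairedTestResult:
    test_name: str
    n_effective: int
    statistic: float
    p_two_tailed: float
    method: str  # "exact" | "normal"


@dataclass(frozen=True)
class GroupComparisonResult:
    grouping: str
    summaries: dict[str, tuple[int, float, float]]  # label -> (n, mean, sd)
    test_name: str
    statistic: float
    p_two_tailed: float


def _signflip_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of 2*W+ over all sign assignments (subset-sum enumeration)."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return counts


def wilcoxon_signed_rank(
    x, y=None, *, exact_limit: int = 25
) -> PairedTestResult:
    """Two-tailed Wilcoxon signed-rank test on paired data (or differences).

    Pass paired samples ``x, y`` or precomputed differences ``x`` alone.
    The statistic is W+, the sum of midranks of positive differences.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    center2 = int(round(2 * ranks.sum()))  # 2 * E[2*W+]/2 = sum of doubled ranks

    if n <= exact_limit:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _signflip_distribution(doubled)
        # support index s = 2*W+; null center (doubled twice) is sum of doubled ranks
        support = np.arange(len(counts))
        dev_obs = abs(2 * int(round(2 * w_plus)) - center2)
        mask = np.abs(2 * support - center2) >= dev_obs
        p = float(counts[mask].sum() / counts.sum())
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        dev = w_plus - mu
        if dev == 0:
            p = 1.0
        else:
            tie_counts = np.unique(np.rint(2 * ranks).astype(int), return_counts=True)[1]
            sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(
                ((tie_counts**3 - tie_counts) / 48.0).sum()
            )
            if sigma2 <= 0:
                raise DegenerateDataError("null variance is zero (all differences tied)")
            z = (abs(dev) - 0.5) / np.sqrt(sigma2)
            p = min(1.0, 2.0 * float(stats.norm.sf(max(z, 0.0))))
        method = "normal"
    return PairedTestResult(
        test_name="wilcoxon_signed_rank",
        n_effective=n,
        statistic=w_plus,
        p_two_tailed=min(1.0, p),
        method=method,
    )


def _ranksum_distribution(n_total: int, n_a: int) -> np.ndarray:
    """Counts of the group-A rank sum over all size-n_a subsets of ranks 1..n_total."""
    max_sum = sum(range(n_total - n_a + 1, n_total + 1))
    dp = np.zeros((n_a + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for v in range(1, n_total + 1):
        for k in range(min(n_a, v), 0, -1):
            dp[k, v:] += dp[k - 1, : max_sum + 1 - v]
    return dp[n_a]


def mann_whitney_u(group_a, group_b, *, exact_limit: int = 20) -> PairedTestResult:
    """Two-tailed Mann-Whitney U test between two independent groups.

    The statistic is U for group A.  Exact enumeration is used when
    nA + nB <= ``exact_limit`` and there are no cross-sample ties; otherwise a
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise InsufficientDataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0
    n = n_a + n_b
    has_ties = len(np.unique(pooled)) < n

    if n <= exact_limit and not has_ties:
        ranksum_counts = _ranksum_distribution(n, n_a)
        support = np.arange(len(ranksum_counts))
        u_support = support - n_a * (n_a + 1) / 2.0
        dev_obs = abs(2 * u_a - n_a * n_b)
        mask = np.abs(2 * u_support - n_a * n_b) >= dev_obs - 1e-9
        p = float(ranksum_counts[mask].sum() / ranksum_counts.sum())
        method = "exact"
    else:
        mu = n_a * n_b / 2.0
        dev = u_a - mu
        if dev == 0:
            p = 1.0
        else:
            _, tie_counts = np.unique(pooled, return_counts=True)
            tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
            sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
            if sigma2 <= 0:
                raise DegenerateDataError("null variance is zero (all values tied)")
            z = (abs(dev) - 0.5) / np.sqrt(sigma2)
            p = min(1.0, 2.0 * float(stats.norm.sf(max(z, 0.0))))
        method = "normal"
    return PairedTestResult(
        test_name="mann_whitney_u",
        n_effective=n,
        statistic=float(u_a),
        p_two_tailed=min(1.0, p),
        method=method,
    )


def compare_by_covariate(
    values: pd.Series, metadata: pd.DataFrame, grouping: str, *, age_cutoff: float = 60.0
) -> GroupComparisonResult:
    """Compare a per-patient metric across clinicopathological groups.

    ``values`` is indexed by patient_id.  Groupings: ``age`` (<=cutoff vs
    >cutoff), ``tnm_stage``, ``differentiation`` (patients with unknown
    differentiation are excluded).  Two groups are compared with the
    Mann-Whitney U test; more than two with Kruskal-Wallis.
    """
    meta = metadata.set_index("patient_id").loc[values.index]
    if grouping == "age":
        labels = np.where(meta["age"] <= age_cutoff, f"<= {age_cutoff:g}", f"> {age_cutoff:g}")
        labels = pd.Series(labels, index=values.index)
    elif grouping == "tnm_stage":
        labels = meta["tnm_stage"]
    elif grouping == "differentiation":
        labels = meta["differentiation"]
        keep = labels != "unknown"
        labels, values = labels[keep], values[keep]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    groups = {str(g): values[labels == g].to_numpy(dtype=float) for g in sorted(labels.unique())}
    groups = {g: v for g, v in groups.items() if len(v) > 0}
    if len(groups) < 2:
        raise DegenerateDataError(f"grouping {grouping!r} yields fewer than 2 non-empty groups")
    summaries = {
        g: (len(v), float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0)
        for g, v in groups.items()
    }
    if len(groups) == 2:
        (va, vb) = groups.values()
        res = mann_whitney_u(va, vb)
        return GroupComparisonResult(grouping, summaries, res.test_name, res.statistic, res.p_two_tailed)
    if np.ptp(np.concatenate(list(groups.values()))) == 0:
        return GroupComparisonResult(grouping, summaries, "kruskal_wallis", 0.0, 1.0)
    stat, p = stats.kruskal(*groups.values())
    return GroupComparisonResult(grouping, summaries, "kruskal_wallis", float(stat), float(p))


def median_split(values: pd.Series) -> pd.Series:
    """Split at the median: values <= median -> "low", > median -> "high".

    With odd n the median observation lands in "low", keeping the split
    deterministic.  Raises if fewer than 2 values.
    """
    values = pd.Series(values)
    if len(values) < 2:
        raise InsufficientDataError("median split needs at least 2 values")
    cutoff = float(np.median(values.to_numpy(dtype=float)))
    return pd.Series(np.where(values <= cutoff, "low", "high"), index=values.index)


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate at the distinct observed times."""

    table: pd.DataFrame = field(repr=False)  # time, n_at_risk, n_events, n_censored, survival

    def survival_at(self, t: float) -> float:
        tab = self.table
        past = tab[tab["time"] <= t]
        return float(past["survival"].iloc[-1]) if len(past) else 1.0


def kaplan_meier(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator with right censoring.

    ``events`` is 1 for an observed event, 0 for censoring; censored subjects
    leave the risk set after their time.  S(t) = prod_{t_i <= t} (1 - d_i/n_i).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise InsufficientDataError("no subjects")
    if t.min() < 0 or not np.isin(e, [0, 1]).all():
        raise ValueError("times must be >= 0 and events binary")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    rows = []
    surv = 1.0
    n_at_risk = len(t)
    for time in np.unique(t):
        here = t == time
        d = int(e[here].sum())
        c = int(here.sum()) - d
        if d > 0:
            surv *= 1.0 - d / n_at_risk
        rows.append(
            {"time": float(time), "n_at_risk": n_at_risk, "n_events": d, "n_censored": c, "survival": surv}
        )
        n_at_risk -= d + c
    return SurvivalCurve(table=pd.DataFrame(rows))


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    observed_a: float
    expected_a: float


def log_rank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test (1 df): chi2 = (O_A - E_A)^2 / V.

    At each distinct event time, E_A is the hypergeometric expectation of
    group-A events and V its variance; both sum over event times.
    """
    ta, ea = np.asarray(times_a, dtype=float), np.asarray(events_a, dtype=int)
    tb, eb = np.asarray(times_b, dtype=float), np.asarray(events_b, dtype=int)
    if ea.sum() + eb.sum() == 0:
        raise DegenerateDataError("no events in either group")
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    group_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    event_times = np.unique(all_t[all_e == 1])

    observed = expected = variance = 0.0
    for time in event_times:
        at_risk = all_t >= time
        n = int(at_risk.sum())
        n_a = int((at_risk & group_a).sum())
        here = (all_t == time) & (all_e == 1)
        d = int(here.sum())
        d_a = int((here & group_a).sum())
        observed += d_a
        expected += d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if variance == 0:
        return LogRankResult(0.0, 1.0, observed, expected)
    chi2 = (observed - expected) ** 2 / variance
    return LogRankResult(float(chi2), float(stats.chi2.sf(chi2, df=1)), observed, expected)


@dataclass(frozen=True)
class SurvivalStratification:
    cutoff: float
    labels: pd.Series = field(repr=False)
    curves: dict[str, SurvivalCurve] = field(repr=False)
    log_rank: LogRankResult | None


def survival_stratification(
    metric: pd.Series, metadata: pd.DataFrame, time_col: str = "os_time", event_col: str = "os_event"
) -> SurvivalStratification:
    """Median-split a per-patient metric and compare survival between the halves."""
    labels = median_split(metric)
    meta = metadata.set_index("patient_id").loc[metric.index]
    curves: dict[str, SurvivalCurve] = {}
    groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in ("low", "high"):
        sel = labels == g
        if sel.sum() == 0:
            continue
        t = meta.loc[sel.to_numpy(), time_col].to_numpy(dtype=float)
        e = meta.loc[sel.to_numpy(), event_col].to_numpy(dtype=int)
        curves[g] = kaplan_meier(t, e)
        groups[g] = (t, e)
    lr = None
    if len(groups) == 2:
        try:
            lr = log_rank_test(*groups["low"], *groups["high"])
        except DegenerateDataError:  # no events at all: curves still reportable
            lr = None
    return SurvivalStratification(
        cutoff=float(np.median(metric.to_numpy(dtype=float))), labels=labels, curves=curves, log_rank=lr
    )
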