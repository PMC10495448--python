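"""Survival and group-comparison statistics, implemented natively.

Covers the estimators the analysis reports: Kaplan-Meier product-limit
curves with median survival ("not reached" when the curve never crosses
0.5), the two-group log-rank test, the Mann-Whitney U test (exact by
enumeration for small samples, normal approximation with tie correction
otherwise), and derivation of the three clinical endpoints — progression-
free survival (PFS), overall survival (OS), and after-relapse survival
(ARS, time from first detection/prediction of the TP53 abnormality to
death or censoring).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMEstimate",
    "LogRankResult",
    "derive_endpoints",
    "km_estimate",
    "logrank_test",
    "mann_whitney_u",
]


@dataclass
class KMEstimate:
    """Product-limit survival curve.

    ``times`` are the distinct event times; ``survival`` the value of S(t)
    just after each; ``at_risk`` and ``events`` the risk-set size and event
    count at each. ``median`` is the smallest event time with S(t) <= 0.5,
    or None when never reached.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    median: float | None

    def survival_at(self, t: float) -> float:
        """S(t): 1 before the first event, stepping down at event times."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float  # chi-square, 1 df for two groups
    p_value: float


def derive_endpoints(clinical: pd.DataFrame) -> pd.DataFrame:
    """Turn a day-based clinical table into per-endpoint survival records.

    Expects columns sample_id, group, progression_day, death_day,
    followup_day, abnormality_day (days since diagnosis; NaN = never
    observed). Emits one row per sample per derivable endpoint with
    endpoint / time_days / event:

    * PFS — time to progression or death, whichever first, else censored
      at last follow-up;
    * OS — time to death, else censored at last follow-up;
    * ARS — time from first abnormality detection/prediction to death or
      censoring (only for samples with an abnormality day).
    """
    required = {"sample_id", "followup_day"}
    if not required <= set(clinical.columns):
        raise ValueError(f"clinical table needs columns {sorted(required)}")
    rows = []
    for rec in clinical.itertuples():
        fu = float(rec.followup_day)
        prog = getattr(rec, "progression_day", np.nan)
        death = getattr(rec, "death_day", np.nan)
        abn = getattr(rec, "abnormality_day", np.nan)
        group = getattr(rec, "group", "")

        pfs_candidates = [t for t in (prog, death) if not pd.isna(t)]
        if pfs_candidates:
            pfs_time, pfs_event = min(pfs_candidates), 1
        else:
            pfs_time, pfs_event = fu, 0
        os_time, os_event = (float(death), 1) if not pd.isna(death) else (fu, 0)
        for endpoint, time, event in (
            ("PFS", pfs_time, pfs_event),
            ("OS", os_time, os_event),
        ):
            if time < 0:
                raise ValueError(
                    f"negative {endpoint} duration for sample {rec.sample_id}"
                )
            rows.append(
                dict(sample_id=rec.sample_id, endpoint=endpoint,
                     time_days=float(time), event=event, group=group)
            )
        if not pd.isna(abn):
            ars_time = os_time - float(abn)
            if ars_time < 0:
                raise ValueError(
                    f"negative ARS duration for sample {rec.sample_id}"
                )
            rows.append(
                dict(sample_id=rec.sample_id, endpoint="ARS",
                     time_days=float(ars_time), event=os_event, group=group)
            )
    return pd.DataFrame(rows)


def km_estimate(
    times: Sequence[float], events: Sequence[int]
) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    At tied times, events are processed before censorings (both leave the
    risk set after the step). Without censoring the curve equals
    1 minus the empirical CDF.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("no survival records")
    if (t < 0).any():
        raise ValueError("times must be non-negative")

    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])

    surv_vals, at_risk_vals, event_counts = [], [], []
    s = 1.0
    for et in event_times:
        n_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        surv_vals.append(s)
        at_risk_vals.append(n_risk)
        event_counts.append(d)

    surv = np.asarray(surv_vals)
    median = None
    crossed = np.nonzero(surv <= 0.5)[0]
    if crossed.size:
        median = float(event_times[crossed[0]])
    return KMEstimate(
        times=event_times,
        survival=surv,
        at_risk=np.asarray(at_risk_vals),
        events=np.asarray(event_counts),
        median=median,
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> LogRankResult:
    """Two-group log-rank test (1 df).

    At each distinct event time the observed events in group A are
    compared with the hypergeometric expectation given the pooled risk
    set; the squared standardized sum of O - E is chi-square(1) under the
    null of equal hazards.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")

    all_times = np.concatenate([ta, tb])
    all_events = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones_like(ta), np.zeros_like(tb)]).astype(bool)
    event_times = np.unique(all_times[all_events == 1])

    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = all_times >= et
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = (all_times == et) & (all_events == 1)
        d = int(dying.sum())
        d_a = int((dying & in_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0.0:
        return LogRankResult(statistic=0.0, p_value=1.0)
    chi2 = o_minus_e**2 / var
    return LogRankResult(statistic=float(chi2), p_value=float(stats.chi2.sf(chi2, 1)))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x against y with tie-averaged ranks."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[: x.size].sum()
    return r_x - x.size * (x.size + 1) / 2.0


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie-averaged ranks.

    Exact p by enumerating all label assignments when min(n) <= 8 and
    n_x + n_y <= 16 (two-sided via distance of U from its null mean,
    which is tie-safe); otherwise the normal approximation with tie
    correction (no continuity correction).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = xa.size, ya.size
    u_obs = _u_statistic(xa, ya)
    mu = nx * ny / 2.0

    if min(nx, ny) <= 8 and nx + ny <= 16:
        pooled = np.concatenate([xa, ya])
        dev_obs = abs(u_obs - mu)
        total = 0
        extreme = 0
        for idx in itertools.combinations(range(nx + ny), nx):
            total += 1
            u = _u_statistic(pooled[list(idx)], np.delete(pooled, list(idx)))
            if abs(u - mu) >= dev_obs - 1e-12:
                extreme += 1
        return float(u_obs), extreme / total

    pooled = np.concatenate([xa, ya])
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
    if sigma2 == 0.0:
        return float(u_obs), 1.0
    z = (u_obs - mu) / math.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(u_obs), float(min(p, 1.0))
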