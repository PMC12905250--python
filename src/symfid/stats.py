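"""Fidelity statistics implemented in-house.

Spearman rank correlation with an exact permutation p-value at small n,
the continuity-corrected Wilson score interval for a binomial proportion
(the interval R's ``prop.test`` reports), and the Kaplan-Meier
product-limit survival estimator.

These are the only inferential statistics the pipeline computes itself;
the correlations in this system involve 6-7 species, where the exact
permutation null is preferable to the t approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_N_MAX = 8  # full n! enumeration up to here (8! = 40,320)


@dataclass(frozen=True)
class SpearmanResult:
    r: float
    p_two_sided: float
    n: int
    method: str  # "exact_permutation" | "t_approximation"


def _rank_correlation(rx: np.ndarray, ry: np.ndarray) -> float:
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x, y, exact_n_max: int = EXACT_N_MAX) -> SpearmanResult:
    """Spearman correlation with two-sided significance.

    Ties receive average ranks.  For n <= ``exact_n_max`` the p-value is
    exact: all n! orderings of one rank vector are enumerated and the
    fraction with |r| at least the observed |r| reported.  For larger n the
    usual t approximation with n - 2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = _rank_correlation(rx, ry)
    if n <= exact_n_max:
        tol = 1e-12
        target = abs(r) - tol
        hits = 0
        total = math.factorial(n)
        for perm in itertools.permutations(ry):
            if abs(_rank_correlation(rx, np.array(perm))) >= target:
                hits += 1
        return SpearmanResult(r=r, p_two_sided=hits / total, n=n, method="exact_permutation")
    t = r * math.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return SpearmanResult(r=r, p_two_sided=min(p, 1.0), n=n, method="t_approximation")


@dataclass(frozen=True)
class ProportionCi:
    k: int
    n: int
    estimate: float
    lo: float
    hi: float
    conf: float = 0.95


def wilson_ci(k: int, n: int, conf: float = 0.95, continuity: bool = True) -> ProportionCi:
    """Wilson score interval for a binomial proportion.

    With ``continuity=True`` (default) this is the continuity-corrected
    interval, numerically identical to the one ``prop.test`` prints: the
    Wilson formula is evaluated at k/n shifted by the Yates correction
    0.5/n, with the correction capped at |k - n/2|/n so it vanishes at an
    exactly balanced count.  Bounds are clipped to [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    p = k / n
    z = sps.norm.ppf(1.0 - (1.0 - conf) / 2.0)
    z2 = z * z

    def wilson(pc: float, sign: float) -> float:
        centre = pc + z2 / (2 * n)
        half = z * math.sqrt(pc * (1 - pc) / n + z2 / (4 * n * n))
        return (centre + sign * half) / (1 + z2 / n)

    yates = min(0.5, abs(k - n * 0.5)) if continuity else 0.0
    pl = p - yates / n
    ph = p + yates / n
    lo = 0.0 if pl <= 0 else wilson(pl, -1.0)
    hi = 1.0 if ph >= 1 else wilson(ph, +1.0)
    if k == 0:
        lo = 0.0
    if k == n:
        hi = 1.0
    return ProportionCi(k=k, n=n, estimate=p, lo=max(0.0, lo), hi=min(1.0, hi), conf=conf)


@dataclass
class KmCurve:
    """Kaplan-Meier product-limit curve.

    ``event_times`` are the distinct death times in increasing order;
    ``survival[i]`` is S(t) just after ``event_times[i]``; ``n_at_risk[i]``
    the risk-set size just before it.
    """

    event_times: list[float]
    survival: list[float]
    n_at_risk: list[int]

    def survival_at(self, t: float) -> float:
        s = 1.0
        for et, sv in zip(self.event_times, self.survival):
            if et <= t:
                s = sv
            else:
                break
        return s


def kaplan_meier(records: pd.DataFrame) -> KmCurve:
    """Product-limit estimator from a table with columns day, event.

    event = 1 marks a death, 0 right-censoring.  At tied times deaths are
    processed before censorings, so individuals censored at a death time
    still count in that time's risk set.
    """
    if records.empty:
        raise ValueError("empty survival table")
    days = np.asarray(records["day"], dtype=float)
    events = np.asarray(records["event"], dtype=int)
    if (days < 0).any():
        raise ValueError("days must be >= 0")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("event must be 0 or 1")
    order = np.lexsort((1 - events, days))  # by time, deaths before censorings
    days, events = days[order], events[order]
    at_risk = len(days)
    s = 1.0
    event_times, survival, n_at_risk = [], [], []
    i = 0
    while i < len(days):
        t = days[i]
        deaths = 0
        censored = 0
        while i < len(days) and days[i] == t:
            if events[i] == 1:
                deaths += 1
            else:
                censored += 1
            i += 1
        if deaths > 0:
            event_times.append(float(t))
            n_at_risk.append(at_risk)
            s *= 1.0 - deaths / at_risk
            survival.append(s)
        at_risk -= deaths + censored
    return KmCurve(event_times=event_times, survival=survival, n_at_risk=n_at_risk)
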