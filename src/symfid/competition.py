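"""Within-host competition: selection coefficient and Malthusian rate.

Dual-infection qPCR time series give copy numbers of a native and a
non-native symbiont strain in the same hosts.  Two estimators of the
non-native strain's relative fitness:

* the slope of ln(non-native / native) against time (ordinary least
  squares on per-day replicate means); the slope is ln(omega), where omega
  is the per-day multiplicative selection coefficient, so a negative slope
  means a non-native disadvantage;

* the Malthusian selection rate r: for each consecutive pair of sampling
  days, the difference in the strains' realised per-day exponential growth
  rates over that interval, averaged across intervals.

On noiseless exponential trajectories both estimators equal the difference
in Malthusian parameters exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

REQUIRED_COLUMNS = ("replicate", "day", "strain", "copies")
STRAINS = ("native", "non_native")


class ZeroCopiesError(ValueError):
    """A zero copy number makes the log ratio undefined under policy 'error'."""


def correct_background(copies: float, ntc_mean: float) -> float:
    """Subtract the mean no-template-control signal, clipping at zero."""
    if copies < 0 or ntc_mean < 0:
        raise ValueError("copy numbers must be non-negative")
    return max(copies - ntc_mean, 0.0)


def _validate(table: pd.DataFrame, max_day: float | None) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"abundance table lacks columns: {missing}")
    df = table.copy()
    if max_day is not None:
        df = df[df["day"] <= max_day]
    if df.empty:
        raise ValueError("no observations in the fitting window")
    unknown = set(df["strain"]) - set(STRAINS)
    if unknown:
        raise ValueError(f"unknown strain labels: {sorted(unknown)}")
    dup = df.duplicated(subset=["replicate", "day", "strain"])
    if dup.any():
        raise ValueError("duplicate (replicate, day, strain) observations")
    return df


def _wide(df: pd.DataFrame) -> pd.DataFrame:
    wide = df.pivot_table(
        index=["replicate", "day"], columns="strain", values="copies", aggfunc="first"
    )
    if wide.isna().any().any() or wide.shape[1] < 2:
        raise ValueError("each (replicate, day) needs both native and non_native")
    return wide


def log_ratio_series(
    table: pd.DataFrame,
    zero_policy: str = "error",
    pseudo_count: float = 1.0,
    ntc_mean: float = 0.0,
    max_day: float | None = None,
) -> pd.DataFrame:
    """Per-day mean of ln(non-native / native) across replicates.

    ``zero_policy`` is ``"error"`` (raise on zero copies) or
    ``"pseudo_count"`` (add ``pseudo_count`` to every copy number before
    taking the ratio).  An optional NTC background is subtracted first.
    Returns a frame with columns ``day`` and ``ln_ratio``.
    """
    df = _validate(table, max_day)
    if ntc_mean > 0:
        df = df.assign(copies=df["copies"].map(lambda c: correct_background(c, ntc_mean)))
    wide = _wide(df)
    nn, nat = wide["non_native"].to_numpy(float), wide["native"].to_numpy(float)
    if zero_policy == "error":
        if (nn <= 0).any() or (nat <= 0).any():
            raise ZeroCopiesError(
                "zero copy numbers; use zero_policy='pseudo_count' to proceed"
            )
    elif zero_policy == "pseudo_count":
        nn, nat = nn + pseudo_count, nat + pseudo_count
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    ratios = pd.DataFrame(
        {"day": wide.index.get_level_values("day"), "ln_ratio": np.log(nn / nat)}
    )
    out = ratios.groupby("day", as_index=False)["ln_ratio"].mean()
    return out.sort_values("day").reset_index(drop=True)


@dataclass(frozen=True)
class SelectionEstimate:
    slope_ln_omega: float
    omega: float
    intercept: float
    n_timepoints: int
    r_malthusian: float | None = None


def fit_selection_coefficient(series: pd.DataFrame) -> SelectionEstimate:
    """OLS of the mean log abundance ratio on day.

    The headline selection statistic is the slope, ln(omega); omega itself
    is exp(slope) and the intercept estimates the log of the initial ratio.
    """
    days = np.asarray(series["day"], dtype=float)
    y = np.asarray(series["ln_ratio"], dtype=float)
    if len(np.unique(days)) < 2:
        raise ValueError("need at least 2 distinct days to fit a slope")
    fit = sps.linregress(days, y)
    slope = float(fit.slope)
    return SelectionEstimate(
        slope_ln_omega=slope,
        omega=math.exp(slope),
        intercept=float(fit.intercept),
        n_timepoints=len(days),
    )


def selection_rate_malthusian(
    table: pd.DataFrame,
    zero_policy: str = "error",
    pseudo_count: float = 1.0,
    ntc_mean: float = 0.0,
    max_day: float | None = None,
) -> float:
    """Mean difference in per-day Malthusian parameters across intervals.

    Replicate-mean densities are formed per day and strain; for each
    consecutive day pair (t_prev, t) the interval selection rate is
    [ln(nn_t / nn_prev) - ln(nat_t / nat_prev)] / (t - t_prev); r is the
    mean over intervals.  The denominator is the elapsed interval: dividing
    by absolute day t would double-count time for later intervals and
    cannot return a constant rate even on exact exponentials.
    """
    df = _validate(table, max_day)
    if ntc_mean > 0:
        df = df.assign(copies=df["copies"].map(lambda c: correct_background(c, ntc_mean)))
    means = df.groupby(["day", "strain"])["copies"].mean().unstack("strain")
    if means.isna().any().any():
        raise ValueError("each day needs observations of both strains")
    if len(means) < 2:
        raise ValueError("need at least 2 timepoints")
    nn, nat = means["non_native"].to_numpy(float), means["native"].to_numpy(float)
    if zero_policy == "error":
        if (nn <= 0).any() or (nat <= 0).any():
            raise ZeroCopiesError(
                "zero mean densities; use zero_policy='pseudo_count' to proceed"
            )
    elif zero_policy == "pseudo_count":
        nn, nat = nn + pseudo_count, nat + pseudo_count
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    days = means.index.to_numpy(float)
    dt = np.diff(days)
    if (dt <= 0).any():
        raise ValueError("days must be strictly increasing")
    rates = (np.diff(np.log(nn)) - np.diff(np.log(nat))) / dt
    return float(rates.mean())


def estimate_selection(
    table: pd.DataFrame,
    zero_policy: str = "error",
    pseudo_count: float = 1.0,
    ntc_mean: float = 0.0,
    max_day: float | None = None,
) -> SelectionEstimate:
    """Both estimators on one abundance table (slope/omega plus r)."""
    series = log_ratio_series(table, zero_policy, pseudo_count, ntc_mean, max_day)
    base = fit_selection_coefficient(series)
    r = selection_rate_malthusian(table, zero_policy, pseudo_count, ntc_mean, max_day)
    return SelectionEstimate(
        slope_ln_omega=base.slope_ln_omega,
        omega=base.omega,
        intercept=base.intercept,
        n_timepoints=base.n_timepoints,
        r_malthusian=r,
    )
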