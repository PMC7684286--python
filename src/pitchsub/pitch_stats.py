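"""Behavioral pitch statistics for the light-off substitution paradigm.

Implements the d' effect-size machinery used throughout the analysis:

* daily summaries (mean, sample variance, CV, light-off contingency),
* the normalized pitch change between two days,
  ``d'_{i,j} = (p̄_j − p̄_i) / sqrt((σ_i² + σ_j²) / 2)``,
* average daily changes during reinforcement (d̄'_LO) and over the last four
  baseline days (d̄'_B),
* direction δ = sign(d'_{b,l}) and aligned magnitude ā' = δ·⟨d'_{i−1,i}⟩,
* the adaptive threshold controller (morning reset to yesterday's median),
* the paradigm start/end criteria (|d'_{i−4,i}| < 0.5; 2.5 d' shift),
* within-syllable pitch-trace d' curves at 1-ms resolution,
* the binomial same-direction probability across birds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Minimum renditions per day for a bird-day to enter cross-bird comparisons.
MIN_RENDITIONS_PER_DAY = 100


@dataclass
class DailySummary:
    bird_id: str
    day: int
    mean: float
    variance: float
    count: int
    cv: float
    contingency: float | None = None
    threshold: float | None = None


class ThresholdController:
    """Closed-loop light-off threshold.

    Every morning the threshold resets to the previous day's median pitch
    (computed over all, uncurated renditions), so the neutral expectation of
    the light-off contingency is 50%.  ``side='high'`` triggers on pitch
    strictly above the threshold, ``'low'`` strictly below; equality never
    triggers.  ``side='random'`` ignores pitch and flips a fair coin per
    rendition.  If a day produced no data (e.g. a recording crash) and
    ``carry_forward`` is set, the previous threshold is reused.
    """

    def __init__(
        self,
        side: str,
        current_threshold: float | None = None,
        carry_forward: bool = True,
    ):
        if side not in ("high", "low", "random"):
            raise ValueError(f"unknown side {side!r}")
        self.side = side
        self.current_threshold = current_threshold
        self.carry_forward = carry_forward

    def update(self, yesterday_pitches) -> float | None:
        """Morning reset; returns the new threshold (None for random side)."""
        if self.side == "random":
            return None
        if yesterday_pitches is None or len(yesterday_pitches) == 0:
            if self.carry_forward and self.current_threshold is not None:
                return self.current_threshold
            raise ValueError("no pitches from yesterday and no carried threshold")
        self.current_threshold = float(np.median(yesterday_pitches))
        return self.current_threshold

    def assign(self, pitches, rng: np.random.Generator | None = None) -> np.ndarray:
        """Per-rendition stimulus flags for one day's pitches."""
        pitches = np.asarray(pitches, dtype=float)
        if self.side == "random":
            if rng is None:
                raise ValueError("random side needs an rng")
            return rng.random(pitches.size) < 0.5
        if self.current_threshold is None:
            raise ValueError("threshold not set; call update() first")
        if self.side == "high":
            return pitches > self.current_threshold
        return pitches < self.current_threshold


def update_threshold(controller: ThresholdController, yesterday_pitches) -> float:
    """Functional form of the morning threshold reset."""
    return controller.update(yesterday_pitches)


def daily_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Per bird-day mean, sample variance, count, CV (percent) and light-off
    contingency.  CV_i = 100 σ_i / p̄_i."""
    if len(table) == 0:
        raise ValueError("empty rendition table")
    grouped = table.groupby(["bird_id", "day"], sort=True)
    out = grouped.agg(
        mean=("pitch_hz", "mean"),
        variance=("pitch_hz", lambda x: x.var(ddof=1) if len(x) > 1 else 0.0),
        count=("pitch_hz", "size"),
        contingency=("stimulus", "mean"),
    ).reset_index()
    out["cv"] = 100.0 * np.sqrt(out["variance"]) / out["mean"]
    return out[["bird_id", "day", "mean", "variance", "count", "cv", "contingency"]]


def dprime(mean_i, var_i, mean_j, var_j) -> float:
    """Normalized pitch change between day i and day j (dimensionless).

    Antisymmetric in the day order and invariant under a common rescaling of
    all pitches.
    """
    denom = 0.5 * (var_i + var_j)
    if denom <= 0:
        raise ValueError("both variances are zero: d' undefined")
    return float((mean_j - mean_i) / math.sqrt(denom))


def dprime_between(summaries: pd.DataFrame, day_i: int, day_j: int) -> float:
    """d' between two summarized days of a single bird's summary table."""
    rows = summaries.set_index("day")
    si, sj = rows.loc[day_i], rows.loc[day_j]
    return dprime(si["mean"], si["variance"], sj["mean"], sj["variance"])


def daily_changes(summaries: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-day d' values, one row per (bird, day pair i-1 -> i)."""
    records = []
    for bird, sub in summaries.groupby("bird_id", sort=True):
        sub = sub.sort_values("day")
        days = sub["day"].to_numpy()
        means = sub["mean"].to_numpy()
        variances = sub["variance"].to_numpy()
        for k in range(1, len(days)):
            records.append(
                dict(
                    bird_id=bird, day=int(days[k]), prev_day=int(days[k - 1]),
                    dprime=dprime(means[k - 1], variances[k - 1], means[k], variances[k]),
                )
            )
    return pd.DataFrame.from_records(records)


def average_daily_change(
    summaries: pd.DataFrame, days: "list[int] | np.ndarray"
) -> float:
    """Mean consecutive-day d' over a window of days.

    ``days`` lists the days *i* whose change d'_{i−1,i} enters the average —
    all reinforcement days starting from the second for d̄'_LO, or the last
    four baseline days for d̄'_B.
    """
    days = sorted(int(d) for d in days)
    if len(days) < 1:
        raise ValueError("window must contain at least one day pair")
    changes = daily_changes(summaries)
    sel = changes[changes["day"].isin(days)]
    if len(sel) < len(days):
        raise ValueError("window contains days without a summarized predecessor")
    return float(sel["dprime"].mean())


def direction_and_magnitude(
    summaries: pd.DataFrame, baseline_last_day: int, stimulus_last_day: int
) -> tuple[int, float]:
    """Global direction δ = sign(d'_{b,l}) and aligned magnitude
    ā' = δ · ⟨d'_{i−1,i}⟩ over the reinforcement days."""
    if baseline_last_day >= stimulus_last_day:
        raise ValueError("baseline day must precede the last stimulus day")
    overall = dprime_between(summaries, baseline_last_day, stimulus_last_day)
    if overall == 0:
        logger.warning("d'_{b,l} is exactly 0; defining direction as +1")
        delta = 1
    else:
        delta = int(np.sign(overall))
    stim_days = [
        int(d)
        for d in summaries["day"].unique()
        if baseline_last_day + 1 < d <= stimulus_last_day
    ]
    mean_change = average_daily_change(summaries, stim_days)
    return delta, float(delta * mean_change)


def paradigm_criteria(
    summaries: pd.DataFrame,
    phase: str,
    baseline_end: int | None = None,
) -> str:
    """Start/end decision at the last summarized day *i*.

    ``phase='baseline'``: returns ``start_ok`` when the last five baseline
    days are stable (|d'_{i−4,i}| < 0.5, strict), else ``continue``.
    ``phase='stimulus'``: returns ``end_shift`` once the shift relative to
    the last baseline day exceeds 2.5 d', ``end_stable`` when the last five
    days are stable again, else ``continue``.
    """
    sub = summaries.sort_values("day")
    days = sub["day"].to_numpy()
    if len(days) < 5:
        raise ValueError("need at least 5 summarized days")
    i = int(days[-1])
    stable = abs(dprime_between(sub, i - 4, i)) < 0.5
    if phase == "baseline":
        return "start_ok" if stable else "continue"
    if phase != "stimulus":
        raise ValueError(f"unknown phase {phase!r}")
    if baseline_end is None:
        raise ValueError("stimulus phase needs the last baseline day")
    if abs(dprime_between(sub, baseline_end, i)) > 2.5:
        return "end_shift"
    return "end_stable" if stable else "continue"


def pitch_trace_dprime(
    traces_day_a: np.ndarray,
    traces_day_b: np.ndarray,
    flip: bool = False,
) -> np.ndarray:
    """Per-time-point d' between two days' within-syllable pitch traces.

    ``traces_day_*`` are (renditions x time) arrays on a common 1-ms grid
    aligned to the light-off window onset.  ``flip`` negates the curve, used
    for birds that decreased pitch so curves average constructively.
    """
    a = np.asarray(traces_day_a, dtype=float)
    b = np.asarray(traces_day_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("trace sets must be 2-D with a shared time grid")
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    var_a, var_b = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    denom = np.sqrt(0.5 * (var_a + var_b))
    curve = np.divide(
        mean_b - mean_a, denom, out=np.zeros_like(denom), where=denom > 0
    )
    return -curve if flip else curve


def binomial_direction_prob(k: int, n: int, tail: str = "greater") -> float:
    """Probability that k of n birds drift in the same direction by chance.

    Under the null each bird drifts up or down with probability 1/2.  The
    tail convention is explicit because reported one-number claims depend on
    it: ``greater`` = P(X >= k), ``less`` = P(X <= k), ``two-sided`` =
    P(X >= k) + P(X <= n − k) (equal-tailed at p = 1/2).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    dist = stats.binom(n, 0.5)
    if tail == "greater":
        return float(dist.sf(k - 1))
    if tail == "less":
        return float(dist.cdf(k))
    if tail == "two-sided":
        return float(min(1.0, dist.sf(k - 1) + dist.cdf(n - k)))
    raise ValueError(f"unknown tail {tail!r}")


def per_day_contingency(table: pd.DataFrame, stimulus_days_only: bool = True) -> pd.DataFrame:
    """Mean per-day stimulus fraction per bird (reinforcement days only by
    default)."""
    t = table
    if stimulus_days_only:
        stim_days = t[t["stimulus"]].groupby("bird_id")["day"].min()
        keep = [
            (row.bird_id in stim_days.index) and (row.day >= stim_days[row.bird_id])
            for row in t.itertuples()
        ]
        t = t[np.array(keep, dtype=bool)]
    per_day = t.groupby(["bird_id", "day"])["stimulus"].mean().reset_index()
    return per_day.groupby("bird_id")["stimulus"].mean().rename("contingency").reset_index()
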