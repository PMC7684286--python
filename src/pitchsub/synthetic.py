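"""Synthetic per-rendition pitch tables for all five cohorts.

Each simulated bird sings a Gaussian-distributed pitch every rendition.  The
daily mean carries a slow drift plus, on reinforcement days, a response of a
stated d'/day effect size toward (or away from) the stimulus zone.  The
light-off stimulus is assigned per rendition by a closed-loop threshold
controller that resets every morning to the previous day's median pitch —
the same rule the behavioral paradigm uses — except for subs-rand birds,
where the stimulus is a fair coin regardless of pitch.

Cohorts: subs (deaf, substituted), unsubs (deaf control), LO (hearing,
light-off), noLO (hearing control), subs_rand (deaf, random 50% light-off).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pitch_stats import ThresholdController

GROUPS = ("subs", "unsubs", "LO", "noLO", "subs_rand")
CONTROL_GROUPS = ("unsubs", "noLO")

#: Canonical column order of a rendition table.
COLUMNS = (
    "bird_id", "group", "target_side", "day", "rendition", "pitch_hz", "stimulus"
)


@dataclass(frozen=True)
class BirdParams:
    """Generative parameters of one synthetic bird.

    ``response_per_day`` is signed in d' units per day: positive values move
    the daily mean pitch *toward* the stimulus zone (raising the light-off
    contingency), negative values move it away.  ``drift_per_day`` is an
    unconditional drift in the same units.  ``singing_trend`` multiplies the
    expected rendition count by ``(1 + trend)`` per day.
    """

    bird_id: str
    group: str
    target_side: str = "none"  # high / low / none
    baseline_mean_pitch: float = 700.0
    baseline_sd: float = 7.0  # CV ~ 1% of the mean
    drift_per_day: float = 0.0
    response_per_day: float = 0.0
    renditions_per_day_mean: float = 200.0
    singing_trend: float = 0.0
    n_baseline_days: int = 5
    n_stimulus_days: int = 11
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.target_side not in ("high", "low", "none"):
            raise ValueError(f"unknown target_side {self.target_side!r}")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        if self.renditions_per_day_mean < 1:
            raise ValueError("renditions_per_day_mean must be >= 1")
        if self.n_baseline_days < 5:
            raise ValueError("need >= 5 baseline days (start criterion)")
        if self.group in CONTROL_GROUPS and self.target_side != "none":
            raise ValueError("control birds have no target side")
        if self.group in ("subs", "LO") and self.target_side == "none":
            raise ValueError(f"{self.group} birds need a target side")


def _zone_sign(target_side: str) -> float:
    return {"high": 1.0, "low": -1.0, "none": 0.0}[target_side]


def simulate_bird(
    params: BirdParams, controller: ThresholdController | None = None
) -> pd.DataFrame:
    """Simulate one bird's rendition table, closing the loop with the
    threshold controller on stimulus days."""
    side = "random" if params.group == "subs_rand" else params.target_side
    if controller is None:
        controller = ThresholdController(side=side if side != "none" else "high")
    elif params.group != "subs_rand" and side not in ("none", controller.side):
        raise ValueError(
            f"controller side {controller.side!r} conflicts with bird target "
            f"side {side!r}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(params.seed if params.seed is not None else 0)
    )
    stimulated = params.group in ("subs", "LO", "subs_rand")
    sign = _zone_sign(params.target_side)
    n_days = params.n_baseline_days + params.n_stimulus_days

    records = []
    prev_pitches: np.ndarray | None = None
    for day in range(1, n_days + 1):
        in_stim = day > params.n_baseline_days
        mean = (
            params.baseline_mean_pitch
            + params.drift_per_day * params.baseline_sd * (day - 1)
        )
        if in_stim and stimulated:
            days_in = day - params.n_baseline_days
            mean += sign * params.response_per_day * params.baseline_sd * days_in
        expected = params.renditions_per_day_mean * (1 + params.singing_trend) ** (
            day - 1
        )
        count = max(1, int(rng.poisson(max(expected, 0.0))))
        pitches = rng.normal(mean, params.baseline_sd, size=count)
        pitches = np.maximum(pitches, 1e-6)  # pitch is physically positive

        if in_stim and stimulated:
            controller.update(prev_pitches)
            stimulus = controller.assign(pitches, rng)
        else:
            stimulus = np.zeros(count, dtype=bool)
        for k in range(count):
            records.append(
                (
                    params.bird_id, params.group, params.target_side,
                    day, k + 1, pitches[k], bool(stimulus[k]),
                )
            )
        prev_pitches = pitches
    return pd.DataFrame.from_records(records, columns=list(COLUMNS))


def simulate_cohort(design: Sequence[BirdParams], seed: int = 0) -> pd.DataFrame:
    """Concatenate per-bird simulations with reproducible per-bird seeds.

    Per-bird seeds are derived with ``SeedSequence([seed, index])``, so
    appending a bird to the design never perturbs the birds before it.
    Birds carrying an explicit ``seed`` keep it.
    """
    ids = [p.bird_id for p in design]
    if len(set(ids)) != len(ids):
        dupes = sorted({b for b in ids if ids.count(b) > 1})
        raise ValueError(f"duplicate bird_id(s): {dupes}")
    tables = []
    for index, params in enumerate(design):
        if params.seed is None:
            child = int(
                np.random.SeedSequence([int(seed), index]).generate_state(1)[0]
                % (2**31)
            )
            params = replace(params, seed=child)
        tables.append(simulate_bird(params))
    if not tables:
        return pd.DataFrame(columns=list(COLUMNS))
    return pd.concat(tables, ignore_index=True)


# Study-condition defaults, per cohort.  Effect sizes are the reported
# fixed effects (0.19 d'/day toward the zone in deaf substituted birds,
# 0.08 d'/day away from it in hearing light-off birds); singing trends are
# the per-day multiplicative rates matching the reported relative changes
# over an 11-day reinforcement period (+25%, -34%, -9%, +8%).
_GROUP_DEFAULTS = {
    "subs": dict(response_per_day=0.19, singing_trend=0.0205),
    "unsubs": dict(response_per_day=0.0, singing_trend=-0.0371),
    "LO": dict(response_per_day=-0.08, singing_trend=-0.0085),
    "noLO": dict(response_per_day=0.0, singing_trend=0.0070),
    "subs_rand": dict(response_per_day=0.0, singing_trend=-0.0550),
}


def default_cohort(
    n_subs: int = 10,
    n_unsubs: int = 12,
    n_lo: int = 12,
    n_nolo: int = 12,
    n_subs_rand: int = 2,
    **overrides,
) -> list[BirdParams]:
    """Study-sized design: deaf substituted/control, hearing LO/control and
    subs-rand birds, target sides alternating high/low within each treated
    group."""

    def birds(group: str, n: int, sides: Iterable[str]) -> list[BirdParams]:
        out = []
        for k, side in zip(range(n), sides):
            kwargs = dict(_GROUP_DEFAULTS[group])
            kwargs.update(overrides)
            out.append(
                BirdParams(
                    bird_id=f"{group}{k + 1:02d}", group=group, target_side=side,
                    **kwargs,
                )
            )
        return out

    import itertools

    alternating = itertools.cycle(("high", "low"))
    none = itertools.repeat("none")
    design = []
    design += birds("subs", n_subs, alternating)
    design += birds("unsubs", n_unsubs, none)
    design += birds("LO", n_lo, itertools.cycle(("high", "low")))
    design += birds("noLO", n_nolo, none)
    design += birds("subs_rand", n_subs_rand, itertools.cycle(("high", "low")))
    return design
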