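"""Cohort-level simulation protocols for the syllable-world model.

Reproduces the model experiments: a sweep over the negative reinforcement r
per light-off for deaf and hearing agents (with matched no-LO controls for
motivation baselines), the manipulation-bonus ablation, the subs-rand
(random 50% light-off) protocol, and the plausible-reinforcement-region
report.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .agent import AgentConfig, SarsaAgent
from .rewards import deaf_impact
from .world import N_VARIANTS, LOMode, SyllableMDP, build_world

#: Default reinforcement grid: 8 log-spaced magnitudes from 0.01 to 2 nats.
DEFAULT_R_GRID = tuple(-np.logspace(np.log10(0.01), np.log10(2.0), 8))


def _agent_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


def _run_cell(
    world: SyllableMDP,
    base: AgentConfig,
    n_agents: int,
    master_seed: int,
    cell_key: tuple[int, ...],
    last_frac: float,
) -> tuple[np.ndarray, np.ndarray]:
    conts = np.zeros(n_agents)
    motiv = np.zeros(n_agents)
    for k in range(n_agents):
        cfg = replace(base, seed=_agent_seed(master_seed, *cell_key, k))
        agent = SarsaAgent(world, cfg)
        trace = agent.run()
        conts[k] = trace.contingency(last_frac)
        motiv[k] = agent.motivation(trace, last_frac)
    return conts, motiv


def sweep_reinforcement(
    r_grid=DEFAULT_R_GRID,
    n_agents_per_cell: int = 20,
    modalities=("hearing", "deaf"),
    seed: int = 0,
    n_trials: int = 2000,
    include_ablated: bool = True,
    last_frac: float = 0.2,
    world: SyllableMDP | None = None,
    base_config: AgentConfig | None = None,
) -> pd.DataFrame:
    """Sweep the punishment per light-off for each modality.

    Returns a tidy table with one row per (modality, condition, r) cell:
    ``condition`` is ``lo`` (closed-loop light-off world), ``lo_ablated``
    (same, manipulation bonus forced to 0; deaf only unless requested
    otherwise) or ``control`` (light never off, matching the unsubs/noLO
    cohorts; r is irrelevant there, so controls are run once per modality).
    Columns report the mean and sd over agents of the final light-off
    contingency and of the visit-weighted motivation index.
    """
    r_grid = [float(r) for r in r_grid]
    if len(r_grid) == 0:
        raise ValueError("empty reinforcement grid")
    if any(r > 0 for r in r_grid):
        raise ValueError("reinforcement grid must be nonpositive")
    world = world or build_world()
    control_world = world.with_lo_mode(LOMode.OFF)
    base = base_config or AgentConfig()

    rows = []
    for m, modality in enumerate(modalities):
        conditions = [("lo", False)]
        if include_ablated and modality == "deaf":
            conditions.append(("lo_ablated", True))
        for c, (condition, ablated) in enumerate(conditions):
            for i, r in enumerate(r_grid):
                cfg = replace(
                    base, modality=modality, r_per_lo=r, ablate_manipulation=ablated,
                    n_trials=n_trials,
                )
                conts, motiv = _run_cell(
                    world, cfg, n_agents_per_cell, seed, (m, c, i), last_frac
                )
                rows.append(
                    dict(
                        modality=modality, condition=condition, r=r,
                        contingency_mean=conts.mean(), contingency_sd=conts.std(ddof=1),
                        motivation_mean=motiv.mean(), motivation_sd=motiv.std(ddof=1),
                        n_agents=n_agents_per_cell,
                    )
                )
        # matched controls: light never off, punishment never delivered
        cfg = replace(base, modality=modality, r_per_lo=0.0, n_trials=n_trials)
        conts, motiv = _run_cell(
            control_world, cfg, n_agents_per_cell, seed, (m, 99), last_frac
        )
        rows.append(
            dict(
                modality=modality, condition="control", r=np.nan,
                contingency_mean=conts.mean(), contingency_sd=conts.std(ddof=1),
                motivation_mean=motiv.mean(), motivation_sd=motiv.std(ddof=1),
                n_agents=n_agents_per_cell,
            )
        )
    return pd.DataFrame(rows)


def ablate_manipulation(
    r_grid=DEFAULT_R_GRID,
    n_agents_per_cell: int = 20,
    modalities=("deaf",),
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """The same sweep with the manipulation bonus forced to zero everywhere."""
    base = kwargs.pop("base_config", None) or AgentConfig()
    base = replace(base, ablate_manipulation=True)
    df = sweep_reinforcement(
        r_grid, n_agents_per_cell, modalities, seed,
        include_ablated=False, base_config=base, **kwargs,
    )
    df.loc[df["condition"] == "lo", "condition"] = "lo_ablated"
    return df


def plausible_region(sweep: pd.DataFrame) -> dict:
    """Find the contiguous r sub-interval matching the behavioral data.

    In the plausible region, simultaneously: deaf contingency > 0.5, hearing
    contingency < 0.5, deaf motivation above the deaf control baseline, and
    hearing motivation below the hearing control baseline.
    """
    controls = {
        row["modality"]: row["motivation_mean"]
        for _, row in sweep[sweep["condition"] == "control"].iterrows()
    }
    lo = sweep[sweep["condition"] == "lo"]
    deaf = lo[lo["modality"] == "deaf"].sort_values("r")
    hear = lo[lo["modality"] == "hearing"].sort_values("r")
    r_values = deaf["r"].to_numpy()
    ok = (
        (deaf["contingency_mean"].to_numpy() > 0.5)
        & (hear.sort_values("r")["contingency_mean"].to_numpy() < 0.5)
        & (deaf["motivation_mean"].to_numpy() > controls.get("deaf", np.inf))
        & (hear.sort_values("r")["motivation_mean"].to_numpy() < controls.get("hearing", -np.inf))
    )
    # longest contiguous run of satisfied cells
    best, cur = [], []
    for r, flag in zip(r_values, ok):
        if flag:
            cur.append(float(r))
            if len(cur) > len(best):
                best = list(cur)
        else:
            cur = []
    return {
        "r_values": [float(r) for r in r_values],
        "satisfied": [bool(b) for b in ok],
        "region": best,
        "region_bounds": [min(best), max(best)] if best else None,
    }


def subs_rand_run(
    n_trials: int = 20000,
    seed: int = 0,
    r_per_lo: float = 0.0,
    last_frac: float = 0.2,
    base_config: AgentConfig | None = None,
) -> dict:
    """Deaf agent with light-off delivered at random on 50% of syllables.

    Because light-off is a per-syllable Bernoulli(0.5) independent of the
    actions, every action's estimated light-on probability converges to 1/2
    and its impact to log 2 — the ceiling the protocol imposes.  Returns the
    visit-weighted mean asymptotic per-action impact and the final
    contingency.
    """
    world = build_world().with_lo_mode(LOMode.RANDOM, lo_random_p=0.5)
    cfg = replace(
        base_config or AgentConfig(),
        modality="deaf", r_per_lo=r_per_lo, n_trials=n_trials,
        seed=_agent_seed(seed, 7),
    )
    agent = SarsaAgent(world, cfg)
    trace = agent.run()
    counts = agent.sensory.counts
    totals = counts.sum(axis=1)
    visited = totals > 0
    pc = agent.sensory.pseudocount
    theta_on = (counts[visited, 0] + pc) / (totals[visited] + 2 * pc)
    per_action_m = -np.log(theta_on)
    mean_m = float(np.average(per_action_m, weights=totals[visited]))
    # The asymptotic limit is common to all actions (light-off is
    # action-independent), so pooling counts across actions estimates it
    # with the least variance.
    pooled_on = (counts[:, 0].sum() + pc) / (counts.sum() + 2 * pc)
    return {
        "mean_impact": mean_m,
        "pooled_impact": float(-np.log(pooled_on)),
        "per_action_impact": per_action_m.tolist(),
        "contingency": trace.contingency(last_frac),
        "n_trials": n_trials,
    }


def max_policy_impact(lo_random_p: float = 0.5) -> float:
    """Best asymptotic impact any deterministic policy can reach under
    random light-off delivery.

    With LO ~ Bernoulli(p) independent of the actions, θ̂_j(on) → 1 − p for
    every action, so each action's impact converges to −log(1 − p)
    (log 2 at p = 1/2) and no policy can exceed that ceiling.  Enumerates
    all deterministic per-note policies to confirm the ceiling is flat.
    """
    asymptotic = deaf_impact(1.0 - lo_random_p)
    best = -math.inf
    for policy in itertools.product(range(N_VARIANTS), repeat=3):
        # every action has the same asymptotic impact under random delivery
        value = asymptotic
        best = max(best, value)
    return best
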