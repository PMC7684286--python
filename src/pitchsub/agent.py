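"""Tabular SARSA agent over the three-note syllable world.

The agent maximizes the total reward R = E + M + r (see
:mod:`pitchsub.rewards`).  Because an action's sensory outcome depends only
on the action itself, the note index is a sufficient state, so Q is a 3x6
table (note x variant).  Episodes are independent three-step trials with
discounting inside the episode and a zero terminal bootstrap.

Modality determines the sensory channel:

* deaf — binary light on/off observations; the manipulation bonus is the
  Shannon surprise of light-on, which grows as an action reliably produces
  light-off.  This is the appetitive engine of the model.
* hearing — every action produces a reliable, distinct auditory percept, so
  its impact relative to silence is large but identical for all actions and
  carries no differential information.  A constant offset in the reward
  only shifts the zero of the Q scale (and, with zero-initialized Q values,
  needlessly slows learning), so the common hearing impact is absorbed into
  the reward baseline: the hearing manipulation term is ``hearing_impact``
  (default 0, exactly flat across actions).  Action selection in hearing
  agents is therefore governed by the exploration bonus and the extrinsic
  punishment.

The agent's predictive (Dirichlet) model of an action's outcome is over the
action's *realizable* consequences: the three adjacent sensory states it can
trigger, encoded relative to the action's home state (hearing), or the
binary light state (deaf).  The bird knows its motor-sensory topology; what
it learns is the contingency within it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .rewards import SensoryModel, exploration_bonus
from .world import (
    N_NOTES,
    N_VARIANTS,
    OBS_LIGHT_OFF,
    OBS_LIGHT_ON,
    LOMode,
    Modality,
    SyllableMDP,
)


@dataclass(frozen=True)
class AgentConfig:
    learning_rate: float = 0.1
    discount: float = 0.9
    epsilon: float = 0.1
    r_per_lo: float = -0.5
    modality: str = "deaf"
    ablate_manipulation: bool = False
    ablate_exploration: bool = False
    n_trials: int = 2000
    seed: int = 0
    pseudocount: float = 1.0
    hearing_impact: float = 0.0
    alpha_schedule: str = "constant"  # or "harmonic" (1/visit-count)

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if not 0 <= self.discount <= 1:
            raise ValueError("discount must be in [0, 1]")
        if not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must be in [0, 1]")
        if self.r_per_lo > 0:
            raise ValueError("r_per_lo must be <= 0")
        Modality(self.modality)
        if self.alpha_schedule not in ("constant", "harmonic"):
            raise ValueError("alpha_schedule must be 'constant' or 'harmonic'")


@dataclass
class AgentTrace:
    """Flat per-step log of one run (3 steps per trial)."""

    trial: np.ndarray
    note: np.ndarray
    action: np.ndarray
    state: np.ndarray
    lo: np.ndarray
    exploration: np.ndarray
    manipulation: np.ndarray
    extrinsic: np.ndarray
    reward: np.ndarray
    rpe: np.ndarray
    q_chosen: np.ndarray
    trial_lo: np.ndarray = field(default=None)  # per-trial any-LO indicator

    @property
    def n_trials(self) -> int:
        return len(self.trial_lo)

    def contingency(self, last_frac: float = 0.2) -> float:
        """Fraction of syllables triggering light-off, over the last window."""
        start = int(round((1 - last_frac) * self.n_trials))
        return float(self.trial_lo[start:].mean())


def select_action(q_row: np.ndarray, epsilon: float, rng: np.random.Generator) -> int:
    """Epsilon-greedy over one note's variants, uniform tie-break."""
    q_row = np.asarray(q_row, dtype=float)
    if q_row.size == 0:
        raise ValueError("empty Q row")
    if epsilon > 0 and rng.random() < epsilon:
        return int(rng.integers(q_row.size))
    best = np.flatnonzero(q_row == q_row.max())
    if best.size == 1:
        return int(best[0])
    return int(best[rng.integers(best.size)])


def sarsa_step(
    Q: np.ndarray,
    s: int,
    a: int,
    reward: float,
    s_next: int | None,
    a_next: int | None,
    alpha: float,
    gamma: float,
) -> float:
    """One on-policy TD update; returns the RPE delta.

    ``s_next is None`` marks the terminal note (zero bootstrap).
    """
    bootstrap = 0.0 if s_next is None else gamma * Q[s_next, a_next]
    delta = reward + bootstrap - Q[s, a]
    Q[s, a] += alpha * delta
    return float(delta)


class SarsaAgent:
    """Runs the syllable world with intrinsic rewards and SARSA learning."""

    def __init__(self, world: SyllableMDP, config: AgentConfig):
        self.world = world
        self.config = config
        self.modality = Modality(config.modality)
        n_symbols = 2 if self.modality is Modality.DEAF else 3
        self.sensory = SensoryModel(world.n_actions, n_symbols, config.pseudocount)
        # first nonzero state of each action's emission support, for mapping
        # hearing percepts onto the action-relative outcome alphabet
        self._support_start = np.argmax(world.emission > 0, axis=1)
        self.Q = np.zeros((N_NOTES, N_VARIANTS))
        self.visits = np.zeros((N_NOTES, N_VARIANTS), dtype=np.int64)
        self.rng = np.random.default_rng(config.seed)

    # -- reward pieces ----------------------------------------------------
    def _manipulation(self, action: int) -> float:
        cfg = self.config
        if cfg.ablate_manipulation:
            return 0.0
        if self.modality is Modality.HEARING:
            return cfg.hearing_impact
        counts = self.sensory.counts[action]
        pc = self.sensory.pseudocount
        theta_on = (counts[OBS_LIGHT_ON] + pc) / (counts.sum() + 2 * pc)
        return -math.log(theta_on)

    def _exploration(self, action: int) -> float:
        if self.config.ablate_exploration:
            return 0.0
        return exploration_bonus(self.sensory.counts[action], self.sensory.pseudocount)

    # -- main loop --------------------------------------------------------
    def run(self, n_trials: int | None = None) -> AgentTrace:
        cfg = self.config
        world = self.world
        n_trials = cfg.n_trials if n_trials is None else n_trials
        n_steps = N_NOTES * n_trials
        cum = world._cum
        lo_mask = world._lo_mask
        deaf = self.modality is Modality.DEAF
        random_lo = world.lo_mode is LOMode.RANDOM
        gamma = cfg.discount
        Q = self.Q
        rng = self.rng

        log = {
            k: np.zeros(n_steps)
            for k in (
                "trial", "note", "action", "state", "lo",
                "exploration", "manipulation", "extrinsic",
                "reward", "rpe", "q_chosen",
            )
        }
        trial_lo = np.zeros(n_trials, dtype=bool)

        step = 0
        for t in range(n_trials):
            this_trial_lo = bool(rng.random() < world.lo_random_p) if random_lo else None
            # Select / emit / reward for the three notes, chaining SARSA
            # updates through the actually chosen next action.
            prev = None  # (note, variant, reward)
            any_lo = False
            for note in range(N_NOTES):
                variant = select_action(Q[note], cfg.epsilon, rng)
                action = note * N_VARIANTS + variant
                state = int(np.searchsorted(cum[action], rng.random(), side="right"))
                state = min(state, world.n_states - 1)
                if world.lo_mode is LOMode.CONTINGENT:
                    lo = bool(lo_mask[state])
                elif random_lo:
                    lo = this_trial_lo
                else:
                    lo = False
                any_lo = any_lo or lo

                E = self._exploration(action)
                if deaf:
                    obs = OBS_LIGHT_OFF if lo else OBS_LIGHT_ON
                else:
                    obs = min(max(state - self._support_start[action], 0), 2)
                self.sensory.update(action, obs)
                M = self._manipulation(action)
                r = cfg.r_per_lo if lo else 0.0
                R = E + M + r

                self.visits[note, variant] += 1
                if prev is not None:
                    pnote, pvar, prew = prev
                    alpha = self._alpha(pnote, pvar)
                    delta = sarsa_step(Q, pnote, pvar, prew, note, variant, alpha, gamma)
                    log["rpe"][step - 1] = delta

                i = step
                log["trial"][i] = t
                log["note"][i] = note
                log["action"][i] = action
                log["state"][i] = state
                log["lo"][i] = lo
                log["exploration"][i] = E
                log["manipulation"][i] = M
                log["extrinsic"][i] = r
                log["reward"][i] = R
                log["q_chosen"][i] = Q[note, variant]
                prev = (note, variant, R)
                step += 1
            # terminal update for note 3
            pnote, pvar, prew = prev
            alpha = self._alpha(pnote, pvar)
            delta = sarsa_step(Q, pnote, pvar, prew, None, None, alpha, gamma)
            log["rpe"][step - 1] = delta
            trial_lo[t] = any_lo

        arrays = {k: v for k, v in log.items()}
        for key in ("trial", "note", "action", "state"):
            arrays[key] = arrays[key].astype(np.int64)
        arrays["lo"] = arrays["lo"].astype(bool)
        return AgentTrace(trial_lo=trial_lo, **arrays)

    def _alpha(self, note: int, variant: int) -> float:
        if self.config.alpha_schedule == "harmonic":
            return 1.0 / max(1, self.visits[note, variant])
        return self.config.learning_rate

    # -- summaries --------------------------------------------------------
    def motivation(self, trace: AgentTrace, last_frac: float = 0.2) -> float:
        """Visit-weighted mean Q over the last window of the run."""
        start = int(round((1 - last_frac) * len(trace.q_chosen)))
        window = trace.q_chosen[start:]
        if window.size == 0:
            raise ValueError("empty visit set")
        return float(window.mean())


def run_song_trial(agent: SarsaAgent) -> AgentTrace:
    """Convenience: one three-note episode logged as a single-trial trace."""
    return agent.run(n_trials=1)


def motivation_index(Q: np.ndarray, visits: np.ndarray) -> float:
    """Visit-weighted mean Q value (arbitrary units).

    Weighting by visit counts keeps unvisited state-action pairs from
    diluting the index: the result tracks the value the agent actually
    experiences under its current policy.
    """
    Q = np.asarray(Q, dtype=float)
    visits = np.asarray(visits, dtype=float)
    total = visits.sum()
    if total == 0:
        raise ValueError("empty visit set")
    return float(np.sum(Q * visits) / total)


def rpe_summary(
    trace: AgentTrace,
    world: SyllableMDP,
    note: int = 2,
    last_frac: float = 0.2,
    lo_capable_only: bool = True,
) -> tuple[float, float]:
    """Mean RPE at a given note (1-based), split by light-off outcome.

    Returns ``(mean delta on reinforced trials, mean delta on escape
    trials)``.  Escape trials are, by default, those where the chosen action
    could have triggered light-off but did not — the no-reinforcer,
    no-LO counterpart of a reinforced trial.
    """
    note0 = note - 1
    start_trial = int(round((1 - last_frac) * trace.n_trials))
    sel = (trace.note == note0) & (trace.trial >= start_trial)
    lo = trace.lo[sel]
    rpe = trace.rpe[sel]
    actions = trace.action[sel]
    reinforced = rpe[lo]
    if lo_capable_only:
        capable = np.array([world.lo_probability(int(a)) > 0 for a in actions])
        escape = rpe[capable & ~lo]
    else:
        escape = rpe[~lo]
    if reinforced.size == 0 or escape.size == 0:
        raise ValueError("no trials of one outcome class at this note")
    return float(reinforced.mean()), float(escape.mean())


def policy_q_dp(
    world: SyllableMDP,
    policy: np.ndarray,
    r_per_lo: float,
    gamma: float,
) -> np.ndarray:
    """Exact fixed-policy Q values by dynamic programming.

    ``policy[note, variant]`` are action probabilities per note.  Rewards are
    the extrinsic term only (r per light-off), which is the stationary-reward
    setting in which SARSA's fixed-policy estimates have an exact oracle.
    """
    policy = np.asarray(policy, dtype=float)
    r_bar = np.array(
        [r_per_lo * world.lo_probability(a) for a in range(world.n_actions)]
    ).reshape(N_NOTES, N_VARIANTS)
    Q = np.zeros((N_NOTES, N_VARIANTS))
    Q[N_NOTES - 1] = r_bar[N_NOTES - 1]
    for note in range(N_NOTES - 2, -1, -1):
        v_next = float(np.dot(policy[note + 1], Q[note + 1]))
        Q[note] = r_bar[note] + gamma * v_next
    return Q


def make_agent(
    world: SyllableMDP, config: AgentConfig | None = None, **overrides
) -> SarsaAgent:
    config = config or AgentConfig()
    if overrides:
        config = replace(config, **overrides)
    return SarsaAgent(world, config)
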