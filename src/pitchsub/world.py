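"""Discrete generative environment for the syllable-production model.

A simulated bird produces one syllable per trial as a sequence of three
*notes*.  At each note it picks one of six motor *variants*, so a full
syllable is a path through 18 actions.  Each action stochastically triggers
one of three adjacent sensory states; a designated subset of states switches
the chamber light off (LO).  Deaf agents observe only the binary light state,
hearing agents observe the full sensory state.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

N_NOTES = 3
N_VARIANTS = 6
N_ACTIONS = N_NOTES * N_VARIANTS

#: Default light-off states, 0-based indices (states 13-16 in 1-based labels).
#: They straddle the note-2 / note-3 boundary: the last note-2 variant can
#: reach state 12 (label 13), and four of the six note-3 variants are centred
#: inside the LO zone.
DEFAULT_LO_STATES = (12, 13, 14, 15)

DEFAULT_KERNEL = (0.25, 0.5, 0.25)


class LOMode(str, enum.Enum):
    """How light-off is delivered.

    ``contingent``: LO whenever the emitted state is in ``lo_states`` (the
    closed-loop paradigm).  ``random``: one Bernoulli draw per syllable,
    independent of actions (the subs-rand protocol).  ``off``: the light never
    goes off (unsubs / noLO control worlds).
    """

    CONTINGENT = "contingent"
    RANDOM = "random"
    OFF = "off"


class Modality(str, enum.Enum):
    DEAF = "deaf"
    HEARING = "hearing"


# Deaf observation symbols.
OBS_LIGHT_ON = 0
OBS_LIGHT_OFF = 1


@dataclass(frozen=True)
class SyllableMDP:
    """Validated three-note, six-variant syllable world.

    ``emission[a]`` is the probability vector over sensory states for action
    ``a``; every row has exactly three nonzero entries on adjacent states.
    The no-action baseline is a distinguished "silence" percept with the
    light on, so the baseline distribution places zero mass on light-off.
    """

    n_states: int
    emission: np.ndarray  # (N_ACTIONS, n_states)
    lo_states: frozenset[int]
    lo_mode: LOMode = LOMode.CONTINGENT
    lo_random_p: float = 0.5
    _cum: np.ndarray = field(init=False, repr=False, compare=False)
    _lo_mask: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_cum", np.cumsum(self.emission, axis=1))
        mask = np.zeros(self.n_states, dtype=bool)
        mask[list(self.lo_states)] = True
        object.__setattr__(self, "_lo_mask", mask)

    @property
    def n_actions(self) -> int:
        return self.emission.shape[0]

    def note_of(self, action: int) -> int:
        return action // N_VARIANTS

    def actions_of_note(self, note: int) -> range:
        return range(note * N_VARIANTS, (note + 1) * N_VARIANTS)

    def lo_probability(self, action: int) -> float:
        """Probability that this action lands in the LO zone (contingent mode)."""
        if self.lo_mode is LOMode.OFF:
            return 0.0
        if self.lo_mode is LOMode.RANDOM:
            return self.lo_random_p
        return float(self.emission[action, self._lo_mask].sum())

    def with_lo_mode(self, mode: LOMode | str, lo_random_p: float = 0.5) -> "SyllableMDP":
        """Same emission structure with a different light-off delivery rule."""
        return SyllableMDP(
            n_states=self.n_states,
            emission=self.emission,
            lo_states=self.lo_states,
            lo_mode=LOMode(mode),
            lo_random_p=lo_random_p,
        )


def _default_emission(n_states: int, kernel: tuple[float, ...]) -> np.ndarray:
    """One home state per action; the 3-point kernel is centred on the home
    state, with edge actions' windows shifted inward so every row keeps
    exactly three nonzero adjacent entries."""
    width = len(kernel)
    half = width // 2
    emission = np.zeros((N_ACTIONS, n_states))
    for a in range(N_ACTIONS):
        home = a * (n_states // N_ACTIONS)  # identity map when n_states == 18
        center = int(np.clip(home, half, n_states - 1 - half))
        emission[a, center - half : center - half + width] = kernel
    return emission


def build_world(config: dict | None = None) -> SyllableMDP:
    """Construct and validate a :class:`SyllableMDP`.

    ``config`` keys (all optional): ``n_states`` (default 18), ``kernel``
    (default ``(0.25, 0.5, 0.25)``), ``lo_states`` (0-based indices, default
    states 13-16 in 1-based labels), ``emission`` (full matrix overriding the
    kernel construction), ``lo_mode``, ``lo_random_p``.
    """
    config = dict(config or {})
    n_states = int(config.get("n_states", N_ACTIONS))
    lo_states = tuple(config.get("lo_states", DEFAULT_LO_STATES))
    lo_mode = LOMode(config.get("lo_mode", LOMode.CONTINGENT))
    lo_random_p = float(config.get("lo_random_p", 0.5))

    if "emission" in config:
        emission = np.asarray(config["emission"], dtype=float)
    else:
        kernel = tuple(config.get("kernel", DEFAULT_KERNEL))
        if len(kernel) != 3:
            raise ValueError("emission kernel must have 3 entries")
        emission = _default_emission(n_states, kernel)

    if emission.shape != (N_ACTIONS, n_states):
        raise ValueError(
            f"emission must be ({N_ACTIONS}, {n_states}), got {emission.shape}"
        )
    row_sums = emission.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-9):
        bad = int(np.argmax(np.abs(row_sums - 1.0)))
        raise ValueError(f"emission row {bad} sums to {row_sums[bad]!r}, not 1")
    if np.any(emission < 0):
        raise ValueError("emission probabilities must be nonnegative")

    if lo_mode is LOMode.CONTINGENT:
        if not lo_states:
            raise ValueError("lo_states must be nonempty in contingent mode")
        if any(s < 0 or s >= n_states for s in lo_states):
            raise ValueError(f"lo_states out of range [0, {n_states})")
        if len(set(lo_states)) >= n_states:
            raise ValueError("lo_states must be a strict subset of the states")

    return SyllableMDP(
        n_states=n_states,
        emission=emission,
        lo_states=frozenset(lo_states),
        lo_mode=lo_mode,
        lo_random_p=lo_random_p,
    )


def emit_step(
    world: SyllableMDP,
    action: int,
    modality: Modality | str,
    rng: np.random.Generator,
    trial_lo: bool | None = None,
) -> tuple[int, bool, int]:
    """Sample one action's sensory outcome.

    Returns ``(sensory_state, lo_flag, observation)``.  In ``random`` LO mode
    the per-syllable light state must be supplied as ``trial_lo`` (one draw is
    shared by the whole syllable).  The deaf observation is the binary light
    state; the hearing observation is the sensory state itself.
    """
    if not 0 <= action < world.n_actions:
        raise ValueError(f"invalid action {action}")
    modality = Modality(modality)
    state = int(np.searchsorted(world._cum[action], rng.random(), side="right"))
    state = min(state, world.n_states - 1)
    if world.lo_mode is LOMode.CONTINGENT:
        lo = bool(world._lo_mask[state])
    elif world.lo_mode is LOMode.RANDOM:
        if trial_lo is None:
            raise ValueError("random LO mode requires the per-syllable trial_lo flag")
        lo = bool(trial_lo)
    else:
        lo = False
    if modality is Modality.DEAF:
        obs = OBS_LIGHT_OFF if lo else OBS_LIGHT_ON
    else:
        obs = state
    return state, lo, obs
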