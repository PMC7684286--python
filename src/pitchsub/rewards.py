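"""Intrinsic reward components.

The agent's per-action reward is R_j = E_j + M_j + r_j:

* E_j — exploration bonus: the Bayesian expected information gain about
  action j's sensory-outcome distribution from one more observation, under a
  Dirichlet model.  Positive, strictly decreasing in experience, vanishing.
* M_j — manipulation (impact) bonus: the Kullback-Leibler divergence, in
  nats, between the no-action sensory distribution θ̂₀ and the distribution
  θ̂_j following action j.  For a deaf agent the alphabet is binary
  (light on / light off) and θ̂₀ = (on: 1, off: 0), so M_j reduces exactly to
  the Shannon surprise of light-on, −log θ̂_j(on).
* r_j — extrinsic punishment, r_j ≤ 0, delivered only on light-off events.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma


def estimate_theta(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Posterior-mean (Laplace-smoothed) outcome distribution.

    ``theta_k = (counts_k + pseudocount) / (total + pseudocount * K)``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty observation alphabet")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    alpha = counts + pseudocount
    return alpha / alpha.sum()


def manipulation_bonus(
    theta0: np.ndarray, theta_j: np.ndarray, allow_inf: bool = False
) -> float:
    """Impact of action j: D_KL(θ̂₀ ‖ θ̂_j) in nats.

    Raises if θ̂₀ puts mass where θ̂_j has none (infinite impact) unless
    ``allow_inf`` is set.
    """
    theta0 = np.asarray(theta0, dtype=float)
    theta_j = np.asarray(theta_j, dtype=float)
    if theta0.shape != theta_j.shape:
        raise ValueError("distributions must share an alphabet")
    support = theta0 > 0
    if np.any(theta_j[support] == 0):
        if allow_inf:
            return float("inf")
        raise ValueError("theta0 has mass on a zero of theta_j: infinite impact")
    p = theta0[support]
    q = theta_j[support]
    return float(np.sum(p * (np.log(p) - np.log(q))))


def deaf_impact(theta_on: float) -> float:
    """Deaf special case: M = −log θ̂_j(on) (θ̂₀ is certain light-on)."""
    if not 0 < theta_on <= 1:
        raise ValueError("theta_on must lie in (0, 1]")
    return float(-np.log(theta_on))


def exploration_bonus(counts: np.ndarray, pseudocount: float = 1.0) -> float:
    """Expected information gain from one more observation of this action.

    With Dirichlet parameters α = counts + pseudocount and α₀ = Σα, the KL
    divergence from the current posterior to the posterior after observing
    symbol k is log(α₀/α_k) + ψ(α_k+1) − ψ(α₀+1); the bonus averages this
    over the posterior-predictive probabilities α_k/α₀.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty observation alphabet")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    alpha = counts + pseudocount
    a0 = alpha.sum()
    gain = np.log(a0 / alpha) + digamma(alpha + 1.0) - digamma(a0 + 1.0)
    return float(np.dot(alpha / a0, gain))


def total_reward(
    exploration: float, manipulation: float, lo_flag: bool, r_per_lo: float
) -> float:
    """R = E + M + (r per LO, on light-off events only)."""
    if r_per_lo > 0:
        raise ValueError("extrinsic reinforcement per LO must be <= 0")
    return exploration + manipulation + (r_per_lo if lo_flag else 0.0)


class SensoryModel:
    """Per-action observation counts with Dirichlet smoothing.

    Tracks, for each of ``n_actions`` actions, how often each symbol of an
    ``n_symbols`` observation alphabet followed the action.  The no-action
    baseline θ̂₀ is imposed, not estimated: a distinguished light-on percept
    (silence) with zero mass on light-off.
    """

    def __init__(self, n_actions: int, n_symbols: int, pseudocount: float = 1.0):
        if n_symbols < 1:
            raise ValueError("empty observation alphabet")
        self.pseudocount = float(pseudocount)
        self.counts = np.zeros((n_actions, n_symbols), dtype=float)

    def update(self, action: int, symbol: int) -> None:
        self.counts[action, symbol] += 1.0

    def theta(self, action: int) -> np.ndarray:
        return estimate_theta(self.counts[action], self.pseudocount)

    def exploration(self, action: int) -> float:
        return exploration_bonus(self.counts[action], self.pseudocount)

    def total(self, action: int) -> float:
        return float(self.counts[action].sum())
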