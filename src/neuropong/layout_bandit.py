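"""EXP3 adversarial bandit over motor-layout configurations.

One motor layout (arm) is chosen per rally.  The rally score (number of
paddle hits) maps to a loss

    L_i = min(score_i, 10) / 10 - 1,       L_i in [-1, 0],

so a zero-hit rally costs -1 and ten or more hits cost 0.  The standard
exponential-weight scheme is used: arms are drawn from the exploration-
mixed distribution p_i = (1 - gamma) w_i / sum(w) + gamma / K, and the
chosen arm's weight is updated with the importance-weighted reward
r / p_arm where r = L + 1 in [0, 1].  EXP3 makes no stationarity
assumption, which matters here because the culture driving the scores is
itself changing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

DEFAULT_GAMMA = 0.1
SCORE_CAP = 10
_WEIGHT_CEILING = 1e100  # renormalize before weights overflow

__all__ = ["BanditState", "rally_loss", "select_arm", "update"]


def rally_loss(score: int) -> float:
    """Loss of a rally from its hit count: ``min(score, 10)/10 - 1``."""
    if score < 0:
        raise ValueError("score must be non-negative")
    return min(score, SCORE_CAP) / SCORE_CAP - 1.0


@dataclass
class BanditState:
    """Weights and exploration rate of an EXP3 bandit over K arms."""

    n_arms: int
    gamma: float = DEFAULT_GAMMA
    weights: np.ndarray = None
    history: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")
        if self.n_arms < 2:
            raise ValueError("need at least two arms")
        if self.weights is None:
            self.weights = np.ones(self.n_arms)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.n_arms,) or np.any(self.weights <= 0):
            raise ValueError("weights must be positive, one per arm")

    def probabilities(self) -> np.ndarray:
        """Exploration-mixed selection distribution (sums to 1, each
        component >= gamma / K)."""
        w = self.weights / self.weights.sum()
        return (1.0 - self.gamma) * w + self.gamma / self.n_arms


def select_arm(state: BanditState, rng: np.random.Generator) -> int:
    """Draw an arm from the current mixed distribution."""
    arm = int(rng.choice(state.n_arms, p=state.probabilities()))
    state.history.append(arm)
    return arm


def update(state: BanditState, arm: int, loss: float) -> BanditState:
    """Importance-weighted exponential update of the chosen arm only."""
    if not -1.0 <= loss <= 0.0:
        raise ValueError("loss must lie in [-1, 0]")
    reward = loss + 1.0
    p = state.probabilities()[arm]
    estimate = reward / p
    weights = state.weights.copy()
    weights[arm] *= math.exp(state.gamma * estimate / state.n_arms)
    if weights.max() > _WEIGHT_CEILING:
        # renormalize before overflow; keep a floor so no weight
        # underflows to exactly zero
        weights = np.maximum(weights / weights.max(), 1e-300)
    return BanditState(n_arms=state.n_arms, gamma=state.gamma,
                       weights=weights, history=state.history)
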