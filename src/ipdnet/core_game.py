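"""Prisoner's dilemma primitives: moves, payoff parameters, single-game payoff.

The game is the standard two-player prisoner's dilemma with payoffs
T (temptation) > R (reward) > P (punishment) >= S (sucker), and
2R > T + S so that mutual cooperation beats alternating exploitation.
A move is encoded as the indicator X in {0, 1} with cooperation <-> 1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = ["Move", "PayoffParams", "game_payoff"]


class Move(enum.IntEnum):
    """A single prisoner's dilemma move; the integer value is the
    cooperation indicator X (C=1, D=0)."""

    D = 0
    C = 1


@dataclass(frozen=True)
class PayoffParams:
    """Payoff parameters (R, S, T, P) of the dilemma.

    Defaults to the classic (3, 0, 5, 1). Validity (T > R > P >= S and
    2R > T + S) is checked on construction.
    """

    R: float = 3.0
    S: float = 0.0
    T: float = 5.0
    P: float = 1.0

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P >= self.S):
            raise ValueError(
                f"payoffs must satisfy T > R > P >= S, got "
                f"(R,S,T,P)=({self.R},{self.S},{self.T},{self.P})"
            )
        if not (2 * self.R > self.T + self.S):
            raise ValueError("payoffs must satisfy 2R > T + S")

    @property
    def matrix(self) -> np.ndarray:
        """Row player's payoff matrix [[R, S], [T, P]] indexed by
        (own defection, their defection) -- i.e. row 0 is cooperation."""
        return np.array([[self.R, self.S], [self.T, self.P]], dtype=float)

    @property
    def vector(self) -> np.ndarray:
        """Payoffs ordered by joint outcome (CC, CD, DC, DD) from the
        row player's perspective: (R, S, T, P)."""
        return np.array([self.R, self.S, self.T, self.P], dtype=float)

    def lookup(self) -> np.ndarray:
        """Payoff lookup table indexed by 2*own + their (moves as X)."""
        # index 0: (D,D)->P, 1: (D,C)->T, 2: (C,D)->S, 3: (C,C)->R
        return np.array([self.P, self.T, self.S, self.R], dtype=float)


def game_payoff(my: Move, their: Move, params: PayoffParams | None = None) -> float:
    """Payoff of one simultaneous game from the row player's perspective.

    Equivalent to the bilinear form omega_i^T [[R,S],[T,P]] omega_j with
    omega = (X, 1-X).
    """
    if params is None:
        params = PayoffParams()
    omega_i = np.array([int(my), 1 - int(my)], dtype=float)
    omega_j = np.array([int(their), 1 - int(their)], dtype=float)
    return float(omega_i @ params.matrix @ omega_j)
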