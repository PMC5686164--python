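"""The 14 tournament strategies.

Each strategy is a policy over the history of one iterated pairwise game.
A compact sufficient statistic (:class:`PairHistory` for scalar play,
:class:`StateArrays` for vectorized play) drives every policy:

* the opponent's last three moves (a 3-move window),
* the player's own last move,
* running counts of the opponent's cooperations and defections.

Ten of the strategies are memory-one, i.e. fully described by a vector
(p_CC, p_CD, p_DC, p_DD) of cooperation probabilities conditioned on the
previous joint outcome (own move listed first); :func:`memory_one_vector`
exposes that algebraic form. The remaining four (TF2T, HARD_TFT,
HARD_TF2T, HARD_MAJO) need the longer window or the full counts.

First moves: every strategy opens with cooperation except HARD_MAJO
(opens with defection) and RANDOM (a fair coin).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .core_game import Move

__all__ = [
    "StrategyId",
    "MemoryOneVector",
    "PairHistory",
    "StateArrays",
    "first_move",
    "first_move_prob",
    "next_move",
    "memory_one_vector",
    "cooperation_probs",
    "DETERMINISTIC",
    "MEMORY_ONE",
]


class StrategyId(enum.Enum):
    """Closed enumeration of the 14 tournament strategies."""

    AC = "ac"
    AD = "ad"
    RANDOM = "random"
    TFT = "tft"
    GTFT = "gtft"
    WSLS = "wsls"
    ZDE = "zde"
    ZDG = "zdg"
    HARD_JOSS = "hard_joss"
    TF2T = "tf2t"
    GRIM = "grim"
    HARD_TFT = "hard_tft"
    HARD_MAJO = "hard_majo"
    HARD_TF2T = "hard_tf2t"

    @classmethod
    def from_token(cls, token: str) -> "StrategyId":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ValueError(f"unknown strategy token {token!r}") from None

    @property
    def token(self) -> str:
        return self.value


@dataclass(frozen=True)
class MemoryOneVector:
    """Cooperation probabilities after outcomes CC, CD, DC, DD
    (own move listed first)."""

    p_cc: float
    p_cd: float
    p_dc: float
    p_dd: float

    def __post_init__(self) -> None:
        for v in self.as_tuple():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"memory-one entries must lie in [0,1], got {v}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_cc, self.p_cd, self.p_dc, self.p_dd)

    def as_array(self) -> np.ndarray:
        return np.array(self.as_tuple(), dtype=float)


# Memory-one representations. The zero-determinant vectors implement the
# chi = 3 extortionate relation s_X - P = 3 (s_Y - P) (ZDE) and its
# generous counterpart s_X - R = 3 (s_Y - R) (ZDG).
_MEMORY_ONE: dict[StrategyId, MemoryOneVector] = {
    StrategyId.AC: MemoryOneVector(1, 1, 1, 1),
    StrategyId.AD: MemoryOneVector(0, 0, 0, 0),
    StrategyId.RANDOM: MemoryOneVector(0.5, 0.5, 0.5, 0.5),
    StrategyId.TFT: MemoryOneVector(1, 0, 1, 0),
    StrategyId.GTFT: MemoryOneVector(1, 1 / 3, 1, 1 / 3),
    StrategyId.WSLS: MemoryOneVector(1, 0, 0, 1),
    StrategyId.ZDE: MemoryOneVector(11 / 13, 1 / 2, 7 / 26, 0),
    StrategyId.ZDG: MemoryOneVector(1, 2 / 11, 1, 4 / 11),
    StrategyId.HARD_JOSS: MemoryOneVector(0.9, 0, 0.9, 0),
    StrategyId.GRIM: MemoryOneVector(1, 0, 0, 0),
}

MEMORY_ONE = frozenset(_MEMORY_ONE)

#: Strategies whose next move is a deterministic function of the history.
DETERMINISTIC = frozenset(
    s
    for s in StrategyId
    if s
    not in {
        StrategyId.RANDOM,
        StrategyId.GTFT,
        StrategyId.HARD_JOSS,
        StrategyId.ZDE,
        StrategyId.ZDG,
    }
)


def memory_one_vector(strategy: StrategyId) -> MemoryOneVector | None:
    """The memory-one vector of ``strategy``, or None when the strategy
    is not memory-one (TF2T, HARD_TFT, HARD_TF2T, HARD_MAJO)."""
    if not isinstance(strategy, StrategyId):
        raise TypeError(f"expected StrategyId, got {strategy!r}")
    return _MEMORY_ONE.get(strategy)


def first_move_prob(strategy: StrategyId) -> float:
    """Probability that ``strategy`` cooperates on the very first move.

    Every strategy opens cooperatively unless its own definition forces
    the first move: AD always defects, HARD_MAJO opens with defection,
    and RANDOM flips its fair coin from round one.
    """
    if strategy in (StrategyId.HARD_MAJO, StrategyId.AD):
        return 0.0
    if strategy is StrategyId.RANDOM:
        return 0.5
    return 1.0


def first_move(strategy: StrategyId, rng: np.random.Generator | None = None) -> Move:
    """First move of ``strategy``; RANDOM requires an rng for its coin flip."""
    p = first_move_prob(strategy)
    if p == 1.0:
        return Move.C
    if p == 0.0:
        return Move.D
    if rng is None:
        raise ValueError("RANDOM's first move needs a random generator")
    return Move.C if rng.random() < p else Move.D


@dataclass
class PairHistory:
    """Sufficient statistic of one pairwise game history.

    ``window`` holds the opponent's last (up to three) moves, most recent
    first. Rounds beyond the window only survive in the cooperation /
    defection counts, which is all any of the 14 policies needs.
    """

    window: tuple[Move, ...] = ()
    own_last: Move | None = None
    opp_coop: int = 0
    opp_def: int = 0
    round_index: int = 0

    @property
    def grim_triggered(self) -> bool:
        return self.opp_def > 0

    def validate(self) -> None:
        if self.opp_coop < 0 or self.opp_def < 0:
            raise ValueError("negative opponent move counts")
        if self.opp_coop + self.opp_def != self.round_index:
            raise ValueError(
                f"counts ({self.opp_coop}+{self.opp_def}) do not sum to "
                f"round index {self.round_index}"
            )
        if len(self.window) > 3:
            raise ValueError("window longer than 3 moves")
        if self.round_index > 0 and self.own_last is None:
            raise ValueError("missing own move after round 1")

    def update(self, own: Move, opp: Move) -> None:
        """Record one simultaneous round."""
        self.window = (opp,) + self.window[:2]
        self.own_last = own
        if opp is Move.C:
            self.opp_coop += 1
        else:
            self.opp_def += 1
        self.round_index += 1

    def _window_padded(self) -> tuple[int, int, int]:
        # unplayed rounds pad as cooperation, which never falsely triggers
        # any of the window policies
        w = [int(m) for m in self.window]
        while len(w) < 3:
            w.append(1)
        return w[0], w[1], w[2]


def cooperation_prob(strategy: StrategyId, h: PairHistory) -> float:
    """Probability that ``strategy`` cooperates next, given history ``h``
    with at least one round played."""
    h.validate()
    if h.round_index < 1:
        raise ValueError("use first_move before any round has been played")
    w1, w2, w3 = h._window_padded()
    own = int(h.own_last)
    vec = _MEMORY_ONE.get(strategy)
    if strategy is StrategyId.GRIM:
        return 0.0 if h.grim_triggered else 1.0
    if vec is not None:
        idx = (1 - own) * 2 + (1 - w1)
        return vec.as_tuple()[idx]
    if strategy is StrategyId.TF2T:
        return 0.0 if (w1 == 0 and w2 == 0) else 1.0
    if strategy is StrategyId.HARD_TFT:
        return 0.0 if (w1 == 0 or w2 == 0 or w3 == 0) else 1.0
    if strategy is StrategyId.HARD_TF2T:
        return 0.0 if ((w1 == 0 and w2 == 0) or (w2 == 0 and w3 == 0)) else 1.0
    if strategy is StrategyId.HARD_MAJO:
        return 0.0 if h.opp_def >= h.opp_coop else 1.0
    raise ValueError(f"unknown strategy {strategy!r}")


def next_move(
    strategy: StrategyId, h: PairHistory, rng: np.random.Generator | None = None
) -> Move:
    """Next move of ``strategy`` given history ``h``.

    A genuinely stochastic decision (0 < p < 1) consumes exactly one
    uniform draw from ``rng``; deterministic decisions consume none.
    """
    p = cooperation_prob(strategy, h)
    if p == 1.0:
        return Move.C
    if p == 0.0:
        return Move.D
    if rng is None:
        raise ValueError(f"{strategy.token} needs a random generator here")
    return Move.C if rng.random() < p else Move.D


# ---------------------------------------------------------------------------
# Vectorized policy evaluation, shared by the round-robin and network engines.
# ---------------------------------------------------------------------------


@dataclass
class StateArrays:
    """Per-game state arrays for ``n`` simultaneous pairwise games,
    all from one side's perspective. Window entries for rounds not yet
    played are padded with cooperation (see PairHistory)."""

    n: int
    own_last: np.ndarray = field(default=None)  # type: ignore[assignment]
    w1: np.ndarray = field(default=None)  # type: ignore[assignment]
    w2: np.ndarray = field(default=None)  # type: ignore[assignment]
    w3: np.ndarray = field(default=None)  # type: ignore[assignment]
    opp_coop: np.ndarray = field(default=None)  # type: ignore[assignment]
    opp_def: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.own_last is None:
            self.own_last = np.ones(self.n, dtype=np.int8)
            self.w1 = np.ones(self.n, dtype=np.int8)
            self.w2 = np.ones(self.n, dtype=np.int8)
            self.w3 = np.ones(self.n, dtype=np.int8)
            self.opp_coop = np.zeros(self.n, dtype=np.int64)
            self.opp_def = np.zeros(self.n, dtype=np.int64)

    def record(self, own: np.ndarray, opp: np.ndarray) -> None:
        """Push one round of moves (cooperation indicators)."""
        self.w3[:] = self.w2
        self.w2[:] = self.w1
        self.w1[:] = opp
        self.own_last[:] = own
        self.opp_coop += opp
        self.opp_def += 1 - opp


def cooperation_probs(strategy: StrategyId, s: StateArrays) -> np.ndarray:
    """Vectorized cooperation probabilities of ``strategy`` for every game
    in ``s`` (rounds >= 1; use first_move_prob for the opening round)."""
    if strategy is StrategyId.GRIM:
        return np.where(s.opp_def > 0, 0.0, 1.0)
    vec = _MEMORY_ONE.get(strategy)
    if vec is not None:
        idx = (1 - s.own_last) * 2 + (1 - s.w1)
        return vec.as_array()[idx]
    if strategy is StrategyId.TF2T:
        return np.where((s.w1 == 0) & (s.w2 == 0), 0.0, 1.0)
    if strategy is StrategyId.HARD_TFT:
        return np.where((s.w1 == 0) | (s.w2 == 0) | (s.w3 == 0), 0.0, 1.0)
    if strategy is StrategyId.HARD_TF2T:
        bad = ((s.w1 == 0) & (s.w2 == 0)) | ((s.w2 == 0) & (s.w3 == 0))
        return np.where(bad, 0.0, 1.0)
    if strategy is StrategyId.HARD_MAJO:
        return np.where(s.opp_def >= s.opp_coop, 0.0, 1.0)
    raise ValueError(f"unknown strategy {strategy!r}")
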