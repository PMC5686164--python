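"""Tournament 1: the two-player round-robin among all 14 strategies.

Each unordered pair of distinct strategies plays an iterated game of
10,000 rounds repeated 100 times (defaults). The side with the higher
aggregate payoff wins; an exact tie goes to the side with the higher
self-play aggregate under the same protocol; a further tie is a draw.
The loser of a decided match is the *weak* strategy and the winner the
*strong* one -- the labels the network tournament consumes.

Players never see the horizon: policies only read the pair history, so
the engine's round count cannot leak into strategy decisions.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np

from .core_game import PayoffParams
from .strategies import (
    DETERMINISTIC,
    StateArrays,
    StrategyId,
    cooperation_probs,
    first_move_prob,
)

__all__ = ["Verdict", "MatchOutcome", "Scoreboard", "play_iterated", "decide", "scoreboard"]


class Verdict(enum.Enum):
    A_WINS = "a"
    B_WINS = "b"
    DRAW = "draw"


@dataclass(frozen=True)
class MatchOutcome:
    a: StrategyId
    b: StrategyId
    total_a: float
    total_b: float
    self_a: float
    self_b: float
    verdict: Verdict

    @property
    def weak(self) -> StrategyId | None:
        if self.verdict is Verdict.A_WINS:
            return self.b
        if self.verdict is Verdict.B_WINS:
            return self.a
        return None

    @property
    def strong(self) -> StrategyId | None:
        if self.verdict is Verdict.A_WINS:
            return self.a
        if self.verdict is Verdict.B_WINS:
            return self.b
        return None


def _moves(strategy: StrategyId, p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if strategy in DETERMINISTIC:
        return p.astype(np.int8)  # p is exactly 0 or 1
    return (rng.random(p.shape[0]) < p).astype(np.int8)


def play_iterated(
    a: StrategyId,
    b: StrategyId,
    rounds: int,
    rng: np.random.Generator | None = None,
    repeats: int = 1,
    params: PayoffParams | None = None,
    collapse_deterministic: bool = True,
) -> tuple[float, float]:
    """Aggregate payoffs of one iterated match, summed over ``rounds``
    rounds and ``repeats`` independent repeats.

    Repeats run as a vectorized batch on independent draws from ``rng``.
    A fully deterministic pair produces identical repeats, so with
    ``collapse_deterministic`` it is played once and scaled -- exactly.
    """
    if rounds < 1:
        raise ValueError("need at least one round")
    if params is None:
        params = PayoffParams()
    if rng is None:
        rng = np.random.default_rng()
    scale = 1
    if collapse_deterministic and a in DETERMINISTIC and b in DETERMINISTIC:
        scale, repeats = repeats, 1
    lut = params.lookup()
    sa = StateArrays(repeats)
    sb = StateArrays(repeats)
    tot_a = np.zeros(repeats)
    tot_b = np.zeros(repeats)
    for t in range(rounds):
        if t == 0:
            pa = np.full(repeats, first_move_prob(a))
            pb = np.full(repeats, first_move_prob(b))
        else:
            pa = cooperation_probs(a, sa)
            pb = cooperation_probs(b, sb)
        ma = _moves(a, pa, rng)
        mb = _moves(b, pb, rng)
        tot_a += lut[2 * ma + mb]
        tot_b += lut[2 * mb + ma]
        sa.record(ma, mb)
        sb.record(mb, ma)
    return float(tot_a.sum()) * scale, float(tot_b.sum()) * scale


def decide(a_total: float, b_total: float, a_self: float, b_self: float) -> Verdict:
    """Head-to-head aggregate decides; an exact tie falls back to the
    self-play aggregate; a further exact tie is a draw."""
    if a_total > b_total:
        return Verdict.A_WINS
    if b_total > a_total:
        return Verdict.B_WINS
    if a_self > b_self:
        return Verdict.A_WINS
    if b_self > a_self:
        return Verdict.B_WINS
    return Verdict.DRAW


@dataclass
class Scoreboard:
    outcomes: dict[tuple[StrategyId, StrategyId], MatchOutcome]
    self_play: dict[StrategyId, float]

    @property
    def n_non_draw(self) -> int:
        return sum(1 for o in self.outcomes.values() if o.verdict is not Verdict.DRAW)

    @property
    def weak_strong(self) -> dict[tuple[StrategyId, StrategyId], MatchOutcome]:
        """Decided matches keyed (weak, strong)."""
        return {
            (o.weak, o.strong): o
            for o in self.outcomes.values()
            if o.verdict is not Verdict.DRAW
        }


def scoreboard(
    rounds: int = 10_000,
    repeats: int = 100,
    rng: np.random.Generator | int | None = None,
    params: PayoffParams | None = None,
) -> Scoreboard:
    """Full round-robin over the C(14,2) = 91 unordered pairs.

    Self-play aggregates are computed once per strategy (mean of the two
    symmetric sides) and reused for every tie-break.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    ids = list(StrategyId)
    self_play: dict[StrategyId, float] = {}
    for s in ids:
        ta, tb = play_iterated(s, s, rounds, rng, repeats, params)
        self_play[s] = (ta + tb) / 2.0
    outcomes = {}
    for a, b in itertools.combinations(ids, 2):
        ta, tb = play_iterated(a, b, rounds, rng, repeats, params)
        verdict = decide(ta, tb, self_play[a], self_play[b])
        outcomes[(a, b)] = MatchOutcome(a, b, ta, tb, self_play[a], self_play[b], verdict)
    return Scoreboard(outcomes=outcomes, self_play=self_play)
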