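"""Tournament 2: the divide-and-conquer networked game.

Every edge of the network hosts its own independent iterated prisoner's
dilemma: a node holds a single strategy but chooses a per-neighbor move
from that edge's private history. Fitness accrues per node over an epoch
of R rounds (default 200) either as the accumulated payoff phi_i or the
degree-averaged payoff psi_i = phi_i / k_i. At each epoch boundary every
node synchronously adopts the strategy of the fittest member of its
closed neighborhood (best-takes-over; self keeps on ties, uniform choice
among strictly-better tied neighbors). Edge histories persist across
strategy changes, so a convert's first move is its new strategy's
response to the inherited history, not a fresh opening move.

A run stops at the extinction of either strategy (checked at epoch
boundaries, the only time composition can change) or at a round cap
(default 20,000), where the weak-strategy frequency is averaged over the
final 2,000 rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_game import PayoffParams
from .netgen import Assignment, Network
from .strategies import StateArrays, StrategyId, cooperation_probs, first_move_prob

__all__ = [
    "EpochConfig",
    "FitnessRecord",
    "TrajectoryResult",
    "DiagnosticFitness",
    "DncEngine",
    "run",
]


@dataclass(frozen=True)
class EpochConfig:
    measure: str = "psi"  # "phi" (accumulated) or "psi" (average)
    epoch_rounds: int = 200
    max_rounds: int = 20_000
    tail_rounds: int = 2_000
    #: reset the fitness accumulator at each epoch boundary (the epoch sum
    #: reading of phi); False accumulates from round 1 for sensitivity checks
    reset_each_epoch: bool = True

    def __post_init__(self) -> None:
        if self.measure not in ("phi", "psi"):
            raise ValueError("measure must be 'phi' or 'psi'")
        if self.max_rounds % self.epoch_rounds != 0:
            raise ValueError("max_rounds must be divisible by epoch_rounds")
        if self.tail_rounds > self.max_rounds:
            raise ValueError("tail window longer than the run")


@dataclass(frozen=True)
class FitnessRecord:
    node: int
    phi: float
    psi: float
    k: int


@dataclass
class TrajectoryResult:
    """Outcome of one divide-and-conquer run."""

    weak_counts: list[int]  # composition in force during each epoch
    termination_round: int
    extinct: bool
    f_w: float
    n_nodes: int = 0

    @property
    def weak_fractions(self) -> np.ndarray:
        return np.asarray(self.weak_counts, dtype=float) / self.n_nodes


@dataclass(frozen=True)
class DiagnosticFitness:
    """Closed-form per-round fitness of a node that played one uniform
    move with all neighbors: G = k (Delta X + T W + P (1 - W)) with
    Delta = S - P + (R - T + P - S) W, W the local cooperation frequency."""

    node: int
    round_index: int
    W: float
    X: int
    delta: float
    G: float


class DncEngine:
    """Vectorized state of one networked match.

    Per-edge state lives in two half-edge slots (one per endpoint); the
    policy of each endpoint's current strategy is evaluated on its half.
    """

    def __init__(
        self,
        network: Network,
        assignment: Assignment,
        config: EpochConfig | None = None,
        params: PayoffParams | None = None,
        rng: np.random.Generator | int | None = None,
    ) -> None:
        self.network = network
        self.assignment = assignment
        self.config = config or EpochConfig()
        self.params = params or PayoffParams()
        if rng is None or isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.rng = rng

        e = network.edges
        self.n_edges = e.shape[0]
        self.owner = np.concatenate([e[:, 0], e[:, 1]])
        m = self.n_edges
        self.partner_half = np.concatenate(
            [np.arange(m, 2 * m), np.arange(0, m)]
        )
        self.codes = assignment.strategies.copy()  # 0 weak / 1 strong per node
        self.state = StateArrays(2 * m)
        self.phi = np.zeros(network.n)
        self.deg = network.degrees.astype(float)
        self.round_index = 0
        self.rounds_in_epoch = 0
        self.last_moves: np.ndarray | None = None
        self._lut = self.params.lookup()
        # half-edge slots owned by each node, for diagnostics and updates
        order = np.argsort(self.owner, kind="stable")
        bounds = np.searchsorted(self.owner[order], np.arange(network.n + 1))
        self._halves_of = [order[bounds[i] : bounds[i + 1]] for i in range(network.n)]

    # -- one round ---------------------------------------------------------

    def step_round(self) -> np.ndarray:
        """Play one simultaneous round on every edge; accrue payoffs."""
        n_half = 2 * self.n_edges
        own_strat = self.codes[self.owner]
        if self.round_index == 0:
            p_weak = np.full(n_half, first_move_prob(self.assignment.weak))
            p_strong = np.full(n_half, first_move_prob(self.assignment.strong))
        else:
            p_weak = cooperation_probs(self.assignment.weak, self.state)
            p_strong = cooperation_probs(self.assignment.strong, self.state)
        p = np.where(own_strat == 0, p_weak, p_strong)
        moves = (self.rng.random(n_half) < p).astype(np.int8)
        opp = moves[self.partner_half]
        pay = self._lut[2 * moves.astype(np.intp) + opp]
        self.phi += np.bincount(self.owner, weights=pay, minlength=self.network.n)
        self.state.record(moves, opp)
        self.round_index += 1
        self.rounds_in_epoch += 1
        self.last_moves = moves
        return moves

    # -- epoch bookkeeping -------------------------------------------------

    def fitness(self) -> np.ndarray:
        if self.config.measure == "phi":
            return self.phi
        return self.phi / self.deg

    def epoch_fitness(self) -> list[FitnessRecord]:
        """Per-node fitness records for a completed epoch; resets the
        accumulator when the epoch-sum reading of phi is in force."""
        if self.rounds_in_epoch != self.config.epoch_rounds:
            raise RuntimeError(
                f"epoch has {self.rounds_in_epoch} rounds, "
                f"expected {self.config.epoch_rounds}"
            )
        recs = [
            FitnessRecord(i, float(self.phi[i]), float(self.phi[i] / self.deg[i]), int(self.deg[i]))
            for i in range(self.network.n)
        ]
        return recs

    def local_update(self, fitness: np.ndarray) -> np.ndarray:
        """Best-takes-over from a synchronous fitness snapshot: keep own
        strategy when own fitness matches the closed-neighborhood maximum,
        else copy a strictly fittest neighbor (uniform among ties)."""
        new_codes = self.codes.copy()
        adj = self.network.adjacency
        for i in range(self.network.n):
            nbrs = adj[i]
            nf = fitness[nbrs]
            mx = nf.max()
            if fitness[i] >= mx:
                continue
            best = nbrs[nf == mx]
            pick = best[0] if best.size == 1 else self.rng.choice(best)
            new_codes[i] = self.codes[pick]
        return new_codes

    def end_epoch(self) -> None:
        fit = self.fitness()
        self.codes = self.local_update(fit)
        if self.config.reset_each_epoch:
            self.phi[:] = 0.0
        self.rounds_in_epoch = 0

    # -- diagnostics -------------------------------------------------------

    def eq_diagnostic(self, node: int) -> DiagnosticFitness | None:
        """Closed-form round fitness of ``node`` for the last played round;
        None when the node split its moves across edges (the closed form
        only exists for a uniform move)."""
        if self.last_moves is None:
            raise RuntimeError("no round has been played yet")
        halves = self._halves_of[node]
        mine = self.last_moves[halves]
        if mine.size == 0 or not np.all(mine == mine[0]):
            return None
        x = int(mine[0])
        w = float(self.last_moves[self.partner_half[halves]].mean())
        p = self.params
        dlt = p.S - p.P + (p.R - p.T + p.P - p.S) * w
        g = self.deg[node] * (dlt * x + p.T * w + p.P * (1 - w))
        return DiagnosticFitness(
            node=node, round_index=self.round_index, W=w, X=x, delta=dlt, G=float(g)
        )

    # -- full run ----------------------------------------------------------

    def run(self) -> TrajectoryResult:
        cfg = self.config
        n = self.network.n
        if self.assignment.weak == self.assignment.strong:
            # degenerate match: only one strategy exists, extinct by label
            return TrajectoryResult([n], 0, True, 1.0, n)
        n_epochs = cfg.max_rounds // cfg.epoch_rounds
        weak_counts: list[int] = []
        for _ in range(n_epochs):
            weak_counts.append(int(np.sum(self.codes == 0)))
            for _ in range(cfg.epoch_rounds):
                self.step_round()
            self.end_epoch()
            n_weak = int(np.sum(self.codes == 0))
            if n_weak == 0 or n_weak == n:
                return TrajectoryResult(
                    weak_counts, self.round_index, True, float(n_weak == n), n
                )
        # cap reached: average the weak fraction over the tail window,
        # weighting each epoch by its round overlap with the window
        start = cfg.max_rounds - cfg.tail_rounds
        weights = np.array(
            [
                max(0, min((e + 1) * cfg.epoch_rounds, cfg.max_rounds) - max(e * cfg.epoch_rounds, start))
                for e in range(n_epochs)
            ],
            dtype=float,
        )
        f_w = float(np.average(np.array(weak_counts) / n, weights=weights))
        return TrajectoryResult(weak_counts, self.round_index, False, f_w, n)


def run(
    network: Network,
    assignment: Assignment,
    config: EpochConfig | None = None,
    params: PayoffParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> TrajectoryResult:
    """Convenience wrapper: build a :class:`DncEngine` and run it."""
    return DncEngine(network, assignment, config, params, rng).run()
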