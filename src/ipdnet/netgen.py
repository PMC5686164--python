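"""Generation of the tournament networks and degree-ranked strategy seeding.

Two families are used, matching the study conditions:

* Watts-Strogatz small worlds (ring lattice of even degree k, each edge's
  far endpoint rewired independently with probability p, resampling on
  self-loop/duplicate collisions, so the edge count stays N k / 2), and
* Barabasi-Albert scale-free graphs grown from a complete seed on m0
  nodes by preferential attachment of m distinct edges per new node.

Presets: wssn1 (1024, 6, 0.1), wssn2 (1024, 6, 0.2), basn1 (1024, 3, 3),
basn2 (2048, 3, 3). Assignment places half the population on the weak
strategy, forcing the eps = floor(alpha * N/2) highest-degree nodes to be
weak and scattering the remaining weak players uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .strategies import StrategyId

__all__ = [
    "Network",
    "Assignment",
    "generate_ws",
    "generate_ba",
    "generate_preset",
    "degree_ranking",
    "assign",
    "PRESETS",
]

PRESETS: dict[str, dict] = {
    "wssn1": {"kind": "ws", "N": 1024, "k": 6, "p": 0.1},
    "wssn2": {"kind": "ws", "N": 1024, "k": 6, "p": 0.2},
    "basn1": {"kind": "ba", "N": 1024, "m": 3, "m0": 3},
    "basn2": {"kind": "ba", "N": 2048, "m": 3, "m0": 3},
}


@dataclass
class Network:
    """An undirected simple graph held as a canonical edge array
    (each row u < v, rows lexicographically sorted)."""

    n: int
    edges: np.ndarray
    _adjacency: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64)
        if e.ndim != 2 or e.shape[1] != 2:
            raise ValueError("edges must be an (E, 2) array")
        if e.size and (e.min() < 0 or e.max() >= self.n):
            raise ValueError("edge endpoint outside [0, n)")
        if np.any(e[:, 0] == e[:, 1]):
            raise ValueError("self-loops are not allowed")
        e = np.sort(e, axis=1)
        order = np.lexsort((e[:, 1], e[:, 0]))
        e = e[order]
        if e.shape[0] > 1 and np.any(np.all(e[1:] == e[:-1], axis=1)):
            raise ValueError("duplicate edges are not allowed")
        object.__setattr__(self, "edges", e)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        mapping = {u: i for i, u in enumerate(sorted(g.nodes()))}
        edges = np.array(
            [[mapping[u], mapping[v]] for u, v in g.edges()], dtype=np.int64
        ).reshape(-1, 2)
        return cls(n=g.number_of_nodes(), edges=edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges))
        return g

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def degrees(self) -> np.ndarray:
        return np.bincount(self.edges.ravel(), minlength=self.n)

    @property
    def adjacency(self) -> list[np.ndarray]:
        if self._adjacency is None:
            adj: list[list[int]] = [[] for _ in range(self.n)]
            for u, v in self.edges:
                adj[u].append(int(v))
                adj[v].append(int(u))
            self._adjacency = [np.array(a, dtype=np.int64) for a in adj]
        return self._adjacency

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())


def _as_seed(rng: np.random.Generator | int | None):
    if rng is None:
        return np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    return rng


def generate_ws(
    N: int,
    k: int,
    p: float,
    rng: np.random.Generator | int | None = None,
    require_connected: bool = True,
) -> Network:
    """Watts-Strogatz small-world graph with exactly N k / 2 edges."""
    if not (N > k >= 2) or k % 2 != 0:
        raise ValueError("need N > k >= 2 with k even")
    if not (0.0 <= p <= 1.0):
        raise ValueError("rewiring probability must lie in [0, 1]")
    rng = _as_seed(rng)
    if require_connected:
        g = nx.connected_watts_strogatz_graph(N, k, p, tries=200, seed=rng)
    else:
        g = nx.watts_strogatz_graph(N, k, p, seed=rng)
    return Network.from_networkx(g)


def generate_ba(
    N: int, m: int, m0: int, rng: np.random.Generator | int | None = None
) -> Network:
    """Barabasi-Albert graph grown from a complete seed on m0 nodes;
    edge count is C(m0, 2) + (N - m0) m."""
    if not (N >= m0 >= m >= 1):
        raise ValueError("need N >= m0 >= m >= 1")
    rng = _as_seed(rng)
    if N == m0:
        return Network.from_networkx(nx.complete_graph(m0))
    g = nx.barabasi_albert_graph(N, m, seed=rng, initial_graph=nx.complete_graph(m0))
    return Network.from_networkx(g)


def generate_preset(name: str, rng: np.random.Generator | int | None = None) -> Network:
    try:
        preset = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    if preset["kind"] == "ws":
        return generate_ws(preset["N"], preset["k"], preset["p"], rng)
    return generate_ba(preset["N"], preset["m"], preset["m0"], rng)


@dataclass(frozen=True)
class Assignment:
    """Node-to-strategy map for one network match."""

    strategies: np.ndarray  # 0 = weak, 1 = strong, per node
    weak: StrategyId
    strong: StrategyId
    alpha: float
    eps: int

    @property
    def n_weak(self) -> int:
        return int(np.sum(self.strategies == 0))

    def strategy_of(self, node: int) -> StrategyId:
        return self.weak if self.strategies[node] == 0 else self.strong


def degree_ranking(net: Network, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Nodes ordered by degree descending; degree ties broken by a seeded
    shuffle (stable sort over a random permutation), so nearly-regular
    graphs carry no positional bias while staying reproducible."""
    rng = _as_seed(rng)
    perm = rng.permutation(net.n)
    deg = net.degrees[perm]
    return perm[np.argsort(-deg, kind="stable")]


def assign(
    net: Network,
    weak: StrategyId,
    strong: StrategyId,
    alpha: float,
    rng: np.random.Generator | int | None = None,
    ranking: np.ndarray | None = None,
) -> Assignment:
    """Half/half split with eps = floor(alpha * N/2) weak players forced
    onto the highest-degree nodes and the rest placed uniformly."""
    if net.n % 2 != 0:
        raise ValueError("assignment needs an even number of nodes")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    rng = _as_seed(rng)
    mu = net.n // 2
    eps = int(np.floor(alpha * mu))
    if ranking is None:
        ranking = degree_ranking(net, rng)
    top = ranking[:eps]
    rest = ranking[eps:]
    extra = rng.choice(rest, size=mu - eps, replace=False)
    strategies = np.ones(net.n, dtype=np.int8)
    strategies[top] = 0
    strategies[extra] = 0
    return Assignment(
        strategies=strategies, weak=weak, strong=strong, alpha=float(alpha), eps=eps
    )
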