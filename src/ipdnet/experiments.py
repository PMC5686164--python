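"""The alpha-sweep experiment grid and its protocol accounting.

A sweep runs one (weak, strong) match over a grid of alpha values (the
fraction of the weak half forced onto the highest-degree nodes), with a
fixed number of replicates per alpha. Seeds derive from a root seed
through ``numpy`` SeedSequence spawn keys indexed by (match, alpha,
replicate), so any single run is reproducible in isolation and partial
sweeps are resumable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_game import PayoffParams
from .dnc_engine import DncEngine, EpochConfig
from .netgen import PRESETS, Network, assign, generate_preset
from .strategies import StrategyId

__all__ = ["SweepPlan", "run_sweep", "run_match", "accounting", "full_protocol_totals"]


def _default_alphas() -> np.ndarray:
    return np.round(np.arange(0, 101) / 100.0, 2)


@dataclass
class SweepPlan:
    network: str  # preset name
    measure: str  # "phi" | "psi"
    matches: list[tuple[StrategyId, StrategyId]]  # (weak, strong)
    alphas: np.ndarray = field(default_factory=_default_alphas)
    replicates: int = 10
    config: EpochConfig | None = None
    params: PayoffParams | None = None
    #: regenerate the network for every replicate (default); False fixes
    #: one network per preset for the whole sweep
    fresh_network_per_replicate: bool = True

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        if a.ndim != 1 or np.any(a < 0) or np.any(a > 1) or np.any(np.diff(a) <= 0):
            raise ValueError("alphas must be strictly increasing within [0, 1]")
        self.alphas = a
        if self.network not in PRESETS:
            raise ValueError(f"unknown network preset {self.network!r}")
        if self.config is None:
            self.config = EpochConfig(measure=self.measure)
        elif self.config.measure != self.measure:
            raise ValueError("config.measure disagrees with plan measure")


def _rngs(root_seed: int, match_i: int, alpha_i: int, rep: int):
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(match_i, alpha_i, rep))
    net_ss, assign_ss, game_ss = ss.spawn(3)
    return (
        np.random.default_rng(net_ss),
        np.random.default_rng(assign_ss),
        np.random.default_rng(game_ss),
    )


def run_match(
    network: Network,
    weak: StrategyId,
    strong: StrategyId,
    alpha: float,
    config: EpochConfig,
    assign_rng: np.random.Generator,
    game_rng: np.random.Generator,
    params: PayoffParams | None = None,
):
    """One (network, alpha) replicate: seed strategies and run to
    extinction or the round cap."""
    assignment = assign(network, weak, strong, alpha, assign_rng)
    engine = DncEngine(network, assignment, config, params, game_rng)
    return engine.run()


def run_sweep(plan: SweepPlan, root_seed: int = 0) -> pd.DataFrame:
    """Execute the full grid; one tidy row per (match, alpha, replicate)."""
    rows = []
    fixed_net: dict[int, Network] = {}
    for mi, (weak, strong) in enumerate(plan.matches):
        for ai, alpha in enumerate(plan.alphas):
            for rep in range(plan.replicates):
                net_rng, assign_rng, game_rng = _rngs(root_seed, mi, ai, rep)
                if plan.fresh_network_per_replicate:
                    net = generate_preset(plan.network, net_rng)
                else:
                    if rep not in fixed_net:
                        fixed_net[rep] = generate_preset(
                            plan.network,
                            np.random.default_rng(
                                np.random.SeedSequence(
                                    entropy=root_seed, spawn_key=(1 << 20, rep)
                                )
                            ),
                        )
                    net = fixed_net[rep]
                res = run_match(
                    net, weak, strong, alpha, plan.config, assign_rng, game_rng, plan.params
                )
                rows.append(
                    {
                        "network": plan.network,
                        "measure": plan.measure,
                        "weak": weak.token,
                        "strong": strong.token,
                        "alpha": float(alpha),
                        "replicate": rep,
                        "seed": root_seed,
                        "f_w": res.f_w,
                        "termination_round": res.termination_round,
                        "extinct": res.extinct,
                    }
                )
    return pd.DataFrame(rows)


def _preset_edges(name: str) -> int:
    preset = PRESETS[name]
    if preset["kind"] == "ws":
        return preset["N"] * preset["k"] // 2
    m0, m = preset["m0"], preset["m"]
    return m0 * (m0 - 1) // 2 + (preset["N"] - m0) * m


def accounting(plan: SweepPlan) -> dict[str, int]:
    """Pure protocol arithmetic for a sweep plan: round and game counts,
    no simulation involved."""
    rounds_per_match = len(plan.alphas) * plan.replicates * plan.config.max_rounds
    games_per_round = _preset_edges(plan.network)
    return {
        "rounds_per_match": rounds_per_match,
        "n_matches": len(plan.matches),
        "total_rounds": rounds_per_match * len(plan.matches),
        "games_per_round": games_per_round,
        "total_games": rounds_per_match * len(plan.matches) * games_per_round,
    }


def full_protocol_totals(
    n_matches: int = 54,
    n_configurations: int = 8,
    n_alphas: int = 101,
    replicates: int = 10,
    max_rounds: int = 20_000,
) -> dict[str, int]:
    """Round totals of the full published protocol: 101 alphas x 10
    replicates x 20,000 rounds per match, over 54 decided matches and
    8 (network, fitness-measure) configurations."""
    per_match = n_alphas * replicates * max_rounds
    return {
        "rounds_per_match": per_match,
        "total_rounds": per_match * n_matches * n_configurations,
    }
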