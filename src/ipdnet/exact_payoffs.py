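"""Exact long-run expected payoffs for strategy pairs.

Three resolution branches, recorded in the ``method`` tag of each
:class:`PayoffExpectation`:

``determinant``
    Both strategies memory-one and the joint 4-state chain ergodic: the
    Press-Dyson determinant ratio D(p, s, S_x) / D(p, s, 1) gives the
    stationary per-round payoff in closed form.

``cycle``
    Any pair whose joint play is a finite Markov chain (every pair not
    involving HARD_MAJO, whose cooperation-majority counter is unbounded):
    the joint chain over (own last move, opponent 3-move window, grim flag)
    per side is built exactly, its recurrent classes and their stationary
    laws are solved, and the limit average weights each class by the
    absorption probability from the defined first moves. Deterministic
    pairs degenerate to a single trajectory entering a cycle. HARD_MAJO
    against a deterministic opponent is resolved on the trajectory itself,
    with a drift argument proving periodicity despite the unbounded counter.

``simulated``
    HARD_MAJO against a stochastic opponent: batched Monte Carlo
    (>= 10^6 total rounds by default) with a chain-level standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .core_game import PayoffParams
from .strategies import (
    DETERMINISTIC,
    MemoryOneVector,
    StateArrays,
    StrategyId,
    cooperation_probs,
    first_move_prob,
    memory_one_vector,
)

__all__ = [
    "PayoffExpectation",
    "transition_matrix",
    "evolve_state",
    "expected_payoff",
    "delta",
    "payoff_table",
    "stationary_state",
]

#: joint-outcome order used throughout: CC, CD, DC, DD (A's move first)
_OUTCOMES = ("CC", "CD", "DC", "DD")

#: |D(p, s, 1)| below this is treated as a non-ergodic chain
ERGODIC_TOL = 1e-9


@dataclass(frozen=True)
class PayoffExpectation:
    """Expected per-round payoff of strategy ``a`` against ``b`` in the
    long-run (stationary / limit-average) sense."""

    a: StrategyId
    b: StrategyId
    value: float
    method: str  # determinant | cycle | simulated
    stderr: float = 0.0


def transition_matrix(p: MemoryOneVector, s: MemoryOneVector) -> np.ndarray:
    """Markov transition matrix of the joint outcome (CC, CD, DC, DD) from
    A's perspective, A playing ``p`` and B playing ``s``.

    B conditions on the outcome from its own side, so rows CD and DC use
    s_DC and s_CD respectively.
    """
    pa = p.as_array()
    # B's cooperation probability in A's state order: CC, CD->s_DC, DC->s_CD, DD
    pb = s.as_array()[[0, 2, 1, 3]]
    m = np.empty((4, 4))
    m[:, 0] = pa * pb
    m[:, 1] = pa * (1 - pb)
    m[:, 2] = (1 - pa) * pb
    m[:, 3] = (1 - pa) * (1 - pb)
    return m


def evolve_state(phi: np.ndarray, m: np.ndarray) -> np.ndarray:
    """One step of the state-vector evolution phi(t) = phi(t-1) M."""
    phi = np.asarray(phi, dtype=float)
    m = np.asarray(m, dtype=float)
    if phi.shape != (4,) or m.shape != (4, 4):
        raise ValueError("state vector must be length 4 and M must be 4x4")
    if np.any(m < -1e-12) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("M is not a stochastic matrix")
    out = phi @ m
    if not np.isclose(out.sum(), phi.sum(), atol=1e-10):  # pragma: no cover
        raise AssertionError("evolution lost probability mass")
    return out


def _press_dyson_det(p: MemoryOneVector, s: MemoryOneVector, f: np.ndarray) -> float:
    """The 4x4 determinant D(p, s, f) whose ratio gives stationary payoffs."""
    pcc, pcd, pdc, pdd = p.as_tuple()
    scc, scd, sdc, sdd = s.as_tuple()
    mat = np.array(
        [
            [-1 + pcc * scc, -1 + pcc, -1 + scc, f[0]],
            [pcd * sdc, -1 + pcd, sdc, f[1]],
            [pdc * scd, pdc, -1 + scd, f[2]],
            [pdd * sdd, pdd, sdd, f[3]],
        ]
    )
    return float(np.linalg.det(mat))


def stationary_state(p: MemoryOneVector, s: MemoryOneVector) -> np.ndarray:
    """Stationary joint-outcome distribution of an ergodic memory-one pair,
    solved from phi M = phi with normalization."""
    m = transition_matrix(p, s)
    a = np.vstack([m.T - np.eye(4), np.ones(4)])
    b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    phi, *_ = np.linalg.lstsq(a, b, rcond=None)
    if np.any(phi < -1e-9):
        raise ValueError("chain is not ergodic; no valid stationary state")
    phi = np.clip(phi, 0.0, None)
    return phi / phi.sum()


# ---------------------------------------------------------------------------
# Exact finite joint chain (all pairs without HARD_MAJO)
# ---------------------------------------------------------------------------

# A side state is (own_last, w1, w2, w3, grim): the own previous move, the
# opponent's last three moves (padded with C before they exist) and the
# grim trigger flag.


def _side_prob(strategy: StrategyId, state: tuple[int, int, int, int, int]) -> float:
    own, w1, w2, w3, grim = state
    if strategy is StrategyId.GRIM:
        return 0.0 if grim else 1.0
    vec = memory_one_vector(strategy)
    if vec is not None:
        return vec.as_tuple()[(1 - own) * 2 + (1 - w1)]
    if strategy is StrategyId.TF2T:
        return 0.0 if (w1 == 0 and w2 == 0) else 1.0
    if strategy is StrategyId.HARD_TFT:
        return 0.0 if (w1 == 0 or w2 == 0 or w3 == 0) else 1.0
    if strategy is StrategyId.HARD_TF2T:
        return 0.0 if ((w1 == 0 and w2 == 0) or (w2 == 0 and w3 == 0)) else 1.0
    raise ValueError(f"{strategy} has no finite side state")


def _initial_joint_states(a: StrategyId, b: StrategyId):
    """Distribution over joint states after the first simultaneous round."""
    fa, fb = first_move_prob(a), first_move_prob(b)
    out = []
    for ma, qa in ((1, fa), (0, 1 - fa)):
        if qa == 0:
            continue
        for mb, qb in ((1, fb), (0, 1 - fb)):
            if qb == 0:
                continue
            sa = (ma, mb, 1, 1, int(mb == 0))
            sb = (mb, ma, 1, 1, int(ma == 0))
            out.append(((sa, sb), qa * qb))
    return out


def _chain_limit_payoffs(
    a: StrategyId, b: StrategyId, params: PayoffParams
) -> tuple[float, float]:
    """Exact limit-average payoffs (for A and B) of a finite-chain pair via
    recurrent-class analysis and absorption from the first moves."""
    import networkx as nx

    init = _initial_joint_states(a, b)
    # breadth-first enumeration of reachable joint states
    index: dict = {}
    trans: list[list[tuple[int, float]]] = []
    frontier = [st for st, _ in init]
    for st in frontier:
        index[st] = len(index)
        trans.append([])
    pos = 0
    while pos < len(frontier):
        sa, sb = frontier[pos]
        pa = _side_prob(a, sa)
        pb = _side_prob(b, sb)
        for ma, qa in ((1, pa), (0, 1 - pa)):
            if qa == 0:
                continue
            for mb, qb in ((1, pb), (0, 1 - pb)):
                if qb == 0:
                    continue
                na = (ma, mb, sa[1], sa[2], sa[4] | (mb == 0))
                nb = (mb, ma, sb[1], sb[2], sb[4] | (ma == 0))
                nxt = (na, nb)
                if nxt not in index:
                    index[nxt] = len(index)
                    trans.append([])
                    frontier.append(nxt)
                trans[pos].append((index[nxt], qa * qb))
        pos += 1

    n = len(frontier)
    lut = params.lookup()
    pay_a = np.array([lut[2 * sa[0] + sb[0]] for sa, sb in frontier])
    pay_b = np.array([lut[2 * sb[0] + sa[0]] for sa, sb in frontier])

    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from((i, j) for i in range(n) for j, _ in trans[i])
    sccs = list(nx.strongly_connected_components(g))
    comp_of = {}
    for ci, comp in enumerate(sccs):
        for v in comp:
            comp_of[v] = ci
    recurrent = []
    for ci, comp in enumerate(sccs):
        if all(comp_of[j] == ci for v in comp for j, _ in trans[v]):
            recurrent.append(ci)

    p_mat = np.zeros((n, n))
    for i in range(n):
        for j, q in trans[i]:
            p_mat[i, j] += q

    # stationary payoff of each recurrent class
    class_pay = {}
    for ci in recurrent:
        idx = sorted(sccs[ci])
        sub = p_mat[np.ix_(idx, idx)]
        k = len(idx)
        aa = np.vstack([sub.T - np.eye(k), np.ones(k)])
        bb = np.zeros(k + 1)
        bb[-1] = 1.0
        pi, *_ = np.linalg.lstsq(aa, bb, rcond=None)
        pi = np.clip(pi, 0.0, None)
        pi /= pi.sum()
        class_pay[ci] = (float(pi @ pay_a[idx]), float(pi @ pay_b[idx]))

    # absorption probabilities from the initial distribution
    state_class = np.full(n, -1)
    for ci in recurrent:
        for v in sccs[ci]:
            state_class[v] = ci
    transient = np.where(state_class < 0)[0]
    absorb = {}  # class -> probability vector over all states
    for ci in recurrent:
        h = np.zeros(n)
        h[state_class == ci] = 1.0
        if transient.size:
            q = p_mat[np.ix_(transient, transient)]
            r = p_mat[transient] @ h
            ht = np.linalg.solve(np.eye(transient.size) - q, r)
            h[transient] = ht
        absorb[ci] = h

    ea = eb = 0.0
    for st, w in init:
        i = index[st]
        for ci in recurrent:
            pa_c, pb_c = class_pay[ci]
            ea += w * absorb[ci][i] * pa_c
            eb += w * absorb[ci][i] * pb_c
    return ea, eb


# ---------------------------------------------------------------------------
# HARD_MAJO vs deterministic opponents: trajectory cycle detection
# ---------------------------------------------------------------------------


def _full_side_state(strategy, own, window, grim, d):
    # d = opponent cooperations - defections; only HARD_MAJO consults it
    if strategy is StrategyId.HARD_MAJO:
        return (own, window, int(d <= 0))
    if strategy is StrategyId.GRIM:
        return (own, window, grim)
    return (own, window)


def _det_next(strategy, own, window, grim, d):
    if strategy is StrategyId.HARD_MAJO:
        return 0 if d <= 0 else 1
    if strategy is StrategyId.GRIM:
        return 0 if grim else 1
    st = (own, window[0], window[1], window[2], grim)
    p = _side_prob(strategy, st)
    assert p in (0.0, 1.0)
    return int(p)


def _trajectory_limit_payoffs(
    a: StrategyId, b: StrategyId, params: PayoffParams, cap: int = 200_000
) -> tuple[float, float]:
    """Exact limit-average payoffs of a deterministic pair by playing from
    the defined first moves until the joint state provably repeats.

    With HARD_MAJO involved the joint state carries the unbounded counter
    difference d; a repeat of the reduced state (d replaced by its decision
    sign) counts as a cycle when d itself returned, or when d drifted
    monotonically while its sign stayed fixed over the whole block, which
    pins every future block to the same moves.
    """
    lut = params.lookup()
    ma = 1 if first_move_prob(a) == 1.0 else 0
    mb = 1 if first_move_prob(b) == 1.0 else 0
    own_a, own_b = ma, mb
    win_a, win_b = (mb, 1, 1), (ma, 1, 1)
    grim_a, grim_b = int(mb == 0), int(ma == 0)
    d_a, d_b = (1 if mb else -1), (1 if ma else -1)

    seen: dict = {}
    hist: list[tuple[float, float, int, int]] = []  # payoff_a, payoff_b, d_a, d_b
    for t in range(cap):
        key = (
            _full_side_state(a, own_a, win_a, grim_a, d_a),
            _full_side_state(b, own_b, win_b, grim_b, d_b),
        )
        if key in seen:
            for t1 in seen[key]:
                da1, db1 = hist[t1][2], hist[t1][3]
                delta_a, delta_b = d_a - da1, d_b - db1
                block = hist[t1:t]
                ok = True
                for strat, dlt, i in ((a, delta_a, 2), (b, delta_b, 3)):
                    if strat is not StrategyId.HARD_MAJO or dlt == 0:
                        continue
                    ds = [row[i] for row in block]
                    if dlt > 0 and min(ds) <= 0:
                        ok = False
                    if dlt < 0 and max(ds) > 0:
                        ok = False
                if ok:
                    pa = sum(r[0] for r in block) / len(block)
                    pb = sum(r[1] for r in block) / len(block)
                    return pa, pb
            seen[key].append(t)
        else:
            seen[key] = [t]

        na = _det_next(a, own_a, win_a, grim_a, d_a)
        nb = _det_next(b, own_b, win_b, grim_b, d_b)
        hist.append((float(lut[2 * na + nb]), float(lut[2 * nb + na]), d_a, d_b))
        win_a = (nb,) + win_a[:2]
        win_b = (na,) + win_b[:2]
        grim_a |= nb == 0
        grim_b |= na == 0
        d_a += 1 if nb else -1
        d_b += 1 if na else -1
        own_a, own_b = na, nb
        # record the state AFTER this round for the next key; but payoffs are
        # aligned so block [t1, t) averages the moves made from those states
    raise RuntimeError(f"no provable cycle for {a} vs {b} within {cap} rounds")


# ---------------------------------------------------------------------------
# Monte Carlo fallback (HARD_MAJO vs stochastic opponents)
# ---------------------------------------------------------------------------


def _simulate_pair(
    a: StrategyId,
    b: StrategyId,
    params: PayoffParams,
    rng: np.random.Generator,
    chains: int = 128,
    rounds: int = 8192,
    burn: int = 1024,
) -> tuple[float, float, float, float]:
    """Batched simulation of ``chains`` independent pair games; returns
    (mean_a, se_a, mean_b, se_b) of the post-burn-in per-round payoffs."""
    lut = params.lookup()
    sa = StateArrays(chains)
    sb = StateArrays(chains)
    tot_a = np.zeros(chains)
    tot_b = np.zeros(chains)
    for t in range(rounds):
        if t == 0:
            pa = np.full(chains, first_move_prob(a))
            pb = np.full(chains, first_move_prob(b))
        else:
            pa = cooperation_probs(a, sa)
            pb = cooperation_probs(b, sb)
        ma = (rng.random(chains) < pa).astype(np.int8)
        mb = (rng.random(chains) < pb).astype(np.int8)
        if t >= burn:
            tot_a += lut[2 * ma + mb]
            tot_b += lut[2 * mb + ma]
        sa.record(ma, mb)
        sb.record(mb, ma)
    span = rounds - burn
    mean_a = tot_a / span
    mean_b = tot_b / span
    se_a = float(mean_a.std(ddof=1) / np.sqrt(chains))
    se_b = float(mean_b.std(ddof=1) / np.sqrt(chains))
    return float(mean_a.mean()), se_a, float(mean_b.mean()), se_b


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


@lru_cache(maxsize=512)
def _pair_expectations(
    a: StrategyId, b: StrategyId, params: PayoffParams, sim_seed: int
) -> tuple[PayoffExpectation, PayoffExpectation]:
    va = memory_one_vector(a)
    vb = memory_one_vector(b)
    if va is not None and vb is not None:
        denom = _press_dyson_det(va, vb, np.ones(4))
        if abs(denom) > ERGODIC_TOL:
            ea = _press_dyson_det(va, vb, params.vector) / denom
            fb = params.vector[[0, 2, 1, 3]]  # B's payoffs in A's state order
            eb = _press_dyson_det(va, vb, fb) / denom
            return (
                PayoffExpectation(a, b, ea, "determinant"),
                PayoffExpectation(b, a, eb, "determinant"),
            )
    hm = StrategyId.HARD_MAJO
    if a is not hm and b is not hm:
        ea, eb = _chain_limit_payoffs(a, b, params)
        return (
            PayoffExpectation(a, b, ea, "cycle"),
            PayoffExpectation(b, a, eb, "cycle"),
        )
    if a in DETERMINISTIC and b in DETERMINISTIC:
        ea, eb = _trajectory_limit_payoffs(a, b, params)
        return (
            PayoffExpectation(a, b, ea, "cycle"),
            PayoffExpectation(b, a, eb, "cycle"),
        )
    rng = np.random.default_rng(sim_seed)
    ea, se_a, eb, se_b = _simulate_pair(a, b, params, rng)
    return (
        PayoffExpectation(a, b, ea, "simulated", se_a),
        PayoffExpectation(b, a, eb, "simulated", se_b),
    )


def expected_payoff(
    a: StrategyId,
    b: StrategyId,
    params: PayoffParams | None = None,
    sim_seed: int = 0,
) -> PayoffExpectation:
    """Long-run expected per-round payoff E(a, b) of ``a`` against ``b``."""
    if params is None:
        params = PayoffParams()
    return _pair_expectations(a, b, params, sim_seed)[0]


def delta(
    a: StrategyId,
    b: StrategyId,
    params: PayoffParams | None = None,
    sim_seed: int = 0,
) -> float:
    """The invasion statistic delta(a, b) = E(a, a) - E(b, a): how much a
    resident ``a`` earns among its own kind beyond what an invading ``b``
    earns against ``a``."""
    return (
        expected_payoff(a, a, params, sim_seed).value
        - expected_payoff(b, a, params, sim_seed).value
    )


def payoff_table(
    params: PayoffParams | None = None, sim_seed: int = 0, as_frame: bool = True
):
    """All 196 ordered-pair expectations E(row, column).

    Returns a pandas DataFrame of values (``as_frame=True``) or a dict
    keyed by ordered pair with full :class:`PayoffExpectation` records.
    """
    if params is None:
        params = PayoffParams()
    records: dict[tuple[StrategyId, StrategyId], PayoffExpectation] = {}
    ids = list(StrategyId)
    for i, a in enumerate(ids):
        for b in ids[i:]:
            ea, eb = _pair_expectations(a, b, params, sim_seed)
            records[(a, b)] = ea
            records[(b, a)] = eb
    if not as_frame:
        return records
    data = [[records[(a, b)].value for b in ids] for a in ids]
    tokens = [s.token for s in ids]
    return pd.DataFrame(data, index=tokens, columns=tokens)
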