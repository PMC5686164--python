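# ipdnet

Iterated prisoner's dilemma tournaments on social networks.

`ipdnet` is a simulator for studying how *social capital* — a player's
position in a network — interacts with *strategy quality* in the evolution
of cooperation. It implements:

* **14 classic strategies** (AC, AD, Random, TFT, GTFT, WSLS, extortionate
  and generous zero-determinant strategies ZDe/ZDg, Hard Joss, TF2T, Grim,
  Hard TFT, Hard Majority, Hard TF2T) as policies over a per-opponent game
  history.
* **Exact expected-payoff algebra.** For two memory-one strategies
  **p** = (p_CC, p_CD, p_DC, p_DD) and **s**, the joint outcome follows a
  4-state Markov chain; when that chain is ergodic the stationary payoff is
  the determinant ratio E = D(p, s, S_x) / D(p, s, 1) with
  S_x = (R, S, T, P). Non-ergodic and longer-memory pairs are resolved by
  exact recurrent-class / cycle analysis, and the Hard-Majority pairs that
  have no finite state space by batched simulation.
* **A round-robin tournament** (10,000 rounds × 100 repeats per pair) that
  labels each decided pair's loser *weak* and winner *strong*.
* **The divide-and-conquer network game.** Every edge of a Watts–Strogatz
  or Barabási–Albert network hosts an independent iterated game; a node
  holds one strategy but picks a per-neighbor move. After each epoch of
  R = 200 rounds, fitness is the accumulated payoff
  φ_i = Σ_{j∈N_i} Σ_r P_ijr or the degree average ψ_i = φ_i / k_i, and
  every node copies the strategy of the fittest member of its closed
  neighborhood (best-takes-over). A fraction α of the weak half of the
  population can be forced onto the highest-degree nodes
  (ε = ⌊α N/2⌋), which is the experiment's central dial.

Payoffs default to (R, S, T, P) = (3, 0, 5, 1).

## Worked example

```python
import numpy as np
from ipdnet import (StrategyId as S, payoff_table, delta,
                    generate_preset, assign, DncEngine, EpochConfig)

df = payoff_table()
print(df.loc[["tft", "zde", "random"], ["tft", "zde", "random"]].round(3))
#          tft    zde  random
# tft     3.00  1.000   2.250
# zde     1.00  1.000   2.562
# random  2.25  1.521   2.250

print(delta(S.TFT, S.ZDE), delta(S.ZDE, S.TFT))   # 2.0 0.0

ss = np.random.SeedSequence(1)
net_rng, a_rng, g_rng = (np.random.default_rng(c) for c in ss.spawn(3))
net = generate_preset("basn1", net_rng)            # N=1024 scale-free, 3066 edges
a = assign(net, S.TFT, S.ZDE, alpha=0.0, rng=a_rng)
res = DncEngine(net, a, EpochConfig(measure="psi"), rng=g_rng).run()
print(res.f_w)                                     # 0.9463
```

Reading: head-to-head TFT earns 1 per round against the extortioner ZDe
(they descend into mutual defection), so ZDe wins the pairwise match and
TFT is the *weak* strategy. But δ(TFT, ZDe) = E(TFT,TFT) − E(ZDe,TFT) = 2
is far larger than δ(ZDe, TFT) = 0: a TFT cluster supports itself while
ZDe clusters starve. On the network the weak TFT therefore takes over
~94% of the population under average-payoff fitness.

The same machinery is scriptable from the shell:

```sh
ipdnet expected --a gtft --b ad        # E(gtft, ad) = 0.666667 [determinant]
ipdnet table --out table.csv
ipdnet roundrobin --rounds 10000 --repeats 100 --seed 1 --out scoreboard.csv
ipdnet dnc run --network basn1 --weak tft --strong zde --fitness psi \
    --alpha 0.0 --seed 1 --out run.csv
ipdnet dnc sweep --config sweep.yaml --seed 1 --out results.csv
```

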